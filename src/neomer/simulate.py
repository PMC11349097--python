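"""Synthetic data with known ground truth for every pipeline stage.

Generators cover the four kinds of raw input the pipeline consumes:

* module count profiles, drawn by planting multiplicative enrichment of
  chosen (module A, module B) sequence pairs into a Dirichlet baseline over
  the full library and sampling multinomial reads;
* barcoded, scaffold-conformant sequencing reads realising those counts,
  with per-base substitution error;
* sigmoidal qPCR fluorescence traces with known efficiency and crossing
  cycle;
* labelled two-class cohorts with configurable effect sizes on the eight
  RTp features plus age and sex.

Every generator is a pure function of its configuration and seed, and
returns the ground truth alongside the data so recovery tests never infer
truth from the generated files.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .counting import FrequencyVector, ModuleCountTable
from .enrichment import SampleLibraryProfile
from .qpcr import AmplificationCurve
from .modeling import FeatureTable
from .scaffold import NeomerScaffold, decode_kmer, make_scaffold

RTP_FEATURES = [
    "Rvs HAM2753", "Rvs HAM6700", "Rvs HAM6968", "Rvs HAM8505",
    "Rvs c-LAM1", "Rvs c-LAM168", "Rvs c-LAM262", "Rvs c-LAM2709",
]


@dataclass
class PlantedPair:
    iA: int
    iB: int
    enrichment_factor: float
    group: str  # "high" or "low"


@dataclass
class SimulationConfig:
    """Study conditions for the selection-stage simulation.

    Defaults mirror the selection design: ten high-amyloid and ten
    low-amyloid samples, a common baseline library shared by all samples
    with mild sample-to-sample heterogeneity, and a handful of sequence
    pairs multiplicatively enriched in one group.
    """

    seed: int = 0
    k: int = 4
    n_high: int = 10
    n_low: int = 10
    depth: int = 1_000_000
    planted: tuple[PlantedPair, ...] = ()
    base_concentration: float = 5.0
    sample_heterogeneity_cv: float = 0.05
    seq_error_rate: float = 0.0


@dataclass
class GroundTruth:
    planted: list[dict]
    parameters: dict

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def default_planted(k: int, n_pairs: int = 5, factor: float = 5.0,
                    group: str = "high", seed: int = 0) -> tuple[PlantedPair, ...]:
    """A planted "motif family": one module-A key with ``n_pairs`` module-B keys.

    The screening statistic sees each sample only through the outer product
    of its module marginals, so a planted set is identifiable exactly when
    it is closed under the product of its module-A and module-B key sets.
    A family sharing one module-A motif (as selection acting on a structural
    motif would produce) is the smallest such set; arbitrary pair sets are
    accepted by :func:`simulate_profiles` but their cross pairs become
    equally enriched and are recorded as such in the ground truth.
    """
    rng = np.random.default_rng(seed)
    m = 4**k
    iA = int(rng.integers(m))
    iBs = rng.choice(m, size=n_pairs, replace=False)
    return tuple(PlantedPair(iA, int(b), factor, group) for b in iBs)


def _marginal_boosts(
    planted: Sequence[PlantedPair], group: str, m: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-key multiplicative boosts on the module marginals for one group.

    Each planted pair contributes sqrt(factor) to its module-A key and
    sqrt(factor) to its module-B key (max across pairs sharing a key), so
    the pair's reconstructed frequency gains the full enrichment factor.
    """
    rboost = np.ones(m)
    cboost = np.ones(m)
    for p in planted:
        if p.group == group:
            s = math.sqrt(p.enrichment_factor)
            rboost[p.iA] = max(rboost[p.iA], s)
            cboost[p.iB] = max(cboost[p.iB], s)
    return rboost, cboost


def simulate_profiles(
    config: SimulationConfig,
    analytic: bool = False,
) -> tuple[list[SampleLibraryProfile], list[tuple[ModuleCountTable, ModuleCountTable]], GroundTruth]:
    """Module-count profiles with planted full-library enrichment.

    For each sample a full-library frequency vector over 4^(2k) sequences
    is drawn around a shared Dirichlet baseline, planted pairs are
    multiplied by their enrichment factor when the sample belongs to the
    planted group, reads are drawn multinomially at the configured depth,
    and the read vector is marginalised into module-A and module-B counts.
    With ``analytic=True`` the multinomial step is skipped and module
    frequencies are the exact marginals (the infinite-depth limit).

    For k > 5 the full-library vector (4^(2k) entries) is too large to
    materialise; the simulation then works on module marginals directly
    with a rank-one update per planted pair — an approximation noted in
    the ground truth.
    """
    rng = np.random.default_rng(config.seed)
    m = 4**config.k
    groups = ["high"] * config.n_high + ["low"] * config.n_low
    sample_ids = [f"{g}_{i:02d}" for i, g in enumerate(groups)]

    for p in config.planted:
        if not (0 <= p.iA < m and 0 <= p.iB < m):
            raise ValueError(f"planted pair ({p.iA},{p.iB}) out of range for k={config.k}")

    profiles: list[SampleLibraryProfile] = []
    tables: list[tuple[ModuleCountTable, ModuleCountTable]] = []
    full_resolution = config.k <= 5

    if full_resolution:
        baseline = rng.dirichlet(np.full(m * m, config.base_concentration))
    else:
        baseA = rng.dirichlet(np.full(m, config.base_concentration))
        baseB = rng.dirichlet(np.full(m, config.base_concentration))

    for sid, group in zip(sample_ids, groups):
        if full_resolution:
            # per-sample heterogeneity around the shared baseline
            shape = 1.0 / config.sample_heterogeneity_cv**2
            f = baseline * rng.gamma(shape, 1.0 / shape, m * m)
            # rank-one enrichment: selection acting on module motifs pulls
            # every sequence carrying them, so planted signal reaches the
            # module marginals (a single-cell boost would not)
            rboost, cboost = _marginal_boosts(config.planted, group, m)
            f = (f.reshape(m, m) * np.outer(rboost, cboost)).ravel()
            f = f / f.sum()
            if analytic:
                F = f.reshape(m, m)
                cA = F.sum(axis=1)
                cB = F.sum(axis=0)
                fa = FrequencyVector(sid, "A", cA)
                fb = FrequencyVector(sid, "B", cB)
                profiles.append(SampleLibraryProfile(sid, group, fa, fb))
                continue
            draws = rng.multinomial(config.depth, f).reshape(m, m)
            cA = draws.sum(axis=1)
            cB = draws.sum(axis=0)
        else:
            shape = 1.0 / config.sample_heterogeneity_cv**2
            fa_ = baseA * rng.gamma(shape, 1.0 / shape, m)
            fb_ = baseB * rng.gamma(shape, 1.0 / shape, m)
            fa_, fb_ = fa_ / fa_.sum(), fb_ / fb_.sum()
            rboost, cboost = _marginal_boosts(config.planted, group, m)
            fa_, fb_ = fa_ * rboost, fb_ * cboost
            fa_, fb_ = fa_ / fa_.sum(), fb_ / fb_.sum()
            if analytic:
                profiles.append(SampleLibraryProfile(
                    sid, group,
                    FrequencyVector(sid, "A", fa_),
                    FrequencyVector(sid, "B", fb_)))
                continue
            cA = rng.multinomial(config.depth, fa_)
            cB = rng.multinomial(config.depth, fb_)

        ta = ModuleCountTable(sid, "A", config.k, cA, int(cA.sum()), int(cA.sum()))
        tb = ModuleCountTable(sid, "B", config.k, cB, int(cB.sum()), int(cB.sum()))
        tables.append((ta, tb))
        fa = FrequencyVector(sid, "A", cA / cA.sum())
        fb = FrequencyVector(sid, "B", cB / cB.sum())
        profiles.append(SampleLibraryProfile(sid, group, fa, fb))

    enriched_grid = {}
    for group in ("high", "low"):
        rb, cb = _marginal_boosts(config.planted, group, m)
        ia, ib = np.nonzero(rb > 1)[0], np.nonzero(cb > 1)[0]
        if len(ia):
            enriched_grid[group] = {"iA": ia.tolist(), "iB": ib.tolist()}
    truth = GroundTruth(
        planted=[asdict(p) for p in config.planted],
        parameters={
            "enriched_grid": enriched_grid,
            "seed": config.seed, "k": config.k, "depth": config.depth,
            "n_high": config.n_high, "n_low": config.n_low,
            "base_concentration": config.base_concentration,
            "sample_heterogeneity_cv": config.sample_heterogeneity_cv,
            "full_resolution": full_resolution, "analytic": analytic,
        },
    )
    return profiles, tables, truth


def simulate_reads(
    tables: Sequence[tuple[ModuleCountTable, ModuleCountTable]],
    scaffold: NeomerScaffold,
    barcodes: dict[str, str],
    seq_error_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, list[str]]:
    """FASTQ text realising the module count tables, one record list per module.

    Each counted key yields that many reads: sample barcode followed by the
    module sub-template with the key's nucleotides at the random positions,
    then i.i.d. substitution errors at ``seq_error_rate`` per base.
    Returns {"A": fastq_lines, "B": fastq_lines}.
    """
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    out: dict[str, list[str]] = {"A": [], "B": []}
    for ta, tb in tables:
        for module, table in (("A", ta), ("B", tb)):
            template = scaffold.module_template(module)
            barcode = barcodes[table.sample_id]
            rand_pos = [i for i, c in enumerate(template) if c == "N"]
            n_read = 0
            for idx in np.nonzero(table.counts)[0]:
                key = decode_kmer(int(idx), table.k)
                body = list(template)
                for pos, nt in zip(rand_pos, key):
                    body[pos] = nt
                clean = barcode + "".join(body)
                for _ in range(int(table.counts[idx])):
                    seq = np.frombuffer(clean.encode(), dtype=np.uint8).copy()
                    if seq_error_rate > 0:
                        hit = rng.random(len(seq)) < seq_error_rate
                        if hit.any():
                            shift = rng.integers(1, 4, size=int(hit.sum()))
                            cur = np.searchsorted(bases, seq[hit])
                            seq[hit] = bases[(cur + shift) % 4]
                    n_read += 1
                    rid = f"@{table.sample_id}:{module}:{n_read}"
                    s = seq.tobytes().decode()
                    out[module] += [rid, s, "+", "I" * len(s)]
    return out


@dataclass
class QpcrTruth:
    well_id: str
    sample_id: str
    aptamarker: str
    run_id: str
    E: float
    Cq: float


def simulate_qpcr(
    truths: Sequence[QpcrTruth],
    noise_sigma: float = 0.01,
    n_cycles: int = 40,
    baseline_level: float = 100.0,
    fmax: float = 5_000_000.0,
    seed: int = 0,
) -> list[AmplificationCurve]:
    """Sigmoidal amplification traces with known (E*, Cq*) per well.

    F[c] = B (1 + eta_c) + F0 E^c / (1 + F0 E^c / Fmax) with multiplicative
    Gaussian noise eta on the whole trace; F0 is solved so the noiseless
    trace crosses six times the baseline exactly at Cq*.
    """
    rng = np.random.default_rng(seed)
    curves = []
    B = baseline_level
    for t in truths:
        if not 1.0 < t.E <= 2.2:
            raise ValueError("true efficiency must be in (1, 2.2]")
        if not 6.0 < t.Cq < n_cycles - 6:
            raise ValueError("true Cq must sit well inside the cycle range")
        # 6x-baseline crossing at Cq*: signal there must equal 5B after saturation
        f0 = 5.0 * B / ((1.0 - 5.0 * B / fmax) * t.E**t.Cq)
        c = np.arange(1, n_cycles + 1, dtype=float)
        sig = f0 * t.E**c
        sig = sig / (1.0 + sig / fmax)
        F = (B + sig) * (1.0 + noise_sigma * rng.standard_normal(n_cycles))
        curves.append(
            AmplificationCurve(t.well_id, t.sample_id, t.aptamarker, t.run_id,
                               np.arange(1, n_cycles + 1), F)
        )
    return curves


def flat_curve(well_id="w0", sample_id="s0", aptamarker="a0", run_id="r0",
               n_cycles: int = 40, baseline_level: float = 100.0,
               noise_sigma: float = 0.0, seed: int = 0) -> AmplificationCurve:
    """A no-amplification trace (template absent)."""
    rng = np.random.default_rng(seed)
    F = baseline_level * (1.0 + noise_sigma * rng.standard_normal(n_cycles))
    return AmplificationCurve(well_id, sample_id, aptamarker, run_id,
                              np.arange(1, n_cycles + 1), F)


@dataclass
class CohortConfig:
    """Two-class cohort emulating the screening study's structure.

    390 samples with a stratified 291/99 train/test split; features are the
    eight RTp proportions (Dirichlet on the simplex, class-dependent
    concentration shifts), age (older in the high-amyloid class), sex
    (null) and clinical class (CN/MCI, mildly associated). ``rtp_effects``
    are per-feature log-fold shifts of the Dirichlet concentration in the
    high-amyloid class.
    """

    seed: int = 0
    n_samples: int = 390
    train_fraction: float = 291 / 390
    prevalence: float = 0.5
    rtp_effects: tuple[float, ...] = (0.0,) * 8
    rtp_concentration: float = 60.0
    age_effect_years: float = 4.0
    age_mean: float = 73.0
    age_sd: float = 6.5
    mci_prob: tuple[float, float] = (0.20, 0.35)  # (low class, high class)


STRONG_RTP_EFFECTS = (0.8, 0.6, 0.5, 0.4, -0.5, -0.6, -0.4, -0.3)


def strong_cohort_config(seed: int = 0) -> CohortConfig:
    """Preset with strongly informative RTp features (clearly separable classes)."""
    return CohortConfig(seed=seed, rtp_effects=STRONG_RTP_EFFECTS)


def null_cohort_config(seed: int = 0) -> CohortConfig:
    """Preset where no feature carries signal (age and clinical class null too)."""
    return CohortConfig(seed=seed, rtp_effects=(0.0,) * 8,
                        age_effect_years=0.0, mci_prob=(0.25, 0.25))


def simulate_cohort(config: CohortConfig) -> tuple[FeatureTable, GroundTruth]:
    """Labelled feature table with a recorded stratified train/test split."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    labels = (rng.random(n) < config.prevalence).astype(int)
    base_alpha = np.full(8, config.rtp_concentration / 8)
    effects = np.asarray(config.rtp_effects, dtype=float)
    rtp = np.empty((n, 8))
    for i in range(n):
        alpha = base_alpha * np.exp(effects * labels[i])
        rtp[i] = rng.dirichlet(alpha)
    age = config.age_mean + config.age_effect_years * (labels - 0.5) \
        + config.age_sd * rng.standard_normal(n)
    sex = rng.integers(0, 2, size=n)
    p_mci = np.where(labels == 1, config.mci_prob[1], config.mci_prob[0])
    clin = (rng.random(n) < p_mci).astype(int)  # 1 = MCI, 0 = CN

    ids = [f"S{i:04d}" for i in range(n)]
    features = pd.DataFrame(rtp, columns=RTP_FEATURES, index=ids)
    features["Age"] = age
    features["Sex"] = sex
    features["Clinical Classification"] = clin
    labels_s = pd.Series(labels, index=ids, name="label")

    # stratified split at train_fraction
    split = pd.Series("test", index=ids, name="split")
    for cls in (0, 1):
        members = np.array([i for i, l in zip(ids, labels) if l == cls])
        perm = rng.permutation(len(members))
        n_train = int(round(config.train_fraction * len(members)))
        split.loc[members[perm[:n_train]]] = "train"

    table = FeatureTable(features, labels_s, split)
    truth = GroundTruth(
        planted=[],
        parameters={
            "seed": config.seed, "n_samples": n,
            "rtp_effects": list(config.rtp_effects),
            "age_effect_years": config.age_effect_years,
            "mci_prob": list(config.mci_prob),
            "train_fraction": config.train_fraction,
            "n_train": int((split == "train").sum()),
            "n_test": int((split == "test").sum()),
        },
    )
    return table, truth
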