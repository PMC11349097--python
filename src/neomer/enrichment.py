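"""Differential-enrichment screening over the outer-product library.

The frequency of each full-library sequence (iA, iB) in a sample is
estimated as the product of its module-A and module-B marginal frequencies,
freqA[iA] * freqB[iB] — a rank-one reconstruction of the 4^k x 4^k
frequency matrix. For a two-group contrast the screening statistic per
sequence is

    z = (mean_num - mean_den) / ((sd_num + sd_den) / 2)

where means and sample standard deviations (ddof=1) are taken over the
reconstructed per-sample frequencies within the numerator and denominator
groups. The full matrix is never materialised per sample: the scan walks
row blocks and keeps a running top-K, yielding results identical to the
exhaustive computation.

Candidate "Aptamarkers" are then chosen from the top-K by a separation
margin: the minimum reconstructed frequency among numerator-group samples
minus the maximum among denominator-group samples, positive exactly when
the two groups are completely separated.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .counting import FrequencyVector
from .scaffold import NeomerScaffold, decode_kmer

HIGH_VS_LOW = "high_vs_low"
LOW_VS_HIGH = "low_vs_high"


@dataclass
class SampleLibraryProfile:
    """One sample's module-A and module-B frequency vectors plus group label."""

    sample_id: str
    group: str  # "high" or "low"
    freqA: FrequencyVector
    freqB: FrequencyVector

    def __post_init__(self) -> None:
        if len(self.freqA.freqs) != len(self.freqB.freqs):
            raise ValueError("module A and B vectors must share k")

    @property
    def m(self) -> int:
        return len(self.freqA.freqs)


@dataclass
class ZScoreHit:
    iA: int
    iB: int
    mean_num: float
    mean_den: float
    sd_num: float
    sd_den: float
    z: float
    fold: float
    separation: float = math.nan

    def key_seqs(self, k: int) -> tuple[str, str]:
        return decode_kmer(self.iA, k), decode_kmer(self.iB, k)


@dataclass
class ContrastResult:
    direction: str
    top_hits: list[ZScoreHit]
    selected: list[ZScoreHit]
    parameters: dict
    n_zero_sd: int = 0

    def to_frame(self, scaffold: NeomerScaffold | None = None) -> pd.DataFrame:
        k = self.parameters["k"]
        rows = []
        for h in self.top_hits:
            sa, sb = h.key_seqs(k)
            row = {
                "iA_seq": sa,
                "iB_seq": sb,
                "z": h.z,
                "fold": h.fold,
                "separation": h.separation,
                "mean_num": h.mean_num,
                "mean_den": h.mean_den,
                "sd_num": h.sd_num,
                "sd_den": h.sd_den,
            }
            if scaffold is not None and scaffold.n_random == 2 * k:
                row["aptamer_seq"] = scaffold.fill(sa + sb)
            rows.append(row)
        return pd.DataFrame(rows)


def full_frequency(profile: SampleLibraryProfile, iA: int, iB: int) -> float:
    """Outer-product estimate of one full-library sequence frequency."""
    return float(profile.freqA.freqs[iA] * profile.freqB.freqs[iB])


def _group_matrices(
    profiles: Sequence[SampleLibraryProfile], direction: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stack module frequencies into (samples x m) arrays per contrast side."""
    if direction == HIGH_VS_LOW:
        num_label, den_label = "high", "low"
    elif direction == LOW_VS_HIGH:
        num_label, den_label = "low", "high"
    else:
        raise ValueError(f"unknown direction {direction!r}")
    num = [p for p in profiles if p.group == num_label]
    den = [p for p in profiles if p.group == den_label]
    if len(num) < 2 or len(den) < 2:
        raise ValueError("need at least 2 samples per group for a standard deviation")
    for p in profiles:
        if not (p.freqA.freqs.any() and p.freqB.freqs.any()):
            raise ValueError(f"sample {p.sample_id!r} has an all-zero module profile")
    FA_n = np.stack([p.freqA.freqs for p in num])
    FB_n = np.stack([p.freqB.freqs for p in num])
    FA_d = np.stack([p.freqA.freqs for p in den])
    FB_d = np.stack([p.freqB.freqs for p in den])
    return FA_n, FB_n, FA_d, FB_d


def _block_stats(FA: np.ndarray, FB: np.ndarray, rows: slice):
    """Group mean and ddof-1 SD of outer-product frequencies for a row block.

    Two passes over the samples: the first contracts the rank-one products
    into the block mean, the second accumulates centred squared deviations
    one sample at a time, so peak memory stays at O(block_rows x m) and the
    variance is free of the cancellation a raw sum-of-squares would incur.
    """
    n = FA.shape[0]
    A = FA[:, rows]
    mean = (A.T @ FB) / n
    ss = np.zeros_like(mean)
    for s in range(n):
        d = np.outer(A[s], FB[s]) - mean
        ss += d * d
    return mean, np.sqrt(ss / (n - 1))


def _lex_top_k(z, iA, iB, K):
    """Indices of the top-K by (z desc, iA asc, iB asc)."""
    order = np.lexsort((iB, iA, -z))
    return order[:K]


def contrast_zscores(
    profiles: Sequence[SampleLibraryProfile],
    direction: str = HIGH_VS_LOW,
    K: int = 10_000,
    block_rows: int = 256,
    fold_pseudocount: float | None = None,
    matched_totals: Sequence[int] | None = None,
) -> ContrastResult:
    """Blocked scan of all (iA, iB) sequences, returning the top-K by z score.

    Sequences whose two group SDs are both zero carry no variance
    information; they are excluded from ranking and counted in
    ``n_zero_sd``. The fold statistic (mean_num + eps) / (mean_den + eps)
    is reporting-only and never used for ranking; its pseudocount defaults
    to the reciprocal geometric mean of per-sample matched read totals when
    those are supplied, else 1e-9.
    """
    FA_n, FB_n, FA_d, FB_d = _group_matrices(profiles, direction)
    m = FA_n.shape[1]
    if fold_pseudocount is None:
        if matched_totals:
            fold_pseudocount = 1.0 / math.exp(
                np.mean([math.log(t) for t in matched_totals])
            )
        else:
            fold_pseudocount = 1e-9
    eps = fold_pseudocount

    best: dict[str, np.ndarray] | None = None
    n_zero_sd = 0
    for start in range(0, m, block_rows):
        rows = slice(start, min(start + block_rows, m))
        mean_n, sd_n = _block_stats(FA_n, FB_n, rows)
        mean_d, sd_d = _block_stats(FA_d, FB_d, rows)
        denom = (sd_n + sd_d) / 2.0
        valid = denom > 0
        n_zero_sd += int((~valid).sum())
        if not valid.any():
            continue
        r_idx, c_idx = np.nonzero(valid)
        z = (mean_n[valid] - mean_d[valid]) / denom[valid]
        cand = {
            "z": z,
            "iA": (r_idx + start).astype(np.int64),
            "iB": c_idx.astype(np.int64),
            "mean_num": mean_n[valid],
            "mean_den": mean_d[valid],
            "sd_num": sd_n[valid],
            "sd_den": sd_d[valid],
        }
        # prune the block to its own top-K before merging
        keep = _lex_top_k(cand["z"], cand["iA"], cand["iB"], K)
        cand = {k: v[keep] for k, v in cand.items()}
        if best is None:
            best = cand
        else:
            merged = {k: np.concatenate([best[k], cand[k]]) for k in best}
            keep = _lex_top_k(merged["z"], merged["iA"], merged["iB"], K)
            best = {k: v[keep] for k, v in merged.items()}
    if best is None:
        raise ValueError("no sequence had nonzero variance in either group")

    hits = [
        ZScoreHit(
            iA=int(best["iA"][i]),
            iB=int(best["iB"][i]),
            mean_num=float(best["mean_num"][i]),
            mean_den=float(best["mean_den"][i]),
            sd_num=float(best["sd_num"][i]),
            sd_den=float(best["sd_den"][i]),
            z=float(best["z"][i]),
            fold=float((best["mean_num"][i] + eps) / (best["mean_den"][i] + eps)),
        )
        for i in range(len(best["z"]))
    ]
    k = int(round(math.log(m, 4)))
    params = {
        "direction": direction,
        "K": K,
        "block_rows": block_rows,
        "sd_convention": "sample (ddof=1)",
        "fold_pseudocount": eps,
        "k": k,
        "tie_break": "z desc, iA asc, iB asc",
    }
    return ContrastResult(direction, hits, [], params, n_zero_sd)


def separation_score(
    hit: ZScoreHit, profiles: Sequence[SampleLibraryProfile], direction: str
) -> float:
    """Min-max margin between groups for one sequence.

    min over numerator-group samples of the reconstructed frequency minus
    max over denominator-group samples; positive iff every numerator sample
    lies above every denominator sample.
    """
    num_label = "high" if direction == HIGH_VS_LOW else "low"
    num = [full_frequency(p, hit.iA, hit.iB) for p in profiles if p.group == num_label]
    den = [full_frequency(p, hit.iA, hit.iB) for p in profiles if p.group != num_label]
    return min(num) - max(den)


def select_candidates(
    result: ContrastResult,
    profiles: Sequence[SampleLibraryProfile],
    n_select: int = 4,
) -> ContrastResult:
    """Pick the ``n_select`` top hits with the largest separation margin.

    Ties are broken by higher z, then ascending (iA, iB); deterministic.
    The result's hits are annotated with their separation in place.
    """
    if n_select > len(result.top_hits):
        raise ValueError("n_select exceeds the number of ranked hits")
    for h in result.top_hits:
        h.separation = separation_score(h, profiles, result.direction)
    ranked = sorted(
        result.top_hits, key=lambda h: (-h.separation, -h.z, h.iA, h.iB)
    )
    result.selected = ranked[:n_select]
    result.parameters["n_select"] = n_select
    result.parameters["separation_metric"] = "min(num) - max(den)"
    return result


def brute_force_contrast(
    profiles: Sequence[SampleLibraryProfile], direction: str = HIGH_VS_LOW
) -> list[ZScoreHit]:
    """Exhaustive per-sequence contrast, as an independent oracle.

    Materialises every (iA, iB) with plain-Python statistics; intended for
    k <= 4 only. Sequences with two zero SDs are omitted, mirroring the
    blocked scan's exclusion rule.
    """
    num_label = "high" if direction == HIGH_VS_LOW else "low"
    num = [p for p in profiles if p.group == num_label]
    den = [p for p in profiles if p.group != num_label]
    m = num[0].m
    hits = []
    for iA in range(m):
        for iB in range(m):
            xn = [float(p.freqA.freqs[iA]) * float(p.freqB.freqs[iB]) for p in num]
            xd = [float(p.freqA.freqs[iA]) * float(p.freqB.freqs[iB]) for p in den]
            sd_n = statistics.stdev(xn)
            sd_d = statistics.stdev(xd)
            if sd_n + sd_d == 0:
                continue
            mean_n = statistics.fmean(xn)
            mean_d = statistics.fmean(xd)
            z = (mean_n - mean_d) / ((sd_n + sd_d) / 2.0)
            hits.append(
                ZScoreHit(iA, iB, mean_n, mean_d, sd_n, sd_d, z,
                          fold=math.nan)
            )
    hits.sort(key=lambda h: (-h.z, h.iA, h.iB))
    return hits
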