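"""Quantification of Aptamarkers from raw qPCR fluorescence.

The analysis works from raw fluorescence-by-cycle traces, one per well:

1. baseline = mean fluorescence over cycles 1-5;
2. Cq = the fractional cycle at which fluorescence first reaches six times
   the baseline, interpolated linearly between the two flanking cycles;
3. amplification efficiency E = 10^slope of the best least-squares fit of
   log10(baseline-subtracted fluorescence) against cycle, over contiguous
   windows in the exponential region above Cq and before the plateau;
4. per-run normalisation: the run mean of Cq (and of E) is divided by a
   fixed reference value to give a factor; each well's value is divided by
   its run's factor;
5. duplicate wells are merged when the coefficient of variation of their
   normalised Cq is within threshold (percent);
6. relative template amount RT = (1/E)^Cq, and per-sample proportions
   RTp_i = RT_i / sum_j RT_j over the aptamarker panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_THRESHOLD_MULTIPLE = 6.0
DEFAULT_CV_THRESHOLD = 6.0
DEFAULT_REF_CQ = 20.0
DEFAULT_REF_E = 1.9


@dataclass
class AmplificationCurve:
    well_id: str
    sample_id: str
    aptamarker_name: str
    run_id: str
    cycles: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles, dtype=np.int64)
        self.fluorescence = np.asarray(self.fluorescence, dtype=np.float64)
        if self.cycles.shape != self.fluorescence.shape:
            raise ValueError("cycles and fluorescence must have equal length")
        if len(self.cycles) < 10:
            raise ValueError("need at least 10 cycles")
        if not np.all(np.isfinite(self.fluorescence)):
            raise ValueError("fluorescence must be finite")


@dataclass
class QuantResult:
    sample_id: str
    aptamarker_name: str
    run_id: str
    baseline: float = math.nan
    Cq: float = math.nan
    E: float = math.nan
    Cq_norm: float = math.nan
    E_norm: float = math.nan
    RT: float = math.nan
    qc_pass: bool = False
    qc_reason: str = ""
    fit_window: tuple[int, int] | None = None
    fit_r2: float = math.nan


@dataclass
class RunNormalization:
    run_id: str
    mean_Cq: float
    mean_E: float
    ref_Cq: float
    ref_E: float

    @property
    def factor_Cq(self) -> float:
        return self.mean_Cq / self.ref_Cq

    @property
    def factor_E(self) -> float:
        return self.mean_E / self.ref_E


@dataclass
class RtpProfile:
    sample_id: str
    rtp: dict[str, float]
    missing: tuple[str, ...] = ()


def baseline(curve: AmplificationCurve) -> float:
    """Mean fluorescence over the first five cycles."""
    return float(np.mean(curve.fluorescence[:5]))


def call_cq(
    curve: AmplificationCurve,
    threshold_multiple: float = DEFAULT_THRESHOLD_MULTIPLE,
) -> tuple[float, float, str]:
    """Fractional threshold-crossing cycle.

    Returns ``(Cq, baseline, qc_reason)``; Cq is NaN with a reason when the
    trace never reaches threshold_multiple x baseline, or reaches it within
    the baseline window itself (cycles 1-5), where the baseline estimate is
    meaningless.
    """
    base = baseline(curve)
    thresh = threshold_multiple * base
    F = curve.fluorescence
    cyc = curve.cycles
    head = F[:5]
    # amplification already under way inside the baseline window makes the
    # baseline estimate meaningless
    if head.min() > 0 and head.max() / head.min() >= threshold_multiple:
        return math.nan, base, "early crossing"
    above = np.nonzero(F >= thresh)[0]
    if len(above) == 0:
        return math.nan, base, "no crossing"
    c = int(above[0])
    if cyc[c] <= 5:
        return math.nan, base, "early crossing"
    if F[c] == thresh or c == 0:
        return float(cyc[c]), base, ""
    # two-point linear interpolation between the flanking cycles
    frac = (thresh - F[c - 1]) / (F[c] - F[c - 1])
    return float(cyc[c - 1] + frac * (cyc[c] - cyc[c - 1])), base, ""


def _plateau_end(Fp: np.ndarray, start: int, window_min: int) -> int:
    """Last cycle index (exclusive) usable for the log-linear fit.

    A preliminary efficiency is taken from the first ``window_min`` cycles
    above Cq; the window ends where the per-cycle gain falls below
    1 + 0.25 * (E_prelim - 1), i.e. where saturation has eaten three
    quarters of the exponential gain.
    """
    n = len(Fp)
    pre = Fp[start : start + window_min]
    if len(pre) < 2 or np.any(pre <= 0):
        return n
    slope = stats.linregress(np.arange(len(pre)), np.log10(pre)).slope
    e_prelim = 10**slope
    cutoff = 1.0 + 0.25 * (e_prelim - 1.0)
    for c in range(start, n - 1):
        if Fp[c] <= 0 or Fp[c + 1] / Fp[c] < cutoff:
            return c + 1
    return n


def estimate_efficiency(
    curve: AmplificationCurve,
    Cq: float,
    window_min: int = 4,
) -> tuple[float, dict]:
    """Per-cycle amplification factor from the log-linear region above Cq.

    Fits log10 of baseline-subtracted fluorescence against cycle over every
    contiguous window of length >= window_min that starts at or after
    ceil(Cq) and ends before the detected plateau; returns 10^slope of the
    window with the highest R^2 (ties: earliest, then longest window).
    E is NaN with a diagnostic reason if no all-positive window exists or
    the fitted value is implausible (outside (1, 3]).
    """
    base = baseline(curve)
    Fp = curve.fluorescence - base
    cyc = curve.cycles
    start = int(np.searchsorted(cyc, math.ceil(Cq)))
    end = _plateau_end(Fp, start, window_min)
    best: tuple[float, int, int] | None = None  # (r2, start, length)
    best_slope = math.nan
    for s in range(start, end - window_min + 1):
        if Fp[s] <= 0:
            continue
        for e in range(s + window_min, end + 1):
            seg = Fp[s:e]
            if np.any(seg <= 0):
                break
            fit = stats.linregress(cyc[s:e], np.log10(seg))
            r2 = fit.rvalue**2
            # prefer high r2, then early start, then long window
            if best is None or (r2, -s, e - s) > (best[0], best[1], best[2]):
                best = (r2, -s, e - s)
                best_slope = fit.slope
                best_win = (int(cyc[s]), int(cyc[e - 1]))
    if best is None:
        return math.nan, {"reason": "no exponential region"}
    E = 10**best_slope
    diag = {"window": best_win, "r2": best[0]}
    if not (1.0 < E <= 3.0):
        diag["reason"] = "implausible efficiency"
        return math.nan, diag
    return float(E), diag


def quantify_well(
    curve: AmplificationCurve,
    threshold_multiple: float = DEFAULT_THRESHOLD_MULTIPLE,
    window_min: int = 4,
) -> QuantResult:
    """Baseline, Cq and E for one well; qc_pass reflects every stage."""
    res = QuantResult(curve.sample_id, curve.aptamarker_name, curve.run_id)
    cq, base, reason = call_cq(curve, threshold_multiple)
    res.baseline = base
    if reason:
        res.qc_reason = reason
        return res
    res.Cq = cq
    E, diag = estimate_efficiency(curve, cq, window_min)
    if math.isnan(E):
        res.qc_reason = diag["reason"]
        return res
    res.E = E
    res.fit_window = diag["window"]
    res.fit_r2 = diag["r2"]
    res.qc_pass = True
    return res


def normalize_run(
    results: Sequence[QuantResult],
    ref_Cq: float = DEFAULT_REF_CQ,
    ref_E: float = DEFAULT_REF_E,
) -> tuple[RunNormalization, list[QuantResult]]:
    """Divide each well's Cq and E by its run's normalisation factor.

    The factor is the run mean over qc-passing wells divided by a fixed
    reference value, so runs whose raw values differ by a common
    multiplicative shift land on identical normalised values.
    """
    passing = [r for r in results if r.qc_pass]
    if not passing:
        raise ValueError("run has no qc-passing wells")
    run_id = passing[0].run_id
    norm = RunNormalization(
        run_id,
        mean_Cq=float(np.mean([r.Cq for r in passing])),
        mean_E=float(np.mean([r.E for r in passing])),
        ref_Cq=ref_Cq,
        ref_E=ref_E,
    )
    out = []
    for r in results:
        r2 = replace(r)
        if r.qc_pass:
            r2.Cq_norm = r.Cq / norm.factor_Cq
            r2.E_norm = r.E / norm.factor_E
        out.append(r2)
    return norm, out


def replicate_qc(
    replicates: Sequence[QuantResult],
    cv_threshold: float = DEFAULT_CV_THRESHOLD,
) -> QuantResult:
    """Merge duplicate wells if their normalised Cq values agree.

    CV% = 100 * sd(ddof=1) / mean over the replicate Cq_norm values; the
    pair passes when CV% <= cv_threshold, yielding replicate-averaged
    Cq_norm and E_norm and the derived RT = (1/E)^Cq. Any replicate that
    failed upstream QC fails the pair.
    """
    first = replicates[0]
    merged = QuantResult(first.sample_id, first.aptamarker_name, first.run_id)
    if any(not r.qc_pass for r in replicates):
        merged.qc_reason = "; ".join(
            r.qc_reason or "replicate failed" for r in replicates if not r.qc_pass
        )
        return merged
    cqs = np.array([r.Cq_norm for r in replicates])
    if np.any(np.isnan(cqs)):
        merged.qc_reason = "unnormalized replicate"
        return merged
    cv = 100.0 * float(np.std(cqs, ddof=1)) / float(np.mean(cqs))
    if cv > cv_threshold:
        merged.qc_reason = f"replicate CV {cv:.2f} > {cv_threshold}"
        return merged
    merged.Cq_norm = float(np.mean(cqs))
    merged.E_norm = float(np.mean([r.E_norm for r in replicates]))
    merged.Cq = float(np.mean([r.Cq for r in replicates]))
    merged.E = float(np.mean([r.E for r in replicates]))
    merged.RT = relative_template(merged.E_norm, merged.Cq_norm)
    merged.qc_pass = True
    return merged


def relative_template(E: float, Cq: float) -> float:
    """Relative amount of template, RT = (1/E)^Cq."""
    if not E > 1.0:
        raise ValueError("efficiency must exceed 1")
    return (1.0 / E) ** Cq


def rtp_profile(
    sample_id: str, rts: dict[str, float]
) -> RtpProfile:
    """Per-sample proportions of RT across the aptamarker panel.

    NaN entries are recorded as missing and excluded from the denominator;
    the returned proportions sum to 1 over the non-missing aptamarkers.
    """
    present = {k: v for k, v in rts.items() if not math.isnan(v)}
    if not present:
        raise ValueError(f"sample {sample_id!r}: no non-missing RT values")
    total = sum(present.values())
    rtp = {k: (present[k] / total if k in present else math.nan) for k in rts}
    missing = tuple(k for k in rts if k not in present)
    return RtpProfile(sample_id, rtp, missing)


def quantify_plate(
    curves: pd.DataFrame,
    threshold_multiple: float = DEFAULT_THRESHOLD_MULTIPLE,
    cv_threshold: float = DEFAULT_CV_THRESHOLD,
    ref_Cq: float = DEFAULT_REF_CQ,
    ref_E: float = DEFAULT_REF_E,
    window_min: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full qPCR pipeline from a long-format fluorescence table.

    ``curves`` needs columns run_id, well_id, sample_id, aptamarker, cycle,
    fluorescence. Returns (per-well results, per-run normalisation table,
    samples x aptamarkers RTp matrix). Samples with any missing aptamarker
    after replicate QC are dropped from the RTp matrix (strict
    complete-case policy).
    """
    required = {"run_id", "well_id", "sample_id", "aptamarker", "cycle", "fluorescence"}
    if not required <= set(curves.columns):
        raise ValueError(f"missing columns: {sorted(required - set(curves.columns))}")

    well_results: dict[str, list] = {}
    per_run: dict[str, list[tuple[str, QuantResult]]] = {}
    for (run, well, sample, apt), grp in curves.groupby(
        ["run_id", "well_id", "sample_id", "aptamarker"], sort=True
    ):
        grp = grp.sort_values("cycle")
        curve = AmplificationCurve(
            str(well), str(sample), str(apt), str(run),
            grp["cycle"].to_numpy(), grp["fluorescence"].to_numpy(),
        )
        res = quantify_well(curve, threshold_multiple, window_min)
        per_run.setdefault(str(run), []).append((str(well), res))

    norm_rows = []
    normalized: dict[tuple[str, str], list[QuantResult]] = {}
    well_rows = []
    for run, pairs in per_run.items():
        results = [r for _, r in pairs]
        try:
            norm, updated = normalize_run(results, ref_Cq, ref_E)
            norm_rows.append(
                {"run_id": run, "mean_Cq": norm.mean_Cq, "mean_E": norm.mean_E,
                 "factor_Cq": norm.factor_Cq, "factor_E": norm.factor_E}
            )
        except ValueError:
            updated = results
        for (well, _), r in zip(pairs, updated):
            well_rows.append(
                {"run_id": run, "well_id": well, "sample_id": r.sample_id,
                 "aptamarker": r.aptamarker_name, "baseline": r.baseline,
                 "Cq": r.Cq, "E": r.E, "Cq_norm": r.Cq_norm, "E_norm": r.E_norm,
                 "qc_pass": r.qc_pass, "qc_reason": r.qc_reason}
            )
            normalized.setdefault((r.sample_id, r.aptamarker_name), []).append(r)

    rtp_rows = {}
    for sample in sorted({s for s, _ in normalized}):
        rts = {}
        for (s, apt), reps in normalized.items():
            if s != sample:
                continue
            merged = replicate_qc(reps, cv_threshold)
            rts[apt] = merged.RT if merged.qc_pass else math.nan
        if any(math.isnan(v) for v in rts.values()):
            continue  # complete-case policy
        profile = rtp_profile(sample, rts)
        rtp_rows[sample] = profile.rtp

    rtp_df = pd.DataFrame.from_dict(rtp_rows, orient="index").sort_index()
    rtp_df.index.name = "sample_id"
    return pd.DataFrame(well_rows), pd.DataFrame(norm_rows), rtp_df
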