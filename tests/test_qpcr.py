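"""Baseline/Cq/efficiency calling, normalisation, replicate QC and RTp."""

import math

import numpy as np
import pytest

from neomer.qpcr import (
    AmplificationCurve,
    QuantResult,
    baseline,
    call_cq,
    estimate_efficiency,
    normalize_run,
    quantify_plate,
    quantify_well,
    relative_template,
    replicate_qc,
    rtp_profile,
)
from neomer.simulate import QpcrTruth, flat_curve, simulate_qpcr


def _curve(fluor, **kw):
    fluor = np.asarray(fluor, float)
    return AmplificationCurve(
        kw.get("well", "w"), kw.get("sample", "s"), kw.get("apt", "a"),
        kw.get("run", "r"), np.arange(1, len(fluor) + 1), fluor)


def _exp_curve(E, base=100.0, start=10, amp=1.0, n=30):
    """Flat baseline, then an exact exponential 'amp * E^(c-start)' added."""
    c = np.arange(1, n + 1, dtype=float)
    sig = np.where(c >= start, amp * E ** (c - start), 0.0)
    return _curve(base + sig)


class TestBaseline:
    def test_mean_of_first_five(self):
        cur = _curve([90, 95, 100, 105, 110] + [100] * 10)
        assert baseline(cur) == 100.0

    def test_constant_curve(self):
        assert baseline(_curve([42.0] * 12)) == 42.0


class TestCallCq:
    def test_linear_interpolation_between_flanking_cycles(self):
        """Baseline 100, F[18]=500, F[19]=700: threshold 600 crossed at 18.5."""
        F = [100.0] * 17 + [500.0, 700.0, 900.0, 1000.0]
        cq, base, reason = call_cq(_curve(F))
        assert base == 100.0 and reason == ""
        assert cq == pytest.approx(18.5)

    def test_exact_integer_crossing(self):
        F = [100.0] * 9 + [600.0] + [1000.0] * 5
        cq, _, reason = call_cq(_curve(F))
        assert cq == 10.0 and reason == ""

    def test_flat_curve_never_crosses(self):
        cq, _, reason = call_cq(_curve([100.0] * 20))
        assert math.isnan(cq) and reason == "no crossing"

    def test_early_crossing_flagged(self):
        F = [100.0, 100.0, 700.0] + [900.0] * 10
        cq, _, reason = call_cq(_curve(F))
        assert math.isnan(cq) and reason == "early crossing"

    def test_left_shift_reduces_cq_by_shift(self):
        truth = QpcrTruth("w", "s", "a", "r", 1.9, 24.0)
        (c1,) = simulate_qpcr([truth], noise_sigma=0.0)
        shifted = _curve(np.concatenate([c1.fluorescence[3:],
                                         [c1.fluorescence[-1]] * 3]))
        cq1, _, _ = call_cq(c1)
        cq2, _, _ = call_cq(shifted)
        # tiny deviation allowed: the shifted baseline window sees slightly
        # more of the growing signal, nudging the threshold
        assert cq2 == pytest.approx(cq1 - 3, abs=1e-3)


class TestEfficiency:
    @pytest.mark.parametrize("E", [2.0, 1.8])
    def test_exact_exponential(self, E):
        cur = _exp_curve(E)
        cq, _, _ = call_cq(cur)
        est, diag = estimate_efficiency(cur, cq)
        assert est == pytest.approx(E, abs=1e-9)
        assert diag["r2"] == pytest.approx(1.0, abs=1e-12)

    def test_no_exponential_region(self):
        cur = _curve([100.0] * 14 + [700.0] + [90.0] * 10)
        est, diag = estimate_efficiency(cur, 15.0)
        assert math.isnan(est) and diag["reason"] == "no exponential region"

    def test_noisy_sigmoid_recovery(self):
        """True E 1.9, 1% multiplicative noise: recovered within 0.05."""
        rng = np.random.default_rng(0)
        truths = [QpcrTruth(f"w{i}", "s", "a", "r", 1.9,
                            float(rng.uniform(18, 26))) for i in range(40)]
        curves = simulate_qpcr(truths, noise_sigma=0.01, seed=1)
        ok = 0
        for t, c in zip(truths, curves):
            res = quantify_well(c)
            ok += res.qc_pass and abs(res.E - t.E) <= 0.05
        assert ok >= 38  # >= 95%


class TestNormalization:
    def _results(self, cqs, es, run="r1"):
        out = []
        for i, (cq, e) in enumerate(zip(cqs, es)):
            r = QuantResult("s%d" % i, "a", run, Cq=cq, E=e, qc_pass=True)
            out.append(r)
        return out

    def test_identity_when_mean_equals_reference(self):
        res = self._results([20, 24], [1.9, 1.9])
        norm, updated = normalize_run(res, ref_Cq=22, ref_E=1.9)
        assert norm.factor_Cq == 1.0
        assert [u.Cq_norm for u in updated] == [20, 24]

    def test_arithmetic(self):
        res = self._results([24, 24], [1.9, 1.9])
        norm, updated = normalize_run(res, ref_Cq=20, ref_E=1.9)
        assert norm.factor_Cq == pytest.approx(1.2)
        assert updated[0].Cq_norm == pytest.approx(20.0)

    def test_multiplicative_run_shift_cancels(self):
        r1 = self._results([20.0, 22.0, 24.0], [1.8, 1.9, 2.0], run="r1")
        r2 = self._results([23.0, 25.3, 27.6], [1.8, 1.9, 2.0], run="r2")
        _, u1 = normalize_run(r1)
        _, u2 = normalize_run(r2)
        for a, b in zip(u1, u2):
            assert a.Cq_norm == pytest.approx(b.Cq_norm)

    def test_empty_run_rejected(self):
        with pytest.raises(ValueError):
            normalize_run([QuantResult("s", "a", "r", qc_pass=False)])


class TestReplicateQC:
    def _rep(self, cq_norm, e_norm=1.9, ok=True):
        return QuantResult("s", "a", "r", Cq=cq_norm, E=e_norm,
                           Cq_norm=cq_norm, E_norm=e_norm, qc_pass=ok)

    def test_identical_replicates_pass(self):
        merged = replicate_qc([self._rep(20.0), self._rep(20.0)])
        assert merged.qc_pass and merged.Cq_norm == 20.0
        assert merged.RT == pytest.approx((1 / 1.9) ** 20)

    def test_discordant_replicates_fail(self):
        """Cq 20 vs 30: CV = 100*sd/mean = 28.28% > 6."""
        merged = replicate_qc([self._rep(20.0), self._rep(30.0)])
        assert not merged.qc_pass
        assert "28.28" in merged.qc_reason

    def test_one_failed_replicate_fails_pair(self):
        merged = replicate_qc([self._rep(20.0),
                               QuantResult("s", "a", "r", qc_reason="no crossing")])
        assert not merged.qc_pass


class TestRelativeTemplate:
    def test_closed_form(self):
        assert relative_template(2.0, 10.0) == pytest.approx(9.765625e-4)
        assert relative_template(2.0, 0.0) == 1.0

    def test_monotone_decreasing_in_cq(self):
        rts = [relative_template(1.9, cq) for cq in range(0, 30, 3)]
        assert all(a > b for a, b in zip(rts, rts[1:]))

    def test_requires_amplification(self):
        with pytest.raises(ValueError):
            relative_template(0.9, 10.0)


class TestRtp:
    def test_equal_rts(self):
        prof = rtp_profile("s", {f"a{i}": 2.5e-4 for i in range(8)})
        assert all(v == pytest.approx(0.125) for v in prof.rtp.values())

    def test_proportions(self):
        prof = rtp_profile("s", {"a": 3.0, "b": 1.0, "c": 0.0})
        assert prof.rtp == pytest.approx({"a": 0.75, "b": 0.25, "c": 0.0})

    def test_sums_to_one_and_scale_invariant(self):
        rng = np.random.default_rng(3)
        rts = {f"a{i}": float(v) for i, v in enumerate(rng.random(8))}
        p1 = rtp_profile("s", rts)
        p2 = rtp_profile("s", {k: 1e6 * v for k, v in rts.items()})
        assert sum(p1.rtp.values()) == pytest.approx(1.0, abs=1e-9)
        for k in rts:
            assert p1.rtp[k] == pytest.approx(p2.rtp[k])

    def test_missing_marker_recorded(self):
        prof = rtp_profile("s", {"a": 1.0, "b": math.nan})
        assert prof.missing == ("b",)
        assert prof.rtp["a"] == 1.0

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            rtp_profile("s", {"a": math.nan})


class TestEndToEnd:
    def test_known_wells_recovered_through_plate_pipeline(self):
        rng = np.random.default_rng(8)
        apts = [f"apt{i}" for i in range(8)]
        truths, rows = [], []
        for s in range(3):
            for apt in apts:
                E = float(rng.uniform(1.8, 2.0))
                cq = float(rng.uniform(18, 24))
                for rep in range(2):
                    truths.append(QpcrTruth(f"w{s}_{apt}_{rep}", f"S{s}",
                                            apt, "run1", E, cq))
        curves = simulate_qpcr(truths, noise_sigma=0.005, seed=9)
        for c in curves:
            for cyc, f in zip(c.cycles, c.fluorescence):
                rows.append({"run_id": c.run_id, "well_id": c.well_id,
                             "sample_id": c.sample_id,
                             "aptamarker": c.aptamarker_name,
                             "cycle": int(cyc), "fluorescence": f})
        import pandas as pd

        wells, norms, rtp = quantify_plate(pd.DataFrame(rows))
        assert wells["qc_pass"].all()
        assert len(norms) == 1
        assert rtp.shape == (3, 8)
        np.testing.assert_allclose(rtp.sum(axis=1), 1.0, atol=1e-9)

    def test_flat_well_is_dropped_by_complete_case_policy(self):
        import pandas as pd

        truths = [QpcrTruth(f"w{r}", "S0", "apt0", "run1", 1.9, 22.0)
                  for r in range(2)]
        curves = simulate_qpcr(truths, noise_sigma=0.0)
        curves += [flat_curve(f"f{r}", "S0", "apt1", "run1") for r in range(2)]
        rows = [
            {"run_id": c.run_id, "well_id": c.well_id, "sample_id": c.sample_id,
             "aptamarker": c.aptamarker_name, "cycle": int(cyc), "fluorescence": f}
            for c in curves for cyc, f in zip(c.cycles, c.fluorescence)
        ]
        wells, _, rtp = quantify_plate(pd.DataFrame(rows))
        assert (~wells.loc[wells["aptamarker"] == "apt1", "qc_pass"]).all()
        assert rtp.empty
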