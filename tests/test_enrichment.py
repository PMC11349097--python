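"""Outer-product reconstruction, Z-score contrast and candidate selection."""

import math

import numpy as np
import pytest

from neomer.counting import FrequencyVector
from neomer.enrichment import (
    HIGH_VS_LOW,
    LOW_VS_HIGH,
    SampleLibraryProfile,
    ZScoreHit,
    brute_force_contrast,
    contrast_zscores,
    full_frequency,
    select_candidates,
    separation_score,
)
from neomer.simulate import SimulationConfig, default_planted, simulate_profiles


def _profile(sid, group, fa, fb):
    return SampleLibraryProfile(
        sid, group,
        FrequencyVector(sid, "A", np.asarray(fa, float)),
        FrequencyVector(sid, "B", np.asarray(fb, float)),
    )


def _random_profiles(k, n_high, n_low, seed):
    rng = np.random.default_rng(seed)
    m = 4**k
    out = []
    for i in range(n_high + n_low):
        group = "high" if i < n_high else "low"
        fa = rng.dirichlet(np.full(m, 2.0))
        fb = rng.dirichlet(np.full(m, 2.0))
        out.append(_profile(f"s{i}", group, fa, fb))
    return out


class TestFullFrequency:
    def test_toy_product(self):
        p = _profile("s", "high", [0.5, 0.5, 0, 0], [0.25, 0.75, 0, 0])
        assert full_frequency(p, 0, 1) == 0.375

    def test_total_mass_is_one(self):
        p = _random_profiles(2, 1, 1, 0)[0]
        total = sum(full_frequency(p, i, j) for i in range(16) for j in range(16))
        assert abs(total - 1.0) < 1e-9

    def test_one_hot_module_b_recovers_module_a(self):
        fb = np.zeros(4)
        fb[2] = 1.0
        p = _profile("s", "high", [0.1, 0.2, 0.3, 0.4], fb)
        for i in range(4):
            assert full_frequency(p, i, 2) == p.freqA.freqs[i]


class TestContrastZscores:
    def test_hand_computed_z(self):
        """Two samples per group with known reconstructed frequencies.

        Module B is one-hot so reconstructed frequency equals the module A
        entry: high {0.4, 0.5}, low {0.1, 0.2} gives mean diff 0.3 and
        ddof-1 SDs of 0.07071 each, z = 0.3 / 0.07071 = 4.2426.
        """
        onehot = [0.0, 1.0, 0.0, 0.0]
        profiles = [
            _profile("h1", "high", [0.4, 0.6, 0, 0], onehot),
            _profile("h2", "high", [0.5, 0.5, 0, 0], onehot),
            _profile("l1", "low", [0.1, 0.9, 0, 0], onehot),
            _profile("l2", "low", [0.2, 0.8, 0, 0], onehot),
        ]
        result = contrast_zscores(profiles, HIGH_VS_LOW, K=16, block_rows=2)
        hit = next(h for h in result.top_hits if (h.iA, h.iB) == (0, 1))
        assert hit.z == pytest.approx(4.242640687119285, abs=1e-12)
        assert hit.mean_num == pytest.approx(0.45)
        assert hit.sd_num == pytest.approx(math.sqrt(0.005))

    def test_identical_groups_give_zero_z(self):
        fa, fb = [0.2, 0.3, 0.1, 0.4], [0.25, 0.25, 0.4, 0.1]
        fa2, fb2 = [0.3, 0.2, 0.2, 0.3], [0.2, 0.3, 0.3, 0.2]
        profiles = [
            _profile("h1", "high", fa, fb), _profile("h2", "high", fa2, fb2),
            _profile("l1", "low", fa, fb), _profile("l2", "low", fa2, fb2),
        ]
        result = contrast_zscores(profiles, HIGH_VS_LOW, K=16)
        assert all(h.z == pytest.approx(0.0, abs=1e-12) for h in result.top_hits)

    def test_direction_reversal_negates_z(self):
        profiles = _random_profiles(2, 3, 3, seed=3)
        fwd = contrast_zscores(profiles, HIGH_VS_LOW, K=256)
        rev = contrast_zscores(profiles, LOW_VS_HIGH, K=256)
        fwd_map = {(h.iA, h.iB): h.z for h in fwd.top_hits}
        rev_map = {(h.iA, h.iB): h.z for h in rev.top_hits}
        for key in fwd_map:
            assert rev_map[key] == pytest.approx(-fwd_map[key], abs=1e-12)

    def test_fewer_than_two_samples_rejected(self):
        profiles = _random_profiles(2, 1, 2, seed=4)
        with pytest.raises(ValueError):
            contrast_zscores(profiles, HIGH_VS_LOW)

    def test_scale_invariance_of_frequencies(self, scaffold4):
        """Multiplying one sample's counts by a constant leaves z unchanged."""
        cfg = SimulationConfig(seed=11, k=2, depth=5000, n_high=3, n_low=3)
        profiles, tables, _ = simulate_profiles(cfg)
        ta, tb = tables[0]
        fa = (ta.counts * 7) / (ta.counts.sum() * 7)
        fb = (tb.counts * 7) / (tb.counts.sum() * 7)
        scaled = [_profile(profiles[0].sample_id, profiles[0].group, fa, fb)]
        scaled += profiles[1:]
        r1 = contrast_zscores(profiles, HIGH_VS_LOW, K=50)
        r2 = contrast_zscores(scaled, HIGH_VS_LOW, K=50)
        assert [(h.iA, h.iB) for h in r1.top_hits] == [(h.iA, h.iB) for h in r2.top_hits]
        for h1, h2 in zip(r1.top_hits, r2.top_hits):
            assert h1.z == pytest.approx(h2.z, abs=1e-12)


class TestOracleEquivalence:
    @pytest.mark.parametrize("k", [2, 3, 4])
    @pytest.mark.parametrize("block_rows", [1, 7, 256])
    def test_blocked_scan_matches_brute_force(self, k, block_rows):
        """Top-K membership, ordering and z values agree to 1e-12."""
        profiles = _random_profiles(k, 4, 4, seed=20 + k)
        K = 500
        fast = contrast_zscores(profiles, HIGH_VS_LOW, K=K, block_rows=block_rows)
        slow = brute_force_contrast(profiles, HIGH_VS_LOW)[:K]
        assert len(fast.top_hits) == len(slow)
        for f, s in zip(fast.top_hits, slow):
            assert (f.iA, f.iB) == (s.iA, s.iB)
            assert f.z == pytest.approx(s.z, abs=1e-12)

    def test_zero_sd_sequences_excluded(self):
        onehot = [0.0, 1.0, 0.0, 0.0]
        profiles = [
            _profile("h1", "high", [0.4, 0.6, 0, 0], onehot),
            _profile("h2", "high", [0.5, 0.5, 0, 0], onehot),
            _profile("l1", "low", [0.1, 0.9, 0, 0], onehot),
            _profile("l2", "low", [0.2, 0.8, 0, 0], onehot),
        ]
        result = contrast_zscores(profiles, HIGH_VS_LOW, K=16)
        # module-A rows 2,3 are zero everywhere (8 cells) and module-B
        # columns 0,2,3 are zero for the live rows (6 cells): only the
        # two cells (0,1) and (1,1) carry variance
        assert result.n_zero_sd == 14
        assert len(result.top_hits) == 2


class TestSeparation:
    def test_positive_margin(self):
        onehot = [0.0, 1.0]
        profiles = [
            _profile("h1", "high", [0.4, 0.6], onehot),
            _profile("h2", "high", [0.5, 0.5], onehot),
            _profile("l1", "low", [0.1, 0.9], onehot),
            _profile("l2", "low", [0.2, 0.8], onehot),
        ]
        hit = ZScoreHit(0, 1, 0, 0, 0, 0, 0, 1)
        assert separation_score(hit, profiles, HIGH_VS_LOW) == pytest.approx(0.2)

    def test_overlapping_groups_negative(self):
        onehot = [0.0, 1.0]
        profiles = [
            _profile("h1", "high", [0.3, 0.7], onehot),
            _profile("h2", "high", [0.5, 0.5], onehot),
            _profile("l1", "low", [0.35, 0.65], onehot),
            _profile("l2", "low", [0.1, 0.9], onehot),
        ]
        hit = ZScoreHit(0, 1, 0, 0, 0, 0, 0, 1)
        assert separation_score(hit, profiles, HIGH_VS_LOW) == pytest.approx(-0.05)

    def test_identical_groups_nonpositive(self):
        fa = [0.3, 0.7]
        profiles = [
            _profile("h1", "high", fa, [0, 1.0]),
            _profile("h2", "high", fa, [0, 1.0]),
            _profile("l1", "low", fa, [0, 1.0]),
            _profile("l2", "low", fa, [0, 1.0]),
        ]
        hit = ZScoreHit(0, 1, 0, 0, 0, 0, 0, 1)
        assert separation_score(hit, profiles, HIGH_VS_LOW) <= 0


class TestSelection:
    def test_planted_family_is_selected(self):
        planted = default_planted(3, n_pairs=4, factor=6.0, seed=77)
        cfg = SimulationConfig(seed=78, k=3, depth=500_000, planted=planted)
        profiles, _, _ = simulate_profiles(cfg)
        result = contrast_zscores(profiles, HIGH_VS_LOW, K=1000)
        result = select_candidates(result, profiles, n_select=4)
        assert {(h.iA, h.iB) for h in result.selected} == {
            (p.iA, p.iB) for p in planted
        }

    def test_n_select_zero(self):
        profiles = _random_profiles(2, 2, 2, seed=30)
        result = contrast_zscores(profiles, HIGH_VS_LOW, K=50)
        result = select_candidates(result, profiles, n_select=0)
        assert result.selected == []

    def test_n_select_exceeding_hits_rejected(self):
        profiles = _random_profiles(2, 2, 2, seed=31)
        result = contrast_zscores(profiles, HIGH_VS_LOW, K=10)
        with pytest.raises(ValueError):
            select_candidates(result, profiles, n_select=11)

    def test_selection_is_deterministic(self):
        profiles = _random_profiles(2, 3, 3, seed=32)
        r1 = select_candidates(contrast_zscores(profiles, HIGH_VS_LOW, K=100),
                               profiles, 4)
        r2 = select_candidates(contrast_zscores(profiles, HIGH_VS_LOW, K=100),
                               profiles, 4)
        assert [(h.iA, h.iB) for h in r1.selected] == [
            (h.iA, h.iB) for h in r2.selected
        ]
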