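"""Umbrella rank test: oracle agreement, null calibration, peak geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ohnorhythm.errors import ConfigurationError, InputError
from ohnorhythm.rhythm import (
    RhythmTester,
    detect_rhythms,
    peak_statistics,
    rhythm_test,
    umbrella_statistic,
)
from ohnorhythm.simulate import SimulationConfig, simulate_counts


def oracle_umbrella(groups, peak, trough):
    """All-pairs concordance count by explicit double loops: the
    independent reference for the umbrella statistic."""
    k = len(groups)

    def arc(start, end):
        out = [start]
        i = start
        while i != end:
            i = (i + 1) % k
            out.append(i)
        return out

    total = 0.0
    for indices, rising in ((arc(trough, peak), True), (arc(peak, trough), False)):
        for x in range(len(indices)):
            for y in range(x + 1, len(indices)):
                earlier, later = indices[x], indices[y]
                for u in groups[earlier]:
                    for v in groups[later]:
                        hi, lo = (v, u) if rising else (u, v)
                        if hi > lo:
                            total += 1.0
                        elif hi == lo:
                            total += 0.5
    return total


@st.composite
def rank_instances(draw):
    k = draw(st.integers(min_value=3, max_value=6))
    sizes = draw(
        st.lists(st.integers(min_value=1, max_value=3), min_size=k, max_size=k).filter(
            lambda s: sum(s) <= 16
        )
    )
    groups = [
        draw(st.lists(st.integers(min_value=0, max_value=6), min_size=n, max_size=n))
        for n in sizes
    ]
    peak = draw(st.integers(min_value=0, max_value=k - 1))
    trough = draw(st.integers(min_value=0, max_value=k - 1).filter(lambda t: t != peak))
    return groups, peak, trough


class TestUmbrellaStatistic:
    @given(rank_instances())
    @settings(max_examples=150, deadline=None)
    def test_matches_brute_force_oracle(self, instance):
        groups, peak, trough = instance
        s, s_max = umbrella_statistic(groups, peak, trough)
        assert s == pytest.approx(oracle_umbrella(groups, peak, trough))
        assert 0 <= s <= s_max

    def test_perfect_umbrella_reaches_maximum(self):
        groups = [[1, 2], [5, 6], [9, 10], [7, 8], [3, 4], [0.5, 0.1]]
        s, s_max = umbrella_statistic(groups, peak_index=2, trough_index=5)
        assert s == s_max

    def test_all_ties_give_half_maximum(self):
        groups = [[2.0, 2.0]] * 5
        s, s_max = umbrella_statistic(groups, 1, 3)
        assert s == pytest.approx(s_max / 2)

    @given(rank_instances())
    @settings(max_examples=60, deadline=None)
    def test_invariant_under_monotone_transform(self, instance):
        groups, peak, trough = instance
        s0, _ = umbrella_statistic(groups, peak, trough)
        warped = [[np.exp(0.5 * v) + 3 for v in g] for g in groups]
        s1, _ = umbrella_statistic(warped, peak, trough)
        assert s1 == pytest.approx(s0)

    def test_identical_peak_and_trough_rejected(self):
        with pytest.raises(InputError):
            umbrella_statistic([[1], [2], [3]], 1, 1)


class TestNullDistribution:
    def test_monte_carlo_agrees_with_full_enumeration(self):
        """On 6 observations the exact null is enumerable; Monte-Carlo
        p-values must land within 3 binomial standard errors of it,
        hypothesis by hypothesis."""
        groups = [[1.0, 2.0], [5.0, 4.0], [3.0, 2.5]]
        pooled = np.concatenate(groups)
        n_perm = 100_000
        exact = RhythmTester([2, 2, 2], method="exact").hypothesis_pvalues(pooled)
        mc = RhythmTester(
            [2, 2, 2], method="monte_carlo", n_perm=n_perm, seed=7
        ).hypothesis_pvalues(pooled)
        se = np.sqrt(exact * (1 - exact) / n_perm)
        assert np.all(np.abs(mc - exact) <= 3 * se + 2.0 / n_perm)

    def test_cutoff_is_strict_at_alpha(self, rhythm_results):
        _, _, res = rhythm_results
        tested = res[res["p_value"].notna()]
        assert (tested["is_cyclic"] == (tested["p_value"] < 0.01)).all()

    def test_small_n_perm_rejected(self):
        with pytest.raises(ConfigurationError):
            RhythmTester([2, 2, 2], method="monte_carlo", n_perm=50)

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ConfigurationError):
            rhythm_test([[1, 2], [3, 4]])

    def test_null_pvalues_super_uniform(self):
        """Flat negative-binomial genes: the empirical CDF of combined
        p-values must stay inside the 99% DKW band below the uniform
        (Bonferroni makes the test conservative)."""
        cfg = SimulationConfig(
            n_genes=500, organs=("skin",), cyclic_fraction=0.0, n_replicates=1, seed=21
        )
        cm, _ = simulate_counts(cfg)
        res = detect_rhythms(cm, seed=5)
        p = np.sort(res["p_value"].to_numpy())
        ecdf = np.arange(1, p.size + 1) / p.size
        band = np.sqrt(np.log(2 / 0.01) / (2 * p.size))
        assert np.max(ecdf - p) <= band


class TestPeakStatistics:
    ZTS = (0.5, 3.5, 6.5, 9.5, 12.5, 15.5, 18.5, 21.5)

    def test_direct_definition(self):
        rel = [0.5, 0.8, 2.0, 1.5, 1.0, 0.9, 0.2, 0.6]
        peak, shape, amplitude, degenerate = peak_statistics(rel, self.ZTS)
        assert (peak, shape, amplitude, degenerate) == (6.5, 12.0, 1.8, False)

    def test_circular_wraparound(self):
        rel = [1.2, 0.3, 0.9, 1.0, 1.1, 1.15, 1.18, 1.9]
        peak, shape, _, _ = peak_statistics(rel, self.ZTS)
        assert peak == 21.5 and shape == 6.0

    def test_constant_profile_degenerate(self):
        peak, shape, amplitude, degenerate = peak_statistics([1.0] * 8, self.ZTS)
        assert degenerate and amplitude == 0.0 and np.isnan(peak)


class TestRecovery:
    def test_modal_recovered_peak_equals_planted_phase(self):
        """For strongly rhythmic planted genes detected as cyclic, the
        most frequent recovered peak Zt per planted phase is the phase
        itself (3 h sampling resolution)."""
        cfg = SimulationConfig(
            n_genes=400,
            organs=("eye",),
            cyclic_fraction=1.0,
            amplitude_range=(1.0, 1.0),
            seed=7,
        )
        cm, truth = simulate_counts(cfg)
        res = detect_rhythms(cm, n_perm=100_000, seed=5)
        merged = res.merge(truth, on=["gene_id", "organ"], suffixes=("", "_true"))
        detected = merged[merged["is_cyclic"]]
        assert len(detected) > 100
        for phase, grp in detected.groupby("true_peak_zt"):
            if len(grp) >= 10:
                assert grp["peak_zt"].mode().iloc[0] == phase

    def test_detection_beats_planted_fraction(self, rhythm_results):
        _, truth, res = rhythm_results
        merged = res.merge(truth, on=["gene_id", "organ"])
        planted = merged[merged["is_cyclic_y"]]
        flat = merged[~merged["is_cyclic_y"]]
        assert planted["is_cyclic_x"].mean() > 0.5
        assert flat["is_cyclic_x"].mean() < 0.05
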