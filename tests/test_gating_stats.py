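"""NPo, dwell statistics, group comparison and the occupancy diagnostic."""

import numpy as np
import pytest

from tricchan import (
    GatingModel,
    binomial_occupancy_check,
    compare_groups,
    dwell_summary,
    extract_dwells,
    gating_report,
    npo,
    simulate_state_path,
    weighted_npo,
)
from tricchan.idealization import IdealizedRecord


def _record(levels, durations, n_levels=4):
    durations = np.asarray(durations, float)
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return IdealizedRecord(
        levels=np.asarray(levels),
        starts=starts,
        durations=durations,
        n_levels=n_levels,
        dead_time=0.0,
        total_time=float(durations.sum()),
    )


def _record_from_path(path):
    starts = np.concatenate([[0.0], np.cumsum(path.durations)[:-1]])
    return IdealizedRecord(
        levels=path.levels,
        starts=starts,
        durations=path.durations,
        n_levels=path.n_monomers + 1,
        dead_time=0.0,
        total_time=path.total_duration,
    )


class TestNpo:
    def test_all_closed_is_zero(self):
        assert npo(_record([0], [5.0])) == 0.0

    def test_half_open_is_half(self):
        assert npo(_record([0, 1], [2.5, 2.5])) == pytest.approx(0.5)

    def test_unweighted_by_level(self):
        # time at level 3 counts the same as time at level 1
        assert npo(_record([0, 3], [2.5, 2.5])) == pytest.approx(0.5)
        assert weighted_npo(_record([0, 3], [2.5, 2.5])) == pytest.approx(0.5)
        assert weighted_npo(_record([0, 1], [2.5, 2.5])) == pytest.approx(0.5 / 3)

    def test_invariant_under_event_merging(self):
        a = _record([0, 1, 1, 0], [1.0, 1.0, 2.0, 1.0])
        b = _record([0, 1, 0], [1.0, 3.0, 1.0])
        assert npo(a) == pytest.approx(npo(b))

    def test_matches_binomial_prediction(self, wt_model):
        """Simulated trimer: NPo -> 1 - (1-p)^3."""
        path = simulate_state_path(wt_model, 500.0, seed=17)
        rec = _record_from_path(path)
        p = wt_model.p_open
        assert npo(rec) == pytest.approx(1 - (1 - p) ** 3, abs=0.01)


class TestDwellSummary:
    def test_constant_dwells(self):
        mean, sd, rate = dwell_summary([2.0, 2.0, 2.0])
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(0.0)
        assert rate == pytest.approx(0.5)

    def test_exponential_sample_mean(self):
        rng = np.random.default_rng(0)
        mean, _, rate = dwell_summary(rng.exponential(1 / 100.0, 10_000))
        assert mean == pytest.approx(0.01, rel=0.02)
        assert rate == pytest.approx(100.0, rel=0.02)

    def test_closed_dwell_rate_is_3_k_open(self, wt_model):
        path = simulate_state_path(wt_model, 500.0, seed=19)
        rec = _record_from_path(path)
        dwells = extract_dwells(rec, 0, drop_censored=True)
        _, _, rate = dwell_summary(dwells)
        assert rate == pytest.approx(3 * wt_model.k_open, rel=0.05)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dwell_summary([])


class TestCompareGroups:
    def test_identical_groups_contract(self):
        t, _, p = compare_groups([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert t == 0.0
        assert p == 1.0

    def test_extreme_separation(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 1e-3, 4)
        b = 1.0 + rng.normal(0.0, 1e-3, 4)
        _, _, p = compare_groups(a, b)
        assert p < 0.01

    def test_pooled_variance_textbook_value(self):
        """{1,2,3} vs {2,3,4}: pooled t = -sqrt(3/2) ~ -1.225."""
        t, df, _ = compare_groups([1, 2, 3], [2, 3, 4], equal_var=True)
        assert t == pytest.approx(-1.2247448, abs=1e-6)
        assert df == 4

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])


class TestBinomialOccupancyCheck:
    def test_exact_binomial_fractions_give_small_chi2(self):
        # alternating path whose time fractions are exactly Binomial(3, 1/2)
        frac = [0.125, 0.375, 0.375, 0.125]
        levels, durations = [], []
        for _ in range(200):
            for lv in (0, 1, 2, 3, 2, 1):
                levels.append(lv)
                durations.append(frac[lv] / (2 if lv in (1, 2) else 1) / 200)
        rec = _record(levels, durations)
        _, chi2, p = binomial_occupancy_check(rec, 3)
        assert chi2 == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_independence_simulator_not_rejected(self, wt_model):
        path = simulate_state_path(wt_model, 1000.0, seed=23)
        p_hat, _, p_value = binomial_occupancy_check(_record_from_path(path), 3)
        assert p_hat == pytest.approx(0.5, abs=0.02)
        assert p_value > 0.01

    def test_cooperative_signature_rejected(self):
        # all-or-none gating: time split between fully closed and fully open
        levels = [0, 1, 2, 3, 2, 1] * 50
        durations = []
        for lv in levels:
            durations.append(0.5 if lv in (0, 3) else 1e-4)
        rec = _record(levels, durations)
        _, chi2, p = binomial_occupancy_check(rec, 3)
        assert chi2 > 50
        assert p < 1e-6

    def test_level_count_mismatch_rejected(self):
        rec = _record([0, 1, 0], [1.0, 1.0, 1.0], n_levels=3)
        with pytest.raises(ValueError):
            binomial_occupancy_check(rec, 3)


class TestMutantOrdering:
    def test_destabilized_plug_increases_npo_and_open_dwell(self):
        """Doubling k_open and halving k_close raises NPo and lengthens open dwells.

        This is the direction of the plug-mutant phenotype (a more open,
        longer-lived open state) asserted as an ordering on simulations.
        """
        g = (0.0, 42.2, 100.6, 163.7)
        wt = GatingModel(k_open=20.0, k_close=80.0, level_conductances=g)
        mut = GatingModel(k_open=40.0, k_close=40.0, level_conductances=g)
        rec_wt = _record_from_path(simulate_state_path(wt, 300.0, seed=31))
        rec_mut = _record_from_path(simulate_state_path(mut, 300.0, seed=31))
        assert npo(rec_mut) > npo(rec_wt)
        rep_wt, rep_mut = gating_report(rec_wt), gating_report(rec_mut)
        assert rep_mut.mean_open_dwell > rep_wt.mean_open_dwell
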