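import numpy as np
import pandas as pd
import pytest

from licfret.kinetics import (
    aggregate_release_rate, fraction_outcome, interval_statistics,
    per_state_release_frequency, release_event_frame,
    time_in_state_fraction,
)
from licfret.traces import FluorTrace


def labels_of(seq):
    return np.asarray(seq, dtype=object)


class TestReleaseFrequency:
    def test_binomial_rate_and_se(self):
        """2 events in 100 high frames at 1-s frames -> 0.02 +/- 0.014."""
        mols = [(labels_of(["high"] * 50), 50),
                (labels_of(["high"] * 50), 50)]
        rates = per_state_release_frequency(mols, frame_dt=1.0)
        high = rates["high"]
        assert high.n_events == 2 and high.n_frames == 100
        assert high.rate == pytest.approx(0.02)
        assert high.se == pytest.approx(np.sqrt(0.02 * 0.98 / 100), rel=1e-6)

    def test_zero_events_rule_of_three_bound(self):
        mols = [(labels_of(["high"] * 200), None)]
        rates = per_state_release_frequency(mols, frame_dt=1.0)
        assert rates["high"].rate == 0.0
        assert rates["high"].upper95 == pytest.approx(3 / 200)

    def test_rate_scales_inversely_with_frame_interval(self):
        mols = [(labels_of(["high"] * 100), 100)]
        r1 = per_state_release_frequency(mols, frame_dt=1.0)["high"].rate
        r2 = per_state_release_frequency(mols, frame_dt=0.5)["high"].rate
        assert r2 == pytest.approx(2 * r1)

    def test_event_charged_to_state_of_preceding_frame(self):
        lab = labels_of(["high"] * 8 + ["low", "low"])
        rates = per_state_release_frequency([(lab, 10)], frame_dt=1.0)
        assert rates["low"].n_events == 1
        assert rates["high"].n_events == 0

    def test_unlabeled_gap_before_release_uses_last_labeled_frame(self):
        lab = labels_of(["high"] * 8 + ["invalid", "invalid"])
        rates = per_state_release_frequency([(lab, 10)], frame_dt=1.0)
        assert rates["high"].n_events == 1

    def test_no_frames_in_state_reported_undefined(self):
        rates = per_state_release_frequency(
            [(labels_of(["high"] * 10), None)], frame_dt=1.0)
        assert rates["low"].rate is None

    def test_aggregate_pools_counts(self):
        mols = [(labels_of(["high"] * 95 + ["low"] * 5), 100)]
        rates = per_state_release_frequency(mols, frame_dt=2.0)
        assert aggregate_release_rate(rates, 2.0) == pytest.approx(
            1 / 100 / 2.0)


class TestReleaseEventFrame:
    def make(self, coloc, valid=None):
        n = len(coloc)
        if valid is None:
            valid = np.ones(n, bool)
        return FluorTrace(molecule_id="m", frame_dt=1.0,
                          protocol="continuous_green",
                          channels={("Dex", "Dem"): np.zeros(n)},
                          valid_mask=np.asarray(valid, bool),
                          colocalized_mask=np.asarray(coloc, bool))

    def test_departure_mid_trace_is_an_event(self):
        assert release_event_frame(self.make([1, 1, 1, 0, 0])) == 3

    def test_bound_at_end_is_censored(self):
        assert release_event_frame(self.make([0, 1, 1, 1, 1])) is None

    def test_bleach_terminated_trace_is_censored(self):
        tr = self.make([1, 1, 1, 0, 0], valid=[1, 1, 0, 0, 0])
        assert release_event_frame(tr) is None


class TestIntervalStatistics:
    def test_mean_and_sem_closed_form(self):
        st = interval_statistics([2.0, 4.0, 6.0], n_bootstrap=0)
        assert st.mean == pytest.approx(4.0)
        assert st.sem == pytest.approx(2.0 / np.sqrt(3), rel=1e-6)

    def test_survival_starts_at_one(self):
        st = interval_statistics([1.0, 2.0, 5.0], n_bootstrap=0)
        assert st.survival.survival[0] == 1.0

    def test_product_limit_equals_empirical_without_censoring(self, rng):
        x = rng.exponential(5.0, 60)
        st = interval_statistics(x, n_bootstrap=0)
        for t, s in zip(st.survival.times, st.survival.survival):
            assert s == pytest.approx(np.mean(x > t), abs=1e-9)

    def test_bootstrap_ci_contains_point_estimate(self, rng):
        x = rng.exponential(5.0, 40)
        cen = rng.random(40) < 0.3
        st = interval_statistics(x, cen, n_bootstrap=200, seed=1)
        assert (st.survival.lower <= st.survival.survival + 1e-12).all()
        assert (st.survival.upper >= st.survival.survival - 1e-12).all()

    def test_all_censored_refuses_mean_but_returns_curve(self):
        st = interval_statistics([3.0, 4.0], censored=[True, True],
                                 n_bootstrap=0)
        assert st.mean is None
        assert len(st.survival.times) > 0

    def test_seeded_bootstrap_reproducible(self, rng):
        x = rng.exponential(5.0, 30)
        a = interval_statistics(x, n_bootstrap=100, seed=5)
        b = interval_statistics(x, n_bootstrap=100, seed=5)
        np.testing.assert_array_equal(a.survival.lower, b.survival.lower)


class TestFractions:
    def test_time_in_state_printed_counts(self):
        """141 low of 25,388 labeled frames -> 0.555% low."""
        lab = labels_of(["low"] * 141 + ["high"] * (25388 - 141))
        frac = time_in_state_fraction(lab)
        assert frac["low"] == pytest.approx(141 / 25388)
        assert frac["low"] == pytest.approx(0.00555, abs=2e-5)

    def test_all_high(self):
        frac = time_in_state_fraction(labels_of(["high"] * 10))
        assert frac == {"low": 0.0, "high": 1.0}

    def test_binomial_fraction_and_se(self):
        ev = pd.DataFrame({"hit": [True] * 50 + [False] * 50})
        out = fraction_outcome(ev, lambda df: df.hit)
        assert out.fraction == 0.5
        assert out.se == pytest.approx(0.05)

    def test_zero_successes_rule_of_three(self):
        ev = pd.DataFrame({"hit": [False] * 10})
        out = fraction_outcome(ev, lambda df: df.hit)
        assert out.fraction == 0.0
        assert out.upper95 == pytest.approx(0.3)


class TestRecovery:
    def test_unbent_fraction_recovered_from_wt_simulation(self, orc_dataset,
                                                          photo):
        """The labeled low-state time fraction matches the generating
        unbent dwell fraction (0.5%) on WT ORC traces."""
        from licfret.analysis import orc_release_analysis
        traces, _ = orc_dataset
        res = orc_release_analysis(traces, photo)
        assert res["state_fractions"]["low"] == pytest.approx(0.005,
                                                              abs=0.004)
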