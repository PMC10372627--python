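import numpy as np
import pytest

from licfret.fret import ESeries
from licfret.segmentation import (
    MixtureFit, detect_peaks, detect_transitions, fit_global_mixture,
    fit_mixture, flag_nonspecific, state_labels, trough_threshold,
)


def eseries(values, valid=None, frame_dt=1.0):
    values = np.asarray(values, float)
    if valid is None:
        valid = np.isfinite(values)
    return ESeries(efret=values, total=np.full(len(values), 100.0),
                   valid_mask=np.asarray(valid, bool), frame_dt=frame_dt)


class TestFitMixture:
    def test_degenerate_sample_flagged(self):
        fit = fit_mixture(np.full(50, 0.4), 1, n_bootstrap=0)
        assert fit.degenerate
        assert fit.centers[0] == 0.4
        assert fit.widths[0] == 0.0

    def test_two_component_sampling_oracle(self, rng):
        """Centers of a well-separated mixture recovered within 0.01."""
        x = np.concatenate([rng.normal(0.12, 0.05, 2500),
                            rng.normal(0.55, 0.05, 2500)])
        fit = fit_mixture(x, 2, n_restarts=5, n_bootstrap=50)
        assert fit.centers[0] == pytest.approx(0.12, abs=0.01)
        assert fit.centers[1] == pytest.approx(0.55, abs=0.01)
        assert (fit.center_ses < 0.01).all()

    def test_extra_component_gains_little_on_unimodal_data(self, rng):
        x = rng.normal(0.4, 0.05, 2000)
        ll1 = fit_mixture(x, 1, n_restarts=3, n_bootstrap=0).log_likelihood
        ll2 = fit_mixture(x, 2, n_restarts=3, n_bootstrap=0).log_likelihood
        # likelihood-ratio gain far below a meaningful model-selection margin
        assert ll2 - ll1 < 10.0

    def test_sample_too_small_rejected(self):
        with pytest.raises(ValueError, match="need >="):
            fit_mixture(np.linspace(0, 1, 15), 2)


class TestGlobalMixture:
    def test_identical_groups_match_pooled_fit(self, rng):
        x = np.concatenate([rng.normal(0.2, 0.05, 1500),
                            rng.normal(0.6, 0.05, 1500)])
        gfit = fit_global_mixture({"a": x, "b": x.copy()}, 2, n_restarts=5)
        pooled = fit_mixture(x, 2, n_restarts=5, n_bootstrap=0)
        np.testing.assert_allclose(gfit.centers, pooled.centers, atol=0.01)

    def test_shared_centers_recovered_across_weights(self, rng):
        """TW1/TW2-like groups sharing centers but not weights."""
        g1 = np.concatenate([rng.normal(0.12, 0.05, 4000),
                             rng.normal(0.55, 0.05, 1000)])
        g2 = np.concatenate([rng.normal(0.12, 0.05, 800),
                             rng.normal(0.55, 0.05, 4200)])
        fit = fit_global_mixture({"tw1": g1, "tw2": g2}, 2, n_restarts=5)
        assert fit.centers[0] == pytest.approx(0.12, abs=0.02)
        assert fit.centers[1] == pytest.approx(0.55, abs=0.02)
        # per-group weights reflect each group's composition
        assert fit.group_params["tw1"][0][0] > 0.6
        assert fit.group_params["tw2"][0][0] < 0.4

    def test_global_centers_within_hull_of_per_group_centers(self, rng):
        groups = {}
        for k, w in enumerate([0.8, 0.5, 0.2]):
            n = 3000
            n1 = int(w * n)
            groups[k] = np.concatenate([rng.normal(0.12, 0.05, n1),
                                        rng.normal(0.55, 0.05, n - n1)])
        gfit = fit_global_mixture(groups, 2, n_restarts=5)
        per = [fit_mixture(v, 2, n_restarts=5, n_bootstrap=0).centers
               for v in groups.values()]
        per = np.vstack(per)
        for j in range(2):
            assert per[:, j].min() - 0.01 <= gfit.centers[j] <= \
                per[:, j].max() + 0.01

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            fit_global_mixture({"a": np.zeros(100)}, 2)


class TestTrough:
    def test_symmetric_mixture_trough_is_midpoint(self):
        fit = MixtureFit(n_components=2, centers=np.array([0.12, 0.55]),
                         widths=np.array([0.08, 0.08]),
                         weights=np.array([0.5, 0.5]), log_likelihood=0.0)
        assert trough_threshold(fit) == pytest.approx(0.335, abs=1e-4)

    def test_asymmetric_weights_shift_trough_toward_light_component(self):
        fit = MixtureFit(n_components=2, centers=np.array([0.12, 0.55]),
                         widths=np.array([0.08, 0.08]),
                         weights=np.array([0.8, 0.2]), log_likelihood=0.0)
        assert trough_threshold(fit) > 0.335

    def test_merged_components_raise(self):
        fit = MixtureFit(n_components=2, centers=np.array([0.40, 0.42]),
                         widths=np.array([0.1, 0.1]),
                         weights=np.array([0.5, 0.5]), log_likelihood=0.0)
        with pytest.raises(ValueError, match="trough"):
            trough_threshold(fit)

    def test_one_component_fit_rejected(self):
        fit = MixtureFit(n_components=1, centers=np.array([0.4]),
                         widths=np.array([0.1]), weights=np.array([1.0]),
                         log_likelihood=0.0)
        with pytest.raises(ValueError):
            trough_threshold(fit)


class TestTransitions:
    def test_single_frame_dip_is_not_a_transition(self):
        segs = detect_transitions(eseries([0.6, 0.6, 0.1, 0.6, 0.6]), 0.28)
        assert segs.transitions == []
        assert all(label == "high" for label in segs.labels)

    def test_persistent_drop_called_at_first_low_frame(self):
        segs = detect_transitions(eseries([0.6, 0.6, 0.1, 0.1, 0.1]), 0.28)
        assert segs.transitions == [(2, "high", "low")]
        assert segs.segments == [("high", 0, 1), ("low", 2, 4)]

    def test_all_high_gives_one_segment(self):
        segs = detect_transitions(eseries([0.5, 0.6, 0.7, 0.9]), 0.28)
        assert segs.segments == [("high", 0, 3)]

    def test_threshold_equality_counts_as_high(self):
        segs = detect_transitions(eseries([0.28, 0.28, 0.28]), 0.28)
        assert segs.frames_in_state("high") == 3

    def test_invalid_frames_break_no_runs(self):
        vals = [0.6, 0.6, np.nan, 0.1, 0.1, np.nan, 0.1]
        segs = detect_transitions(eseries(vals), 0.28)
        assert segs.transitions == [(3, "high", "low")]
        assert segs.labels[2] == "invalid"
        assert segs.frames_in_state("low") == 3

    def test_all_invalid_gives_empty_segmentation(self):
        segs = detect_transitions(eseries([np.nan, np.nan]), 0.28)
        assert segs.segments == []
        assert segs.transitions == []

    def test_calls_match_ground_truth_on_simulated_traces(self, photo):
        """Transition calls land within persistence x frame_dt of the true
        state-change times for well-separated states at noise SD ~0.1."""
        from licfret.fret import compute_efret, default_total_floor
        from licfret.schemes import default_scheme
        from licfret.simulate import render_traces, simulate_path
        scheme = default_scheme("MCM_51")
        frame_dt, persistence = 0.25, 2
        checked = 0
        for seed in range(30):
            path = simulate_path(scheme, 60.0, seed=seed)
            t_dep = path.first_entry("OCCM_deposited")
            if t_dep is None:
                continue
            tr = render_traces(path, None, scheme, photo, "simultaneous",
                               frame_dt, seed=seed) \
                if not any(s in scheme.sliding_states
                           for s, _, _ in path.intervals) else None
            if tr is None:
                continue
            es = compute_efret(tr, default_total_floor(photo.background_sd))
            segs = detect_transitions(es, 0.335, persistence)
            ups = [f for f, o, n in segs.transitions if n == "high"]
            if not ups:
                continue
            checked += 1
            t_call = (ups[0] + 0.5) * frame_dt
            assert abs(t_call - t_dep) <= 2 * persistence * frame_dt
        assert checked >= 5


class TestPeaksAndFlags:
    def test_two_separated_runs_are_two_peaks(self):
        es = eseries([0.1, 0.6, 0.6, 0.1, 0.1, 0.7, 0.7, 0.7, 0.1])
        assert detect_peaks(es, 0.28) == [(1, 2), (5, 7)]

    def test_short_run_is_not_a_peak(self):
        es = eseries([0.1, 0.6, 0.1, 0.1])
        assert detect_peaks(es, 0.28) == []

    def test_always_low_molecule_flagged(self):
        assert flag_nonspecific(eseries([0.1, 0.2, 0.15, 0.1]), 0.28)

    def test_one_persistent_high_run_not_flagged(self):
        assert not flag_nonspecific(eseries([0.1, 0.6, 0.6, 0.1]), 0.28)

    def test_no_valid_frames_rejected(self):
        with pytest.raises(ValueError):
            flag_nonspecific(eseries([np.nan]), 0.28)

    def test_flagged_fraction_matches_generated_nonspecific_rate(self, photo):
        from licfret.analysis import orc_release_analysis
        from licfret.simulate import DatasetConfig, simulate_dataset
        cfg = DatasetConfig(variant="ORC_only", n_molecules=200,
                            tmax_s=600.0, frame_dt_s=1.0,
                            protocol="continuous_green", seed=13,
                            photophysics=photo, nonspecific_fraction=0.1)
        traces, events = simulate_dataset(cfg)
        res = orc_release_analysis(traces, photo)
        total = res["n_molecules"] + res["n_flagged_nonspecific"]
        flagged = res["n_flagged_nonspecific"] / total
        true_rate = events.nonspecific.mean()
        assert abs(flagged - true_rate) < 0.05


class TestStateLabels:
    def test_raw_labels_keep_single_frame_excursions(self):
        labels = state_labels(eseries([0.6, 0.6, 0.1, 0.6]), 0.28)
        assert list(labels) == ["high", "high", "low", "high"]

    def test_extension_fills_unusable_frames_within_dwell(self):
        es = eseries([0.6, np.nan, 0.6, np.nan], frame_dt=1.0)
        labels = state_labels(es, 0.28, extend_mask=np.array([1, 1, 1, 0],
                                                            bool))
        assert list(labels) == ["high", "high", "high", "invalid"]
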