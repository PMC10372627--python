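import numpy as np
import pytest

from licfret.schemes import KineticScheme, default_scheme
from licfret.simulate import (
    DatasetConfig, Photophysics, efret_from_distance, render_traces,
    simulate_dataset, simulate_path, simulate_sliding,
)

TWO_STATE = KineticScheme(
    variant_id="toy", states=("a", "b"),
    rates={("a", "b"): 1.0, ("b", "a"): 1.0},
    efret_map={"a": 0.6, "b": 0.1}, initial_state="a",
    unbound_states=frozenset())


class TestGillespie:
    def test_no_transitions_gives_single_interval(self):
        s = KineticScheme(variant_id="frozen", states=("a",), rates={},
                          efret_map={}, initial_state="a",
                          unbound_states=frozenset())
        path = simulate_path(s, 100.0, seed=1)
        assert path.intervals == (("a", 0.0, 100.0),)

    def test_same_seed_identical_paths(self):
        p1 = simulate_path(TWO_STATE, 500.0, seed=7)
        p2 = simulate_path(TWO_STATE, 500.0, seed=7)
        assert p1.intervals == p2.intervals

    def test_intervals_contiguous_and_cover_range(self):
        path = simulate_path(TWO_STATE, 200.0, seed=3)
        assert path.intervals[0][1] == 0.0
        assert path.intervals[-1][2] == 200.0
        for (_, _, e0), (_, s1, _) in zip(path.intervals, path.intervals[1:]):
            assert e0 == s1

    def test_symmetric_two_state_occupancy_matches_closed_form(self):
        """Long-run occupancy of each state vs the stationary solution,
        within 3 Monte-Carlo SDs."""
        pi = TWO_STATE.stationary_distribution()
        occs = []
        for seed in range(40):
            occ = simulate_path(TWO_STATE, 500.0, seed=seed).occupancy()
            occs.append(occ.get("a", 0.0) / 500.0)
        occs = np.asarray(occs)
        mc_sd = occs.std(ddof=1) / np.sqrt(len(occs))
        assert abs(occs.mean() - pi["a"]) < 3 * mc_sd


class TestSliding:
    def test_zero_diffusion_constant_position(self):
        walk = simulate_sliding(10.0, 0.0, (-100, 100), 0.1, 5.0, seed=0)
        assert np.all(walk.positions == 10.0)

    def test_msd_matches_2dt(self):
        """Ensemble MSD of the unconstrained walk equals 2 D t."""
        d, t, dt = 100.0, 5.0, 0.05
        disp = []
        for seed in range(800):
            w = simulate_sliding(0.0, d, (-1e7, 1e7), dt, t, seed=seed)
            disp.append(w.positions[-1])
        disp = np.asarray(disp)
        msd = (disp**2).mean()
        se = (disp**2).std(ddof=1) / np.sqrt(len(disp))
        assert abs(msd - 2 * d * t) < 3 * se
        assert abs(disp.mean()) < 3 * disp.std() / np.sqrt(len(disp))

    @pytest.mark.parametrize("seed", [0, 5, 17])
    def test_positions_stay_within_bounds(self, seed):
        w = simulate_sliding(5.0, 500.0, (-10.0, 20.0), 0.1, 50.0, seed=seed)
        assert w.positions.min() >= -10.0
        assert w.positions.max() <= 20.0

    def test_start_outside_bounds_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            simulate_sliding(50.0, 1.0, (-10, 10), 0.1, 1.0, seed=0)


class TestForster:
    def test_closed_form_values(self):
        assert efret_from_distance(6.0, 6.0) == pytest.approx(0.5)
        assert efret_from_distance(0.0, 6.0) == pytest.approx(1.0)
        assert efret_from_distance(12.0, 6.0) == pytest.approx(1 / 65)

    def test_distant_dye_gives_negligible_transfer(self):
        # >10 nm separation is effectively dark for R0 = 6 nm
        assert efret_from_distance(10.5, 6.0) < 0.04


class TestRender:
    def test_noiseless_bent_state_efret_exact(self):
        scheme = default_scheme("ORC_only")
        path = simulate_path(scheme, 400.0, seed=2)
        photo = Photophysics(background_sd=0.0, bleach_rate_donor=0.0,
                             bleach_rate_acceptor=0.0)
        tr = render_traces(path, None, scheme, photo, "continuous_green",
                           1.0, seed=0)
        dem = tr.channels[("Dex", "Dem")]
        aem = tr.channels[("Dex", "Aem")]
        # frames fully inside the bent state read exactly E = 0.62
        for state, a, b in path.intervals:
            if state != "ORC_bent":
                continue
            f0, f1 = int(np.ceil(a)), int(np.floor(b))
            if f1 - f0 < 1:
                continue
            e = aem[f0:f1] / (dem[f0:f1] + aem[f0:f1])
            assert np.allclose(e, 0.62)

    def test_quencher_variant_scales_donor_only(self):
        scheme = default_scheme("OCCM_quench")
        path = simulate_path(scheme, 200.0, seed=5)
        photo = Photophysics(background_sd=0.0, bleach_rate_donor=0.0,
                             bleach_rate_acceptor=0.0)
        tr = render_traces(path, None, scheme, photo, "simultaneous", 0.25,
                           seed=0)
        assert ("Dex", "Aem") not in tr.channels
        donor = tr.channels[("Dex", "Dem")]
        q = scheme.quench_map["ORC_bent"]
        for state, a, b in path.intervals:
            f0, f1 = int(np.ceil(a / 0.25)), int(np.floor(b / 0.25))
            if f1 - f0 < 1:
                continue
            seg = donor[f0:f1]
            if state in ("ORC_bent", "OCCM_bent"):
                assert np.allclose(seg, photo.donor_brightness * (1 - q))
            elif state in ("OCCM_unbent", "OCCM_deposited"):
                assert np.allclose(seg, photo.donor_brightness)

    def test_acceptor_bleach_drops_fret_channel_to_background(self):
        scheme = default_scheme("ORC_only")
        path = simulate_path(scheme, 400.0, seed=2)
        photo = Photophysics(background_sd=0.0, bleach_rate_donor=0.0,
                             bleach_rate_acceptor=0.05)
        tr = render_traces(path, None, scheme, photo, "continuous_green",
                           1.0, seed=3)
        aem = tr.channels[("Dex", "Aem")]
        dead = ~tr.valid_mask & tr.colocalized_mask
        if dead.any():
            assert np.allclose(aem[dead], 0.0)


class TestDataset:
    def test_molecule_count(self, photo):
        cfg = DatasetConfig(variant="ORC_only", n_molecules=10, tmax_s=50.0,
                            frame_dt_s=1.0, seed=0, photophysics=photo)
        traces, events = simulate_dataset(cfg)
        assert len(traces) == 10
        assert len(events) == 10

    def test_nonpositive_molecule_count_rejected(self):
        with pytest.raises(ValueError):
            DatasetConfig(variant="ORC_only", n_molecules=0, tmax_s=10.0,
                          frame_dt_s=1.0)

    def test_bit_reproducible_from_master_seed(self, photo):
        cfg = DatasetConfig(variant="MCM_51", n_molecules=5, tmax_s=100.0,
                            frame_dt_s=0.25, seed=9, photophysics=photo)
        t1, e1 = simulate_dataset(cfg)
        t2, e2 = simulate_dataset(cfg)
        for a, b in zip(t1, t2):
            for pair in a.channels:
                assert np.array_equal(a.channels[pair], b.channels[pair])
        assert e1.equals(e2)

    def test_wt_ground_truth_event_ordering(self, mcm_dataset):
        """Pathway order: arrival < unbending <= deposition < Cdc6 release
        < sliding onset < Cdt1 release, in every molecule where observed."""
        _, events = mcm_dataset
        order = ["t_mcm_arrival", "t_unbend", "t_deposit", "t_cdc6_release",
                 "t_slide_onset", "t_cdt1_release"]
        for _, row in events.iterrows():
            times = [row[c] for c in order]
            observed = [t for t in times if np.isfinite(t)]
            assert observed == sorted(observed)
            # censoring is suffix-only: once an event is missing, all
            # downstream events are missing too
            flags = [np.isfinite(t) for t in times]
            assert flags == sorted(flags, reverse=True)

    def test_mean_unbending_delay_near_generating_value(self, photo):
        cfg = DatasetConfig(variant="MCM_51", n_molecules=150, tmax_s=150.0,
                            frame_dt_s=0.25, seed=4, photophysics=photo)
        _, events = simulate_dataset(cfg)
        delays = (events.t_unbend - events.t_mcm_arrival).dropna()
        sem = delays.std() / np.sqrt(len(delays))
        assert abs(delays.mean() - 3.9) < 3 * sem

    def test_unbending_precedes_cdc6_release(self, mcm_dataset):
        _, events = mcm_dataset
        both = events.dropna(subset=["t_unbend", "t_cdc6_release"])
        assert (both.t_unbend < both.t_cdc6_release).all()
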