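"""Stochastic simulator of origin-licensing fluorescence trajectories.

The generator works in three layers.  An exact event-driven (Gillespie)
simulation of a :class:`~licfret.schemes.KineticScheme` produces a
continuous-time state path, so the ground truth carries no discretization
bias.  If the path visits a sliding-capable state, an unbiased reflected
random walk supplies the complex position on the DNA, and the dye-pair
distance sets the instantaneous FRET efficiency through the Förster
sixth-power law.  Finally the renderer integrates state occupancy over
camera frames, applies single-step photobleaching and additive Gaussian
background noise, and emits a :class:`~licfret.traces.FluorTrace` per
molecule together with a ground-truth event table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .schemes import KineticScheme, default_scheme
from .traces import FluorTrace

__all__ = [
    "StatePath", "PositionSeries", "Photophysics", "DatasetConfig",
    "simulate_path", "simulate_sliding", "efret_from_distance",
    "dye_pair_distance", "render_traces", "simulate_dataset",
    "EVENT_COLUMNS",
]

EVENT_COLUMNS = [
    "t_orc_arrival", "t_mcm_arrival", "t_unbend", "t_deposit",
    "t_cdc6_release", "t_cdt1_release", "t_slide_onset", "t_off",
]


@dataclass(frozen=True)
class StatePath:
    """Contiguous (state, start, end) intervals covering [0, tmax]."""

    intervals: tuple[tuple[str, float, float], ...]
    seed: int

    @property
    def tmax(self) -> float:
        return self.intervals[-1][2]

    def state_at(self, t: float) -> str:
        for s, a, b in self.intervals:
            if a <= t < b:
                return s
        return self.intervals[-1][0]

    def first_entry(self, state: str) -> float | None:
        for s, a, _ in self.intervals:
            if s == state:
                return a
        return None

    def occupancy(self) -> dict[str, float]:
        """Total time spent in each state."""
        occ: dict[str, float] = {}
        for s, a, b in self.intervals:
            occ[s] = occ.get(s, 0.0) + (b - a)
        return occ


@dataclass(frozen=True)
class PositionSeries:
    """Sliding positions (bp relative to the first ACS base) on a time grid."""

    times: np.ndarray
    positions: np.ndarray
    diffusion_coeff: float
    bounds: tuple[float, float]

    def at(self, t) -> np.ndarray:
        """Piecewise-constant lookup (positions are samples every dt)."""
        return np.interp(t, self.times, self.positions)


@dataclass(frozen=True)
class Photophysics:
    """Brightness, background and bleaching parameters of one dye pair.

    Brightnesses are total counts/frame at frame_dt = 1 s scale-free: the
    renderer treats them as counts per frame regardless of frame_dt, which
    mimics adjusting exposure with the acquisition rate.
    """

    donor_brightness: float = 1000.0
    acceptor_brightness: float = 800.0
    background_mean: float = 0.0
    background_sd: float = 140.0
    bleach_rate_donor: float = 1e-4
    bleach_rate_acceptor: float = 1e-4
    forster_radius: float = 6.0
    bp_to_nm: float = 0.34

    def __post_init__(self):
        if self.donor_brightness <= 0 or self.acceptor_brightness <= 0:
            raise ValueError("brightnesses must be positive")
        if self.bleach_rate_donor < 0 or self.bleach_rate_acceptor < 0:
            raise ValueError("bleach rates must be nonnegative")


def simulate_path(scheme: KineticScheme, tmax: float, seed: int) -> StatePath:
    """Exact continuous-time Markov trajectory of one molecule.

    A scheme with no transitions out of the current state yields a single
    full-length interval.  Identical seeds give identical paths.
    """
    if tmax <= 0:
        raise ValueError("tmax must be positive")
    rng = np.random.default_rng(seed)
    t = 0.0
    state = scheme.initial_state
    intervals: list[tuple[str, float, float]] = []
    while t < tmax:
        outs = scheme.out_rates(state)
        total = sum(k for _, k in outs)
        if total == 0.0:
            intervals.append((state, t, tmax))
            break
        dwell = rng.exponential(1.0 / total)
        t_next = t + dwell
        if t_next >= tmax:
            intervals.append((state, t, tmax))
            break
        probs = np.array([k for _, k in outs]) / total
        nxt = outs[rng.choice(len(outs), p=probs)][0]
        intervals.append((state, t, t_next))
        state, t = nxt, t_next
    return StatePath(intervals=tuple(intervals), seed=seed)


def simulate_sliding(start_pos: float, diffusion_coeff: float,
                     bounds: tuple[float, float], dt: float, duration: float,
                     seed: int) -> PositionSeries:
    """Unbiased reflected random walk sampled every ``dt`` seconds.

    Gaussian steps of SD sqrt(2 D dt) are folded back at the bounds, so the
    walk has zero mean displacement and MSD = 2 D t while unconstrained.
    """
    lo, hi = bounds
    if not lo <= start_pos <= hi:
        raise ValueError(f"start position {start_pos} outside bounds {bounds}")
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = max(1, int(np.ceil(duration / dt)))
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, np.sqrt(2.0 * diffusion_coeff * dt), size=n)
    pos = np.empty(n + 1)
    pos[0] = start_pos
    pos[1:] = start_pos + np.cumsum(steps)
    # fold trajectory back into [lo, hi] (exact for reflecting boundaries)
    width = hi - lo
    if width > 0:
        p = np.mod(pos - lo, 2 * width)
        pos = lo + np.where(p <= width, p, 2 * width - p)
    else:
        pos[:] = lo
    times = np.arange(n + 1) * dt
    return PositionSeries(times=times, positions=pos,
                          diffusion_coeff=diffusion_coeff, bounds=bounds)


def efret_from_distance(r, forster_radius: float):
    """Förster transfer efficiency 1 / (1 + (r/R0)^6)."""
    if forster_radius <= 0:
        raise ValueError("forster_radius must be positive")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be nonnegative")
    out = 1.0 / (1.0 + (r / forster_radius) ** 6)
    return float(out) if out.ndim == 0 else out


def dye_pair_distance(protein_bp, dye_bp: float, axial_offset_nm: float = 2.0,
                      bp_to_nm: float = 0.34):
    """Distance between a protein label and a DNA dye on straight DNA.

    The in-axis separation is |protein - dye| bp at 0.34 nm/bp; the label's
    offset from its DNA contact point is added in quadrature.
    """
    lateral = np.abs(np.asarray(protein_bp, dtype=float) - dye_bp) * bp_to_nm
    return np.sqrt(lateral**2 + axial_offset_nm**2)


def _frame_overlap(a: float, b: float, n_frames: int, frame_dt: float):
    """Fraction of each frame covered by the interval [a, b)."""
    edges = np.arange(n_frames + 1) * frame_dt
    lo = np.clip(a, edges[:-1], edges[1:])
    hi = np.clip(b, edges[:-1], edges[1:])
    return np.maximum(hi - lo, 0.0) / frame_dt


def _sliding_efret_per_frame(scheme: KineticScheme, positions: PositionSeries,
                             n_frames: int, frame_dt: float,
                             weights: np.ndarray) -> np.ndarray:
    """Occupancy-weighted mean E over sliding sub-samples in each frame.

    ``weights`` is the per-frame fraction of time in sliding states; the
    returned array already includes that weight.
    """
    out = np.zeros(n_frames)
    if positions is None or not weights.any():
        return out
    prot = positions.positions + scheme.protein_offset_bp
    r = dye_pair_distance(prot, scheme.dye_position_bp,
                          axial_offset_nm=scheme.axial_offset_nm,
                          bp_to_nm=scheme.bp_to_nm)
    e = efret_from_distance(r, scheme.forster_radius_nm)
    frames = np.minimum((positions.times / frame_dt).astype(int), n_frames - 1)
    keep = positions.times < n_frames * frame_dt
    sums = np.bincount(frames[keep], weights=e[keep], minlength=n_frames)
    counts = np.bincount(frames[keep], minlength=n_frames)
    mean_e = np.divide(sums, counts, out=np.zeros(n_frames),
                       where=counts > 0)
    return mean_e * weights


def render_traces(path: StatePath, positions: PositionSeries | None,
                  scheme: KineticScheme, photo: Photophysics, protocol: str,
                  frame_dt: float, seed: int,
                  molecule_id: str = "mol") -> FluorTrace:
    """Turn a state path (+ sliding positions) into a noisy camera trace.

    Per-frame intensities integrate state occupancy over the frame.  Donor
    emission splits between donor and acceptor channels according to each
    state's E_FRET (quencher variants instead scale donor emission by
    1 - quench factor and carry no FRET acceptor channel).  Photobleaching
    is single-step; Gaussian background noise is added per channel.
    """
    if frame_dt <= 0:
        raise ValueError("frame_dt must be positive")
    if protocol not in ("continuous_green", "simultaneous", "alternating"):
        raise ValueError(f"unknown protocol {protocol!r}")
    sliding_visited = any(s in scheme.sliding_states
                          for s, _, _ in path.intervals)
    if sliding_visited and positions is None:
        raise ValueError("positions required for sliding-capable states")

    rng = np.random.default_rng(seed)
    n_frames = int(round(path.tmax / frame_dt))
    quench_variant = bool(scheme.quench_map)

    bound_frac = np.zeros(n_frames)
    donor_emit = np.zeros(n_frames)   # occupancy-weighted (1-q)(1-E)
    fret_emit = np.zeros(n_frames)    # occupancy-weighted (1-q)E
    slide_frac = np.zeros(n_frames)

    for state, a, b in path.intervals:
        if not scheme.is_bound(state):
            continue
        w = _frame_overlap(a, b, n_frames, frame_dt)
        bound_frac += w
        q = scheme.quench_map.get(state, 0.0)
        if state in scheme.sliding_states:
            slide_frac += w * (1.0 - q)
        else:
            e = scheme.efret_map.get(state, 0.0)
            donor_emit += w * (1.0 - q) * (1.0 - e)
            fret_emit += w * (1.0 - q) * e
    if sliding_visited:
        e_slide = _sliding_efret_per_frame(scheme, positions, n_frames,
                                           frame_dt, slide_frac)
        donor_emit += slide_frac - e_slide
        fret_emit += e_slide

    # single-step photobleaching: exponential waiting times; the donor clock
    # starts when its protein first arrives, the DNA acceptor clock at t=0
    arrivals = [a for s, a, _ in path.intervals if scheme.is_bound(s)]
    t_arrive = arrivals[0] if arrivals else path.tmax
    t_bleach_d = t_arrive + _bleach_time(rng, photo.bleach_rate_donor)
    t_bleach_a = _bleach_time(rng, photo.bleach_rate_acceptor)
    frame_mid = (np.arange(n_frames) + 0.5) * frame_dt
    donor_alive = frame_mid < t_bleach_d
    acceptor_alive = frame_mid < t_bleach_a

    bd = photo.donor_brightness
    channels: dict[tuple[str, str], np.ndarray] = {}
    channels[("Dex", "Dem")] = bd * donor_emit * donor_alive
    if quench_variant:
        # red-excited Mcm2-7 label reports its own DNA association
        mcm_frac = np.zeros(n_frames)
        for state, a, b in path.intervals:
            if state.startswith("OCCM"):
                mcm_frac += _frame_overlap(a, b, n_frames, frame_dt)
        channels[("Aex", "Aem")] = (photo.acceptor_brightness * mcm_frac
                                    * acceptor_alive)
        valid = donor_alive
    else:
        channels[("Dex", "Aem")] = bd * fret_emit * acceptor_alive
        channels[("Aex", "Aem")] = (photo.acceptor_brightness
                                    * acceptor_alive.astype(float))
        valid = donor_alive & acceptor_alive

    for pair in channels:
        noise = rng.normal(photo.background_mean, photo.background_sd,
                           size=n_frames)
        channels[pair] = channels[pair] + noise

    return FluorTrace(
        molecule_id=molecule_id,
        frame_dt=frame_dt,
        protocol=protocol,
        channels=channels,
        valid_mask=valid,
        colocalized_mask=bound_frac > 0.5,
        meta={"seed": seed, "variant": scheme.variant_id},
    )


def _bleach_time(rng, rate: float) -> float:
    return rng.exponential(1.0 / rate) if rate > 0 else np.inf


def events_from_path(path: StatePath, scheme: KineticScheme) -> dict:
    """Ground-truth event times (s) for one molecule; NaN = did not occur."""
    row = {c: np.nan for c in EVENT_COLUMNS}
    for event, state in scheme.event_states.items():
        t = path.first_entry(state)
        if t is not None:
            row[f"t_{event}"] = t
    deposited = scheme.event_states.get("deposit")
    row["salt_stable"] = bool(deposited
                              and path.first_entry(deposited) is not None)
    return row


@dataclass(frozen=True)
class DatasetConfig:
    """Configuration of one simulated experiment."""

    variant: str
    n_molecules: int
    tmax_s: float
    frame_dt_s: float
    protocol: str = "simultaneous"
    seed: int = 0
    photophysics: Photophysics = field(default_factory=Photophysics)
    nonspecific_fraction: float = 0.0
    sliding_dt_s: float | None = None  # default frame_dt / 4

    def __post_init__(self):
        if self.n_molecules <= 0:
            raise ValueError("n_molecules must be positive")
        if self.tmax_s <= 0 or self.frame_dt_s <= 0:
            raise ValueError("tmax_s and frame_dt_s must be positive")


def simulate_dataset(config: DatasetConfig,
                     scheme: KineticScheme | None = None):
    """Simulate a whole experiment: traces plus ground-truth event table.

    Returns ``(traces, events)`` where ``events`` is a DataFrame with one
    row per molecule (event times in s, NaN = censored at experiment end)
    and a ``salt_stable`` flag for productive loading.  A ``nonspecific``
    column marks molecules drawn as nonspecific binders (no high-FRET state;
    emulated by swapping the bent-state E for the unbent one).
    Bit-reproducible for a fixed master seed.
    """
    if scheme is None:
        scheme = default_scheme(config.variant)
    master = np.random.SeedSequence(config.seed)
    per_mol = master.spawn(config.n_molecules)
    ns_rng = np.random.default_rng(master.spawn(1)[0])
    nonspecific = ns_rng.random(config.n_molecules) < config.nonspecific_fraction

    traces, rows = [], []
    slide_dt = config.sliding_dt_s or config.frame_dt_s / 4.0
    for i, ss in enumerate(per_mol):
        child = np.random.default_rng(ss)
        seeds = child.integers(0, 2**31 - 1, size=3)
        mol_scheme = scheme
        if nonspecific[i]:
            mol_scheme = _nonspecific_variant(scheme)
        path = simulate_path(mol_scheme, config.tmax_s, int(seeds[0]))
        positions = _positions_for_path(path, mol_scheme, slide_dt,
                                        int(seeds[1]))
        trace = render_traces(path, positions, mol_scheme,
                              config.photophysics, config.protocol,
                              config.frame_dt_s, int(seeds[2]),
                              molecule_id=f"{config.variant}_{i:04d}")
        row = events_from_path(path, mol_scheme)
        row["molecule_id"] = trace.molecule_id
        row["tmax_s"] = config.tmax_s
        row["nonspecific"] = bool(nonspecific[i])
        rows.append(row)
        traces.append(trace)
    events = pd.DataFrame(rows).set_index("molecule_id")
    return traces, events


def _positions_for_path(path: StatePath, scheme: KineticScheme,
                        dt: float, seed: int) -> PositionSeries | None:
    """Sliding positions spanning the sliding portion of the path.

    The series is simulated on the absolute time grid from the first entry
    into a sliding state to the end of the path, so frame lookup is direct.
    """
    starts = [a for s, a, _ in path.intervals if s in scheme.sliding_states]
    if not starts:
        return None
    t0 = starts[0]
    walk = simulate_sliding(scheme.deposit_position_bp, scheme.diffusion_coeff,
                            scheme.bounds, dt, path.tmax - t0, seed)
    return PositionSeries(times=walk.times + t0, positions=walk.positions,
                          diffusion_coeff=walk.diffusion_coeff,
                          bounds=walk.bounds)


def _nonspecific_variant(scheme: KineticScheme) -> KineticScheme:
    """Nonspecifically bound molecules never reach the high-FRET state."""
    if not scheme.efret_map:
        return scheme
    low = min(scheme.efret_map.values())
    return replace(scheme, efret_map={s: low for s in scheme.efret_map})
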