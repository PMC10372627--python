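"""Figure-class analyses combining the lower-level building blocks.

Each function here mirrors one experiment class end to end on a set of
traces: ORC dissociation kinetics per bending state, unquenching delays,
deposition delays, sliding-onset calls and their ordering against labeled
Cdc6/Cdt1 departures.  They are the units the pipeline recipes, the
acceptance checks, and parameter-recovery tests all share.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import kinetics, ordering, segmentation
from .fret import (compute_efret, default_total_floor,
                   noise_scale as fret_noise_scale, unquench_series)
from .simulate import DatasetConfig, simulate_dataset

__all__ = [
    "eseries_for", "orc_release_analysis", "unbending_delays",
    "deposition_delays", "call_sliding_onsets", "cdc6_sliding_ordering",
    "snap_to_frames",
]

ORC_THRESHOLD = 0.28  # trough threshold of the bent/unbent dye pair


def eseries_for(traces, photo):
    """E_FRET series per trace with the default total-emission floor."""
    floor = default_total_floor(photo.background_sd)
    return [compute_efret(t, total_floor=floor) for t in traces]


def snap_to_frames(times, frame_dt: float):
    """Quantize event times to the mid-time of their containing frame."""
    t = np.asarray(times, dtype=float)
    return np.floor(t / frame_dt) * frame_dt + 0.5 * frame_dt


def orc_release_analysis(traces, photo, threshold: float = ORC_THRESHOLD,
                         persistence: int = 2,
                         nonspecific_persistence: int = 4) -> dict:
    """Per-state apparent release rates of ORC from its E_FRET states.

    Excludes molecules that never reach the high state (nonspecific
    binders), labels every remaining frame by raw threshold (each frame's
    own E_FRET decides its state; frames whose E_FRET is individually
    unusable inherit the previous label so the whole dwell is counted),
    assigns each release event to the state of the last labeled frame
    before departure, and pools frames and events across molecules.
    """
    frame_dt = traces[0].frame_dt
    pooled, n_flagged, n_used = [], 0, 0
    pooled_values = []
    for trace in traces:
        es = compute_efret(trace,
                           total_floor=default_total_floor(photo.background_sd))
        if not es.valid_mask.any():
            continue
        # the nonspecific screen asks for a longer high run than transition
        # timing does: it classifies molecules, so a couple of noise-flipped
        # frames must not rescue a binder that was never genuinely bent
        if segmentation.flag_nonspecific(es, threshold,
                                         nonspecific_persistence):
            n_flagged += 1
            continue
        n_used += 1
        labels = segmentation.state_labels(
            es, threshold,
            extend_mask=trace.valid_mask & trace.colocalized_mask)
        pooled.append((labels, kinetics.release_event_frame(trace)))
        pooled_values.append(es.valid_values())
    if not pooled:
        raise ValueError("no analyzable molecules")
    rates = kinetics.per_state_release_frequency(pooled, frame_dt)
    fractions = kinetics.time_in_state_fraction([s for s, _ in pooled])
    return {
        "rates": rates,
        "aggregate_rate": kinetics.aggregate_release_rate(rates, frame_dt),
        "state_fractions": fractions,
        "n_molecules": n_used,
        "n_flagged_nonspecific": n_flagged,
        "efret_values": np.concatenate(pooled_values),
    }


def unbending_delays(traces, events: pd.DataFrame, factor: float = 2.0):
    """Called (unquench - Mcm2-7 arrival) intervals on quencher-DNA traces.

    Mcm2-7 arrival comes from the red-excited channel appearance (frame
    quantized); the unbending call is the first unquenching step candidate
    after arrival.  Molecules without an arrival or without a post-arrival
    candidate are dropped (the latter counted as censored-at-end).
    """
    intervals, censored = [], []
    for trace in traces:
        t_arr = _mcm_arrival_from_red(trace)
        if t_arr is None:
            continue
        _, cands = unquench_series(trace, factor=factor)
        t_cands = (cands + 0.5) * trace.frame_dt
        after = t_cands[t_cands >= t_arr]
        if len(after):
            intervals.append(after[0] - t_arr)
            censored.append(False)
        else:
            last_valid = np.flatnonzero(trace.valid_mask
                                        & trace.colocalized_mask)
            if len(last_valid):
                intervals.append((last_valid[-1] + 0.5) * trace.frame_dt
                                 - t_arr)
                censored.append(True)
    return np.asarray(intervals), np.asarray(censored, dtype=bool)


def _mcm_arrival_from_red(trace) -> float | None:
    """First persistent appearance of the red-excited Mcm2-7 signal."""
    red = trace.channels.get(("Aex", "Aem"))
    if red is None:
        return None
    ok = trace.valid_mask
    if ok.sum() < 4:
        return None
    scale = fret_noise_scale(red[ok])
    hi = np.percentile(red[ok], 90)
    if hi < 4 * scale:
        return None  # red channel never rises above background
    above = (red >= 0.5 * hi) & ok
    for k in range(len(above) - 1):
        if above[k] and above[k + 1]:
            return (k + 0.5) * trace.frame_dt
    return None


def deposition_delays(traces, events: pd.DataFrame, photo,
                      threshold: float, persistence: int = 2):
    """Called (deposition - Mcm2-7 arrival) intervals on MCM-FRET traces.

    Arrival is the first colocalized frame (the donor rides on Mcm2-7);
    deposition is the first low-to-high transition at or after arrival.
    """
    intervals, censored = [], []
    for es, trace in zip(eseries_for(traces, photo), traces):
        coloc = np.flatnonzero(trace.colocalized_mask)
        if len(coloc) == 0:
            continue
        t_arr = (coloc[0] + 0.5) * trace.frame_dt
        if not es.valid_mask.any():
            continue
        segs = segmentation.detect_transitions(es, threshold, persistence)
        # deposition call = first frame labeled high at/after arrival (the
        # up-transition frame for most molecules; the first valid frame for
        # a molecule that deposited within its first frames)
        high_frames = np.flatnonzero(segs.labels == "high")
        high_frames = high_frames[(high_frames + 0.5) * trace.frame_dt
                                  >= t_arr]
        if len(high_frames):
            intervals.append((high_frames[0] + 0.5) * trace.frame_dt - t_arr)
            censored.append(False)
        else:
            last = np.flatnonzero(es.valid_mask)[-1]
            intervals.append((last + 0.5) * trace.frame_dt - t_arr)
            censored.append(True)
    return np.asarray(intervals), np.asarray(censored, dtype=bool)


def call_sliding_onsets(traces, photo, threshold: float,
                        persistence: int = 2) -> pd.Series:
    """Sliding-onset call per molecule: first persistent E_FRET decrease.

    The onset is the first high-to-low transition following the first
    entry into the high (deposited) state; molecules that never reach the
    high state or never leave it get NaN.
    """
    calls = {}
    for es, trace in zip(eseries_for(traces, photo), traces):
        calls[trace.molecule_id] = np.nan
        if not es.valid_mask.any():
            continue
        segs = segmentation.detect_transitions(es, threshold, persistence)
        seen_high = segs.labels[np.flatnonzero(es.valid_mask)[0]] == "high"
        for f, old, new in segs.transitions:
            if old == "low" and new == "high":
                seen_high = True
            elif seen_high and old == "high" and new == "low":
                calls[trace.molecule_id] = (f + 0.5) * trace.frame_dt
                break
    return pd.Series(calls, name="t_slide_call")


def cdc6_sliding_ordering(traces, events: pd.DataFrame, photo,
                          threshold: float, ref: str = "t_cdc6_release",
                          persistence: int = 2) -> ordering.SignedIntervals:
    """Signed intervals from a labeled release event to the sliding call.

    The reference release time comes from the red-excited label's ground
    truth, quantized to the frame grid; the sliding onset is called from
    the E_FRET decrease.  Positive intervals mean the release preceded the
    E_FRET decrease.
    """
    frame_dt = traces[0].frame_dt
    calls = call_sliding_onsets(traces, photo, threshold, persistence)
    table = events.copy()
    table = table.join(calls)
    table["_ref_snapped"] = snap_to_frames(table[ref], frame_dt)
    return ordering.signed_intervals(table, "_ref_snapped", "t_slide_call")
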