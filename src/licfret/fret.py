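"""Effective FRET efficiency series and donor-unquenching detection.

E_FRET here is the *effective* (apparent) efficiency A_em/(D_em + A_em)
under donor excitation — no gamma or crosstalk correction is applied, since
the state assignments and kinetics downstream only require a consistent
ratiometric observable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traces import FluorTrace

__all__ = ["ESeries", "compute_efret", "unquench_series", "default_total_floor"]


@dataclass
class ESeries:
    """Per-frame effective FRET efficiency with a validity mask."""

    efret: np.ndarray
    total: np.ndarray
    valid_mask: np.ndarray
    frame_dt: float
    molecule_id: str = ""

    @property
    def times(self) -> np.ndarray:
        return (np.arange(len(self.efret)) + 0.5) * self.frame_dt

    def valid_values(self) -> np.ndarray:
        return self.efret[self.valid_mask]


def default_total_floor(background_sd: float) -> float:
    """Total-emission floor below which E_FRET is meaningless noise.

    Three background SDs suppresses unbounded ratios when both dyes are
    dark (dark frames are additionally gated by the colocalization mask)
    while keeping the floor well below the total emission of a bound
    molecule.  A higher floor silently conditions the kept frames on
    upward total-noise fluctuations, which biases E_FRET upward in
    low-efficiency states and thins dwell denominators.
    """
    return 3.0 * background_sd


def compute_efret(trace: FluorTrace, total_floor: float = 0.0) -> ESeries:
    """E_FRET = A_em / (D_em + A_em) per donor-excited frame.

    Frames failing any of (total >= total_floor, colocalized, valid) are
    invalid; values are clipped into [0, 1] (background subtraction can
    push individual channels slightly negative).
    """
    trace.require_channels([("Dex", "Dem"), ("Dex", "Aem")])
    dem = trace.channels[("Dex", "Dem")]
    aem = trace.channels[("Dex", "Aem")]
    total = dem + aem
    valid = (trace.valid_mask & trace.colocalized_mask
             & (total >= total_floor) & (total > 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(valid, aem / total, np.nan)
    e = np.clip(e, 0.0, 1.0)
    return ESeries(efret=e, total=total, valid_mask=valid,
                   frame_dt=trace.frame_dt, molecule_id=trace.molecule_id)


def noise_scale(values: np.ndarray) -> float:
    """Robust per-frame noise SD from median absolute frame differences."""
    d = np.diff(np.asarray(values, dtype=float))
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2))


def unquench_series(trace: FluorTrace, factor: float = 2.0,
                    min_step: float | None = None,
                    confirm_frames: int = 4):
    """Donor-intensity series and step-up (unquenching) candidates.

    A candidate frame ``k`` marks a persistent donor-intensity increase:
    the mean of frames ``k, k+1`` must exceed the mean of frames
    ``k-2, k-1`` by ``factor`` and by an absolute step of at least
    ``min_step`` (default 3x the robust per-frame noise SD), with both new
    frames individually elevated — so a single-frame spike never qualifies.
    The elevated level must persist: the mean of the next
    ``confirm_frames`` valid frames has to stay at least 0.75 * min_step
    above the pre-step level, which rejects transient noise excursions
    (genuine unquenching is a lasting loss of the quencher contact).
    Consecutive qualifying frames collapse to the first.

    Returns ``(donor, candidates)`` with candidates as frame indices.
    """
    if trace.protocol not in ("continuous_green", "simultaneous",
                              "alternating"):
        raise ValueError(f"unknown protocol {trace.protocol!r}")
    donor = trace.channels[("Dex", "Dem")]
    ok = trace.valid_mask & trace.colocalized_mask
    if ok.sum() < 4:
        return donor, np.array([], dtype=int)
    scale = noise_scale(donor[ok])
    if min_step is None:
        min_step = 3.0 * scale
    cands = []
    prev_candidate = False
    for k in range(2, len(donor) - 1):
        if not (ok[k] and ok[k + 1] and ok[k - 1] and ok[k - 2]):
            prev_candidate = False
            continue
        prev = 0.5 * (donor[k - 2] + donor[k - 1])
        nxt = 0.5 * (donor[k] + donor[k + 1])
        is_step = (nxt >= factor * max(prev, scale)
                   and nxt - prev >= min_step
                   and donor[k] >= prev + 0.5 * (nxt - prev)
                   and donor[k + 1] >= prev + 0.5 * (nxt - prev))
        if is_step and confirm_frames > 0:
            post = donor[k:][ok[k:]][:confirm_frames]
            is_step = post.mean() >= prev + 0.75 * min_step
        if is_step and not prev_candidate:
            cands.append(k)
        prev_candidate = is_step
    return donor, np.asarray(cands, dtype=int)
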