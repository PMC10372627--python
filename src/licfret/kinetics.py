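"""Dwell-time, release-rate, survival and interval statistics.

Apparent per-state dissociation rates follow the frame-counting convention
of the single-molecule assay: the state of frame *n* decides which state an
ensuing release (frame *n+1* back at background) is charged to, and the
rate is the number of release events divided by the total time spent in
that state (frames x frame interval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .segmentation import StateSegments
from .traces import FluorTrace

__all__ = [
    "ReleaseRate", "SurvivalCurve", "IntervalStats", "Fraction",
    "release_event_frame", "per_state_release_frequency",
    "aggregate_release_rate",
    "interval_statistics", "time_in_state_fraction", "fraction_outcome",
]


@dataclass
class ReleaseRate:
    """Apparent release rate of one E_FRET state."""

    state: str
    n_events: int
    n_frames: int
    rate: float | None       # s^-1; None when no frames observed
    se: float | None
    upper95: float | None    # one-sided rule-of-three bound when 0 events


@dataclass
class SurvivalCurve:
    times: np.ndarray
    survival: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_at_risk: np.ndarray


@dataclass
class IntervalStats:
    mean: float | None
    sem: float | None
    n_observed: int
    n_censored: int
    survival: SurvivalCurve

    @property
    def cumulative(self) -> np.ndarray:
        return 1.0 - self.survival.survival


@dataclass
class Fraction:
    fraction: float
    se: float
    n: int
    upper95: float | None = None  # rule-of-three bound for 0 successes


def release_event_frame(trace: FluorTrace) -> int | None:
    """Frame index at which the labeled protein released, or None.

    Release is the first frame after the last colocalized frame, provided
    the recording continued (otherwise the dwell is censored at the end)
    and the dyes were still reporting (a bleach-terminated trace is
    censored, not dissociated).
    """
    coloc = np.flatnonzero(trace.colocalized_mask)
    if len(coloc) == 0:
        return None
    last = int(coloc[-1])
    if last == trace.n_frames - 1:
        return None  # still bound at experiment end
    if not trace.valid_mask[last]:
        return None  # dye bleached before departure: censored
    return last + 1


def per_state_release_frequency(molecules, frame_dt: float) -> dict:
    """Per-state apparent release rates pooled over molecules.

    Parameters
    ----------
    molecules : iterable of (labels, release_frame or None)
        Per-frame state labels of each molecule (a label array from
        :func:`~licfret.segmentation.state_labels`, or a
        :class:`~licfret.segmentation.StateSegments`) plus the frame at
        which the protein released (None = censored).  The release event is
        charged to the state of the last labeled frame preceding the
        release frame.
    frame_dt : float
        Frame interval in seconds.

    Returns
    -------
    dict mapping state label ("low"/"high") to :class:`ReleaseRate` with
    rate = events / frames / frame_dt and binomial SE.
    """
    if frame_dt <= 0:
        raise ValueError("frame_dt must be positive")
    frames = {"low": 0, "high": 0}
    events = {"low": 0, "high": 0}
    for labels, release_frame in molecules:
        if isinstance(labels, StateSegments):
            labels = labels.labels
        for label in ("low", "high"):
            frames[label] += int(np.sum(labels == label))
        if release_frame is None:
            continue
        before = labels[:release_frame]
        labeled = np.flatnonzero((before == "low") | (before == "high"))
        if len(labeled) == 0:
            continue
        events[str(before[labeled[-1]])] += 1

    out = {}
    for label in ("low", "high"):
        n_f, n_e = frames[label], events[label]
        if n_f == 0:
            out[label] = ReleaseRate(label, n_e, 0, None, None, None)
            continue
        p = n_e / n_f
        rate = p / frame_dt
        se = np.sqrt(p * (1.0 - p) / n_f) / frame_dt
        upper = 3.0 / n_f / frame_dt if n_e == 0 else None
        out[label] = ReleaseRate(label, n_e, n_f, rate, se, upper)
    return out


def aggregate_release_rate(rates: dict, frame_dt: float) -> float:
    """Overall apparent release rate (s^-1), all states pooled."""
    n_events = sum(r.n_events for r in rates.values())
    n_frames = sum(r.n_frames for r in rates.values())
    if n_frames == 0:
        raise ValueError("no frames observed")
    return n_events / n_frames / frame_dt


def interval_statistics(intervals, censored=None, n_bootstrap: int = 1000,
                        seed: int = 0) -> IntervalStats:
    """Mean +/- SEM and product-limit survival of a set of dwell intervals.

    The mean and SEM use observed (uncensored) intervals only; the survival
    curve is the Kaplan-Meier product-limit estimator honoring censoring,
    with a 95% CI from a seeded nonparametric bootstrap over molecules.
    When every interval is censored the mean is refused (None) and only the
    curve is returned.
    """
    intervals = np.asarray(intervals, dtype=float)
    if censored is None:
        censored = np.zeros(len(intervals), dtype=bool)
    censored = np.asarray(censored, dtype=bool)
    if len(intervals) == 0:
        raise ValueError("need at least one interval")
    observed = ~censored

    kmf = KaplanMeierFitter()
    kmf.fit(intervals, event_observed=observed)
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy()
    n_at_risk = np.array([(intervals >= t).sum() for t in times])

    rng = np.random.default_rng(seed)
    if n_bootstrap > 0:
        boot = np.empty((n_bootstrap, len(times)))
        idx_all = np.arange(len(intervals))
        for b in range(n_bootstrap):
            idx = rng.choice(idx_all, size=len(idx_all), replace=True)
            k = KaplanMeierFitter()
            k.fit(intervals[idx], event_observed=observed[idx])
            boot[b] = k.survival_function_at_times(times).to_numpy()
        lower = np.quantile(boot, 0.025, axis=0)
        upper = np.quantile(boot, 0.975, axis=0)
        # the CI must contain the point estimate
        lower = np.minimum(lower, surv)
        upper = np.maximum(upper, surv)
    else:
        lower = upper = surv
    curve = SurvivalCurve(times=times, survival=surv, lower=lower,
                          upper=upper, n_at_risk=n_at_risk)

    if observed.any():
        obs = intervals[observed]
        mean = float(obs.mean())
        sem = float(obs.std(ddof=1) / np.sqrt(len(obs))) if len(obs) > 1 else None
    else:
        mean = sem = None
    return IntervalStats(mean=mean, sem=sem, n_observed=int(observed.sum()),
                         n_censored=int(censored.sum()), survival=curve)


def time_in_state_fraction(segments) -> dict[str, float]:
    """Fraction of labeled colocalized frames spent in each E_FRET state."""
    if isinstance(segments, (StateSegments, np.ndarray)):
        segments = [segments]
    frames = {"low": 0, "high": 0}
    for segs in segments:
        labels = segs.labels if isinstance(segs, StateSegments) else segs
        for label in frames:
            frames[label] += int(np.sum(labels == label))
    total = sum(frames.values())
    if total == 0:
        raise ValueError("no valid labeled frames")
    return {label: n / total for label, n in frames.items()}


def fraction_outcome(events: pd.DataFrame, predicate) -> Fraction:
    """Binomial fraction of molecules satisfying a predicate, with SE.

    ``predicate`` maps the event table to a boolean Series (one entry per
    molecule).  SE = sqrt(f(1-f)/n); for zero successes the one-sided 95%
    rule-of-three bound 3/n is attached.
    """
    hits = np.asarray(predicate(events), dtype=bool)
    n = len(hits)
    if n == 0:
        raise ValueError("empty event table")
    f = hits.mean()
    se = float(np.sqrt(f * (1.0 - f) / n))
    upper = 3.0 / n if hits.sum() == 0 else None
    return Fraction(fraction=float(f), se=se, n=n, upper95=upper)
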