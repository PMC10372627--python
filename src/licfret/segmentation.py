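"""E_FRET state segmentation: mixture fits, trough thresholds, transitions.

State calling is deliberately threshold-based (not hidden-Markov): a frame
is high iff its E_FRET is at or above the threshold, and a state change is
only accepted once the value stays on the new side for a minimum number of
consecutive frames (default two).  Thresholds come from the trough of a
fitted two-component Gaussian mixture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .fret import ESeries

log = logging.getLogger(__name__)

__all__ = [
    "MixtureFit", "StateSegments", "fit_mixture", "fit_global_mixture",
    "trough_threshold", "detect_transitions", "detect_peaks",
    "flag_nonspecific", "state_labels",
]

MIN_GROUP_SIZE_PER_COMPONENT = 10


@dataclass
class MixtureFit:
    """Fitted Gaussian mixture over E_FRET values (centers ascending)."""

    n_components: int
    centers: np.ndarray
    widths: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    center_ses: np.ndarray | None = None
    degenerate: bool = False
    #: per-group (weights, widths) when fitted globally with shared centers
    group_params: dict = field(default_factory=dict)

    def density(self, x, group=None):
        x = np.asarray(x, dtype=float)
        if group is not None and group in self.group_params:
            weights, widths = self.group_params[group]
        else:
            weights, widths = self.weights, self.widths
        out = np.zeros_like(x, dtype=float)
        for w, mu, sd in zip(weights, self.centers, widths):
            out += w * norm.pdf(x, mu, max(sd, 1e-12))
        return out


@dataclass
class StateSegments:
    """Per-frame low/high/invalid labels and the derived segments.

    ``segments`` are ``(label, start_frame, end_frame)`` with inclusive
    ends; ``transitions`` are ``(frame, from_label, to_label)`` stamped at
    the first frame of the persistent run on the new side.
    """

    labels: np.ndarray  # dtype=object: "low" | "high" | "invalid"
    segments: list[tuple[str, int, int]]
    transitions: list[tuple[int, str, str]]
    threshold: float
    frame_dt: float

    def frames_in_state(self, label: str) -> int:
        return int(np.sum(self.labels == label))


def _fit_once(values: np.ndarray, n_components: int, seed) -> GaussianMixture:
    gm = GaussianMixture(n_components=n_components, covariance_type="diag",
                         n_init=1, random_state=seed, reg_covar=1e-8)
    gm.fit(values.reshape(-1, 1))
    return gm

def _to_fit(gm: GaussianMixture, values: np.ndarray) -> MixtureFit:
    order = np.argsort(gm.means_.ravel())
    return MixtureFit(
        n_components=gm.n_components,
        centers=gm.means_.ravel()[order],
        widths=np.sqrt(gm.covariances_.ravel()[order]),
        weights=gm.weights_[order],
        log_likelihood=float(gm.score(values.reshape(-1, 1)) * len(values)),
    )


def fit_mixture(values, n_components: int = 1, n_restarts: int = 10,
                seed: int = 0, n_bootstrap: int = 200) -> MixtureFit:
    """Maximum-likelihood Gaussian mixture fit of pooled E_FRET values.

    Best of ``n_restarts`` seeded EM runs (ties broken by log-likelihood,
    then by the lowest first center); center standard errors by
    nonparametric bootstrap (``n_bootstrap`` resamples; 0 skips them).
    A zero-variance sample returns a flagged single-point fit.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < MIN_GROUP_SIZE_PER_COMPONENT * n_components:
        raise ValueError(
            f"need >= {MIN_GROUP_SIZE_PER_COMPONENT * n_components} values, "
            f"got {len(values)}")
    if np.ptp(values) == 0.0:
        c = values[0]
        return MixtureFit(n_components=n_components,
                          centers=np.full(n_components, c),
                          widths=np.zeros(n_components),
                          weights=np.full(n_components, 1.0 / n_components),
                          log_likelihood=np.inf, degenerate=True)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        gm = _fit_once(values, n_components, rng.integers(2**31 - 1))
        fit = _to_fit(gm, values)
        key = (fit.log_likelihood, -fit.centers[0])
        if best is None or key > best[0]:
            best = (key, fit)
    fit = best[1]
    if n_bootstrap > 0:
        boots = np.empty((n_bootstrap, n_components))
        for b in range(n_bootstrap):
            sample = rng.choice(values, size=len(values), replace=True)
            gm = _fit_once(sample, n_components, rng.integers(2**31 - 1))
            boots[b] = np.sort(gm.means_.ravel())
        fit.center_ses = boots.std(axis=0, ddof=1)
    return fit


def fit_global_mixture(groups: dict, n_components: int = 2,
                       n_restarts: int = 10, seed: int = 0,
                       max_iter: int = 500, tol: float = 1e-8,
                       max_width: float = 0.2) -> MixtureFit:
    """Gaussian mixture with centers shared across groups.

    Component centers are global; weights and widths are free per group,
    fitted by EM on the pooled likelihood.  Groups smaller than
    ``10 * n_components`` have their free parameters tied to the pooled
    values (a warning is logged).  Component SDs are capped at
    ``max_width``: E_FRET states have sub-0.2 spreads, and without the cap
    a component can degenerate into a broad collector for the few frames
    (sliding transients, transition straddles) that belong to no state,
    dragging the shared centers with it.
    """
    if len(groups) < 2:
        raise ValueError("global fit needs at least 2 groups")
    data = {g: np.asarray(v, dtype=float)[np.isfinite(v)]
            for g, v in groups.items()}
    small = [g for g, v in data.items()
             if len(v) < MIN_GROUP_SIZE_PER_COMPONENT * n_components]
    for g in small:
        log.warning("group %r below minimum size; tying its parameters "
                    "to pooled values", g)
    pooled = np.concatenate(list(data.values()))
    rng = np.random.default_rng(seed)

    best = None
    for _ in range(max(1, n_restarts)):
        out = _global_em(data, pooled, small, n_components, rng, max_iter,
                         tol, max_width)
        key = (out.log_likelihood, -out.centers[0])
        if best is None or key > best[0]:
            best = (key, out)
    return best[1]


def _global_em(data, pooled, small, k, rng, max_iter, tol,
               max_width) -> MixtureFit:
    # init centers from pooled quantiles with jitter; widths from pooled SD
    qs = np.linspace(0.2, 0.8, k)
    centers = np.quantile(pooled, qs) + rng.normal(0, 0.02, size=k)
    sd0 = max(pooled.std(), 1e-3)
    params = {g: (np.full(k, 1.0 / k), np.full(k, sd0)) for g in data}
    free = [g for g in data if g not in small]
    ll_prev = -np.inf
    for _ in range(max_iter):
        resp, ll = {}, 0.0
        for g, x in data.items():
            w, s = params[g]
            comp = w * norm.pdf(x[:, None], centers[None, :],
                                np.maximum(s, 1e-6)[None, :])
            tot = comp.sum(axis=1)
            tot = np.maximum(tot, 1e-300)
            resp[g] = comp / tot[:, None]
            ll += float(np.log(tot).sum())
        # shared centers from all groups
        num = sum((resp[g] * data[g][:, None]).sum(axis=0) for g in data)
        den = sum(resp[g].sum(axis=0) for g in data)
        centers = num / np.maximum(den, 1e-12)
        # per-group weights and widths (small groups tied to pooled)
        pooled_r = np.vstack([resp[g] for g in data])
        pooled_x = np.concatenate([data[g] for g in data])
        pw = pooled_r.mean(axis=0)
        pvar = ((pooled_r * (pooled_x[:, None] - centers[None, :]) ** 2
                 ).sum(axis=0) / np.maximum(pooled_r.sum(axis=0), 1e-12))
        ps = np.clip(np.sqrt(np.maximum(pvar, 1e-12)), 1e-3, max_width)
        for g in data:
            if g in small or g not in free:
                params[g] = (pw.copy(), ps.copy())
                continue
            r, x = resp[g], data[g]
            w = r.mean(axis=0)
            var = ((r * (x[:, None] - centers[None, :]) ** 2).sum(axis=0)
                   / np.maximum(r.sum(axis=0), 1e-12))
            params[g] = (w, np.clip(np.sqrt(np.maximum(var, 1e-12)),
                                    1e-3, max_width))
        if abs(ll - ll_prev) < tol * (1 + abs(ll)):
            ll_prev = ll
            break
        ll_prev = ll
    order = np.argsort(centers)
    group_params = {g: (params[g][0][order], params[g][1][order])
                    for g in data}
    return MixtureFit(
        n_components=k,
        centers=centers[order],
        widths=ps[order],
        weights=pw[order],
        log_likelihood=ll_prev,
        group_params=group_params,
    )


def trough_threshold(fit: MixtureFit, group=None) -> float:
    """E_FRET at the density trough between the two component centers.

    The threshold separating low and high states is the local minimum of the
    fitted mixture density on the open interval between the centers; merged
    (effectively unimodal) fits raise an error.
    """
    if fit.n_components != 2:
        raise ValueError("trough threshold needs a 2-component fit")
    c1, c2 = fit.centers
    if not c1 < c2:
        raise ValueError("component centers are not distinct")
    res = minimize_scalar(lambda x: fit.density(x, group=group),
                          bounds=(c1, c2), method="bounded",
                          options={"xatol": 1e-8})
    x = float(res.x)
    span = c2 - c1
    interior = c1 + 1e-3 * span < x < c2 - 1e-3 * span
    dens = fit.density(np.array([c1, x, c2]), group=group)
    if not interior or not (dens[1] < dens[0] and dens[1] < dens[2]):
        raise ValueError("mixture density has no interior trough "
                         "(components merged / unimodal fit)")
    return x


def _smooth_states(raw: np.ndarray, persistence: int) -> np.ndarray:
    """Persistence filter over a boolean high/low sequence (valid frames).

    A state change is accepted only when the new side persists for at least
    ``persistence`` consecutive valid frames; shorter excursions inherit the
    prior state.  The initial state is the side of the first persistent run.
    """
    n = len(raw)
    runs = []  # (value, start, length) over the compressed sequence
    i = 0
    while i < n:
        j = i
        while j < n and raw[j] == raw[i]:
            j += 1
        runs.append((raw[i], i, j - i))
        i = j
    init = next((v for v, _, ln in runs if ln >= persistence), runs[0][0])
    out = np.empty(n, dtype=bool)
    state = init
    for v, start, ln in runs:
        if v != state and ln >= persistence:
            state = v
        out[start:start + ln] = state
    return out


def detect_transitions(eseries: ESeries, threshold: float,
                       persistence: int = 2) -> StateSegments:
    """Label frames low/high and call persistent threshold crossings.

    A frame is high iff E_FRET >= threshold.  Transitions are stamped at the
    first frame of a run of >= ``persistence`` frames on the new side; runs
    shorter than that inherit the prior state.  Invalid frames neither break
    runs nor contribute to them.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    n = len(eseries.efret)
    labels = np.full(n, "invalid", dtype=object)
    valid_idx = np.flatnonzero(eseries.valid_mask)
    if len(valid_idx) == 0:
        return StateSegments(labels=labels, segments=[], transitions=[],
                             threshold=threshold, frame_dt=eseries.frame_dt)
    raw = eseries.efret[valid_idx] >= threshold
    smooth = _smooth_states(raw, persistence)
    labels[valid_idx] = np.where(smooth, "high", "low")

    transitions, segments = [], []
    seg_start = valid_idx[0]
    for k in range(1, len(valid_idx)):
        if smooth[k] != smooth[k - 1]:
            frame = int(valid_idx[k])
            old = "high" if smooth[k - 1] else "low"
            new = "high" if smooth[k] else "low"
            transitions.append((frame, old, new))
            segments.append((old, int(seg_start), int(valid_idx[k - 1])))
            seg_start = frame
    last = "high" if smooth[-1] else "low"
    segments.append((last, int(seg_start), int(valid_idx[-1])))
    return StateSegments(labels=labels, segments=segments,
                         transitions=transitions, threshold=threshold,
                         frame_dt=eseries.frame_dt)


def state_labels(eseries: ESeries, threshold: float,
                 extend_mask=None) -> np.ndarray:
    """Raw per-frame threshold labels (no persistence smoothing).

    Each valid frame is labeled high iff E_FRET >= threshold.  Within
    ``extend_mask`` (e.g. colocalized, dye-alive frames), frames whose
    E_FRET is individually unusable inherit the previous label, so every
    frame of a dwell has a state — the convention under which release
    frequencies divide events by total frames in each state.
    """
    n = len(eseries.efret)
    labels = np.full(n, "invalid", dtype=object)
    valid = eseries.valid_mask
    labels[valid] = np.where(eseries.efret[valid] >= threshold,
                             "high", "low")
    if extend_mask is not None:
        current = "invalid"
        for i in range(n):
            if labels[i] != "invalid":
                current = labels[i]
            elif extend_mask[i] and current != "invalid":
                labels[i] = current
    return labels


def detect_peaks(eseries: ESeries, threshold: float,
                 persistence: int = 2) -> list[tuple[int, int]]:
    """Maximal runs of >= ``persistence`` consecutive high frames.

    Returns (start_frame, end_frame) inclusive per peak, counted over valid
    frames only (invalid frames neither break nor extend a run).
    """
    valid_idx = np.flatnonzero(eseries.valid_mask)
    if len(valid_idx) == 0:
        return []
    high = eseries.efret[valid_idx] >= threshold
    peaks = []
    i = 0
    while i < len(high):
        if high[i]:
            j = i
            while j < len(high) and high[j]:
                j += 1
            if j - i >= persistence:
                peaks.append((int(valid_idx[i]), int(valid_idx[j - 1])))
            i = j
        else:
            i += 1
    return peaks


def flag_nonspecific(eseries: ESeries, threshold: float,
                     persistence: int = 2) -> bool:
    """True iff the molecule never shows a persistent high-E_FRET state.

    Molecules that never reach the high state during colocalization likely
    bound DNA nonspecifically and are excluded from downstream kinetics.
    """
    if not eseries.valid_mask.any():
        raise ValueError("molecule has no valid frames")
    return len(detect_peaks(eseries, threshold, persistence)) == 0
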