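"""Time-aligned E_FRET probability-density heat maps.

Traces are aligned to a common zero (typically the first Mcm2-7 arrival)
and their valid E_FRET samples pooled into a two-dimensional Gaussian
kernel density over (time, E_FRET).  Following the construction used for
single-molecule heat maps, each vertical time slice is renormalized to
integrate to one over the E_FRET axis, so the map shows the conditional
density of E_FRET among molecules still visible at that time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HeatMap", "efret_heatmap", "window_slices", "DEFAULT_WINDOWS"]

#: time windows (s after first arrival) used for per-window mixture fits
DEFAULT_WINDOWS = [(0.0, 4.0), (4.0, 15.0), (15.0, 50.0), (50.0, 100.0)]


@dataclass
class HeatMap:
    t_grid: np.ndarray
    e_grid: np.ndarray
    density: np.ndarray        # shape (len(e_grid), len(t_grid)); NaN slices masked
    fraction_bound: np.ndarray
    fraction_ci: np.ndarray    # (2, len(t_grid)) binomial 95% CI
    n_visible: np.ndarray


def _aligned_samples(eseries_list, t_zero):
    """(t, E) pairs of valid frames, and per-molecule visibility spans."""
    ts, es, spans = [], [], []
    for k, series in enumerate(eseries_list):
        z = 0.0 if t_zero is None else float(t_zero[k])
        t = series.times - z
        m = series.valid_mask
        ts.append(t[m])
        es.append(series.efret[m])
        if m.any():
            # visibility spans whole frames, not mid-frame sample times
            half = series.frame_dt / 2.0
            spans.append((t[m].min() - half, t[m].max() + half))
    if not spans:
        raise ValueError("no valid frames in any trace")
    return np.concatenate(ts), np.concatenate(es), spans


def efret_heatmap(eseries_list, t_zero=None, t_range=(0.0, 100.0),
                  sd_t: float = 5.0, sd_e: float = 0.05,
                  grid_dt: float = 1.0, grid_de: float = 0.005,
                  e_range=(0.0, 1.0)) -> HeatMap:
    """Kernel-density heat map of E_FRET against aligned time.

    A normal kernel (SD ``sd_t`` along time, ``sd_e`` along E_FRET) is
    evaluated on a discrete grid (resolution ``grid_dt`` x ``grid_de``) and
    each time slice is renormalized so its E_FRET density integrates to one.
    ``t_zero`` gives the per-molecule alignment time (e.g. first Mcm2-7
    arrival); slices where no molecule is visible are NaN-masked.  The
    fraction-bound curve counts molecules whose valid span covers each
    slice, with a normal-approximation binomial 95% CI.
    """
    if min(sd_t, sd_e, grid_dt, grid_de) <= 0:
        raise ValueError("kernel SDs and grid steps must be positive")
    t, e, spans = _aligned_samples(eseries_list, t_zero)
    t_grid = np.arange(t_range[0], t_range[1] + grid_dt / 2, grid_dt)
    e_grid = np.arange(e_range[0], e_range[1] + grid_de / 2, grid_de)

    # separable Gaussian kernels: density = K_t(t) @ K_e(e)^T accumulated
    wt = np.exp(-0.5 * ((t_grid[:, None] - t[None, :]) / sd_t) ** 2)
    we = np.exp(-0.5 * ((e_grid[:, None] - e[None, :]) / sd_e) ** 2)
    density = we @ wt.T  # (n_e, n_t)

    n_total = len(eseries_list)
    n_visible = np.array([sum(a <= tc <= b for a, b in spans)
                          for tc in t_grid])
    for j in range(len(t_grid)):
        if n_visible[j] == 0:
            density[:, j] = np.nan
            continue
        integral = np.trapezoid(density[:, j], e_grid)
        if integral > 0:
            density[:, j] /= integral
        else:
            density[:, j] = np.nan

    frac = n_visible / n_total
    se = np.sqrt(frac * (1 - frac) / n_total)
    ci = np.clip(np.vstack([frac - 1.96 * se, frac + 1.96 * se]), 0.0, 1.0)
    return HeatMap(t_grid=t_grid, e_grid=e_grid, density=density,
                   fraction_bound=frac, fraction_ci=ci, n_visible=n_visible)


def window_slices(eseries_list, windows=None, t_zero=None) -> dict:
    """Pool valid E_FRET values into half-open aligned time windows.

    Windows are ``[start, end)`` in seconds after the alignment zero; a
    value at exactly the boundary belongs to the later window.  Returns a
    mapping ``(start, end) -> values`` ready for mixture fitting; empty
    windows yield empty arrays.
    """
    if windows is None:
        windows = DEFAULT_WINDOWS
    for i, (a, b) in enumerate(windows):
        if b <= a:
            raise ValueError(f"window {i} is empty or inverted: {(a, b)}")
        for c, d in windows[i + 1:]:
            if max(a, c) < min(b, d):
                raise ValueError("windows overlap")
    t, e, _ = _aligned_samples(eseries_list, t_zero)
    return {(a, b): e[(t >= a) & (t < b)] for a, b in windows}
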