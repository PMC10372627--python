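"""Multi-channel fluorescence trace container and I/O.

Traces are per-frame, per-channel corrected intensities for one DNA
location.  Channels are keyed by ``(excitation, emission)`` pairs using the
labels ``Dex``/``Aex`` (532-nm green / 633-nm red excitation) and
``Dem``/``Aem`` (donor / acceptor emission band).  Tabular CSV (one row per
frame per molecule) is the canonical interchange format; HDF5 is the bulk
format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "FluorTrace", "write_traces", "read_traces", "demultiplex",
    "subtract_background", "REQUIRED_CHANNELS",
]

#: channels a protocol cannot do without
REQUIRED_CHANNELS = {
    "continuous_green": [("Dex", "Dem")],
    "simultaneous": [("Dex", "Dem")],
    "alternating": [("Dex", "Dem"), ("Dex", "Aem")],
}

_CHANNEL_COLUMNS = {
    ("Dex", "Dem"): "Dex_Dem",
    ("Dex", "Aem"): "Dex_Aem",
    ("Aex", "Aem"): "Aex_Aem",
}
_COLUMN_CHANNELS = {v: k for k, v in _CHANNEL_COLUMNS.items()}


@dataclass
class FluorTrace:
    """Per-frame corrected intensities for one DNA molecule location.

    ``valid_mask`` marks frames usable for FRET (dyes unbleached);
    ``colocalized_mask`` marks frames during which a labeled protein is
    present at the DNA spot.
    """

    molecule_id: str
    frame_dt: float
    protocol: str
    channels: dict[tuple[str, str], np.ndarray]
    valid_mask: np.ndarray
    colocalized_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.frame_dt <= 0:
            raise ValueError("frame_dt must be positive")
        lengths = {len(v) for v in self.channels.values()}
        lengths |= {len(self.valid_mask), len(self.colocalized_mask)}
        if len(lengths) != 1:
            raise ValueError("all channel arrays and masks must share length")

    @property
    def n_frames(self) -> int:
        return len(self.valid_mask)

    @property
    def times(self) -> np.ndarray:
        """Mid-frame times in seconds."""
        return (np.arange(self.n_frames) + 0.5) * self.frame_dt

    def require_channels(self, pairs) -> None:
        for pair in pairs:
            if pair not in self.channels:
                raise ValueError(
                    f"trace {self.molecule_id} lacks required channel "
                    f"{_CHANNEL_COLUMNS.get(pair, pair)}"
                )


def _trace_frame(trace: FluorTrace) -> pd.DataFrame:
    df = pd.DataFrame({
        "molecule_id": trace.molecule_id,
        "frame": np.arange(trace.n_frames),
        "time_s": trace.times,
    })
    for pair, col in _CHANNEL_COLUMNS.items():
        if pair in trace.channels:
            df[col] = trace.channels[pair]
    df["valid"] = trace.valid_mask.astype(int)
    df["colocalized"] = trace.colocalized_mask.astype(int)
    df["frame_dt"] = trace.frame_dt
    df["protocol"] = trace.protocol
    return df


def write_traces(traces, path) -> None:
    """Write traces to CSV (``.csv``) or HDF5 (anything else)."""
    traces = list(traces)
    if not traces:
        raise ValueError("no traces to write")
    path = Path(path)
    if path.suffix == ".csv":
        pd.concat([_trace_frame(t) for t in traces]).to_csv(path, index=False)
        return
    with h5py.File(path, "w") as f:
        for t in traces:
            g = f.create_group(t.molecule_id)
            g.attrs["frame_dt"] = t.frame_dt
            g.attrs["protocol"] = t.protocol
            for pair, arr in t.channels.items():
                g.create_dataset(_CHANNEL_COLUMNS[pair], data=arr)
            g.create_dataset("valid", data=t.valid_mask)
            g.create_dataset("colocalized", data=t.colocalized_mask)


def _check_required(trace: FluorTrace) -> FluorTrace:
    trace.require_channels(REQUIRED_CHANNELS.get(trace.protocol, []))
    return trace


def read_traces(path) -> list[FluorTrace]:
    """Read traces written by :func:`write_traces` (lossless round trip)."""
    path = Path(path)
    traces = []
    if path.suffix == ".csv":
        df = pd.read_csv(path)
        for mol, sub in df.groupby("molecule_id", sort=False):
            channels = {
                _COLUMN_CHANNELS[c]: sub[c].to_numpy(float)
                for c in sub.columns if c in _COLUMN_CHANNELS
            }
            traces.append(_check_required(FluorTrace(
                molecule_id=str(mol),
                frame_dt=float(sub["frame_dt"].iloc[0]),
                protocol=str(sub["protocol"].iloc[0]),
                channels=channels,
                valid_mask=sub["valid"].to_numpy() > 0,
                colocalized_mask=sub["colocalized"].to_numpy() > 0,
            )))
        return traces
    with h5py.File(path, "r") as f:
        for mol in f:
            g = f[mol]
            channels = {
                _COLUMN_CHANNELS[name]: g[name][...].astype(float)
                for name in g if name in _COLUMN_CHANNELS
            }
            traces.append(_check_required(FluorTrace(
                molecule_id=mol,
                frame_dt=float(g.attrs["frame_dt"]),
                protocol=str(g.attrs["protocol"]),
                channels=channels,
                valid_mask=g["valid"][...].astype(bool),
                colocalized_mask=g["colocalized"][...].astype(bool),
            )))
    return traces


def demultiplex(raw: np.ndarray, protocol: str) -> dict[str, np.ndarray]:
    """Split a raw interleaved frame series by excitation laser.

    With alternating excitation, even-index frames are green-excited and
    odd-index frames red-excited; a trailing unpaired frame is dropped.
    Simultaneous / continuous protocols pass through unchanged.
    """
    raw = np.asarray(raw)
    if protocol != "alternating":
        return {"green": raw}
    n = len(raw)
    if n % 2:
        log.info("alternating series of odd length %d: trailing frame dropped", n)
        raw = raw[: n - 1]
    return {"green": raw[0::2], "red": raw[1::2]}


def subtract_background(trace: FluorTrace, background: dict) -> FluorTrace:
    """Subtract a per-channel background estimate; no negative clamping.

    ``background`` maps channel pairs to scalars or arrays broadcastable to
    the channel length.  Negative values are retained deliberately: clamping
    would bias E_FRET ratios at low intensity.
    """
    channels = {}
    for pair, arr in trace.channels.items():
        bg = np.asarray(background.get(pair, 0.0), dtype=float)
        if bg.ndim and len(bg) != len(arr):
            raise ValueError(
                f"background for {pair} has length {len(bg)}, expected {len(arr)}"
            )
        channels[pair] = arr - bg
    return replace(trace, channels=channels)


def estimate_background(trace: FluorTrace) -> dict:
    """Median intensity over non-colocalized frames, per channel."""
    free = ~trace.colocalized_mask
    if not free.any():
        return {pair: 0.0 for pair in trace.channels}
    return {pair: float(np.median(arr[free]))
            for pair, arr in trace.channels.items()}
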