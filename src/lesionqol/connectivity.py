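"""Resting-state functional connectivity from node time series.

Node series are band-pass filtered to the low-frequency band of spontaneous
BOLD fluctuations (0.008-0.09 Hz by default), correlated pairwise, and the
Pearson correlations are Fisher z-transformed into a full connectivity
matrix.  The matrix is reduced to the within-network connectivity of each
node: the mean z-value to the other nodes of that node's network.  By
default the left and right halves of a network are treated as separate
pools; bilateral pooling is available via a switch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NodeTimeSeries",
    "ConnectivityMatrix",
    "CORRELATION_CLIP",
    "bandpass_filter",
    "connectivity_matrix",
    "within_network_connectivity",
]

#: Correlations are clipped to +/- this value before atanh so z stays finite.
CORRELATION_CLIP = 1.0 - 1e-7


@dataclass
class NodeTimeSeries:
    """Node x timepoint signal matrix for one subject."""

    subject: str
    data: np.ndarray  # (n_nodes, n_timepoints)
    node_ids: list[int]
    tr_seconds: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be 2D (nodes x time)")
        if self.data.shape[0] != len(self.node_ids):
            raise ValueError("node_ids length does not match data rows")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 nodes")
        if self.data.shape[1] < 8:
            raise ValueError("need at least 8 timepoints")
        if not np.isfinite(self.data).all():
            raise ValueError(f"subject {self.subject!r}: non-finite values in time series")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.node_ids)

    def save(self, path: str | Path) -> None:
        df = self.to_frame().T
        df.columns = [f"node_{i}" for i in self.node_ids]
        df.to_csv(path, sep="\t", index=False)
        Path(str(path) + ".json").write_text(
            f'{{"subject": "{self.subject}", "tr_seconds": {self.tr_seconds}}}\n'
        )

    @classmethod
    def load(cls, path: str | Path, subject: str, tr_seconds: float) -> "NodeTimeSeries":
        df = pd.read_csv(path, sep="\t")
        node_ids = [int(c.removeprefix("node_")) for c in df.columns]
        return cls(subject, df.to_numpy().T, node_ids, tr_seconds)


@dataclass
class ConnectivityMatrix:
    """Symmetric node x node matrix of Fisher-z correlations (diagonal NaN)."""

    subject: str
    z: np.ndarray
    node_ids: list[int]
    excluded_nodes: list[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=self.node_ids, columns=self.node_ids)


def bandpass_filter(
    ts: NodeTimeSeries, low_hz: float = 0.008, high_hz: float = 0.09
) -> NodeTimeSeries:
    """Frequency-domain band-pass with cosine roll-off; removes the mean.

    The passband [low_hz, high_hz] has unit gain; the gain falls to zero over
    a half-cosine transition of width ``low_hz/2`` below the band and 0.01 Hz
    above it (clipped at DC and Nyquist).  Output length equals input length.
    """
    nyquist = 1.0 / (2.0 * ts.tr_seconds)
    if not (0 <= low_hz < high_hz < nyquist):
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz invalid for Nyquist {nyquist:.4f} Hz"
        )
    n = ts.data.shape[1]
    freqs = np.fft.rfftfreq(n, d=ts.tr_seconds)
    w_low = low_hz / 2.0
    w_high = 0.01
    gain = np.zeros_like(freqs)
    inband = (freqs >= low_hz) & (freqs <= high_hz)
    gain[inband] = 1.0
    rising = (freqs >= low_hz - w_low) & (freqs < low_hz)
    gain[rising] = 0.5 * (1 + np.cos(np.pi * (low_hz - freqs[rising]) / w_low))
    falling = (freqs > high_hz) & (freqs <= high_hz + w_high)
    gain[falling] = 0.5 * (1 + np.cos(np.pi * (freqs[falling] - high_hz) / w_high))
    gain[0] = 0.0  # mean removal
    spec = np.fft.rfft(ts.data, axis=1) * gain
    out = np.fft.irfft(spec, n=n, axis=1)
    return NodeTimeSeries(ts.subject, out, list(ts.node_ids), ts.tr_seconds)


def connectivity_matrix(ts: NodeTimeSeries) -> ConnectivityMatrix:
    """Fisher-z Pearson correlation matrix between node series.

    Zero-variance nodes are excluded with a warning; correlations are clipped
    at +/-(1 - 1e-7) before atanh so the z-values are always finite.  The
    diagonal is set to NaN (self-connectivity is undefined).
    """
    sd = ts.data.std(axis=1)
    valid = sd > 0
    excluded = [nid for nid, v in zip(ts.node_ids, valid) if not v]
    if excluded:
        warnings.warn(
            f"subject {ts.subject!r}: excluding constant nodes {excluded}",
            stacklevel=2,
        )
    if valid.sum() < 2:
        raise ValueError(f"subject {ts.subject!r}: fewer than 2 nodes with signal variance")
    data = ts.data[valid]
    r = np.corrcoef(data)
    z = np.arctanh(np.clip(r, -CORRELATION_CLIP, CORRELATION_CLIP))
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, np.nan)
    node_ids = [nid for nid, v in zip(ts.node_ids, valid) if v]
    return ConnectivityMatrix(ts.subject, z, node_ids, excluded)


def within_network_connectivity(
    cm: ConnectivityMatrix, regions: pd.DataFrame, bilateral: bool = False
) -> pd.Series:
    """Mean z of each node to the other nodes of its network.

    ``regions`` is the node-atlas region table (indexed by label, columns
    ``hemisphere`` and ``class_``).  With ``bilateral=False`` (default) the
    left and right parts of a network form separate pools; with
    ``bilateral=True`` a network pools both hemispheres.  Nodes whose pool
    has a single member get NaN with a warning.
    """
    missing = [nid for nid in cm.node_ids if nid not in regions.index]
    if missing:
        raise ValueError(f"nodes absent from the region table: {missing}")
    if bilateral:
        pool_of = {nid: regions.loc[nid, "class_"] for nid in cm.node_ids}
    else:
        pool_of = {
            nid: (regions.loc[nid, "hemisphere"], regions.loc[nid, "class_"])
            for nid in cm.node_ids
        }
    pools: dict[object, list[int]] = {}
    for nid, p in pool_of.items():
        pools.setdefault(p, []).append(nid)
    idx_of = {nid: i for i, nid in enumerate(cm.node_ids)}
    out = pd.Series(np.nan, index=pd.Index(cm.node_ids, name="node"), name="wnc")
    for p, members in pools.items():
        if len(members) < 2:
            warnings.warn(f"network pool {p!r} has a single node; WNC undefined", stacklevel=2)
            continue
        rows = [idx_of[m] for m in members]
        sub = cm.z[np.ix_(rows, rows)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out.loc[members] = np.nanmean(sub, axis=1)
    return out
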