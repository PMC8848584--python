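"""Spike detection, interspike-interval extraction and preprocessing.

The classifier consumes fixed-length normalized ISI vectors.  A membrane
trace becomes a spike train (upward threshold crossings followed by a local
maximum, with a refractory window), the spike train becomes an ISI sequence
(pairwise differences), and the ISI sequence is truncated to 1024 intervals
and min–max scaled to [0, 1] per sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .chay import MembraneTrace

__all__ = [
    "SpikeTrain",
    "ISISequence",
    "detect_spikes",
    "extract_isi",
    "preprocess",
    "TARGET_LENGTH",
]

TARGET_LENGTH = 1024
CLASS_NAMES = ("PD", "RD", "CD", "IMD")


@dataclass
class SpikeTrain:
    """Strictly increasing spike times with provenance."""

    times: np.ndarray
    source_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("spike times must be one-dimensional")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class ISISequence:
    """Interspike intervals, optionally labeled with a rhythm class 0..3."""

    values: np.ndarray
    label: Optional[int] = None
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.label is not None and self.label not in (0, 1, 2, 3):
            raise ValueError(f"label must be in {{0,1,2,3}}, got {self.label}")
        if not self.normalized and len(self.values) and np.any(self.values <= 0):
            raise ValueError("raw interspike intervals must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def class_name(self) -> Optional[str]:
        return CLASS_NAMES[self.label] if self.label is not None else None


def detect_spikes(
    trace: MembraneTrace,
    threshold: float = 0.0,
    refractory: float = 2.0,
) -> SpikeTrain:
    """Detect spikes as upward threshold crossings followed by a local maximum.

    A crossing that falls within ``refractory`` time units of the previous
    accepted spike is suppressed.  The spike time is the time of the first
    local maximum at or after the crossing.  An empty train is a valid result.
    """
    V = np.asarray(trace.V)
    t = np.asarray(trace.t)
    if len(V) == 0:
        raise ValueError("trace is empty")
    crossings = np.flatnonzero((V[:-1] < threshold) & (V[1:] >= threshold)) + 1
    times = []
    last = -np.inf
    n = len(V)
    for idx in crossings:
        # walk forward to the first local maximum
        j = idx
        while j + 1 < n and V[j + 1] > V[j]:
            j += 1
        if j + 1 >= n and j != n - 1:
            continue
        tj = t[j]
        if tj - last >= refractory:
            times.append(tj)
            last = tj
    meta = dict(trace.meta)
    meta.update({"threshold": threshold, "refractory": refractory})
    return SpikeTrain(times=np.asarray(times, dtype=float), source_meta=meta)


def extract_isi(train: SpikeTrain, label: Optional[int] = None) -> ISISequence:
    """Pairwise differences of spike times; requires at least two spikes."""
    if len(train) < 2:
        raise ValueError(f"insufficient spikes: need >= 2, got {len(train)}")
    return ISISequence(values=np.diff(train.times), label=label,
                       meta=dict(train.source_meta))


def minmax_normalize(x: np.ndarray) -> np.ndarray:
    """Per-sequence min–max scaling to [0, 1]; a constant sequence maps to zeros."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def zscore_normalize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def preprocess(
    seq: ISISequence,
    target_len: int = TARGET_LENGTH,
    normalization: str = "minmax",
) -> ISISequence:
    """Truncate to the first ``target_len`` intervals, then normalize per
    sequence (default min–max to [0, 1])."""
    if len(seq) < target_len:
        raise ValueError(
            f"sequence too short: {len(seq)} intervals, need at least {target_len}"
        )
    x = seq.values[:target_len]
    if normalization == "minmax":
        x = minmax_normalize(x)
    elif normalization == "zscore":
        x = zscore_normalize(x)
    elif normalization == "none":
        x = x.copy()
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    meta = dict(seq.meta)
    meta["normalization"] = normalization
    return ISISequence(values=x, label=seq.label, normalized=normalization != "none",
                       meta=meta)
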