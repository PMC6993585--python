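"""Core data containers shared by all pipeline stages.

The pipeline operates on two kinds of multichannel recordings:

* hemodynamic time series (``HemoSeries``) — channel x sample matrices of
  oxygenated-hemoglobin concentration change (dHbO) sampled every ``dt_s``
  seconds, tied to a ``ChannelLayout`` that knows which optode pairs are
  standard-separation (~30 mm, cortically sensitive) and which are
  short-separation (~15 mm, scalp-only), and which region of interest (ROI)
  each standard channel covers;
* EEG potentials (``EEGRecording``) — electrode x sample matrices in uV with
  a sampling rate and a bad-channel mask.

Containers are thin: plain numpy arrays plus metadata, validated on
construction.  All analysis functions take and return these types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: canonical ROI labels: frontal, sensorimotor (central), parietal,
#: temporal, occipital
ROI_LABELS: tuple[str, ...] = ("F", "C", "P", "T", "O")


@dataclass(frozen=True)
class ChannelLayout:
    """Optode-pair layout: channel ids, separation class and ROI labels.

    Parameters
    ----------
    channel_ids
        One id per measurement channel (standard channels first by
        convention, but any order is accepted).
    is_short
        Boolean per channel; ``True`` marks a short-separation channel.
    roi
        ROI label per channel.  Short channels carry the label ``"S"``.
    """

    channel_ids: tuple[str, ...]
    is_short: np.ndarray
    roi: tuple[str, ...]

    def __post_init__(self) -> None:
        is_short = np.asarray(self.is_short, dtype=bool)
        object.__setattr__(self, "is_short", is_short)
        object.__setattr__(self, "channel_ids", tuple(self.channel_ids))
        object.__setattr__(self, "roi", tuple(self.roi))
        n = len(self.channel_ids)
        if is_short.shape != (n,) or len(self.roi) != n:
            raise ValueError("channel_ids, is_short and roi must have equal length")

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    @property
    def standard_idx(self) -> np.ndarray:
        """Indices of standard-separation channels."""
        return np.flatnonzero(~self.is_short)

    @property
    def short_idx(self) -> np.ndarray:
        """Indices of short-separation channels."""
        return np.flatnonzero(self.is_short)

    def to_dict(self) -> dict:
        return {
            "channel_ids": list(self.channel_ids),
            "is_short": self.is_short.astype(int).tolist(),
            "roi": list(self.roi),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelLayout":
        return cls(
            channel_ids=tuple(d["channel_ids"]),
            is_short=np.asarray(d["is_short"], dtype=bool),
            roi=tuple(d["roi"]),
        )


@dataclass
class HemoSeries:
    """dHbO time series: ``hbo`` is a [channels x samples] float matrix."""

    hbo: np.ndarray
    dt_s: float
    layout: ChannelLayout | None = None

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, dtype=float)
        if self.hbo.ndim != 2:
            raise ValueError("hbo must be a 2-D [channels x samples] matrix")
        if not np.all(np.isfinite(self.hbo)):
            raise ValueError("hbo contains non-finite values")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if self.layout is not None and self.layout.n_channels != self.hbo.shape[0]:
            raise ValueError("layout channel count does not match hbo rows")

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[1]

    @property
    def rate_hz(self) -> float:
        return 1.0 / self.dt_s

    def with_data(self, hbo: np.ndarray) -> "HemoSeries":
        """Copy of this series with a new data matrix of the same shape."""
        return HemoSeries(hbo=hbo, dt_s=self.dt_s, layout=self.layout)


@dataclass
class EEGRecording:
    """EEG potentials: ``v`` is a [electrodes x samples] float matrix (uV)."""

    v: np.ndarray
    rate_hz: float
    electrode_ids: tuple[str, ...] = ()
    bad: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if self.v.ndim != 2:
            raise ValueError("v must be a 2-D [electrodes x samples] matrix")
        if not np.all(np.isfinite(self.v)):
            raise ValueError("v contains non-finite values")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if not self.electrode_ids:
            self.electrode_ids = tuple(f"E{i + 1:02d}" for i in range(self.v.shape[0]))
        if self.bad is None:
            self.bad = np.zeros(self.v.shape[0], dtype=bool)
        else:
            self.bad = np.asarray(self.bad, dtype=bool)
        if self.bad.shape != (self.v.shape[0],):
            raise ValueError("bad mask must have one entry per electrode")

    @property
    def n_electrodes(self) -> int:
        return self.v.shape[0]

    @property
    def n_samples(self) -> int:
        return self.v.shape[1]

    @property
    def good_idx(self) -> np.ndarray:
        return np.flatnonzero(~self.bad)


def edge_index(n_channels: int) -> np.ndarray:
    """Upper-triangle edge list for ``n_channels`` nodes.

    Returns an [n_edges x 2] integer array of (i, j) with i < j, in
    row-major upper-triangle order, so ``n_edges == C(n_channels, 2)``.
    """
    iu = np.triu_indices(n_channels, k=1)
    return np.column_stack(iu)
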