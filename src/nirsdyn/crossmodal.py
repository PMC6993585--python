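"""Microstate-network coupling: HRF convolution, resampling, group test.

The binary switching series of each EEG microstate is convolved with the
canonical double-gamma hemodynamic response function, downsampled to the
fNIRS sampling rate (1 / 0.057 s = 17.5439 Hz), and correlated (Pearson)
with the centroid dRSFC time course of each network cluster.  Per-subject
correlation matrices are Fisher-z transformed and each cell is tested
against zero across subjects with a one-sample t-test (reported
uncorrected; optional Benjamini-Hochberg FDR).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sp_signal
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .microstates import MicrostateLabels

FNIRS_RATE_HZ = 1.0 / 0.057  # 17.5439 Hz at 4 decimal places


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma HRF (SPM-style parameterization)."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_disp_s: float = 1.0
    undershoot_disp_s: float = 1.0
    peak_undershoot_ratio: float = 6.0
    duration_s: float = 32.0


@dataclass
class CrossModalResult:
    r: np.ndarray  # [subjects x clusters x states]
    z: np.ndarray
    group_t: np.ndarray  # [clusters x states]
    group_p: np.ndarray
    fdr_mask: np.ndarray | None = None


def hrf_kernel(rate_hz: float, params: HRFParams | None = None) -> np.ndarray:
    """Sampled canonical HRF: difference of two gamma densities.

    ``h(t) = g(t; peak) - g(t; undershoot) / ratio``, sampled at
    ``rate_hz`` for ``duration_s`` seconds and normalized to peak 1 (scale
    is irrelevant to correlations).
    """
    if params is None:
        params = HRFParams()
    t = np.arange(0.0, params.duration_s, 1.0 / rate_hz)
    peak = stats.gamma.pdf(t, params.peak_delay_s / params.peak_disp_s,
                           scale=params.peak_disp_s)
    under = stats.gamma.pdf(t, params.undershoot_delay_s / params.undershoot_disp_s,
                            scale=params.undershoot_disp_s)
    h = peak - under / params.peak_undershoot_ratio
    return h / np.abs(h).max()


def smooth_states(labels: MicrostateLabels, kernel: np.ndarray | None = None) -> np.ndarray:
    """Causal convolution of each binary microstate row with the HRF.

    Output has the same length as the input (trailing convolution samples
    dropped).
    """
    if kernel is None:
        kernel = hrf_kernel(labels.rate_hz)
    n = labels.binary.shape[1]
    out = np.stack([np.convolve(row, kernel)[:n] for row in labels.binary])
    return out


def resample_to_fnirs(
    x: np.ndarray, from_rate_hz: float, to_rate_hz: float = FNIRS_RATE_HZ
) -> np.ndarray:
    """Anti-aliased polyphase resampling onto the fNIRS clock."""
    if to_rate_hz >= from_rate_hz:
        raise ValueError("resample_to_fnirs expects a rate reduction")
    frac = Fraction(to_rate_hz / from_rate_hz).limit_denominator(10000)
    return sp_signal.resample_poly(np.asarray(x, float), frac.numerator,
                                   frac.denominator, axis=-1)


def correlate_and_test(
    centroids: list[np.ndarray],
    smoothed_states: list[np.ndarray],
    fdr: bool = False,
    alpha: float = 0.05,
) -> CrossModalResult:
    """Per-subject cluster-by-microstate correlations and the group test.

    ``centroids[s]`` is [clusters x T_s] (dRSFC centroid time courses on
    the fNIRS clock); ``smoothed_states[s]`` is [states x T'_s] (HRF-smoothed
    occupancy resampled to the fNIRS rate).  Each pair of series is
    truncated to the common length before correlating.
    """
    if len(centroids) != len(smoothed_states):
        raise ValueError("need one state matrix per centroid matrix")
    if len(centroids) < 3:
        raise ValueError("group test requires >= 3 subjects")
    rs = []
    for C, S in zip(centroids, smoothed_states):
        T = min(C.shape[1], S.shape[1])
        Cc = C[:, :T] - C[:, :T].mean(axis=1, keepdims=True)
        Sc = S[:, :T] - S[:, :T].mean(axis=1, keepdims=True)
        nc = np.linalg.norm(Cc, axis=1)
        ns = np.linalg.norm(Sc, axis=1)
        nc[nc == 0] = 1.0
        ns[ns == 0] = 1.0
        rs.append((Cc / nc[:, None]) @ (Sc / ns[:, None]).T)
    r = np.stack(rs)  # [S x clusters x states]
    z = np.arctanh(np.clip(r, -0.999999, 0.999999))
    t, p = stats.ttest_1samp(z, 0.0, axis=0)
    mask = None
    if fdr:
        reject, _, _, _ = multipletests(p.ravel(), alpha=alpha, method="fdr_bh")
        mask = reject.reshape(p.shape)
    return CrossModalResult(r=r, z=z, group_t=t, group_p=p, fdr_mask=mask)
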