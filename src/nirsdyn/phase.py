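"""Instantaneous phase of network time courses via a complex Gabor wavelet.

A centroid time course x(t) is convolved with a Gaussian-windowed complex
exponential centered at frequency f (default 0.08 Hz, envelope width
sigma_t = 10 s).  The argument of the complex result is the instantaneous
phase theta(t); the analytic-signal convention is used, so the phase of a
pure cosine at f advances at +360 f degrees per second.  Phase differences
between two network time courses, wrapped to (-180, 180], describe their
momentary synchronization: near 0 deg the networks co-fluctuate
("positive synchronization", -45..45 deg), near 180 deg they are
anti-phase ("reverse synchronization", beyond +-135 deg).

The fingerprint histogram is the circular distribution of the phase
difference over the recording (percent of samples per angular bin).
Samples within one truncation radius of either end of the series are
convolution edge effects and are excluded from histograms and
synchronization fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve


@dataclass(frozen=True)
class GaborParams:
    f_hz: float = 0.08
    sigma_t_s: float = 10.0
    trunc_sigmas: float = 4.0

    def __post_init__(self) -> None:
        if self.f_hz <= 0 or self.sigma_t_s <= 0 or self.trunc_sigmas <= 0:
            raise ValueError("Gabor parameters must be positive")


@dataclass
class PhaseTrace:
    """Phase in degrees, wrapped to (-180, 180], with a validity mask.

    ``valid`` is False within the kernel truncation radius of either end
    (boundary-unreliable) and wherever the phase is undefined.
    """

    theta_deg: np.ndarray
    valid: np.ndarray
    dt_s: float
    source: str = ""


@dataclass
class FingerprintHistogram:
    bin_edges_deg: np.ndarray
    percent: np.ndarray
    reference_rings = (10.0, 20.0, 30.0)


def wrap_degrees(d: np.ndarray) -> np.ndarray:
    """Wrap angles (degrees) to the interval (-180, 180]."""
    return 180.0 - np.mod(180.0 - np.asarray(d, float), 360.0)


def gabor_kernel(p: GaborParams, dt_s: float) -> np.ndarray:
    """Sampled complex Gabor kernel, truncated at +-trunc_sigmas * sigma_t
    and normalized to unit energy.

    The kernel is ``exp(-t^2 / (2 sigma^2)) * exp(+i 2 pi f t)``; convolving
    with it equals correlating the signal against the conventional
    negative-exponent Gabor atom, which yields the analytic-signal phase.
    """
    radius = int(round(p.trunc_sigmas * p.sigma_t_s / dt_s))
    t = np.arange(-radius, radius + 1) * dt_s
    g = np.exp(-(t**2) / (2 * p.sigma_t_s**2)) * np.exp(1j * 2 * np.pi * p.f_hz * t)
    return g / np.linalg.norm(g)


def gabor_phase(
    x: np.ndarray, dt_s: float, params: GaborParams | None = None, source: str = ""
) -> PhaseTrace:
    """Instantaneous phase of a time course (degrees in (-180, 180])."""
    if params is None:
        params = GaborParams()
    x = np.asarray(x, dtype=float)
    g = gabor_kernel(params, dt_s)
    if x.size < g.size:
        raise ValueError(
            f"series length {x.size} shorter than Gabor kernel length {g.size}"
        )
    radius = (g.size - 1) // 2
    w = fftconvolve(x, g, mode="same")
    amp = np.abs(w)
    theta = wrap_degrees(np.degrees(np.angle(w)))
    valid = np.ones(x.size, dtype=bool)
    valid[:radius] = False
    valid[x.size - radius :] = False
    undefined = amp < 1e-12 * max(np.abs(x).max(), 1e-300)
    theta[undefined] = np.nan
    valid &= ~undefined
    return PhaseTrace(theta_deg=theta, valid=valid, dt_s=dt_s, source=source)


def phase_difference(a: PhaseTrace, b: PhaseTrace) -> PhaseTrace:
    """Wrapped phase difference theta_a - theta_b in (-180, 180]."""
    if a.theta_deg.shape != b.theta_deg.shape or a.dt_s != b.dt_s:
        raise ValueError("phase traces must share length and sampling")
    d = wrap_degrees(a.theta_deg - b.theta_deg)
    return PhaseTrace(
        theta_deg=d,
        valid=a.valid & b.valid,
        dt_s=a.dt_s,
        source=f"{a.source}-{b.source}",
    )


def fingerprint(dtheta: PhaseTrace, n_bins: int = 24) -> FingerprintHistogram:
    """Circular histogram (percent per bin) of a phase-difference trace."""
    vals = dtheta.theta_deg[dtheta.valid]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no valid samples for fingerprint")
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    # domain is (-180, 180]: values exactly at -180 cannot occur after
    # wrapping; 180 belongs to the last bin
    counts, _ = np.histogram(np.clip(vals, -179.9999999, 180.0), bins=edges)
    return FingerprintHistogram(bin_edges_deg=edges, percent=100.0 * counts / vals.size)


def classify_sync(dtheta: PhaseTrace) -> dict:
    """Fractions of valid time in positive / reverse / other synchronization.

    positive: phase difference in (-45, 45]; reverse: in (135, 180] or
    (-180, -135]; other: the remainder.
    """
    d = dtheta.theta_deg[dtheta.valid]
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise ValueError("no valid samples to classify")
    positive = (d > -45.0) & (d <= 45.0)
    reverse = (d > 135.0) | (d <= -135.0)
    return {
        "positive": float(positive.mean()),
        "reverse": float(reverse.mean()),
        "other": float(1.0 - positive.mean() - reverse.mean()),
    }
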