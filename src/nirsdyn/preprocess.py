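"""fNIRS preprocessing: MBLL conversion, filtering, short-channel regression.

The chain mirrors standard continuous-wave fNIRS practice for resting-state
connectivity work:

1. optical-density changes at three wavelengths -> dHbO / dHbR via the
   modified Beer-Lambert law (least-squares over the extinction system;
   the differential pathlength factor is fixed at 1, i.e. concentrations
   are in arbitrary consistent units — only correlations are consumed
   downstream);
2. zero-phase band-pass 0.01-1.5 Hz (drop drifts and high-frequency noise);
3. regression of each standard channel on the mean of the short-separation
   channels (removes shared scalp physiology: cardiac, respiration, Mayer
   waves, slow superficial drifts);
4. final zero-phase low-pass < 0.15 Hz retaining the spontaneous
   hemodynamic band.

All filters are 4th-order Butterworth applied forward-backward
(``sosfiltfilt``), preserving phase for the later phase-difference
analysis.  Every step is linear and length-preserving.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import ChannelLayout, HemoSeries


@dataclass
class OpticalRecording:
    """Optical-density change, [channels x samples x wavelengths]."""

    od: np.ndarray
    wavelengths_nm: tuple[float, ...] = (780.0, 805.0, 830.0)
    dt_s: float = 0.057
    layout: ChannelLayout | None = None

    def __post_init__(self) -> None:
        self.od = np.asarray(self.od, dtype=float)
        if self.od.ndim != 3:
            raise ValueError("od must be [channels x samples x wavelengths]")
        if self.od.shape[2] != len(self.wavelengths_nm):
            raise ValueError("wavelength axis does not match wavelengths_nm")
        if not np.all(np.isfinite(self.od)):
            raise ValueError("od contains non-finite values")


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction coefficients per wavelength: {nm: (e_HbO, e_HbR)}.

    Default values (1/(mM cm)) are literature coefficients for the three
    wavelengths of a typical CW machine; 805 nm sits at the isosbestic
    point where HbO and HbR absorb equally.
    """

    table: dict = None

    def __post_init__(self) -> None:
        if self.table is None:
            object.__setattr__(
                self,
                "table",
                {
                    780.0: (0.735, 1.075),
                    805.0: (0.860, 0.860),
                    830.0: (1.008, 0.740),
                },
            )
        for wl, (eo, er) in self.table.items():
            if eo <= 0 or er <= 0:
                raise ValueError(f"non-positive extinction at {wl} nm")

    def matrix(self, wavelengths: tuple[float, ...]) -> np.ndarray:
        """[n_wavelengths x 2] extinction matrix (columns: HbO, HbR)."""
        rows = []
        for wl in wavelengths:
            if wl not in self.table:
                raise ValueError(f"no extinction coefficients for {wl} nm")
            rows.append(self.table[wl])
        return np.asarray(rows, dtype=float)


def mbll_convert(
    rec: OpticalRecording, ext: ExtinctionTable | None = None
) -> tuple[HemoSeries, np.ndarray]:
    """Modified Beer-Lambert law: dOD -> (dHbO, dHbR).

    Solves, per channel and sample, the least-squares system
    ``dOD_lambda = e_HbO(lambda) * dHbO + e_HbR(lambda) * dHbR`` (pathlength
    absorbed into units).  Returns the dHbO series and the dHbR matrix;
    downstream analysis uses HbO only.
    """
    if ext is None:
        ext = ExtinctionTable()
    E = ext.matrix(rec.wavelengths_nm)
    if np.linalg.matrix_rank(E) < 2:
        raise ValueError(
            f"extinction system singular for wavelengths {rec.wavelengths_nm}"
        )
    pinv = np.linalg.pinv(E)  # [2 x n_wl]
    # od: [C x T x W] -> conc: [C x T x 2]
    conc = np.einsum("kw,ctw->ctk", pinv, rec.od)
    hbo = conc[:, :, 0]
    hbr = conc[:, :, 1]
    return HemoSeries(hbo=hbo, dt_s=rec.dt_s, layout=rec.layout), hbr


def _butter_sos(dt_s: float, low_hz: float | None, high_hz: float | None, order: int):
    nyq = 0.5 / dt_s
    if high_hz is not None and high_hz >= nyq:
        raise ValueError(f"cutoff {high_hz} Hz >= Nyquist {nyq:.3f} Hz")
    if low_hz and high_hz:
        return signal.butter(order, [low_hz / nyq, high_hz / nyq], "band", output="sos")
    if high_hz:
        return signal.butter(order, high_hz / nyq, "low", output="sos")
    return signal.butter(order, low_hz / nyq, "high", output="sos")


def bandpass(
    x: HemoSeries, low_hz: float = 0.01, high_hz: float = 1.5, order: int = 4
) -> HemoSeries:
    """Zero-phase Butterworth band-pass (default 0.01-1.5 Hz)."""
    if not (0 <= low_hz < high_hz):
        raise ValueError("need 0 <= low_hz < high_hz")
    sos = _butter_sos(x.dt_s, low_hz, high_hz, order)
    return x.with_data(signal.sosfiltfilt(sos, x.hbo, axis=-1))


def final_lowpass(x: HemoSeries, high_hz: float = 0.15, order: int = 4) -> HemoSeries:
    """Zero-phase low-pass retaining the spontaneous band (< 0.15 Hz)."""
    sos = _butter_sos(x.dt_s, None, high_hz, order)
    return x.with_data(signal.sosfiltfilt(sos, x.hbo, axis=-1))


def short_channel_regress(x: HemoSeries, layout: ChannelLayout | None = None) -> HemoSeries:
    """Regress every standard channel on the mean short-channel time course.

    Ordinary least squares with an intercept; the residual replaces the
    standard channel's signal.  Short channels are passed through
    unchanged.  Raises if the layout has no short channels — in that case
    the caller must skip the regression step explicitly.
    """
    if layout is None:
        layout = x.layout
    if layout is None:
        raise ValueError("short_channel_regress needs a channel layout")
    short = layout.short_idx
    if short.size == 0:
        raise ValueError(
            "layout has no short-separation channels; skip the regression "
            "step explicitly if none were recorded"
        )
    reg = x.hbo[short].mean(axis=0)
    A = np.column_stack([np.ones_like(reg), reg])
    std = layout.standard_idx
    beta, *_ = np.linalg.lstsq(A, x.hbo[std].T, rcond=None)
    resid = x.hbo[std] - (A @ beta).T
    out = x.hbo.copy()
    out[std] = resid
    return x.with_data(out)


def preprocess_chain(
    x: HemoSeries,
    layout: ChannelLayout | None = None,
    low_hz: float = 0.01,
    high_hz: float = 1.5,
    final_hz: float = 0.15,
    order: int = 4,
    skip_regression: bool = False,
) -> HemoSeries:
    """Full chain: band-pass -> short-channel regression -> low-pass.

    The short-channel regressor is computed from the band-passed data, so
    both sides of the regression have seen identical filtering.
    """
    y = bandpass(x, low_hz, high_hz, order)
    if not skip_regression:
        y = short_channel_regress(y, layout)
    return final_lowpass(y, final_hz, order)
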