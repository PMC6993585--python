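"""MBLL conversion, filtering and short-channel regression."""

import numpy as np
import pytest

from nirsdyn import SynthConfig, simulate_subject
from nirsdyn.core import ChannelLayout, HemoSeries
from nirsdyn.preprocess import (
    ExtinctionTable,
    OpticalRecording,
    bandpass,
    final_lowpass,
    mbll_convert,
    preprocess_chain,
    short_channel_regress,
)

DT = 0.057


def _series(data, layout=None):
    return HemoSeries(hbo=np.atleast_2d(data), dt_s=DT, layout=layout)


def _sine(f_hz, n=6000, dt=DT):
    return np.sin(2 * np.pi * f_hz * np.arange(n) * dt)


def _steady_amplitude(y):
    """Peak amplitude away from filter transients."""
    inner = y[y.size // 4 : -y.size // 4]
    return np.abs(inner).max()


# ---------------------------------------------------------------------------
# MBLL


class TestMBLL:
    def test_zero_od_gives_zero_concentrations(self):
        rec = OpticalRecording(od=np.zeros((2, 50, 3)))
        hbo, hbr = mbll_convert(rec)
        assert np.allclose(hbo.hbo, 0.0)
        assert np.allclose(hbr, 0.0)

    def test_linearity_in_od(self, rng):
        od = rng.standard_normal((3, 40, 3))
        h1, _ = mbll_convert(OpticalRecording(od=od))
        h2, _ = mbll_convert(OpticalRecording(od=2 * od))
        assert np.allclose(2 * h1.hbo, h2.hbo, atol=1e-12)

    def test_matches_pseudoinverse_oracle(self):
        ext = ExtinctionTable()
        od_vec = np.array([0.013, -0.004, 0.021])
        rec = OpticalRecording(od=od_vec[None, None, :])
        hbo, hbr = mbll_convert(rec, ext)
        # independent oracle: explicit normal-equations solution
        E = ext.matrix((780.0, 805.0, 830.0))
        expected = np.linalg.solve(E.T @ E, E.T @ od_vec)
        assert abs(hbo.hbo[0, 0] - expected[0]) < 1e-10 * max(1, abs(expected[0]))
        assert abs(hbr[0, 0] - expected[1]) < 1e-10 * max(1, abs(expected[1]))

    def test_singular_extinction_rejected(self):
        ext = ExtinctionTable(table={780.0: (1.0, 1.0), 805.0: (2.0, 2.0), 830.0: (3.0, 3.0)})
        rec = OpticalRecording(od=np.zeros((1, 5, 3)))
        with pytest.raises(ValueError, match="singular"):
            mbll_convert(rec, ext)


# ---------------------------------------------------------------------------
# filters


class TestFilters:
    def test_dc_rejected_by_bandpass(self):
        y = bandpass(_series(np.full(6000, 5.0))).hbo[0]
        assert _steady_amplitude(y) < 0.05

    @pytest.mark.parametrize("f, lo, hi", [(0.05, 0.9, 1.1), (3.0, 0.0, 0.1)])
    def test_bandpass_amplitude_response(self, f, lo, hi):
        y = bandpass(_series(_sine(f))).hbo[0]
        assert lo <= _steady_amplitude(y) <= hi

    @pytest.mark.parametrize("f, lo, hi", [(0.05, 0.9, 1.1), (1.0, 0.0, 0.1)])
    def test_final_lowpass_amplitude_response(self, f, lo, hi):
        y = final_lowpass(_series(_sine(f))).hbo[0]
        assert lo <= _steady_amplitude(y) <= hi

    def test_zero_in_zero_out(self):
        y = final_lowpass(_series(np.zeros(500))).hbo
        assert np.allclose(y, 0.0)

    def test_cutoff_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(_series(np.zeros(100)), 0.01, 10.0)


# ---------------------------------------------------------------------------
# short-channel regression


def _toy_layout():
    return ChannelLayout(
        channel_ids=("A", "B", "S1", "S2"),
        is_short=np.array([False, False, True, True]),
        roi=("F", "F", "S", "S"),
    )


class TestShortChannelRegression:
    def test_perfect_regressor_removed(self, rng):
        layout = _toy_layout()
        s = rng.standard_normal(400)
        data = np.vstack([s, rng.standard_normal(400), s, s])
        out = short_channel_regress(_series(data, layout))
        assert np.allclose(out.hbo[0], 0.0, atol=1e-10)

    def test_orthogonal_channel_untouched(self):
        layout = _toy_layout()
        n = 4000
        t = np.arange(n) * DT
        x = np.sin(2 * np.pi * 0.05 * t)
        s = np.sin(2 * np.pi * 0.10 * t)  # orthogonal over many cycles
        data = np.vstack([x, x, s, s])
        out = short_channel_regress(_series(data, layout))
        assert np.corrcoef(out.hbo[0], x)[0, 1] >= 0.999

    def test_residual_uncorrelated_with_regressor(self, rng):
        layout = _toy_layout()
        data = rng.standard_normal((4, 500))
        out = short_channel_regress(_series(data, layout))
        reg = data[2:].mean(axis=0)
        for ch in range(2):
            assert abs(np.corrcoef(out.hbo[ch], reg)[0, 1]) < 1e-10

    def test_no_short_channels_raises(self):
        layout = ChannelLayout(
            channel_ids=("A", "B"),
            is_short=np.array([False, False]),
            roi=("F", "F"),
        )
        with pytest.raises(ValueError, match="skip"):
            short_channel_regress(_series(np.zeros((2, 50)), layout))

    def test_superficial_signal_removed_on_synthetic_data(self):
        """After regression the superficial signal's contribution is gone:
        at a duration where the chance-correlation floor of independent
        band-limited signals is below 0.05, the residual correlation with
        the planted scalp signal drops from > 0.5 to < 0.05."""
        cfg = SynthConfig(duration_s=1920.0, seed=21)
        sub = simulate_subject(cfg, seed=21)
        clean = preprocess_chain(sub.hemo)
        sup = sub.truth.superficial_sig
        std = clean.layout.standard_idx
        pre = np.mean([abs(np.corrcoef(sub.hemo.hbo[c], sup)[0, 1]) for c in std])
        post = np.mean([abs(np.corrcoef(clean.hbo[c], sup)[0, 1]) for c in std])
        assert pre > 0.5
        assert post < 0.05


# ---------------------------------------------------------------------------
# whole chain


class TestChain:
    def test_chain_is_linear(self, rng):
        # linear in the standard channels; the short channels define the
        # regression projection, so they are shared between the inputs
        layout = _toy_layout()
        x = rng.standard_normal((4, 2000))
        y = rng.standard_normal((4, 2000))
        y[2:] = x[2:]
        a, b = 1.7, -0.4
        fx = preprocess_chain(_series(x, layout)).hbo
        fy = preprocess_chain(_series(y, layout)).hbo
        fxy = preprocess_chain(_series(a * x + b * y, layout)).hbo
        scale = max(np.abs(fxy).max(), 1e-12)
        assert np.allclose(fxy, a * fx + b * fy, atol=1e-8 * scale)

    def test_sample_count_preserved(self, short_subject):
        clean = preprocess_chain(short_subject.hemo)
        assert clean.n_samples == short_subject.hemo.n_samples
        assert clean.n_channels == short_subject.hemo.n_channels

    def test_short_channel_mean_decorrelated_after_chain(self):
        cfg = SynthConfig(duration_s=1920.0, seed=22)
        sub = simulate_subject(cfg, seed=22)
        clean = preprocess_chain(sub.hemo)
        short_mean = clean.hbo[clean.layout.short_idx].mean(axis=0)
        rs = [
            abs(np.corrcoef(clean.hbo[c], short_mean)[0, 1])
            for c in clean.layout.standard_idx
        ]
        assert np.mean(rs) < 0.05
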