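"""EEG microstate analysis: preprocessing, GFP peaks, AAHC, backfitting.

EEG microstates are quasi-stable scalp topographies (~80-120 ms each) that
tile the resting recording.  The segmentation pipeline:

1. band-pass 1-100 Hz with a 50 Hz notch, mask channels whose peak
   amplitude exceeds five times the pooled standard deviation, re-reference
   to the average of the good channels, and downsample to 125 Hz;
2. compute global field power (GFP) — the across-electrode standard
   deviation at each sample — and take the maps at GFP maxima as the
   high-SNR representative topographies;
3. cluster those maps with atomize-agglomerate hierarchical clustering
   (AAHC): start from singleton clusters, repeatedly dissolve the cluster
   contributing least global explained variance (GEV) and reassign its
   members to the template of highest squared spatial correlation
   (polarity-invariant); the template set is recorded at each k;
4. select k by the cross-validation criterion
   ``CV(k) = sigma_res^2 * ((n_e - 1) / (n_e - 1 - k))^2`` — residual
   variance penalized by degrees of freedom — minimized over the scanned
   range;
5. backfit: label every sample with the template of greatest
   polarity-invariant spatial correlation, producing an exhaustive,
   exclusive binary indicator series per microstate.

Spatial correlation is always computed on average-referenced (zero-mean
across electrodes) maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .core import EEGRecording

logger = logging.getLogger(__name__)


@dataclass
class GFPSeries:
    gfp: np.ndarray
    peak_indices: np.ndarray


@dataclass
class MicrostateModel:
    """Template maps with the per-k selection criteria.

    ``templates[k]`` is a [k x electrodes] stack of zero-mean unit-norm
    maps; ``cv`` and ``gev`` map k -> criterion value; ``chosen_k``
    minimizes CV over the scanned range.
    """

    templates: dict
    cv: dict
    gev: dict
    chosen_k: int
    labels: dict | None = None  # per-k map assignments (clustered subset)
    polarity_invariant: bool = True

    @property
    def chosen_templates(self) -> np.ndarray:
        return self.templates[self.chosen_k]


@dataclass
class MicrostateLabels:
    label: np.ndarray  # [samples]
    binary: np.ndarray  # [k x samples], rows sum to 1 per sample
    rate_hz: float


# ---------------------------------------------------------------------------
# preprocessing


def preprocess_eeg(
    raw: EEGRecording,
    band_hz: tuple[float, float] = (1.0, 100.0),
    notch_hz: float = 50.0,
    bad_sd_factor: float = 5.0,
    target_rate_hz: float = 125.0,
    order: int = 4,
) -> EEGRecording:
    """Filter, mask bad channels, average re-reference, downsample.

    A channel is bad when its peak absolute amplitude (after filtering)
    exceeds ``bad_sd_factor`` times the pooled standard deviation of all
    channels.  Re-referencing subtracts the mean of the good channels from
    every good channel at each sample.
    """
    if raw.rate_hz < 250:
        raise ValueError("EEG sampling rate must be >= 250 Hz")
    nyq = raw.rate_hz / 2.0
    lo, hi = band_hz
    if hi >= nyq:
        hi = 0.99 * nyq
    sos = signal.butter(order, [lo / nyq, hi / nyq], "band", output="sos")
    v = signal.sosfiltfilt(sos, raw.v, axis=-1)
    if lo < notch_hz < hi:
        b, a = signal.iirnotch(notch_hz, Q=30.0, fs=raw.rate_hz)
        v = signal.filtfilt(b, a, v, axis=-1)

    pooled_sd = v.std()
    bad = np.abs(v).max(axis=1) > bad_sd_factor * pooled_sd
    if bad.any():
        logger.warning("masking %d bad channels: %s",
                       bad.sum(), [raw.electrode_ids[i] for i in np.flatnonzero(bad)])
    good = ~bad
    if good.sum() < 3:
        raise ValueError("fewer than 3 channels survive the amplitude rule")
    v = v - v[good].mean(axis=0, keepdims=True)

    frac = Fraction(target_rate_hz / raw.rate_hz).limit_denominator(1000)
    # short anti-alias FIR: microstate segments last ~100 ms, so the
    # default long polyphase filter would smear state boundaries badly
    ntaps = 4 * max(frac.numerator, frac.denominator) + 1
    h = signal.firwin(ntaps, 1.0 / frac.denominator)  # resample_poly scales by `up`
    v = signal.resample_poly(v, frac.numerator, frac.denominator, axis=-1, window=h)
    return EEGRecording(
        v=v,
        rate_hz=raw.rate_hz * frac.numerator / frac.denominator,
        electrode_ids=raw.electrode_ids,
        bad=bad,
    )


def gfp(x: EEGRecording) -> GFPSeries:
    """Global field power (population SD across good electrodes) and its
    strict local maxima; plateaus take the left-most sample."""
    good = x.good_idx
    if good.size < 2:
        raise ValueError("GFP needs >= 2 good electrodes")
    g = x.v[good].std(axis=0)
    n = g.size
    peaks = []
    i = 1
    while i < n - 1:
        if g[i] > g[i - 1]:
            j = i
            while j + 1 < n and g[j + 1] == g[i]:
                j += 1
            if j + 1 < n and g[j + 1] < g[i]:
                peaks.append(i)  # left-most sample of the plateau
            i = j + 1
        else:
            i += 1
    return GFPSeries(gfp=g, peak_indices=np.asarray(peaks, dtype=int))


def peak_maps(x: EEGRecording, g: GFPSeries | None = None) -> np.ndarray:
    """[n_peaks x good-electrodes] maps at GFP maxima, average-referenced."""
    if g is None:
        g = gfp(x)
    maps = x.v[x.good_idx][:, g.peak_indices].T
    return maps - maps.mean(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# AAHC clustering


def _center(maps: np.ndarray) -> np.ndarray:
    return maps - maps.mean(axis=1, keepdims=True)


def _normalize(maps: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(maps, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    return maps / nrm


def _cluster_template(members: np.ndarray) -> np.ndarray:
    """Polarity-invariant cluster template: first principal axis of the
    member maps (zero-mean, unit norm)."""
    if members.shape[0] == 1:
        return _normalize(_center(members))[0]
    M = _center(members)
    _, _, vt = np.linalg.svd(M, full_matrices=False)
    t = vt[0]
    return t / np.linalg.norm(t)


def gev_of_labels(
    maps: np.ndarray, weights: np.ndarray, templates: np.ndarray, labels: np.ndarray
) -> float:
    """Global explained variance of a labeled template fit.

    GEV = sum_t (w_t * corr(map_t, template_{l(t)}))^2 / sum_t w_t^2 with
    polarity-invariant spatial correlation and GFP weights w.
    """
    u = _normalize(_center(maps))
    c = np.einsum("te,te->t", u, templates[labels])
    return float(np.sum((weights * c) ** 2) / np.sum(weights**2))


def aahc(
    maps: np.ndarray,
    k_range: range = range(1, 9),
    weights: np.ndarray | None = None,
    max_maps: int | None = 1000,
    seed: int | None = None,
) -> MicrostateModel:
    """Atomize-agglomerate hierarchical clustering of topographic maps.

    ``maps`` is [n_maps x electrodes].  ``weights`` (default: each map's
    GFP) enter the GEV computation.  When ``max_maps`` is set and exceeded,
    a random subset of maps is clustered (standard practice to bound the
    quadratic agglomeration cost).
    """
    maps = _center(np.asarray(maps, float))
    if weights is None:
        weights = maps.std(axis=1)
    weights = np.asarray(weights, float)
    n = maps.shape[0]
    if max_maps is not None and n > max_maps:
        rng = np.random.default_rng(seed)
        sel = np.sort(rng.choice(n, size=max_maps, replace=False))
        maps, weights = maps[sel], weights[sel]
        n = max_maps
    n_e = maps.shape[1]
    kmax = min(max(k_range), n)
    kmin = min(k_range)
    if kmax < max(k_range):
        logger.warning("k range truncated to %d (only %d maps)", kmax, n)

    u = _normalize(maps)  # unit-norm zero-mean maps for correlations
    labels = np.arange(n)
    templates = {c: u[c].copy() for c in range(n)}
    # GEV contribution per cluster
    w2_total = float(np.sum(weights**2))

    def contribution(c: int) -> float:
        idx = np.flatnonzero(labels == c)
        corr = u[idx] @ templates[c]
        return float(np.sum((weights[idx] * corr) ** 2) / w2_total)

    contrib = {c: contribution(c) for c in templates}

    recorded: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    n_clusters = len(templates)
    while True:
        if kmin <= n_clusters <= kmax:
            tpl = np.stack([templates[c] for c in sorted(templates)])
            remap = {c: i for i, c in enumerate(sorted(templates))}
            recorded[n_clusters] = (tpl, np.array([remap[c] for c in labels]))
        if n_clusters <= kmin:
            break
        # atomize the weakest cluster
        worst = min(contrib, key=lambda c: (contrib[c], c))
        members = np.flatnonzero(labels == worst)
        del templates[worst], contrib[worst]
        others = sorted(templates)
        T = np.stack([templates[c] for c in others])
        corr2 = (u[members] @ T.T) ** 2
        target = np.asarray(others)[np.argmax(corr2, axis=1)]
        labels[members] = target
        for c in np.unique(target):
            idx = np.flatnonzero(labels == c)
            templates[c] = _cluster_template(maps[idx])
            contrib[c] = contribution(c)
        n_clusters -= 1

    gev_k, cv_k = {}, {}
    total_var = float(np.sum(maps**2) / (n * (n_e - 1)))
    for k, (tpl, lab) in recorded.items():
        gev_k[k] = gev_of_labels(maps, weights, tpl, lab)
        # residual variance of the polarity-invariant template fit
        a = np.einsum("te,te->t", maps, tpl[lab])  # projection coefficients
        resid = np.sum(maps**2) - np.sum(a**2)
        sigma2 = resid / (n * (n_e - 1))
        if k >= n_e - 1:
            cv_k[k] = float("inf")  # no residual degrees of freedom left
        else:
            cv_k[k] = float(sigma2 * ((n_e - 1) / (n_e - 1 - k)) ** 2)

    ks = sorted(recorded)
    chosen = min(ks, key=lambda k: cv_k[k])
    return MicrostateModel(
        templates={k: recorded[k][0] for k in ks},
        cv=cv_k,
        gev=gev_k,
        chosen_k=chosen,
        labels={k: recorded[k][1] for k in ks},
    )


def cluster_microstates(
    x: EEGRecording,
    k_range: range = range(1, 9),
    max_maps: int | None = 1000,
    seed: int | None = None,
) -> MicrostateModel:
    """GFP peaks -> AAHC template model for one (preprocessed) recording."""
    g = gfp(x)
    if g.peak_indices.size < max(k_range):
        raise ValueError("too few GFP peaks for the requested k range")
    maps = peak_maps(x, g)
    return aahc(maps, k_range=k_range, weights=g.gfp[g.peak_indices],
                max_maps=max_maps, seed=seed)


def group_templates(
    models: list[MicrostateModel], k: int, k_range: range | None = None
) -> np.ndarray:
    """Group-level templates: pool every subject's k templates and cluster
    the pooled set with the same AAHC down to k maps."""
    pooled = np.concatenate([m.templates[k] for m in models], axis=0)
    gm = aahc(pooled, k_range=range(k, k + 1), weights=np.ones(pooled.shape[0]),
              max_maps=None)
    return gm.templates[k]


# ---------------------------------------------------------------------------
# backfitting


def backfit(x: EEGRecording, templates: np.ndarray) -> MicrostateLabels:
    """Label each sample with the best-matching template.

    Spatial correlation is polarity-invariant and computed on
    average-referenced maps.  Samples with a flat (zero-variance) map keep
    the previous sample's label.
    """
    k = templates.shape[0]
    v = x.v[x.good_idx]
    if templates.shape[1] != v.shape[0]:
        raise ValueError("template electrode count does not match recording")
    maps = v - v.mean(axis=0, keepdims=True)  # re-reference per sample
    nrm = np.linalg.norm(maps, axis=0)
    t_unit = _normalize(_center(templates))
    corr = np.abs(t_unit @ maps)  # [k x samples], unnormalized by map norm
    label = np.argmax(corr, axis=0)
    flat = nrm < 1e-12 * max(nrm.max(), 1e-300)
    if flat.any():
        logger.warning("%d flat samples keep the previous label", int(flat.sum()))
        for t in np.flatnonzero(flat):
            label[t] = label[t - 1] if t > 0 else 0
    binary = np.zeros((k, label.size))
    binary[label, np.arange(label.size)] = 1.0
    return MicrostateLabels(label=label, binary=binary, rate_hz=x.rate_hz)


def segment_durations(label: np.ndarray, rate_hz: float) -> np.ndarray:
    """Durations (ms) of the contiguous constant-label segments."""
    label = np.asarray(label)
    change = np.flatnonzero(np.diff(label) != 0)
    bounds = np.r_[-1, change, label.size - 1]
    return np.diff(bounds) / rate_hz * 1000.0
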