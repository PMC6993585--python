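"""Static and sliding-window functional connectivity and its variability.

Dynamic resting-state functional connectivity (dRSFC) is the windowed
Pearson correlation of every channel pair: a window of fixed length slides
along the recording in steps of one sample (by default) and the
correlation within each window gives one time point of the edge's
connectivity time course.  With 36 standard channels there are
C(36, 2) = 630 edges.  Static RSFC (sRSFC) is the same correlation over
the entire recording.

Variability of an edge's dRSFC is the sample variance of its windowed
correlations.  Edges are categorized by the unordered ROI pair of their
endpoints (5 ROIs -> 5 within-ROI + 10 between-ROI = 15 categories), and
group comparisons contrast within-ROI vs between-ROI vs short-channel-pair
variability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ChannelLayout, HemoSeries, edge_index

logger = logging.getLogger(__name__)


@dataclass
class DRSFCSeries:
    """Edge x window matrix of sliding-window correlations.

    ``r[e, w]`` is the Pearson correlation of edge ``e``'s two channels in
    window ``w``.  Zero-variance windows are marked NaN.  ``edges`` maps
    edge index -> (i, j) channel indices into ``channel_idx`` of the source
    series; ``window_times_s`` are window-center times.
    """

    r: np.ndarray
    edges: np.ndarray
    channel_idx: np.ndarray
    window_len_samples: int
    step_samples: int
    dt_s: float
    window_times_s: np.ndarray

    @property
    def n_edges(self) -> int:
        return self.r.shape[0]

    @property
    def n_windows(self) -> int:
        return self.r.shape[1]


@dataclass
class SRSFCMatrix:
    """Full-duration correlation matrix with optional group statistics."""

    r: np.ndarray
    channel_idx: np.ndarray
    group_t: np.ndarray | None = None
    group_p: np.ndarray | None = None
    fdr_mask: np.ndarray | None = None


@dataclass
class VariabilityReport:
    """Per-edge dRSFC variance with ROI-pair categorization."""

    edge_var: np.ndarray
    category: list
    category_mean: dict
    category_sd: dict
    mean_within: float
    mean_between: float


def _select_channels(x: HemoSeries, channels: str | np.ndarray) -> np.ndarray:
    if isinstance(channels, str):
        if x.layout is None:
            raise ValueError("channel selection by class requires a layout")
        if channels == "standard":
            return x.layout.standard_idx
        if channels == "short":
            return x.layout.short_idx
        if channels == "all":
            return np.arange(x.n_channels)
        raise ValueError(f"unknown channel selection {channels!r}")
    return np.asarray(channels, dtype=int)


def sliding_window_corr(
    x: HemoSeries,
    window_s: float = 20.0,
    step_samples: int = 1,
    channels: str | np.ndarray = "standard",
) -> DRSFCSeries:
    """Sliding-window Pearson correlation for every channel pair.

    The window length in samples is ``round(window_s / dt_s)`` and the
    window is shifted by ``step_samples`` (default one sample).  Windows in
    which either channel has zero variance yield NaN and are logged.
    """
    idx = _select_channels(x, channels)
    if idx.size < 2:
        raise ValueError("need at least two channels")
    data = x.hbo[idx]
    wl = int(round(window_s / x.dt_s))
    if wl < 3:
        raise ValueError("window must span at least 3 samples")
    n = data.shape[1]
    if n < wl:
        raise ValueError(f"series ({n} samples) shorter than window ({wl})")

    edges = edge_index(idx.size)
    starts = np.arange(0, n - wl + 1, step_samples)

    # windowed sums via cumulative sums; exact rational-free arithmetic in
    # float64, validated against a naive per-window recomputation in tests
    cs = np.concatenate([np.zeros((data.shape[0], 1)), np.cumsum(data, axis=1)], axis=1)
    cs2 = np.concatenate(
        [np.zeros((data.shape[0], 1)), np.cumsum(data**2, axis=1)], axis=1
    )
    s1 = cs[:, starts + wl] - cs[:, starts]  # [C x W]
    s2 = cs2[:, starts + wl] - cs2[:, starts]

    prod = data[edges[:, 0]] * data[edges[:, 1]]  # [E x n]
    csx = np.concatenate([np.zeros((edges.shape[0], 1)), np.cumsum(prod, axis=1)], axis=1)
    sxy = csx[:, starts + wl] - csx[:, starts]

    vi = wl * s2 - s1**2  # wl^2 * variance
    cov = wl * sxy - s1[edges[:, 0]] * s1[edges[:, 1]]
    denom2 = vi[edges[:, 0]] * vi[edges[:, 1]]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(np.maximum(denom2, 0.0))
    bad = denom2 <= 0
    if bad.any():
        logger.warning("%d zero-variance windows marked undefined", int(bad.sum()))
        r[bad] = np.nan
    np.clip(r, -1.0, 1.0, out=r)

    times = (starts + (wl - 1) / 2.0) * x.dt_s
    return DRSFCSeries(
        r=r,
        edges=edges,
        channel_idx=idx,
        window_len_samples=wl,
        step_samples=step_samples,
        dt_s=x.dt_s,
        window_times_s=times,
    )


def static_rsfc(x: HemoSeries, channels: str | np.ndarray = "standard") -> SRSFCMatrix:
    """Pearson correlation over the whole recording."""
    idx = _select_channels(x, channels)
    data = x.hbo[idx]
    sd = data.std(axis=1)
    const = sd == 0
    if const.any():
        logger.warning("%d constant channels marked undefined in sRSFC", const.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data)
    r[const, :] = np.nan
    r[:, const] = np.nan
    np.fill_diagonal(r, 1.0)
    return SRSFCMatrix(r=r, channel_idx=idx)


def group_srsfc_test(matrices: list[SRSFCMatrix], alpha: float = 0.01) -> SRSFCMatrix:
    """Edge-wise one-sample t-test across subjects on Fisher-z values,
    Benjamini-Hochberg FDR corrected at ``alpha``.

    Returns the group-mean correlation matrix with t, p and the FDR
    significance mask on the off-diagonal entries.
    """
    if len(matrices) < 2:
        raise ValueError("group test requires >= 2 subjects")
    n_ch = matrices[0].r.shape[0]
    edges = edge_index(n_ch)
    rs = np.array([m.r[edges[:, 0], edges[:, 1]] for m in matrices])  # [S x E]
    z = np.arctanh(np.clip(rs, -0.999999, 0.999999))
    t, p = stats.ttest_1samp(z, 0.0, axis=0)
    reject, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")

    mean_r = np.tanh(z.mean(axis=0))
    out_r = np.eye(n_ch)
    out_t = np.zeros((n_ch, n_ch))
    out_p = np.ones((n_ch, n_ch))
    mask = np.zeros((n_ch, n_ch), dtype=bool)
    out_r[edges[:, 0], edges[:, 1]] = out_r[edges[:, 1], edges[:, 0]] = mean_r
    out_t[edges[:, 0], edges[:, 1]] = out_t[edges[:, 1], edges[:, 0]] = t
    out_p[edges[:, 0], edges[:, 1]] = out_p[edges[:, 1], edges[:, 0]] = p
    mask[edges[:, 0], edges[:, 1]] = mask[edges[:, 1], edges[:, 0]] = reject
    return SRSFCMatrix(
        r=out_r, channel_idx=matrices[0].channel_idx, group_t=out_t, group_p=out_p, fdr_mask=mask
    )


def edge_categories(d: DRSFCSeries, layout: ChannelLayout) -> list[str]:
    """Unordered ROI-pair label per edge, e.g. ``"F-F"`` or ``"F-P"``."""
    rois = [layout.roi[c] for c in d.channel_idx]
    labels = []
    for i, j in d.edges:
        a, b = sorted((rois[i], rois[j]))
        labels.append(f"{a}-{b}")
    return labels


def variability(d: DRSFCSeries, layout: ChannelLayout) -> VariabilityReport:
    """Per-edge variance of the windowed correlations, by ROI category.

    NaN (undefined) windows are excluded from each edge's variance.  The
    report carries, per category, the mean and SD of edge variances, plus
    the subject-level mean within-ROI and between-ROI variance used by the
    group comparison.
    """
    edge_var = np.array(
        [np.nanvar(row, ddof=1) if np.isfinite(row).sum() >= 2 else np.nan for row in d.r]
    )
    cats = edge_categories(d, layout)
    uniq = sorted(set(cats))
    cmean, csd = {}, {}
    for c in uniq:
        v = edge_var[[i for i, lab in enumerate(cats) if lab == c]]
        v = v[np.isfinite(v)]
        if v.size < 2:
            logger.warning("category %s has <2 edges; excluded from tests", c)
        cmean[c] = float(v.mean()) if v.size else np.nan
        csd[c] = float(v.std(ddof=1)) if v.size > 1 else np.nan
    within = [c for c in uniq if c.split("-")[0] == c.split("-")[1]]
    between = [c for c in uniq if c.split("-")[0] != c.split("-")[1]]
    wmask = np.array([cats[i].split("-")[0] == cats[i].split("-")[1] for i in range(len(cats))])
    return VariabilityReport(
        edge_var=edge_var,
        category=cats,
        category_mean=cmean,
        category_sd=csd,
        mean_within=float(np.nanmean(edge_var[wmask])) if wmask.any() else np.nan,
        mean_between=float(np.nanmean(edge_var[~wmask])) if (~wmask).any() else np.nan,
    )


def short_channel_variability(x: HemoSeries, window_s: float = 20.0, step_samples: int = 1) -> float:
    """Mean dRSFC variance over the short-channel pairs of one subject."""
    d = sliding_window_corr(x, window_s=window_s, step_samples=step_samples, channels="short")
    v = np.array([np.nanvar(row, ddof=1) for row in d.r])
    return float(np.nanmean(v))


def variability_group_tests(
    within: np.ndarray, between: np.ndarray, short: np.ndarray | None = None
) -> dict:
    """Two-sample t-tests between subject-level mean variabilities.

    Inputs are per-subject means (within-ROI, between-ROI and, optionally,
    short-channel-pair variance).  The family of reported comparisons is
    Bonferroni-corrected: within-vs-between alone when no short values are
    given, otherwise the three pairwise comparisons.
    """
    within = np.asarray(within, float)
    between = np.asarray(between, float)
    comps = {"within_vs_between": (within, between)}
    if short is not None:
        short = np.asarray(short, float)
        comps["within_vs_short"] = (within, short)
        comps["between_vs_short"] = (between, short)
    m = len(comps)
    out = {}
    for name, (a, b) in comps.items():
        t, p = stats.ttest_ind(a, b)
        out[name] = {
            "t": float(t),
            "p": float(p),
            "p_bonferroni": float(min(1.0, p * m)),
            "mean_diff": float(a.mean() - b.mean()),
        }
    out["correction"] = f"bonferroni x{m}"
    return out
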