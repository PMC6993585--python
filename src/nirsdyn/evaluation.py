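"""Parameter-recovery and calibration experiments on synthetic cohorts.

Each function simulates data with :mod:`nirsdyn.synthetic`, runs the
relevant analysis stages exactly as a user would, and summarizes how well
the planted structure was recovered.  They are consumed by the test suite
and by ``scripts/acceptance.py``; problem sizes are arguments so callers
can trade precision for runtime.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from . import clustering, connectivity, crossmodal, microstates, preprocess
from .synthetic import SynthConfig, simulate_subject

FNIRS_DT_S = 0.057


def fnirs_rate_hz(dt_s: float = FNIRS_DT_S) -> float:
    """Sampling rate implied by the sampling interval (57 ms -> 17.5439 Hz)."""
    return 1.0 / dt_s


def subject_drsfc(
    config: SynthConfig, seed: int, step_samples: int = 10
) -> tuple[object, connectivity.DRSFCSeries, preprocess.HemoSeries]:
    """Simulate one subject and run preprocessing + sliding-window dFC."""
    sub = simulate_subject(config, seed=seed)
    clean = preprocess.preprocess_chain(sub.hemo)
    d = connectivity.sliding_window_corr(clean, step_samples=step_samples)
    return sub, d, clean


# ---------------------------------------------------------------------------
# community recovery / validity scan


def community_recovery(
    seed: int,
    n_subjects: int = 20,
    restarts: int = 30,
    step_samples: int = 10,
    config: SynthConfig | None = None,
) -> dict:
    """ARI between k-means edge clusters and the planted communities.

    Each subject is clustered at k = number of planted communities
    (networks + the stable local cluster).
    """
    config = config or SynthConfig()
    aris = []
    for s in range(n_subjects):
        sub, d, _ = subject_drsfc(config, seed + s, step_samples)
        k = sub.truth.n_communities
        sol = clustering.kmeans_edges(d, k, restarts=restarts, seed=seed + s)
        aris.append(adjusted_rand_score(sub.truth.edge_community, sol.labels))
    return {"ari": aris, "mean_ari": float(np.mean(aris))}


def validity_replicates(
    seed: int,
    n_replicates: int = 20,
    n_subjects: int = 8,
    restarts: int = 8,
    k_range: range = range(2, 9),
    step_samples: int = 12,
    config: SynthConfig | None = None,
) -> dict:
    """How often the validity-scan elbow picks the planted network count."""
    config = config or SynthConfig()
    chosen = []
    for rep in range(n_replicates):
        base = seed + 1000 * rep
        series = [
            subject_drsfc(config, base + s, step_samples)[1] for s in range(n_subjects)
        ]
        scan = clustering.validity_scan(
            series, k_range=k_range, restarts=restarts, seed=base
        )
        chosen.append(scan.chosen_k)
    hit = float(np.mean([c == config.n_networks for c in chosen]))
    return {"chosen_k": chosen, "hit_rate": hit, "target_k": config.n_networks}


# ---------------------------------------------------------------------------
# variability ordering


def variability_experiment(
    seed: int,
    n_subjects: int = 20,
    step_samples: int = 10,
    config: SynthConfig | None = None,
) -> dict:
    """Within-ROI vs between-ROI vs short-channel dRSFC variability."""
    config = config or SynthConfig()
    within, between, short = [], [], []
    for s in range(n_subjects):
        _, d, clean = subject_drsfc(config, seed + s, step_samples)
        rep = connectivity.variability(d, clean.layout)
        within.append(rep.mean_within)
        between.append(rep.mean_between)
        short.append(
            connectivity.short_channel_variability(clean, step_samples=step_samples)
        )
    tests = connectivity.variability_group_tests(
        np.array(within), np.array(between), np.array(short)
    )
    return {
        "mean_within": float(np.mean(within)),
        "mean_between": float(np.mean(between)),
        "mean_short": float(np.mean(short)),
        "tests": tests,
    }


# ---------------------------------------------------------------------------
# microstate recovery


def microstate_recovery(
    seed: int,
    n_subjects: int = 10,
    config: SynthConfig | None = None,
    k_range: range = range(1, 9),
    max_maps: int = 1000,
) -> dict:
    """Template similarity, backfit accuracy and dwell-time recovery."""
    config = config or SynthConfig()
    tpl_r, acc, dwell, chosen = [], [], [], []
    for s in range(n_subjects):
        sub = simulate_subject(config, seed=seed + s)
        clean = microstates.preprocess_eeg(sub.eeg)
        model = microstates.cluster_microstates(
            clean, k_range=k_range, max_maps=max_maps, seed=seed + s
        )
        chosen.append(model.chosen_k)
        k = config.n_states
        tpl = model.templates[k]
        tt = sub.truth.ms_templates[:, clean.good_idx]
        tt = tt - tt.mean(axis=1, keepdims=True)
        tt /= np.linalg.norm(tt, axis=1, keepdims=True)
        C = np.abs(
            (tpl / np.linalg.norm(tpl, axis=1, keepdims=True)) @ tt.T
        )
        rows, cols = linear_sum_assignment(-C)
        tpl_r.append(float(C[rows, cols].min()))
        perm = np.empty(k, dtype=int)
        perm[rows] = cols
        lab = microstates.backfit(clean, tpl)
        decim = int(round(sub.eeg.rate_hz / lab.rate_hz))
        truth_seq = sub.truth.ms_sequence[::decim][: lab.label.size]
        acc.append(float((perm[lab.label] == truth_seq).mean()))
        dwell.append(float(microstates.segment_durations(lab.label, lab.rate_hz).mean()))
    return {
        "min_template_r": float(np.min(tpl_r)),
        "mean_template_r": float(np.mean(tpl_r)),
        "mean_accuracy": float(np.mean(acc)),
        "mean_dwell_ms": float(np.mean(dwell)),
        "chosen_k": chosen,
        "chosen_k_rate": float(np.mean([c == config.n_states for c in chosen])),
    }


# ---------------------------------------------------------------------------
# microstate-network coupling


def _crossmodal_cohort(
    config: SynthConfig, seed: int, n_subjects: int, restarts: int, step_samples: int
) -> crossmodal.CrossModalResult:
    """Run the full cross-modal analysis on one cohort.

    Clusters and microstates are matched to the planted networks and
    templates per subject so that cells of the group matrix have a fixed
    meaning across subjects.
    """
    cents, states = [], []
    k_comm = config.n_networks + 1
    for s in range(n_subjects):
        sub = simulate_subject(config, seed=seed + s)
        clean = preprocess.preprocess_chain(sub.hemo)
        d = connectivity.sliding_window_corr(clean, step_samples=step_samples)
        sol = clustering.kmeans_edges(d, k_comm, restarts=restarts, seed=seed + s)
        comm = sub.truth.edge_community.copy()
        comm[comm == -1] = config.n_networks
        overlap = np.zeros((k_comm, k_comm))
        for c in range(k_comm):
            for g in range(k_comm):
                overlap[c, g] = np.sum((sol.labels == c) & (comm == g))
        rows, cols = linear_sum_assignment(-overlap)
        cluster_of_comm = np.empty(k_comm, dtype=int)
        cluster_of_comm[cols] = rows
        cent = sol.centroids[cluster_of_comm][: config.n_networks]

        ceeg = microstates.preprocess_eeg(sub.eeg)
        model = microstates.cluster_microstates(
            ceeg, k_range=range(1, config.n_states + 3), max_maps=800, seed=seed + s
        )
        tpl = model.templates[config.n_states]
        tt = sub.truth.ms_templates[:, ceeg.good_idx]
        tt = tt - tt.mean(axis=1, keepdims=True)
        C = np.abs(
            (tpl / np.linalg.norm(tpl, axis=1, keepdims=True))
            @ (tt / np.linalg.norm(tt, axis=1, keepdims=True)).T
        )
        rows, cols = linear_sum_assignment(-C)
        order = np.empty(config.n_states, dtype=int)
        order[cols] = rows
        lab = microstates.backfit(ceeg, tpl[order])
        sm = crossmodal.smooth_states(lab)
        sm = crossmodal.resample_to_fnirs(sm, lab.rate_hz)
        cents.append(cent)
        states.append(np.atleast_2d(sm)[:, ::step_samples])
    return crossmodal.correlate_and_test(cents, states)


def coupling_replicates(
    seed: int,
    n_replicates: int = 6,
    n_subjects: int = 10,
    restarts: int = 15,
    step_samples: int = 10,
    config: SynthConfig | None = None,
) -> dict:
    """Detection of the planted microstate-network coupling.

    Reports, over replicate cohorts: how often the coupled cell of the
    cluster-by-microstate matrix is significant (p < 0.05), and how often
    it carries the largest group |t|.  Specificity is measured on matched
    *null* cohorts (coupling disabled): there every cell is genuinely null
    and the cell-wise significance rate estimates the false-positive rate.
    """
    config = config or SynthConfig()
    net, state = config.coupling_pair
    detected, strongest = [], []
    null_hits = 0
    null_cells = 0
    null_cfg = dataclasses.replace(config, coupling_pair=None)
    for rep in range(n_replicates):
        base = seed + 7919 * rep
        res = _crossmodal_cohort(config, base, n_subjects, restarts, step_samples)
        detected.append(bool(res.group_p[net, state] < 0.05))
        strongest.append(
            bool(np.argmax(np.abs(res.group_t)) == net * res.group_t.shape[1] + state)
        )
        res0 = _crossmodal_cohort(null_cfg, base + 37, n_subjects, restarts, step_samples)
        null_hits += int((res0.group_p < 0.05).sum())
        null_cells += res0.group_p.size
    return {
        "detection_rate": float(np.mean(detected)),
        "strongest_cell_rate": float(np.mean(strongest)),
        "null_false_positive_rate": float(null_hits / null_cells),
    }


# ---------------------------------------------------------------------------
# type-I calibration


def variability_test_type_I(
    seed: int, n_resamples: int = 2000, n_subjects: int = 20, alpha: float = 0.05
) -> float:
    """Type-I error of the within-vs-between two-sample t-test under the
    null (both groups drawn from the same distribution of subject-level
    mean variabilities)."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_resamples):
        a = 0.15 + 0.03 * rng.standard_normal(n_subjects)
        b = 0.15 + 0.03 * rng.standard_normal(n_subjects)
        _, p = stats.ttest_ind(a, b)
        hits += p < alpha
    return hits / n_resamples


def crossmodal_test_type_I(
    seed: int,
    n_cohorts: int = 200,
    n_subjects: int = 20,
    n_timepoints: int = 800,
    alpha: float = 0.05,
) -> float:
    """Type-I error of the cross-modal group test under the null.

    Each subject contributes the correlation of two independent smooth
    (autocorrelated) series — mimicking an HRF-smoothed occupancy against
    an unrelated centroid time course — Fisher-z transformed and tested
    against zero across subjects.
    """
    rng = np.random.default_rng(seed)
    hits = 0

    def smooth(n_series: int) -> np.ndarray:
        x = rng.standard_normal((n_series, n_timepoints))
        k = np.hanning(101)
        k /= k.sum()
        return np.apply_along_axis(lambda r: np.convolve(r, k, "same"), 1, x)

    for _ in range(n_cohorts):
        a = smooth(n_subjects)
        b = smooth(n_subjects)
        a = a - a.mean(axis=1, keepdims=True)
        b = b - b.mean(axis=1, keepdims=True)
        r = np.sum(a * b, axis=1) / (
            np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
        )
        z = np.arctanh(r)
        _, p = stats.ttest_1samp(z, 0.0)
        hits += p < alpha
    return hits / n_cohorts
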