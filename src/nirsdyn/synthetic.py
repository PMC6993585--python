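"""Synthetic resting-state fNIRS-EEG cohorts with planted ground truth.

The generator emulates an eyes-closed resting recording of the kind the
pipeline is built for: 36 standard-separation + 4 short-separation fNIRS
channels over five scalp ROIs sampled every 57 ms, and ~30-channel EEG at
1000 Hz, 8 minutes long.  Ground truth that every downstream stage is meant
to recover is planted explicitly and exported alongside the data:

* inter-ROI couplings are grouped into a small number of functional
  *networks*: each network is a set of ROI pairs (e.g. a frontal-parietal-
  temporal triangle) whose coupling strength is slowly modulated in time by
  a smooth activation bump per network; activations are staggered so at any
  moment essentially one network is "on", which makes recovery
  identifiable.  Channels are drawn from a time-varying target covariance
  (per-channel band-limited 0.01-0.15 Hz latents mixed by its Cholesky
  factor), so a between-ROI edge's windowed correlation tracks its
  network's planted coupling curve;
* channels within one ROI are strongly and stably correlated (local
  connectivity is not modulated), so within-ROI connectivity is high and
  steady while between-ROI connectivity swings — the ordering the
  variability analysis should find.  Within-ROI edges form the planted
  "background" community: local, stable, belonging to no modulated
  network;
* every channel, standard and short, picks up a common superficial
  (scalp) signal with cardiac (~1 Hz), respiratory (~0.3 Hz), Mayer-wave
  (~0.1 Hz) and very-slow drift components; short channels contain little
  else, which is what makes short-channel regression work;
* EEG potentials switch among a small set of zero-mean, mutually orthogonal
  template topographies (microstates) in contiguous segments whose dwell
  times are uniform on a configured range (default 80-120 ms); occupancy of
  one state is biased upward when the coupling of one network is high,
  planting the cross-modal association.

Everything is drawn from one ``numpy`` generator seeded from the config, so
a fixed seed gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import ROI_LABELS, ChannelLayout, EEGRecording, HemoSeries, edge_index

BACKGROUND = -1  # community id of the stable within-ROI edges


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic cohort; defaults mirror the target setup.

    Channel counts, sampling and duration follow the acquisition the
    pipeline expects (36 standard + 4 short channels, 57 ms sampling, 8 min;
    EEG at 1000 Hz).  Gains are in units of the unit-variance latent
    signals.
    """

    n_std_channels: int = 36
    n_short_channels: int = 4
    n_rois: int = 5
    n_networks: int = 3
    duration_s: float = 480.0
    dt_s: float = 0.057
    eeg_rate_hz: float = 1000.0
    n_electrodes: int = 30
    n_states: int = 3
    dwell_range_ms: tuple[float, float] = (80.0, 120.0)
    # hemodynamic covariance targets (channel signal variance is 1)
    within_roi_cov: float = 0.75
    between_roi_cov: float = 0.65
    sup_gain: float = 1.0
    noise_sd: float = 0.3
    # network activation-cycle frequency (Hz); activations of the
    # n_networks are staggered within one cycle
    coupling_freq_hz: float = 0.004
    # EEG sensor noise, uV-scale units per electrode (template loadings
    # are ~0.2 at unit template norm)
    eeg_noise_sd: float = 0.05
    # cross-modal planting: (network id, microstate id); None disables
    coupling_pair: tuple[int, int] | None = (0, 0)
    coupling_strength: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_std_channels <= 0 or self.n_short_channels < 0:
            raise ValueError("channel counts must be positive")
        if self.n_rois < 1 or self.n_networks < 1:
            raise ValueError("n_rois and n_networks must be >= 1")
        if self.dt_s <= 0 or self.duration_s <= 0:
            raise ValueError("dt_s and duration_s must be positive")
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if self.eeg_rate_hz < 2000.0 / self.dwell_range_ms[0]:
            # need at least a handful of samples per dwell segment
            raise ValueError("eeg_rate_hz too low to represent dwell times")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s / self.dt_s))

    @property
    def n_eeg_samples(self) -> int:
        return int(round(self.duration_s * self.eeg_rate_hz))


@dataclass
class GroundTruth:
    """Planted latent structure exported next to the synthetic data.

    ``edge_community[e]`` is the planted network id of standard-channel
    edge ``e`` (upper-triangle order), or ``BACKGROUND`` for the stable
    local (within-ROI) community.  ``coupling_mod`` is the [networks x samples] modulation in
    [0, 1]; ``superficial_sig`` the shared scalp signal; ``ms_sequence``
    the planted microstate id per EEG sample; ``ms_templates`` the
    [states x electrodes] topographies; ``coupling_pair`` the
    (network, microstate) pair whose dynamics were linked.
    """

    pair_network: dict | None = None  # "ROI-ROI" label -> network id
    edge_community: np.ndarray | None = None
    coupling_mod: np.ndarray | None = None
    superficial_sig: np.ndarray | None = None
    ms_sequence: np.ndarray | None = None
    ms_templates: np.ndarray | None = None
    coupling_pair: tuple[int, int] | None = None

    @property
    def n_communities(self) -> int:
        """Number of distinct planted edge communities (incl. background)."""
        return len(np.unique(self.edge_community))

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        return {
            "pair_network": self.pair_network,
            "edge_community": arr(self.edge_community),
            "coupling_mod": arr(self.coupling_mod),
            "superficial_sig": arr(self.superficial_sig),
            "ms_sequence": arr(self.ms_sequence),
            "ms_templates": arr(self.ms_templates),
            "coupling_pair": list(self.coupling_pair) if self.coupling_pair else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        def arr(x, dtype=float):
            return None if x is None else np.asarray(x, dtype=dtype)

        return cls(
            pair_network=d.get("pair_network"),
            edge_community=arr(d.get("edge_community"), int),
            coupling_mod=arr(d.get("coupling_mod")),
            superficial_sig=arr(d.get("superficial_sig")),
            ms_sequence=arr(d.get("ms_sequence"), int),
            ms_templates=arr(d.get("ms_templates")),
            coupling_pair=tuple(d["coupling_pair"]) if d.get("coupling_pair") else None,
        )


# ---------------------------------------------------------------------------
# layout


def gen_layout(config: SynthConfig) -> ChannelLayout:
    """Build the channel layout: standard channels split over ROIs (within
    one channel of an even split), plus short-separation channels."""
    labels = list(ROI_LABELS)
    while len(labels) < config.n_rois:
        labels.append(f"R{len(labels) + 1}")
    labels = labels[: config.n_rois]

    groups = np.array_split(np.arange(config.n_std_channels), config.n_rois)
    roi = [""] * config.n_std_channels
    for g, lab in zip(groups, labels):
        for i in g:
            roi[i] = lab

    ids = [f"CH{i + 1:02d}" for i in range(config.n_std_channels)]
    ids += [f"SH{i + 1}" for i in range(config.n_short_channels)]
    is_short = np.r_[
        np.zeros(config.n_std_channels, bool), np.ones(config.n_short_channels, bool)
    ]
    roi += ["S"] * config.n_short_channels
    return ChannelLayout(channel_ids=tuple(ids), is_short=is_short, roi=tuple(roi))


def roi_pair_networks(config: SynthConfig, layout: ChannelLayout) -> dict:
    """Assignment of inter-ROI couplings (unordered ROI pairs) to networks.

    Each planted network is a set of ROI pairs whose coupling waxes and
    wanes together — the spatial signature downstream clustering should
    recover.  For the default five ROIs and three networks the assignment
    is two "triangles" (fully coupled ROI triples) plus the remaining
    pairs; in general pairs are dealt round-robin.  Within-ROI couplings
    are stable local connectivity and belong to no network.
    """
    std = layout.standard_idx
    seen = []
    for i in std:
        if layout.roi[i] not in seen:
            seen.append(layout.roi[i])
    pairs = [(a, b) for ai, a in enumerate(seen) for b in seen[ai + 1 :]]

    def key(p):  # canonical unordered label
        return "-".join(sorted(p))

    assign = {}
    if len(seen) == 5 and config.n_networks == 3:
        # fronto-central-parietal triangle (plus the temporo-occipital
        # coupling), and two chains linking anterior regions through the
        # temporal / occipital region
        F, C, P, T, O = seen
        for a, b in [(F, C), (F, P), (C, P), (T, O)]:
            assign[key((a, b))] = 0
        for a, b in [(F, T), (C, T), (P, O)]:
            assign[key((a, b))] = 1
        for a, b in [(F, O), (C, O), (P, T)]:
            assign[key((a, b))] = 2
    else:
        for i, p in enumerate(pairs):
            assign[key(p)] = i % config.n_networks
    return assign


# ---------------------------------------------------------------------------
# signal building blocks


def _band_limited_noise(
    rng: np.random.Generator, n: int, dt: float, low: float, high: float, size: int = 1
) -> np.ndarray:
    """Unit-variance Gaussian noise with a flat spectrum on [low, high] Hz.

    Built by masking the Fourier transform of white noise, so the power is
    spread evenly over the band (maximizing the effective degrees of
    freedom per analysis window for a given bandwidth).
    """
    x = rng.standard_normal((size, n))
    f = np.fft.rfftfreq(n, d=dt)
    mask = (f >= low) & (f <= high)
    spec = np.fft.rfft(x, axis=-1) * mask
    y = np.fft.irfft(spec, n=n, axis=-1)
    sd = y.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return y / sd


def superficial_signal(rng: np.random.Generator, n: int, dt: float) -> np.ndarray:
    """Shared scalp signal: cardiac + respiratory + Mayer + slow drift.

    Frequencies jitter slightly around their physiological centers; the
    result is standardized to unit variance.
    """
    t = np.arange(n) * dt
    f_card = 1.0 + 0.05 * rng.standard_normal()
    f_resp = 0.30 + 0.02 * rng.standard_normal()
    f_mayer = 0.10 + 0.005 * rng.standard_normal()
    sig = (
        0.8 * np.sin(2 * np.pi * f_card * t + rng.uniform(0, 2 * np.pi))
        + 0.6 * np.sin(2 * np.pi * f_resp * t + rng.uniform(0, 2 * np.pi))
        + 0.7 * np.sin(2 * np.pi * f_mayer * t + rng.uniform(0, 2 * np.pi))
        + 0.5 * _band_limited_noise(rng, n, dt, 0.01, 0.05)[0]
    )
    return sig / sig.std()


def coupling_modulation(
    config: SynthConfig, rng: np.random.Generator
) -> np.ndarray:
    """[networks x samples] planted coupling strength in [0, 1].

    Each network's coupling is a train of smooth sin^2 activation bumps;
    the K networks split the activation cycle (period 1/coupling_freq_hz)
    evenly, so bumps are staggered and non-overlapping — at any moment at
    most one network is strongly coupled.  The cycle phase is random per
    subject (resting dynamics are not time-locked across subjects).
    """
    n = config.n_samples
    t = np.arange(n) * config.dt_s
    K = config.n_networks
    phase0 = rng.uniform(0, 1)
    cycle = np.mod(config.coupling_freq_hz * t + phase0, 1.0)
    mod = np.empty((K, n))
    for k in range(K):
        x = np.mod(cycle - k / K, 1.0) * K  # in [0, K); active while < 1
        bump = np.sin(np.pi * np.clip(x, 0.0, 1.0)) ** 2
        # flat-topped bump: smooth ramps, saturated plateau
        mod[k] = np.where(x < 1.0, np.minimum(1.0, 3.0 * bump), 0.0)
    return mod


# ---------------------------------------------------------------------------
# hemodynamics


def gen_hemo(
    layout: ChannelLayout,
    config: SynthConfig,
    rng: np.random.Generator | None = None,
    coupling_mod: np.ndarray | None = None,
) -> tuple[HemoSeries, GroundTruth]:
    """Generate the dHbO recording and its ground truth.

    Standard channels are drawn from a time-varying target covariance:
    unit signal variance per channel, ``within_roi_cov`` between channels
    of the same ROI (stable), and ``between_roi_cov * m_g(t)`` between
    channels of two ROIs whose pair belongs to network g (per-network
    amplitudes are shrunk where needed to keep the covariance positive
    definite).  Independent band-limited (0.01-0.15 Hz) latents, one per
    channel, are mixed by the Cholesky factor of that covariance at each
    sample.  The shared superficial signal and white sensor noise are
    added on top; short channels carry superficial signal plus noise only.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_samples
    window_min = int(round(20.0 / config.dt_s))
    if n < window_min:
        raise ValueError(
            f"duration {config.duration_s}s too short for one 20-s analysis window"
        )
    dt = config.dt_s
    std = layout.standard_idx
    short = layout.short_idx

    pair_net = roi_pair_networks(config, layout)
    rois = [layout.roi[i] for i in std]
    if coupling_mod is None:
        coupling_mod = coupling_modulation(config, rng)
    sup = superficial_signal(rng, n, dt)

    # per-network amplitude, shrunk by the most negative eigenvalue of the
    # network's ROI-pair adjacency so the channel covariance stays PD
    roi_names = sorted(set(rois))
    nr = len(roi_names)
    amp = np.full(config.n_networks, config.between_roi_cov)
    for g in range(config.n_networks):
        adj = np.zeros((nr, nr))
        for key, net in pair_net.items():
            if net == g:
                a, b = key.split("-")
                ia, ib = roi_names.index(a), roi_names.index(b)
                adj[ia, ib] = adj[ib, ia] = 1.0
        lam = np.linalg.eigvalsh(adj)
        lmin = abs(min(lam.min(), -1.0))
        amp[g] = min(config.between_roi_cov, 0.9 * config.within_roi_cov / lmin)

    # coupling -> covariance is affine: when a network is fully on the
    # ROI-pair covariance reaches amp; between activations the pair is
    # mildly anti-correlated (resting networks alternate between
    # synchronization and anti-synchronization)
    def cov_of(m: np.ndarray, g: int) -> np.ndarray:
        return amp[g] * (1.25 * m - 0.25)

    # target channel covariance per sample: [n x S x S]
    S = len(std)
    roi_of = np.array([roi_names.index(r) for r in rois])
    C = np.empty((n, S, S))
    base = np.where(
        roi_of[:, None] == roi_of[None, :], config.within_roi_cov, 0.0
    )
    np.fill_diagonal(base, 1.0)
    C[:] = base
    for key, g in pair_net.items():
        a, b = key.split("-")
        ia = np.flatnonzero(roi_of == roi_names.index(a))
        ib = np.flatnonzero(roi_of == roi_names.index(b))
        block = cov_of(coupling_mod[g], g)  # [n]
        C[:, ia[:, None], ib[None, :]] = block[:, None, None]
        C[:, ib[:, None], ia[None, :]] = block[:, None, None]

    # numerical guard: shrink the modulated blocks toward zero until the
    # covariance is comfortably positive definite at every sample
    shrink = 1.0
    for _ in range(20):
        try:
            L = np.linalg.cholesky(C - 1e-9 * np.eye(S))
            break
        except np.linalg.LinAlgError:
            shrink = 0.9
            C = base + (C - base) * shrink
    else:
        raise ValueError("channel covariance could not be made positive definite")
    latents = _band_limited_noise(rng, n, dt, 0.01, 0.15, S)  # [S x n]
    sig = np.einsum("tij,jt->it", L, latents)

    hbo = np.zeros((layout.n_channels, n))
    hbo[std] = sig + config.sup_gain * sup
    hbo[short] = config.sup_gain * sup
    hbo += config.noise_sd * rng.standard_normal(hbo.shape)

    edges = edge_index(S)
    community = np.empty(edges.shape[0], dtype=int)
    for e, (i, j) in enumerate(edges):
        if roi_of[i] == roi_of[j]:
            community[e] = BACKGROUND  # stable local (within-ROI) coupling
        else:
            a, b = sorted((rois[i], rois[j]))
            community[e] = pair_net[f"{a}-{b}"]

    truth = GroundTruth(
        pair_network=pair_net,
        edge_community=community,
        coupling_mod=coupling_mod,
        superficial_sig=sup,
    )
    return HemoSeries(hbo=hbo, dt_s=dt, layout=layout), truth


# ---------------------------------------------------------------------------
# EEG


def microstate_templates(
    rng: np.random.Generator, n_states: int, n_electrodes: int
) -> np.ndarray:
    """Mutually orthogonal, zero-mean, unit-norm template topographies.

    Maps are low-order spatial harmonics over the electrode ring
    (``cos(m * theta + phase)`` with distinct integer m), mimicking the
    smooth dipolar/quadrupolar gradients of real scalp topographies.
    Harmonics of distinct order are exactly orthogonal on the uniform
    grid and their entries are bounded by sqrt(2 / n_electrodes).
    """
    if n_states >= n_electrodes // 2:
        raise ValueError("need n_states < n_electrodes / 2")
    theta = 2 * np.pi * np.arange(n_electrodes) / n_electrodes
    maps = np.stack(
        [
            np.sqrt(2.0 / n_electrodes) * np.cos((m + 1) * theta + rng.uniform(0, 2 * np.pi))
            for m in range(n_states)
        ]
    )
    return maps - maps.mean(axis=1, keepdims=True)  # exactly zero-mean already


def _state_sequence(
    config: SynthConfig,
    rng: np.random.Generator,
    coupling_mod: np.ndarray | None,
) -> np.ndarray:
    """Semi-Markov microstate sequence with uniform dwell times.

    Dwell per segment ~ U(dwell_range); the successor state is never the
    current one (so segments stay contiguous and dwell statistics hold).
    When a coupling pair is configured, the probability of entering the
    coupled state scales with the coupled network's coupling modulation,
    linking microstate occupancy to hemodynamic network strength.
    """
    n = config.n_eeg_samples
    k = config.n_states
    lo, hi = config.dwell_range_ms
    seq = np.empty(n, dtype=np.int32)
    pair = config.coupling_pair if (coupling_mod is not None and k > 1) else None
    if pair is not None:
        net, coupled_state = pair
        # coupling modulation resampled onto the EEG clock
        idx = np.clip(
            (np.arange(n) / config.eeg_rate_hz / config.dt_s).astype(int),
            0,
            coupling_mod.shape[1] - 1,
        )
        mod_eeg = coupling_mod[net, idx]
    state = int(rng.integers(k))
    t = 0
    while t < n:
        dwell = int(round(rng.uniform(lo, hi) / 1000.0 * config.eeg_rate_hz))
        dwell = max(dwell, 1)
        seq[t : t + dwell] = state
        t += dwell
        if k == 1:
            continue
        cand = [s for s in range(k) if s != state]
        if pair is not None and coupled_state != state:
            w = np.ones(len(cand))
            m = mod_eeg[min(t, n - 1)]
            for i, s in enumerate(cand):
                if s == coupled_state:
                    w[i] = 1.0 + 2.0 * config.coupling_strength * m
            w /= w.sum()
            state = int(rng.choice(cand, p=w))
        else:
            state = int(rng.choice(cand))
    return seq


def gen_eeg(
    config: SynthConfig,
    rng: np.random.Generator | None = None,
    coupling_mod: np.ndarray | None = None,
) -> tuple[EEGRecording, GroundTruth]:
    """Generate switching-topography EEG and its ground truth.

    potentials(t) = template[state(t)] * amplitude(t) + sensor noise, where
    amplitude is a rectified alpha-band (8-12 Hz) envelope so that global
    field power oscillates on a ~50 ms scale, giving dense GFP maxima.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = config.n_eeg_samples
    dt = 1.0 / config.eeg_rate_hz
    templates = microstate_templates(rng, config.n_states, config.n_electrodes)
    seq = _state_sequence(config, rng, coupling_mod)

    # the momentary map is the active template carried by a saturated
    # alpha-band oscillation (zero-mean, so it passes the 1 Hz high-pass;
    # saturation keeps the field away from zero except at brief polarity
    # reversals); global field power then peaks every ~50 ms, the classic
    # substrate for microstate analysis
    alpha = _band_limited_noise(rng, n, dt, 8.0, 12.0)[0]
    carrier = np.tanh(2.5 * alpha)
    v = templates[seq].T * carrier
    v = v + config.eeg_noise_sd * rng.standard_normal(v.shape)

    truth = GroundTruth(
        ms_sequence=seq,
        ms_templates=templates,
        coupling_pair=config.coupling_pair,
    )
    return EEGRecording(v=v, rate_hz=config.eeg_rate_hz), truth


# ---------------------------------------------------------------------------
# whole subjects / cohorts


@dataclass
class SyntheticSubject:
    hemo: HemoSeries
    eeg: EEGRecording
    truth: GroundTruth


def simulate_subject(config: SynthConfig, seed: int | None = None) -> SyntheticSubject:
    """One subject: fNIRS and EEG sharing the same planted coupling."""
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    layout = gen_layout(config)
    hemo, truth = gen_hemo(layout, config, rng=rng)
    eeg, eeg_truth = gen_eeg(config, rng=rng, coupling_mod=truth.coupling_mod)
    truth.ms_sequence = eeg_truth.ms_sequence
    truth.ms_templates = eeg_truth.ms_templates
    truth.coupling_pair = eeg_truth.coupling_pair
    return SyntheticSubject(hemo=hemo, eeg=eeg, truth=truth)


def simulate_cohort(
    config: SynthConfig, n_subjects: int = 20, seed: int | None = None
) -> list[SyntheticSubject]:
    """Independent subjects; subject s uses seed ``seed + s``."""
    if seed is None:
        seed = config.seed
    return [simulate_subject(config, seed=seed + s) for s in range(n_subjects)]
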