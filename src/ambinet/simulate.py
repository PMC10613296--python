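"""Synthetic datasets with known ground truth for every analysis stage.

Four generators mirror the four input kinds the analyses consume:

* :func:`gen_behavior` -- logistic choice behavior with RT inflation
  under ambiguity and optional confidence ratings.
* :func:`gen_spikes` -- Poisson spiking with condition-dependent rates
  and a rate step at a known onset latency.
* :func:`gen_eeg_epochs` -- band-limited oscillatory epochs with
  controlled pairwise coherence (shared-signal mixing, closed-form
  coherence) and delta-envelope -> alpha-envelope coupling.
* :func:`gen_mvar_series` -- multichannel series from a known stable
  MVAR process.

All generators are deterministic given their truth's ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, hilbert, sosfiltfilt

from .bands import BANDS, get_band
from .datasets import BehavioralSession, EEGEpochs, NeuronData, SourceSeries, SpikeDataset
from .design import AMBIGUITY_LEVELS, AMBIGUITY_SCORE, LEVEL_CODES, MORPH_GRID, group_ambiguity

__all__ = [
    "BehaviorTruth",
    "SpikeTruth",
    "EEGTruth",
    "MVARTruth",
    "gen_behavior",
    "gen_spikes",
    "gen_eeg_epochs",
    "gen_mvar_series",
    "companion_spectral_radius",
]


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

@dataclass
class BehaviorTruth:
    """Generative ground truth for one participant's judgment behavior.

    The choice model is the logistic psychometric curve
    ``P(fear | x) = p_inf / (1 + exp(-alpha_slope (x - x_half)))``;
    reaction times are ``rt_base`` plus an ambiguity-dependent gain
    (linearly interpolated between anchor and high ambiguity) plus
    zero-mean Gaussian noise truncated at zero.
    """

    p_inf: float = 1.0
    x_half: float = 50.0
    alpha_slope: float = 0.12
    rt_base: float = 1.2
    rt_ambiguity_gain: float = 0.15
    rt_noise_sd: float = 0.25
    confidence_model: "dict[str, float] | None" = field(
        default_factory=lambda: {"anchor": 1.3, "intermediate": 1.8, "high": 2.3}
    )
    n_trials_per_level: int = 36
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.p_inf <= 1.05:
            raise ValueError("p_inf must be in (0, 1.05]")
        if self.alpha_slope <= 0:
            raise ValueError("alpha_slope must be > 0")
        if self.rt_base <= 0:
            raise ValueError("rt_base must be > 0")
        if self.rt_ambiguity_gain < 0 or self.rt_noise_sd < 0:
            raise ValueError("rt gain/noise must be >= 0")
        if self.n_trials_per_level < 1:
            raise ValueError("n_trials_per_level must be positive")


def gen_behavior(
    truth: BehaviorTruth,
    participant_id: str = "sim",
    group_label: str | None = None,
) -> BehavioralSession:
    """Simulate one participant of the morph judgment task."""
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    morphs = np.repeat(MORPH_GRID, truth.n_trials_per_level)
    rng.shuffle(morphs)
    from scipy.special import expit

    p_fear = truth.p_inf * expit(truth.alpha_slope * (morphs - truth.x_half))
    choices = np.where(rng.random(morphs.size) < p_fear, "fear", "happy")
    score = np.array([AMBIGUITY_SCORE[group_ambiguity(m)] for m in morphs])
    rt = (
        truth.rt_base
        + truth.rt_ambiguity_gain * score
        + truth.rt_noise_sd * rng.standard_normal(morphs.size)
    )
    rt = np.clip(rt, 1e-3, None)  # truncated at zero (kept strictly positive)
    trials = pd.DataFrame(
        {
            "trial_index": np.arange(morphs.size),
            "morph_pct": morphs,
            "choice": choices,
            "rt_s": rt,
        }
    )
    if truth.confidence_model is not None:
        mean_conf = np.array(
            [truth.confidence_model[group_ambiguity(m)] for m in morphs]
        )
        conf = np.clip(
            np.rint(mean_conf + 0.5 * rng.standard_normal(morphs.size)), 1, 3
        ).astype(int)
        conf_rt = np.clip(
            0.6 + 0.15 * score + 0.15 * rng.standard_normal(morphs.size), 1e-3, None
        )
        trials["confidence"] = conf
        trials["confidence_rt_s"] = conf_rt
    return BehavioralSession(participant_id, trials, group_label)


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

@dataclass
class SpikeTruth:
    """Ground truth for a population of condition-modulated Poisson units.

    Each trial fires at ``baseline_rate`` until ``onset_latency_s`` and at
    ``baseline_rate + modulation_per_level * (level_code - reference_code)``
    afterwards (level codes: anchor 1, intermediate 2, high 3).  Negative
    modulation with ``reference_code=3`` models a unit that steps up from
    baseline for unambiguous faces; positive modulation with
    ``reference_code=1`` one that steps up for the most ambiguous faces.
    """

    n_neurons: int = 30
    region_label: str = "amygdala"
    baseline_rate: float = 5.0
    modulation_per_level: float = -1.5
    onset_latency_s: float = 0.3
    trial_duration: float = 2.0
    n_trials_per_level: int = 50
    reference_code: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_neurons < 1 or self.n_trials_per_level < 1:
            raise ValueError("counts must be positive")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if not 0 <= self.onset_latency_s < self.trial_duration:
            raise ValueError("onset_latency_s must lie within the trial")
        if self.reference_code not in LEVEL_CODES.values():
            raise ValueError("reference_code must be one of the level codes 1..3")
        worst = self.baseline_rate + min(
            self.modulation_per_level * (code - self.reference_code)
            for code in LEVEL_CODES.values()
        )
        if worst < 0:
            raise ValueError(
                f"modulation drives the rate negative (min rate {worst:.3f} Hz)"
            )


def _poisson_trial_times(rng, rate, t0, t1, n_trials):
    """Homogeneous Poisson spike times in [t0, t1) for a batch of trials."""
    counts = rng.poisson(rate * (t1 - t0), size=n_trials)
    u = rng.random(int(counts.sum())) * (t1 - t0) + t0
    return np.split(u, np.cumsum(counts)[:-1])


def gen_spikes(
    truth: SpikeTruth,
    ambiguity_levels: "tuple[str, ...]" = AMBIGUITY_LEVELS,
) -> SpikeDataset:
    """Simulate trial-aligned spike trains for a population of units."""
    truth.validate()
    if not set(ambiguity_levels) <= set(AMBIGUITY_LEVELS):
        raise ValueError(f"unknown ambiguity levels in {ambiguity_levels}")
    rng = np.random.default_rng(truth.seed)
    levels = np.repeat(list(ambiguity_levels), truth.n_trials_per_level)
    codes = np.array([LEVEL_CODES[lv] for lv in levels])
    post_rates = truth.baseline_rate + truth.modulation_per_level * (
        codes - truth.reference_code
    )
    n_trials = levels.size
    neurons = []
    for i in range(truth.n_neurons):
        pre = _poisson_trial_times(
            rng, truth.baseline_rate, 0.0, truth.onset_latency_s, n_trials
        ) if truth.onset_latency_s > 0 else [np.empty(0)] * n_trials
        # post-onset segment, level-dependent rate
        dur = truth.trial_duration - truth.onset_latency_s
        counts = rng.poisson(post_rates * dur)
        u = rng.random(int(counts.sum())) * dur + truth.onset_latency_s
        post = np.split(u, np.cumsum(counts)[:-1])
        spike_times = [np.sort(np.concatenate([a, b])) for a, b in zip(pre, post)]
        neurons.append(
            NeuronData(
                neuron_id=f"{truth.region_label}_{i:03d}",
                region=truth.region_label,
                levels=levels.copy(),
                spike_times=spike_times,
                duration=truth.trial_duration,
            )
        )
    return SpikeDataset(neurons)


# ---------------------------------------------------------------------------
# EEG epochs
# ---------------------------------------------------------------------------

@dataclass
class EEGTruth:
    """Ground truth for oscillatory trial epochs.

    Each channel is a sum of unit-variance band-limited components (one
    per canonical band).  A coherence target for (pair, band) replaces
    the two channels' band components with a shared/private mixture:
    with mixing weight ``w`` on a shared unit-variance component and
    ``sqrt(1 - w^2)`` on private noise, the analytic magnitude-squared
    coherence is ``w^4``, so ``w = target ** 0.25``.

    ``cfc_gain`` scales the Pz alpha component by
    ``(1 + gain * z(delta envelope))`` so the delta envelope linearly
    drives the alpha envelope.

    ``coherence_targets`` maps ``((chan_a, chan_b), band_name)`` to either
    a coherence in [0, 1] or a per-condition dict; ``cfc_gain`` is a
    scalar or per-condition dict.
    """

    n_channels: int = 5
    channel_names: "list[str]" = field(
        default_factory=lambda: ["Pz", "Cz", "FCz", "Fz", "Oz"]
    )
    fs: float = 250.0
    epoch_window: tuple[float, float] = (-0.5, 1.5)
    coherence_targets: dict = field(
        default_factory=lambda: {
            (("Pz", "Cz"), band): {"anchor": 0.45, "intermediate": 0.35, "high": 0.25}
            for band in ("theta", "alpha", "beta")
        }
    )
    cfc_gain: "float | dict" = field(
        default_factory=lambda: {"anchor": 0.1, "intermediate": 0.2, "high": 0.3}
    )
    n_trials_per_condition: int = 40
    sensor_noise_sd: float = 0.0
    #: per-band component amplitude; set a band to 0 to omit it (e.g. for a
    #: delta/alpha-only null where the two envelopes are exactly independent,
    #: free of shared leakage through the adjacent theta band)
    band_amplitudes: "dict[str, float]" = field(
        default_factory=lambda: {b: 1.0 for b in BANDS}
    )
    seed: int = 0

    def validate(self) -> None:
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must equal n_channels")
        for name in ("Pz", "Cz", "FCz"):
            if name not in self.channel_names:
                raise ValueError(f"channel_names must include {name!r}")
        hi = max(b.hi for b in BANDS.values())
        if self.fs < 2 * hi:
            raise ValueError(f"fs must be >= {2 * hi} Hz for the synthesis bands")
        for (pair, band), target in self.coherence_targets.items():
            vals = target.values() if isinstance(target, dict) else [target]
            for v in vals:
                if not 0 <= v <= 1:
                    raise ValueError(f"coherence target {v} for {pair}/{band} not in [0,1]")
            for ch in pair:
                if ch not in self.channel_names:
                    raise ValueError(f"coherence target names unknown channel {ch!r}")
            get_band(band)


def _band_noise(rng, sos, shape):
    """Unit-variance band-limited Gaussian noise, per-row normalized."""
    x = sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _per_condition(value, condition):
    return value[condition] if isinstance(value, dict) else value


def gen_eeg_epochs(truth: EEGTruth) -> EEGEpochs:
    """Simulate multichannel trial epochs with controlled coherence and CFC."""
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    t0, t1 = truth.epoch_window
    n_samp = int(round((t1 - t0) * truth.fs))
    names = list(truth.channel_names)
    n_cond_trials = truth.n_trials_per_condition
    sos_by_band = {
        name: butter(4, band.edges, btype="bandpass", fs=truth.fs, output="sos")
        for name, band in BANDS.items()
    }
    all_data, all_cond = [], []
    for condition in AMBIGUITY_LEVELS:
        shape = (n_cond_trials, n_samp)
        comps = {
            (ch, band): _band_noise(rng, sos, shape)
            for ch in names
            for band, sos in sos_by_band.items()
        }
        for (pair, band), target in truth.coherence_targets.items():
            coh = float(_per_condition(target, condition))
            band = get_band(band).name
            w = coh ** 0.25
            shared = _band_noise(rng, sos_by_band[band], shape)
            for ch in pair:
                private = _band_noise(rng, sos_by_band[band], shape)
                comps[(ch, band)] = w * shared + np.sqrt(1.0 - w * w) * private
        # delta envelope of Pz multiplicatively drives the Pz alpha envelope
        gain = float(_per_condition(truth.cfc_gain, condition))
        if gain != 0.0:
            delta = comps[("Pz", "delta")]
            env = np.abs(hilbert(delta, axis=-1))
            z = (env - env.mean(axis=-1, keepdims=True)) / env.std(
                axis=-1, keepdims=True
            )
            modulator = np.clip(1.0 + gain * z, 0.05, None)
            comps[("Pz", "alpha")] = comps[("Pz", "alpha")] * modulator
        data = np.zeros((len(names), n_samp, n_cond_trials))
        for ci, ch in enumerate(names):
            total = sum(
                truth.band_amplitudes.get(band, 1.0) * comps[(ch, band)]
                for band in BANDS
            )
            if truth.sensor_noise_sd > 0:
                total = total + truth.sensor_noise_sd * rng.standard_normal(shape)
            data[ci] = total.T
        all_data.append(data)
        all_cond.append(np.repeat(condition, n_cond_trials))
    return EEGEpochs(
        np.concatenate(all_data, axis=2),
        truth.fs,
        names,
        np.concatenate(all_cond),
        t0=t0,
    )


# ---------------------------------------------------------------------------
# MVAR source series
# ---------------------------------------------------------------------------

def companion_spectral_radius(coeff_matrices: np.ndarray) -> float:
    """Spectral radius of the companion matrix of an MVAR(p) process."""
    A = np.asarray(coeff_matrices, dtype=float)
    if A.ndim == 2:
        A = A[None]
    p, n, _ = A.shape
    comp = np.zeros((n * p, n * p))
    comp[:n] = A.transpose(1, 0, 2).reshape(n, n * p)
    if p > 1:
        comp[n:, : n * (p - 1)] = np.eye(n * (p - 1))
    return float(np.abs(np.linalg.eigvals(comp)).max())


def _default_roi_coeffs() -> np.ndarray:
    """Stable 6-source MVAR(2): every ROI is self-autoregressive and the
    dmPFC drives the other sources at lag 1 (top-down pattern)."""
    n = 6
    A1 = 0.5 * np.eye(n)
    A1[1:, 0] = 0.25  # dmPFC (source 0) -> all others
    A2 = -0.15 * np.eye(n)
    return np.stack([A1, A2])


@dataclass
class MVARTruth:
    """Ground-truth MVAR process ``x_t = sum_k A_k x_{t-k} + e_t``."""

    coeff_matrices: np.ndarray = field(default_factory=_default_roi_coeffs)
    noise_cov: np.ndarray | None = None
    source_names: "list[str] | None" = field(
        default_factory=lambda: ["R.dmPFC", "L.SFG", "R.vmPFC", "R.dlPFC", "IPL", "L.occipital"]
    )
    fs: float = 250.0
    n_samples: int = 75  # per trial (0.3 s at 250 Hz)
    n_trials: int = 40
    seed: int = 0

    @property
    def n_sources(self) -> int:
        return np.asarray(self.coeff_matrices).shape[-1]

    @property
    def order(self) -> int:
        A = np.asarray(self.coeff_matrices)
        return 1 if A.ndim == 2 else A.shape[0]

    def validate(self) -> None:
        A = np.asarray(self.coeff_matrices, dtype=float)
        if A.ndim == 2:
            A = A[None]
        if A.shape[1] != A.shape[2]:
            raise ValueError("coefficient matrices must be square")
        radius = companion_spectral_radius(A)
        if radius >= 1.0:
            raise ValueError(
                f"unstable MVAR process (companion spectral radius {radius:.3f} >= 1)"
            )
        if self.noise_cov is not None:
            C = np.asarray(self.noise_cov, dtype=float)
            if C.shape != (A.shape[1], A.shape[1]):
                raise ValueError("noise_cov shape mismatch")
            if np.linalg.eigvalsh(C).min() <= 0:
                raise ValueError("noise_cov must be positive definite")


def gen_mvar_series(truth: MVARTruth) -> SourceSeries:
    """Simulate a stable MVAR process; burn-in of ``10 * order + 100``
    samples is generated and discarded per trial."""
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    A = np.asarray(truth.coeff_matrices, dtype=float)
    if A.ndim == 2:
        A = A[None]
    p, n, _ = A.shape
    C = np.eye(n) if truth.noise_cov is None else np.asarray(truth.noise_cov, float)
    L = np.linalg.cholesky(C)
    burn = 10 * p + 100
    total = truth.n_samples + burn
    out = np.empty((n, truth.n_samples, truth.n_trials))
    for tr in range(truth.n_trials):
        e = rng.standard_normal((total, n)) @ L.T
        x = np.zeros((total, n))
        for t in range(total):
            acc = e[t].copy()
            for k in range(1, min(p, t) + 1):
                acc += A[k - 1] @ x[t - k]
            x[t] = acc
        out[:, :, tr] = x[burn:].T
    names = truth.source_names or [f"src{i}" for i in range(n)]
    if len(names) != n:
        raise ValueError("source_names length must match the process dimension")
    data = out[:, :, 0] if truth.n_trials == 1 else out
    return SourceSeries(data, truth.fs, list(names))
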