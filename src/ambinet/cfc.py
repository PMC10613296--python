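"""Delta-band amplitude cross-frequency coupling.

The low-frequency delta envelope and a higher band's envelope
(theta/alpha/beta) are extracted per trial by zero-phase band-pass
filtering followed by the analytic-signal amplitude; edge samples (10%
per side, filter transients) are excluded.  The modulation index is
the standardized regression coefficient of the high-band envelope on
the delta envelope, with samples pooled across trials within a
participant/condition.  Its significance is assessed by a trial-pairing
permutation (the delta envelopes are re-paired with the high-band
envelopes of shuffled trials), which respects the strong within-trial
autocorrelation of envelopes.

A phase-amplitude variant (Tort-style phase-binned mean-amplitude
index) is provided for completeness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, hilbert, sosfiltfilt

from ._stats import rm_anova
from .bands import get_band
from .datasets import EEGEpochs

__all__ = [
    "band_envelope",
    "edge_mask",
    "amplitude_cfc",
    "phase_amplitude_cfc",
    "cfc_condition_contrast",
    "CFCResult",
]


def band_envelope(data: np.ndarray, fs: float, band, axis: int = -1) -> np.ndarray:
    """Amplitude envelope of a band: zero-phase band-pass then |analytic|.

    ``data`` may be any array with time along ``axis``.  The caller is
    responsible for dropping edge samples (see :func:`edge_mask`).
    """
    b = get_band(band)
    if b.hi >= fs / 2:
        raise ValueError(f"band {b.name} exceeds Nyquist ({fs / 2} Hz)")
    sos = butter(4, b.edges, btype="bandpass", fs=fs, output="sos")
    filtered = sosfiltfilt(sos, np.asarray(data, dtype=float), axis=axis)
    return np.abs(hilbert(filtered, axis=axis))


def edge_mask(n_samples: int, fraction: float = 0.1) -> np.ndarray:
    """Boolean mask keeping the central samples (True = keep)."""
    n_edge = int(round(fraction * n_samples))
    mask = np.ones(n_samples, dtype=bool)
    if n_edge:
        mask[:n_edge] = False
        mask[-n_edge:] = False
    return mask


@dataclass(frozen=True)
class CFCResult:
    pair: tuple[str, str]  # (low band, high band)
    modulation_index: float
    p_value: float
    condition: str | None
    channel: str
    n_trials: int
    method: str = "amplitude"


def _pooled_envelopes(
    epochs: EEGEpochs, low, high, channel: str, condition: str | None,
    edge_fraction: float,
):
    ep = epochs.select(condition) if condition is not None else epochs
    if ep.n_trials < 2:
        raise ValueError("cross-frequency coupling needs >= 2 trials")
    x = ep.data[ep.channel_index(channel)]  # samples x trials
    low_env = band_envelope(x, ep.fs, low, axis=0)
    high_env = band_envelope(x, ep.fs, high, axis=0)
    keep = edge_mask(ep.n_samples, edge_fraction)
    return low_env[keep], high_env[keep], ep.n_trials


def _standardized_slope(low: np.ndarray, high: np.ndarray) -> float:
    zl = (low - low.mean()) / low.std()
    zh = (high - high.mean()) / high.std()
    return float(np.mean(zl * zh))


def amplitude_cfc(
    epochs: EEGEpochs,
    low="delta",
    high="alpha",
    channel: str = "Pz",
    condition: str | None = None,
    method: str = "pooled",
    n_perm: int = 200,
    seed: "int | np.random.Generator" = 0,
    edge_fraction: float = 0.1,
) -> CFCResult:
    """Amplitude-amplitude coupling of a low band onto a high band.

    ``method="pooled"`` (default) regresses the standardized high-band
    envelope on the standardized low-band envelope with samples pooled
    across trials; ``method="per-trial"`` averages per-trial slopes.
    The two-sided p-value comes from ``n_perm`` trial-pairing shuffles.
    """
    if method not in ("pooled", "per-trial"):
        raise ValueError("method must be 'pooled' or 'per-trial'")
    low_env, high_env, n_trials = _pooled_envelopes(
        epochs, low, high, channel, condition, edge_fraction
    )
    if np.ptp(low_env) <= 1e-12 * max(1.0, float(np.abs(low_env).max())):
        raise ValueError("degenerate (constant) low-band envelope regressor")

    def index_of(le, he):
        if method == "pooled":
            return _standardized_slope(le.ravel(), he.ravel())
        slopes = [
            _standardized_slope(le[:, t], he[:, t]) for t in range(le.shape[1])
        ]
        return float(np.mean(slopes))

    observed = index_of(low_env, high_env)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n_trials)
        exceed += abs(index_of(low_env, high_env[:, perm])) >= abs(observed)
    p = (1.0 + exceed) / (n_perm + 1.0)
    return CFCResult(
        pair=(get_band(low).name, get_band(high).name),
        modulation_index=observed,
        p_value=float(p),
        condition=condition,
        channel=channel,
        n_trials=n_trials,
        method=f"amplitude-{method}",
    )


def phase_amplitude_cfc(
    epochs: EEGEpochs,
    low="delta",
    high="alpha",
    channel: str = "Pz",
    condition: str | None = None,
    n_bins: int = 18,
    edge_fraction: float = 0.1,
) -> CFCResult:
    """Phase-amplitude variant: normalized-entropy (Tort) modulation index
    of the high-band amplitude over low-band phase bins.  Provided as an
    alternative view; the amplitude-amplitude index is the primary one."""
    ep = epochs.select(condition) if condition is not None else epochs
    x = ep.data[ep.channel_index(channel)]
    b = get_band(low)
    sos = butter(4, b.edges, btype="bandpass", fs=ep.fs, output="sos")
    phase = np.angle(hilbert(sosfiltfilt(sos, x, axis=0), axis=0))
    amp = band_envelope(x, ep.fs, high, axis=0)
    keep = edge_mask(ep.n_samples, edge_fraction)
    phase, amp = phase[keep].ravel(), amp[keep].ravel()
    bins = np.linspace(-np.pi, np.pi, n_bins + 1)
    which = np.clip(np.digitize(phase, bins) - 1, 0, n_bins - 1)
    mean_amp = np.array([amp[which == i].mean() if (which == i).any() else 0.0
                         for i in range(n_bins)])
    pdist = mean_amp / mean_amp.sum()
    pdist = np.where(pdist > 0, pdist, 1e-12)
    mi = float((np.log(n_bins) + (pdist * np.log(pdist)).sum()) / np.log(n_bins))
    return CFCResult(
        pair=(get_band(low).name, get_band(high).name),
        modulation_index=mi,
        p_value=np.nan,
        condition=condition,
        channel=channel,
        n_trials=ep.n_trials,
        method="phase-amplitude",
    )


def cfc_table(
    epochs: EEGEpochs,
    low="delta",
    highs=("theta", "alpha", "beta"),
    channel: str = "Pz",
    conditions: "list[str] | None" = None,
    **kwargs,
) -> pd.DataFrame:
    """Tidy CFC results over high bands and conditions."""
    if conditions is None:
        conditions = list(pd.unique(epochs.condition))
    rows = []
    for cond in conditions:
        for high in highs:
            r = amplitude_cfc(epochs, low, high, channel, cond, **kwargs)
            rows.append(
                {
                    "condition": cond,
                    "channel": channel,
                    "low_band": r.pair[0],
                    "high_band": r.pair[1],
                    "index": r.modulation_index,
                    "p_value": r.p_value,
                }
            )
    return pd.DataFrame(rows)


def cfc_condition_contrast(indices: pd.DataFrame) -> dict:
    """One-way repeated-measures ANOVA of CFC indices across conditions
    (participants x conditions table)."""
    return rm_anova(indices)
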