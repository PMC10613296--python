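"""Event-related cross-channel magnitude-squared coherence.

Coherence between a source channel (Pz by default, the site of the
late positive potential) and every other channel:

    Gamma^2_xy(f) = |G_xy(f)|^2 / (G_xx(f) G_yy(f))

where the cross- and auto-spectra are averaged across trials (each
trial is one Hann-tapered segment).  The headline summary is the mean
coherence over the combined 4-23 Hz range, compared across ambiguity
conditions with a one-way repeated-measures ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import get_window

from ._stats import rm_anova
from .bands import COHERENCE_BAND
from .datasets import EEGEpochs

__all__ = [
    "CoherenceSpectrum",
    "coherence_map",
    "coherence_condition_contrast",
    "band_coherence_table",
]


@dataclass
class CoherenceSpectrum:
    pair: tuple[str, str]
    freqs: np.ndarray
    coherence: np.ndarray
    band: tuple[float, float]
    band_mean: float
    n_segments: int


def coherence_map(
    epochs: EEGEpochs,
    source: str = "Pz",
    band: tuple[float, float] = COHERENCE_BAND,
    condition: str | None = None,
    window: "tuple[float, float] | None" = (0.0, None),
) -> "dict[str, CoherenceSpectrum]":
    """Trial-averaged coherence of every channel with the source channel.

    Each trial contributes one Hann-tapered, demeaned segment; the
    cross-spectrum is averaged across trials before normalization, so
    with K trials the estimator has the usual ~1/K bias for independent
    signals.  ``window`` restricts the analysis to a time range relative
    to stimulus onset (default: the full post-stimulus epoch).
    """
    src_idx = epochs.channel_index(source)  # KeyError if missing
    ep = epochs.select(condition) if condition is not None else epochs
    if window is not None:
        t0 = window[0] if window[0] is not None else ep.times[0]
        t1 = window[1] if window[1] is not None else ep.times[-1] + 1.0 / ep.fs
        ep = ep.crop(t0, t1)
    k = ep.n_trials
    if k < 2:
        raise ValueError("coherence needs >= 2 trials (degenerate at 1 otherwise)")
    if k < 8:
        warnings.warn(f"only {k} trials; coherence estimates will be noisy")
    lo, hi = band
    if not 0 < lo < hi < ep.fs / 2:
        raise ValueError(f"band {band} outside (0, {ep.fs / 2}) Hz")
    taper = get_window("hann", ep.n_samples)
    x = ep.data - ep.data.mean(axis=1, keepdims=True)
    spec = np.fft.rfft(taper[None, :, None] * x, axis=1)  # ch x freq x trial
    freqs = np.fft.rfftfreq(ep.n_samples, d=1.0 / ep.fs)
    auto = np.mean(np.abs(spec) ** 2, axis=2)  # ch x freq
    src = spec[src_idx]
    in_band = (freqs >= lo) & (freqs <= hi)
    if not in_band.any():
        raise ValueError(f"frequency grid has no bins inside {band} Hz")
    out = {}
    for ci, name in enumerate(ep.channel_names):
        cross = np.mean(src * np.conj(spec[ci]), axis=1)
        denom = auto[src_idx] * auto[ci]
        with np.errstate(invalid="ignore", divide="ignore"):
            coh = np.abs(cross) ** 2 / denom
        coh = np.where(denom > 0, coh, 0.0)
        if ci == src_idx:
            coh = np.ones_like(coh)
        out[name] = CoherenceSpectrum(
            pair=(source, name),
            freqs=freqs,
            coherence=coh,
            band=(lo, hi),
            band_mean=float(coh[in_band].mean()),
            n_segments=k,
        )
    return out


def band_coherence_table(
    epochs: EEGEpochs,
    source: str = "Pz",
    band: tuple[float, float] = COHERENCE_BAND,
    conditions: "list[str] | None" = None,
    window: "tuple[float, float] | None" = (0.0, None),
) -> pd.DataFrame:
    """Tidy per-condition, per-channel band-mean coherence."""
    if conditions is None:
        conditions = list(pd.unique(epochs.condition))
    rows = []
    for cond in conditions:
        for name, cs in coherence_map(epochs, source, band, cond, window).items():
            rows.append(
                {
                    "condition": cond,
                    "source": source,
                    "channel": name,
                    "band_lo": band[0],
                    "band_hi": band[1],
                    "coherence": cs.band_mean,
                    "n_trials": cs.n_segments,
                }
            )
    return pd.DataFrame(rows)


def coherence_condition_contrast(band_means: pd.DataFrame) -> dict:
    """One-way repeated-measures ANOVA across ambiguity conditions.

    ``band_means`` is a complete participants x conditions table of
    band-mean coherences.
    """
    return rm_anova(band_means)
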