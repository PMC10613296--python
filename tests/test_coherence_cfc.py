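"""Coherence estimation and delta-band cross-frequency coupling."""

import numpy as np
import pytest

from ambinet.cfc import (
    amplitude_cfc,
    band_envelope,
    cfc_condition_contrast,
    edge_mask,
    phase_amplitude_cfc,
)
from ambinet.coherence import coherence_condition_contrast, coherence_map
from ambinet.datasets import EEGEpochs
from ambinet.simulate import EEGTruth, gen_eeg_epochs

FS = 250.0


def _epochs_from(data, names, condition=None):
    n_trials = data.shape[2]
    cond = condition if condition is not None else np.repeat("anchor", n_trials)
    return EEGEpochs(data, FS, names, cond, t0=-0.5)


def _band_noise(rng, shape, lo=4.0, hi=23.0):
    from scipy.signal import butter, sosfiltfilt

    sos = butter(4, (lo, hi), btype="bandpass", fs=FS, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(shape), axis=1)
    return x / x.std()


# ---------------------------------------------------------------------------
# coherence
# ---------------------------------------------------------------------------

def test_copy_channel_coherence_is_one():
    rng = np.random.default_rng(0)
    x = _band_noise(rng, (1, 500, 30))
    data = np.concatenate([x, x.copy()], axis=0)
    cm = coherence_map(_epochs_from(data, ["Pz", "copy"]))
    assert cm["copy"].band_mean == pytest.approx(1.0)
    assert np.all((0 <= cm["copy"].coherence) & (cm["copy"].coherence <= 1 + 1e-12))


def test_signal_plus_equal_noise_coherence_half():
    """y = x + n with equal in-band power: closed-form coherence = 0.5."""
    rng = np.random.default_rng(1)
    x = _band_noise(rng, (1, 500, 300))
    n = _band_noise(rng, (1, 500, 300))
    data = np.concatenate([x, x + n], axis=0)
    cm = coherence_map(_epochs_from(data, ["Pz", "mix"]))
    assert cm["mix"].band_mean == pytest.approx(0.5, abs=0.05)


def test_independent_channels_bias_one_over_k():
    rng = np.random.default_rng(2)
    k = 50
    data = rng.standard_normal((2, 400, k))
    cm = coherence_map(_epochs_from(data, ["Pz", "other"]))
    assert cm["other"].band_mean == pytest.approx(1.0 / k, abs=0.012)


def test_coherence_symmetric_and_gain_invariant():
    rng = np.random.default_rng(3)
    x = _band_noise(rng, (1, 500, 60))
    y = 0.7 * x + 0.7 * _band_noise(rng, (1, 500, 60))
    data = np.concatenate([x, y], axis=0)
    ep = _epochs_from(data, ["Pz", "B"])
    fwd = coherence_map(ep, source="Pz")["B"].band_mean
    rev = coherence_map(ep, source="B")["Pz"].band_mean
    assert fwd == pytest.approx(rev, abs=1e-12)
    scaled = _epochs_from(data * np.array([3.0, 0.2])[:, None, None], ["Pz", "B"])
    assert coherence_map(scaled)["B"].band_mean == pytest.approx(fwd, abs=1e-10)


def test_coherence_monotone_in_shared_fraction():
    rng = np.random.default_rng(4)
    est = []
    for w in [0.3, 0.5, 0.7, 0.85, 1.0]:
        s = _band_noise(rng, (1, 500, 100))
        a = w * s + np.sqrt(1 - w * w) * _band_noise(rng, (1, 500, 100))
        b = w * s + np.sqrt(1 - w * w) * _band_noise(rng, (1, 500, 100))
        data = np.concatenate([a, b], axis=0)
        est.append(coherence_map(_epochs_from(data, ["Pz", "B"]))["B"].band_mean)
    assert np.all(np.diff(est) > 0)


def test_coherence_shared_mixing_closed_form():
    """w-mixing gives coherence w^4 (the generator's closed form)."""
    truth = EEGTruth(coherence_targets={(("Pz", "Cz"), "alpha"): 0.5},
                     cfc_gain=0.0, n_trials_per_condition=150, seed=6,
                     band_amplitudes={"delta": 1, "theta": 0, "alpha": 1, "beta": 0})
    ep = gen_eeg_epochs(truth)
    cm = coherence_map(ep, band=(8, 13), condition="anchor")
    assert cm["Cz"].band_mean == pytest.approx(0.5, abs=0.06)


def test_coherence_input_validation(default_epochs):
    with pytest.raises(KeyError):
        coherence_map(default_epochs, source="nope")
    two = EEGEpochs(default_epochs.data[:, :, :1], default_epochs.fs,
                    default_epochs.channel_names, default_epochs.condition[:1])
    with pytest.raises(ValueError):
        coherence_map(two)
    with pytest.raises(ValueError):
        coherence_map(default_epochs, band=(4, 200))


def test_rm_anova_matches_textbook_sums_of_squares():
    """RM-ANOVA F for a hand-computed 3x3 table from explicit SS arithmetic."""
    import pandas as pd

    table = pd.DataFrame(
        {"c1": [1.0, 2.0, 3.0], "c2": [2.0, 4.0, 3.5], "c3": [3.0, 5.0, 6.0]}
    )
    vals = table.to_numpy()
    grand = vals.mean()
    ss_cond = vals.shape[0] * ((vals.mean(axis=0) - grand) ** 2).sum()
    ss_subj = vals.shape[1] * ((vals.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((vals - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df_cond = vals.shape[1] - 1
    df_err = (vals.shape[0] - 1) * (vals.shape[1] - 1)
    f_manual = (ss_cond / df_cond) / (ss_err / df_err)
    res = coherence_condition_contrast(table)
    assert res["statistic"] == pytest.approx(f_manual, rel=1e-9)
    assert res["df"] == (df_cond, df_err)


def test_rm_anova_identical_columns_f_zero():
    import pandas as pd

    col = [0.2, 0.4, 0.3, 0.5]
    table = pd.DataFrame({"a": col, "b": col, "c": col})
    assert coherence_condition_contrast(table)["statistic"] == pytest.approx(0.0)


def test_rm_anova_missing_cells_error():
    import pandas as pd

    table = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, np.nan]})
    with pytest.raises(ValueError):
        coherence_condition_contrast(table)


# ---------------------------------------------------------------------------
# envelopes / CFC
# ---------------------------------------------------------------------------

def test_pure_sinusoid_envelope_constant():
    t = np.arange(0, 4, 1 / FS)
    x = 2.0 * np.sin(2 * np.pi * 10 * t)
    env = band_envelope(x, FS, "alpha")
    core = env[edge_mask(env.size, 0.1)]
    assert core.std() / core.mean() < 0.05
    assert core.mean() == pytest.approx(2.0, rel=0.05)


def test_am_carrier_envelope_recovery():
    t = np.arange(0, 4, 1 / FS)
    a = 1.0 + 0.4 * np.sin(2 * np.pi * 0.5 * t)
    x = a * np.sin(2 * np.pi * 10 * t)
    env = band_envelope(x, FS, (5, 20))
    keep = edge_mask(env.size, 0.1)
    rms = np.sqrt(np.mean((env[keep] - a[keep]) ** 2)) / a[keep].mean()
    assert rms < 0.05


def test_white_noise_envelope_rayleigh_mean():
    """Narrowband Gaussian noise has a Rayleigh envelope: mean = sigma*sqrt(pi/2)."""
    rng = np.random.default_rng(5)
    x = rng.standard_normal(200_000)
    from scipy.signal import butter, sosfiltfilt

    sos = butter(4, (1, 4), btype="bandpass", fs=FS, output="sos")
    xb = sosfiltfilt(sos, x)
    env = band_envelope(x, FS, "delta")
    keep = edge_mask(env.size, 0.05)
    assert env[keep].mean() == pytest.approx(
        xb[keep].std() * np.sqrt(np.pi / 2), rel=0.03
    )


def test_band_above_nyquist_rejected():
    with pytest.raises(ValueError):
        band_envelope(np.zeros(100), 50.0, "beta")  # 13-30 Hz vs 25 Hz Nyquist


def test_cfc_known_slope_construction():
    """High envelope proportional to the delta envelope gives a strong
    positive standardized slope with small permutation p."""
    truth = EEGTruth(cfc_gain={"anchor": 0.0, "intermediate": 0.0, "high": 0.6},
                     coherence_targets={}, n_trials_per_condition=30, seed=7)
    ep = gen_eeg_epochs(truth)
    r = amplitude_cfc(ep, condition="high", n_perm=199, seed=0)
    assert r.modulation_index > 0.15
    assert r.p_value < 0.05
    null = amplitude_cfc(ep, condition="anchor", n_perm=199, seed=0)
    assert abs(null.modulation_index) < r.modulation_index


def test_cfc_constant_regressor_errors(default_epochs):
    flat = EEGEpochs(
        np.ones_like(default_epochs.data), default_epochs.fs,
        default_epochs.channel_names, default_epochs.condition,
    )
    with pytest.raises(ValueError):
        amplitude_cfc(flat, condition="anchor")


def test_cfc_invariant_to_linear_rescaling(default_epochs):
    r1 = amplitude_cfc(default_epochs, condition="high", n_perm=0, seed=0)
    scaled = EEGEpochs(default_epochs.data * 37.5, default_epochs.fs,
                       default_epochs.channel_names, default_epochs.condition)
    r2 = amplitude_cfc(scaled, condition="high", n_perm=0, seed=0)
    assert r1.modulation_index == pytest.approx(r2.modulation_index, abs=1e-10)


def test_cfc_monotone_in_gain():
    indices = []
    for gain in [0.0, 0.15, 0.3, 0.45, 0.6]:
        truth = EEGTruth(cfc_gain=gain, coherence_targets={},
                         n_trials_per_condition=30, seed=8)
        ep = gen_eeg_epochs(truth)
        indices.append(
            amplitude_cfc(ep, condition="anchor", n_perm=0, seed=0).modulation_index
        )
    assert np.all(np.diff(indices) > 0)


def test_cfc_selectivity_alpha_only_coupling():
    """Delta->alpha-only synthesis leaves delta-theta and delta-beta null."""
    truth = EEGTruth(cfc_gain=0.5, coherence_targets={},
                     n_trials_per_condition=40, seed=9)
    ep = gen_eeg_epochs(truth)
    r_alpha = amplitude_cfc(ep, high="alpha", condition="high", n_perm=199, seed=0)
    r_theta = amplitude_cfc(ep, high="theta", condition="high", n_perm=199, seed=0)
    r_beta = amplitude_cfc(ep, high="beta", condition="high", n_perm=199, seed=0)
    assert r_alpha.p_value < 0.05
    assert r_alpha.modulation_index > max(
        abs(r_theta.modulation_index), abs(r_beta.modulation_index)
    )


def test_cfc_condition_power():
    """A 0.1/0.2/0.3 condition gradient with participant noise is detected
    by the RM-ANOVA in most replicates."""
    import pandas as pd

    rng = np.random.default_rng(10)
    detected = 0
    n_rep = 30
    for _ in range(n_rep):
        table = pd.DataFrame(
            {
                "anchor": 0.1 + 0.05 * rng.standard_normal(22),
                "intermediate": 0.2 + 0.05 * rng.standard_normal(22),
                "high": 0.3 + 0.05 * rng.standard_normal(22),
            }
        )
        detected += cfc_condition_contrast(table)["p_value"] < 0.05
    assert detected / n_rep >= 0.8


def test_phase_amplitude_variant_detects_known_coupling():
    rng = np.random.default_rng(11)
    t = np.arange(0, 2, 1 / FS)
    trials = []
    for _ in range(20):
        phase = 2 * np.pi * 2.0 * t + rng.uniform(0, 2 * np.pi)
        delta = np.sin(phase)
        alpha = (1 + 0.8 * np.cos(phase)) * np.sin(2 * np.pi * 10 * t)
        trials.append(delta + alpha + 0.1 * rng.standard_normal(t.size))
    data = np.stack(trials, axis=1)[None, :, :]
    ep = _epochs_from(data, ["Pz"])
    r = phase_amplitude_cfc(ep, condition="anchor")
    assert r.modulation_index > 0.01
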