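"""Unit selection, PSTH and differential-latency inference."""

import numpy as np
import pytest

from ambinet.datasets import NeuronData, SpikeDataset
from ambinet.simulate import SpikeTruth, gen_spikes
from ambinet.spikes import (
    compute_psth,
    cumulative_curves,
    differential_latency,
    filter_units,
    group_cumulative_curves,
    latency_permutation,
    population_binomial,
    select_ambiguity_neurons,
)


def _constant_rate_neuron(rate, n_trials=20, duration=2.0, seed=0, nid="n"):
    rng = np.random.default_rng(seed)
    levels = np.tile(["anchor", "intermediate", "high"], n_trials)[: n_trials * 3]
    times = [
        np.sort(rng.random(rng.poisson(rate * duration)) * duration)
        for _ in range(levels.size)
    ]
    return NeuronData(nid, "amygdala", levels, times, duration)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def test_filter_units_rate_criterion():
    slow = _constant_rate_neuron(0.05, seed=1, nid="slow")
    fast = _constant_rate_neuron(5.0, seed=2, nid="fast")
    kept = filter_units(SpikeDataset([slow, fast]))
    assert [n.neuron_id for n in kept] == ["fast"]


def test_filter_units_boundary_inclusive():
    # exactly 0.2 Hz: 0.4 spikes per 2 s trial on average, built by hand
    levels = np.array(["anchor"] * 5 + ["high"] * 5, dtype=object)
    times = [np.array([0.5])] * 4 + [np.array([], dtype=float)] * 6
    neuron = NeuronData("edge", "amygdala", levels, times, duration=2.0)
    assert neuron.mean_rate == pytest.approx(0.2)
    assert len(filter_units(SpikeDataset([neuron]))) == 1


def test_filter_units_all_pass_identity(small_spikes):
    assert len(filter_units(small_spikes)) == len(small_spikes)


def test_filter_units_empty_errors():
    with pytest.raises(ValueError):
        SpikeDataset([])


# ---------------------------------------------------------------------------
# PSTH
# ---------------------------------------------------------------------------

def test_psth_rate_arithmetic():
    """One spike per trial inside a 250 ms bin gives 4 Hz."""
    levels = np.array(["anchor"] * 10, dtype=object)
    times = [np.array([0.6])] * 10
    neuron = NeuronData("n", "amygdala", levels, times, duration=2.0)
    psth = compute_psth(neuron)
    b = int(0.6 / 0.25)
    assert psth.rates[0, b] == pytest.approx(4.0)
    assert psth.rates[0].sum() == pytest.approx(4.0)  # all other bins zero


def test_psth_empty_trains_all_zero():
    levels = np.array(["anchor"] * 5, dtype=object)
    neuron = NeuronData("n", "amygdala", levels,
                        [np.array([], dtype=float)] * 5, duration=2.0)
    assert np.all(compute_psth(neuron).rates == 0)


def test_psth_matches_poisson_rate():
    neuron = _constant_rate_neuron(10.0, n_trials=170, seed=3)
    psth = compute_psth(neuron)
    n_trials = (neuron.levels == "anchor").sum()
    se = np.sqrt(10.0 / (n_trials * 0.25))
    row = psth.conditions.index("anchor")
    assert np.all(np.abs(psth.rates[row] - 10.0) < 4 * se)


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def test_selection_noise_free_linear_neuron():
    """Deterministic 10/8/6 Hz rates at levels 1/2/3: selected, prefers
    unambiguous faces."""
    rng = np.random.default_rng(0)
    levels = np.repeat(["anchor", "intermediate", "high"], 30)
    rate = {"anchor": 10, "intermediate": 8, "high": 6}
    times = []
    for lv in levels:
        n = rate[lv] * 2  # deterministic count over the 2 s trial
        times.append(np.sort(rng.random(n) * 2.0))
    neuron = NeuronData("n", "amygdala", levels, times, 2.0)
    (sel,) = select_ambiguity_neurons(SpikeDataset([neuron]))
    assert sel.selected
    assert sel.preference == "unambiguous"
    assert sel.slope < 0


def test_selection_ignores_spikes_outside_window():
    levels = np.repeat(["anchor", "intermediate", "high"], 10)
    times = [np.array([0.1, 1.9])] * 30  # all outside 250-1750 ms
    neuron = NeuronData("n", "amygdala", levels, times, 2.0)
    (sel,) = select_ambiguity_neurons(SpikeDataset([neuron]))
    assert not sel.selected
    assert np.isnan(sel.p_value)


def test_selection_null_fraction_small_sample():
    """Selection fraction over null Poisson units stays near 5%."""
    hits, total = 0, 0
    for s in range(8):
        ds = gen_spikes(
            SpikeTruth(n_neurons=50, baseline_rate=5.0, modulation_per_level=0.0,
                       n_trials_per_level=30, seed=300 + s)
        )
        sels = select_ambiguity_neurons(ds)
        hits += sum(x.selected for x in sels)
        total += len(sels)
    band = 3 * np.sqrt(0.05 * 0.95 / total)
    assert abs(hits / total - 0.05) < band


# ---------------------------------------------------------------------------
# binomial population test
# ---------------------------------------------------------------------------

def test_population_binomial_tail_conventions():
    assert population_binomial(0, 100, 0.05, include_observed=True) == pytest.approx(1.0)
    strict = population_binomial(0, 100, 0.05)
    assert strict == pytest.approx(1 - 0.95**100)
    with pytest.raises(ValueError):
        population_binomial(10, 5)


# ---------------------------------------------------------------------------
# cumulative curves
# ---------------------------------------------------------------------------

def test_cumulative_single_spike_step():
    levels = np.array(["anchor"], dtype=object)
    neuron = NeuronData("n", "amygdala", levels, [np.array([0.5])], duration=2.0)
    curve = cumulative_curves(neuron)["anchor"]
    assert curve[int(0.499 / 0.001)] == 0
    assert curve[int(0.501 / 0.001)] == 1
    assert curve[-1] == 1


def test_cumulative_monotone_and_total(small_spikes):
    for neuron in small_spikes:
        for level, curve in cumulative_curves(neuron).items():
            assert np.all(np.diff(curve) >= 0)
            idx = neuron.levels == level
            mean_count = np.mean([neuron.spike_times[i].size
                                  for i in np.flatnonzero(idx)])
            assert curve[-1] == pytest.approx(mean_count)


# ---------------------------------------------------------------------------
# latency
# ---------------------------------------------------------------------------

def _step_groups(onset, seed, n_neurons=15, n_trials=60):
    ds = gen_spikes(
        SpikeTruth(n_neurons=n_neurons, baseline_rate=5.0, modulation_per_level=-5.0,
                   reference_code=3, onset_latency_s=onset,
                   n_trials_per_level=n_trials, seed=seed)
    )
    return group_cumulative_curves(ds, "anchor", "high")


def test_latency_null_no_cluster():
    pref = np.tile(np.linspace(0, 10, 500), (5, 1))
    res = differential_latency(pref, pref.copy(), np.arange(500) / 1000.0)
    assert res.latency_ms is None


def test_latency_recovers_step_onset():
    pref, non, times = _step_groups(onset=0.3, seed=21, n_neurons=30, n_trials=100)
    res = differential_latency(pref, non, times)
    assert res.latency_ms is not None
    assert 300 <= res.latency_ms <= 360


def test_latency_shift_equivariance():
    """Moving the step from 300 to 600 ms shifts the recovered latency by
    about 300 ms on matched seeds."""
    r300 = differential_latency(*_step_groups(0.3, seed=22, n_neurons=30, n_trials=100))
    r600 = differential_latency(*_step_groups(0.6, seed=22, n_neurons=30, n_trials=100))
    assert r300.latency_ms is not None and r600.latency_ms is not None
    assert abs((r600.latency_ms - r300.latency_ms) - 300) <= 40


def test_latency_insensitive_to_baseline_rate():
    """Adding unit-specific constant-rate spikes to BOTH conditions leaves
    the latency essentially unchanged."""
    pref, non, times = _step_groups(onset=0.4, seed=23, n_neurons=30, n_trials=100)
    base = differential_latency(pref, non, times).latency_ms
    rng = np.random.default_rng(0)
    extra_rates = rng.uniform(2, 20, size=pref.shape[0])
    # constant rate adds a linear ramp to a cumulative count curve
    ramp = extra_rates[:, None] * times[None, :]
    shifted = differential_latency(pref + ramp, non + ramp, times).latency_ms
    assert shifted is not None
    assert abs(shifted - base) <= 15


def test_latency_requires_three_units():
    curves = np.zeros((2, 100))
    with pytest.raises(ValueError):
        differential_latency(curves, curves, np.arange(100) / 1000.0)


def test_latency_permutation_separates_onsets():
    pa, na, times = _step_groups(0.3, seed=24, n_neurons=20, n_trials=80)
    pb, nb, _ = _step_groups(0.6, seed=25, n_neurons=20, n_trials=80)
    res = latency_permutation(pa, na, pb, nb, times, n_perm=200, seed=1)
    assert res.p_value < 0.05
    assert res.observed_diff_ms == pytest.approx(-300, abs=60)


def test_latency_permutation_exchangeable_null():
    pa, na, times = _step_groups(0.4, seed=26, n_neurons=24, n_trials=80)
    half = pa.shape[0] // 2
    res = latency_permutation(
        pa[:half], na[:half], pa[half:], na[half:], times, n_perm=100, seed=2
    )
    assert res.p_value > 0.05


def test_latency_permutation_deterministic():
    pa, na, times = _step_groups(0.3, seed=27)
    pb, nb, _ = _step_groups(0.6, seed=28)
    r1 = latency_permutation(pa, na, pb, nb, times, n_perm=50, seed=9)
    r2 = latency_permutation(pa, na, pb, nb, times, n_perm=50, seed=9)
    assert r1.p_value == r2.p_value
    np.testing.assert_array_equal(r1.null_diffs, r2.null_diffs)
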