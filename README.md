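# ambinet

Analysis toolkit for studying how the brain processes **emotion
ambiguity** in morphed fear–happy faces, built for the multimodal
paradigm in which participants judge faces drawn from a seven-level
morph grid (0, 30, 40, 50, 60, 70, 100 % fear) collapsed into three
ambiguity levels — *anchor* (0/100), *intermediate* (30/70) and *high*
(40–60).  It targets researchers who want a tested, reusable pipeline
for the paradigm's behavioral, single-neuron and EEG analyses, and a
synthetic-data module that generates every input kind with known ground
truth so each stage can be validated without human recordings.

## What it computes

**Behavior.**  The proportion of "fear" choices is fitted with the
logistic psychometric curve

```
P(x) = P_inf / (1 + exp(-α (x - x_half)))
```

giving the discrimination threshold `x_half` and sensitivity `α`
(least squares on per-level proportions, multi-start bounded
optimization).  Condition summaries: the (high − anchor)/anchor
modulation index for RT, confidence and confidence RT, and the raw
RT difference ΔRT ("ambiguity sensitivity").

**Single neurons.**  Units ≥ 0.2 Hz are screened by trial-by-trial
regression of the 250–1750 ms firing rate on the ordinal ambiguity
level (selected at p < 0.05; exact binomial test against the 5 %
chance level).  Differential response latency: 1-ms cumulative spike
counts, a one-tailed paired t-test across units at every time point
(preferred > non-preferred condition), Benjamini–Hochberg correction
at 0.01 with a > 10-point cluster rule, and a 1000-run label-shuffling
permutation test for group latency differences.

**EEG.**  Event-related magnitude-squared coherence
`Γ²(f) = |G_xy|² / (G_xx G_yy)` between the Pz source channel and all
others over 4–23 Hz (trials as Hann-tapered segments), and delta-band
amplitude cross-frequency coupling: the standardized regression slope
of the theta/alpha/beta envelope on the delta envelope over the 2-s
epoch, with a trial-pairing permutation p-value.  Condition contrasts
use one-way repeated-measures ANOVA.

**Directed connectivity.**  MVAR models (least-squares, BIC/AIC order
selection) and the row-normalized directed transfer function
`γ²_ij(f) = |H_ij(f)|² / Σ_m |H_im(f)|²` on 1–30 Hz, with a
trial-shuffling permutation test for band-mean directed flow.

**Prediction.**  The affine map `y = a·ΔRT + b` (defaults
a = 2.4739, b = −0.1329) predicts amygdala–dmPFC functional
connectivity from behavioral ambiguity sensitivity; group comparisons
against controls use two-tailed two-sample t-tests.

## Worked example

Simulate two unit populations with known onset latencies — 30
amygdala-like units stepping +10 Hz above a 5 Hz baseline at 300 ms
for unambiguous faces, and 30 dmPFC-like units stepping at 600 ms for
the most ambiguous faces (100 trials per condition) — then recover the
latencies and test their difference:

```python
from ambinet.simulate import SpikeTruth, gen_spikes
from ambinet.spikes import group_cumulative_curves, latency_permutation

amy = gen_spikes(SpikeTruth(n_neurons=30, region_label="amygdala",
                            baseline_rate=5.0, modulation_per_level=-5.0,
                            reference_code=3, onset_latency_s=0.3,
                            n_trials_per_level=100, seed=1))
dmpfc = gen_spikes(SpikeTruth(n_neurons=30, region_label="dmPFC",
                              baseline_rate=5.0, modulation_per_level=5.0,
                              reference_code=1, onset_latency_s=0.6,
                              n_trials_per_level=100, seed=2))

pa, na, times = group_cumulative_curves(amy, "anchor", "high")
pb, nb, _ = group_cumulative_curves(dmpfc, "high", "anchor")
perm = latency_permutation(pa, na, pb, nb, times, n_perm=1000, seed=0)
print(f"amygdala-like latency: {perm.latency_a_ms:.0f} ms")
print(f"dmPFC-like latency:    {perm.latency_b_ms:.0f} ms")
print(f"difference {perm.observed_diff_ms:.0f} ms, permutation p = {perm.p_value:.4f}")
```

```
amygdala-like latency: 314 ms
dmPFC-like latency:    612 ms
difference -298 ms, permutation p = 0.0010
```

The recovered latencies sit a few milliseconds after the true rate
steps (the cumulative-sum statistic needs a short accumulation before
the paired t-test separates the conditions), and the permutation test
rejects the hypothesis that the two populations diverge at the same
time.

A full simulate → analyze → report run over every stage:

```bash
ambinet run --seed 1 --out demo_run      # writes CSV/JSON reports
```

or per stage: `ambinet simulate`, `ambinet behavior-fit`,
`ambinet spikes-select`, `ambinet spikes-latency`, `ambinet coherence`,
`ambinet cfc`, `ambinet dtf`, `ambinet predict` (see `--help`).

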