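# Methods

This note documents the models, estimators, numerical choices and
limitations of `ambinet`.  Time is in seconds relative to stimulus
onset, sample indexing is 0-based, and bins are half-open `[t, t+Δ)`.

## Task design constants

The morph grid is fixed to {0, 30, 40, 50, 60, 70, 100} % fear; the
ambiguity grouping is anchor = {0, 100}, intermediate = {30, 70},
high = {40, 50, 60}.  Ordinal level codes (anchor 1, intermediate 2,
high 3) are used wherever a regressor is needed; only their ordering
matters for two-sided inference.  Band edges are delta 1–4, theta 4–8,
alpha 8–13, beta 13–30 Hz — a single definition shared by the
synthetic-epoch generator, the coherence module and the CFC module.
The Pz-seeded coherence summary uses the combined 4–23 Hz range.

## Psychometric model

Choices are modeled as `P(fear|x) = P_inf / (1 + exp(-α(x - x_half)))`.
The fit minimizes the sum of squared deviations between observed
**per-level proportions** and the curve (not a trial-level
likelihood), which weights each morph level equally.  Bounds:
`P_inf ∈ (0, 1.05]`, `x_half ∈ [0, 100]`, `α ∈ (0, 5]`; the optimizer
is `scipy.optimize.least_squares` restarted from a moment-based guess
plus a coarse grid over threshold and slope, which avoids the local
minima that appear in flat-slope regimes.  Sessions whose per-level
proportions are constant (e.g. all choices identical) are flagged
`converged=False` with a diagnostic — the slope is unidentifiable
there and no number is invented.

ΔRT (ambiguity sensitivity) is the raw difference of mean RT between
high-ambiguity and anchor trials, in **seconds**.  The modulation
index of a measure is `(mean_high − mean_anchor)/mean_anchor`;
trials with a missing value are dropped per measure, not per session.

## Single-unit selection and differential latency

Units with whole-task mean rate below 0.2 Hz are excluded (boundary
inclusive).  Selection regresses the per-trial firing rate in the
250–1750 ms window on the level code (OLS, two-sided slope p < 0.05);
preference is classified by comparing mean window rates at high
ambiguity vs anchor, ties going to "unambiguous".  The population
test is the **strict** binomial upper tail `P(X > k)` at a 5 % chance
level — this is the `1 − binocdf(k, n, p)` convention, reproducible
from the reported unit counts; `include_observed=True` gives
`P(X ≥ k)`.

Latency uses 1-ms cumulative spike counts averaged over trials.  At
every time point a one-tailed paired t-test across units asks whether
the preferred condition's cumulative count exceeds the non-preferred
one; p-values are Benjamini–Hochberg adjusted over time points and
thresholded at 0.01; significant points form maximal runs, and runs
of length ≤ 10 are discarded.  The latency is the first point of the
**largest** surviving run.  Rationale: before the true divergence the
paired t statistic is a scale-free random walk (cumulative sums are
strongly autocorrelated), so occasional brief early runs survive any
pointwise threshold; a sustained rate difference, by contrast,
accumulates without bound and always dominates the run-length
ordering.  `pick="first"` restores the earliest-run rule.  Because
the t-test is paired within units, the estimate is insensitive to
between-unit baseline-rate differences (adding a constant-rate ramp
to both conditions leaves it unchanged; this is tested).

The group comparison permutes the unit-to-group assignment (each unit
carries its preferred/non-preferred curve pair), recomputes both
latencies per shuffle, and reports the plus-one-corrected fraction of
null |differences| at least as large as the observed one.  Shuffles
with an undefined latency are dropped and counted; a warning fires if
they exceed half the shuffles.  The choice to shuffle group (region)
membership rather than condition labels follows from the tested
statistic being a *between-group* latency difference.

## EEG coherence

Each trial is one segment: demeaned, Hann-tapered, FFT at the native
frequency resolution of the analysis window (default: the full
post-stimulus epoch, 0–1.5 s).  Cross- and auto-spectra are averaged
over trials before normalization; the band summary is the unweighted
mean over in-band bins.  With K independent segments the estimator has
the standard ~1/K positive bias under independence, which the tests
verify by Monte Carlo.  Fewer than 2 trials is an error (the estimate
degenerates to 1); fewer than 8 triggers a warning.  Only Pz serves as
source by default; any channel can be passed explicitly.

## Cross-frequency coupling

Envelopes come from zero-phase band-pass filtering (4th-order
Butterworth, `sosfiltfilt`) followed by the analytic-signal amplitude;
10 % of samples at each edge are excluded to suppress filter
transients.  The primary index is amplitude–amplitude: the
standardized regression slope (equivalently the correlation) of the
high-band envelope on the delta envelope, samples pooled across trials
within a participant/condition (`method="per-trial"` averages
per-trial slopes instead).  Envelope samples are strongly
autocorrelated, so a parametric regression p would be badly
anticonservative; significance instead comes from a trial-pairing
permutation (re-pairing delta envelopes with high-band envelopes of
shuffled trials), which preserves within-trial autocorrelation and is
exact under the null.  A phase–amplitude variant (Tort-style
normalized-entropy index over 18 phase bins) is provided for
comparison but is not part of the primary analysis path.

## MVAR and the directed transfer function

`x_t = Σ_k A_k x_{t−k} + e_t` is fitted by multichannel least squares;
multi-trial inputs stack per-trial lagged designs so no regression row
crosses a trial boundary.  Automatic order selection minimizes BIC
(AIC optional) over orders 1–20; fits with companion spectral radius
≥ 1 are flagged unstable, never silently used.  The DTF is
`γ²_ij(f) = |H_ij|²/Σ_m |H_im|²` with
`H(f) = (I − Σ_k A_k e^{−i2πfk/fs})^{−1}`, on a 1 Hz grid over
1–30 Hz; rows sum to one by construction.  DTF does not separate
direct from cascaded influence — on a 1→2→3 chain the 1→3 flow is
nonzero, and a test asserts this so users are not misled.  Source
reconstruction (inverse imaging) is out of scope: the module consumes
ROI time series directly, windowed to 300–600 ms post-stimulus by
convention before fitting.

Significance: each source's trial assignment is permuted
independently, destroying cross-source temporal alignment while
preserving every source's own spectrum; the MVAR is refitted at the
observed order and the band-mean DTF recomputed per shuffle; p-values
are plus-one-corrected upper-tail fractions per directed pair.

## Connectivity prediction

`y = a·ΔRT + b` with defaults a = 2.4739 (connectivity units per
second) and b = −0.1329, treated as configuration; a least-squares
refit from paired (ΔRT, connectivity) data is available but the
defaults are used throughout the pipeline.  ΔRT is in seconds — if a
data source records milliseconds the predictions scale by 1000, so
the input validator warns when RT columns look like milliseconds.
Because the map is affine, every group-comparison statistic on
predicted y equals the same statistic on ΔRT (asserted to 1e-10);
predicted connectivity is reported normalized by subtracting the
control-group mean.  The connectivity unit is the dimensionless scale
of the fitted model; no claim is made about measured patient
connectivity.

## Synthetic data: what it emulates and what it does not

* **Behavior**: Bernoulli choices from the logistic curve; RTs are
  baseline + an ambiguity gain (linearly interpolated through the
  intermediate level) + Gaussian noise truncated at zero.  The RT
  distribution family is a modeling choice — real RTs are
  right-skewed; the analyses only use condition means, which are
  insensitive to this.  Confidence ratings are a rounded, clipped
  Gaussian around a per-condition mean.  Defaults (α = 0.12,
  x_half = 50, RT base 1.2 s, gain 0.15 s, noise 0.25 s, 36
  trials/level) reflect typical values for this paradigm.
* **Spikes**: piecewise-homogeneous Poisson with a rate step at the
  onset latency — a step, not a ramp, so the latency ground truth is
  unambiguous for recovery tests.  Rate = baseline before onset and
  `baseline + modulation × (level code − reference code)` after.
* **EEG epochs**: sums of unit-variance band-limited Gaussian
  components per canonical band, 250 Hz, −0.5 to +1.5 s.  Pairwise
  coherence is injected by shared-signal mixing with weight
  `w = target^(1/4)` (closed-form coherence w⁴).  Delta→alpha coupling
  multiplies the Pz alpha component by `1 + gain × z(delta envelope)`.
  Adjacent-band filter leakage makes envelopes of neighboring bands
  weakly dependent even at zero gain; null calibrations therefore use
  a delta/alpha-only configuration (`band_amplitudes`) where the two
  envelopes are exactly independent.  Not emulated: volume conduction,
  1/f background, artifacts (blinks, line noise), non-stationarity —
  so passing tests validate the estimators, not artifact robustness.
* **MVAR sources**: exact simulation of the stated process with
  ≥ 10 × order + 100 burn-in samples per trial; the default 6-source
  order-2 process has one hub driving the others at lag 1
  (a top-down pattern) and is verified stable.

## Problem sizes and reproducibility

The acceptance script (`scripts/acceptance.py`) uses: 30 + 30 units ×
100 trials/condition for latency recovery (median over 5 independent
simulations — a single simulation has a small residual chance of an
early merged cluster, see the latency section — with a 1000-shuffle
permutation test on the first); 200 units × 100 replicates for the
selection null; 400 replicates × 999 shuffles for the CFC type-I
rate; 120 replicates × 499 shuffles × 6 directed pairs for the DTF
type-I rate; 300 trials for the coherence closed forms; 10⁵ samples
for the AR(1) variance; 100 participants × 200 trials/level for
psychometric recovery.  One global `--seed` expands into per-analysis
seeds through `numpy.random.SeedSequence`, and the pipeline derives
per-stage seeds the same way, so every stage is individually
reproducible.

## Known limitations

* The latency estimator's pointwise t-test ignores the temporal
  dependence of cumulative sums; the cluster rule and largest-cluster
  choice mitigate but do not remove this (see above).
* Coherence targets are exact only within a synthesis band; measuring
  across bands containing independent components dilutes the value.
* The DTF permutation requires trial-structured input (≥ 20 trials);
  long single-series surrogates are not implemented.
* Group-level contrasts assume complete participant × condition
  tables; missing cells are an error, not imputed.
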