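# Methods

## The analysis chain

The package operationalizes one question: does the trial-by-trial state of a
small cortical population immediately before a stimulus predict (i) the
animal's discrimination accuracy and (ii) the stimulus information carried by
the evoked population response?

All stages share one primitive, the **median-split state label**: trials are
ranked by spike counts in a 200-ms pre-stimulus window and the lower half is
labeled *low*, the upper half *high*. The split is rank-based with ties at
the median broken by trial order (earlier trial → low). Thresholding at the
median *value* cannot guarantee equal halves in discrete count data; the
rank rule can, and equal halves are required downstream (equal-power
behavioral comparisons, balanced decoder training sets). A consequence used
by the tests: the split is invariant under any monotone transform of the
counts, so normalizing before or after splitting is immaterial for tie-free
data.

**Trial filtering.** Only discrimination trials with |Δθ| ≤ 10° enter the
analyses (easier trials sit at the behavioral ceiling and carry almost no
incorrect responses); positive and negative Δθ are pooled. Match trials
(Δθ = 0) are included in behavioral denominators by default and can be
excluded via `AnalysisConfig.include_match` — the field convention is not
settled, so both denominators are one flag apart for sensitivity analysis.
If an odd number of trials survives, the last trial in temporal order is
dropped; a deterministic, order-dependent rule keeps the two state halves
exactly equal without randomness.

**Coupling (p_same).** The cell's own labels are computed from its raw
counts; the population trace is the mean of the *remaining* cells'
min-max-normalized counts (normalization stops high-rate cells from
dominating the mean). Chance level for p_same is 0.5; significance uses the
normal-approximation binomial interval n(0.5 ± (1.96/2)·√n⁻¹·n) = n/2 ±
0.98√n, kept in count units and unrounded. The companion behavioral
statistic is Δ% = 100·(P_low − P_high)/P̄ with P̄ the session-wide fraction
correct on the same trials (alternative denominator P_high selectable); the
denominator convention for the per-cell version is not standardized, so it
is configurable rather than hard-coded.

**Pooling.** For pool size k, each of the C(n, k) subsets yields a pooled
trace (mean of member neurons' normalized counts) and hence its own labels
and per-state performance; performances are averaged across pools at each k
and divided by session performance so sessions can be averaged without
weighting bias toward high-yield recordings. Beyond `pool_cap` (default
2,000) subsets per size, a seeded uniform sample without replacement is
used; recording-scale sessions (≤ 13 neurons, C(13,6) = 1,716) remain
exhaustive. Exact identity: because every trial is in exactly one state,
(perf_low + perf_high)/2 ≡ 1 after normalization, at every k — the suite
uses this as a conservation check.

**Decoding.** Classes are the target-evoked and test-evoked population count
vectors (counts, not rates — the two epochs may have different window
lengths, and the discriminant is scale-invariant per class anyway). Scatter
matrices follow the (n−1)·cov convention, Q = Sw/(n₁+n₂−2).
PCC = Φ(√d²/2): the exact accuracy of the optimal linear rule for two
homoscedastic Gaussians at Mahalanobis distance √d², the only form that
recovers PCC = 0.5 at d² = 0 and PCC → 1 as d² → ∞. The shuffled variant
diagonalizes Q, quantifying information with between-neuron correlations
removed; it can be larger or smaller than d². The projected decomposition
reports |wᵀΔμ| and √(wᵀQw) with w = w*/‖w*‖, whose ratio equals √d² exactly
in the unregularized case.

Numerical choices: Sw (equivalently Q) is inverted after adding a relative
ridge `ridge · tr(Q)/dim · I` (default 1e−6) because per-state trial counts
can approach the neuron count; with ridge = 0 a singular matrix falls back
to the Moore–Penrose pseudo-inverse with a logged warning. State-conditioned
fits skip a pool when a state cell has fewer than dim + 2 trials.

**Noise correlations.** Pairwise Pearson correlations of test-evoked counts,
z-scored per neuron within each stimulus condition (target orientation ×
Δθ) so stimulus-driven mean differences do not masquerade as correlated
noise, computed within each state and averaged across conditions weighted
by trial count. Zero-variance cells skip the affected pairs. The same
within-condition logic applies to the Fano factor (variance inflation by
stimulus mixing), with an across-condition mode available since the
conditioning convention differs between labs.

**Working-memory control.** If pre-test activity carried a memory trace of
the target orientation, state labels could confound stimulus identity. The
control decodes target orientation from pre-test counts with a linear
discriminant, 100 seeded 70/30 train/validation splits, against a
label-permutation chance band. On default synthetic sessions
(`memory_leak = 0`) accuracy sits inside the band; a planted leak is
detected.

## The synthetic generator

Per trial t, a scalar latent state s_t ~ N(0,1), i.i.d. across trials —
explicitly *no* autoregressive structure, matching the absence of trial-lag
autocorrelation in the data being emulated. Neuron i couples to the state
with strength c_i ∈ [0,1]:

    pre-stimulus rate  λ_it = b_i · exp(σ_s (c_i s_t + √(1−c_i²) η_it)),
    counts ~ Poisson(λ_it · 0.2 s)

The log-normal link keeps rates positive and the marginal rate distribution
unimodal — the recordings show a continuum of excitability, not discrete
UP/DOWN states. Each 200-ms window of the pre-test ladder (offsets 0–800 ms)
and the pre-target window draws its own independent state; behavior and
evoked modulation are tied to the offset-0 pre-test state only, so window
sweeps and pre-target alignments have a planted null.

Evoked responses: Gaussian-shaped orientation tuning f_i(θ) (5 spks/s floor,
30 spks/s peak, 30° bandwidth, preferred orientations uniform), multiplied
by a state gain (1 + g·s_t) and by a shared log-normal trial gain whose SD
depends on the state sign (σ_low < σ_high), then Poisson. The shared gain
applies to both evoked epochs of a trial, keyed to the pre-test state, so
state-conditioned decoding sees the planted effect. Behavioral outcome:
correct with probability Φ(d_eff/2)(1−lapse) + lapse/2, where d_eff takes a
low- or high-state value by sign(s_t) — the generative analog of the median
split, giving recovery tests a known target. An optional difficulty exponent
scales the *mean* sensitivity by (|Δθ|/Δθ_max)^exponent on non-match trials
while the state shift stays additive; harder discriminations then sit closer
to chance, where the same state shift moves accuracy more (the psychophysical
ceiling effect).

Default parameters and what anchors them:

| parameter | default | anchor |
|---|---|---|
| n_trials / n_neurons | 400 / 10 | typical session yield (4–13 neurons) |
| baseline b_i | log-normal, median 12 spks/s | mean pre-stimulus rate ≈ 13.5 spks/s |
| state_sd σ_s | 0.6 | large low↔high rate separation relative to the mean |
| coupling c_i | Beta(2, 1.4) | heterogeneous spectrum; measured mean p_same ≈ 0.58 (chance 0.5) |
| evoked_gain_slope g | 0.10 | ≈ 7–11% higher evoked rates in the high state as measured through each cell's own split |
| shared_noise (σ_low, σ_high) | (0.05, 0.15) | measured r_sc ≈ 0.05 low vs ≈ 0.10 high |
| d_eff (low, high), lapse | 1.1, 0.55, 0.05 | ≈ 70% vs 60% correct by state; ≈ 65% overall on hard trials |
| delay | fixed 1050 ms or U(250, 750) ms | the two experimental delay regimes |

The gain slope trades off against the decoding contrast: a stronger
multiplicative gain scales the orientation signal (Δμ) up in the high state,
offsetting the extra shared noise there, and any state-dependent *mean*
offset leaks into within-state shared variance through label
misclassification. g = 0.10 keeps the evoked-rate direction recoverable per
neuron (by paired test across neurons) while preserving the low-state
decoding advantage in ≈ 90% of sessions at 12 neurons × 800 trials.

What the generator does **not** emulate: negative noise-correlation pairs
(the shared gain is purely positive, so the planted correlation matrix has
no negative entries, unlike the ~30% negative pairs seen in recordings);
slow within-session nonstationarity; spike-sorting artifacts; realistic
tuning diversity (one bandwidth, one peak rate); eye-movement, pupil, or
LFP channels. Passing recovery tests therefore shows the *analysis chain*
is correct and sensitive at realistic counts and effect sizes — not that
real cortex behaves like the model.

## Unimodality diagnostic

Pooled pre-stimulus rate distributions are checked with a KDE mode count:
a Gaussian KDE (Scott bandwidth, floored at the count quantization step —
5 spks/s for one spike in a 200-ms window — to avoid comb artifacts on
discrete rates) is scanned for local maxima with prominence ≥ 10% of the
peak density; one mode = unimodal.

## Determinism

Every stochastic step (generation, pool subsampling, bootstrap, splits)
flows from explicit seeds; per-session seeds derive from the cohort master
seed via `SeedSequence`. Identical configuration and seed reproduce
byte-identical result CSVs, which the run manifest certifies with content
hashes.

## Problem sizes

Recovery-style checks in the test suite run at 12 neurons × 800 trials per
session and up to 50 sessions per cohort — the scale of the emulated
experiments; cohort-level directional checks (window sweeps, alignment and
difficulty contrasts) use 14–30 sessions, where session-level sampling noise
(SE of a per-session behavioral gap ≈ 5–7% at 400–800 trials) averages down
enough for single-seed determinism.

## Known limitations

* p_same has a compressed dynamic range at realistic rates (≈ 2–3 spikes
  per 200-ms window): Poisson discretization attenuates the cell-state
  estimate, so even c_i = 1 yields p_same well below 1. Rank recovery of
  the coupling spectrum is accurate; absolute calibration of c_i from
  p_same is not attempted.
* The closed-form PCC assumes homoscedastic Gaussian classes; spike counts
  are neither, so PCC is an information index, not a prediction of an
  empirical cross-validated decoder.
* The binomial significance interval uses the normal approximation
  (matching the convention it mirrors); at small n it disagrees with an
  exact test only at counts adjacent to the interval edge.
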