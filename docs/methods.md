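# Methods

This note records the models, conventions and numerical choices behind
`beatssep`, in the order data flow through the package.

## Stimulus synthesis

The stimulus is `sin(2π·333.3·t) · env(t) · mod(t)` over 33 s, where
`env` tiles one asymmetric-Hanning cycle — a half-raised-cosine rise over
22 ms from 0 to 1 followed immediately by a half-raised-cosine fall over
394 ms back to 0 — zero-padded to the 2.4 Hz amplitude-modulation period
(≈416.67 ms).  The cycle is evaluated in continuous time (`t mod 1/2.4`)
rather than in rounded samples, so the AM rate is exactly 2.4 Hz at any
sampling rate; the price is that the envelope peak is attained exactly
only when a sample lands on the 22 ms mark (true at 1000 Hz, off by
< 1 sample at 44.1 kHz).

The 11 Hz secondary modulator is `(1 + m·sin(2π·11·t))/(1+m)`; its depth
is not fixed by the published stimulus description, so `m` is a
parameter with default 0.5, normalised so the combined envelope still
peaks at 1.  The final 3 s of the 36 s trial are a verbatim copy of the
first 3 s of the fully modulated waveform (`extension_source="start"`;
`"end"` available — the description says only that 3 s "were copied").
The probe is an 880 Hz tone burst of 40 ms with 5 ms raised-cosine
on/off ramps appended outside the nominal duration (the source is silent
on ramps; without them the burst splatters broadband energy).  The burst
uses cosine phase and a half-sample-offset gate so that every sample in
its window is actually modified — this makes the burst's temporal support
equal to its specification, which the tests pin down.  The ternary probe
onset follows the body text (33.732 s); a figure caption says 33.772 s,
and the field is overridable.  WAVs are written as 32-bit float PCM.

## Synthetic multi-lab data

Each subject owns a baseline SSEP amplitude per frequency
(0.8/1.2/1.6/2.4 Hz), drawn once from a truncated-at-zero normal across
subjects, and a per-frequency phase fixed across trials (the steady-state
assumption that makes trial averaging amplitude-preserving).  Imagery
adds a deterministic increment at the congruent frequency (1.2 Hz in
binary imagery, 0.8 Hz in ternary; default 0.03 μV).  Drawing the
baseline once and adding increments — rather than drawing every
condition cell independently — keeps amplitudes nonnegative while making
the within-subject condition contrast exactly the configured increment;
independent truncated draws would bias the contrast whenever a cell mean
sits near zero, which defeats parameter-recovery testing.  Defaults
(stimulus-frequency amplitude 0.07 μV, beat-frequency baselines
0.02 μV, between-subject SD 0.02 μV, increment 0.03 μV, subject-level
measurement noise 0.03 μV) mirror the grand pattern of the published
per-lab summary table.

Two generator tiers share this population model:

* **EEG tier** — trials are the subject's multi-sine signal on every
  channel times a zero-mean dipolar gain map (alternating ±1), plus
  independent 1/f^α (α = 1, spectrally shaped, flat below 0.1 Hz) and
  white noise per channel and trial.  The zero-mean gain map matters:
  average referencing subtracts the instantaneous channel mean, so a
  channel-uniform signal would be annihilated; with ±1 gains the
  reference is the identity on signal and the channel-averaged spectral
  amplitude equals the generating amplitude.  Trials are 36 s from
  stimulus onset so epoching is genuinely exercised.
* **amplitude tier** — emits the subject-level amplitude estimates the
  pipeline would produce (truth + Gaussian measurement noise, signed, as
  noise-subtracted spectra are).  Replicated recovery studies of the
  meta-analytic stage run on this tier; rerunning the full EEG chain for
  156 subjects × 3 conditions × trials × channels × 36 000 samples
  hundreds of times is not a sensible use of compute when the EEG chain
  itself is validated exactly against a closed form (below).

Behavior: accuracy is Bernoulli with a logistic link on amplitudes and
covariates; a probe is scored ON-beat when its metrical position matches
the imagery performed.  Imagery-success ratings follow an ordered-logit
cut-point model on 1–7 (the analysis only ever uses rating means).
What the synthetic data do **not** contain: artifacts (ocular/muscle),
ERP transients, realistic scalp topographies, non-stationary noise.
Passing tests therefore demonstrate the statistical machinery, not
robustness to real-world recording pathologies — artifact correction is
deliberately outside this package (a `cleaner` hook accepts pre-cleaned
epochs).

## SSEP extraction

Order of operations: average reference → zero-phase Butterworth
high-pass (0.1 Hz, order 4, applied forward–backward on the continuous
per-trial record, *before* epoching, so settling transients mostly fall
outside the window) → 32 s epoch starting 1 s post-onset → trial
average → single-sided amplitude spectrum `2|X_k|/N` (μV; no window, no
zero padding; Δf = 1/32 s = 0.03125 Hz — the nominal "0.03 Hz"
resolution is treated as a rounded statement of this value) →
neighbor-bin noise subtraction → 3-bin target mean → unweighted channel
average, keeping sign.

Neighbor bins are the integer offsets {−4, −3, +3, +4}: at this
resolution the only four bins whose centres fall in the ±[0.09, 0.15] Hz
window, two per side.  Edge bins use whatever subset stays in range.
The target bin is `round(f0/Δf)` with round-half-to-even
(0.8 → 26, 1.2 → 38, 1.6 → 51, 2.4 → 77); the target frequencies are
deliberately not bin centres, so spectral leakage is part of the
measured quantity.  The closed-form Dirichlet-kernel module reproduces
the entire spectral chain for noiseless multi-sine input to machine
precision (tested at 1e−9), including mutual leakage between components
(complex bin values are summed before magnitudes are taken) and the
phase advance `2πf₀·(epoch offset)` from epoching.

The drift filter is the one stage with no closed form: a 0.1 Hz
zero-phase IIR filter has multi-second settling, and its edge transients
perturb sub-Hz bins at the few-×10⁻⁴ μV level on 36 s records.  Oracle
equivalence is therefore asserted with the filter bypassed
(`hp_cutoff=None` — on drift-free input the filter is a no-op by
design), while separate tests bound its in-band effect (2.4 Hz estimate
moves < 1%; DC rejected; 0.01 Hz drift attenuated > 90%).  Butterworth
order 4 is a package choice (no order is published).  Inputs at other
rates are polyphase-resampled to 1000/1024 Hz first.

Signed (not rectified) noise-subtracted amplitudes are averaged across
electrodes — consistent with the negative condition means visible in the
published per-lab table.

## Per-lab statistics

The one-way repeated-measures ANOVA uses the classical subject ×
condition decomposition; Greenhouse–Geisser ε is estimated from the
double-centred sample covariance of conditions and applied
unconditionally (no sphericity pre-test; the uncorrected p is also
reported).  Effect size is partial η² = SS_cond/(SS_cond+SS_error).
Post-hoc paired t tests use Bonferroni with m = 3 (the three pairwise
contrasts within one frequency), capped at 1 — the cap reproduces the
many p = 1.00 entries in the published post-hoc table.  Correlation
matrices use pairwise deletion and report undefined cells (constant
column, n < 3) as missing, mirroring the dash entries in the published
correlation table.

### A priori power

The power routine computes noncentral-F power for the within-factors
repeated-measures convention: Cohen's f² = η²/(1−η²), noncentrality
λ = f²·(N−1)·m·ε/(1−ρ) with m repeated measures and correlation ρ among
them, critical value from df₁ = (m−1)·ε and df₂ = (N−g)(m−1)·ε with g
condition groups.  Under the study parameterization (η² = .06, α = .05,
g = 3, m = 10, ρ = .5, ε = 1) the smallest n with power ≥ .80 is 15.
The mapping of "conditions" and "repeated measures" onto the power
formula's groups/measurements — and whether λ scales with N or with the
error degrees of freedom N−1 — is genuinely underdetermined in standard
tool descriptions; this package adopts the error-df scaling, documents
it here, and validates the distributional computation by Monte Carlo:
`mc_rm_power` simulates the matching compound-symmetric design (unit
variance, correlation ρ, level means scaled so the true noncentrality
equals the convention's λ), runs the package's own RM-ANOVA on every
draw, and agrees with the analytic power within ±0.02 at 10⁴ replicates.
That simulation is an end-to-end check of the noncentral-F tail and of
the ANOVA implementation; it cannot adjudicate the N vs N−1 convention
(the two differ by less than Monte-Carlo resolution at these sizes).

## Meta-analysis

Per-lab effects are raw within-subject contrasts: mean (or median) of
subject-level amplitude differences between two conditions at one beat
frequency, with SE = sd(diff)/√n in mean mode.  Pooling is
inverse-variance random effects; τ² by REML (default: bounded profile
search plus the standard fixed-point refinement, matching an independent
implementation to ~10⁻⁶ and maximising the restricted likelihood to
10⁻¹⁰) or DerSimonian–Laird in closed form.  Q uses fixed-effect
weights; I² = max(0, (Q−df)/Q)·100 and H² = Q/df (the Q-based textbook
definitions — implementations that define H² from τ²/s² print 1.00
when τ̂² = 0 where this package prints Q/df).  Confidence intervals and
p-values are Wald; no Knapp–Hartung adjustment (the replication's
symmetric intervals indicate Wald).  Meta-regression re-estimates τ²
under the moderator model (REML with the design matrix inside the
restricted likelihood) and reports the model-predicted effect at the
moderator mean and mean ± 1 SD — the "three diamonds" convention; the
evaluation points are a package choice, since the display convention is
not defined anywhere authoritative.

Exact reproduction of the published pooled estimates is out of reach by
construction: the per-lab summary table carries condition means and SDs
but not the within-subject pairing, so paired SEs — and hence the
weights — require raw data.  What is reproducible from the table is the
per-lab mean differences and their cross-lab ranges, which the
acceptance suite checks exactly.

Median mode estimates the subject-level spread from the interquartile
range (σ̂ = IQR/(2·Φ⁻¹(0.75)) ≈ IQR/1.349) and uses the asymptotic
SE(median) = √(π/2)·σ̂/√n, the quantile-based estimator of the
medians-meta-analysis literature; a seeded bootstrap SE (2000 resamples)
is available.  For symmetric subject-level differences median pooling
converges to mean pooling, which is tested by simulation.

## Trial-level logistic regression

Maximum likelihood by IRLS from β = 0, with the per-iteration deviance
retained (likelihood ascent is asserted in tests); convergence at
max|Δβ| < 10⁻⁸.  Fitted probabilities pinned at 0/1 or a singular
weighted system set a non-convergence flag with a diagnostic — no silent
output under separation.  Default subject handling is cluster-robust
SEs by subject (sandwich with G/(G−1) correction): full subject dummies
are exactly collinear with lab dummies (and absorb the subject-constant
covariates music/dance years), so the dummy encoding is provided only as
a fidelity mode with an explicit rank check that names the aliased
columns and can drop the redundant lab dummies.  Wald χ² = (β/SE)² with
1 df per term.  Subject-level amplitudes are broadcast across a
subject's trials (`--amp-granularity subject` semantics); true
single-trial spectra can be merged upstream when available — which of
the two the original analysis used is not stated.

## Exclusions and accounting

Exclusion filtering is two-phase: individually excluded participants are
removed first (failed imagery training, artifacts in > 50% of data,
experimenter error, rhythmic movement), then any lab with fewer than 8
remaining participants is dropped whole, its members marked
`lab_too_small` — the order matches the narrative of the lab that was
excluded only after individual exclusions shrank it to n = 4.  Applied
to the per-lab tested/included counts of the packaged summary table this
yields 212 tested, 152 included across 13 retained labs.

## Problem sizes in the test suite

Unit and property tests run the EEG tier at 1–2 labs × 2–3 subjects ×
2 channels × 2–4 trials (full 36 s trials, so epoching/leakage behavior
is identical to full scale); replicated recovery studies run the
amplitude tier at the study's 13 × 12 geometry with 400 replicates, the
power Monte Carlo uses 10⁴ replicates, noise-subtraction unbiasedness
500 realizations, and logistic selectivity 200 replicates of 2 400
trials.  These sizes were chosen so every stochastic check has its
stated Monte-Carlo resolution; none of the statistical machinery depends
on the recording dimensions.

## Known limitations

* No artifact handling (by design); real recordings must be cleaned
  before entering the pipeline.
* The generator's channel model is a crude ±1 topography; channel-space
  questions (topographies, interpolation) are out of scope.
* H²/I² conventions differ between implementations when τ̂² = 0 (see
  above); comparisons across tools should use Q and τ² directly.
* The power convention reproduces the study's printed minimum sample
  size under a documented but not uniquely determined mapping; the
  alternative N-scaling yields 14 under otherwise identical inputs.
* Median-difference SEs assume approximate normality of subject-level
  differences; with heavy tails prefer the bootstrap flag.
* The 3-bin estimator reads the leakage-attenuated amplitude (factor
  ≈ 0.40 at 1.2 Hz for a 32 s rectangular epoch), and on magnitude
  spectra the per-bin noise floor adds a Rician upward bias that
  compresses condition *differences* when the leaked signal sits below
  the noise floor.  Condition contrasts in μV are therefore
  conservative estimates of the underlying amplitude difference; the
  end-to-end tests target increment × leakage factor in the low-noise
  regime where the Rician term is negligible.
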