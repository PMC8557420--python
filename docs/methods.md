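# Methods

## Model

Gene flow from a donor into a recipient population is described by a
migration-rate history m(t), t generations before sampling, with total
migrant fraction α = ∫ m(t) dt. A neutral introgressed segment that
entered t generations ago has been broken by recombination for t
generations, so its genetic length is exponential with rate t (lengths
in Morgan throughout). The entry time of a randomly chosen *segment*
is length-biased relative to m(t) — older migrants contribute
proportionally more segments — with density ∝ t·m(t).

The extended pulse takes m(t) = α·Gamma(shape k, rate k/t_m), mean
t_m. Then:

* entry times of segments: Gamma(shape k+1, rate k/t_m), mean
  (k+1)/k·t_m, variance (k+1)t_m²/k²;
* segment lengths: Lomax with shape k+1 and scale k/t_m; mean 1/t_m
  for every k, variance (k+1)/((k−1)t_m²), infinite at k = 1;
* ALD decay: D(l) ∝ (1+t_m·l/k)^−k, fitted as A(1+t_m·l/k)^−k + c
  with amplitude A and background c.

Duration is summarized as t_d = 4·t_m/√k (four conditional standard
deviations of the migration density); k = 16·t_m²/t_d². The k → ∞
limit is the instantaneous pulse (exponential lengths, exponential ALD
decay); k = 1 with t_m = 1/m is constant migration, where the
*last*-migration time at a locus is exponential with rate m and the
length density is 2m²/(m+l)³.

**Parameterization convention.** The Gamma distributions are always
specified by shape and *rate*: migration has rate k/t_m so its mean is
t_m, and entry times are Gamma(k+1, rate k/t_m). This is the only
convention under which the stated entry-time moments hold, and it is
the one used everywhere in the code and docs (`scipy` calls use
`scale = t_m/k`).

**Assumptions.** The total introgressed fraction is small: segments do
not recombine with each other, genetic drift and selection on
introgressed material are ignored, and segment counts do not deplete
the donor signal. The replacement of older migrant material by later
migrants can be accommodated by the effective rate
m_e(t) = m(t)·exp(−∫₀ᵗ m(s) ds) (`effective_migration`), which
integrates to 1 − e^(−α); at α ≈ 0.03 the correction is below 2% and
is not applied by default.

## Segment ↔ ALD duality

The ALD curve is the scaled expected overlap
D(l) = E(K)/G · ∫ₗ^∞ P(x)(x−l) dx of a segment with a pair of loci l
apart, so P(l) ∝ D″(l). `ald_from_segment_density` evaluates the
integral by adaptive quadrature (`scipy.integrate.quad` to infinity;
the Lomax integrand has a finite mean-excess for shape > 1, which
k ≥ 1 guarantees). `segment_density_from_ald` uses a central second
difference with default step 1e−6 Morgan — small enough that the
truncation error is negligible on curves with decay rates of order
10³/Morgan while cancellation error stays below ~1e−10 relative — and
logs a warning when materially negative values appear, the signature
of a step too coarse for the curvature. At l = 0 the forward transform
reduces to E(K)/G times the mean segment length, which fixes the
proportionality constant so that D(0) = A + c matches the fitting
forms.

## Simulation

`draw_segment_times` draws entry times from Gamma(k+1, rate k/t_m);
`draw_segment_lengths` draws each length exponential with rate
T_i − s, where s is the sampling time (generations before present,
0 = present-day sample). Sampling "50 generations after gene flow
ended" means s = t_m − t_d/2 − 50. Entry times are continuous, so
ties have probability zero and no deduplication is needed.
`draw_segment_lengths` refuses entry times at or before the sampling
time (such segments would not exist in the sample);
`simulate_segments(..., condition_on_sampling=True)` instead
rejection-resamples them, i.e. conditions the entry-time distribution
on the segment being observable — the physically sensible behaviour
when the Gamma tail crosses the sampling time, used by the power
analysis.

`make_migration_schedule` discretizes α·Gamma(k, rate k/t_m) onto
integer generations in the window [t_m − t_d/2, t_m + t_d/2] (clipped
to ≥ 1) and rescales to sum exactly to α. t_d = 1 collapses the
window to the single generation nearest t_m, recovering the
one-generation pulse. The default ±t_d/2 window covers ≈95% of the
Gamma mass; any window excluding more than 1% of mass is logged as a
warning, so the default window warns by design — the renormalization
to α is exact regardless. Truncation pulls the schedule's mean
slightly below t_m for long pulses (the Gamma is right-skewed); the
effect is under one generation for t_d ≤ ~100 and grows roughly as
t_d²/t_m beyond that, which is why the schedule-accuracy test pins
t_d ∈ {10, 100}. Schedules are written as (generation,
migrant_fraction) TSV rows, directly usable as per-generation pulse
events in coalescent simulators.

`simulate_ald_curve` evaluates the extended decay on a cM grid and
adds i.i.d. Gaussian noise — a synthetic stand-in for weighted-LD
output computed from genotype panels. It reproduces the functional
form and noise level but none of the structure of real weighted-LD
estimation: no SNP ascertainment, no correlation between neighbouring
bins, no jackknife error structure. Passing round-trip tests on these
curves therefore demonstrates the correctness of the fitting
machinery, not robustness to real ALDER output pathologies.

## Inference

**Segments.** The simple-pulse MLE is closed-form, t̂_m = 1/mean(L),
clipped to [1, 5000] generations (clipping is flagged). The extended
fit maximizes the Lomax likelihood with L-BFGS-B in (log t_m, log k)
with analytic gradients — the log parameterization conditions the
problem and turns the box constraints t_m ∈ [1, 5000],
k ∈ [2, 1e10] into simple bounds. Ten starts (configurable) from a
coarse grid of shapes k ∈ {2.5, 4, 36, 300, 3000, 1e6} crossed with
time scales {0.5, 1, 2}×(1/mean) guard against the flat ridge in k;
the best objective wins. No truncation adjustment is applied to the
likelihood when length cutoffs (`filter_segments`, conventionally
0.05–1.2 cM) have been used — fits to heavily filtered data are
biased, and the filter logs what it removed.

**ALD curves.** Weighted-LD points at distances below d0 (default
0.05 cM, configurable, e.g. 0.02 cM) are excluded: very short-range LD
can reflect incomplete lineage sorting rather than gene flow. The
decay is then fit by nonlinear least squares in (t_m, 1/k, A, c) with
bounds t_m ∈ [1, 5000], 1/k ∈ [1e−10, 1/2], A ≥ 0; each of ten
restarts runs a seeded differential-evolution global search followed
by bounded trust-region least squares, and the lowest-RSS fit is kept
(ties go to the earliest restart, so results are reproducible under
the seed). The inverse-shape parameterization makes the exponential
limit an interior-ish boundary at 1/k → 0 rather than a runaway
k → ∞. Model comparison between the two curve fits uses the
normalized RSS difference (RSS_simple − RSS_extended)/RSS_simple —
there is no likelihood here, so this is a descriptive, not formal,
comparison; it is defined as 0 when the simple fit is already exact.

**Likelihood-ratio test.** The simple pulse is the k → ∞ boundary of
the extended model, so the LR statistic is not asymptotically χ²₁.
`lrt_extended_vs_simple` simulates its null distribution by parametric
bootstrap: n_boot datasets of the observed size from the fitted
exponential, both models refit on each; the p-value is the fraction of
null LRs ≥ observed, and the decision compares the observed LR with
the empirical (1−level) quantile. LR values are clipped at 0 (the
nested optimum can come out a hair negative from optimizer tolerance).

## Power analysis

`run_power_grid` crosses durations × sample sizes × sampling schemes
at fixed t_m. For each (n, scheme) cell an empirical cutoff is taken
as the (1−level) quantile of LRs from n_null matched one-generation-
pulse simulations (lengths exponential with rate t_m − s); the cutoff
is shared across durations within the cell, since the null does not
depend on the alternative's duration. Power is the fraction of
extended-pulse replicates whose LR exceeds the cutoff. Default level
0.05. Mean LRs above 10 are clipped in the display column of
`summarize_power` only, never in inference.

Default problem sizes — n ∈ {100, 10⁴} segments, 20 replicates per
cell, 100 null simulations per cutoff, medians over three seeds in the
distinguishability tests — were chosen so the whole analysis runs in
about a minute on one CPU while leaving the qualitative structure
(power rising with duration and sample size, and with sampling closer
to the event) well clear of Monte-Carlo noise. The same experiment
scales to the 10⁵-segment, 100-replicate design by changing arguments.

## Numerical choices

* Lomax and extended-ALD evaluations go through `log1p`, so k = 1e10
  is exact to ~1e−5 against the exponential forms and nothing
  overflows.
* All internal lengths are Morgan and times generations; cM appears
  only in file I/O and the `ALDCurve` container (which mirrors the
  file format), converted by exactly 100 at the boundary.
* Recombination-map queries outside the covered span are clamped to
  the nearest end with a warning; trimming unreliable map ends is left
  to the user. In constant-rate mode, genetic length is
  (end − start) × rate; with a constant-rate map both modes agree to
  1e−12.
* Degenerate inputs fail loudly: empty samples, non-positive lengths,
  entry times after sampling, inverted intervals, non-monotone maps
  and non-numeric rows all raise with the offending file line where
  applicable.

## Known limitations

* No coalescent machinery: the simulator draws from the model itself,
  so model-misspecification questions (drift, variable recombination,
  segment-calling error) are out of scope; migration schedules can be
  exported to study them externally.
* Durations of *old* pulses are weakly identified — the likelihood in
  k is nearly flat when t_d ≪ t_m and sampling is at the present —
  so fitted t_d should only be trusted in the recent/long-pulse regime
  (the tests pin t_m = 450, t_d = 800 sampled 50 generations after
  gene flow as a recoverable case).
* No jackknife or weighting of ALD points: the curve is taken as
  given, and no interval estimation is claimed beyond the optional
  bootstrap machinery.
* Segment-length likelihoods ignore truncation by length cutoffs, as
  noted above.
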