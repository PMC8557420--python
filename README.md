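# admixpulse

Dating gene flow between diverged populations — e.g. Neandertal
introgression into non-Africans — from the genetic signal it leaves
behind: the lengths of introgressed chromosome segments and the decay
of ancestry linkage disequilibrium (ALD) with genetic distance.

Most admixture-dating methods assume gene flow happened in a single
generation. `admixpulse` implements an **extended pulse model** in
which the per-generation migration rate follows a Gamma density

```
m(t) = α · Γ(k, rate k/t_m)(t)
```

with mean admixture time *t_m* (generations before sampling), shape
*k*, and total introgressed fraction α. The duration of gene flow is
summarized as *t_d* = 4 *t_m* / √*k*. Two classical models are the
limits: *k* → ∞ is the instantaneous pulse, *k* = 1 (with
*t_m* = 1/*m*) is constant ongoing migration.

Under this model the package provides closed forms for both
observables:

* **segment lengths** *L* (Morgan) follow a Lomax (Pareto II)
  distribution with shape *k* + 1 and scale *k*/*t_m*:
  P(L = l) = (k+1)(k/t_m)^(k+1) (k/t_m + l)^−(k+2),
  with mean 1/*t_m* for every *k* and variance
  (k+1)/((k−1) t_m²);
* **ALD decay** with genetic distance *l*:
  D(l) = A (1 + t_m l / k)^−k + c,
  where *A* is the amplitude and *c* background LD.

The two summaries carry the same information: D(l) is the scaled
integral ∫ₗ^∞ P(x)(x − l) dx of the length density, and conversely
P(l) ∝ D″(l); both transforms are implemented and cross-checked.

On top of the closed forms the package provides

* simulation of segments (entry times are Gamma(*k*+1, rate *k*/*t_m*),
  lengths exponential given elapsed time), synthetic ALD curves, and
  discretized per-generation migration schedules for coalescent
  simulators;
* maximum-likelihood fitting of segment lengths and restarted
  global+local nonlinear least squares for ALD curves, as
  scikit-learn-style estimators with thin function wrappers;
* a parametric-bootstrap likelihood-ratio test of extended vs. simple
  pulse (the simple pulse is a boundary case, so χ² asymptotics do not
  apply) and a power analysis over durations, sample sizes and
  sampling times;
* readers/writers for HapMap-format recombination maps, segment TSVs
  and two-column weighted-LD curves, plus an `admixpulse` command line
  (`simulate`, `fit-segments`, `fit-ald`, `lrt`, `power`).

## Worked example

```python
import admixpulse as ap

pulse = ap.PulseParams.from_duration(t_m=1500, t_d=1000)   # k = 36

segs = ap.simulate_segments(10_000, pulse, seed=42)
print("mean length (cM):", round(segs.lengths.mean() * 100, 4))

simple = ap.fit_segments_simple(segs)
extended = ap.fit_segments_extended(segs)
print(f"simple:   t_m = {simple.t_m:.1f}   loglik = {simple.loglik:.1f}")
print(f"extended: t_m = {extended.t_m:.1f}  t_d = {extended.t_d:.1f}  loglik = {extended.loglik:.1f}")

res = ap.lrt_extended_vs_simple(segs.lengths, n_boot=100, seed=0)
print(f"LR = {res.lr:.2f}  p = {res.p_value:.2f}  cutoff(5%) = {res.cutoff:.2f}")
```

prints

```
mean length (cM): 0.0672
simple:   t_m = 1487.6   loglik = 63049.1
extended: t_m = 1487.6  t_d = 1243.2  loglik = 63058.0
LR = 8.93  p = 0.00  cutoff(5%) = 1.98
```

Both models recover the mean admixture time (within ~1%: the mean
segment length is 1/*t_m* under either model). The duration is far
less certain — 1243 fitted vs. 1000 simulated generations — but with
10,000 segments and a 1000-generation pulse the likelihood-ratio test
still rejects the one-generation pulse (LR = 8.9 against an empirical
5% cutoff of 2.0). With fewer segments, or gene flow further in the
past, the two scenarios become statistically indistinguishable; the
`power` subcommand maps out where that happens.

Converting a fitted time to calendar years at 29 years per generation:

```python
>>> ap.generations_to_ky(1682), ap.generations_to_ky(1526)
(49, 44)
```

so a fit of 1,682 generations corresponds to gene flow around 49 ka.

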