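# Methods

This note describes, in this package's own words, the statistical model, the
algorithms, and the design decisions that shape the implementation, including
the places where our reconstruction behaves differently from the published
benchmark numbers it is modelled on.

## Model

All methods fit the whole-genome regression

```
y = 1 mu + Z g + e,        e ~ N(0, I sigma_e2),
```

where `Z` is the column-centred and scaled (standardized) genotype matrix of
the reference individuals and `g` the vector of marker effects on that
standardized scale. The BayesR prior places each effect in one of four normal
components,

```
g_i | b_i = k  ~  N(0, sigma_k2),     sigma_k2 = c_k * sigma_g2,
```

with a fixed variance ladder `c = (0, 0.0006, 0.006, 0.06)` for ~10K-marker
panels (a `(0, 0.0001, 0.001, 0.01)` profile is provided for dense panels).
The first component is a point mass at zero — the spike — so the prior is a
spike-and-slab mixture. The mixing proportions `Pr` carry a
`Dirichlet(alpha)` prior, `alpha = (1,1,1,1)` by default. The total genetic
variance `sigma_g2` and the residual variance used for initialization come
from a REML fit of the GBLUP model (single eigendecomposition of the genomic
relationship matrix `K = ZZ'/m`, then a bounded one-dimensional search over
heritability with the total variance profiled out).

## The EM algorithm with a prediction-error correction

The EM algorithm (`embayesr.em.run_em`) estimates one effect at a time.
For marker `i` the data enter through the scalar

```
r_i = Z_i' y_dagger,
```

where `y_dagger` is the phenotype corrected for the mean and all *other*
markers' effects. The key idea is that those other effects are themselves
estimates with error, so `r_i` is modelled, under component `k`, as

```
r_i ~ N(0,  zz_i^2 sigma_k2 + zz_i sigma_e2 + w_i),      zz_i = Z_i'Z_i,
```

where `w_i = Z_i' PEV Z_i` injects the prediction error covariance (PEV) of
the GBLUP breeding values. The PEV matrix is computed once, before the EM
iterations, from the REML fit:

```
PEV = sigma_g2 K - (sigma_g2 K) P (sigma_g2 K),
```

with `P` the inverse phenotypic covariance after absorbing the fixed mean by
generalized least squares. The leave-one-marker-out PEV is approximated by
this all-marker PEV, since one marker in 10 050 is negligible. Component
posterior probabilities `P_ik` follow from Bayes' rule via log-sum-exp;
after each full sweep the mixing proportions (`Pr_k` proportional to
`sum_i P_ik + alpha_k`), the error variance
(`sigma_e2 = (RSS + tr(PEV)) / n`) and the mean are refreshed. Sweeps visit
markers in ascending order with immediate residual updates (Gauss–Seidel
style), and the residual is recomputed from scratch every 100 sweeps to stop
floating-point drift. Convergence requires the relative squared change of
the effect vector to fall below `gamma = 1e-10`.

### The spike-aware mode update

The in-loop effect update is the posterior mode, damped by the posterior
probability of being non-null:

```
g_i  <-  (1 - P_i1) * r_i / (zz_i + sigma_e2 * sum_{k>=2} P_ik / sigma_k2).
```

The damping factor `(1 - P_i1)` carries the spike's point mass at zero into
the update and is a deliberate design decision. An undamped mode — `r_i`
over the posterior-weighted ridge denominator alone — ignores the spike
entirely: for the ~99% of markers with `P_i1` near 1, the slab terms
contribute about 1% of `zz_i`, so each marker would keep an essentially
least-squares value and the sweep converges to a near-interpolating, badly
overfitted solution (validation accuracy collapses toward zero). With the
damping, markers confidently in the spike are driven to zero while markers
confidently in a slab get the slab's ridge shrinkage; the two regimes are
bridged smoothly. A posterior-*mean* update (spike contributes zero, each
slab its own ridge estimate, mixed by `P_ik`) is available as a switch and
gives near-identical predictions at convergence.

### What the PEV correction does

`w_i` enters only the component-membership variances, and `tr(PEV)` only the
`sigma_e2` update. Both widen the model's view of noise to account for the
estimation error of all other markers: without them, residual noise that is
really "other markers estimated imperfectly" is attributed to the marker
under consideration, so borderline markers are kept with inflated effects
and the mixture is pushed away from the spike.

## The ablation and an estimator-inconsistency finding

The without-PEV variant used for ablation drops `w_i` from the membership
variances *and* `tr(PEV)` from the `sigma_e2` update, everything else
identical. On our simulated data this variant does not merely lose a few
points of accuracy — at `h2 = 0.45` and full scale (2500 reference
individuals, 10 050 markers) it is *bistable* and typically collapses:

- Without `tr(PEV)`, the `sigma_e2` estimator is inconsistent. Each sweep
  the model absorbs a little more residual into marker effects, `RSS/n`
  falls, the smaller `sigma_e2` makes slab membership cheaper, which absorbs
  more residual. At `h2 = 0.45` this feedback runs away: `sigma_e2` drops
  from ~1.6 to ~1e-4 within ~50 sweeps, a quarter of all markers end in the
  second component, and validation accuracy falls to ~0.45–0.53 — roughly 45
  percentage points below the with-PEV fit.
- Holding `sigma_e2` fixed at its REML value (a *different* ablation that
  re-estimates nothing) removes the collapse entirely and scores within 1–3
  points of the with-PEV fit, because REML's `sigma_e2` already prices in
  most of what `w_i` would add.
- At `h2 = 0.10` the system is bistable across replicates: on some seeds
  the feedback never runs away (`sigma_e2` stays at 5–8) and the ablation
  loses only ~1–3 points, while on others (including the replicates behind
  the reported reproduction numbers) it collapses exactly as at
  `h2 = 0.45`, with validation accuracy falling to ~0.23.

So on this package's genotype surrogate there is no ablation variant that
loses the moderate 4–8 points reported for the original study's
coalescent-simulated data: the faithful ablation either collapses
completely or, in the benign low-heritability basin, loses only 1–3
points. We ship the faithful
ablation and report its behaviour honestly; the corresponding end-to-end
assertions in `tests/test_acceptance.py` fail, and we read those failures as
falsifying the *transfer of the published ablation magnitudes to this
surrogate*, not as a defect of the estimator itself (the with-PEV method,
the Gibbs reference, and every oracle-level check agree). The likely root
cause of the difference is linkage disequilibrium: the surrogate's
first-order-Markov LD is much weaker than coalescent LD, which changes both
the GBLUP baseline (see below) and the severity of the overfitting feedback.

## The Gibbs reference

`embayesr.gibbs` implements the identical model with all unknowns sampled
from their full conditionals: per-marker component membership
(categorical), effect (normal), mixing proportions (Dirichlet), error
variance (scaled inverse-chi-square with a flat prior), and the mean.
Uncertainty in other markers' effects is handled by the sampling itself, so
no PEV correction enters. Posterior means over thinned post-burn-in draws
(default 10 000 iterations, 2 000 burn-in, thin 10) summarize the chain. On
markers the EM model confidently places in the largest component, EM point
estimates and Gibbs posterior means agree to within a few percent; on
borderline small-effect markers the EM estimates are noticeably more
shrunken than the posterior means, as expected of a mode-style estimator.

## The genotype surrogate and its consequences

The simulator (`embayesr.simulate`) is a deliberately simple surrogate for a
coalescent simulation: allele frequencies from a `1/p` site-frequency
spectrum (floored at MAF 0.01), haplotypes from a first-order Markov chain
along markers with adjacent-marker correlation 0.5, dosages as two
haplotypes. QTL are 50 of the 10 050 markers, with effects 17/16/17 from the
three slab distributions (mixture architecture) or all from one normal
(single-normal architecture); residual variance is set from the realized TBV
variance so heritability is exact in expectation.

Because QTL are genotyped and LD is weak, marker-based mixture models are
*stronger* here than on coalescent data (validation accuracy ~0.95 at
`h2 = 0.45` versus ~0.97 reported at much higher panel density), while
GBLUP is much *weaker* (~0.35 versus ~0.67–0.78): the GRM dilutes 50 causal
markers across 10 050 columns and weak LD provides no support between them.
This makes the mixture-beats-GBLUP contrast far larger than published, and
makes the published "GBLUP is competitive on the single-normal architecture"
claim untransferable — the corresponding assertion also fails honestly.
Convergence is likewise faster here (roughly 75–85 sweeps at `h2 = 0.45`,
hundreds to a few thousand at `h2 = 0.10`) than the published ~2 500,
consistent with the cleaner signal.

Two further published patterns transfer only partially:

- *Prior insensitivity.* The published claim is that accuracy is unchanged
  (within 0.01) across extreme Dirichlet pseudo-count vectors. On our
  surrogate the spread can reach ~0.025 on a replicate whose baseline fit is
  relatively weak: pseudo-counts that push prior mass toward the larger slab
  components (`alpha = (1,1,100,1)` or `(1,1,1,100)`) *raise* accuracy by
  ~0.02, because with only 50 genotyped causal markers and weak LD the data
  reward keeping moderate effects un-shrunken.
- *Gibbs bias slope.* The regression of TBV on GEBV for the Gibbs sampler
  sits near 1 but can land marginally outside a 0.9–1.1 band on individual
  replicates (we observed 1.102).

## Numerical notes

- Inner loops (EM sweep, Gibbs chain) are `numba`-compiled over
  Fortran-ordered `Z`; a full-scale EM sweep costs ~65 ms.
- All randomness flows through `numpy.random.default_rng`; experiment-level
  sub-seeds are derived from a master seed via `SeedSequence` over CRC-32
  label hashes, kept below 2^31.
- The EM objective (expected complete-data log posterior with the spike's
  delta term dropped) is tracked as a diagnostic. It is not asserted to be
  monotone: the prescribed initialization (all effects 0.01, `Pr_2` near
  0.5) produces an overfit-then-prune transient during which the tracked
  surrogate decreases before stabilizing.
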