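# Methods

## The background model

A capture Hi-C count for a directed pair (bait *i*, other end *j*) at
genomic distance *d* is modelled as the sum of two independent components
(a Delaporte distribution):

    X_ij = NB(mu_ij, r) + Poisson(lambda_j),    mu_ij = s_i * s_j * f(d)

* `f(d)` — the distance-decay function, handled on the log–log scale over
  the fit range 10 kb – 1.5 Mb and extrapolated linearly (in log–log)
  outside it. Three parametrisations are fitted by ordinary least squares
  to the per-bin estimates: cubic (a0 + a1·x + a2·x² + a3·x³ in x = log d),
  linear (b0 + b1·x), and "theoretical" (c0 − x, the d⁻¹ power law expected
  for long polymers at large separation). The cubic fit is the active
  model for scoring.
* `r` — a single global NB size (dispersion) parameter; larger r means
  closer to Poisson.
* `s_i` — a fixed multiplicative bait bias; `s_j` — an other-end bias
  treated as a draw from pooled empirical distributions (five quantile
  pools by marginal count). When a fragment sits in the *bait role* its
  fixed bias is used; in the *other-end role* it is represented by its
  pool's mean. This asymmetric treatment is deliberate: it is the
  mechanism that makes bait–bait scores direction-dependent, and the
  evaluation battery measures exactly that. A `symmetrized=True` scoring
  mode uses fixed biases on both sides of bait–bait pairs and restores
  exact reversibility, isolating the mechanism.
* `lambda_j` — per-pool technical-noise rates estimated from
  trans-chromosomal pairs (every trans read is attributed to noise):
  pool rate = trans reads / possible trans pairs in the pool.

The upper-tail p-value P(X ≥ k) is computed in natural-log space with the
exact finite decomposition
P(X ≥ k) = Σ_{j<k} Pois(j; λ) · P(NB ≥ k−j) + P(Pois ≥ k); the vectorised
path truncates the Poisson sum where its mass falls below 1e-16, which is
exact to double precision for realistic λ (≤ 0.01 per possible pair).

## Scoring and weighting

    score = max(0, -log p + log w(d))

`w(d)` is a four-parameter bounded logistic in log distance (lower
asymptote, upper asymptote, midpoint, slope ≥ 0), constrained monotone
non-increasing with values in [0, 1]; it plays the role of a prior
probability of interaction and penalises distant calls. Interactions are
declared at score > 5 (strict), the "normal score threshold" (NST). The
score composition is the weighted-p-value form soft-thresholded at zero;
with it, a pair needs log p < −(5 + |log w(d)|) to be called, which
reproduces the interplay between the score threshold and the
reproducibility function g(ρ) measured by `score_eval`.

Default weight parameters are the synthetic generator's ground-truth prior
curve (0.01, 0.3, 12, 2) unless the user supplies a 4-value parameter
file. These are *not* any production caller's defaults; they are the
generating truth of this package's simulations, which makes
"default-vs-re-estimated weights" comparisons well-posed.

## Estimation pipeline

Order: distance function → biases → dispersion → technical noise.

1. **f(d)**: geometric mean of the non-zero counts per 20 kb distance bin
   (75 bins to 1.5 Mb); bins with no positive count are flagged empty, not
   zero. Important regime note: conditioning on "non-zero" biases the
   estimator upward wherever the per-pair mean drops below ~1 read, which
   flattens the apparent decay at large distances at typical depth. The
   estimator is consistent in the deep-count regime (a few reads per pair
   at 1.5 Mb); the parameter-recovery tests therefore run at deep-library
   level, and slope estimates on shallower simulations are expected to be
   compressed (−0.5 to −0.7 rather than −1). The cubic fit absorbs this
   curvature, which is precisely what the curvature statistic
   K = ∫ |y″|/(1+y′²)^{3/2} dx (quadrature over log 10⁴ … log 1.5×10⁶;
   exactly 0 for affine fits) quantifies.
2. **Biases**: a two-pass weighted ratio estimator. Each bait's counts are
   regressed through the origin on the expected counts under f(d) with
   unit biases; the slope is s_i. Weights are inverse working variances
   (mu + mu²/r0, with r0 from a method-of-moments fit), so the
   hypervariable shortest-distance pairs cannot dominate; pairs below the
   10 kb fit floor are excluded for the same reason. Pass 2 repeats this
   per other end given the bait biases. Both sets are normalised to
   geometric mean 1; fragments with no usable signal are flagged
   unestimable and their pairs dropped from scoring (with a logged count)
   rather than given a zero bias. This deliberately simplified two-pass
   scheme preserves the fixed-bait / random-other-end structure without a
   full iterative fit.
3. **Dispersion r**: profile maximum likelihood with per-pair means fixed,
   optimised on log r (bounded Brent, tolerance 1e-6, cap 1e6). Inputs
   with no evidence of overdispersion (Pearson statistic within 2 SEs of
   its Poisson-null expectation) return the cap with a warning.
4. **λ pools**: five quantile pools by marginal trans count; rate = pooled
   trans reads / pooled possible trans pairs. The companion diagnostic
   checks that pool medians and variances rise from the first pool to the
   last, the signature of pooling tracking fragment visibility.

The pipeline fits the model on the first replicate and scores every
replicate with it, so replicate-to-replicate differences reflect counts,
not re-estimated models.

## Monte-Carlo goodness of fit

Per bin, the null is X ~ NB(s1·s2·f(d), r) with s1, s2 resampled from the
estimated bait/pooled-other-end empirical bias distributions and d uniform
across the bin; the Poisson component is omitted, matching the
small-distance approximation being tested. Because this mixture has no
tractable CDF, the reference CDF is the empirical CDF of a pooled
simulation of n_sim × n_pairs draws, and an *independent* second pool of
n_sim replicates supplies the null distribution of the discrete KS
statistic (max |ECDF − CDF| over the observed atoms). The p-value
estimator (1 + #{D_sim ≥ D_obs})/(1 + n_sim) is floored at 1/(n_sim+1);
values at the floor are printed as "<floor". Canonical settings are
5000 simulations of 5000 pairs; the pipeline default is 500 × 1000 and the
calibration tests use 500 × 1000 with 200 bin/seed draws, sizes chosen so
the battery completes in seconds while the binomial check on the nominal
0.05 level retains power. D_obs uses *all* observed pairs in the bin;
calibration draws observed samples of n_pairs so the observed and
simulated statistics are exchangeable.

## The synthetic generator

The generator emulates the statistical structure the caller assumes — and
only that structure:

* one contiguous synthetic chromosome, gamma-distributed fragment lengths
  (mean 4 kb, HindIII-like, floor 150 bp), an evenly spaced deterministic
  bait subset, plus an unbaited decoy chromosome whose sole purpose is to
  furnish trans pairs for λ estimation;
* decay f(d) = exp(c0)/d with c0 = log 3×10⁵ by default (~15 reads per
  pair at 20 kb, ~0.2 at 1.5 Mb — a realistic per-replicate depth for a
  targeted library);
* log-normal biases: baits sd 0.25, other ends sd 0.5 (wider, reflecting
  uncaptured-fragment heterogeneity; large enough to make the score
  asymmetry measurable at desk scale);
* λ rising linearly 0.001 → 0.01 across five pools, so the "trend
  upwards" diagnostic has a real signal;
* spiked true interactions: each cis pair within 1.5 Mb is true with
  probability given by the logistic prior (0.01, 0.3, 12, 2) and receives
  a multiplier uniform in [3, 10] — detectable but not trivially separable
  at default depth;
* replicates share the truth and draw independent NB + Poisson noise from
  seed-sequence-spawned streams. Everything is bit-reproducible from
  (parameters, seed).

Perturbations emulate cancer-genome artefacts: CNV regions thin
(binomial) or amplify (added Poisson) counts integer-exactly with the
right mean; a breakpoint (chrom, a, b) fuses two loci, resampling every
spanning pair at effective distance d − (b − a), floored at 10 kb (a
junction-scale gap). Map distances are left untouched — the analyst does
not know about the rearrangement — which distorts the fitted decay curve
exactly the way such events do in practice: mid-range enrichment that
pushes the cubic coefficient a3 negative. The mechanism tests use fusion
spans of a few hundred kb, the scale at which the enrichment lands in the
middle of the fit range.

What the generator does **not** emulate: real restriction-site spacing
from a genome sequence, read-level artefacts (the Poisson term is the
abstraction), inter-fragment correlation beyond shared biases, and
karyotype-specific rearrangement geometry. Passing tests therefore
demonstrate that the estimators and diagnostics behave correctly under the
model's own assumptions — not that the model captures everything in real
libraries.

## Thresholds and optimisation

The FDR-proxy objective t ↦ 1 − Jaccard(significant sets at score > t) is
piecewise constant, so its numerical minimisation is optimiser-dependent —
a property the battery reports rather than hides. The quasi-Newton path
runs scipy's L-BFGS-B with forward-difference gradients (step 0.5) on the
continuous threshold; the simplex path runs Nelder–Mead. On flat stretches
L-BFGS-B legitimately stays at its starting point (the NST) while
Nelder–Mead can wander to distant plateaus; both results are reported with
their achieved FDR, the returned threshold rounded to the nearest integer.
Search bounds [0, 10⁴], start at the NST. Ties throughout the integer
threshold scans break toward the smaller threshold (favouring
sensitivity). When every significant set is empty the objective is defined
as 1 (worst), which keeps the search away from degenerate thresholds.

g(ρ) inversion scans ρ over [−50, −1] at step 0.1 and bisects the first
bracketing interval; because g is a ratio of counts it is piecewise
constant too, so the returned ρ* is the evaluated point whose g is closest
to the target, and absence (no crossing) is a reported value, not an
error.

## Reweighting comparison

Observed prior per bin = fraction of tested pairs (union over replicates)
with log p < ρ in *every* replicate; pairs missing from any replicate
count as non-reproducible. Curves are fitted at ρ = −10 and, when it
exists, at ρ* (where g(ρ*) = 0.05); the lower-RSS fit wins. RSS is
computed on the prior-probability scale over non-empty bins only, with the
number of excluded zero bins reported alongside — exclusion deflates the
RSS, and the count makes that visible. Scores are then recomputed from the
stored log p-values (the null does not change, only w(d)) and the report
carries the per-replicate-averaged Jaccard between default-weight and
custom-weight calls plus the change (custom − default) in score
correlation, % reversible, FDR at the NST and FNR.

## Numerical conventions and degenerate inputs

* All probability arithmetic in natural-log space; logsumexp for
  convolutions; p-value tails via `nbinom.logsf`.
* Strict inequalities: significance is score > t; g(ρ) failure is
  score < t; robustness is log p < ρ.
* Constant sequences have LOM 0 by convention (monotone), with a warning.
* Jaccard of all-empty sets, symmetry with < 3 usable pairs, reversibility
  with no significant direction, and ρ* with no crossing are *absent*
  values with warnings, not silent zeros.
* The weight fit uses three deterministic starting points (slopes 0.5, 2,
  5, midpoint at the median log distance) and bounded least squares;
  monotonicity is enforced by the slope's sign constraint.
* Distance of a pair = absolute difference of fragment midpoints; trans
  pairs carry no distance and contribute only to λ.
* Scored output is written at 6 significant digits; round-trips are exact
  to 1e-5.

## Problem sizes

The default pipeline configuration simulates 1000 fragments (~4 Mb) with
100 baits, a 200-fragment decoy, 2 replicates, and runs the KS battery at
500 simulations × 1000 pairs per bin — about 15 s on one CPU. The test
suite uses 250–600-fragment maps and the canonical recovery sizes (50,000
pairs for slope and dispersion; 200 in-range pairs per bait for bias
recovery at deep-library level, where the ±10% recovery band corresponds
to roughly two standard errors of the information-limited estimator).

## Known limitations

* The caller is a minimal realisation of the stated model, not a
  re-implementation of any production tool: bias estimation is two-pass
  rather than iterative, replicates are not merged before scoring, and no
  outlier rejection is applied to the distance fit.
* The geometric-mean distance estimator's shallow-depth flattening (above)
  is inherited by everything downstream of f(d) at low depth; the cubic
  fit compensates within the fit range but the true decay exponent is not
  identified there.
* The FDR and FNR quantities are proxies built on reproducibility
  assumptions (true calls replicate, false ones do not); they support
  comparisons between thresholds, not calibrated error statements.
* λ estimation assumes every trans read is noise; real inter-chromosomal
  biology would inflate it.
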