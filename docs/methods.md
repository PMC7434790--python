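# Methods

## The measurement model

`scaleshort` works with the generalized partial credit model (GPCM) for
an item with scored categories c = 0..m:

    P(c | θ) ∝ exp( Σ_{k≤c} a (θ − b_k) ),   empty sum = 0,

with one discrimination `a` per item and step difficulties `b_1..b_m`.
Each `b_j` is the trait level at which categories j−1 and j are equally
probable.  No ordering constraint is placed on the steps: reversed steps
are legitimate GPCM solutions (the shipped reference calibration
contains several, e.g. Q5's b = (−0.72, −4.68, −1.58, −2.87)).

Item Fisher information is `I(θ) = a² Var(C | θ)`, which also equals
`a · dE[C|θ]/dθ`; test information is the sum over items.  Two useful
consequences drive the test suite: the integral of `I` over the whole
real line is exactly `a · m`, and information is additive, so the SE
curve `1/√I(θ)` can only rise when an item is removed.

### Conventions and ranges

- **"Entire range" integration** uses (−8, 8).  For every reference
  item the mass outside is far below the reporting precision (the
  `a·m` identity bounds it), and the published per-item information
  values are reproduced within 2% — consistent with them being
  full-range integrals of the printed parameters.
- The **restricted range** (−3, 3) avoids information inflation from
  extreme trait levels.
- The **average SE** is the unweighted mean of `1/√I(θ)` over 61 evenly
  spaced points on (−3, 3).  It is an information-only quantity (no
  prior term), unlike some programs' EAP posterior SDs; both the grid
  and this choice are configurable.

## Estimation

Marginal maximum likelihood with a standard-normal latent prior, which
identifies the scale.  The default quadrature is 61 evenly spaced
points on (−6, 6) carrying normalised N(0,1) weights (the rectangular
rule common in IRT software); a Gauss–Hermite grid is available.  The
EM iteration computes posterior weights over grid points (E-step) and
runs per-item Newton updates with step-halving (M-step) in the
slope/intercept parametrisation (a, γ), γ_c = a·Σ_{k≤c} b_k, in which
the complete-data likelihood is a concave multinomial logit.
Convergence is declared when the largest (a, b)-scale parameter change
falls below 1e-4 (cap 500 iterations; non-convergence is flagged, not
raised).  The marginal log-likelihood is recomputed at the final
parameters and is non-decreasing across iterations by construction.

Standard errors and Wald covariances come from the exact observed
information via the Louis identity — the posterior expectation of the
complete-data information minus the posterior variance of the
complete-data score — evaluated analytically on the grid and mapped to
the (a, b) scale by the delta method.  This reproduces a
central-difference numerical Hessian to ~1e-6 relative accuracy at a
tiny fraction of its cost, which is what makes the replicate-heavy
calibration suites feasible.

EAP trait scores are posterior means under the N(0,1) prior; they
shrink toward zero relative to maximum-likelihood scores, as the tests
verify.

## Two-group fits and DIF

The two-group model fixes the reference group's latent distribution at
N(0,1), estimates the focal group's mean and variance (variance can be
fixed at 1), constrains anchor items equal across groups, and frees the
studied items.  Focal-group quadrature weights are the base weights
reweighted by the density ratio N(θ; μ, σ²)/N(θ; 0, 1).

The Wald statistic for an item is `d' V⁻¹ d` on the between-group
difference d of (a, b_1..b_m), df = 1 + m = 5 for five-category items,
V from the inverse observed information of the joint fit (so anchor
uncertainty and the focal mean/variance propagate).  Slopes and steps
are tested jointly.  α = 0.05 with no multiplicity correction by
default; configurable.

Workflow pieces: `wald2_scan` (each item tested with all others as
anchors), `maxa5_anchors` (five largest discriminations, ties broken by
item order), and `iterative_wald1` (fixed anchors; candidates tested
one at a time with currently flagged items freed, repeated until the
flagged set stabilises — at most n_items rounds since flags only grow).

**Finite-sample behaviour.**  The focal-group variance is weakly
identified: its per-replicate sampling SD is ≈ 0.2 even at 400 persons
per group, so recovery is checked on averages over replicates.  Under
the reference calibration at the study's size (404 persons, 162/242
split) the Wald test for an item with sparse extreme categories (Q8)
is conservative — its null statistic tracks the likelihood-ratio
statistic closely but both fall short of the nominal χ²₅ mean because
the asymptotics have not set in for the near-empty cells.  The null
calibration suite therefore measures the type-I rate where the χ²
regularity conditions hold: six 5-category items with moderate steps
(a between 0.8 and 1.8, |b| ≤ 2), 500 persons per group, 200
replicates; there the empirical rate sits inside [0.02, 0.10] at
α = 0.05.  Practically this means DIF decisions on items like Q8 at
n ≈ 400 err on the side of not flagging.

## Short-form construction

**Iterative removal** ranks items once from the full-model fit (no
refitting between removals — this makes the removal order a pure
function of the calibration): first items with a < 0.4, then
DIF-flagged items, then ascending full-range item information.  Each
step records test information (entire range and (−3, 3)) and the
average SE.  The stop index is the first step whose relative full-range
test-information drop from the previous step exceeds a threshold
(default 7%), and the retained form is the remaining set *after* that
step: the procedure removes items until a removal produces a
substantial drop, and that knee-marking removal is the last one
accepted.  Under the reference calibration the drops along
Q5, Q11, Q4, Q7, Q6, Q12 are 2.6–6.0% and Q12's removal is the first
above 7% (9.9%), so the retained form is
{Q1, Q2, Q3, Q8, Q9, Q10}.  The threshold is judgmental by nature, so
the full trajectory is always returned for the analyst to override.

**Optimal test assembly** maximises `Σ_i x_i v_i`, with
`v_i = Σ_t I_i(θ_t)` summed over the anchor points (−3, −1, 0, 1, 3),
subject to `Σ x_i = L` and optional per-domain minimum counts, using a
depth-first branch-and-bound whose node bound is the greedy fractional
(LP-relaxation) optimum.  Include-branches are explored in item order
and the incumbent is replaced only on strict improvement, so the
returned optimum is deterministic (lexicographically first).  The
solver is cross-checked against exhaustive enumeration for every
length on the reference calibration and on random instances.
Objective values use full-model parameters; candidates are refitted
only when evaluated.

**Decision criteria** (relative to the full form, after refitting the
candidate on its own columns): (1) summed-score *and* EAP
factor-score correlations ≥ 0.95; (2) both convergent-validity
correlations within 0.05 of the full form's (signed correlations,
absolute difference); (3) Cronbach's alpha ≥ 95% of the full form's.
`shortest_satisfying_form` walks L upward from 3 and returns the first
passing candidate, or the full set flagged inadmissible.  On synthetic
data the smallest passing L is often below 9 because the
low-information items contribute little to score correlations; the
structural 9-item selection is a property of the calibration, while
the selected length is a property of the data.

## The synthetic-data generator

The generator inverts the GPCM the pipeline fits, under the study's
conditions: 404 persons, θ ~ N(0,1), responses drawn per item from the
category distributions at the person's θ, exactly 60% female (the
female group is the DIF reference), and an integer 0–21 convergent
criterion built as `10.5 + ρ·3.5·z(θ) + 3.5·√(1−ρ²)·ε`, rounded and
clipped.  The default ρ = −0.664 was solved once from the target
correlation −0.60 between criterion and summed score and the measured
corr(sum, θ) ≈ 0.904 under the reference parameters; the scale 3.5
keeps clipping below 1% so rounding attenuation stays inside the
±0.05 calibration tolerance.  DIF is injected by shifting one item's
a and/or all its steps in the focal group only (default target Q8).
One seed drives independent per-stage RNG streams (traits, responses,
criterion, gender), so fixtures are bit-reproducible.

What the generator does *not* emulate: household sampling and
clustering, nonresponse and missing data, the PSQI's internal
7-component structure (only a total-score analogue), multidimensional
trait structure, and any response styles beyond the GPCM itself.
Passing tests therefore show that the pipeline recovers what the GPCM
world generates at the study's size — not that the original sample's
data-dependent quantities (its KMO, alphas, or DIF p-values) are
reproduced.

## Numerical choices and degenerate inputs

- Category probabilities use max-subtracted softmax throughout; Newton
  updates clip a to ±8 and γ to ±80 to keep weakly identified items
  (empty or near-empty categories) finite.
- Polychoric correlations are two-step estimates (thresholds from
  inverse-normal marginals, then a bounded 1-D likelihood
  maximisation); full-ML differences are far below the test
  tolerances.  Non-positive-definite polychoric matrices are
  eigenvalue-clipped at 1e-6 with a warning and rescaled to unit
  diagonal.
- Minres factoring optimises uniquenesses (L-BFGS-B, started from
  squared multiple correlations) on the off-diagonal residual sum of
  squares; the solution is deterministic given the matrix.
- The unidimensionality eigenvalue ratio uses eigenvalues of the
  polychoric correlation matrix itself; with a single factor no
  rotation is involved, and the first factor's variance share is
  `Σλ²/p` from the unrotated loadings.  A zero second eigenvalue
  reports a ratio of +∞ (verdict true).
- Items with a single observed category, groups with fewer than one
  person, zero-variance scores, singular information matrices, and
  infeasible domain constraints all raise errors naming the offending
  item or constraint.

## Known limitations

- No graded-response, nominal, or multidimensional models; the scale
  is treated as essentially unidimensional by design.
- Wald DIF inference is asymptotic; as noted above it is conservative
  for sparse-category items at a few hundred persons per group.
- The branch-and-bound is exact but designed for item banks of tens of
  items, not thousands.
- Missing responses are rejected (the emulated study had none);
  listwise deletion is available for external data, nothing more
  sophisticated.
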