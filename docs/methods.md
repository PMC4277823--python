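# Methods

## Model and hypothesis

Three independent binomial arms: `X_T ~ Bin(n_T, pi_T)` (experimental),
`X_R ~ Bin(n_R, pi_R)` (active reference), `X_P ~ Bin(n_P, pi_P)` (placebo),
higher response meaning better outcome.  The non-inferiority margin is taken
as a fraction `f = 1 - theta` of the unknown reference effect,
`Delta = f (pi_R - pi_P)`, which turns "T is not worse than R by more than
Delta" into the retention-fraction hypothesis

```
H0: psi <= 0  vs  H1: psi > 0,     psi = pi_T - theta*pi_R - (1-theta)*pi_P .
```

`theta` must lie strictly in (0, 1); `theta = 0.6` or `0.8` are typical.  The
preliminary requirement that the reference beat placebo (`pi_R > pi_P`) is
assumed established separately and is not retested here; it enters only
through the shape of the null nuisance space.

## Estimation

The unrestricted MLE is the per-arm proportions.  The restricted MLE (RMLE)
under `H0` equals the MLE whenever `psi_hat <= 0`; otherwise it maximises the
likelihood kernel on the boundary `pi_T = theta*pi_R + (1-theta)*pi_P` over
the closure `{0 <= pi_P <= pi_R <= 1}` of the nuisance space (the strict
`pi_P < pi_R` of the parameter space is relaxed to its closure: a supremum
over an open set is attained on the closure, and the closed triangle avoids
degenerate feasibility).  The constrained kernel is concave in
`(pi_P, pi_R)` — each arm contributes a binomial log-likelihood composed with
an affine map — so the maximiser is found reliably.

Two implementations share the work:

* **Scalar** (`rmle`): bounded L-BFGS-B from five deterministic starts on the
  reparametrised unit square `(pi_P, q)` with `pi_R = pi_P + q(1-pi_P)`, a
  201x201 grid fallback, the batch solution as an extra candidate, and a
  Nelder-Mead polish; the best candidate wins.  Verified against 500x500 and
  2001x2001 grid oracles.
* **Batch** (`rmle_batch`): a damped, projected Newton iteration run
  simultaneously over arbitrarily many outcomes (an exact-power run needs the
  RMLE at every point of a lattice with ~2x10^5 outcomes, which rules out
  per-outcome calls into an off-the-shelf optimiser).  Projection onto the
  triangle can stall the iteration when the optimum lies on the diagonal
  `pi_P = pi_R` or on an edge, so the exact solutions of those
  lower-dimensional problems are computed as candidates: on the diagonal all
  three arms share one rate and the maximiser is the pooled proportion
  (closed form); the `pi_P = 0` and `pi_R = 1` edges are one-dimensional
  concave problems solved by vectorised bisection on the derivative.  The
  best candidate is kept per outcome.  Agreement with the scalar solver is
  tested exhaustively on small lattices.

A `psi_hat > 1e-12` tolerance decides the RMLE branch: outcomes sitting
exactly on the boundary otherwise flip branches on float noise.

## Test statistics

All three standardise `psi_hat = x_T/n_T - theta*x_R/n_R - (1-theta)*x_P/n_P`:
Wald (`T_W`) divides by the standard error with variances at the MLE, score
(`T_R`) uses the RMLE plug-in (the numerator stays the unrestricted
`psi_hat`), and the signed-root LRT (`T_L`) is
`sign(psi_hat) sqrt(2 max(deviance, 0))` — the clamp absorbs optimizer
tolerance of order -1e-12.  When the plug-in variance is exactly zero the
statistic is set to +inf / 0 / -inf according to the sign of `psi_hat`,
which preserves the outcome ordering the tail-set engines rely on.

Two structural facts worth noting (both tested): when the RMLE branch returns
the MLE, `T_R = T_W` exactly and `T_L = 0`; and because `T_L` is identically
0 on the null side, it is *not* antisymmetric under response/non-response
reflection and its boundary distribution is `max(Z, 0)`-like rather than
N(0,1) — the N(0,1) limit applies to its strictly monotone extension, the
signed root of the deviance against the `psi = 0` constrained fit, which the
package also exposes (`signed_null_deviance_batch`) and uses internally.

## P-value engines

All five report `P(T >= t_obs)` with closed ties (`>=`), which is what makes
`p(x) >= P(X = x)` and hence valid type-I error control possible on a lattice.

* **AM**: `1 - Phi(t_obs)`.
* **SAM**: the cumulant generating function of `psi_hat` at the `psi = 0`
  RMLE is `K(t) = sum_k n_k log(1 - pi_k + pi_k e^{c_k t})` with lattice
  coefficients `c = (1/n_T, -theta/n_R, -(1-theta)/n_P)`; the saddlepoint
  `K'(t_hat) = s` is solved by safeguarded Newton/bisection (the binomial CGF
  is entire, so the bracket expands geometrically with no cap on `|t|`), and
  the Lugannani-Rice tail `1 - Phi(r) - phi(r)(1/r - 1/lambda)` is returned,
  with the third-cumulant limit substituted when `|r| < 1e-5` (removable
  singularity at the mean).  The tail event is mapped to the `psi_hat` scale:
  `s = psi_hat_obs` for `T_W` and `T_R` (both standardise the same contrast,
  so their saddlepoint p-values coincide), while for `T_L` the observed value
  is inverted along a one-dimensional profile of fractional pseudo-data
  through the null point, using the monotone extension above (the raw
  statistic is flat at 0 on the null side, so inverting it directly is
  ill-posed).  Thresholds outside the open attainable range of `psi_hat`
  fall back to the normal tail with a logged warning.  Rates within 1e-8 of
  {0, 1} are snapped to exact degeneracy before the range check so that
  boundary-clipped optimiser output does not masquerade as an interior CGF.
* **EUM**: supremum of the enumerated tail over the full null space
  `{psi <= 0, 0 <= pi_P <= pi_R <= 1, 0 <= pi_T <= 1}`, by a 101x101 grid on
  `(pi_P, pi_R)` crossed with a coarse `psi` grid (step 0.05), followed by
  Nelder-Mead refinement around the best grid point.  The sup for the
  statistics that degenerate at the simplex corners (notably `T_W`) is
  genuinely attained near `pi_R = 1`, making the exact test extremely
  conservative there; see "Discrepancies" below.
* **AUM**: the same enumerated tail evaluated only at the `psi = 0` RMLE.
* **BTM**: `B` parametric-bootstrap draws at the `psi = 0` RMLE, plain
  proportion `#{T* >= t_obs}/B` (no smoothing; the plain proportion is the
  quantity consistent with AUM as `B` grows), default `B = 10,000`, fully
  determined by the seed.

Enumeration is capped at 10^7 outcomes (configurable); beyond that the
engines refuse and point to the bootstrap / Monte-Carlo paths.

## Exact operating characteristics

The exact rejection rate of a procedure at true rates `pi` is the
probability-weighted sum of `I(p(x) <= alpha)` over the whole outcome
lattice.  Per-outcome p-values depend only on (sizes, theta, method,
statistic) — not on the true rates — so they are computed once and cached
across a design grid.  Two vectorisation tricks keep this desk-scale: for
EUM, one cumulative sum over the statistic-sorted lattice yields the tails of
*all* thresholds at a given nuisance point simultaneously, so a p-value
lattice costs O(grid x lattice); AUM lattices use the same sorted-cumsum per
outcome.  Inside size studies EUM uses a reduced 51x51 nuisance grid and BTM
uses `B = 1,000` by default (both overridable) — scaled-down relative to
standalone testing, as the full settings would be disproportionate inside a
multi-configuration sweep.  Monte-Carlo mode (`mc_rejection_rate`) simulates
trials instead and doubles as an independent cross-check of the enumeration
(tested at 100,000 trials, agreeing within 3 Monte-Carlo standard errors).

The boundary design grid sweeps `pi_P = 0.05, ..., 0.50` and
`pi_R = pi_P + 0.05, ..., 0.95` (steps configurable) with
`pi_T = theta*pi_R + (1-theta)*pi_P`, i.e. 135 null configurations per
(margin, size, allocation); sizes `n_l = n * lambda_l / sum(lambda)` must
divide exactly — non-integral splits are an error, not a rounding.
`summarize_sizes` reports per (method, statistic) the median, min, max and
the proportion of sizes inside (0.045, 0.055).

## Synthetic trials

`generate_fixtures` draws iid trials `x_k ~ Bin(n_k, pi_k)` from a seeded
generator — exactly the sampling model of the analysis, which is also the
model under which the exact enumeration is *exact*.  Simulated checks in the
tests therefore probe the implementation, not model misspecification: real
trials add dropout, misclassification and centre effects that neither the
generator nor the exact calculations represent.

## Numerical choices

* Likelihood work uses the kernel (binomial coefficients dropped); constants
  cancel in maximisation and likelihood ratios.  `log_likelihood` returns the
  full log-pmf by default so it can be checked against independent binomial
  pmf implementations, with `kernel=True` for estimation.
* `0 * log 0 = 0` throughout (`xlogy`); a rate of 0/1 incompatible with the
  observed count yields -inf, never an exception.
* Tail ties use a 1e-9 tolerance on the statistic scale, applied identically
  in the scalar masks and in the sorted-cumsum lattice path, so the two
  routes agree bit-for-bit on lattices with near-tied statistics.
* Per spec of the closed-tie convention, the tail at threshold +inf equals
  the probability mass of the +inf-statistic (degenerate-variance) outcomes,
  not 0.
* The CGF is evaluated in log-sum-exp form; saddlepoint roots are polished to
  `|K'(t) - s| <= 1e-12`.

## Discrepancies with previously published values

Three groups of previously published numbers for the worked example and the
power table could not be reproduced, and the package deliberately does not
match them; in each case an independent brute-force oracle sides with the
package:

1. **Score/LRT p-values for the worked example.**  The published asymptotic
   p-values (0.162, 0.164 at `theta = 0.6`) correspond to a restricted MLE
   that is measurably off the constrained optimum (a point near
   `(pi_P, pi_R) = (0.120, 0.193)` reproduces both published digits, while
   the true argmax `(0.1265, 0.1954)` — confirmed by a 2001x2001 grid —
   gives 0.1634 and 0.1664).  The Wald entries, which do not involve the
   RMLE, match to four digits.
2. **The exact-unconditional Wald p-value** (published 0.185).  The supremum
   over the full null space is ~0.446, attained near the all-success corner
   where Wald statistics explode; the tail rises monotonically toward that
   corner, so 0.185 can only arise from a search bounded away from the
   boundary.  The package computes the faithful supremum.
3. **Exact powers of the asymptotic test** (published 13.4/12.3/19.0%).
   Enumeration and an independent 500,000-trial simulation both give
   21.4/20.5/29.1% at the one-sided 5% level; the published column is
   reproduced almost exactly by using the two-sided critical value
   `z_{0.975}` instead, and is internally inconsistent with the published
   approximate-unconditional powers (a liberal test cannot be less powerful
   than a calibrated one).

## Known limitations

* EUM with Wald or LRT statistics is extremely conservative (the honest sup
  is corner-dominated); the score statistic, whose RMLE-based variance tames
  the corners, is the sensible companion to EUM — and to everything else.
* The saddlepoint engine approximates the tail of `psi_hat`, not of each
  statistic's own (equivalent up to the threshold mapping for `T_W`/`T_R`,
  profile-mapped for `T_L`); no lattice continuity correction is applied, so
  accuracy at `n_k ~ 10` is ~1e-2, not 1e-3.
* Enumeration memory/time grow with the product of arm sizes; beyond the cap
  use the bootstrap engine or Monte-Carlo mode.
* One margin per analysis: joint procedures (e.g. requiring the
  reference-beats-placebo test simultaneously) and prespecified absolute
  margins are out of scope.
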