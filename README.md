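# triarm

Small-sample non-inferiority testing for **three-arm clinical trials with
binary endpoints** (test treatment T, active reference R, placebo P).

A two-arm non-inferiority trial cannot demonstrate assay sensitivity from its
own data; adding a placebo arm fixes that, and shifts the statistical question
to a *retention-fraction* hypothesis: with response probabilities
`pi_T, pi_R, pi_P` and a fixed retention fraction `theta` in (0, 1),

```
H0: psi <= 0   vs   H1: psi > 0,    psi = pi_T - theta*pi_R - (1 - theta)*pi_P
```

i.e. the new treatment must preserve at least `100*theta` % of the reference
effect over placebo.  Standard large-sample tests for this hypothesis misbehave
when the arms are small or the data sparse; this package implements the
small-sample toolkit:

**Test statistics** (all asymptotically N(0,1) on the boundary `psi = 0`)

| statistic | standardisation |
|---|---|
| `T_W` (Wald) | variance of `psi_hat` plugged in at the unrestricted MLE (Blackwelder-style) |
| `T_R` (score) | variance at the restricted MLE under `psi = 0` (Farrington–Manning-style) |
| `T_L` (signed-root LRT) | `sign(psi_hat) * sqrt(2 [l(MLE) - l(RMLE)])` |

where `psi_hat = x_T/n_T - theta*x_R/n_R - (1-theta)*x_P/n_P` and
`Var(psi_hat) = pi_T(1-pi_T)/n_T + theta^2 pi_R(1-pi_R)/n_R + (1-theta)^2 pi_P(1-pi_P)/n_P`.
The restricted MLE maximises the product-binomial likelihood with
`pi_T = theta*pi_R + (1-theta)*pi_P` substituted, over `0 <= pi_P <= pi_R <= 1`.

**P-value engines**

* `AM` — asymptotic normal tail `1 - Phi(t_obs)`;
* `SAM` — saddlepoint (Lugannani–Rice) approximation to the lattice tail of
  `psi_hat`, built from its cumulant generating function at the null RMLE;
* `EUM` — exact unconditional: supremum of the enumerated tail probability
  over the entire null nuisance space;
* `AUM` — approximate unconditional: the enumerated tail at the null RMLE only;
* `BTM` — parametric bootstrap estimate of the same tail.

**Operating characteristics** — exact type-I error and power of any
(statistic, engine) pair by full enumeration of the outcome lattice, with
per-outcome p-values cached so one lattice serves a whole design grid.

## Worked example

The built-in example is a functional-dyspepsia trial in which adverse events
occurred in 12/58 patients on simethicone (test), 10/59 on cisapride
(reference) and 7/61 on placebo:

```
$ triarm test --counts 12/58,10/59,7/61 --theta 0.6 --method am --stat all
method stat  t_obs  p_value  reject
    AM    w 0.9430   0.1728   False
    AM    r 0.9805   0.1634   False
    AM    l 0.9684   0.1664   False
```

None of the statistics comes close to the 5% level: there is no evidence that
simethicone retains 60% of the cisapride effect on adverse-event rates.  The
small-sample engines agree — e.g. the approximate-unconditional p-values at
`theta = 0.6` are (0.166, 0.165, 0.178) for (`T_W`, `T_R`, `T_L`).

Exact power of the asymptotic Wald test for a balanced 30-patient design with
`pi_P = 0.15`, `pi_R = pi_T = 0.5`:

```
$ triarm power --n 30 --alloc 1:1:1 --theta 0.6 --pi 0.5,0.5,0.15 --method am --stat w
method stat  value  is_power
    AM    w 0.2139      True
```

i.e. a 21.4% chance of declaring non-inferiority — such designs are badly
underpowered, which is the point of studying them exactly.  The `size` and
`grid` commands evaluate type-I error at single boundary configurations and
over the standard boundary design grid (135 `(pi_P, pi_R)` pairs per margin,
size and allocation), and every command accepts `--format json|tsv|text`,
`--seed`, and a YAML config file mirroring the flags.

The same functionality is available as a library:

```python
from triarm import TrialCounts, Margin, StatisticKind, p_approx_unconditional

counts = TrialCounts(12, 58, 10, 59, 7, 61)
pv = p_approx_unconditional(counts, Margin(0.6), StatisticKind.SCORE)
print(pv.value)        # 0.16499...
```

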