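"""Likelihood and maximum-likelihood estimation for the three-arm binomial model.

A three-arm non-inferiority trial observes independent counts

    X_T ~ Bin(n_T, pi_T)   (experimental treatment)
    X_R ~ Bin(n_R, pi_R)   (active reference)
    X_P ~ Bin(n_P, pi_P)   (placebo)

with higher response probability meaning a better outcome.  The retention
hypothesis for a fraction ``theta`` in (0, 1) is

    H0: psi <= 0   vs   H1: psi > 0,      psi = pi_T - theta*pi_R - (1-theta)*pi_P,

i.e. the experimental arm must retain at least ``100*theta`` percent of the
reference-over-placebo effect.  This module provides the joint log-likelihood,
the unrestricted MLE, and the restricted MLE (RMLE) obtained by maximising the
likelihood under the null boundary ``pi_T = theta*pi_R + (1-theta)*pi_P`` over
the nuisance space ``{0 <= pi_P <= pi_R <= 1}``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import gammaln, xlogy, xlog1py

__all__ = [
    "TrialCounts",
    "RateTriple",
    "Margin",
    "log_likelihood",
    "mle",
    "psi_of",
    "rmle",
    "rmle_batch",
    "constrained_loglik",
]

_EPS = 1e-12


@dataclass(frozen=True)
class TrialCounts:
    """Observed responses and arm sizes, ordered (test, reference, placebo)."""

    x_T: int
    n_T: int
    x_R: int
    n_R: int
    x_P: int
    n_P: int

    def __post_init__(self) -> None:
        for x, n, arm in (
            (self.x_T, self.n_T, "T"),
            (self.x_R, self.n_R, "R"),
            (self.x_P, self.n_P, "P"),
        ):
            if int(x) != x or int(n) != n:
                raise ValueError(f"arm {arm}: counts must be integers, got x={x}, n={n}")
            if n < 1:
                raise ValueError(f"arm {arm}: sample size must be >= 1, got {n}")
            if not 0 <= x <= n:
                raise ValueError(f"arm {arm}: need 0 <= x <= n, got x={x}, n={n}")

    @property
    def xs(self) -> tuple[int, int, int]:
        return (self.x_T, self.x_R, self.x_P)

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (self.n_T, self.n_R, self.n_P)


@dataclass(frozen=True)
class RateTriple:
    """Response probabilities (pi_T, pi_R, pi_P); a parameter point, MLE or RMLE."""

    pi_T: float
    pi_R: float
    pi_P: float

    def __post_init__(self) -> None:
        for p, arm in ((self.pi_T, "T"), (self.pi_R, "R"), (self.pi_P, "P")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"arm {arm}: probability {p} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.pi_T, self.pi_R, self.pi_P])


@dataclass(frozen=True)
class Margin:
    """Retention fraction theta in (0, 1).

    The classical non-inferiority margin is Delta = f*(pi_R - pi_P) with
    f = 1 - theta; theta is the fraction of the reference effect that the
    experimental arm must preserve.
    """

    theta: float

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < 1.0:
            raise ValueError(f"retention fraction must lie in (0, 1), got {self.theta}")

    @property
    def f(self) -> float:
        """Margin fraction f = 1 - theta."""
        return 1.0 - self.theta


def _binom_loglik(x, n, p, kernel: bool):
    """Binomial log-pmf, with 0*log(0) = 0; -inf when p conflicts with x."""
    out = xlogy(x, p) + xlog1py(n - x, -p)
    if not kernel:
        out = out + gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
    return out


def log_likelihood(counts: TrialCounts, rates: RateTriple, *, kernel: bool = False) -> float:
    """Joint log-likelihood of the three independent binomial arms.

    With ``kernel=True`` the binomial coefficients are dropped; the kernel is
    what estimation routines maximise (the constant cancels in likelihood
    ratios).  Returns ``-inf`` when some ``pi_k`` in {0, 1} is incompatible
    with the observed count (e.g. ``pi_k = 0`` but ``x_k > 0``).
    """
    total = 0.0
    for x, n, p in (
        (counts.x_T, counts.n_T, rates.pi_T),
        (counts.x_R, counts.n_R, rates.pi_R),
        (counts.x_P, counts.n_P, rates.pi_P),
    ):
        total += float(_binom_loglik(x, n, p, kernel))
    return total


def mle(counts: TrialCounts) -> RateTriple:
    """Unrestricted MLE: the per-arm sample proportions (x_T/n_T, x_R/n_R, x_P/n_P)."""
    return RateTriple(
        counts.x_T / counts.n_T,
        counts.x_R / counts.n_R,
        counts.x_P / counts.n_P,
    )


def psi_of(rates: RateTriple, margin: Margin) -> float:
    """Retention contrast psi = pi_T - theta*pi_R - (1-theta)*pi_P."""
    th = margin.theta
    return rates.pi_T - th * rates.pi_R - (1.0 - th) * rates.pi_P


def constrained_loglik(a, b, counts: TrialCounts, margin: Margin):
    """Kernel log-likelihood on the null boundary psi = 0.

    ``a = pi_P`` and ``b = pi_R``; the test-arm rate is the induced
    ``pi_T = theta*b + (1-theta)*a``.  Accepts scalars or arrays.
    """
    th = margin.theta
    pt = th * b + (1.0 - th) * a
    return (
        _binom_loglik(counts.x_T, counts.n_T, pt, True)
        + _binom_loglik(counts.x_R, counts.n_R, b, True)
        + _binom_loglik(counts.x_P, counts.n_P, a, True)
    )


def _constrained_optimum(counts: TrialCounts, margin: Margin) -> tuple[float, float]:
    """Maximise the psi = 0 constrained kernel over {0 <= pi_P <= pi_R <= 1}.

    The objective is concave in (pi_P, pi_R) (each term is a concave log of an
    affine map), so a bounded quasi-Newton search from a handful of
    deterministic starts is reliable; a coarse-grid refinement backs it up
    when the smooth search stalls near a boundary.
    """
    hat = mle(counts)

    # Reparametrise pi_P = a, pi_R = a + q*(1 - a), (a, q) in the unit square,
    # which maps the triangle {a <= b} onto a box for L-BFGS-B.
    def neg(z):
        a = min(max(z[0], 0.0), 1.0)
        q = min(max(z[1], 0.0), 1.0)
        b = a + q * (1.0 - a)
        val = float(constrained_loglik(a, b, counts, margin))
        # large finite penalty instead of inf keeps finite-difference
        # gradients well defined at the box boundary
        return -val if np.isfinite(val) else 1e30

    def from_ab(a, b):
        a = min(max(a, 0.0), 1.0)
        b = min(max(b, a), 1.0)
        q = 0.0 if a >= 1.0 else (b - a) / (1.0 - a)
        return (a, q)

    starts = [
        from_ab(hat.pi_P, max(hat.pi_R, hat.pi_P)),  # projected MLE
        (0.5, 0.5),                                  # centroid
        (0.05, 0.05),
        (0.05, 0.9),
        (0.9, 0.5),
    ]
    bounds = [(_EPS, 1.0 - _EPS), (_EPS, 1.0 - _EPS)]
    candidates: list[tuple[float, float]] = []
    for z0 in starts:
        z0 = (min(max(z0[0], 1e-6), 1 - 1e-6), min(max(z0[1], 1e-6), 1 - 1e-6))
        try:
            res = optimize.minimize(neg, z0, method="L-BFGS-B", bounds=bounds)
            candidates.append((float(res.x[0]), float(res.x[1])))
        except Exception:  # pragma: no cover - optimizer hiccup
            continue
    # Newton solution of the same problem (handles diagonal/edge optima exactly)
    _, nR_, nP_ = rmle_batch(
        counts.x_T, counts.x_R, counts.x_P, counts.n_T, counts.n_R, counts.n_P,
        margin.theta, force_null=True,
    )
    candidates.append(from_ab(float(nP_[0]), float(nR_[0])))
    # coarse-grid fallback: insurance against every smooth search stalling
    aa, qq = np.meshgrid(np.linspace(1e-9, 1 - 1e-9, 201), np.linspace(0, 1, 201))
    bb = aa + qq * (1.0 - aa)
    vals = constrained_loglik(aa, bb, counts, margin)
    k = int(np.argmax(vals))
    candidates.append((float(aa.ravel()[k]), float(qq.ravel()[k])))

    best_z = min(candidates, key=neg)
    res = optimize.minimize(
        neg, best_z, method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 2000},
    )
    z = np.clip(res.x, 0.0, 1.0)
    if neg(tuple(z)) < neg(best_z):
        best_z = (float(z[0]), float(z[1]))
    a, q = best_z
    return float(a), float(a + q * (1.0 - a))


def rmle(counts: TrialCounts, margin: Margin, *, force_null: bool = False) -> RateTriple:
    """Restricted MLE under H0: psi <= 0.

    When the unrestricted MLE already satisfies the null (``psi(MLE) <= 0``)
    it is itself the restricted maximiser and is returned unchanged.
    Otherwise the likelihood is maximised on the null boundary
    ``pi_T = theta*pi_R + (1-theta)*pi_P`` over the closure
    ``{0 <= pi_P <= pi_R <= 1}`` of the nuisance space.

    ``force_null=True`` always takes the boundary branch; this is the
    ``psi = 0`` calibration point used by the unconditional, bootstrap and
    saddlepoint p-value engines.
    """
    hat = mle(counts)
    if not force_null and psi_of(hat, margin) <= 0.0:
        return hat
    a, b = _constrained_optimum(counts, margin)
    th = margin.theta
    return RateTriple(th * b + (1.0 - th) * a, b, a)


# ---------------------------------------------------------------------------
# Vectorised restricted estimation over many outcomes.
#
# Exact enumeration of operating characteristics needs the RMLE at every point
# of the outcome lattice (hundreds of thousands of outcomes), which rules out
# per-point calls into scipy.optimize.  The constrained kernel is concave in
# (pi_P, pi_R), so a damped, projected Newton iteration run simultaneously on
# all outcomes converges in a few dozen steps.
# ---------------------------------------------------------------------------


def _batch_obj(a, b, xT, nT, xR, nR, xP, nP, theta):
    pt = theta * b + (1.0 - theta) * a
    return (
        xlogy(xT, pt)
        + xlog1py(nT - xT, -pt)
        + xlogy(xR, b)
        + xlog1py(nR - xR, -b)
        + xlogy(xP, a)
        + xlog1py(nP - xP, -a)
    )


def rmle_batch(xT, xR, xP, nT, nR, nP, theta: float, *, force_null: bool = False,
               tol: float = 1e-10, max_iter: int = 120):
    """Restricted MLEs for arrays of outcomes sharing a common margin.

    Parameters are broadcast against each other; returns arrays
    ``(pi_T, pi_R, pi_P)`` of the restricted estimates.  Outcomes whose
    unrestricted MLE already satisfies the null keep it (unless
    ``force_null``), the rest are solved on the ``psi = 0`` boundary by a
    damped projected Newton iteration on the concave constrained kernel.
    """
    xT, xR, xP, nT, nR, nP = np.broadcast_arrays(
        *(np.atleast_1d(np.asarray(v, dtype=float)) for v in (xT, xR, xP, nT, nR, nP))
    )
    shape = xT.shape
    pT_hat, pR_hat, pP_hat = xT / nT, xR / nR, xP / nP
    psi_hat = pT_hat - theta * pR_hat - (1.0 - theta) * pP_hat

    out_T = pT_hat.copy()
    out_R = pR_hat.copy()
    out_P = pP_hat.copy()

    # tolerance guards against float noise in psi_hat at exact-boundary outcomes
    need = np.ones(shape, dtype=bool) if force_null else (psi_hat > 1e-12)
    if not need.any():
        return out_T, out_R, out_P

    sel = lambda v: v[need]
    cxT, cxR, cxP = sel(xT), sel(xR), sel(xP)
    cnT, cnR, cnP = sel(nT), sel(nR), sel(nP)

    lo, hi = 1e-9, 1.0 - 1e-9
    a = np.clip(sel(pP_hat), 0.02, 0.98)
    b = np.clip(np.maximum(sel(pR_hat), a), 0.02, 0.98)

    def project(a, b):
        a = np.clip(a, lo, hi)
        b = np.clip(b, lo, hi)
        swap = a > b
        if swap.any():
            mid = 0.5 * (a[swap] + b[swap])
            a[swap] = mid
            b[swap] = mid
        return a, b

    def obj(a, b):
        return _batch_obj(a, b, cxT, cnT, cxR, cnR, cxP, cnP, theta)

    th1 = 1.0 - theta
    # active-set Newton: converged points drop out of the iteration
    active = np.arange(a.shape[0])
    fin_a, fin_b = a.copy(), b.copy()
    f = obj(a, b)
    for iteration in range(max_iter):
        pt = theta * b + th1 * a
        # first derivatives of the binomial kernels
        dT = cxT / pt - (cnT - cxT) / (1.0 - pt)
        dR = cxR / b - (cnR - cxR) / (1.0 - b)
        dP = cxP / a - (cnP - cxP) / (1.0 - a)
        ga = th1 * dT + dP
        gb = theta * dT + dR
        # second derivatives (all negative: concavity)
        hT = -cxT / pt**2 - (cnT - cxT) / (1.0 - pt) ** 2
        hR = -cxR / b**2 - (cnR - cxR) / (1.0 - b) ** 2
        hP = -cxP / a**2 - (cnP - cxP) / (1.0 - a) ** 2
        Haa = th1**2 * hT + hP
        Hbb = theta**2 * hT + hR
        Hab = theta * th1 * hT
        det = Haa * Hbb - Hab**2
        ok = det > 1e-300
        # Newton step -H^{-1} g (falls back to a scaled gradient step)
        sa = np.where(ok, -(Hbb * ga - Hab * gb) / np.where(ok, det, 1.0), ga * 1e-3)
        sb = np.where(ok, -(Haa * gb - Hab * ga) / np.where(ok, det, 1.0), gb * 1e-3)
        step = 1.0
        improved = np.zeros(a.shape, dtype=bool)
        a_new, b_new, f_new = a, b, f
        for _halving in range(40):
            ta, tb = project(a + step * sa, b + step * sb)
            tf = obj(ta, tb)
            better = tf > f_new
            if better.any():
                a_new = np.where(better, ta, a_new)
                b_new = np.where(better, tb, b_new)
                f_new = np.where(better, tf, f_new)
                improved |= better
            if improved.all():
                break
            step *= 0.5
        moved = np.hypot(a_new - a, b_new - b)
        a, b, f = a_new, b_new, f_new
        fin_a[active] = a
        fin_b[active] = b
        if iteration > 2:
            done = moved < tol
            if done.all():
                break
            if done.any():
                keep = ~done
                active = active[keep]
                a, b, f = a[keep], b[keep], f[keep]
                cxT, cxR, cxP = cxT[keep], cxR[keep], cxP[keep]
                cnT, cnR, cnP = cnT[keep], cnR[keep], cnP[keep]

    # --- boundary candidates ---------------------------------------------
    # The projected Newton iteration can stall when the maximiser sits on the
    # diagonal pi_P = pi_R or on an edge of the triangle, so compare against
    # the exact solutions of those lower-dimensional problems.
    cxT, cxR, cxP = sel(xT), sel(xR), sel(xP)
    cnT, cnR, cnP = sel(nT), sel(nR), sel(nP)
    f_fin = obj_at(fin_a, fin_b, cxT, cxR, cxP, cnT, cnR, cnP, theta)

    # diagonal pi_P = pi_R = pi_T: pooled proportion, closed form
    diag = np.clip((cxT + cxR + cxP) / (cnT + cnR + cnP), lo, hi)
    f_diag = obj_at(diag, diag, cxT, cxR, cxP, cnT, cnR, cnP, theta)
    take = f_diag > f_fin
    fin_a = np.where(take, diag, fin_a)
    fin_b = np.where(take, diag, fin_b)
    f_fin = np.where(take, f_diag, f_fin)

    # edge pi_P = 0 (only attainable when x_P = 0): 1-D concave in pi_R
    edge0 = cxP == 0
    if edge0.any():
        def dgb(b, m):
            pt = theta * b
            dT = cxT[m] / pt - (cnT[m] - cxT[m]) / (1.0 - pt)
            dR = cxR[m] / b - (cnR[m] - cxR[m]) / (1.0 - b)
            return theta * dT + dR

        b_e = _bisect_concave(dgb, edge0, lo, hi)
        a_e = np.full(b_e.shape, lo)
        f_e = obj_at(a_e, b_e, cxT[edge0], cxR[edge0], cxP[edge0],
                     cnT[edge0], cnR[edge0], cnP[edge0], theta)
        better = f_e > f_fin[edge0]
        idx = np.flatnonzero(edge0)[better]
        fin_a[idx] = a_e[better]
        fin_b[idx] = b_e[better]
        f_fin[idx] = f_e[better]

    # edge pi_R = 1 (only attainable when x_R = n_R): 1-D concave in pi_P
    edge1 = cxR == cnR
    if edge1.any():
        def dga(av, m):
            pt = theta + th1 * av
            dT = cxT[m] / pt - (cnT[m] - cxT[m]) / (1.0 - pt)
            dP = cxP[m] / av - (cnP[m] - cxP[m]) / (1.0 - av)
            return th1 * dT + dP

        a_e = _bisect_concave(dga, edge1, lo, hi)
        b_e = np.full(a_e.shape, hi)
        f_e = obj_at(a_e, b_e, cxT[edge1], cxR[edge1], cxP[edge1],
                     cnT[edge1], cnR[edge1], cnP[edge1], theta)
        better = f_e > f_fin[edge1]
        idx = np.flatnonzero(edge1)[better]
        fin_a[idx] = a_e[better]
        fin_b[idx] = b_e[better]
        f_fin[idx] = f_e[better]

    out_P[need] = fin_a
    out_R[need] = fin_b
    out_T[need] = theta * fin_b + th1 * fin_a
    return out_T, out_R, out_P


def obj_at(a, b, xT, xR, xP, nT, nR, nP, theta):
    return _batch_obj(a, b, xT, nT, xR, nR, xP, nP, theta)


def _bisect_concave(deriv, mask, lo, hi, iters: int = 80):
    """Vectorised bisection for the root of a decreasing derivative on [lo, hi]."""
    m = mask
    left = np.full(int(mask.sum()), lo)
    right = np.full(left.shape, hi)
    g_lo = deriv(left, m)
    g_hi = deriv(right, m)
    # optimum pinned to an endpoint when the derivative does not change sign
    at_lo = g_lo <= 0.0
    at_hi = g_hi >= 0.0
    for _ in range(iters):
        mid = 0.5 * (left + right)
        g = deriv(mid, m)
        go_right = g > 0.0
        left = np.where(go_right, mid, left)
        right = np.where(go_right, right, mid)
    root = 0.5 * (left + right)
    root[at_lo] = lo
    root[at_hi] = hi
    return root
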