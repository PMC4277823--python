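"""Five p-value engines for the retention-fraction non-inferiority test.

Given observed counts, a retention fraction theta and a statistic kind, each
engine returns P(T >= t_obs) under the null, calibrated in a different way:

* AM  — asymptotic normal tail 1 - Phi(t_obs).
* SAM — saddlepoint (Lugannani-Rice-type) approximation to the lattice tail
        of the estimated contrast, built from the cumulant generating
        function of psi_hat at the null restricted MLE.
* EUM — exact unconditional: supremum of the enumerated tail probability
        over the whole null nuisance space (psi <= 0).
* AUM — approximate unconditional: the enumerated tail evaluated at the
        psi = 0 restricted MLE only.
* BTM — parametric bootstrap: Monte-Carlo estimate of the AUM tail.

The enumeration engines share one cached statistic lattice per
(sizes, theta, kind), so repeated calls at different nuisance points cost a
single weighted sum each.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import optimize, stats

from .model import Margin, RateTriple, TrialCounts, rmle, rmle_batch
from .statistics import StatisticKind, statistic, statistic_batch, statistic_lattice

__all__ = [
    "PValue",
    "CGF",
    "BootstrapConfig",
    "LatticeTooLarge",
    "cgf_eval",
    "saddlepoint_root",
    "p_asymptotic",
    "p_saddlepoint",
    "tail_probability",
    "batch_tail_probability",
    "p_exact_unconditional",
    "p_approx_unconditional",
    "p_bootstrap",
]

logger = logging.getLogger(__name__)

#: outcomes whose statistic is within this of the threshold count as ties
#: (the lattice and the scalar path may differ in the last float digits)
TIE_TOL = 1e-9

#: default cap on (n_T+1)(n_R+1)(n_P+1) for full enumeration
DEFAULT_LATTICE_CAP = 10**7


class LatticeTooLarge(ValueError):
    """Outcome lattice exceeds the enumeration cap; use the bootstrap engine."""


@dataclass(frozen=True)
class PValue:
    value: float
    method: str
    kind: StatisticKind
    meta: dict[str, Any] = field(default_factory=dict)


@dataclass(frozen=True)
class BootstrapConfig:
    """Replicate count and seed for the parametric bootstrap."""

    B: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")


# ---------------------------------------------------------------------------
# Cumulant generating function of psi_hat = X_T/n_T - th*X_R/n_R - (1-th)*X_P/n_P
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CGF:
    """CGF of the estimated contrast at a fixed parameter point.

    K(t) = sum_k n_k * log(1 - pi_k + pi_k * exp(c_k t)) with lattice
    coefficients c = (1/n_T, -theta/n_R, -(1-theta)/n_P).  K(0) = 0,
    K'(0) = psi(rates) and K''(0) = Var(psi_hat), and K is strictly convex
    whenever some arm is nondegenerate.
    """

    margin: Margin
    sizes: tuple[int, int, int]
    rates: RateTriple

    @property
    def coefficients(self) -> tuple[float, float, float]:
        nT, nR, nP = self.sizes
        th = self.margin.theta
        return (1.0 / nT, -th / nR, -(1.0 - th) / nP)

    def _arms(self):
        c = self.coefficients
        p = (self.rates.pi_T, self.rates.pi_R, self.rates.pi_P)
        return zip(self.sizes, c, p)

    def eval(self, t: float) -> tuple[float, float, float]:
        """Return (K(t), K'(t), K''(t)); overflow-guarded for large |t|."""
        K = dK = d2K = 0.0
        for n, c, p in self._arms():
            u = c * t
            if p <= 0.0:
                continue  # arm contributes the constant 0
            if p >= 1.0:
                K += n * u
                dK += n * c
                continue
            # log(1 - p + p e^u) in log-sum-exp form
            K += n * np.logaddexp(np.log1p(-p), np.log(p) + u)
            # q = p e^u / (1 - p + p e^u), computed stably via a logistic form
            q = 1.0 / (1.0 + np.exp(np.log1p(-p) - np.log(p) - u))
            dK += n * c * q
            d2K += n * c * c * q * (1.0 - q)
        return float(K), float(dK), float(d2K)

    def third_cumulant_at_zero(self) -> float:
        """K'''(0) = sum n_k c_k^3 pi_k (1-pi_k)(1-2 pi_k)."""
        out = 0.0
        for n, c, p in self._arms():
            out += n * c**3 * p * (1.0 - p) * (1.0 - 2.0 * p)
        return out

    def mean_range(self) -> tuple[float, float]:
        """The open range of K' (attainable interior values of psi_hat)."""
        lo = hi = 0.0
        for n, c, p in self._arms():
            if 0.0 < p < 1.0:
                lo += min(n * c, 0.0)
                hi += max(n * c, 0.0)
            else:
                lo += n * c * p
                hi += n * c * p
        return lo, hi


def cgf_eval(cgf: CGF, t: float) -> tuple[float, float, float]:
    """Convenience wrapper: (K(t), K'(t), K''(t))."""
    return cgf.eval(t)


def saddlepoint_root(cgf: CGF, s: float, *, tol: float = 1e-12) -> float:
    """Solve the saddlepoint equation K'(t) = s.

    K' is strictly increasing, so the root is unique.  ``s`` must lie
    strictly inside the attainable range of psi_hat; the bracket expands
    geometrically (the binomial CGF is entire, so no hard cap on |t|).
    """
    lo, hi = cgf.mean_range()
    if not lo < s < hi:
        raise ValueError(f"threshold {s} outside the open attainable range ({lo}, {hi})")

    def g(t: float) -> float:
        return cgf.eval(t)[1] - s

    width = 1.0
    for _ in range(200):
        if g(-width) < 0.0 < g(width):
            break
        width *= 2.0
        if width > 1e12:
            raise ValueError(f"threshold {s} too close to the attainable extreme")
    root = optimize.brentq(g, -width, width, xtol=1e-14, maxiter=300)
    # Newton polish to drive |K'(t) - s| below tol
    for _ in range(8):
        _, d1, d2 = cgf.eval(root)
        if abs(d1 - s) <= tol or d2 <= 0.0:
            break
        root -= (d1 - s) / d2
    if abs(root) > 1.0:
        logger.info("saddlepoint root |t|=%.3g exceeds 1", abs(root))
    return float(root)


# ---------------------------------------------------------------------------
# (1) asymptotic
# ---------------------------------------------------------------------------


def p_asymptotic(counts: TrialCounts, margin: Margin, kind: StatisticKind) -> PValue:
    """Normal-tail p-value 1 - Phi(t_obs)."""
    t_obs = statistic(counts, margin, kind).value
    return PValue(float(stats.norm.sf(t_obs)), "AM", kind, {"t_obs": t_obs})


# ---------------------------------------------------------------------------
# (2) saddlepoint
# ---------------------------------------------------------------------------


def _lr_tail(cgf: CGF, s: float) -> tuple[float, dict[str, Any]]:
    """Lugannani-Rice-type tail P(psi_hat >= s) at the CGF's parameter point."""
    t_hat = saddlepoint_root(cgf, s)
    K, dK, d2K = cgf.eval(t_hat)
    r2 = 2.0 * max(t_hat * s - K, 0.0)
    r_hat = float(np.sign(t_hat)) * np.sqrt(r2)
    lam = t_hat * np.sqrt(d2K)
    meta: dict[str, Any] = {"t_hat": t_hat, "r_hat": r_hat, "lambda_hat": lam, "s": s}
    if abs(r_hat) < 1e-5:
        # removable singularity at the mean: analytic limit with the
        # third-cumulant (skewness) series term
        _, _, var0 = cgf.eval(0.0)
        k3 = cgf.third_cumulant_at_zero()
        p = 0.5 - k3 / (6.0 * np.sqrt(2.0 * np.pi) * var0**1.5)
        meta["limit_branch"] = True
    else:
        p = stats.norm.sf(r_hat) - stats.norm.pdf(r_hat) * (1.0 / r_hat - 1.0 / lam)
    return float(np.clip(p, 0.0, 1.0)), meta


def _lrt_profile_threshold(counts: TrialCounts, margin: Margin, t_obs: float,
                           null_rates: RateTriple) -> float:
    """Map an observed signed-root LRT value to a threshold on the psi_hat scale.

    Walks fractional pseudo-data x_k(u) = n_k * pi_k(u) along the test-arm
    direction from the null point (where psi_hat = u and the statistic is 0)
    and solves for the u whose signed-root statistic equals ``t_obs``.  The
    inversion uses the signed root of the deviance against the psi = 0
    constrained fit, which extends the LRT statistic strictly monotonically
    through the null side, so the root is unique.
    """
    from .statistics import signed_null_deviance_batch

    nT, nR, nP = counts.sizes
    th = margin.theta

    def stat_at(u: float) -> float:
        pT = float(np.clip(null_rates.pi_T + u, 0.0, 1.0))
        val = signed_null_deviance_batch(
            np.array([pT * nT]), np.array([null_rates.pi_R * nR]),
            np.array([null_rates.pi_P * nP]), counts.sizes, margin,
        )[0]
        return float(val)

    lo, hi = -null_rates.pi_T, 1.0 - null_rates.pi_T
    f_lo, f_hi = stat_at(lo + 1e-9) - t_obs, stat_at(hi - 1e-9) - t_obs
    if f_lo > 0.0 or f_hi < 0.0:
        raise ValueError("observed LRT value outside the attainable profile range")
    u = optimize.brentq(lambda u: stat_at(u) - t_obs, lo + 1e-9, hi - 1e-9, xtol=1e-12)
    return u + (null_rates.pi_T - th * null_rates.pi_R - (1.0 - th) * null_rates.pi_P)


def p_saddlepoint(counts: TrialCounts, margin: Margin, kind: StatisticKind) -> PValue:
    """Saddlepoint tail approximation calibrated at the psi = 0 restricted MLE.

    The tail event is mapped onto the psi_hat scale: for the Wald and score
    statistics the threshold is the observed psi_hat itself (both standardise
    the same contrast), for the signed-root LRT the threshold is recovered by
    inverting the statistic along a 1-D profile.  Falls back to the normal
    tail when the threshold leaves the attainable range.
    """
    t_obs = statistic(counts, margin, kind).value
    tilde = rmle(counts, margin, force_null=True)
    cgf = CGF(margin, counts.sizes, tilde)
    th = margin.theta
    try:
        if kind is StatisticKind.LRT:
            s = _lrt_profile_threshold(counts, margin, t_obs, tilde)
        else:
            hat_psi = (
                counts.x_T / counts.n_T
                - th * counts.x_R / counts.n_R
                - (1.0 - th) * counts.x_P / counts.n_P
            )
            s = hat_psi
        p, meta = _lr_tail(cgf, s)
    except ValueError as err:
        logger.warning("saddlepoint fallback to asymptotic tail: %s", err)
        fallback = p_asymptotic(counts, margin, kind)
        return PValue(fallback.value, "SAM", kind, {"fallback": "AM", "reason": str(err)})
    meta["null_rates"] = (tilde.pi_T, tilde.pi_R, tilde.pi_P)
    meta["t_obs"] = t_obs
    return PValue(p, "SAM", kind, meta)


def sam_tail_batch(sizes, margin: Margin, piT, piR, piP, s) -> np.ndarray:
    """Vectorised Lugannani-Rice tails P(psi_hat >= s_j) at per-row rate triples.

    Rows whose threshold falls outside the open attainable range of psi_hat
    (or whose CGF degenerates) come back NaN; the caller decides the
    fallback.  Used to evaluate saddlepoint p-values over whole outcome
    lattices, where scalar root-finding per outcome would dominate runtime.
    """
    nT, nR, nP = sizes
    th = margin.theta
    piT, piR, piP, s = np.broadcast_arrays(
        *(np.atleast_1d(np.asarray(v, dtype=float)) for v in (piT, piR, piP, s))
    )
    ns = np.array([nT, nR, nP], dtype=float)
    cs = np.array([1.0 / nT, -th / nR, -(1.0 - th) / nP])
    P = np.stack([piT, piR, piP])  # (3, J)
    # rates this close to {0, 1} come from boundary-clipped optimizers; treat
    # them as exactly degenerate so the attainable-range check is honest
    P = np.where(P < 1e-8, 0.0, np.where(P > 1.0 - 1e-8, 1.0, P))

    # open attainable range of psi_hat given degenerate components
    interior = (P > 0.0) & (P < 1.0)
    contrib = np.where(interior, 0.0, ns[:, None] * cs[:, None] * P)
    lo = (np.where(interior, np.minimum(ns[:, None] * cs[:, None], 0.0), contrib)).sum(axis=0)
    hi = (np.where(interior, np.maximum(ns[:, None] * cs[:, None], 0.0), contrib)).sum(axis=0)
    ok = (s > lo + 1e-12) & (s < hi - 1e-12) & interior.any(axis=0)

    logp = np.log(np.clip(P, 1e-300, 1.0))
    log1mp = np.log1p(-np.clip(P, 0.0, 1.0 - 1e-16))

    def K_parts(t):
        u = cs[:, None] * t[None, :]
        # per-arm log MGF of c_k X_k, with degenerate arms linear in t
        with np.errstate(over="ignore"):
            lse = np.logaddexp(log1mp, logp + u)
        lse = np.where(P <= 0.0, 0.0, np.where(P >= 1.0, u, lse))
        K = (ns[:, None] * lse).sum(axis=0)
        q = 1.0 / (1.0 + np.exp(log1mp - logp - u))
        q = np.where(P <= 0.0, 0.0, np.where(P >= 1.0, 1.0, q))
        d1 = (ns[:, None] * cs[:, None] * q).sum(axis=0)
        d2 = (ns[:, None] * cs[:, None] ** 2 * q * (1.0 - q)).sum(axis=0)
        return K, d1, d2

    # safeguarded Newton on K'(t) = s with an expanding bisection bracket
    t = np.zeros(s.shape)
    t_lo = np.full(s.shape, -1.0)
    t_hi = np.full(s.shape, 1.0)
    for _ in range(90):
        _, d1_lo, _ = K_parts(t_lo)
        grow = ok & (d1_lo >= s)
        if not grow.any():
            break
        t_lo[grow] *= 2.0
    for _ in range(90):
        _, d1_hi, _ = K_parts(t_hi)
        grow = ok & (d1_hi <= s)
        if not grow.any():
            break
        t_hi[grow] *= 2.0
    for _ in range(100):
        _, d1, d2 = K_parts(t)
        diff = d1 - s
        below = diff < 0.0
        t_lo = np.where(ok & below, np.maximum(t_lo, t), t_lo)
        t_hi = np.where(ok & ~below, np.minimum(t_hi, t), t_hi)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_new = t - diff / d2
        bad = ~np.isfinite(t_new) | (t_new <= t_lo) | (t_new >= t_hi)
        t_new = np.where(bad, 0.5 * (t_lo + t_hi), t_new)
        if np.max(np.abs(np.where(ok, diff, 0.0))) < 1e-13:
            break
        t = t_new

    K, d1, d2 = K_parts(t)
    r2 = 2.0 * np.maximum(t * s - K, 0.0)
    r = np.sign(t) * np.sqrt(r2)
    lam = t * np.sqrt(d2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.norm.sf(r) - stats.norm.pdf(r) * (1.0 / r - 1.0 / lam)
    # removable singularity at the mean: skewness-corrected limit
    near0 = ok & (np.abs(r) < 1e-5)
    if near0.any():
        _, _, var0 = K_parts(np.zeros(s.shape))
        k3 = (ns[:, None] * cs[:, None] ** 3 * P * (1.0 - P) * (1.0 - 2.0 * P)).sum(axis=0)
        safe = np.maximum(var0, 1e-300)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(near0 & (var0 > 0.0),
                         0.5 - k3 / (6.0 * np.sqrt(2.0 * np.pi) * safe**1.5), p)
        ok = ok & ~(near0 & (var0 <= 0.0))
    p = np.clip(p, 0.0, 1.0)
    return np.where(ok, p, np.nan)


# ---------------------------------------------------------------------------
# enumeration machinery shared by EUM / AUM
# ---------------------------------------------------------------------------


def _check_cap(sizes: tuple[int, int, int], cap: int) -> None:
    n_outcomes = (sizes[0] + 1) * (sizes[1] + 1) * (sizes[2] + 1)
    if n_outcomes > cap:
        raise LatticeTooLarge(
            f"lattice of {n_outcomes} outcomes exceeds the cap {cap}; "
            "use the bootstrap engine instead"
        )


def _pmf_vectors(sizes, rates):
    nT, nR, nP = sizes
    pT = stats.binom.pmf(np.arange(nT + 1), nT, rates[0])
    pR = stats.binom.pmf(np.arange(nR + 1), nR, rates[1])
    pP = stats.binom.pmf(np.arange(nP + 1), nP, rates[2])
    return pT, pR, pP


def tail_probability(kind: StatisticKind, margin: Margin, sizes: tuple[int, int, int],
                     rates: RateTriple, threshold: float, *,
                     cap: int = DEFAULT_LATTICE_CAP) -> float:
    """Exact P(T_kind >= threshold) at the given rates, by full enumeration.

    Sums the product-binomial pmf over every outcome of the lattice whose
    statistic is >= threshold (ties closed, with a small float tolerance).
    The statistic lattice is cached per (sizes, theta, kind).
    """
    _check_cap(sizes, cap)
    if threshold == -np.inf:
        return 1.0
    T = statistic_lattice(sizes, margin, kind)
    mask = T >= threshold - TIE_TOL
    pT, pR, pP = _pmf_vectors(sizes, (rates.pi_T, rates.pi_R, rates.pi_P))
    return float(np.einsum("trp,t,r,p->", mask, pT, pR, pP, optimize=True))


def batch_tail_probability(mask: np.ndarray, sizes, piT, piR, piP,
                           chunk: int = 4096) -> np.ndarray:
    """Tail probability of a fixed outcome set under many parameter points.

    ``mask`` is the (n_T+1, n_R+1, n_P+1) indicator of the tail event;
    ``piT, piR, piP`` are equal-length arrays of rate triples.  Evaluated
    with chunked matrix products so a 100k-point nuisance grid stays cheap.
    """
    nT, nR, nP = sizes
    piT = np.atleast_1d(np.asarray(piT, dtype=float))
    piR = np.atleast_1d(np.asarray(piR, dtype=float))
    piP = np.atleast_1d(np.asarray(piP, dtype=float))
    M = mask.astype(float).reshape((nT + 1) * (nR + 1), nP + 1)
    out = np.empty(piT.shape[0])
    kT, kR, kP = np.arange(nT + 1), np.arange(nR + 1), np.arange(nP + 1)
    for start in range(0, piT.shape[0], chunk):
        sl = slice(start, min(start + chunk, piT.shape[0]))
        PT = stats.binom.pmf(kT[None, :], nT, piT[sl, None])
        PR = stats.binom.pmf(kR[None, :], nR, piR[sl, None])
        PP = stats.binom.pmf(kP[None, :], nP, piP[sl, None])
        A = (M @ PP.T).reshape(nT + 1, nR + 1, -1)
        B = np.einsum("trj,jr->tj", A, PR)
        out[sl] = np.einsum("tj,jt->j", B, PT)
    return out


def null_nuisance_grid(margin: Margin, *, n_grid: int = 101, psi_step: float = 0.05,
                       psi_min: float = -0.95):
    """Grid over the closure of the null nuisance space.

    Points (pi_P, pi_R, psi) with 0 <= pi_P <= pi_R <= 1, psi <= 0 and the
    induced pi_T = psi + theta*pi_R + (1-theta)*pi_P inside [0, 1].  The
    psi grid is coarse: empirically the supremum of the tail sits on the
    psi = 0 face, which gets the full (pi_P, pi_R) resolution.
    """
    th = margin.theta
    psis = np.arange(0.0, psi_min - 1e-9, -psi_step)
    a_axis = np.linspace(0.0, 1.0, n_grid)
    b_axis = np.linspace(0.0, 1.0, n_grid)
    aa, bb = np.meshgrid(a_axis, b_axis, indexing="ij")
    tri = aa <= bb
    blocks = []
    for psi in psis:
        pT = psi + th * bb + (1.0 - th) * aa
        feas = tri & (pT >= 0.0) & (pT <= 1.0)
        blocks.append(
            np.column_stack([
                pT[feas], bb[feas], aa[feas], np.full(int(feas.sum()), psi),
            ])
        )
    return np.vstack(blocks)


def p_exact_unconditional(counts: TrialCounts, margin: Margin, kind: StatisticKind, *,
                          n_grid: int = 101, psi_step: float = 0.05,
                          refine: bool = True, cap: int = DEFAULT_LATTICE_CAP) -> PValue:
    """Exact unconditional p-value: sup over the null nuisance space.

    The tail probability of the observed statistic is maximised over a grid
    on the closure of the null space (psi <= 0), then polished by a local
    derivative-free search around the best grid point.
    """
    _check_cap(counts.sizes, cap)
    T = statistic_lattice(counts.sizes, margin, kind)
    t_obs = float(T[counts.x_T, counts.x_R, counts.x_P])
    mask = T >= t_obs - TIE_TOL

    pts = null_nuisance_grid(margin, n_grid=n_grid, psi_step=psi_step)
    tails = batch_tail_probability(mask, counts.sizes, pts[:, 0], pts[:, 1], pts[:, 2])
    best = int(np.argmax(tails))
    p_grid = float(tails[best])
    argmax = pts[best]
    th = margin.theta

    if refine:
        def neg(z):
            a, b, psi = z
            a = float(np.clip(a, 0.0, 1.0))
            b = float(np.clip(b, a, 1.0))
            psi = float(np.clip(psi, -1.0, 0.0))
            pT = psi + th * b + (1.0 - th) * a
            if not 0.0 <= pT <= 1.0:
                return 0.0
            return -batch_tail_probability(mask, counts.sizes, [pT], [b], [a])[0]

        res = optimize.minimize(
            neg, np.array([argmax[2], argmax[1], argmax[3]]),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 400},
        )
        if -res.fun > p_grid:
            p_grid = float(-res.fun)
            a, b, psi = res.x
            a = float(np.clip(a, 0.0, 1.0))
            b = float(np.clip(b, a, 1.0))
            psi = float(np.clip(psi, -1.0, 0.0))
            argmax = np.array([psi + th * b + (1.0 - th) * a, b, a, psi])

    if argmax[3] < -psi_step / 2:  # diagnostic: sup away from the psi = 0 face
        logger.info("EUM supremum attained at psi=%.4f (off the boundary face)", argmax[3])
    meta = {
        "t_obs": t_obs,
        "argmax": {"pi_T": argmax[0], "pi_R": argmax[1], "pi_P": argmax[2], "psi": argmax[3]},
        "n_grid": n_grid,
        "psi_step": psi_step,
        "refined": refine,
    }
    return PValue(float(np.clip(p_grid, 0.0, 1.0)), "EUM", kind, meta)


def p_approx_unconditional(counts: TrialCounts, margin: Margin, kind: StatisticKind, *,
                           cap: int = DEFAULT_LATTICE_CAP) -> PValue:
    """Approximate unconditional p-value: the tail at the psi = 0 restricted MLE."""
    _check_cap(counts.sizes, cap)
    tilde = rmle(counts, margin, force_null=True)
    T = statistic_lattice(counts.sizes, margin, kind)
    t_obs = float(T[counts.x_T, counts.x_R, counts.x_P])
    p = tail_probability(kind, margin, counts.sizes, tilde, t_obs, cap=cap)
    meta = {"t_obs": t_obs, "null_rates": (tilde.pi_T, tilde.pi_R, tilde.pi_P)}
    return PValue(p, "AUM", kind, meta)


def p_bootstrap(counts: TrialCounts, margin: Margin, kind: StatisticKind,
                cfg: BootstrapConfig) -> PValue:
    """Parametric-bootstrap p-value.

    Draws B trials from independent binomials at the psi = 0 restricted MLE,
    recomputes the statistic for each, and reports the fraction at or above
    the observed value.  Fully determined by ``cfg.seed``.
    """
    tilde = rmle(counts, margin, force_null=True)
    T_obs = statistic_batch(
        np.array([counts.x_T]), np.array([counts.x_R]), np.array([counts.x_P]),
        counts.sizes, margin, kind,
    )[0]
    rng = np.random.default_rng(cfg.seed)
    nT, nR, nP = counts.sizes
    xT = rng.binomial(nT, tilde.pi_T, size=cfg.B)
    xR = rng.binomial(nR, tilde.pi_R, size=cfg.B)
    xP = rng.binomial(nP, tilde.pi_P, size=cfg.B)
    T_star = statistic_batch(xT, xR, xP, counts.sizes, margin, kind)
    p = float(np.mean(T_star >= T_obs - TIE_TOL))
    meta = {
        "B": cfg.B, "seed": cfg.seed, "t_obs": float(T_obs),
        "null_rates": (tilde.pi_T, tilde.pi_R, tilde.pi_P),
    }
    return PValue(p, "BTM", kind, meta)
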