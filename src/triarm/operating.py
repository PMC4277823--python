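"""Exact operating characteristics (type-I error and power) by enumeration.

For a design with per-arm sizes (n_T, n_R, n_P), true rates pi and a test
procedure (statistic kind x p-value method x level alpha), the exact
rejection rate is

    sum over all outcomes x of I(p(x) <= alpha) * prod_k Bin(x_k; n_k, pi_k).

The per-outcome p-values depend only on (sizes, theta, method, kind) — not
on the true rates — so one cached p-value lattice serves every rate
configuration of a design grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import Margin, RateTriple, TrialCounts, psi_of, rmle_batch
from .pvalues import (
    DEFAULT_LATTICE_CAP,
    BootstrapConfig,
    LatticeTooLarge,
    _pmf_vectors,
    batch_tail_probability,
    null_nuisance_grid,
    p_saddlepoint,
)
from .statistics import StatisticKind, statistic_batch, statistic_lattice

__all__ = [
    "DesignConfig",
    "OperatingPoint",
    "pvalue_lattice",
    "exact_rejection_rate",
    "mc_rejection_rate",
    "design_grid",
    "summarize_sizes",
    "points_to_frame",
]

METHODS = ("AM", "SAM", "EUM", "AUM", "BTM")


@dataclass(frozen=True)
class DesignConfig:
    """A trial design: total size, allocation ratio, true rates, margin, level."""

    total_n: int
    allocation: tuple[int, int, int]  # (lambda_P, lambda_R, lambda_T)
    rates: RateTriple
    margin: Margin
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")
        if any(int(l) != l or l < 1 for l in self.allocation):
            raise ValueError(f"allocation ratios must be positive integers: {self.allocation}")
        self.sizes  # validate divisibility eagerly

    @property
    def sizes(self) -> tuple[int, int, int]:
        """Per-arm sizes (n_T, n_R, n_P); total_n must split exactly."""
        lam_P, lam_R, lam_T = self.allocation
        total_lam = lam_P + lam_R + lam_T
        sizes = []
        for lam in (lam_T, lam_R, lam_P):
            n, rem = divmod(self.total_n * lam, total_lam)
            if rem:
                raise ValueError(
                    f"total_n={self.total_n} does not divide exactly under "
                    f"allocation {self.allocation[0]}:{self.allocation[1]}:{self.allocation[2]}"
                )
            sizes.append(n)
        return tuple(sizes)


@dataclass(frozen=True)
class OperatingPoint:
    config: DesignConfig
    method: str
    kind: StatisticKind
    value: float
    is_power: bool
    meta: dict[str, Any] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# per-outcome p-value lattices
# ---------------------------------------------------------------------------

_PLATTICE_CACHE: dict[tuple, np.ndarray] = {}


def _sorted_tail_weights(T: np.ndarray):
    """Order the lattice by decreasing statistic; ties grouped.

    Returns (flat order, per-outcome index into the cumulative tail such that
    cumsum[idx[j]] = P(T >= T_j), honoring ties).
    """
    flat = T.ravel()
    order = np.argsort(-flat, kind="stable")
    sorted_vals = flat[order]
    # rank of the last outcome tied with each value; ties use the same float
    # tolerance as the scalar tail mask (T >= t0 - TIE_TOL)
    from .pvalues import TIE_TOL

    with np.errstate(invalid="ignore"):
        probe = np.where(np.isfinite(sorted_vals), -(sorted_vals - TIE_TOL), -sorted_vals)
    last_tied = np.searchsorted(-sorted_vals, probe, side="right") - 1
    idx = np.empty(flat.shape[0], dtype=np.int64)
    idx[order] = last_tied
    return order, idx


def _aum_lattice(sizes, margin: Margin, kind: StatisticKind) -> np.ndarray:
    """Approximate-unconditional p-value at every outcome of the lattice."""
    nT, nR, nP = sizes
    T = statistic_lattice(sizes, margin, kind)
    xT, xR, xP = np.meshgrid(
        np.arange(nT + 1), np.arange(nR + 1), np.arange(nP + 1), indexing="ij"
    )
    tT, tR, tP = rmle_batch(xT, xR, xP, nT, nR, nP, margin.theta, force_null=True)
    order, tail_idx = _sorted_tail_weights(T)
    oT = xT.ravel()[order]
    oR = xR.ravel()[order]
    oP = xP.ravel()[order]
    flat_tT, flat_tR, flat_tP = tT.ravel(), tR.ravel(), tP.ravel()
    N = T.size
    out = np.empty(N)
    chunk = max(1, int(2e7) // N)
    kTv, kRv, kPv = np.arange(nT + 1), np.arange(nR + 1), np.arange(nP + 1)
    for start in range(0, N, chunk):
        sl = slice(start, min(start + chunk, N))
        PT = stats.binom.pmf(kTv[None, :], nT, flat_tT[sl, None])
        PR = stats.binom.pmf(kRv[None, :], nR, flat_tR[sl, None])
        PP = stats.binom.pmf(kPv[None, :], nP, flat_tP[sl, None])
        w = PT[:, oT] * PR[:, oR] * PP[:, oP]  # (chunk, N) in tail order
        cw = np.cumsum(w, axis=1)
        out[sl] = cw[np.arange(sl.stop - sl.start), tail_idx[sl]]
    return np.minimum(out, 1.0).reshape(T.shape)


def _eum_lattice(sizes, margin: Margin, kind: StatisticKind, *,
                 n_grid: int = 51, psi_step: float = 0.05) -> np.ndarray:
    """Exact-unconditional p-value at every outcome (shared nuisance grid).

    For each nuisance point the tails of *all* thresholds come from one
    cumulative sum over the statistic-ordered lattice, so the whole p-value
    lattice costs O(grid * lattice).
    """
    nT, nR, nP = sizes
    T = statistic_lattice(sizes, margin, kind)
    order, tail_idx = _sorted_tail_weights(T)
    xT, xR, xP = np.meshgrid(
        np.arange(nT + 1), np.arange(nR + 1), np.arange(nP + 1), indexing="ij"
    )
    oT = xT.ravel()[order]
    oR = xR.ravel()[order]
    oP = xP.ravel()[order]
    pts = null_nuisance_grid(margin, n_grid=n_grid, psi_step=psi_step)
    N = T.size
    best = np.zeros(N)
    kTv, kRv, kPv = np.arange(nT + 1), np.arange(nR + 1), np.arange(nP + 1)
    chunk = max(1, int(2e7) // N)
    for start in range(0, pts.shape[0], chunk):
        sl = slice(start, min(start + chunk, pts.shape[0]))
        PT = stats.binom.pmf(kTv[None, :], nT, pts[sl, 0:1])
        PR = stats.binom.pmf(kRv[None, :], nR, pts[sl, 1:2])
        PP = stats.binom.pmf(kPv[None, :], nP, pts[sl, 2:3])
        w = PT[:, oT] * PR[:, oR] * PP[:, oP]
        cw = np.cumsum(w, axis=1)
        np.maximum(best, cw[:, tail_idx].max(axis=0), out=best)
    return np.minimum(best, 1.0).reshape(T.shape)


def _btm_lattice(sizes, margin: Margin, kind: StatisticKind, *,
                 B: int = 1000, seed: int = 0) -> np.ndarray:
    """Bootstrap p-value at every outcome (scaled-down default B)."""
    nT, nR, nP = sizes
    T = statistic_lattice(sizes, margin, kind)
    xT, xR, xP = np.meshgrid(
        np.arange(nT + 1), np.arange(nR + 1), np.arange(nP + 1), indexing="ij"
    )
    tT, tR, tP = rmle_batch(xT, xR, xP, nT, nR, nP, margin.theta, force_null=True)
    rng = np.random.default_rng(seed)
    out = np.empty(T.size)
    flat_T = T.ravel()
    for j, (pT, pR, pP) in enumerate(zip(tT.ravel(), tR.ravel(), tP.ravel())):
        bT = rng.binomial(nT, pT, size=B)
        bR = rng.binomial(nR, pR, size=B)
        bP = rng.binomial(nP, pP, size=B)
        T_star = statistic_batch(bT, bR, bP, sizes, margin, kind)
        out[j] = np.mean(T_star >= flat_T[j] - 1e-9)
    return out.reshape(T.shape)


def _sam_lattice(sizes, margin: Margin, kind: StatisticKind) -> np.ndarray:
    """Saddlepoint p-value at every outcome, fully vectorised.

    Outcomes whose threshold leaves the attainable range fall back to the
    normal tail, matching the scalar engine's behaviour.
    """
    from .pvalues import sam_tail_batch

    nT, nR, nP = sizes
    th = margin.theta
    T = statistic_lattice(sizes, margin, kind)
    xT, xR, xP = np.meshgrid(
        np.arange(nT + 1), np.arange(nR + 1), np.arange(nP + 1), indexing="ij"
    )
    fT = xT.ravel().astype(float)
    fR = xR.ravel().astype(float)
    fP = xP.ravel().astype(float)
    tT, tR, tP = rmle_batch(fT, fR, fP, nT, nR, nP, th, force_null=True)

    if kind is StatisticKind.LRT:
        # invert the signed-root statistic along the test-arm profile:
        # pseudo-data x_T = n_T*(pi_T_null + u) has psi_hat = u + psi(null)
        target = T.ravel()
        lo = -tT + 1e-9
        hi = 1.0 - tT - 1e-9
        finite = np.isfinite(target)

        from .statistics import signed_null_deviance_batch

        def g(u):
            return signed_null_deviance_batch(nT * (tT + u), nR * tR, nP * tP,
                                              sizes, margin) - target

        g_lo = g(lo)
        g_hi = g(hi)
        solvable = finite & (g_lo <= 0.0) & (g_hi >= 0.0)
        left, right = lo.copy(), hi.copy()
        for _ in range(60):
            mid = 0.5 * (left + right)
            pos = g(mid) > 0.0
            right = np.where(pos, mid, right)
            left = np.where(pos, left, mid)
        psi_null = tT - th * tR - (1.0 - th) * tP
        s = 0.5 * (left + right) + psi_null
        s = np.where(solvable, s, np.nan)
    else:
        s = fT / nT - th * fR / nR - (1.0 - th) * fP / nP

    p = sam_tail_batch(sizes, margin, tT, tR, tP, s)
    bad = ~np.isfinite(p)
    if bad.any():
        p[bad] = stats.norm.sf(T.ravel()[bad])
    return p.reshape(T.shape)


def pvalue_lattice(sizes: tuple[int, int, int], margin: Margin, method: str,
                   kind: StatisticKind, *, cap: int = DEFAULT_LATTICE_CAP,
                   **method_cfg) -> np.ndarray:
    """Per-outcome p-values for a whole lattice, cached across rate configs."""
    n_outcomes = (sizes[0] + 1) * (sizes[1] + 1) * (sizes[2] + 1)
    if n_outcomes > cap:
        raise LatticeTooLarge(
            f"lattice of {n_outcomes} outcomes exceeds the cap {cap}; "
            "use Monte-Carlo mode (mc_rejection_rate)"
        )
    method = method.upper()
    key = (sizes, round(margin.theta, 12), method, kind,
           tuple(sorted(method_cfg.items())))
    cached = _PLATTICE_CACHE.get(key)
    if cached is not None:
        return cached
    if method == "AM":
        out = stats.norm.sf(statistic_lattice(sizes, margin, kind))
    elif method == "AUM":
        out = _aum_lattice(sizes, margin, kind)
    elif method == "EUM":
        out = _eum_lattice(sizes, margin, kind, **method_cfg)
    elif method == "BTM":
        out = _btm_lattice(sizes, margin, kind, **method_cfg)
    elif method == "SAM":
        out = _sam_lattice(sizes, margin, kind)
    else:
        raise ValueError(f"unknown p-value method {method!r}; expected one of {METHODS}")
    out.setflags(write=False)
    _PLATTICE_CACHE[key] = out
    return out


# ---------------------------------------------------------------------------
# exact and Monte-Carlo rejection rates
# ---------------------------------------------------------------------------


def exact_rejection_rate(config: DesignConfig, method: str, kind: StatisticKind,
                         **method_cfg) -> OperatingPoint:
    """Exact size (under the null) or power (under an alternative).

    Enumerates the outcome lattice once per (sizes, theta, method, kind),
    then weights the rejection region by the product-binomial pmf at the
    design's true rates.
    """
    sizes = config.sizes
    pvals = pvalue_lattice(sizes, config.margin, method, kind, **method_cfg)
    reject = pvals <= config.alpha
    pT, pR, pP = _pmf_vectors(sizes, (config.rates.pi_T, config.rates.pi_R, config.rates.pi_P))
    value = float(np.clip(np.einsum("trp,t,r,p->", reject, pT, pR, pP, optimize=True), 0.0, 1.0))
    is_power = psi_of(config.rates, config.margin) > 0.0
    return OperatingPoint(config, method.upper(), kind, value, is_power,
                          meta=dict(method_cfg))


def mc_rejection_rate(config: DesignConfig, method: str, kind: StatisticKind,
                      n_sim: int, seed: int, **method_cfg) -> OperatingPoint:
    """Monte-Carlo rejection rate: simulate trials instead of enumerating.

    Intended for designs beyond the enumeration cap, and as an independent
    cross-check of :func:`exact_rejection_rate`.  Only the asymptotic method
    is vectorised; the other engines are evaluated trial by trial.
    """
    sizes = config.sizes
    nT, nR, nP = sizes
    rng = np.random.default_rng(seed)
    xT = rng.binomial(nT, config.rates.pi_T, size=n_sim)
    xR = rng.binomial(nR, config.rates.pi_R, size=n_sim)
    xP = rng.binomial(nP, config.rates.pi_P, size=n_sim)
    if method.upper() == "AM":
        T = statistic_batch(xT, xR, xP, sizes, config.margin, kind)
        pvals = stats.norm.sf(T)
    else:
        from . import pvalues as _pv

        engine = {
            "SAM": _pv.p_saddlepoint,
            "EUM": _pv.p_exact_unconditional,
            "AUM": _pv.p_approx_unconditional,
        }.get(method.upper())
        if engine is None and method.upper() == "BTM":
            cfg = BootstrapConfig(method_cfg.get("B", 1000), method_cfg.get("seed", seed + 1))
            engine = lambda c, m, k: _pv.p_bootstrap(c, m, k, cfg)  # noqa: E731
        if engine is None:
            raise ValueError(f"unknown p-value method {method!r}")
        pvals = np.array([
            engine(TrialCounts(int(a), nT, int(b), nR, int(c), nP), config.margin, kind).value
            for a, b, c in zip(xT, xR, xP)
        ])
    value = float(np.mean(pvals <= config.alpha))
    is_power = psi_of(config.rates, config.margin) > 0.0
    return OperatingPoint(config, method.upper(), kind, value, is_power,
                          meta={"n_sim": n_sim, "seed": seed, **method_cfg})


# ---------------------------------------------------------------------------
# design grids and summaries
# ---------------------------------------------------------------------------


def design_grid(thetas: Sequence[float], total_ns: Sequence[int],
                allocations: Sequence[tuple[int, int, int]], *,
                pi_step: float = 0.05, pi_p_max: float = 0.50,
                pi_r_max: float = 0.95, alpha: float = 0.05) -> list[DesignConfig]:
    """Null-boundary design configurations for a size study.

    For each (theta, n, allocation), sweeps pi_P = pi_step, 2*pi_step, ...,
    pi_p_max and pi_R = pi_P + pi_step, ..., pi_r_max, placing pi_T on the
    null boundary theta*pi_R + (1-theta)*pi_P (so psi = 0 and the rejection
    rate is a type-I error).  Defaults give 135 (pi_P, pi_R) pairs per
    (theta, n, allocation).
    """
    n_p = int(round(pi_p_max / pi_step))
    out: list[DesignConfig] = []
    for theta in thetas:
        margin = Margin(theta)
        for total_n in total_ns:
            for alloc in allocations:
                for i in range(1, n_p + 1):
                    pi_P = round(i * pi_step, 10)
                    if pi_P > pi_p_max + 1e-9:
                        break
                    j = 1
                    while True:
                        pi_R = round(pi_P + j * pi_step, 10)
                        if pi_R > pi_r_max + 1e-9:
                            break
                        pi_T = theta * pi_R + (1.0 - theta) * pi_P
                        out.append(
                            DesignConfig(total_n, tuple(alloc),
                                         RateTriple(pi_T, pi_R, pi_P), margin, alpha)
                        )
                        j += 1
    return out


def points_to_frame(points: Iterable[OperatingPoint]) -> pd.DataFrame:
    """One row per operating point, in the layout the CLI emits as TSV."""
    rows = []
    for pt in points:
        lam_P, lam_R, lam_T = pt.config.allocation
        rows.append({
            "n": pt.config.total_n,
            "allocation": f"{lam_P}:{lam_R}:{lam_T}",
            "theta": pt.config.margin.theta,
            "pi_P": pt.config.rates.pi_P,
            "pi_R": pt.config.rates.pi_R,
            "pi_T": pt.config.rates.pi_T,
            "method": pt.method,
            "kind": pt.kind.value,
            "value": pt.value,
            "is_power": pt.is_power,
        })
    return pd.DataFrame(rows)


def summarize_sizes(points: Sequence[OperatingPoint], *,
                    band: tuple[float, float] = (0.045, 0.055)) -> pd.DataFrame:
    """Per (method, statistic): median/min/max size and share inside the band.

    The band proportion counts strict containment, mirroring the usual
    "type I error within (0.045, 0.055)" bookkeeping for a 5% test.
    """
    if not points:
        raise ValueError("no operating points to summarize")
    df = points_to_frame(points)
    lo, hi = band

    def agg(g: pd.DataFrame) -> pd.Series:
        v = g["value"]
        return pd.Series({
            "median": v.median(),
            "min": v.min(),
            "max": v.max(),
            "prop_in_band": ((v > lo) & (v < hi)).mean(),
            "n_configs": len(v),
        })

    return df.groupby(["method", "kind"]).apply(agg, include_groups=False)
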