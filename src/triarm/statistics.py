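"""Test statistics for the retention-fraction non-inferiority hypothesis.

All three statistics standardise the estimated contrast
``psi_hat = x_T/n_T - theta*x_R/n_R - (1-theta)*x_P/n_P`` and are
asymptotically standard normal on the null boundary:

* ``T_W`` (Wald): psi_hat over its standard error with variances plugged in
  at the unrestricted MLE (Blackwelder-style).
* ``T_R`` (score): the same contrast standardised by the variance at the
  restricted MLE (Farrington-Manning style); the numerator stays the
  unrestricted psi_hat.
* ``T_L`` (signed-root LRT): sign(psi_hat) * sqrt(2 * deviance) between the
  unrestricted and null-restricted fits.

When the plug-in variance degenerates to zero the statistic is +/-inf
according to the sign of psi_hat (0 when psi_hat = 0), which preserves the
ordering the tail-set p-value engines rely on.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy, xlog1py

from .model import Margin, RateTriple, TrialCounts, log_likelihood, mle, psi_of, rmle, rmle_batch

__all__ = [
    "StatisticKind",
    "StatisticValue",
    "variance_psi",
    "wald_statistic",
    "score_statistic",
    "lrt_statistic",
    "statistic",
    "statistic_lattice",
]


class StatisticKind(enum.Enum):
    WALD = "w"
    SCORE = "r"
    LRT = "l"

    @classmethod
    def parse(cls, label: str) -> "StatisticKind":
        label = label.strip().lower()
        aliases = {
            "w": cls.WALD, "wald": cls.WALD, "tw": cls.WALD,
            "r": cls.SCORE, "score": cls.SCORE, "tr": cls.SCORE,
            "l": cls.LRT, "lrt": cls.LRT, "tl": cls.LRT,
        }
        try:
            return aliases[label]
        except KeyError:
            raise ValueError(f"unknown statistic {label!r}; use one of w, r, l") from None


@dataclass(frozen=True)
class StatisticValue:
    value: float
    kind: StatisticKind


def variance_psi(rates: RateTriple, sizes: tuple[int, int, int], margin: Margin) -> float:
    """Plug-in variance of psi_hat at the given rates.

    Var = pi_T(1-pi_T)/n_T + theta^2 pi_R(1-pi_R)/n_R + (1-theta)^2 pi_P(1-pi_P)/n_P.
    """
    nT, nR, nP = sizes
    th = margin.theta
    return (
        rates.pi_T * (1.0 - rates.pi_T) / nT
        + th**2 * rates.pi_R * (1.0 - rates.pi_R) / nR
        + (1.0 - th) ** 2 * rates.pi_P * (1.0 - rates.pi_P) / nP
    )


def _standardise(psi_hat: float, var: float) -> float:
    if var > 0.0:
        return psi_hat / np.sqrt(var)
    if psi_hat > 0.0:
        return np.inf
    if psi_hat < 0.0:
        return -np.inf
    return 0.0


def wald_statistic(counts: TrialCounts, margin: Margin) -> StatisticValue:
    hat = mle(counts)
    psi_hat = psi_of(hat, margin)
    var = variance_psi(hat, counts.sizes, margin)
    return StatisticValue(_standardise(psi_hat, var), StatisticKind.WALD)


def score_statistic(counts: TrialCounts, margin: Margin) -> StatisticValue:
    hat = mle(counts)
    psi_hat = psi_of(hat, margin)
    tilde = rmle(counts, margin)
    var = variance_psi(tilde, counts.sizes, margin)
    return StatisticValue(_standardise(psi_hat, var), StatisticKind.SCORE)


def lrt_statistic(counts: TrialCounts, margin: Margin) -> StatisticValue:
    hat = mle(counts)
    psi_hat = psi_of(hat, margin)
    tilde = rmle(counts, margin)
    deviance = 2.0 * (
        log_likelihood(counts, hat, kernel=True) - log_likelihood(counts, tilde, kernel=True)
    )
    # optimiser tolerance can leave the bracket at -1e-12
    deviance = max(deviance, 0.0)
    return StatisticValue(float(np.sign(psi_hat)) * np.sqrt(deviance), StatisticKind.LRT)


_DISPATCH = {
    StatisticKind.WALD: wald_statistic,
    StatisticKind.SCORE: score_statistic,
    StatisticKind.LRT: lrt_statistic,
}


def statistic(counts: TrialCounts, margin: Margin, kind: StatisticKind) -> StatisticValue:
    """Evaluate the requested statistic on observed counts."""
    return _DISPATCH[kind](counts, margin)


# ---------------------------------------------------------------------------
# Whole-lattice evaluation (vectorised), used by the enumeration engines.
# ---------------------------------------------------------------------------

_LATTICE_CACHE: dict[tuple, np.ndarray] = {}


def _kernel(x, n, p):
    return xlogy(x, p) + xlog1py(n - x, -p)


def statistic_batch(xT, xR, xP, sizes, margin: Margin, kind: StatisticKind) -> np.ndarray:
    """Statistic values for arrays of outcomes at common sizes and margin."""
    nT, nR, nP = sizes
    th = margin.theta
    xT = np.asarray(xT, dtype=float)
    xR = np.asarray(xR, dtype=float)
    xP = np.asarray(xP, dtype=float)
    pT, pR, pP = xT / nT, xR / nR, xP / nP
    psi_hat = pT - th * pR - (1.0 - th) * pP

    if kind is StatisticKind.WALD:
        var = pT * (1 - pT) / nT + th**2 * pR * (1 - pR) / nR + (1 - th) ** 2 * pP * (1 - pP) / nP
    else:
        tT, tR, tP = rmle_batch(xT, xR, xP, nT, nR, nP, th)
        if kind is StatisticKind.SCORE:
            var = (
                tT * (1 - tT) / nT
                + th**2 * tR * (1 - tR) / nR
                + (1 - th) ** 2 * tP * (1 - tP) / nP
            )
        else:
            dev = 2.0 * (
                _kernel(xT, nT, pT) + _kernel(xR, nR, pR) + _kernel(xP, nP, pP)
                - _kernel(xT, nT, tT) - _kernel(xR, nR, tR) - _kernel(xP, nP, tP)
            )
            return np.sign(psi_hat) * np.sqrt(np.maximum(dev, 0.0))

    with np.errstate(divide="ignore", invalid="ignore"):
        t = psi_hat / np.sqrt(var)
    t = np.where(var > 0.0, t, np.where(psi_hat > 0, np.inf, np.where(psi_hat < 0, -np.inf, 0.0)))
    return t


def signed_null_deviance_batch(xT, xR, xP, sizes, margin: Margin) -> np.ndarray:
    """sign(psi_hat) * sqrt(2 * deviance against the psi = 0 constrained fit).

    Coincides with the signed-root LRT statistic wherever psi_hat > 0, but is
    strictly increasing in the contrast on both sides of the null (the LRT
    statistic itself is identically 0 for psi_hat <= 0, where the restricted
    fit equals the MLE).  This monotone extension is what the saddlepoint
    engine inverts when mapping an observed statistic to the psi_hat scale.
    Accepts fractional pseudo-counts.
    """
    nT, nR, nP = sizes
    th = margin.theta
    xT = np.asarray(xT, dtype=float)
    xR = np.asarray(xR, dtype=float)
    xP = np.asarray(xP, dtype=float)
    pT, pR, pP = xT / nT, xR / nR, xP / nP
    psi_hat = pT - th * pR - (1.0 - th) * pP
    tT, tR, tP = rmle_batch(xT, xR, xP, nT, nR, nP, th, force_null=True)
    dev = 2.0 * (
        _kernel(xT, nT, pT) + _kernel(xR, nR, pR) + _kernel(xP, nP, pP)
        - _kernel(xT, nT, tT) - _kernel(xR, nR, tR) - _kernel(xP, nP, tP)
    )
    return np.sign(psi_hat) * np.sqrt(np.maximum(dev, 0.0))


def statistic_lattice(sizes: tuple[int, int, int], margin: Margin, kind: StatisticKind) -> np.ndarray:
    """Statistic at every outcome of the (n_T+1)x(n_R+1)x(n_P+1) lattice.

    The result depends only on (sizes, theta, kind) and is cached: exact
    p-value and operating-characteristic enumeration reuse one lattice across
    arbitrarily many nuisance-parameter configurations.
    """
    key = (sizes, round(margin.theta, 12), kind)
    cached = _LATTICE_CACHE.get(key)
    if cached is not None:
        return cached
    nT, nR, nP = sizes
    xT, xR, xP = np.meshgrid(
        np.arange(nT + 1), np.arange(nR + 1), np.arange(nP + 1), indexing="ij"
    )
    t = statistic_batch(xT, xR, xP, sizes, margin, kind)
    t.setflags(write=False)
    _LATTICE_CACHE[key] = t
    return t
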