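"""Model-quality statistics: R², RMSE, F, CCC, Q², IIC, CII.

Beyond the classical quartet (determination coefficient, root mean
squared error, Fisher F-ratio, Lin's concordance), two less common
criteria drive the Monte Carlo target function:

* IIC, the index of ideality of correlation — the Pearson correlation
  damped by the ratio of the smaller to the larger one-sided mean
  absolute error (residuals below vs. at-or-above zero).  It penalizes
  models whose errors pile up on one side of the identity line.
* CII, the correlation intensity index — one minus the summed
  "protests", where point k protests if deleting it *raises* the set's
  R².  CII near 1 means no single point opposes the correlation.

Conventions: R² is the squared Pearson correlation; CCC uses population
(1/n) moments; RMSE uses the sample (1/(n-1)) denominator, matching the
reference software's reported tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "UndefinedStatisticError",
    "SetStatistics",
    "pearson_r",
    "r2",
    "rmse",
    "f_ratio",
    "ccc",
    "iic",
    "cii",
    "q2_loo",
    "loo_r2_values",
    "set_statistics",
]


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given data (e.g. zero variance)."""


def _pair(observed, calculated):
    o = np.asarray(observed, dtype=float)
    c = np.asarray(calculated, dtype=float)
    if o.shape != c.shape or o.ndim != 1:
        raise ValueError("observed and calculated must be 1-D of equal length")
    if o.size < 2:
        raise ValueError("need at least 2 points")
    if not (np.all(np.isfinite(o)) and np.all(np.isfinite(c))):
        raise ValueError("all values must be finite")
    return o, c


def pearson_r(observed, calculated) -> float:
    o, c = _pair(observed, calculated)
    do, dc = o - o.mean(), c - c.mean()
    so, sc = np.sqrt(np.sum(do**2)), np.sqrt(np.sum(dc**2))
    if so == 0 or sc == 0:
        raise UndefinedStatisticError("zero variance: correlation undefined")
    return float(np.sum(do * dc) / (so * sc))


def r2(observed, calculated) -> float:
    """Determination coefficient = squared Pearson correlation."""
    return pearson_r(observed, calculated) ** 2


def rmse(observed, calculated) -> float:
    """Root mean squared error with the sample (n-1) denominator."""
    o = np.asarray(observed, dtype=float)
    c = np.asarray(calculated, dtype=float)
    if o.size < 1:
        raise ValueError("need at least 1 point")
    if o.size == 1:
        return float(abs(o - c)[0])
    return float(np.sqrt(np.sum((o - c) ** 2) / (o.size - 1)))


def f_ratio(r2_value: float, n: int) -> float:
    """Fisher F for the one-predictor regression: r²(n-2)/(1-r²)."""
    if not 0 <= r2_value <= 1:
        raise ValueError(f"r2 must lie in [0, 1], got {r2_value}")
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if r2_value == 1:
        raise UndefinedStatisticError("r2 = 1 gives infinite F")
    return r2_value * (n - 2) / (1 - r2_value)


def ccc(observed, calculated) -> float:
    """Lin's concordance correlation coefficient (population moments):
    2 cov(o,c) / (var(o) + var(c) + (mean(o) - mean(c))²)."""
    o, c = _pair(observed, calculated)
    mo, mc = o.mean(), c.mean()
    vo, vc = np.mean((o - mo) ** 2), np.mean((c - mc) ** 2)
    cov = np.mean((o - mo) * (c - mc))
    denom = vo + vc + (mo - mc) ** 2
    if denom == 0:
        raise UndefinedStatisticError("both series constant and equal")
    return float(2 * cov / denom)


def iic(observed, calculated) -> float:
    """Index of ideality of correlation.

    With residuals Δk = observed - calculated, split into the negative
    side (Δ < 0) and the non-negative side (Δ >= 0):

        IIC = r(o, c) * min(MAE⁻, MAE⁺) / max(MAE⁻, MAE⁺)

    If one side is empty its MAE is 0, the ratio is 0 and IIC = 0 —
    except for the perfect fit (both sides empty of error), where IIC
    equals r = 1.
    """
    o, c = _pair(observed, calculated)
    d = o - c
    neg = np.abs(d[d < 0])
    pos = np.abs(d[d >= 0])
    if np.all(d == 0):
        return 1.0
    if neg.size == 0 or pos.size == 0:
        return 0.0
    mae_neg, mae_pos = neg.mean(), pos.mean()
    hi = max(mae_neg, mae_pos)
    if hi == 0:
        return 1.0
    return float(pearson_r(o, c) * min(mae_neg, mae_pos) / hi)


def loo_r2_values(observed, calculated) -> np.ndarray:
    """R² of the set with each point deleted in turn, computed from
    downdated sufficient statistics (O(n) total)."""
    o, c = _pair(observed, calculated)
    n = o.size
    if n < 3:
        raise ValueError("need at least 3 points for leave-one-out R²")
    so, sc = o.sum(), c.sum()
    soo, scc, soc = np.sum(o * o), np.sum(c * c), np.sum(o * c)
    m = n - 1
    # per-k sums with point k removed
    sok, sck = so - o, sc - c
    sook, scck, sock = soo - o * o, scc - c * c, soc - o * c
    num = m * sock - sok * sck
    var_o = m * sook - sok**2
    var_c = m * scck - sck**2
    denom = var_o * var_c
    if np.any(denom <= 0):
        raise UndefinedStatisticError(
            "a leave-one-out subset has zero variance; R² undefined"
        )
    return num**2 / denom


def cii(observed, calculated) -> float:
    """Correlation intensity index: 1 - Σk max(0, R²₋k - R²)."""
    o, c = _pair(observed, calculated)
    if o.size < 3:
        raise ValueError("need at least 3 points")
    full = r2(o, c)
    protests = np.maximum(0.0, loo_r2_values(o, c) - full)
    return float(1.0 - protests.sum())


def q2_loo(dcw_values, endpoints) -> float:
    """Leave-one-out cross-validated R² of the one-variable regression
    endpoint ~ descriptor: Q² = 1 - PRESS/SS_tot.

    Uses the hat-matrix identity e_(k) = e_k / (1 - h_k) for the simple
    linear regression, which is exact, so no refitting loop is needed.
    """
    x = np.asarray(dcw_values, dtype=float)
    y = np.asarray(endpoints, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 points for Q², got {n}")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx <= 0:
        raise UndefinedStatisticError("descriptor has zero variance")
    b1 = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    b0 = y.mean() - b1 * x.mean()
    resid = y - (b0 + b1 * x)
    h = 1.0 / n + (x - x.mean()) ** 2 / sxx
    if np.any(h >= 1.0):
        raise UndefinedStatisticError("a leave-one-out fit is degenerate")
    press = np.sum((resid / (1.0 - h)) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise UndefinedStatisticError("endpoint has zero variance")
    return float(1.0 - press / ss_tot)


@dataclass(frozen=True)
class SetStatistics:
    """The per-set summary row: n, R², CCC, IIC, CII, Q², RMSE, F."""

    n: int
    r2: float
    ccc: float
    iic: float
    cii: float
    q2: float
    rmse: float
    f: float

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "r2": self.r2,
            "ccc": self.ccc,
            "iic": self.iic,
            "cii": self.cii,
            "q2": self.q2,
            "rmse": self.rmse,
            "f": self.f,
        }


def set_statistics(observed, calculated) -> SetStatistics:
    """Compute the full statistics row for one set.

    Q² is the leave-one-out statistic of the regression observed ~
    calculated; since the calculated column is an affine image of the
    descriptor, this equals the Q² of the observed ~ descriptor
    regression.
    """
    o, c = _pair(observed, calculated)
    r2_val = r2(o, c)
    return SetStatistics(
        n=int(o.size),
        r2=r2_val,
        ccc=ccc(o, c),
        iic=iic(o, c),
        cii=cii(o, c),
        q2=q2_loo(c, o),
        rmse=rmse(o, c),
        f=f_ratio(r2_val, o.size),
    )
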