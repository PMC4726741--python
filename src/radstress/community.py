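"""Formula-level community statistics for field survey data.

Covers the descriptive toolkit used alongside the mechanistic chemostat
analysis: incidence-based species richness (bias-corrected Chao2 with a
log-normal confidence interval), exact 2x2 odds-ratio inference for
per-species detection contrasts between exposure groups, and collinearity
diagnostics (Pearson correlation, variance inflation factors) for
environmental predictor matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data import IncidenceMatrix

__all__ = [
    "ContingencyTable2x2",
    "Chao2Result",
    "FisherExactResult",
    "chao2_bias_corrected",
    "sample_odds_ratio",
    "fisher_exact",
    "group_detection_table",
    "pearson_correlation",
    "vif",
    "CollinearityError",
]

Z_95 = 1.959963984540054


class CollinearityError(ValueError):
    """The predictor matrix is rank deficient."""


# ---------------------------------------------------------------------------
# Chao2 richness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Chao2Result:
    """Bias-corrected Chao2 incidence-based richness estimate with 95% CI."""

    s_obs: int
    q1: int
    q2: int
    m_samples: int
    estimate: float
    variance: float
    ci_low: float
    ci_high: float


def chao2_bias_corrected(
    incidence: IncidenceMatrix | pd.DataFrame | np.ndarray,
    group: str | None = None,
    *,
    variant: str = "bias_corrected",
    z: float = Z_95,
) -> Chao2Result:
    """Chao2 incidence-based richness from a binary species x sample matrix.

    The default (bias-corrected) estimator is

        estimate = S_obs + ((m-1)/m) * q1*(q1-1) / (2*(q2+1))

    where q1/q2 count species detected in exactly one/two samples.  The 95%
    interval is the standard log-normal interval anchored at S_obs, with the
    matching variance formula.  ``variant='classic'`` uses the original
    estimator S_obs + ((m-1)/m) * q1^2/(2*q2) and its variance (the form
    richness software commonly reports when duplicates are present); it
    requires q2 > 0.
    """
    if isinstance(incidence, IncidenceMatrix):
        matrix = incidence.restrict(group) if group is not None else incidence.presence
    else:
        matrix = pd.DataFrame(incidence)
    values = matrix.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError("incidence values must be binary")
    m = values.shape[1]
    if m < 2:
        raise ValueError(f"Chao2 requires at least 2 samples, got {m}")
    counts = values.sum(axis=1)
    s_obs = int((counts >= 1).sum())
    q1 = int((counts == 1).sum())
    q2 = int((counts == 2).sum())
    A = (m - 1) / m
    if variant == "bias_corrected":
        estimate = s_obs + A * q1 * (q1 - 1) / (2.0 * (q2 + 1))
        variance = (
            A * q1 * (q1 - 1) / (2.0 * (q2 + 1))
            + A**2 * q1 * (2 * q1 - 1) ** 2 / (4.0 * (q2 + 1) ** 2)
            + A**2 * q1**2 * q2 * (q1 - 1) ** 2 / (4.0 * (q2 + 1) ** 4)
        )
    elif variant == "classic":
        if q2 == 0:
            raise ValueError("classic Chao2 requires q2 > 0 (use bias_corrected)")
        r = q1 / q2
        estimate = s_obs + A * q1**2 / (2.0 * q2)
        variance = q2 * (A * r**2 / 2.0 + A**2 * r**3 + A**2 * r**4 / 4.0)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    T = estimate - s_obs
    if T > 0 and variance > 0:
        K = math.exp(z * math.sqrt(math.log(1.0 + variance / T**2)))
        ci_low = s_obs + T / K
        ci_high = s_obs + T * K
    else:
        ci_low = ci_high = float(estimate)
    return Chao2Result(
        s_obs=s_obs,
        q1=q1,
        q2=q2,
        m_samples=m,
        estimate=float(estimate),
        variance=float(variance),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
    )


# ---------------------------------------------------------------------------
# 2x2 odds ratios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Detections/absences of one species in the high and low exposure groups."""

    detected_high: int
    absent_high: int
    detected_low: int
    absent_low: int

    def __post_init__(self) -> None:
        for name in ("detected_high", "absent_high", "detected_low", "absent_low"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {value!r}")

    @property
    def as_array(self) -> np.ndarray:
        return np.array(
            [
                [self.detected_high, self.absent_high],
                [self.detected_low, self.absent_low],
            ]
        )

    def swap_groups(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(
            self.detected_low, self.absent_low, self.detected_high, self.absent_high
        )

    def transpose(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(
            self.detected_high, self.detected_low, self.absent_high, self.absent_low
        )


def sample_odds_ratio(
    table: ContingencyTable2x2, *, haldane_correction: bool = False
) -> float:
    """Cross-product odds ratio (a*d)/(b*c).

    Zero numerator returns 0.0 and zero denominator returns ``inf`` (both
    conventionally flagged rather than raised); a 0/0 table returns NaN.
    ``haldane_correction`` adds 0.5 to every cell first.
    """
    a, b = float(table.detected_high), float(table.absent_high)
    c, d = float(table.detected_low), float(table.absent_low)
    if haldane_correction:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    num, den = a * d, b * c
    if num == 0 and den == 0:
        return math.nan
    if den == 0:
        return math.inf
    return num / den


@dataclass(frozen=True)
class FisherExactResult:
    """Two-sided exact p and exact odds-ratio CI for a 2x2 table."""

    p_value: float
    ci_low: float
    ci_high: float
    alpha: float


def _nch_pmf(M: int, n: int, N: int, psi: float) -> tuple[np.ndarray, np.ndarray]:
    """Fisher noncentral hypergeometric pmf over the support, in a stable way.

    ``M`` population size, ``n`` detected margin, ``N`` high-group margin;
    support is the count x of detected-and-high.
    """
    x_min, x_max = max(0, N + n - M), min(N, n)
    xs = np.arange(x_min, x_max + 1)
    log_w = np.array(
        [
            math.lgamma(N + 1) - math.lgamma(x + 1) - math.lgamma(N - x + 1)
            + math.lgamma(M - N + 1) - math.lgamma(n - x + 1)
            - math.lgamma(M - N - n + x + 1)
            + x * math.log(psi)
            for x in xs
        ]
    )
    log_w -= log_w.max()
    w = np.exp(log_w)
    return xs, w / w.sum()


def _two_sided_p(table: ContingencyTable2x2, psi: float) -> float:
    """Minimum-likelihood two-sided p under odds ratio psi (conditional test).

    Conditions on both margins; sums the noncentral-hypergeometric point
    probabilities of all tables no more probable than the observed one.
    """
    a = table.detected_high
    M = table.detected_high + table.absent_high + table.detected_low + table.absent_low
    n = table.detected_high + table.detected_low  # detected margin
    N = table.detected_high + table.absent_high  # high-group margin
    x_min, x_max = max(0, N + n - M), min(N, n)
    if x_min == x_max:
        return 1.0
    if psi == 0.0:
        return 1.0 if a == x_min else 0.0
    if math.isinf(psi):
        return 1.0 if a == x_max else 0.0
    xs, pmf = _nch_pmf(M, n, N, psi)
    p_obs = pmf[a - x_min]
    return float(pmf[pmf <= p_obs * (1.0 + 1e-9)].sum())


def fisher_exact(
    table: ContingencyTable2x2,
    alpha: float = 0.05,
    *,
    psi_range: tuple[float, float] = (1e-10, 1e10),
    grid_points: int = 241,
) -> FisherExactResult:
    """Exact conditional inference for the odds ratio of a 2x2 table.

    The two-sided p-value uses the minimum-likelihood convention (all tables
    with point probability at most the observed one).  The CI inverts the
    *same* test: it is the set of odds ratios psi whose two-sided p is at
    least ``alpha``, located on a log grid (always containing psi=1) and
    refined by bisection.  This construction makes the interval and the
    p-value exactly dual: the CI excludes 1 iff p < alpha.
    """
    a = table.detected_high
    M = table.detected_high + table.absent_high + table.detected_low + table.absent_low
    n = table.detected_high + table.detected_low
    N = table.detected_high + table.absent_high
    x_min, x_max = max(0, N + n - M), min(N, n)
    p_value = _two_sided_p(table, 1.0)
    if x_min == x_max:  # degenerate margins: OR unidentifiable
        return FisherExactResult(1.0, 0.0, math.inf, alpha)

    lo_grid = np.geomspace(psi_range[0], 1.0, grid_points // 2 + 1)
    hi_grid = np.geomspace(1.0, psi_range[1], grid_points // 2 + 1)[1:]
    psis = np.concatenate([lo_grid, hi_grid])
    accepted = np.array([_two_sided_p(table, psi) >= alpha for psi in psis])
    if not accepted.any():  # pragma: no cover - grid always spans the MLE region
        raise RuntimeError("no odds ratio in the search range is accepted")
    first, last = int(np.argmax(accepted)), int(len(accepted) - 1 - np.argmax(accepted[::-1]))

    def _edge(lo: float, hi: float) -> float:
        # acceptance status differs at lo and hi; bisect in log-psi
        accept_lo = _two_sided_p(table, lo) >= alpha
        for _ in range(60):
            mid = math.sqrt(lo * hi)
            if (_two_sided_p(table, mid) >= alpha) == accept_lo:
                lo = mid
            else:
                hi = mid
        return math.sqrt(lo * hi)

    if a == x_min:
        ci_low = 0.0
    elif first == 0:
        ci_low = float(psis[0])
    else:
        ci_low = _edge(psis[first - 1], psis[first])
    if a == x_max:
        ci_high = math.inf
    elif last == len(psis) - 1:
        ci_high = float(psis[-1])
    else:
        ci_high = _edge(psis[last], psis[last + 1])
    return FisherExactResult(p_value, float(ci_low), float(ci_high), alpha)


def group_detection_table(
    incidence: IncidenceMatrix,
    exposed_group: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-species detection contrast between the two exposure groups.

    Returns one row per species: detection counts in each group, the
    cross-product odds ratio (exposed vs reference), the exact CI and the
    two-sided exact p.  Odds ratios of 0, inf or 0/0 are flagged in the
    ``flag`` column; CIs are still reported.
    """
    levels = incidence.group_levels
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    if exposed_group is None:
        guess = [g for g in levels if str(g).lower() in ("high", "exposed", "1")]
        if len(guess) != 1:
            raise ValueError(
                f"cannot infer the exposed group from {levels}; pass exposed_group"
            )
        exposed_group = guess[0]
    if exposed_group not in levels:
        raise ValueError(f"unknown group {exposed_group!r}; available: {levels}")
    reference = next(g for g in levels if g != exposed_group)
    high = incidence.restrict(exposed_group)
    low = incidence.restrict(reference)
    n_high, n_low = high.shape[1], low.shape[1]
    rows = []
    for species in incidence.species:
        det_high = int(high.loc[species].sum())
        det_low = int(low.loc[species].sum())
        t = ContingencyTable2x2(det_high, n_high - det_high, det_low, n_low - det_low)
        odds = sample_odds_ratio(t)
        exact = fisher_exact(t, alpha=alpha)
        if math.isnan(odds):
            flag = "undefined"
        elif odds == 0:
            flag = "zero"
        elif math.isinf(odds):
            flag = "infinite"
        else:
            flag = ""
        rows.append(
            {
                "species": species,
                "n_detected_high": det_high,
                "n_high": n_high,
                "n_detected_low": det_low,
                "n_low": n_low,
                "odds_ratio": odds,
                "ci_low": exact.ci_low,
                "ci_high": exact.ci_high,
                "p": exact.p_value,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Correlation / collinearity
# ---------------------------------------------------------------------------


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("correlation undefined: zero variance input")
    return float(stats.pearsonr(x, y).statistic)


def vif(predictors: pd.DataFrame | np.ndarray) -> pd.Series:
    """Variance inflation factor of every predictor column.

    VIF_j = 1 / (1 - R^2_j), with R^2_j from the OLS regression (with
    intercept) of column j on all other columns.  Raises
    :class:`CollinearityError`, naming the dependent columns, when the matrix
    is rank deficient.
    """
    X = pd.DataFrame(predictors)
    X.columns = [str(c) for c in X.columns]
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 predictor columns")
    if n <= p:
        raise ValueError(f"need more rows than columns (rows={n}, columns={p})")
    values = X.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("predictor matrix contains non-finite values")
    out = {}
    dependent = []
    for j, col in enumerate(X.columns):
        others = sm.add_constant(np.delete(values, j, axis=1))
        fit = sm.OLS(values[:, j], others).fit()
        r2 = min(fit.rsquared, 1.0)
        if 1.0 - r2 < 1e-12:
            dependent.append(col)
            out[col] = math.inf
        else:
            out[col] = 1.0 / (1.0 - r2)
    if dependent:
        raise CollinearityError(
            f"rank-deficient predictor matrix; linearly dependent column(s): "
            f"{dependent}"
        )
    return pd.Series(out, name="vif")
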