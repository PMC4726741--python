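"""Fitting, information-theoretic model selection and uncertainty analysis.

The workflow mirrors the classic multimodel-inference recipe for small
ecological data sets:

1. each candidate growth law is fitted to the steady-state observations by
   weighted least squares (a Gaussian likelihood with per-observation SDs
   derived from the measurements' 95% CIs);
2. the radiation-independent proliferation component ``g`` is not freely
   adjusted: it is profiled analytically from a critical-dose observation that
   is excluded from the fitted data (``a(R_crit, d) = 0`` is linear in ``g``);
3. candidates are ranked by the small-sample corrected Akaike information
   criterion (AICc); Akaike weights quantify relative support, and evidence
   for a mechanism is the summed weight of the models embodying it;
4. predictions are averaged over the confidence set (ΔAICc below a threshold)
   with renormalized weights ("multimodel inference", MMI);
5. uncertainty comes from a parametric bootstrap: observations are redrawn
   from their error model, the model refitted, and percentile intervals taken.

Entry points: :class:`ChemostatGrowthModel` (single-law fit, statsmodels-style
``fit()`` returning :class:`ChemostatFitResults`), :func:`fit_all_models`
(returns :class:`ModelSelectionResults` for ranking/MMI), and the helpers
:func:`aicc`, :class:`SelectionTable`, :func:`parametric_bootstrap`,
:func:`sensitivity_rcrit`, :func:`rcrit_fold_drop`.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares
from scipy.stats import qmc, truncnorm

from .data import ChemostatDataset, ChemostatObservation
from .growth import (
    ChemostatCondition,
    CriticalDoseResult,
    GrowthModel,
    InvalidParameterError,
    ParameterSet,
    get_model,
    list_models,
)

__all__ = [
    "FitConfig",
    "FitError",
    "ConfigurationError",
    "observation_sd",
    "profile_g",
    "negative_log_likelihood",
    "aicc",
    "ChemostatGrowthModel",
    "ChemostatFitResults",
    "SelectionTable",
    "ModelSelectionResults",
    "fit_all_models",
    "BootstrapSummary",
    "parametric_bootstrap",
    "sensitivity_rcrit",
    "rcrit_fold_drop",
]

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # two-sided 95% normal quantile

#: optimizer box bounds per parameter
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "m": (1e-5, 1.0),
    "g": (0.0, 5.0),
    "q": (0.0, 5.0),
    "k": (0.0, 0.1),
    "delta": (0.0, 1.0),
    "mu": (0.0, 10.0),
    "sigma": (0.0, 10.0),
}

#: characteristic magnitudes used to scale the optimizer's trust region
PARAM_SCALES: dict[str, float] = {
    "m": 1e-3,
    "g": 0.1,
    "q": 0.5,
    "k": 1e-3,
    "delta": 0.05,
    "mu": 0.5,
    "sigma": 0.5,
}

_BIG_RESIDUAL = 1e8


class ConfigurationError(ValueError):
    """The fit configuration and the data are mutually inconsistent."""


class FitError(RuntimeError):
    """All optimizer starts failed."""


@dataclass(frozen=True)
class FitConfig:
    """Choices that define the objective and the optimizer behaviour.

    error_model
        ``'from_ci'`` derives each observation SD from its 95% CI as
        (ci_high - ci_low)/(2 * 1.96), falling back to ``relative_cv`` when
        the CI is absent; ``'relative_cv'`` uses ``cv * value`` throughout.
    fit_critical_dose
        include critical-dose observations in the least-squares objective
        (default False: they are consumed only by the analytic profiling of
        ``g``).
    g_convention
        ``'profile_from_rcrit'`` solves a(R_crit, d) = 0 for ``g`` at the
        reference critical-dose observation (the one at the lowest dilution
        rate); ``'fixed'`` pins ``g`` at ``g_value``; ``'free'`` optimizes
        ``g`` like any other parameter (required when a dataset has no
        critical-dose observation and no external value for ``g``).
    """

    error_model: str = "from_ci"
    cv: float = 0.1
    fit_critical_dose: bool = False
    g_convention: str = "profile_from_rcrit"
    g_value: float | None = None
    n_starts: int = 16
    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    ftol: float = 1e-12
    xtol: float = 1e-12
    rcrit_tol: float = 1e-6
    rcrit_ceiling: float = 1e5

    def __post_init__(self) -> None:
        if self.error_model not in ("from_ci", "relative_cv"):
            raise ConfigurationError(f"unknown error_model {self.error_model!r}")
        if self.cv <= 0:
            raise ConfigurationError("cv must be > 0")
        if self.g_convention not in ("profile_from_rcrit", "fixed", "free"):
            raise ConfigurationError(f"unknown g_convention {self.g_convention!r}")
        if self.g_convention == "fixed" and self.g_value is None:
            raise ConfigurationError("g_convention='fixed' requires g_value")
        if self.n_starts < 1:
            raise ConfigurationError("n_starts must be >= 1")


def observation_sd(obs: ChemostatObservation, config: FitConfig) -> float:
    """Standard deviation assigned to one observation by the error model."""
    if obs.sd is not None:
        if obs.sd == 0:
            raise ConfigurationError(
                f"zero-variance observation at (R={obs.condition.dose_rate}, "
                f"d={obs.condition.dilution_rate})"
            )
        return obs.sd
    if config.error_model == "from_ci":
        if obs.ci_low is not None:
            width = obs.ci_high - obs.ci_low
            if width == 0:
                raise ConfigurationError(
                    f"zero-variance observation (degenerate CI) at "
                    f"(R={obs.condition.dose_rate}, d={obs.condition.dilution_rate})"
                )
            return width / (2.0 * Z_95)
        logger.warning(
            "observation at (R=%s, d=%s) has no CI; falling back to relative_cv "
            "with cv=%s",
            obs.condition.dose_rate,
            obs.condition.dilution_rate,
            config.cv,
        )
    sd = config.cv * abs(obs.value)
    if sd == 0:
        raise ConfigurationError("zero-variance observation (value is 0)")
    return sd


def profile_g(
    model: GrowthModel,
    free_params: ParameterSet,
    dataset: ChemostatDataset,
    config: FitConfig,
) -> float | None:
    """Analytic value of ``g`` implied by the reference critical-dose datum.

    ``a(R, d)`` is affine in ``g`` for every law that contains it, so the
    persistence boundary condition a(R_crit_obs, d_obs) = 0 has a closed-form
    solution.  Returns ``None`` when the law has no ``g`` (the convention is
    inapplicable).  With several critical-dose observations the one at the
    lowest dilution rate is used.
    """
    if "g" not in model.free_parameters:
        return None
    if config.g_convention == "free":
        raise ConfigurationError("g is freely optimized under g_convention='free'")
    if config.g_convention == "fixed":
        return float(config.g_value)
    critical = dataset.critical_dose
    if not critical:
        raise ConfigurationError(
            "g_convention='profile_from_rcrit' requires at least one "
            "critical_dose observation (or use g_convention='fixed')"
        )
    ref = min(critical, key=lambda o: o.condition.dilution_rate)
    r_obs, d_obs = ref.value, ref.condition.dilution_rate
    p0 = free_params.to_dict()
    a0 = float(model._a({**p0, "g": 0.0}, r_obs, d_obs))
    a1 = float(model._a({**p0, "g": 1.0}, r_obs, d_obs))
    coef = a1 - a0
    if coef == 0:
        raise ConfigurationError(
            f"model {model.model_id}: a(R, d) does not depend on g"
        )
    return -a0 / coef


def _predict_one(
    model: GrowthModel,
    params: ParameterSet,
    obs: ChemostatObservation,
    config: FitConfig,
) -> float:
    if obs.kind == "equilibrium":
        return model.equilibrium(params, obs.condition).n_eq
    res = model.critical_dose_rate(
        params,
        obs.condition.dilution_rate,
        tol=config.rcrit_tol,
        ceiling=config.rcrit_ceiling,
    )
    return res.r_crit


def negative_log_likelihood(
    model: GrowthModel,
    params: ParameterSet,
    dataset: ChemostatDataset,
    config: FitConfig | None = None,
) -> float:
    """-2 ln L up to an additive constant: sum of squared weighted residuals.

    Equilibrium rows always contribute; critical-dose rows contribute only
    when ``config.fit_critical_dose``.  Non-finite predictions yield +inf.
    """
    config = config or FitConfig()
    total = 0.0
    for obs in _fitted_observations(dataset, config):
        sd = observation_sd(obs, config)
        if math.isinf(sd):
            continue
        try:
            pred = _predict_one(model, params, obs, config)
        except InvalidParameterError:
            return math.inf
        if not math.isfinite(pred):
            return math.inf
        total += ((obs.value - pred) / sd) ** 2
    return total


def _fitted_observations(
    dataset: ChemostatDataset, config: FitConfig
) -> list[ChemostatObservation]:
    obs = list(dataset.equilibrium)
    if config.fit_critical_dose:
        obs += dataset.critical_dose
    return obs


def aicc(neg2loglik: float, p_free: int, n_obs: int) -> float:
    """Small-sample corrected AIC: -2lnL + 2p + 2p(p+1)/(n-p-1)."""
    if n_obs - p_free - 1 <= 0:
        raise ValueError(
            f"AICc undefined: need n_obs > p_free + 1 (n_obs={n_obs}, p_free={p_free})"
        )
    return neg2loglik + 2 * p_free + 2 * p_free * (p_free + 1) / (n_obs - p_free - 1)


# ---------------------------------------------------------------------------
# Single-model fit
# ---------------------------------------------------------------------------


class ChemostatGrowthModel:
    """Weighted least-squares fit of one growth law to chemostat data.

    Parameters
    ----------
    dataset : ChemostatDataset
        Equilibrium (and optionally critical-dose) observations.
    model : str or GrowthModel
        Which rate law to fit (default the full killing+suppression law M1).
    config : FitConfig, optional
        Objective and optimizer settings.

    Examples
    --------
    >>> mod = ChemostatGrowthModel(dataset, "M1")
    >>> res = mod.fit(seed=1)
    >>> res.params.k, res.aicc  # doctest: +SKIP
    """

    def __init__(
        self,
        dataset: ChemostatDataset,
        model: str | GrowthModel = "M1",
        config: FitConfig | None = None,
    ) -> None:
        self.model = get_model(model) if isinstance(model, str) else model
        self.config = config or FitConfig()
        self.dataset = dataset

        self._obs = _fitted_observations(dataset, self.config)
        self._sds = np.array([observation_sd(o, self.config) for o in self._obs])
        self._values = np.array([o.value for o in self._obs])

        self._profiles_g = (
            "g" in self.model.free_parameters and self.config.g_convention != "free"
        )
        self.free_names: tuple[str, ...] = tuple(
            name
            for name in self.model.free_parameters
            if not (name == "g" and self._profiles_g)
        )
        if self._profiles_g and self.config.g_convention == "profile_from_rcrit":
            if not dataset.critical_dose:
                raise ConfigurationError(
                    f"model {self.model.model_id}: profiling g requires a "
                    "critical_dose observation (or a fixed g)"
                )
        self.n_obs = len(self._obs)
        self.p_free = len(self.free_names)
        if self.n_obs <= self.p_free + 1:
            raise ValueError(
                f"model {self.model.model_id}: need n_obs > p_free + 1 "
                f"(n_obs={self.n_obs}, p_free={self.p_free})"
            )
        self._lb = np.array([self.config.bounds[n][0] for n in self.free_names])
        self._ub = np.array([self.config.bounds[n][1] for n in self.free_names])
        self._scales = np.array([PARAM_SCALES[n] for n in self.free_names])

    # -- objective -----------------------------------------------------------

    def _resolve(self, theta: np.ndarray) -> ParameterSet | None:
        values = dict(zip(self.free_names, (float(v) for v in theta)))
        params = ParameterSet.from_dict(values)
        if self._profiles_g:
            g = profile_g(self.model, params, self.dataset, self.config)
            if g is None or g < 0 or not math.isfinite(g):
                return None
            params = params.replace(g=g)
        return params

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        params = self._resolve(theta)
        if params is None:
            return np.full(self.n_obs, _BIG_RESIDUAL)
        out = np.empty(self.n_obs)
        for i, obs in enumerate(self._obs):
            if math.isinf(self._sds[i]):
                out[i] = 0.0
                continue
            try:
                pred = _predict_one(self.model, params, obs, self.config)
            except InvalidParameterError:
                return np.full(self.n_obs, _BIG_RESIDUAL)
            if not math.isfinite(pred):
                return np.full(self.n_obs, _BIG_RESIDUAL)
            out[i] = (obs.value - pred) / self._sds[i]
        return out

    # -- optimisation --------------------------------------------------------

    def _starts(self, seed: int, n_starts: int) -> np.ndarray:
        """Deterministic characteristic-scale start plus seeded LHS starts.

        The Latin-hypercube sample is drawn log-uniformly within the bounds
        (zero lower bounds are floored at 1e-5 of the upper bound) because the
        parameters span several orders of magnitude.
        """
        first = np.clip(self._scales, self._lb, self._ub)
        if n_starts == 1:
            return first[None, :]
        sampler = qmc.LatinHypercube(d=self.p_free, seed=seed)
        unit = sampler.random(n=n_starts - 1)
        log_lo = np.log(np.maximum(self._lb, 1e-5 * self._ub))
        log_hi = np.log(self._ub)
        lhs = np.exp(qmc.scale(unit, log_lo, log_hi))
        return np.vstack([first, np.clip(lhs, self._lb, self._ub)])

    def fit(
        self,
        seed: int = 0,
        n_starts: int | None = None,
        x0: Sequence[float] | None = None,
    ) -> "ChemostatFitResults":
        """Minimise the weighted objective from multiple seeded starts.

        ``x0`` replaces the multi-start scheme by a single warm start (used by
        the bootstrap).  Deterministic for a given (dataset, config, seed).
        """
        if x0 is not None:
            starts = np.asarray(x0, dtype=float)[None, :]
        else:
            starts = self._starts(seed, n_starts or self.config.n_starts)
        best_theta = None
        best_cost = math.inf
        failures: list[str] = []
        for start in starts:
            try:
                sol = least_squares(
                    self._residuals,
                    np.clip(start, self._lb, self._ub),
                    bounds=(self._lb, self._ub),
                    method="trf",
                    x_scale=self._scales,
                    ftol=self.config.ftol,
                    xtol=self.config.xtol,
                    gtol=1e-12,
                    max_nfev=400 * max(self.p_free, 1),
                )
            except Exception as exc:  # pragma: no cover - optimizer edge case
                failures.append(str(exc))
                continue
            if not np.all(np.isfinite(sol.x)):
                failures.append("non-finite solution")
                continue
            cost = 2.0 * sol.cost  # sum of squared residuals
            if cost < best_cost - 1e-9 or (
                abs(cost - best_cost) <= 1e-9
                and best_theta is not None
                and tuple(sol.x) < tuple(best_theta)
            ):
                best_cost, best_theta = cost, sol.x
        if best_theta is None:
            raise FitError(
                f"model {self.model.model_id}: all {len(starts)} optimizer starts "
                f"failed: {failures}"
            )
        params = self._resolve(best_theta)
        if params is None:
            raise FitError(
                f"model {self.model.model_id}: optimum has infeasible profiled g"
            )
        return ChemostatFitResults(
            model=self.model,
            params=params,
            g_value=params.g if self._profiles_g else None,
            theta=np.asarray(best_theta, dtype=float),
            free_names=self.free_names,
            neg2loglik=float(best_cost),
            n_obs=self.n_obs,
            p_free=self.p_free,
            config=self.config,
            dataset=self.dataset,
            seed=seed,
        )


@dataclass
class ChemostatFitResults:
    """Best-fit parameters and information-criterion bookkeeping for one law."""

    model: GrowthModel
    params: ParameterSet
    g_value: float | None
    theta: np.ndarray
    free_names: tuple[str, ...]
    neg2loglik: float
    n_obs: int
    p_free: int
    config: FitConfig
    dataset: ChemostatDataset
    seed: int

    @property
    def model_id(self) -> str:
        return self.model.model_id

    @property
    def aicc(self) -> float:
        return aicc(self.neg2loglik, self.p_free, self.n_obs)

    # -- predictions ---------------------------------------------------------

    def predict_equilibrium(
        self, dose_rates: Sequence[float], dilution_rate: float
    ) -> np.ndarray:
        """Signed equilibrium concentration over a dose-rate grid."""
        return np.array(
            [
                self.model.equilibrium(
                    self.params, ChemostatCondition(r, dilution_rate)
                ).n_eq
                for r in dose_rates
            ]
        )

    def rcrit(self, dilution_rate: float) -> CriticalDoseResult:
        return self.model.critical_dose_rate(
            self.params,
            dilution_rate,
            tol=self.config.rcrit_tol,
            ceiling=self.config.rcrit_ceiling,
        )

    def predict_rcrit(self, dilution_rates: Sequence[float]) -> np.ndarray:
        return np.array([self.rcrit(d).r_crit for d in dilution_rates])

    # -- uncertainty / sensitivity -------------------------------------------

    def bootstrap(self, n_replicates: int = 1000, seed: int = 0, **kw) -> "BootstrapSummary":
        return parametric_bootstrap(self, n_replicates=n_replicates, seed=seed, **kw)

    def sensitivity_rcrit(
        self, d_grid: Sequence[float], perturbation: float = 0.10, **kw
    ) -> pd.DataFrame:
        return sensitivity_rcrit(
            self.model, self.params, d_grid, perturbation=perturbation, **kw
        )

    def summary(self) -> str:
        lines = [
            f"Chemostat growth model fit: {self.model_id}",
            f"  {self.model.description}",
            f"  (dN/dt)/N = {self.model.expression}",
            f"  n_obs = {self.n_obs}, p_free = {self.p_free}, "
            f"-2lnL = {self.neg2loglik:.4f}, AICc = {self.aicc:.4f}",
            "  parameters:",
        ]
        for name in self.model.free_parameters:
            value = getattr(self.params, name)
            tag = "profiled" if (name == "g" and self.g_value is not None) else "free"
            if name == "g" and self.config.g_convention == "fixed":
                tag = "fixed"
            lines.append(f"    {name:>6} = {value:.6g}  ({tag})")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Selection table / multimodel inference
# ---------------------------------------------------------------------------


class SelectionTable:
    """Per-model AICc ranking with Akaike weights.

    Rows are sorted by increasing ΔAICc; weights are
    exp(-Δ_i/2) / Σ_j exp(-Δ_j/2) and always sum to one.
    """

    def __init__(self, df: pd.DataFrame) -> None:
        required = {"model_id", "delta_aicc", "weight"}
        if not required <= set(df.columns):
            raise ValueError(f"selection table needs columns {sorted(required)}")
        df = df.sort_values("delta_aicc", kind="stable").reset_index(drop=True)
        df["weight"] = df["weight"] / df["weight"].sum()
        self.df = df

    @classmethod
    def from_fits(cls, fits: Iterable[ChemostatFitResults]) -> "SelectionTable":
        fits = list(fits)
        if not fits:
            raise ValueError("at least one fit required")
        rows = pd.DataFrame(
            {
                "model_id": [f.model_id for f in fits],
                "description": [f.model.description for f in fits],
                "expression": [f.model.expression for f in fits],
                "aicc": [f.aicc for f in fits],
            }
        )
        return cls._finish(rows)

    @classmethod
    def from_aicc(cls, aicc_by_model: Mapping[str, float]) -> "SelectionTable":
        rows = pd.DataFrame(
            {"model_id": list(aicc_by_model), "aicc": list(aicc_by_model.values())}
        )
        return cls._finish(rows)

    @classmethod
    def from_delta_aicc(cls, deltas: Mapping[str, float]) -> "SelectionTable":
        """Build from ΔAICc values (recomputing weights)."""
        rows = pd.DataFrame(
            {"model_id": list(deltas), "aicc": list(deltas.values())}
        )
        return cls._finish(rows)

    @classmethod
    def from_weights(
        cls, table: Mapping[str, tuple[float, float]]
    ) -> "SelectionTable":
        """Build from externally reported (ΔAICc, weight) pairs.

        Weights are renormalized to sum to one (reported tables are rounded).
        """
        df = pd.DataFrame(
            {
                "model_id": list(table),
                "delta_aicc": [v[0] for v in table.values()],
                "weight": [v[1] for v in table.values()],
            }
        )
        return cls(df)

    @classmethod
    def _finish(cls, rows: pd.DataFrame) -> "SelectionTable":
        rows = rows.copy()
        rows["delta_aicc"] = rows["aicc"] - rows["aicc"].min()
        rel = np.exp(-rows["delta_aicc"] / 2.0)
        rows["weight"] = rel / rel.sum()
        return cls(rows)

    # -- queries -------------------------------------------------------------

    @property
    def model_ids(self) -> list[str]:
        return list(self.df["model_id"])

    @property
    def best_model(self) -> str:
        return self.df["model_id"].iloc[0]

    def weight(self, model_id: str) -> float:
        row = self.df[self.df["model_id"] == model_id]
        if row.empty:
            raise KeyError(f"model {model_id!r} not in selection table")
        return float(row["weight"].iloc[0])

    def delta(self, model_id: str) -> float:
        row = self.df[self.df["model_id"] == model_id]
        if row.empty:
            raise KeyError(f"model {model_id!r} not in selection table")
        return float(row["delta_aicc"].iloc[0])

    def evidence_sum(self, model_ids: Iterable[str]) -> float:
        """Summed Akaike weight of a set of models (evidence for a mechanism)."""
        return float(sum(self.weight(mid) for mid in model_ids))

    def confidence_set(self, delta_threshold: float = 6.0) -> list[str]:
        """Models with ΔAICc below the threshold; always contains the best."""
        ids = list(self.df.loc[self.df["delta_aicc"] < delta_threshold, "model_id"])
        if not ids:
            ids = [self.best_model]
        return ids

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        with pd.option_context("display.float_format", "{:.3f}".format):
            return self.df.to_string(index=False)


@dataclass
class ModelSelectionResults:
    """Fits of a family of growth laws plus their AICc ranking."""

    fits: dict[str, ChemostatFitResults]
    table: SelectionTable
    failed: dict[str, str]

    @property
    def best(self) -> ChemostatFitResults:
        return self.fits[self.table.best_model]

    def mmi_predict(
        self,
        quantity: str,
        grid: Sequence[float],
        *,
        dilution_rate: float | None = None,
        delta_threshold: float = 6.0,
    ) -> np.ndarray:
        """Akaike-weighted average prediction over the confidence set.

        ``quantity='equilibrium'`` predicts N_eq over a dose-rate ``grid`` at
        the given ``dilution_rate``; ``quantity='critical_dose'`` predicts
        R_crit over a dilution-rate ``grid``.  Weights are renormalized within
        the confidence set; a no-extinction sentinel enters the average as the
        configured dose-rate ceiling (with a warning).
        """
        ids = self.table.confidence_set(delta_threshold)
        weights = np.array([self.table.weight(mid) for mid in ids])
        weights = weights / weights.sum()
        preds = []
        for mid in ids:
            fit = self.fits[mid]
            if quantity == "equilibrium":
                if dilution_rate is None:
                    raise ValueError("equilibrium MMI needs dilution_rate")
                preds.append(fit.predict_equilibrium(grid, dilution_rate))
            elif quantity == "critical_dose":
                values = fit.predict_rcrit(grid)
                if np.isinf(values).any():
                    warnings.warn(
                        f"model {mid} predicts no extinction on part of the grid; "
                        f"using the dose-rate ceiling "
                        f"{fit.config.rcrit_ceiling} Gy/h in the MMI average"
                    )
                    values = np.where(
                        np.isinf(values), fit.config.rcrit_ceiling, values
                    )
                preds.append(values)
            else:
                raise ValueError(f"unknown quantity {quantity!r}")
        return np.tensordot(weights, np.vstack(preds), axes=1)


def fit_all_models(
    dataset: ChemostatDataset,
    models: Sequence[str | GrowthModel] | str = "all",
    config: FitConfig | None = None,
    seed: int = 0,
    n_starts: int | None = None,
) -> ModelSelectionResults:
    """Fit every requested growth law and rank by AICc.

    Laws whose fit is structurally impossible on this dataset (too few
    observations for their parameter count, or a failed optimisation) are
    recorded in ``.failed`` and skipped.
    """
    config = config or FitConfig()
    if models == "all":
        candidates: list[GrowthModel] = list_models()
    else:
        candidates = [get_model(m) if isinstance(m, str) else m for m in models]
    fits: dict[str, ChemostatFitResults] = {}
    failed: dict[str, str] = {}
    for model in candidates:
        try:
            fits[model.model_id] = ChemostatGrowthModel(
                dataset, model, config
            ).fit(seed=seed, n_starts=n_starts)
        except (ValueError, FitError, ConfigurationError) as exc:
            failed[model.model_id] = str(exc)
            logger.warning("model %s not fitted: %s", model.model_id, exc)
    if not fits:
        raise FitError(f"no model could be fitted: {failed}")
    return ModelSelectionResults(
        fits=fits, table=SelectionTable.from_fits(fits.values()), failed=failed
    )


# ---------------------------------------------------------------------------
# Parametric bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapSummary:
    """Percentile confidence intervals from parametric-bootstrap refits."""

    draws: pd.DataFrame  # replicate x parameter (includes profiled g)
    param_ci: pd.DataFrame  # parameter x (ci_low, estimate, ci_high)
    prediction_ci: dict[str, pd.DataFrame]
    n_replicates: int
    n_failed: int
    seed: int

    def param_correlations(self) -> pd.DataFrame:
        """Pearson correlation matrix of the bootstrap parameter draws."""
        return self.draws.corr()


def _redraw_dataset(
    dataset: ChemostatDataset,
    scales: Mapping[int, float],
    rng: np.random.Generator,
) -> ChemostatDataset:
    new_obs = []
    for i, obs in enumerate(dataset.observations):
        scale = scales[i]
        if scale == 0 or math.isinf(scale):
            value = obs.value
        else:
            # normal around the observed value, truncated at zero
            a = (0.0 - obs.value) / scale
            value = float(
                truncnorm.rvs(a, np.inf, loc=obs.value, scale=scale, random_state=rng)
            )
            if obs.kind == "critical_dose" and value <= 0:
                value = obs.value * 1e-6
        changes: dict = {"value": value}
        if obs.ci_low is not None:
            # keep the CI half-widths (hence the derived SD) of the original
            changes["ci_low"] = value - (obs.value - obs.ci_low)
            changes["ci_high"] = value + (obs.ci_high - obs.value)
        new_obs.append(replace(obs, **changes))
    return ChemostatDataset(new_obs, label=dataset.label)


def parametric_bootstrap(
    results: ChemostatFitResults,
    n_replicates: int = 1000,
    seed: int = 0,
    *,
    equilibrium_grid: Sequence[float] | None = None,
    equilibrium_dilution: float | None = None,
    rcrit_grid: Sequence[float] | None = None,
    redraw_scales: Mapping[int, float] | float | None = None,
    max_failure_fraction: float = 0.20,
    alpha: float = 0.05,
) -> BootstrapSummary:
    """Monte-Carlo uncertainty for a fitted law.

    Every observation (including the critical-dose data consumed by the ``g``
    profiling) is redrawn from Normal(value, sd) truncated at zero, the model
    is refitted from the base optimum (warm start), and 2.5/97.5 percentile
    intervals are formed for parameters and, optionally, prediction grids.
    Reproducible for a given seed.  ``redraw_scales`` overrides the
    per-observation SDs (a scalar applies to all observations).
    """
    rng = np.random.default_rng(seed)
    base = results
    dataset = base.dataset
    config = base.config
    if redraw_scales is None:
        scales = {}
        for i, obs in enumerate(dataset.observations):
            try:
                scales[i] = observation_sd(obs, config)
            except ConfigurationError:
                scales[i] = 0.0
    elif np.isscalar(redraw_scales):
        scales = {i: float(redraw_scales) for i in range(len(dataset.observations))}
    else:
        scales = dict(redraw_scales)

    param_names = list(base.free_names) + (["g"] if base.g_value is not None else [])
    draws: list[dict[str, float]] = []
    pred_eq: list[np.ndarray] = []
    pred_rc: list[np.ndarray] = []
    n_failed = 0
    failures: list[str] = []
    for _ in range(n_replicates):
        replicate = _redraw_dataset(dataset, scales, rng)
        try:
            fit = ChemostatGrowthModel(replicate, base.model, config).fit(
                x0=base.theta
            )
        except (FitError, ValueError, ConfigurationError) as exc:
            n_failed += 1
            failures.append(str(exc))
            continue
        row = {n: getattr(fit.params, n) for n in base.free_names}
        if base.g_value is not None:
            row["g"] = fit.params.g
        draws.append(row)
        if equilibrium_grid is not None:
            pred_eq.append(
                fit.predict_equilibrium(equilibrium_grid, equilibrium_dilution)
            )
        if rcrit_grid is not None:
            pred_rc.append(fit.predict_rcrit(rcrit_grid))
    if n_failed > max_failure_fraction * n_replicates:
        raise FitError(
            f"{n_failed}/{n_replicates} bootstrap refits failed; examples: "
            f"{failures[:5]}"
        )
    draws_df = pd.DataFrame(draws, columns=param_names)
    lo_q, hi_q = 100 * alpha / 2, 100 * (1 - alpha / 2)
    estimates = {n: getattr(base.params, n) for n in param_names}
    param_ci = pd.DataFrame(
        {
            "ci_low": draws_df.quantile(lo_q / 100.0),
            "estimate": pd.Series(estimates),
            "ci_high": draws_df.quantile(hi_q / 100.0),
        }
    )
    prediction_ci: dict[str, pd.DataFrame] = {}
    if pred_eq:
        arr = np.vstack(pred_eq)
        prediction_ci["equilibrium"] = pd.DataFrame(
            {
                "dose_rate_gy_per_h": np.asarray(equilibrium_grid, dtype=float),
                "ci_low": np.percentile(arr, lo_q, axis=0),
                "estimate": base.predict_equilibrium(
                    equilibrium_grid, equilibrium_dilution
                ),
                "ci_high": np.percentile(arr, hi_q, axis=0),
            }
        )
    if pred_rc:
        arr = np.vstack(pred_rc)
        finite_ceiling = base.config.rcrit_ceiling
        arr = np.where(np.isinf(arr), finite_ceiling, arr)
        prediction_ci["critical_dose"] = pd.DataFrame(
            {
                "dilution_rate_per_h": np.asarray(rcrit_grid, dtype=float),
                "ci_low": np.percentile(arr, lo_q, axis=0),
                "estimate": base.predict_rcrit(rcrit_grid),
                "ci_high": np.percentile(arr, hi_q, axis=0),
            }
        )
    return BootstrapSummary(
        draws=draws_df,
        param_ci=param_ci,
        prediction_ci=prediction_ci,
        n_replicates=n_replicates,
        n_failed=n_failed,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Sensitivity and derived summaries
# ---------------------------------------------------------------------------


def sensitivity_rcrit(
    model: GrowthModel,
    params: ParameterSet,
    d_grid: Sequence[float],
    perturbation: float = 0.10,
    parameters: Sequence[str] | None = None,
    *,
    ceiling: float = 1e5,
) -> pd.DataFrame:
    """Ratio of R_crit after a one-at-a-time parameter increase to baseline.

    For each dilution rate in ``d_grid`` and each parameter (default: the
    proliferation/killing parameters g, q, delta, k that the law contains),
    one parameter is multiplied by (1 + perturbation) with all others held at
    their supplied values.  Grid points where the population is extinct even
    without radiation yield NaN.
    """
    if parameters is None:
        parameters = [
            p for p in ("g", "q", "delta", "k") if p in model.free_parameters
        ]
    rows = {}
    baseline = np.array(
        [model.critical_dose_rate(params, d, ceiling=ceiling).r_crit for d in d_grid]
    )
    undefined = np.array(
        [
            model.critical_dose_rate(params, d, ceiling=ceiling).extinct_without_radiation
            for d in d_grid
        ]
    )
    for name in parameters:
        perturbed = params.perturbed(name, 1.0 + perturbation)
        values = np.array(
            [
                model.critical_dose_rate(perturbed, d, ceiling=ceiling).r_crit
                for d in d_grid
            ]
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = values / baseline
        ratio[undefined] = np.nan
        rows[name] = ratio
    out = pd.DataFrame(rows, index=pd.Index(np.asarray(d_grid, float), name="dilution_rate_per_h"))
    return out


@dataclass(frozen=True)
class RcritFoldDrop:
    """How much the extinction threshold collapses under an added stressor."""

    fold: float
    d_reference: float
    rcrit_baseline: float
    rcrit_at_reference: float


def rcrit_fold_drop(
    model: GrowthModel,
    params: ParameterSet,
    *,
    baseline_d: float = 0.0,
    equilibrium_factor: float = 2.0,
    ceiling: float = 1e5,
) -> RcritFoldDrop:
    """Fold-decrease of R_crit at the dilution rate that halves N_eq.

    Finds the dilution rate at which the unirradiated equilibrium
    concentration drops by ``equilibrium_factor`` relative to ``baseline_d``,
    then reports R_crit(baseline) / R_crit(at that dilution rate).
    """
    cond0 = ChemostatCondition(0.0, baseline_d)
    n0 = model.equilibrium(params, cond0).n_eq
    if n0 <= 0:
        raise InvalidParameterError("population extinct at the baseline dilution rate")
    target = n0 / equilibrium_factor

    def gap(d: float) -> float:
        return model.equilibrium(params, ChemostatCondition(0.0, d)).n_eq - target

    d_hi = max(baseline_d, 1e-3)
    for _ in range(80):
        if gap(d_hi) < 0:
            break
        d_hi *= 2.0
    else:
        raise RuntimeError("could not bracket the reference dilution rate")
    d_ref = brentq(gap, baseline_d, d_hi, xtol=1e-10)
    r0 = model.critical_dose_rate(params, baseline_d, ceiling=ceiling).r_crit
    r_ref = model.critical_dose_rate(params, d_ref, ceiling=ceiling).r_crit
    if r_ref == 0:
        raise RuntimeError("population extinct without radiation at the reference d")
    return RcritFoldDrop(
        fold=r0 / r_ref,
        d_reference=float(d_ref),
        rcrit_baseline=r0,
        rcrit_at_reference=r_ref,
    )
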