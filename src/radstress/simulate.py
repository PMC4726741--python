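"""Synthetic-data generators for every analysis stage.

Three generators emulate the statistical structure of the three kinds of
inputs the package analyses:

* steady-state chemostat measurements — equilibrium concentrations and
  critical dose rates computed from a chosen true growth law, perturbed by
  multiplicative measurement noise (truncated normal by default, lognormal
  behind a flag), with 95% CI fields derived from the true SD so the fitting
  error model recovers the generating noise level;
* binary species x sample incidence — Bernoulli detections from a logistic
  model with a fixed exposure effect plus normal random intercepts and slopes
  per species (the data-generating form of a logistic GLMM);
* correlated log-normal contaminant profiles — multivariate normal on the log
  scale with a prescribed correlation matrix, optionally driving per-taxon
  presence outcomes through a logistic link.

Every generator is bit-reproducible given its seed and returns a truth record
sufficient to score recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import ChemostatDataset, ChemostatObservation, IncidenceMatrix
from .growth import ChemostatCondition, ParameterSet, get_model

__all__ = [
    "ChemostatDesign",
    "IncidenceDesign",
    "ContaminantDesign",
    "generate_chemostat_dataset",
    "generate_incidence",
    "generate_contaminants",
    "DEFAULT_TRUE_PARAMS",
]

Z_95 = 1.959963984540054

#: default truth for the chemostat generator: the reported best-fit law M1
#: coefficients for chronically gamma-irradiated budding yeast (k, delta, q, m)
#: completed with a baseline proliferation component g = 0.1 h^-1.
DEFAULT_TRUE_PARAMS = ParameterSet(
    m=2.11e-3, g=0.1, q=0.599, k=5.78e-4, delta=4.78e-2
)


@dataclass(frozen=True)
class ChemostatDesign:
    """Design of a simulated steady-state chemostat experiment.

    The default grids mimic the scale of the yeast chemostat study: dose
    rates from 0 to ~100 Gy/h crossed with sub-washout dilution rates, one
    observation per condition, ~5% multiplicative measurement noise.
    """

    model_id: str = "M1"
    params: ParameterSet = DEFAULT_TRUE_PARAMS
    dose_rates: tuple[float, ...] = (0.0, 5.0, 10.0, 20.0, 40.0, 60.0, 80.0)
    dilution_rates: tuple[float, ...] = (0.05, 0.2)
    noise_cv: float = 0.05
    noise_model: str = "truncated_normal"  # or "lognormal"
    n_critical_obs: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.dose_rates or not self.dilution_rates:
            raise ValueError("dose-rate and dilution-rate grids must be nonempty")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.noise_model not in ("truncated_normal", "lognormal"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.n_critical_obs > len(self.dilution_rates):
            raise ValueError("n_critical_obs exceeds the number of dilution rates")


def _noisy(value: float, cv: float, model: str, rng: np.random.Generator) -> float:
    if cv == 0:
        return value
    sd = cv * value
    if model == "lognormal":
        sigma = math.sqrt(math.log(1.0 + cv**2))
        return float(value * rng.lognormal(-0.5 * sigma**2, sigma))
    a = (0.0 - value) / sd
    return float(
        stats.truncnorm.rvs(a, np.inf, loc=value, scale=sd, random_state=rng)
    )


def generate_chemostat_dataset(
    design: ChemostatDesign,
) -> tuple[ChemostatDataset, dict]:
    """Simulate one chemostat experiment; returns (dataset, truth record).

    Equilibrium observations are generated at every (R, d) grid point where
    the true law predicts persistence (a > 0); grid points predicting
    extinction are skipped, as they would be in a real steady-state assay.
    Critical-dose observations are generated at the ``n_critical_obs`` lowest
    dilution rates.  CI fields are value +/- 1.96 * cv * truth so that a
    CI-derived SD matches the generating noise exactly; at ``noise_cv=0`` the
    CI fields are omitted.
    """
    model = get_model(design.model_id)
    rng = np.random.default_rng(design.seed)
    observations: list[ChemostatObservation] = []
    truth_rows: list[dict] = []
    for d in design.dilution_rates:
        for r in design.dose_rates:
            cond = ChemostatCondition(r, d)
            eq = model.equilibrium(design.params, cond)
            if eq.extinct:
                continue
            value = _noisy(eq.n_eq, design.noise_cv, design.noise_model, rng)
            half = Z_95 * design.noise_cv * eq.n_eq
            observations.append(
                ChemostatObservation(
                    kind="equilibrium",
                    condition=cond,
                    value=value,
                    ci_low=None if half == 0 else value - half,
                    ci_high=None if half == 0 else value + half,
                )
            )
            truth_rows.append(
                {"kind": "equilibrium", "dose_rate": r, "dilution_rate": d,
                 "truth": eq.n_eq, "observed": value}
            )
    if not observations:
        raise ValueError("all grid points are extinct under the true parameters")
    for d in sorted(design.dilution_rates)[: design.n_critical_obs]:
        rc = model.critical_dose_rate(design.params, d)
        if rc.extinct_without_radiation or rc.no_extinction:
            continue
        value = _noisy(rc.r_crit, design.noise_cv, design.noise_model, rng)
        half = Z_95 * design.noise_cv * rc.r_crit
        observations.append(
            ChemostatObservation(
                kind="critical_dose",
                condition=ChemostatCondition(0.0, d),
                value=value,
                ci_low=None if half == 0 else value - half,
                ci_high=None if half == 0 else value + half,
            )
        )
        truth_rows.append(
            {"kind": "critical_dose", "dose_rate": np.nan, "dilution_rate": d,
             "truth": rc.r_crit, "observed": value}
        )
    truth = {
        "model_id": design.model_id,
        "params": design.params.to_dict(),
        "noise_cv": design.noise_cv,
        "seed": design.seed,
        "observations": pd.DataFrame(truth_rows),
    }
    return ChemostatDataset(observations, label=f"synthetic-{design.model_id}"), truth


# ---------------------------------------------------------------------------
# Incidence generator (logistic mixed-effects data-generating process)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IncidenceDesign:
    """Design for presence/absence detections across two exposure groups.

    For species i in a sample of group x in {0 (reference/low), 1 (exposed/
    high)}, detection probability is
    ``logit^-1(alpha0 + a_i + (beta + b_i) * x)`` with random intercepts
    ``a_i ~ N(0, sd_intercept^2)`` and random slopes ``b_i ~ N(0, sd_slope^2)``.
    Defaults mirror the scale of the reactor-building fungal survey: 37
    species over 15 low- and 9 high-exposure samples.
    """

    n_species: int = 37
    n_samples_low: int = 15
    n_samples_high: int = 9
    alpha0: float = -1.0
    beta: float = 0.35
    sd_intercept: float = 1.0
    sd_slope: float = 1.0
    group_names: tuple[str, str] = ("low", "high")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_low < 1 or self.n_samples_high < 1:
            raise ValueError("each group needs at least one sample")
        if self.sd_intercept < 0 or self.sd_slope < 0:
            raise ValueError("random-effect SDs must be >= 0")


def generate_incidence(design: IncidenceDesign) -> tuple[IncidenceMatrix, pd.DataFrame]:
    """Simulate a binary incidence matrix; returns (matrix, per-species truth)."""
    rng = np.random.default_rng(design.seed)
    low_name, high_name = design.group_names
    species = [f"sp{i + 1:02d}" for i in range(design.n_species)]
    samples = [f"{low_name}_{j + 1:02d}" for j in range(design.n_samples_low)] + [
        f"{high_name}_{j + 1:02d}" for j in range(design.n_samples_high)
    ]
    x = np.array([0] * design.n_samples_low + [1] * design.n_samples_high)
    a_i = rng.normal(0.0, design.sd_intercept, size=design.n_species)
    b_i = rng.normal(0.0, design.sd_slope, size=design.n_species)
    logits = (design.alpha0 + a_i)[:, None] + (design.beta + b_i)[:, None] * x[None, :]
    probs = 1.0 / (1.0 + np.exp(-logits))
    presence = (rng.random(probs.shape) < probs).astype(int)
    matrix = IncidenceMatrix(
        presence=pd.DataFrame(presence, index=species, columns=samples),
        groups=pd.Series([low_name] * design.n_samples_low
                         + [high_name] * design.n_samples_high, index=samples),
    )
    truth = pd.DataFrame(
        {
            "species": species,
            "random_intercept": a_i,
            "random_slope": b_i,
            "p_low": probs[:, 0],
            "p_high": probs[:, -1],
            "true_log_odds_ratio": design.beta + b_i,
        }
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Contaminant generator (correlated log-normal profiles)
# ---------------------------------------------------------------------------

_DEFAULT_VARIABLES = ("cs137", "tc99", "cr", "no3", "no2")

# log-scale correlation structure emulating co-released waste contaminants;
# the Cr-NO2 entry carries the strong co-release correlation of 0.83
_DEFAULT_CORRELATION = np.array(
    [
        [1.00, 0.50, 0.30, 0.30, 0.30],
        [0.50, 1.00, 0.30, 0.30, 0.30],
        [0.30, 0.30, 1.00, 0.55, 0.83],
        [0.30, 0.30, 0.55, 1.00, 0.55],
        [0.30, 0.30, 0.83, 0.55, 1.00],
    ]
)


@dataclass(frozen=True)
class ContaminantDesign:
    """Design for sample x contaminant matrices with log-scale correlation."""

    n_samples: int = 18
    variables: tuple[str, ...] = _DEFAULT_VARIABLES
    log_means: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0, 0.0)
    log_sds: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)
    correlation: np.ndarray = field(
        default_factory=lambda: _DEFAULT_CORRELATION.copy()
    )
    presence_coefficients: Mapping[str, Mapping[str, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        corr = np.asarray(self.correlation, dtype=float)
        p = len(self.variables)
        if corr.shape != (p, p):
            raise ValueError("correlation matrix shape must match variables")
        if not np.allclose(corr, corr.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        eigvals = np.linalg.eigvalsh(corr)
        if eigvals.min() < -1e-10:
            raise ValueError(
                f"correlation matrix is not positive semi-definite "
                f"(min eigenvalue {eigvals.min():.3g})"
            )
        if len(self.log_means) != p or len(self.log_sds) != p:
            raise ValueError("log_means and log_sds must match variables")


def generate_contaminants(
    design: ContaminantDesign,
) -> tuple[pd.DataFrame, dict]:
    """Simulate correlated log-normal contaminant profiles.

    Returns (sample x variable DataFrame, truth record).  When
    ``presence_coefficients`` maps taxon -> {intercept, variable: coef, ...},
    Bernoulli presence outcomes driven by a logistic model on the log-scale
    variables are added to the truth record (and as extra 0/1 columns).
    """
    rng = np.random.default_rng(design.seed)
    p = len(design.variables)
    sds = np.asarray(design.log_sds)
    cov = np.asarray(design.correlation) * np.outer(sds, sds)
    logs = rng.multivariate_normal(
        np.asarray(design.log_means), cov, size=design.n_samples, method="cholesky"
    )
    values = pd.DataFrame(
        np.exp(logs),
        columns=list(design.variables),
        index=[f"sample_{i + 1:02d}" for i in range(design.n_samples)],
    )
    values.index.name = "sample_id"
    truth: dict = {
        "log_values": pd.DataFrame(logs, columns=list(design.variables)),
        "seed": design.seed,
    }
    if design.presence_coefficients:
        outcomes = {}
        for taxon, coefs in design.presence_coefficients.items():
            eta = np.full(design.n_samples, float(coefs.get("intercept", 0.0)))
            for j, name in enumerate(design.variables):
                eta += float(coefs.get(name, 0.0)) * logs[:, j]
            prob = 1.0 / (1.0 + np.exp(-eta))
            outcomes[taxon] = (rng.random(design.n_samples) < prob).astype(int)
            truth[f"presence_prob_{taxon}"] = prob
        for taxon, presence in outcomes.items():
            values[f"present_{taxon}"] = presence
    return values, truth
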