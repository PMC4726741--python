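"""Observation containers and plain-text I/O.

Two kinds of inputs are handled:

* steady-state chemostat observations — equilibrium cell concentrations
  (10^6 cells/ml, with optional 95% CI) measured at combinations of dose rate
  and dilution rate, plus observed critical dose rates (Gy/h) at given
  dilution rates;
* binary species x sample incidence tables with a two-level exposure group
  label (e.g. low vs high dose rate locations).

CSV schemas are fixed, with units embedded in the column names so that
dose rates are always Gy/h and dilution rates always h^-1.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .growth import ChemostatCondition

__all__ = [
    "ChemostatObservation",
    "ChemostatDataset",
    "IncidenceMatrix",
    "read_chemostat_csv",
    "write_chemostat_csv",
    "read_incidence_csv",
    "write_incidence_csv",
]

CHEMOSTAT_COLUMNS = (
    "dose_rate_gy_per_h",
    "dilution_rate_per_h",
    "obs_type",
    "value",
    "ci_low",
    "ci_high",
)

OBS_KINDS = ("equilibrium", "critical_dose")


@dataclass(frozen=True)
class ChemostatObservation:
    """One measured quantity at one chemostat condition.

    ``kind='equilibrium'``: ``value`` is the steady-state cell concentration
    (10^6 cells/ml) at ``condition``.  ``kind='critical_dose'``: ``value`` is
    the observed critical dose rate (Gy/h) at ``condition.dilution_rate``; the
    condition's ``dose_rate`` field is ignored (conventionally 0).
    ``sd``, when set, overrides any error model during fitting; an infinite
    ``sd`` gives the observation zero weight.
    """

    kind: str
    condition: ChemostatCondition
    value: float
    ci_low: float | None = None
    ci_high: float | None = None
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in OBS_KINDS:
            raise ValueError(
                f"observation kind must be one of {OBS_KINDS}, got {self.kind!r}"
            )
        if not math.isfinite(self.value):
            raise ValueError("observation value must be finite")
        if self.kind == "critical_dose" and self.value <= 0:
            raise ValueError(
                f"critical_dose observation value must be > 0, got {self.value!r}"
            )
        if (self.ci_low is None) != (self.ci_high is None):
            raise ValueError("ci_low and ci_high must be given together")
        if self.ci_low is not None:
            if not (self.ci_low <= self.value <= self.ci_high):
                raise ValueError(
                    f"CI ({self.ci_low}, {self.ci_high}) must bracket the "
                    f"value {self.value}"
                )
        if self.sd is not None and self.sd < 0:
            raise ValueError("observation sd must be >= 0")


@dataclass
class ChemostatDataset:
    """A set of chemostat observations with unique (kind, condition) keys."""

    observations: list[ChemostatObservation]
    label: str = ""

    def __post_init__(self) -> None:
        if not any(o.kind == "equilibrium" for o in self.observations):
            raise ValueError("dataset must contain at least one equilibrium observation")
        seen: set[tuple] = set()
        for o in self.observations:
            key = (o.kind, o.condition.dose_rate, o.condition.dilution_rate)
            if key in seen:
                raise ValueError(f"duplicate observation at {key}")
            seen.add(key)

    @property
    def equilibrium(self) -> list[ChemostatObservation]:
        return [o for o in self.observations if o.kind == "equilibrium"]

    @property
    def critical_dose(self) -> list[ChemostatObservation]:
        return [o for o in self.observations if o.kind == "critical_dose"]

    def __len__(self) -> int:
        return len(self.observations)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for o in self.observations:
            rows.append(
                {
                    "dose_rate_gy_per_h": (
                        o.condition.dose_rate if o.kind == "equilibrium" else np.nan
                    ),
                    "dilution_rate_per_h": o.condition.dilution_rate,
                    "obs_type": o.kind,
                    "value": o.value,
                    "ci_low": np.nan if o.ci_low is None else o.ci_low,
                    "ci_high": np.nan if o.ci_high is None else o.ci_high,
                }
            )
        return pd.DataFrame(rows, columns=list(CHEMOSTAT_COLUMNS))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "") -> "ChemostatDataset":
        missing = [c for c in CHEMOSTAT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required column(s): {missing}")
        observations: list[ChemostatObservation] = []
        errors: list[str] = []
        for idx, row in df.iterrows():
            line = idx + 2  # header is line 1
            try:
                kind = str(row["obs_type"])
                dose = row["dose_rate_gy_per_h"]
                if kind == "critical_dose" and (dose is None or pd.isna(dose)):
                    dose = 0.0  # for critical-dose rows the dose rate IS the value
                ci_low = None if pd.isna(row["ci_low"]) else float(row["ci_low"])
                ci_high = None if pd.isna(row["ci_high"]) else float(row["ci_high"])
                observations.append(
                    ChemostatObservation(
                        kind=kind,
                        condition=ChemostatCondition(
                            dose_rate=float(dose),
                            dilution_rate=float(row["dilution_rate_per_h"]),
                        ),
                        value=float(row["value"]),
                        ci_low=ci_low,
                        ci_high=ci_high,
                    )
                )
            except (ValueError, TypeError, KeyError) as exc:
                errors.append(f"line {line}: {exc}")
        if errors:
            raise ValueError("malformed chemostat rows:\n" + "\n".join(errors))
        if not observations:
            raise ValueError("no observations")
        return cls(observations=observations, label=label)


def read_chemostat_csv(path: str | Path) -> ChemostatDataset:
    """Read a chemostat observation table (see :data:`CHEMOSTAT_COLUMNS`)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no observations") from None
    if df.empty:
        raise ValueError(f"{path}: no observations")
    try:
        return ChemostatDataset.from_dataframe(df, label=path.name)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_chemostat_csv(dataset: ChemostatDataset, path: str | Path) -> None:
    dataset.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Incidence data
# ---------------------------------------------------------------------------


@dataclass
class IncidenceMatrix:
    """Binary species x sample detections with a group label per sample.

    ``presence`` is a species-by-sample 0/1 DataFrame; ``groups`` maps each
    sample id to its exposure group (at most two levels for group contrasts).
    """

    presence: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        values = self.presence.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("presence values must be 0 or 1")
        self.presence = self.presence.astype(int)
        if set(self.presence.columns) != set(self.groups.index):
            raise ValueError("groups must be indexed by the sample ids")
        self.groups = self.groups.reindex(self.presence.columns)
        levels = self.group_levels
        if not levels:
            raise ValueError("at least one group level required")
        for level in levels:
            if (self.groups == level).sum() < 1:
                raise ValueError(f"group {level!r} has no samples")

    @property
    def species(self) -> list[str]:
        return list(self.presence.index)

    @property
    def samples(self) -> list[str]:
        return list(self.presence.columns)

    @property
    def group_levels(self) -> list[str]:
        return sorted(self.groups.unique())

    def restrict(self, group: str) -> pd.DataFrame:
        """Presence submatrix of the samples in one group."""
        if group not in set(self.groups):
            raise KeyError(f"unknown group {group!r}")
        cols = self.groups.index[self.groups == group]
        return self.presence[cols]

    def to_long_dataframe(self) -> pd.DataFrame:
        long = (
            self.presence.rename_axis(index="species", columns="sample_id")
            .stack()
            .rename("present")
            .reset_index()
        )
        long["group"] = long["sample_id"].map(self.groups)
        return long[["species", "sample_id", "group", "present"]]

    @classmethod
    def from_long_dataframe(cls, df: pd.DataFrame) -> "IncidenceMatrix":
        required = ["species", "sample_id", "group", "present"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"missing required column(s): {missing}")
        dup_mask = df.duplicated(subset=["species", "sample_id"], keep=False)
        if dup_mask.any():
            rows = [str(i + 2) for i in df.index[dup_mask]]
            raise ValueError(
                "duplicate (species, sample_id) rows at line(s): " + ", ".join(rows)
            )
        present = pd.to_numeric(df["present"], errors="coerce")
        bad = present.isna() | ~present.isin((0, 1))
        if bad.any():
            rows = [str(i + 2) for i in df.index[bad]]
            raise ValueError("non-binary 'present' values at line(s): " + ", ".join(rows))
        groups_per_sample = df.groupby("sample_id")["group"].nunique()
        if (groups_per_sample > 1).any():
            bad_samples = list(groups_per_sample.index[groups_per_sample > 1])
            raise ValueError(f"samples with conflicting group labels: {bad_samples}")
        n_groups = df["group"].nunique()
        if n_groups > 2:
            raise ValueError(
                f"at most two group levels supported, got {sorted(df['group'].unique())}"
            )
        presence = (
            df.assign(present=present.astype(int))
            .pivot(index="species", columns="sample_id", values="present")
            .fillna(0)
            .astype(int)
        )
        groups = df.drop_duplicates("sample_id").set_index("sample_id")["group"]
        return cls(presence=presence, groups=groups)


def read_incidence_csv(path: str | Path) -> IncidenceMatrix:
    """Read a long-form incidence CSV (species, sample_id, group, present)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no observations") from None
    if df.empty:
        raise ValueError(f"{path}: no observations")
    try:
        return IncidenceMatrix.from_long_dataframe(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_incidence_csv(incidence: IncidenceMatrix, path: str | Path) -> None:
    incidence.to_long_dataframe().to_csv(path, index=False)
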