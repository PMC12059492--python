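"""Domain types and file I/O for long-format ICU cohorts.

A cohort consists of three delimited-text tables:

* **events** — one observation per row: ``stay_id, time_h, variable, value``,
  where ``time_h`` is fractional hours since ICU admission (admission = 0).
* **stays** — one ICU stay per row: ``stay_id, patient_id, icu_los_h,
  death_time_h, age_years, sex, race``.  An empty ``death_time_h`` encodes
  survival to hospital discharge; a value larger than ``icu_los_h`` encodes an
  in-hospital death after ICU discharge.
* **dictionary** — one variable per row, the preprocessing contract
  (:class:`VariableSpec`): value type, in-bin aggregation rule, imputation
  rule, global fallback, and (for categoricals) the ordered category labels.

All writers emit UTF-8 with deterministic row order (stay, then time, then
variable) so that identical cohorts produce byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

VTYPES = ("numeric", "categorical")
AGGREGATIONS = ("median", "mode", "sum", "max", "min", "last")
IMPUTATIONS = ("locf", "linear", "none")

EVENT_COLUMNS = ["stay_id", "time_h", "variable", "value"]
STAY_COLUMNS = [
    "stay_id",
    "patient_id",
    "icu_los_h",
    "death_time_h",
    "age_years",
    "sex",
    "race",
]
DICT_COLUMNS = ["name", "vtype", "aggregation", "imputation", "fallback", "categories"]


class DictionaryMismatchError(ValueError):
    """An event references a variable absent from the variable dictionary."""


class CohortTypeError(TypeError):
    """A value is incompatible with its variable's declared type."""


@dataclass(frozen=True)
class VariableSpec:
    """Per-variable preprocessing contract.

    Parameters
    ----------
    name : str
        Variable identifier, matched against the events table.
    vtype : {"numeric", "categorical"}
    aggregation : {"median", "mode", "sum", "max", "min", "last"}
        Rule for collapsing multiple observations inside one hourly bin.
    imputation : {"locf", "linear", "none"}
        Rule for interior gaps.  Categoricals never use ``linear``.
    fallback : float or str, optional
        Global summary used when a stay has zero observations of this
        variable; normally supplied at fit time from the training split
        (median for numeric, mode for categorical).
    categories : tuple of str, optional
        Ordered category labels (categorical only); may include ``"missing"``.
    """

    name: str
    vtype: str
    aggregation: str
    imputation: str
    fallback: object | None = None
    categories: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.vtype not in VTYPES:
            raise ValueError(f"{self.name}: unknown vtype {self.vtype!r}")
        if self.aggregation not in AGGREGATIONS:
            raise ValueError(
                f"{self.name}: unknown aggregation {self.aggregation!r}"
            )
        if self.imputation not in IMPUTATIONS:
            raise ValueError(f"{self.name}: unknown imputation {self.imputation!r}")
        if self.vtype == "numeric" and self.categories is not None:
            raise ValueError(f"{self.name}: numeric variables carry no categories")
        if self.vtype == "categorical":
            if self.imputation == "linear":
                raise ValueError(
                    f"{self.name}: categorical variables never use linear imputation"
                )
            if not self.categories:
                raise ValueError(f"{self.name}: categorical variable needs categories")
            if len(set(self.categories)) != len(self.categories):
                raise ValueError(f"{self.name}: duplicate category labels")


@dataclass(frozen=True)
class StayMeta:
    """Metadata for one ICU stay; ``death_time_h`` of ``None`` means survived."""

    stay_id: str
    patient_id: str
    icu_los_h: float
    death_time_h: float | None
    age_years: int
    sex: str
    race: str

    def __post_init__(self) -> None:
        if self.death_time_h is not None and not self.death_time_h > 0:
            raise ValueError(f"{self.stay_id}: death_time_h must be positive")


@dataclass
class Cohort:
    """A validated bundle of stays, long-format events, and the dictionary.

    ``stays`` and ``events`` are pandas DataFrames with :data:`STAY_COLUMNS`
    and :data:`EVENT_COLUMNS`; ``dictionary`` maps variable name to
    :class:`VariableSpec`.
    """

    stays: pd.DataFrame
    events: pd.DataFrame
    dictionary: dict[str, VariableSpec] = field(default_factory=dict)

    def validate(self) -> None:
        known_stays = set(self.stays["stay_id"])
        bad = set(self.events["stay_id"]) - known_stays
        if bad:
            raise ValueError(f"events reference unknown stay_ids: {sorted(bad)[:5]}")
        unknown_vars = set(self.events["variable"]) - set(self.dictionary)
        if unknown_vars:
            raise DictionaryMismatchError(
                f"events reference variables absent from the dictionary: "
                f"{sorted(unknown_vars)[:5]}"
            )
        if (self.events["time_h"] < 0).any():
            row = self.events[self.events["time_h"] < 0].iloc[0]
            raise ValueError(
                f"negative event time: stay {row.stay_id} at {row.time_h}h"
            )
        deaths = self.stays["death_time_h"]
        if (deaths.dropna() <= 0).any():
            raise ValueError("death_time_h must be positive when present")

    def stay_meta(self, stay_id: str) -> StayMeta:
        row = self.stays.loc[self.stays["stay_id"] == stay_id]
        if row.empty:
            raise KeyError(stay_id)
        r = row.iloc[0]
        dt = None if pd.isna(r.death_time_h) else float(r.death_time_h)
        return StayMeta(
            stay_id=str(r.stay_id),
            patient_id=str(r.patient_id),
            icu_los_h=float(r.icu_los_h),
            death_time_h=dt,
            age_years=int(r.age_years),
            sex=str(r.sex),
            race=str(r.race),
        )

    def events_for(self, stay_id: str) -> pd.DataFrame:
        return self.events[self.events["stay_id"] == stay_id]

    @property
    def n_stays(self) -> int:
        return len(self.stays)


# ---------------------------------------------------------------------------
# dictionary I/O
# ---------------------------------------------------------------------------

def _spec_to_row(spec: VariableSpec) -> dict:
    return {
        "name": spec.name,
        "vtype": spec.vtype,
        "aggregation": spec.aggregation,
        "imputation": spec.imputation,
        "fallback": "" if spec.fallback is None else spec.fallback,
        "categories": "|".join(spec.categories) if spec.categories else "",
    }


def _row_to_spec(row: Mapping) -> VariableSpec:
    fallback = row.get("fallback", "")
    if fallback in ("", None) or (isinstance(fallback, float) and math.isnan(fallback)):
        fallback = None
    elif row["vtype"] == "numeric":
        fallback = float(fallback)
    cats = row.get("categories", "")
    if isinstance(cats, float) and math.isnan(cats):
        cats = ""
    categories = tuple(str(cats).split("|")) if cats else None
    return VariableSpec(
        name=str(row["name"]),
        vtype=str(row["vtype"]),
        aggregation=str(row["aggregation"]),
        imputation=str(row["imputation"]),
        fallback=fallback,
        categories=categories,
    )


def load_dictionary(path: str | Path) -> dict[str, VariableSpec]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(DICT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"dictionary file missing columns {sorted(missing)}")
    specs = {}
    for i, row in df.iterrows():
        try:
            spec = _row_to_spec(row)
        except (ValueError, KeyError) as exc:
            raise ValueError(f"dictionary row {i + 2}: {exc}") from exc
        specs[spec.name] = spec
    return specs


def write_dictionary(specs: Mapping[str, VariableSpec] | Sequence[VariableSpec],
                     path: str | Path) -> None:
    if isinstance(specs, Mapping):
        specs = list(specs.values())
    rows = [_spec_to_row(s) for s in specs]
    pd.DataFrame(rows, columns=DICT_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# cohort I/O
# ---------------------------------------------------------------------------

def load_cohort(events_path: str | Path, stays_path: str | Path,
                dict_path: str | Path) -> Cohort:
    """Read and validate the three cohort files.

    Raises
    ------
    DictionaryMismatchError
        If an event's variable is not in the dictionary.
    CohortTypeError
        If a numeric variable carries a non-numeric value; the message names
        the stay, variable, and time of the offending row.
    """
    dictionary = load_dictionary(dict_path)
    stays = pd.read_csv(stays_path, dtype={"stay_id": str, "patient_id": str})
    missing = set(STAY_COLUMNS) - set(stays.columns)
    if missing:
        raise ValueError(f"stays file missing columns {sorted(missing)}")
    events = pd.read_csv(events_path, dtype={"stay_id": str, "variable": str,
                                             "value": str})
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise ValueError(f"events file missing columns {sorted(missing)}")
    events["time_h"] = events["time_h"].astype(float)

    parsed = np.empty(len(events), dtype=object)
    for i, (var, val, stay, t) in enumerate(
        zip(events["variable"], events["value"], events["stay_id"],
            events["time_h"])
    ):
        spec = dictionary.get(var)
        if spec is None:
            raise DictionaryMismatchError(
                f"row {i + 2}: variable {var!r} absent from dictionary"
            )
        if spec.vtype == "numeric":
            try:
                parsed[i] = float(val)
            except (TypeError, ValueError) as exc:
                raise CohortTypeError(
                    f"row {i + 2}: non-numeric value {val!r} for numeric "
                    f"variable {var!r} (stay {stay}, time {t}h)"
                ) from exc
        else:
            parsed[i] = str(val)
    events["value"] = parsed

    cohort = Cohort(stays=stays, events=events, dictionary=dictionary)
    cohort.validate()
    return cohort


def write_cohort(cohort: Cohort, events_path: str | Path, stays_path: str | Path,
                 dict_path: str | Path) -> None:
    """Write the three cohort files with deterministic row order."""
    stays = cohort.stays.sort_values("stay_id", kind="mergesort")
    stays.to_csv(stays_path, index=False)
    events = cohort.events.sort_values(
        ["stay_id", "time_h", "variable"], kind="mergesort"
    )
    events.to_csv(events_path, index=False)
    write_dictionary(cohort.dictionary, dict_path)


# ---------------------------------------------------------------------------
# eligibility filter
# ---------------------------------------------------------------------------

def filter_eligible(
    cohort: Cohort,
    min_los_h: float = 12.0,
    max_los_d: float = 30.0,
    min_age: int = 18,
    max_age: int = 80,
) -> tuple[Cohort, dict[str, int]]:
    """Apply the cohort eligibility criteria and tally exclusions.

    Retains stays with ``min_los_h <= icu_los_h <= max_los_d * 24`` and
    ``min_age <= age_years <= max_age`` (bounds inclusive on both ends).
    Events of removed stays are dropped.  Returns the filtered cohort and a
    per-criterion tally; a stay failing several criteria is counted under
    each, with ``excluded_total`` giving the unique count.
    """
    stays = cohort.stays
    los = stays["icu_los_h"].astype(float)
    age = stays["age_years"].astype(float)
    too_short = los < min_los_h
    too_long = los > max_los_d * 24.0
    too_young = age < min_age
    too_old = age > max_age
    excluded = too_short | too_long | too_young | too_old

    tally = {
        "los_short": int(too_short.sum()),
        "los_long": int(too_long.sum()),
        "age_low": int(too_young.sum()),
        "age_high": int(too_old.sum()),
        "excluded_total": int(excluded.sum()),
    }
    kept = stays.loc[~excluded].reset_index(drop=True)
    kept_ids = set(kept["stay_id"])
    events = cohort.events[cohort.events["stay_id"].isin(kept_ids)].reset_index(
        drop=True
    )
    return Cohort(stays=kept, events=events, dictionary=dict(cohort.dictionary)), tally


def restrict_variables(cohort: Cohort, variables: Sequence[str]) -> Cohort:
    """Restrict a cohort to a subset of dictionary variables.

    Used by the cross-cohort harness: the transfer model is trained on the
    common-variable subset only, so both cohorts are narrowed to it.
    """
    variables = list(variables)
    unknown = set(variables) - set(cohort.dictionary)
    if unknown:
        raise DictionaryMismatchError(
            f"variables not in dictionary: {sorted(unknown)}"
        )
    if not variables:
        raise ValueError("common variable set is empty")
    dictionary = {v: cohort.dictionary[v] for v in variables}
    events = cohort.events[cohort.events["variable"].isin(set(variables))]
    return Cohort(
        stays=cohort.stays.copy(),
        events=events.reset_index(drop=True),
        dictionary=dictionary,
    )


def update_fallbacks(dictionary: Mapping[str, VariableSpec],
                     fallbacks: Mapping[str, object]) -> dict[str, VariableSpec]:
    """Return a dictionary with training-set fallback summaries filled in."""
    out = {}
    for name, spec in dictionary.items():
        fb = fallbacks.get(name, spec.fallback)
        out[name] = replace(spec, fallback=fb)
    return out
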