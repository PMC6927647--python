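"""Tabular data model for district-year elk survey, harvest and covariate tables.

The analysis works on three comma-separated input tables (UTF-8, header row,
empty cell = missing):

* ``surveys.csv``   -- district, year, total_count, calves, adult_females,
  adult_males.  A row may carry a total count with no classification (the
  three class columns jointly empty).
* ``harvest.csv``   -- district, year, h_calves, h_adult_females,
  h_adult_males.  The harvest series is continuous even when surveys are not.
* ``covariates.csv`` -- district, year, one column per raw covariate.

This module also owns covariate standardization (centre by the mean, divide by
one sample standard deviation), the pairwise-collinearity screen, the design
specification (main effects, one-year lags, pairwise interactions) and the
observed calves:100-adult-females statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DataValidationError",
    "SurveyObservation",
    "HarvestRecord",
    "CovariateTable",
    "Term",
    "DesignSpec",
    "read_survey_table",
    "write_survey_table",
    "read_harvest_table",
    "write_harvest_table",
    "read_covariate_table",
    "standardize",
    "collinearity_screen",
    "observed_age_ratio",
    "build_design_matrix",
    "default_population_design",
    "default_ageratio_design",
]

HARVEST_TERM = "adult_female_harvest"


class DataValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class SurveyObservation:
    """One district-year spring survey: a total count plus an optional
    classified subsample by age/sex class.

    The three class counts are jointly present or jointly missing; when
    present their sum (the classified total) cannot exceed the total count.
    """

    district: str
    year: int
    total_count: int | None
    count_calves: int | None = None
    count_adult_females: int | None = None
    count_adult_males: int | None = None

    def __post_init__(self) -> None:
        cls = (self.count_calves, self.count_adult_females, self.count_adult_males)
        n_missing = sum(c is None for c in cls)
        if n_missing not in (0, 3):
            raise DataValidationError(
                f"{self.district}/{self.year}: classification counts must be "
                "jointly present or jointly missing"
            )
        for name, val in (
            ("total_count", self.total_count),
            ("calves", self.count_calves),
            ("adult_females", self.count_adult_females),
            ("adult_males", self.count_adult_males),
        ):
            if val is not None and val < 0:
                raise DataValidationError(
                    f"{self.district}/{self.year}: negative {name} ({val})"
                )
        if self.has_classification and self.total_count is not None:
            if self.classified_total > self.total_count:
                raise DataValidationError(
                    f"{self.district}/{self.year}: classified total "
                    f"{self.classified_total} exceeds total count {self.total_count}"
                )

    @property
    def has_classification(self) -> bool:
        return self.count_calves is not None

    @property
    def classified_total(self) -> int | None:
        if not self.has_classification:
            return None
        return self.count_calves + self.count_adult_females + self.count_adult_males


@dataclass(frozen=True)
class HarvestRecord:
    """Estimated fall harvest for one district-year, by age/sex class."""

    district: str
    year: int
    h_calves: int
    h_adult_females: int
    h_adult_males: int

    def __post_init__(self) -> None:
        for name in ("h_calves", "h_adult_females", "h_adult_males"):
            if getattr(self, name) < 0:
                raise DataValidationError(
                    f"{self.district}/{self.year}: negative {name}"
                )


@dataclass
class CovariateTable:
    """District-year covariate values plus (after standardization) the
    per-covariate (mean, sd) scaling metadata needed to invert back to raw
    units.

    ``frame`` has columns ``district``, ``year`` and one column per covariate;
    missing cells are disallowed (validated on read).
    """

    frame: pd.DataFrame
    scaling: dict[str, tuple[float, float]] | None = None

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("district", "year")]

    @property
    def is_standardized(self) -> bool:
        return self.scaling is not None

    def to_raw(self) -> "CovariateTable":
        """Invert standardization exactly using the stored scaling."""
        if not self.is_standardized:
            return self
        out = self.frame.copy()
        for name, (mean, sd) in self.scaling.items():
            out[name] = out[name] * sd + mean
        return CovariateTable(out, scaling=None)

    def value(self, district: str, year: int, name: str) -> float:
        sel = self.frame[(self.frame["district"] == district) & (self.frame["year"] == year)]
        if sel.empty:
            raise KeyError(f"no covariate row for {district}/{year}")
        return float(sel.iloc[0][name])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _opt_int(value) -> int | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    f = float(value)
    if f != int(f):
        raise DataValidationError(f"non-integer count {value!r}")
    return int(f)


def read_survey_table(path) -> list[SurveyObservation]:
    """Read ``surveys.csv``; empty class cells mean the classification is
    missing for that district-year (the total count is still carried)."""
    df = pd.read_csv(path, dtype={"district": str})
    required = {"district", "year", "total_count", "calves", "adult_females", "adult_males"}
    missing = required - set(df.columns)
    if missing:
        raise DataValidationError(f"surveys table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SurveyObservation(
                district=str(row.district),
                year=int(row.year),
                total_count=_opt_int(row.total_count),
                count_calves=_opt_int(row.calves),
                count_adult_females=_opt_int(row.adult_females),
                count_adult_males=_opt_int(row.adult_males),
            )
        )
    return out


def write_survey_table(observations: list[SurveyObservation], path) -> None:
    rows = []
    for o in observations:
        rows.append(
            {
                "district": o.district,
                "year": o.year,
                "total_count": o.total_count,
                "calves": o.count_calves,
                "adult_females": o.count_adult_females,
                "adult_males": o.count_adult_males,
            }
        )
    df = pd.DataFrame(rows, columns=["district", "year", "total_count", "calves",
                                     "adult_females", "adult_males"])
    df.to_csv(path, index=False, float_format="%g")


def read_harvest_table(path) -> list[HarvestRecord]:
    df = pd.read_csv(path, dtype={"district": str})
    required = {"district", "year", "h_calves", "h_adult_females", "h_adult_males"}
    missing = required - set(df.columns)
    if missing:
        raise DataValidationError(f"harvest table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        for col in ("h_calves", "h_adult_females", "h_adult_males"):
            if _opt_int(getattr(row, col)) is None:
                raise DataValidationError(
                    f"{row.district}/{row.year}: harvest value missing for {col}"
                )
        out.append(
            HarvestRecord(
                district=str(row.district),
                year=int(row.year),
                h_calves=_opt_int(row.h_calves),
                h_adult_females=_opt_int(row.h_adult_females),
                h_adult_males=_opt_int(row.h_adult_males),
            )
        )
    return out


def write_harvest_table(records: list[HarvestRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "district": r.district,
                "year": r.year,
                "h_calves": r.h_calves,
                "h_adult_females": r.h_adult_females,
                "h_adult_males": r.h_adult_males,
            }
            for r in records
        ],
        columns=["district", "year", "h_calves", "h_adult_females", "h_adult_males"],
    )
    df.to_csv(path, index=False)


def read_covariate_table(path) -> CovariateTable:
    """Read ``covariates.csv``.  Missing covariate cells are a validation
    error (the study design has complete covariate coverage)."""
    df = pd.read_csv(path, dtype={"district": str})
    if "district" not in df.columns or "year" not in df.columns:
        raise DataValidationError("covariate table needs district and year columns")
    if df.isna().any().any():
        bad = df[df.isna().any(axis=1)][["district", "year"]].iloc[0]
        raise DataValidationError(
            f"missing covariate value at {bad['district']}/{bad['year']}"
        )
    df["year"] = df["year"].astype(int)
    return CovariateTable(df)


# ---------------------------------------------------------------------------
# standardization & screening
# ---------------------------------------------------------------------------

def standardize(table: CovariateTable) -> CovariateTable:
    """Centre each covariate by its mean and divide by one sample standard
    deviation (n-1 denominator), keeping the (mean, sd) so raw units can be
    recovered exactly."""
    if table.is_standardized:
        return table
    frame = table.frame.copy()
    scaling: dict[str, tuple[float, float]] = {}
    for name in table.covariates:
        col = frame[name].to_numpy(dtype=float)
        mean = float(np.mean(col))
        sd = float(np.std(col, ddof=1))
        if sd == 0.0 or not np.isfinite(sd):
            raise DataValidationError(f"covariate {name!r} has zero variance")
        frame[name] = (col - mean) / sd
        scaling[name] = (mean, sd)
    return CovariateTable(frame, scaling=scaling)


def collinearity_screen(
    table: CovariateTable, threshold: float = 0.50
) -> list[tuple[str, str, float]]:
    """All covariate pairs whose |Pearson r| exceeds ``threshold``, sorted by
    |r| descending.  An empty list means the screen passed."""
    names = table.covariates
    if len(names) < 2:
        raise DataValidationError("collinearity screen needs at least 2 covariates")
    values = table.frame[names].to_numpy(dtype=float)
    complete = values[~np.isnan(values).any(axis=1)]
    if complete.shape[0] < 3:
        raise DataValidationError("collinearity screen needs at least 3 complete rows")
    corr = np.corrcoef(complete, rowvar=False)
    flagged = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = float(corr[i, j])
            if abs(r) > threshold:
                flagged.append((names[i], names[j], r))
    flagged.sort(key=lambda t: abs(t[2]), reverse=True)
    return flagged


def observed_age_ratio(obs: SurveyObservation) -> float:
    """Observed calves per 100 adult females; NaN when the classification is
    missing or no adult females were classified."""
    if not obs.has_classification or obs.count_adult_females == 0:
        return float("nan")
    return 100.0 * obs.count_calves / obs.count_adult_females


# ---------------------------------------------------------------------------
# design specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Term:
    """One design column: a main effect ``(covariate, lag)`` or a pairwise
    interaction (elementwise product of two standardized parents)."""

    factors: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if len(self.factors) not in (1, 2):
            raise DataValidationError("a term has one or two factors")
        for _, lag in self.factors:
            if lag not in (0, 1):
                raise DataValidationError("lags other than 0/1 are not supported")

    @property
    def name(self) -> str:
        return "*".join(
            f"{cov}:lag1" if lag else cov for cov, lag in self.factors
        )

    @staticmethod
    def parse(text: str) -> "Term":
        factors = []
        for part in text.split("*"):
            part = part.strip()
            if ":" in part:
                cov, suffix = part.split(":", 1)
                if suffix != "lag1":
                    raise DataValidationError(f"unknown lag suffix in term {text!r}")
                factors.append((cov, 1))
            else:
                factors.append((part, 0))
        return Term(tuple(factors))


@dataclass
class DesignSpec:
    """Ordered list of design terms for the recruitment (or age-ratio) linear
    predictor."""

    terms: list[Term]

    def __post_init__(self) -> None:
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            raise DataValidationError("design terms must be unique")

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.terms]

    def __len__(self) -> int:
        return len(self.terms)

    @staticmethod
    def from_strings(texts: list[str]) -> "DesignSpec":
        return DesignSpec([Term.parse(t) for t in texts])

    @staticmethod
    def from_yaml(path) -> "DesignSpec":
        with open(path) as fh:
            texts = yaml.safe_load(fh)
        if not isinstance(texts, list):
            raise DataValidationError("design YAML must be a list of term strings")
        return DesignSpec.from_strings([str(t) for t in texts])

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump([t.name for t in self.terms], fh)


def default_population_design() -> DesignSpec:
    """The shipped 20-term recruitment design.

    The original study's full term list is in an unavailable supplement; this
    default reconstructs it from the terms the results name explicitly (main
    effects for spring/summer precipitation, spring/summer time-integrated
    NDVI, current and lagged winter severity, lagged summer conditions and the
    three predator indices; interactions of growing-season and predator terms
    with winter severity), padded to the stated 20 columns.
    """
    return DesignSpec.from_strings(
        [
            "spring_precip",
            "summer_precip",
            "spring_ndvi",
            "summer_ndvi",
            "swe",
            "swe:lag1",
            "spring_precip:lag1",
            "summer_precip:lag1",
            "summer_ndvi:lag1",
            "lion_harvest",
            "bear_harvest",
            "wolf_count",
            "summer_precip*swe",
            "spring_ndvi*swe",
            "summer_ndvi*swe",
            "lion_harvest*swe",
            "bear_harvest*swe",
            "wolf_count*swe",
            "summer_precip:lag1*swe:lag1",
            "summer_ndvi:lag1*swe:lag1",
        ]
    )


def default_ageratio_design() -> DesignSpec:
    """The 21-term age-ratio design: the recruitment design plus the
    standardized adult-female harvest term."""
    base = default_population_design()
    return DesignSpec(base.terms + [Term(((HARVEST_TERM, 0),))])


def build_design_matrix(
    table: CovariateTable,
    spec: DesignSpec,
    years: list[int] | None = None,
    extra: dict[str, pd.Series] | None = None,
) -> pd.DataFrame:
    """Design matrix keyed by (district, year).

    ``table`` must already be standardized.  Interaction columns are
    elementwise products of the standardized parent columns.  Lag-1 factors
    take the same district's value in the prior calendar year; a lag term
    requested for a year with no prior covariate row is an error listing the
    affected district-years.  ``extra`` supplies columns (for example the
    standardized adult-female harvest) that live outside the covariate table,
    keyed by (district, year).
    """
    if not table.is_standardized:
        raise DataValidationError("design matrix requires a standardized covariate table")
    extra = extra or {}
    frame = table.frame
    districts = sorted(frame["district"].unique())
    if years is None:
        years = sorted(frame["year"].unique())
    wide = {
        name: frame.pivot(index="district", columns="year", values=name)
        for name in table.covariates
    }

    def factor_values(cov: str, lag: int) -> pd.DataFrame:
        if cov in extra:
            if lag:
                raise DataValidationError(f"lag not supported for extra column {cov!r}")
            ser = extra[cov]
            return pd.DataFrame(
                {y: [ser.get((d, y), np.nan) for d in districts] for y in years},
                index=districts,
            )
        if cov not in wide:
            raise DataValidationError(f"unknown covariate {cov!r} in design")
        grid = wide[cov].reindex(index=districts, columns=[y - lag for y in years])
        grid.columns = years
        return grid

    columns = {}
    for term in spec.terms:
        vals = None
        for cov, lag in term.factors:
            fv = factor_values(cov, lag)
            vals = fv if vals is None else vals * fv
        if vals.isna().any().any():
            bad = [
                f"{d}/{y}"
                for d in districts
                for y in years
                if pd.isna(vals.loc[d, y])
            ]
            raise DataValidationError(
                f"term {term.name!r} not computable for district-years: "
                + ", ".join(bad[:8])
                + ("..." if len(bad) > 8 else "")
            )
        columns[term.name] = vals.stack()

    out = pd.DataFrame(columns)
    out.index.names = ["district", "year"]
    return out[spec.names]
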