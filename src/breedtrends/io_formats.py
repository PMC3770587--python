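"""Reading, validation and writing of the tabular inputs and results.

Four inputs feed the analysis: a breed-by-year registration count matrix
(kennel-club registry counts), per-dog C-BARQ questionnaire records with
14 behavior/temperament scale scores, a per-breed longevity table with a
survey-based and a veterinary-hospital-based estimate, and a per-breed
inherited-disorder count table.  Everything is plain CSV with a header.

The canonical registration format is long (``breed,year,count``); a wide
layout with one column per calendar year is accepted on read.  Years with
no record for a breed are treated as missing, not zero: breeds entered the
registry at different dates and imputing zeros would manufacture spurious
popularity peaks.  All popularity computations therefore run on each
breed's observed span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CBARQ_SCALES",
    "RegistrationMatrix",
    "ValidationError",
    "read_registrations",
    "write_registrations",
    "read_dog_records",
    "aggregate_breed_scores",
    "read_longevity",
    "read_disorders",
    "join_tables",
]

#: The 14 C-BARQ behavior and temperament scales (owner-report instrument,
#: each scored on a bounded 0-4 scale).  Short codes follow the instrument.
CBARQ_SCALES: tuple[str, ...] = (
    "trainability",
    "strangeraggr",
    "owneraggr",
    "dogrivalry",
    "strangerfear",
    "nonsocialfear",
    "dogaggr",
    "dogfear",
    "touchsens",
    "sepprobs",
    "excitability",
    "attachatten",
    "chasing",
    "energy",
)

#: Non-behavioral per-breed columns carried by a trait table.
TRAIT_EXTRA_COLUMNS: tuple[str, ...] = (
    "longevity_survey",
    "longevity_vet",
    "n_disorders",
    "n_dogs",
)


class ValidationError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass
class RegistrationMatrix:
    """Breed x calendar-year registration counts.

    ``counts`` is a DataFrame indexed by consecutive integer years with one
    column per breed; unobserved (breed, year) cells are NaN, observed cells
    are non-negative integers stored as floats.  Each breed must have at
    least two observed years, otherwise its volatility is undefined.
    """

    counts: pd.DataFrame
    observed_span: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.counts
        years = df.index.to_numpy()
        if len(years) == 0 or len(df.columns) == 0:
            raise ValidationError("empty registration matrix")
        if df.columns.duplicated().any():
            dupes = df.columns[df.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate breed identifiers: {dupes}")
        if not np.array_equal(years, np.arange(years[0], years[-1] + 1)):
            raise ValidationError("years must be strictly increasing and consecutive")
        vals = df.to_numpy(dtype=float)
        obs = ~np.isnan(vals)
        if (vals[obs] < 0).any():
            raise ValidationError("negative registration count")
        if (vals[obs] != np.round(vals[obs])).any():
            raise ValidationError("non-integer registration count")
        for breed in df.columns:
            col = df[breed].dropna()
            if len(col) < 2:
                raise ValidationError(
                    f"breed {breed!r} has fewer than 2 observed years"
                )
            self.observed_span.setdefault(
                breed, (int(col.index[0]), int(col.index[-1]))
            )

    @property
    def breeds(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def years(self) -> tuple[int, int]:
        return int(self.counts.index[0]), int(self.counts.index[-1])

    def series(self, breed: str) -> pd.Series:
        """Observed year -> count series for one breed (NaN rows dropped)."""
        return self.counts[breed].dropna()


def _matrix_from_long(df: pd.DataFrame, missing_as_zero: bool) -> RegistrationMatrix:
    dup = df.duplicated(subset=["breed", "year"])
    if dup.any():
        first = df.loc[dup, ["breed", "year"]].iloc[0]
        raise ValidationError(
            f"duplicate (breed, year) entry: ({first['breed']!r}, {first['year']})"
        )
    wide = df.pivot(index="year", columns="breed", values="count").astype(float)
    wide.index = wide.index.astype(int)
    wide = wide.reindex(np.arange(wide.index.min(), wide.index.max() + 1))
    wide.columns.name = None
    wide.index.name = "year"
    if missing_as_zero:
        wide = wide.fillna(0.0)
    return RegistrationMatrix(wide)


def read_registrations(
    path: str | Path, *, missing_as_zero: bool = False
) -> RegistrationMatrix:
    """Read a registration count matrix from CSV.

    Accepts the canonical long format (columns ``breed,year,count``) or a
    wide format whose header is ``breed`` followed by calendar-year column
    names.  Counts must be non-negative integers.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise ValidationError(f"malformed CSV {path}: {exc}") from exc
    cols = [str(c).strip() for c in df.columns]
    df.columns = cols
    if {"breed", "year", "count"}.issubset(cols):
        long = df[["breed", "year", "count"]].copy()
    elif cols and cols[0] == "breed" and all(c.isdigit() for c in cols[1:]):
        long = df.melt(id_vars="breed", var_name="year", value_name="count")
        long = long.dropna(subset=["count"])
        long["year"] = long["year"].astype(int)
    else:
        raise ValidationError(
            f"{path}: expected columns (breed,year,count) or breed + year columns, "
            f"got {cols[:6]}"
        )
    counts = pd.to_numeric(long["count"], errors="coerce")
    bad = counts.isna() & long["count"].notna()
    if bad.any():
        row = long.index[bad][0]
        raise ValidationError(f"{path}: non-numeric count at data row {row + 1}")
    long["count"] = counts
    if (long["count"] < 0).any():
        row = long.index[(long["count"] < 0)][0]
        raise ValidationError(f"{path}: negative count at data row {row + 1}")
    if (long["count"] != long["count"].round()).any():
        row = long.index[long["count"] != long["count"].round()][0]
        raise ValidationError(f"{path}: non-integer count at data row {row + 1}")
    return _matrix_from_long(long, missing_as_zero=missing_as_zero)


def write_registrations(matrix: RegistrationMatrix, path: str | Path) -> None:
    """Write a registration matrix in the canonical long CSV format."""
    stacked = matrix.counts.copy()
    stacked.index.name = "year"
    stacked.columns.name = "breed"
    long = stacked.stack().rename("count").reset_index()
    long["count"] = long["count"].astype(int)
    long[["breed", "year", "count"]].to_csv(path, index=False)


def read_dog_records(path: str | Path) -> pd.DataFrame:
    """Read per-dog C-BARQ records: ``dog_id,breed,<14 scale columns>``.

    Scale scores are bounded reals on the instrument's 0-4 scale and may be
    missing (empty cells).  The 14 scale columns must all be present.
    """
    df = pd.read_csv(path)
    missing = [s for s in CBARQ_SCALES if s not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing C-BARQ scale columns {missing}")
    if "breed" not in df.columns:
        raise ValidationError(f"{path}: missing 'breed' column")
    return df


def aggregate_breed_scores(
    records: pd.DataFrame, min_dogs_per_breed: int = 20
) -> pd.DataFrame:
    """Aggregate per-dog records into breed-typical scale means.

    Dogs of unknown breed are dropped, then breeds with fewer than
    ``min_dogs_per_breed`` retained dogs are dropped (the instrument's
    breed filter; the study default is 20).  Each scale mean is computed
    over the dogs with a non-missing value for that scale; a breed whose
    every dog is missing a scale simply lacks that scale's mean.  Returns a
    DataFrame indexed by breed with the 14 scale means plus ``n_dogs``.
    """
    if min_dogs_per_breed < 1:
        raise ValueError("min_dogs_per_breed must be >= 1")
    if len(records) == 0:
        raise ValidationError("no dog records supplied")
    known = records[
        records["breed"].notna() & (records["breed"].astype(str) != "unknown")
    ]
    if len(known) == 0:
        raise ValidationError("no dog records with a known breed")
    n_dogs = known.groupby("breed").size()
    keep = n_dogs[n_dogs >= min_dogs_per_breed].index
    kept = known[known["breed"].isin(keep)]
    if len(kept) == 0:
        raise ValidationError(
            f"no breed has >= {min_dogs_per_breed} dogs; nothing to aggregate"
        )
    means = kept.groupby("breed")[list(CBARQ_SCALES)].mean()
    means["n_dogs"] = n_dogs.loc[means.index].astype(int)
    means.index = means.index.astype(str)
    return means.sort_index()


def read_longevity(path: str | Path) -> pd.DataFrame:
    """Read per-breed longevity: ``breed,longevity_survey,longevity_vet``.

    Either source may be missing per breed; present values are years and
    must be positive.
    """
    df = pd.read_csv(path)
    for col in ("longevity_survey", "longevity_vet"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
        if (df[col].dropna() <= 0).any():
            raise ValidationError(f"{path}: non-positive value in {col!r}")
    return df.set_index("breed")[["longevity_survey", "longevity_vet"]]


def read_disorders(path: str | Path) -> pd.DataFrame:
    """Read per-breed inherited-disorder counts: ``breed,n_disorders``."""
    df = pd.read_csv(path)
    if "n_disorders" not in df.columns:
        raise ValidationError(f"{path}: missing column 'n_disorders'")
    vals = df["n_disorders"].dropna()
    if (vals < 0).any() or (vals != vals.round()).any():
        raise ValidationError(f"{path}: n_disorders must be non-negative integers")
    return df.set_index("breed")[["n_disorders"]]


def join_tables(
    profiles: pd.DataFrame,
    traits: pd.DataFrame,
    synonym_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Inner-join popularity profiles with a breed trait table.

    Breed names are harmonized via an explicit ``synonym_map`` applied to
    the trait table's index before joining (never fuzzy matching, for
    reproducibility).  Correlations downstream use pairwise-complete
    observations, so the join keeps all columns with their NaNs.
    """
    if synonym_map:
        traits = traits.rename(index=dict(synonym_map))
    joined = profiles.join(traits, how="inner")
    if len(joined) == 0:
        raise ValidationError(
            "no breeds in common between profiles and traits; "
            "check the breed-name synonym map"
        )
    return joined
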