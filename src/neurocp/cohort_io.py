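"""Cohort and region-metric data model plus CSV interchange.

The analysis operates on two tables:

* a **cohort** table with one row per subject: gestational age at birth
  (GAB, weeks), postmenstrual age at scan (PMA, weeks), sex, and the
  preterm/term group label;
* a long-format **region metrics** table with one row per
  (region, metric, subject) carrying a scalar DTI value — FA is unitless
  in [0, 1], diffusivities (MD/AD/RD) are in 1e-3 mm^2/s.

All downstream fitting aligns metric vectors to cohort order via
``subject_id``, so row order in the metrics file is irrelevant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

METRICS = ("FA", "MD", "AD", "RD")
GROUPS = ("preterm", "term")

#: internal sex convention: female = 0, male = 1 (external labels are
#: remapped through ``sex_coding``; only the sign of the sex coefficient
#: depends on this choice).
SEX_FEMALE, SEX_MALE = 0, 1

COHORT_COLUMNS = ("subject_id", "gab", "pma", "sex", "group")
METRIC_COLUMNS = ("region_id", "region_name", "metric", "subject_id", "value")

#: stable column order of the results CSV
RESULT_COLUMNS = (
    "region_id", "region_name", "metric", "delta_hat",
    "a0", "a1", "a2", "a3", "a4",
    "rss", "p_raw", "p_familywise", "delta_sd", "pattern", "n_used", "status",
)


@dataclass
class CohortTable:
    """Per-subject covariates, validated, in file order.

    Arrays are aligned: element ``k`` of every field describes subject ``k``.
    """

    subject_id: np.ndarray
    gab: np.ndarray
    pma: np.ndarray
    sex: np.ndarray
    group: np.ndarray

    def __post_init__(self) -> None:
        self.subject_id = np.asarray(self.subject_id, dtype=object)
        self.gab = np.asarray(self.gab, dtype=float)
        self.pma = np.asarray(self.pma, dtype=float)
        self.sex = np.asarray(self.sex, dtype=int)
        self.group = np.asarray(self.group, dtype=object)
        n = len(self.subject_id)
        for name in ("gab", "pma", "sex", "group"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"column '{name}' has length != {n}")
        ids, counts = np.unique(self.subject_id, return_counts=True)
        if (counts > 1).any():
            dupes = ", ".join(map(str, ids[counts > 1][:5]))
            raise ValidationError(f"duplicate subject_id values: {dupes}")
        if np.isnan(self.gab).any() or np.isnan(self.pma).any():
            raise ValidationError("gab/pma must not contain missing values")
        if (self.gab <= 0).any() or (self.pma <= 0).any():
            raise ValidationError("gab and pma must be positive (weeks)")
        if not np.isin(self.sex, (0, 1)).all():
            raise ValidationError("sex must be coded {0, 1}")
        bad = set(self.group) - set(GROUPS)
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")
        pre = self.gab[self.group == "preterm"]
        term = self.gab[self.group == "term"]
        if pre.size and term.size and pre.max() >= term.min():
            warnings.warn(
                "preterm and term GAB ranges overlap; group labels are kept as given",
                stacklevel=2,
            )

    @property
    def n(self) -> int:
        return len(self.subject_id)

    def subset(self, mask: np.ndarray) -> "CohortTable":
        """Row-subset of the cohort (used for per-region complete cases)."""
        mask = np.asarray(mask)
        return CohortTable(
            self.subject_id[mask], self.gab[mask], self.pma[mask],
            self.sex[mask], self.group[mask],
        )

    def resample(self, idx: np.ndarray) -> "CohortTable":
        """Row-selection *with* repeats (bootstrap); skips the uniqueness check."""
        obj = object.__new__(CohortTable)
        obj.subject_id = self.subject_id[idx]
        obj.gab = self.gab[idx]
        obj.pma = self.pma[idx]
        obj.sex = self.sex[idx]
        obj.group = self.group[idx]
        return obj

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject_id": self.subject_id, "gab": self.gab, "pma": self.pma,
            "sex": self.sex, "group": self.group,
        })


@dataclass
class RegionMetricSet:
    """One metric for one region, aligned to a cohort.

    ``values`` has one entry per cohort subject; entries where ``observed``
    is False are NaN and dropped from that region's fit only.
    """

    region_id: int
    region_name: str
    metric: str
    values: np.ndarray
    observed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.observed is None:
            self.observed = ~np.isnan(self.values)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.observed.shape != self.values.shape:
            raise ValidationError("observed mask and values have different lengths")
        if self.metric not in METRICS:
            raise ValidationError(f"unknown metric '{self.metric}'")
        obs = self.values[self.observed]
        if self.metric == "FA":
            if obs.size and ((obs < 0) | (obs > 1)).any():
                raise ValidationError(
                    f"region {self.region_id}: FA values outside [0, 1]")
        elif obs.size and (obs <= 0).any():
            raise ValidationError(
                f"region {self.region_id}: {self.metric} values must be positive")

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())

    def complete_case(self, cohort: CohortTable) -> tuple[CohortTable, np.ndarray]:
        """Drop subjects missing for this (region, metric); return aligned pair."""
        if len(self.values) != cohort.n:
            raise ValidationError(
                f"region {self.region_id}: {len(self.values)} values for "
                f"{cohort.n}-subject cohort")
        return cohort.subset(self.observed), self.values[self.observed]


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing column(s): {', '.join(missing)}")


def _numeric(series: pd.Series, column: str) -> np.ndarray:
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() & series.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"column '{column}', row {row + 2} (1-based incl. header): "
            f"cannot parse {series.iloc[row]!r} as a number")
    # convert from the original strings: python/numpy strtod is correctly
    # rounded, so written values round-trip bit-exactly
    return np.asarray(series.to_numpy(), dtype=float)


def read_cohort(path, sex_coding: dict | None = None,
                column_map: dict | None = None) -> CohortTable:
    """Read and validate a cohort CSV.

    Parameters
    ----------
    path
        CSV with a header row and (possibly renamed) columns
        ``subject_id, gab, pma, sex, group``.
    sex_coding
        Mapping from the file's sex labels to the internal {0, 1} codes,
        e.g. ``{"M": 1, "F": 0}``. Unneeded when the file already uses 0/1.
    column_map
        Mapping from internal names to the file's column names, e.g.
        ``{"gab": "GA_birth"}``.
    """
    df = pd.read_csv(path, dtype=str)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    _require_columns(df, COHORT_COLUMNS, "cohort CSV")
    sex_raw = df["sex"].str.strip()
    if sex_coding is not None:
        coding = {str(k): v for k, v in sex_coding.items()}
        unknown = set(sex_raw) - set(coding)
        if unknown:
            raise ValidationError(
                f"sex labels {sorted(unknown)} not covered by sex_coding")
        sex = sex_raw.map(coding).to_numpy(dtype=int)
    else:
        sex = _numeric(sex_raw, "sex").astype(int)
    return CohortTable(
        subject_id=df["subject_id"].str.strip().to_numpy(dtype=object),
        gab=_numeric(df["gab"], "gab"),
        pma=_numeric(df["pma"], "pma"),
        sex=sex,
        group=df["group"].str.strip().to_numpy(dtype=object),
    )


def read_region_metrics(path, cohort: CohortTable) -> list[RegionMetricSet]:
    """Read a long-format metrics CSV into per-(region, metric) sets.

    Values are realigned to cohort subject order; subjects present in the
    cohort but absent for a region are recorded as missing for that region.
    """
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, METRIC_COLUMNS, "metrics CSV")
    pos = {sid: k for k, sid in enumerate(cohort.subject_id)}
    unknown = set(df["subject_id"]) - set(pos)
    if unknown:
        raise ValidationError(
            f"metrics CSV references subject(s) not in cohort: "
            f"{', '.join(sorted(map(str, unknown))[:5])}")
    dup = df.duplicated(subset=["region_id", "metric", "subject_id"])
    if dup.any():
        r = df.loc[dup.idxmax()]
        raise ValidationError(
            f"duplicate entry for region {r['region_id']}, metric {r['metric']}, "
            f"subject {r['subject_id']}")
    sets: list[RegionMetricSet] = []
    for (region_id, metric), grp in df.groupby(["region_id", "metric"], sort=True):
        values = np.full(cohort.n, np.nan)
        idx = grp["subject_id"].map(pos).to_numpy()
        values[idx] = _numeric(grp["value"], "value")
        names = grp["region_name"].unique()
        if len(names) != 1:
            raise ValidationError(
                f"region {region_id} has inconsistent names: {list(names)}")
        sets.append(RegionMetricSet(int(region_id), str(names[0]), str(metric),
                                    values))
    return sets


#: 17 significant digits: lossless round-trip for float64
_FLOAT_FMT = "%.17g"


def write_cohort(cohort: CohortTable, path) -> None:
    cohort.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_region_metrics(sets: list[RegionMetricSet], cohort: CohortTable,
                         path) -> None:
    """Write metric sets back to the long CSV format (observed rows only)."""
    frames = []
    for s in sets:
        obs = s.observed
        frames.append(pd.DataFrame({
            "region_id": s.region_id, "region_name": s.region_name,
            "metric": s.metric, "subject_id": cohort.subject_id[obs],
            "value": s.values[obs],
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format=_FLOAT_FMT)


def write_results(results: pd.DataFrame, path) -> None:
    """Write the per-(region, metric) results table with a stable column order.

    Floats are written with ``repr`` precision so a read-back reproduces
    them bit-exactly.
    """
    if results is None or len(results) == 0:
        raise ValidationError("refusing to write an empty results table")
    cols = [c for c in RESULT_COLUMNS if c in results.columns]
    extra = [c for c in results.columns if c not in cols]
    results[cols + extra].to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
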