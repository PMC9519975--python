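"""Monthly sociality phenotypes and fixed-effect design construction.

Scan-sampled proximity data (who was within ~4 m of a subject at an instant)
are aggregated into subject-month records carrying the two response variables:
the number of scans in which the subject was social (had at least one partner)
out of the number of scans taken, and the total number of partners summed over
scans.  Inclusion filters drop under-sampled months (fewer than five scans)
and under-sampled subjects (fewer than six surviving months), and dependent
infants (under one year) are excluded both as subjects and as partners of
their own mothers.

The design builder produces the fixed-effects matrix shared by both model
families: cubic age (z-scored, raw powers) interacted with sex, z-scored
group size, an annual sine/cosine harmonic, and El Nino-Southern Oscillation
phase indicators derived from the bimonthly MEI.v2 climate index.  The Poisson
family additionally uses ln(scans) as an offset for sampling effort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScanRecord",
    "MonthlyRecord",
    "DesignSpec",
    "Design",
    "aggregate_monthly",
    "filter_records",
    "enso_phase",
    "seasonal_terms",
    "build_design",
    "records_to_frame",
    "read_scan_csv",
    "read_monthly_csv",
    "read_climate_csv",
    "RANDOM_TERM_NAMES",
]

#: grouping keys emitted for the random-effects structure (residual is the
#: tenth variance component and needs no key)
RANDOM_TERM_NAMES = (
    "ID",
    "ID:Year",
    "M",
    "M:GroupAlpha:Year",
    "animal",
    "Year",
    "Month:Year",
    "GroupAlpha",
    "GroupAlpha:Year",
)


@dataclass(frozen=True)
class ScanRecord:
    """One instantaneous scan: subject, (year, month[, day]) date, group-alpha
    key, and the identities within ~4 m (possibly empty)."""

    subject: str
    date: tuple  # (year, month) or (year, month, day)
    group: str
    alpha: str
    partners: tuple[str, ...] = ()

    def __post_init__(self):
        if self.subject in self.partners:
            raise ValueError(f"subject {self.subject!r} in its own partner list")


@dataclass
class MonthlyRecord:
    """One subject-month of aggregated proximity data plus covariates."""

    subject: str
    year: int
    month: int
    group: str
    alpha: str
    n_scans: int
    n_social: int
    total_partners: int
    age_years: float
    sex: str | None = None
    group_size: float | None = None
    mei: float | None = None
    mother: str | None = None

    @property
    def enso_phase(self) -> str:
        return enso_phase(self.mei)

    @property
    def group_alpha(self) -> str:
        return f"{self.group}|{self.alpha}"


@dataclass
class DesignSpec:
    """Fixed-effect layout and the scaling constants that make it reproducible.

    ``age_mean/age_sd`` and ``gs_mean/gs_sd`` are the centering/scaling
    constants for age and group size; when None they are computed from the
    records passed to :func:`build_design` and recorded back on the spec.
    """

    age_sex_cubic: bool = True
    group_size: bool = True
    season: bool = True
    enso: bool = True
    offset_log_scans: bool = False  # Poisson family: ln(scans) offset
    season_phase: float = 0.0  # optional phase offset of the annual harmonic
    age_mean: float | None = None
    age_sd: float | None = None
    gs_mean: float | None = None
    gs_sd: float | None = None


@dataclass
class Design:
    """Built design: fixed-effects matrix, random-term keys, offset."""

    X: np.ndarray
    columns: list[str]
    group_keys: pd.DataFrame  # one column per entry of RANDOM_TERM_NAMES
    offset: np.ndarray
    spec: DesignSpec
    records: pd.DataFrame


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def _age_years(birth: tuple, at: tuple) -> float:
    """Age in years at (year, month[, day]), month resolution."""
    return (at[0] - birth[0]) + (at[1] - birth[1]) / 12.0


def aggregate_monthly(
    scans: Iterable[ScanRecord],
    birthdates: Mapping[str, tuple],
    mother_of: Mapping[str, str],
    missing_birthdate: str = "skip",
) -> list[MonthlyRecord]:
    """Pool scans into subject-months with infant exclusions applied.

    A scan counts as social iff at least one partner remains after removing
    partners younger than one year from their own mother's partner list
    (other subjects keep such partners).  Subjects younger than one year at
    scan time contribute no records at all.

    ``missing_birthdate`` controls scans whose subject lacks a birthdate:
    ``"skip"`` drops them with no record, ``"fail"`` raises ``KeyError``.
    """
    if missing_birthdate not in ("skip", "fail"):
        raise ValueError("missing_birthdate must be 'skip' or 'fail'")

    acc: dict[tuple, dict] = {}
    for scan in scans:
        birth = birthdates.get(scan.subject)
        if birth is None:
            if missing_birthdate == "fail":
                raise KeyError(f"no birthdate for subject {scan.subject!r}")
            continue
        age = _age_years(birth, scan.date)
        if age < 1.0:
            continue  # dependent infants are not subjects
        partners = [
            p
            for p in scan.partners
            if not (
                mother_of.get(p) == scan.subject
                and p in birthdates
                and _age_years(birthdates[p], scan.date) < 1.0
            )
        ]
        key = (scan.subject, scan.date[0], scan.date[1])
        slot = acc.setdefault(
            key,
            {
                "group": scan.group,
                "alpha": scan.alpha,
                "n_scans": 0,
                "n_social": 0,
                "total_partners": 0,
                "age_sum": 0.0,
            },
        )
        slot["n_scans"] += 1
        slot["n_social"] += 1 if partners else 0
        slot["total_partners"] += len(partners)
        slot["age_sum"] += age

    out = []
    for (subject, year, month), slot in sorted(acc.items()):
        out.append(
            MonthlyRecord(
                subject=subject,
                year=year,
                month=month,
                group=slot["group"],
                alpha=slot["alpha"],
                n_scans=slot["n_scans"],
                n_social=slot["n_social"],
                total_partners=slot["total_partners"],
                age_years=slot["age_sum"] / slot["n_scans"],
                mother=mother_of.get(subject),
            )
        )
    return out


def filter_records(
    records: Sequence[MonthlyRecord],
    min_scans: int = 5,
    min_months: int = 6,
) -> list[MonthlyRecord]:
    """Apply the sampling-density filters, preserving input order.

    Months with fewer than ``min_scans`` scans are dropped first; subjects
    left with fewer than ``min_months`` months are then dropped entirely.
    Both thresholds are inclusive.
    """
    kept = [r for r in records if r.n_scans >= min_scans]
    months_per_subject: dict[str, set] = {}
    for r in kept:
        months_per_subject.setdefault(r.subject, set()).add((r.year, r.month))
    return [r for r in kept if len(months_per_subject[r.subject]) >= min_months]


# ---------------------------------------------------------------------------
# covariate helpers
# ---------------------------------------------------------------------------

def enso_phase(mei: float) -> str:
    """Classify an MEI.v2 value: warm iff >= 0.5, cool iff <= -0.5, else neutral."""
    if mei is None or not math.isfinite(mei):
        raise ValueError(f"non-finite MEI value: {mei!r}")
    if mei >= 0.5:
        return "warm"
    if mei <= -0.5:
        return "cool"
    return "neutral"


def seasonal_terms(month: int, phase: float = 0.0) -> tuple[float, float]:
    """Annual harmonic: (sin, cos) of 2*pi*month/12 (+ optional phase)."""
    if not (isinstance(month, (int, np.integer)) and 1 <= month <= 12):
        raise ValueError(f"month must be an integer in 1..12, got {month!r}")
    angle = 2.0 * math.pi * month / 12.0 + phase
    return math.sin(angle), math.cos(angle)


def records_to_frame(records: Sequence[MonthlyRecord]) -> pd.DataFrame:
    """Tabular view of monthly records (one row per subject-month)."""
    return pd.DataFrame(
        {
            "subject": [r.subject for r in records],
            "year": [r.year for r in records],
            "month": [r.month for r in records],
            "group": [r.group for r in records],
            "alpha": [r.alpha for r in records],
            "n_scans": [r.n_scans for r in records],
            "n_social": [r.n_social for r in records],
            "total_partners": [r.total_partners for r in records],
            "age_years": [r.age_years for r in records],
            "sex": [r.sex for r in records],
            "group_size": [r.group_size for r in records],
            "mei": [r.mei for r in records],
            "mother": [r.mother for r in records],
        }
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_scan_csv(path) -> list[ScanRecord]:
    """Read ``subject,date,group,alpha_male,partners`` CSV.

    Dates are ``YYYY-MM`` or ``YYYY-MM-DD``; partners are ``;``-separated
    (empty allowed).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        date = tuple(int(p) for p in row["date"].split("-"))
        partners = tuple(p for p in row["partners"].split(";") if p)
        out.append(ScanRecord(row["subject"], date, row["group"],
                              row["alpha_male"], partners))
    return out


def read_monthly_csv(path) -> list[MonthlyRecord]:
    """Read pre-aggregated monthly records, bypassing scan aggregation."""
    df = pd.read_csv(path)
    return [
        MonthlyRecord(
            subject=str(r["subject"]), year=int(r["year"]), month=int(r["month"]),
            group=str(r["group"]), alpha=str(r["alpha_male"]),
            n_scans=int(r["n_scans"]), n_social=int(r["n_social"]),
            total_partners=int(r["total_partners"]),
            age_years=float(r["age_years"]), sex=str(r["sex"]),
            group_size=float(r["group_size"]), mei=float(r["mei"]),
            mother=str(r["mother"]) if "mother" in df.columns and pd.notna(r.get("mother")) else None,
        )
        for _, r in df.iterrows()
    ]


def read_climate_csv(path) -> dict[tuple[int, int], float]:
    """Read ``year,month,mei`` into a (year, month) -> MEI mapping."""
    df = pd.read_csv(path)
    return {
        (int(r["year"]), int(r["month"])): float(r["mei"])
        for _, r in df.iterrows()
    }


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _zscore(x: np.ndarray, mean: float | None, sd: float | None, name: str):
    if mean is None:
        mean = float(np.mean(x))
    if sd is None:
        sd = float(np.std(x))  # population SD; matched by fixed_effect_variance
    if sd == 0.0:
        raise ValueError(f"zero-variance covariate: {name}")
    return (x - mean) / sd, mean, sd


def build_design(
    records: Sequence[MonthlyRecord] | pd.DataFrame,
    spec: DesignSpec | None = None,
) -> Design:
    """Build the fixed-effects matrix, random-term keys, and offset.

    Age enters as z, z^2, z^3 (raw powers of the z-score), each interacted
    with sex (male indicator); ENSO phase as cool/warm indicators (neutral
    reference).  Z-scores use the supplied scaling constants or, when absent,
    the mean/SD of the records themselves (recorded back into the returned
    spec).  The offset is ln(n_scans) when the spec requests it, else zeros.
    """
    spec = replace(spec) if spec is not None else DesignSpec()
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    n = len(df)
    if n == 0:
        raise ValueError("no records")

    cols: list[str] = ["intercept"]
    parts: list[np.ndarray] = [np.ones(n)]

    if spec.age_sex_cubic:
        age = df["age_years"].to_numpy(float)
        age_z, spec.age_mean, spec.age_sd = _zscore(
            age, spec.age_mean, spec.age_sd, "age_years"
        )
        male = (df["sex"].astype(str) == "M").to_numpy(float)
        for p, nm in ((1, "age_z"), (2, "age_z2"), (3, "age_z3")):
            parts.append(age_z**p)
            cols.append(nm)
        parts.append(male)
        cols.append("sex_M")
        for p, nm in ((1, "age_z:sex_M"), (2, "age_z2:sex_M"), (3, "age_z3:sex_M")):
            parts.append((age_z**p) * male)
            cols.append(nm)

    if spec.group_size:
        gs = df["group_size"].to_numpy(float)
        gs_z, spec.gs_mean, spec.gs_sd = _zscore(
            gs, spec.gs_mean, spec.gs_sd, "group_size"
        )
        parts.append(gs_z)
        cols.append("group_size_z")

    if spec.season:
        month = df["month"].to_numpy(int)
        angle = 2.0 * np.pi * month / 12.0 + spec.season_phase
        parts.append(np.sin(angle))
        cols.append("season_sin")
        parts.append(np.cos(angle))
        cols.append("season_cos")

    if spec.enso:
        phases = np.array([enso_phase(v) for v in df["mei"].to_numpy(float)])
        parts.append((phases == "cool").astype(float))
        cols.append("enso_cool")
        parts.append((phases == "warm").astype(float))
        cols.append("enso_warm")

    X = np.column_stack(parts)

    year = df["year"].astype(str)
    ga = df["group"].astype(str) + "|" + df["alpha"].astype(str)
    # subjects with unknown mothers get unique dummy maternal identities so
    # they share no spurious maternal level
    mother = df["mother"].astype(object).where(
        df["mother"].notna(), "MDUM:" + df["subject"].astype(str)
    ).astype(str)
    keys = pd.DataFrame(
        {
            "ID": df["subject"].astype(str),
            "ID:Year": df["subject"].astype(str) + "|" + year,
            "M": mother,
            "M:GroupAlpha:Year": mother + "|" + ga + "|" + year,
            "animal": df["subject"].astype(str),
            "Year": year,
            "Month:Year": df["month"].astype(str) + "|" + year,
            "GroupAlpha": ga,
            "GroupAlpha:Year": ga + "|" + year,
        }
    )

    offset = (
        np.log(df["n_scans"].to_numpy(float))
        if spec.offset_log_scans
        else np.zeros(n)
    )
    return Design(X=X, columns=cols, group_keys=keys, offset=offset,
                  spec=spec, records=df.reset_index(drop=True))
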