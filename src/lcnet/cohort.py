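"""Cohort construction around a diagnosis-code index date.

The index date is the earliest qualifying code inside a closed calendar
window (codes before the window never index a patient — early codes may
have been applied retroactively and do not reflect the diagnosis date).
Deceased patients and patients whose index falls inside an inpatient stay
are excluded; the analysis window is the closed interval from index to
index + ``window_days``.  All interval comparisons are inclusive on both
ends.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass

import pandas as pd

from .synth import AGE_BIN_EDGES, AGE_GROUPS
from .vocab import INDEX_CODE


@dataclass(frozen=True)
class IndexRule:
    """Which code indexes a patient, and when."""

    code: str = INDEX_CODE
    window_start: str = "2021-10-01"
    window_end: str = "2022-05-26"
    window_days: int = 60

    def __post_init__(self) -> None:
        if pd.Timestamp(self.window_start) > pd.Timestamp(self.window_end):
            raise ValueError("window_start after window_end")
        if self.window_days < 0:
            raise ValueError("window_days must be non-negative")


@dataclass(frozen=True)
class SiteCriteria:
    """Minimum per-site data-quality gates.

    Coverage thresholds are inclusive lower bounds; the date-shift bound is
    an inclusive upper bound.
    """

    min_lab_coverage: float = 0.25
    min_valid_end_dates: float = 0.75
    max_date_shift_days: int = 30
    require_index_code_use: bool = True

    def __post_init__(self) -> None:
        for name in ("min_lab_coverage", "min_valid_end_dates"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class CohortSummary:
    """Headline attrition and composition counts with one-decimal percents."""

    n_initial: int
    n_excluded_inpatient_index: int
    n_excluded_deceased: int
    n_base: int
    n_hospitalized_acute: int
    pct_hospitalized_acute: float | None
    n_severe: int
    pct_severe_of_all: float | None
    pct_severe_of_hospitalized: float | None
    n_missing_covid_index: int
    pct_missing_covid_index: float | None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def round_pct(count: int, denom: int) -> float | None:
    """100*count/denom rounded half-up to one decimal; None when denom is 0."""
    if denom == 0:
        return None
    frac = decimal.Decimal(100 * count) / decimal.Decimal(denom)
    return float(frac.quantize(decimal.Decimal("0.1"),
                               rounding=decimal.ROUND_HALF_UP))


def _parse_dates(values: pd.Series, what: str) -> pd.Series:
    parsed = pd.to_datetime(values, format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & values.notna()
    if bad.any():
        row = bad.idxmax()
        raise ValueError(f"unparseable date in {what} at row {row}: "
                         f"{values.loc[row]!r}")
    return parsed


def derive_index(events: pd.DataFrame, rule: IndexRule = IndexRule()) -> pd.Series:
    """Earliest qualifying code date inside [window_start, window_end] per
    person. Persons whose only qualifying codes fall before the window get no
    index at all."""
    hits = events[events["code"] == rule.code]
    if hits.empty:
        return pd.Series(dtype="datetime64[ns]", name="index_date")
    dates = _parse_dates(hits["date"], "coded_events")
    in_window = (dates >= pd.Timestamp(rule.window_start)) & \
                (dates <= pd.Timestamp(rule.window_end))
    idx = (pd.DataFrame({"person_id": hits.loc[in_window, "person_id"],
                         "date": dates[in_window]})
           .groupby("person_id")["date"].min())
    idx.name = "index_date"
    return idx


def assign_age_group(birth_date: pd.Series, at: pd.Series) -> pd.Series:
    """Age at the reference date, binned into the four analysis strata.

    Bins are [0,21), [21,46), [46,66), [66,inf) — total and disjoint over
    ages 0-120.
    """
    age = (at.values - birth_date.values).astype("timedelta64[D]").astype(float) / 365.25
    labels = pd.cut(pd.Series(age, index=birth_date.index),
                    bins=AGE_BIN_EDGES, labels=AGE_GROUPS, right=False)
    return labels.astype(object)


def apply_exclusions(persons: pd.DataFrame, visits: pd.DataFrame,
                     index: pd.Series,
                     tests: pd.DataFrame | None = None) -> pd.DataFrame:
    """Build the cohort frame: one row per indexed person with age group,
    acute-infection flags, and an ``exclusion_reason`` (empty string when
    included).

    Exclusions: deceased persons, and persons whose index date falls inside
    any inpatient visit interval (both ends inclusive).
    """
    if not visits.empty:
        vstart = _parse_dates(visits["start_date"], "visits")
        vend = _parse_dates(visits["end_date"], "visits")
        bad = vend < vstart
        if bad.any():
            row = bad.idxmax()
            raise ValueError(
                f"visit end before start for person "
                f"{visits.loc[row, 'person_id']!r} (row {row})")

    p = persons.set_index("person_id")
    cohort = index.to_frame().join(p, how="inner")
    cohort.index.name = "person_id"

    reason = pd.Series("", index=cohort.index, dtype=object)
    reason[cohort["deceased"].astype(int) == 1] = "deceased"

    if not visits.empty:
        inpat = visits[visits["inpatient"].astype(int) == 1]
        if not inpat.empty:
            merged = inpat.merge(index.rename("index_date"),
                                 left_on="person_id", right_index=True)
            overlap = (pd.to_datetime(merged["start_date"]) <= merged["index_date"]) & \
                      (merged["index_date"] <= pd.to_datetime(merged["end_date"]))
            hit = merged.loc[overlap, "person_id"].unique()
            mask = reason.index.isin(hit) & (reason == "")
            reason[mask] = "inpatient_index"

    cohort["exclusion_reason"] = reason
    cohort["age_group"] = assign_age_group(
        pd.to_datetime(cohort["birth_date"]), cohort["index_date"])
    if tests is not None:
        pos = tests.loc[tests["result"] == "positive", "person_id"].unique()
        cohort["covid_index_available"] = cohort.index.isin(pos).astype(int)
    elif "covid_index_available" not in cohort.columns:
        cohort["covid_index_available"] = 0
    cohort["hospitalized_acute"] = cohort.get(
        "hospitalized_acute", pd.Series(0, index=cohort.index)).astype(int)
    cohort["severe_acute"] = cohort.get(
        "severe_acute", pd.Series(0, index=cohort.index)).astype(int)
    return cohort.reset_index()


def included(cohort: pd.DataFrame) -> pd.DataFrame:
    return cohort[cohort["exclusion_reason"] == ""]


def filter_sites(site_metadata: pd.DataFrame,
                 criteria: SiteCriteria = SiteCriteria()) -> list[str]:
    """Site ids passing every data-quality gate."""
    required = {"site_id", "lab_coverage", "valid_end_date_frac",
                "date_shift_days"}
    missing = required - set(site_metadata.columns)
    if missing:
        raise ValueError(f"site_metadata missing column(s): {sorted(missing)}")
    ok = (site_metadata["lab_coverage"] >= criteria.min_lab_coverage) & \
         (site_metadata["valid_end_date_frac"] >= criteria.min_valid_end_dates) & \
         (site_metadata["date_shift_days"] <= criteria.max_date_shift_days)
    if criteria.require_index_code_use and "n_index_code" in site_metadata.columns:
        ok &= site_metadata["n_index_code"] > 0
    return site_metadata.loc[ok, "site_id"].tolist()


def window_events(cohort: pd.DataFrame, events: pd.DataFrame,
                  window_days: int = 60) -> pd.DataFrame:
    """Events inside each included person's closed analysis window
    [index, index + window_days].

    Events before index are dropped from the window set but are never used
    to exclude a condition: a pre-existing condition recorded again inside
    the window stays in (it may be exacerbated by, or recur with, the
    indexed disease).
    """
    inc = included(cohort)
    merged = events.merge(inc[["person_id", "index_date"]], on="person_id")
    dates = _parse_dates(merged["date"], "coded_events")
    keep = (dates >= merged["index_date"]) & \
           (dates <= merged["index_date"] + pd.Timedelta(days=window_days))
    return merged[keep].drop(columns=["index_date"]).reset_index(drop=True)


def summarize(cohort: pd.DataFrame) -> CohortSummary:
    """Headline attrition and acute-infection composition of the cohort."""
    n_initial = len(cohort)
    n_inp = int((cohort["exclusion_reason"] == "inpatient_index").sum())
    n_dec = int((cohort["exclusion_reason"] == "deceased").sum())
    base = included(cohort)
    n_base = len(base)
    n_hosp = int(base["hospitalized_acute"].sum())
    n_sev = int(base["severe_acute"].sum())
    n_missing = int((base["covid_index_available"].astype(int) == 0).sum())
    return CohortSummary(
        n_initial=n_initial,
        n_excluded_inpatient_index=n_inp,
        n_excluded_deceased=n_dec,
        n_base=n_base,
        n_hospitalized_acute=n_hosp,
        pct_hospitalized_acute=round_pct(n_hosp, n_base),
        n_severe=n_sev,
        pct_severe_of_all=round_pct(n_sev, n_base),
        pct_severe_of_hospitalized=round_pct(n_sev, n_hosp),
        n_missing_covid_index=n_missing,
        pct_missing_covid_index=round_pct(n_missing, n_base),
    )
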