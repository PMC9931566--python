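"""Procedure, medication and code-uptake summaries over the analysis window.

Procedures are filtered of non-informative encounter records (E&M codes
that only say a visit happened), rolled up to high-level categories, and
released with figure-style suppression (a category x age-group cell is
hidden when it covers fewer than 20 patients or less than 1.0% of the
stratum).  Medications are restricted to new starts (no record at any time
before the patient's index) and rolled up to WHO ATC level 3.  Uptake
tracks monthly unique-patient use of the index code and its pre-release
placeholder across the whole lookback range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import vocab
from .cohort import included, round_pct


def filter_informative_procedures(
        events: pd.DataFrame,
        exclusion_list: frozenset[str] | set[str] | None = None,
) -> pd.DataFrame:
    """Drop procedure records that only reflect that an encounter took place
    (e.g. office-visit CPT 99212). An empty exclusion list is the identity."""
    if exclusion_list is None:
        exclusion_list = vocab.NONINFORMATIVE_PROCEDURE_CODES
    ev = events
    if "event_class" in ev.columns:
        ev = ev[ev["event_class"] == "procedure"]
    return ev[~ev["code"].isin(exclusion_list)].reset_index(drop=True)


@dataclass
class ProcedureCategoryTable:
    """Unique-patient counts per procedure category per age stratum.

    ``frame`` columns: category, age_group, n_patients, percent (of the
    stratum size), suppressed (count < 20 or percent < 1.0).  ``shown()``
    returns only the releasable rows.
    """

    frame: pd.DataFrame
    stratum_sizes: dict[str, int]

    def shown(self) -> pd.DataFrame:
        return self.frame[~self.frame["suppressed"]].reset_index(drop=True)


def categorize_procedures(windowed_procedures: pd.DataFrame,
                          cohort: pd.DataFrame,
                          mapping: dict[str, str] | None = None,
                          min_count: int = 20,
                          min_percent: float = 1.0) -> ProcedureCategoryTable:
    """Aggregate procedures into high-level categories per age stratum.

    A patient counts once per category regardless of how many events they
    have in it (unique patient-category pairs).  Codes absent from the
    mapping fall into "uncategorized" with a warning.
    """
    mapping = vocab.PROCEDURE_CATEGORY_OF if mapping is None else mapping
    inc = included(cohort)
    strata = inc.set_index("person_id")["age_group"]
    stratum_sizes = strata.value_counts().to_dict()

    ev = windowed_procedures.copy()
    unmapped = ~ev["code"].isin(mapping)
    if unmapped.any():
        warnings.warn(f"{int(unmapped.sum())} procedure events with unmapped "
                      "codes counted under 'uncategorized'")
    ev["category"] = ev["code"].map(lambda c: mapping.get(c, "uncategorized"))
    ev["age_group"] = ev["person_id"].map(strata)
    ev = ev.dropna(subset=["age_group"])

    pairs = ev.drop_duplicates(["person_id", "category"])
    counts = pairs.groupby(["category", "age_group"], observed=True).size()
    rows = []
    for (cat, group), n in counts.items():
        n_stratum = int(stratum_sizes.get(group, 0))
        pct = round_pct(int(n), n_stratum)
        rows.append({
            "category": cat, "age_group": group, "n_patients": int(n),
            "percent": pct,
            "suppressed": int(n) < min_count or (pct is not None
                                                 and pct < min_percent),
        })
    frame = pd.DataFrame(
        rows, columns=["category", "age_group", "n_patients", "percent",
                       "suppressed"]).sort_values(
        ["category", "age_group"]).reset_index(drop=True)
    return ProcedureCategoryTable(
        frame=frame,
        stratum_sizes={str(k): int(v) for k, v in stratum_sizes.items()})


def new_medications(drug_events: pd.DataFrame, index: pd.Series,
                    window_days: int = 60) -> pd.DataFrame:
    """Drug events for (patient, ingredient) pairs that are new starts:
    at least one record inside [index, index + window_days] and none at any
    time before index (full lookback)."""
    ev = drug_events
    if "event_class" in ev.columns:
        ev = ev[ev["event_class"] == "drug"]
    merged = ev.merge(index.rename("index_date"), left_on="person_id",
                      right_index=True)
    dates = pd.to_datetime(merged["date"])
    in_window = (dates >= merged["index_date"]) & \
                (dates <= merged["index_date"] + pd.Timedelta(days=window_days))
    prior = dates < merged["index_date"]
    key = list(zip(merged["person_id"], merged["code"]))
    prior_pairs = {k for k, p in zip(key, prior) if p}
    keep = in_window & np.array([k not in prior_pairs for k in key])
    return (merged[keep].drop(columns=["index_date"])
            .reset_index(drop=True))


def atc_rollup(new_drug_events: pd.DataFrame, cohort: pd.DataFrame,
               atc_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Unique patients per ATC level-3 class per age stratum.

    Level 3 is the 4-character prefix of the 7-character WHO ATC code
    (e.g. J01CA04 -> J01C).  Ingredients absent from the map land in an
    "unmapped" bucket with a warning.
    """
    atc_map = vocab.ATC_OF_INGREDIENT if atc_map is None else atc_map
    if new_drug_events.empty:
        return pd.DataFrame(columns=["atc_level3", "age_group", "n_patients"])
    inc = included(cohort)
    strata = inc.set_index("person_id")["age_group"]

    ev = new_drug_events.copy()
    unmapped = ~ev["code"].isin(atc_map)
    if unmapped.any():
        warnings.warn(f"{int(unmapped.sum())} drug events with unmapped "
                      "ingredients counted under 'unmapped'")
    ev["atc_level3"] = ev["code"].map(
        lambda c: vocab.atc_level3(atc_map[c]) if c in atc_map else "unmapped")
    ev["age_group"] = ev["person_id"].map(strata)
    ev = ev.dropna(subset=["age_group"])
    pairs = ev.drop_duplicates(["person_id", "atc_level3"])
    out = (pairs.groupby(["atc_level3", "age_group"], observed=True).size()
           .rename("n_patients").reset_index())
    return out.sort_values(["atc_level3", "age_group"]).reset_index(drop=True)


@dataclass
class UptakeSeries:
    """Monthly unique-patient usage counts per tracked code.

    ``frame``: one row per (month, code) over a contiguous month range,
    columns month (period string YYYY-MM), code, n_patients.
    """

    frame: pd.DataFrame
    codes: tuple[str, ...]

    def pivot(self) -> pd.DataFrame:
        return self.frame.pivot(index="month", columns="code",
                                values="n_patients").fillna(0).astype(int)


def uptake_series(events: pd.DataFrame,
                  codes: tuple[str, ...] = (vocab.INDEX_CODE,
                                            vocab.PLACEHOLDER_CODE),
                  date_range: tuple[str, str] = ("2018-01-01", "2022-05-31"),
                  ) -> UptakeSeries:
    """Monthly unique-patient counts per tracked code over the full lookback
    range (not restricted to the analysis window). A patient with several
    records of one code in a month counts once that month."""
    start, end = pd.Timestamp(date_range[0]), pd.Timestamp(date_range[1])
    if start > end:
        raise ValueError("empty date range")
    months = pd.period_range(start, end, freq="M")
    ev = events[events["code"].isin(codes)].copy()
    rows = []
    if not ev.empty:
        dates = pd.to_datetime(ev["date"])
        ev = ev[(dates >= start) & (dates <= end)]
        ev["month"] = pd.to_datetime(ev["date"]).dt.to_period("M").astype(str)
        uniq = ev.drop_duplicates(["person_id", "code", "month"])
        counts = uniq.groupby(["month", "code"]).size()
    else:
        counts = pd.Series(dtype=int)
    for m in months.astype(str):
        for c in codes:
            rows.append({"month": m, "code": c,
                         "n_patients": int(counts.get((m, c), 0))})
    return UptakeSeries(frame=pd.DataFrame(rows), codes=tuple(codes))
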