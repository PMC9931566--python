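"""Area-level SDoH categorization, disparity tests, and disclosure control.

Social-determinants variables (ACS-style percentages keyed by ZIP) are cut
into high / medium / low bands at percentiles of the FULL reference table
(all ZIPs, not just cohort ZIPs); patients are labelled by ZIP lookup, with
unmatched ZIPs labelled "missing".  Rates are compared between cohorts with
the g-test of independence (likelihood-ratio chi-square), and stratified
demographic tables are released with small-cell suppression plus bounded
random shifts on derivable complements.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SDOH_LABELS = ["high", "medium", "low", "missing"]


@dataclass
class SdohCategorization:
    """Percentile cutpoints for one variable plus the per-ZIP band labels.

    Band rule: low < lower cutpoint, high > upper cutpoint, medium in the
    closed interval between them (so a degenerate distribution where both
    cutpoints coincide labels everything medium).
    """

    variable: str
    cutpoints: tuple[float, float]
    labels_by_zip: dict[str, str]

    def label(self, zip_code: str) -> str:
        return self.labels_by_zip.get(zip_code, "missing")


def categorize_sdoh(sdoh_table: pd.DataFrame, variable: str,
                    percentiles: tuple[float, float] = (100 / 3, 200 / 3),
                    ) -> SdohCategorization:
    """Tertile-style banding of one area variable over all reference ZIPs.

    Cutpoints use linear-interpolation percentiles of the non-missing
    values; the banding is scale-invariant (multiplying the variable by a
    positive constant moves the cutpoints with the values).
    """
    if variable not in sdoh_table.columns:
        raise ValueError(f"variable {variable!r} not in SDoH table")
    values = pd.to_numeric(sdoh_table[variable], errors="coerce")
    ok = values.notna()
    if not ok.any():
        raise ValueError(f"variable {variable!r} has no non-missing values")
    lower, upper = np.percentile(values[ok], percentiles, method="linear")
    labels: dict[str, str] = {}
    for z, v in zip(sdoh_table["zip"], values):
        if pd.isna(v):
            labels[str(z)] = "missing"
        elif v < lower:
            labels[str(z)] = "low"
        elif v > upper:
            labels[str(z)] = "high"
        else:
            labels[str(z)] = "medium"
    return SdohCategorization(variable=variable,
                              cutpoints=(float(lower), float(upper)),
                              labels_by_zip=labels)


def label_patients(persons: pd.DataFrame,
                   categorization: SdohCategorization) -> pd.Series:
    """Per-patient band label looked up by ZIP; unmatched ZIP -> missing."""
    return persons["zip"].map(lambda z: categorization.label(str(z)))


# ---------------------------------------------------------------------------
# g-test

@dataclass(frozen=True)
class GTestResult:
    """Likelihood-ratio test of independence on a contingency table."""

    G: float
    df: int
    p_value: float


def g_test(contingency) -> GTestResult:
    """G = 2 sum O ln(O/E) over cells with O > 0, E from the product of the
    margins; df = (r-1)(c-1); p from the chi-square upper tail.

    All-zero rows and columns are dropped first; the cleaned table must be
    at least 2x2 with strictly positive margins.  No continuity or Williams
    correction is applied.
    """
    obs = np.asarray(contingency, dtype=float)
    if obs.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if (obs < 0).any():
        raise ValueError("contingency table must be non-negative")
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2 after dropping "
                         "all-zero rows/columns")
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    g = 2.0 * float(terms.sum())
    g = max(g, 0.0)  # clip tiny negative rounding on exact independence
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return GTestResult(G=g, df=df, p_value=float(stats.chi2.sf(g, df)))


def posthoc_compare(u099_counts: pd.Series, comparator_counts: pd.Series,
                    ) -> pd.DataFrame:
    """Per-category 2x2 g-tests between two cohorts' category counts.

    Both inputs are counts indexed by category (same category structure
    required).  For each category the 2x2 table is cohort membership
    (U09.9 vs comparator) crossed with in/out of the category; p-values are
    Bonferroni-adjusted across the categories actually tested.  Categories
    empty in both cohorts are skipped with a warning.
    """
    a = u099_counts.astype(float)
    b = comparator_counts.astype(float)
    if set(a.index) != set(b.index):
        raise ValueError("category structures differ between cohorts")
    b = b.reindex(a.index)
    n_a, n_b = a.sum(), b.sum()
    rows = []
    for cat in a.index:
        if a[cat] == 0 and b[cat] == 0:
            warnings.warn(f"category {cat!r} empty in both cohorts; skipped")
            continue
        table = np.array([[a[cat], n_a - a[cat]], [b[cat], n_b - b[cat]]])
        res = g_test(table)
        rows.append({
            "category": cat,
            "pct_a": 100.0 * a[cat] / n_a if n_a else np.nan,
            "pct_b": 100.0 * b[cat] / n_b if n_b else np.nan,
            "G": res.G,
            "df": res.df,
            "p_raw": res.p_value,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = np.minimum(out["p_raw"] * len(out), 1.0)
    return out


# ---------------------------------------------------------------------------
# disclosure control

@dataclass(frozen=True)
class SuppressionPolicy:
    """Small-cell suppression with bounded complement shifts.

    Counts in [1, threshold) are displayed as "<threshold"; when exactly one
    cell in a stratum column is suppressed (so a displayed stratum total
    would let a reader derive it), every displayed cell in that column is
    shifted by a nonzero amount in [-max_shift, max_shift], drawn under the
    policy seed and restricted so the shifted display never lands inside
    the suppressed band.  Zero cells display as 0 (they disclose nobody)
    unless they are the only complements of a lone suppressed cell, in
    which case they are complementarily suppressed (a zero cannot be
    shifted out of the banned band).
    """

    threshold: int = 20
    max_shift: int = 5
    seed: int = 0


@dataclass
class DisclosureTable:
    """A stratified count table after suppression and shifting.

    ``frame`` columns: variable, category, age_group, display (string),
    suppressed (bool), shifted (bool), shift (int, 0 if unshifted),
    percent (float or NaN, computed on the displayed/shifted counts).
    True counts are intentionally not carried on the released frame.
    """

    frame: pd.DataFrame
    policy: SuppressionPolicy
    stratum_sizes: dict[str, int]

    def displayed_counts(self) -> pd.Series:
        """Numeric displayed values (NaN where suppressed)."""
        return pd.to_numeric(self.frame["display"], errors="coerce")


def _draw_shift(rng: np.random.Generator, count: int,
                policy: SuppressionPolicy) -> int:
    """A nonzero shift in +-{1..max_shift} keeping count+shift out of
    [1, threshold-1]. The positive half is always admissible."""
    candidates = [s for s in range(-policy.max_shift, policy.max_shift + 1)
                  if s != 0 and not (1 <= count + s < policy.threshold)
                  and count + s >= 0]
    return int(rng.choice(candidates))


def demographic_table(cohort: pd.DataFrame, persons: pd.DataFrame,
                      sdoh_labels: dict[str, pd.Series] | None = None,
                      policy: SuppressionPolicy = SuppressionPolicy(),
                      variables: tuple[str, ...] = ("sex", "race", "ethnicity"),
                      ) -> DisclosureTable:
    """Counts by demographic / SDoH variable x category x age group, with
    the suppression policy applied per (variable, age-group) column.

    ``sdoh_labels`` maps an SDoH variable name to a per-person band label
    series aligned to ``persons`` order or indexed by person_id.
    """
    from .cohort import included  # avoid import cycle
    inc = included(cohort).set_index("person_id")
    p = persons.set_index("person_id").loc[inc.index]
    data = pd.DataFrame({"age_group": inc["age_group"]})
    for var in variables:
        data[var] = p[var]
    if sdoh_labels:
        for var, series in sdoh_labels.items():
            if series.index.equals(persons.index):
                series = pd.Series(series.values, index=persons["person_id"])
            data[var] = series.reindex(inc.index)

    rng = np.random.default_rng(policy.seed)
    stratum_sizes = data["age_group"].value_counts().to_dict()
    rows = []
    all_vars = [c for c in data.columns if c != "age_group"]
    for var in all_vars:
        categories = sorted(data[var].dropna().unique(), key=str)
        counts = (data.groupby(["age_group", var], observed=True).size())
        for group in sorted(stratum_sizes, key=str):
            n_stratum = stratum_sizes[group]
            col = []
            for cat in categories:
                cnt = int(counts.get((group, cat), 0))
                col.append((cat, cnt))
            suppressed = [1 <= cnt < policy.threshold for _, cnt in col]
            # a single suppressed cell is derivable from the stratum total:
            # shift every displayed complement
            shift_column = sum(suppressed) == 1
            if shift_column and not any(
                    cnt > 0 and not sup for (_, cnt), sup in zip(col,
                                                                 suppressed)):
                # no nonzero complement can absorb a shift; zero cells would
                # pin the suppressed value exactly, so suppress them too
                # (complementary suppression)
                suppressed = [sup or cnt == 0 for (_, cnt), sup
                              in zip(col, suppressed)]
                shift_column = False
            for (cat, cnt), sup in zip(col, suppressed):
                shift = 0
                if sup:
                    display = f"<{policy.threshold}"
                    pct = np.nan
                else:
                    shown = cnt
                    if shift_column and cnt > 0:
                        shift = _draw_shift(rng, cnt, policy)
                        shown = cnt + shift
                    display = str(shown)
                    pct = 100.0 * shown / n_stratum if n_stratum else np.nan
                rows.append({
                    "variable": var, "category": cat, "age_group": group,
                    "display": display, "suppressed": sup,
                    "shifted": shift != 0, "shift": shift,
                    "percent": round(pct, 1) if not math.isnan(pct) else np.nan,
                })
    frame = pd.DataFrame(rows)
    return DisclosureTable(frame=frame, policy=policy,
                           stratum_sizes={str(k): int(v)
                                          for k, v in stratum_sizes.items()})


def recoverable_cells(table: DisclosureTable) -> list[tuple[str, str, str]]:
    """Suppressed cells whose exact value a reader could recover from the
    displayed column and the stratum total, by interval arithmetic.

    A displayed unshifted count is exact; a shifted count is known to within
    +-max_shift.  A suppressed cell is recoverable when the feasible
    interval implied by the column collapses to a single value.  The
    suppression policy is safe when this list is empty.
    """
    out = []
    f = table.frame
    for (var, group), col in f.groupby(["variable", "age_group"]):
        if len(col) < 2:
            # a one-category variable IS the stratum margin; totals are
            # treated as public, so there is nothing to audit
            continue
        n = table.stratum_sizes[str(group)]
        sup = col[col["suppressed"]]
        if len(sup) == 0:
            continue
        lo = hi = n
        for _, r in col[~col["suppressed"]].iterrows():
            shown = int(r["display"])
            slack = table.policy.max_shift if r["shifted"] else 0
            lo -= shown + slack
            hi -= max(shown - slack, 0)
        # a lone suppressed cell is known nonzero; with complementary
        # suppression in play a suppressed cell may also be zero
        t = table.policy.threshold
        cell_min = 1 if len(sup) == 1 else 0
        for _, r in sup.iterrows():
            others_min = (len(sup) - 1) * cell_min
            others_max = (len(sup) - 1) * (t - 1)
            cell_lo = max(cell_min, lo - others_max)
            cell_hi = min(t - 1, hi - others_min)
            if cell_lo == cell_hi:
                out.append((var, str(r["category"]), str(group)))
    return out
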