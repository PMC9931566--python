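"""Synthetic OMOP-flavored EHR generator with planted ground truth.

The generator emulates the statistical structure a U09.9 (post-COVID
condition) characterization pipeline needs to be testable without access to
restricted enclave data:

* demographic marginals resembling a large multi-site long-COVID cohort;
* a latent per-patient symptom subtype, drawn from an age-group-specific
  mixture, that emits block-structured condition co-occurrence (conditions
  are emitted conditionally independently given the subtype);
* configurable fractions of inpatient-index, hospitalized-acute, severe and
  missing-COVID-index patients, realized as exact rounded counts by seeded
  assignment so downstream attrition numbers are deterministic;
* ZIP-linked social-determinants gradients, with an optional skew that
  over-samples low-deprivation ZIPs for the coded cohort;
* a temporal shift from placeholder code B94.8 to U09.9 around the coding
  switch date (default 2021-10-01).

One global seed drives a hierarchy of named sub-streams so that adding a
table does not perturb draws in earlier tables.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import vocab

AGE_GROUPS = ["<21", "21–45", "46–65", "66+"]
#: closed age bins matching the group labels, applied as [lo, hi)
AGE_BIN_EDGES = [0, 21, 46, 66, 121]

_STREAMS = {
    "persons": 0,
    "index": 1,
    "subtype": 2,
    "conditions": 3,
    "procedures": 4,
    "drugs": 5,
    "visits": 6,
    "tests": 7,
    "sites": 8,
    "sdoh": 9,
    "history": 10,
    "zips": 11,
}


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the offending field."""


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named sub-stream of the global seed (stable across table additions)."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


def default_subtype_profiles(within: float = 0.55) -> dict[str, dict[str, float]]:
    """Four symptom-subtype emission profiles planted on the bundled condition
    blocks: each subtype emits its own block's conditions with probability
    ``within`` and nothing else (background emission is configured separately).
    """
    profiles: dict[str, dict[str, float]] = {}
    for block in ("cardiopulmonary", "neurological", "gastrointestinal", "comorbid"):
        profiles[block] = {
            name: within for name, _ in vocab.CONDITION_BLOCKS[block]
        }
    return profiles


def default_mixtures() -> dict[str, dict[str, float]]:
    """Age-group subtype mixtures: neurological presentation dominates younger
    adults, comorbid-condition weight grows with age."""
    return {
        "<21": {"cardiopulmonary": 0.25, "neurological": 0.35,
                "gastrointestinal": 0.30, "comorbid": 0.10},
        "21–45": {"cardiopulmonary": 0.30, "neurological": 0.40,
                       "gastrointestinal": 0.20, "comorbid": 0.10},
        "46–65": {"cardiopulmonary": 0.35, "neurological": 0.30,
                       "gastrointestinal": 0.15, "comorbid": 0.20},
        "66+": {"cardiopulmonary": 0.30, "neurological": 0.20,
                "gastrointestinal": 0.10, "comorbid": 0.40},
    }


DEFAULT_SDOH_GRADIENTS: dict[str, tuple[float, float]] = {
    "poverty_pct": (11.0, 6.0),
    "college_pct": (15.0, 8.0),
    "public_insurance_pct": (18.0, 8.0),
    "unemployment_pct": (4.5, 2.0),
}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic population.

    Probability-vector fields must sum to 1 (within 1e-9); emission
    probabilities must lie in [0, 1].  Fractions of special patient classes
    are realized as exact rounded counts: ``frac_inpatient_index`` applies to
    all indexed patients, while the acute-hospitalization / severity /
    missing-COVID-index fractions apply to the post-exclusion base cohort,
    mirroring how those proportions are reported.
    """

    n_patients: int = 3000
    age_group_weights: tuple[float, ...] = (0.07, 0.34, 0.41, 0.18)
    subtype_profiles: dict[str, dict[str, float]] = field(
        default_factory=default_subtype_profiles)
    subtype_mixture_by_age: dict[str, dict[str, float]] = field(
        default_factory=default_mixtures)
    background_condition_rate: float = 0.03
    frac_inpatient_index: float = 0.084
    frac_hospitalized_acute: float = 0.097
    frac_severe_given_hospitalized: float = 0.242
    frac_missing_covid_index: float = 0.372
    frac_deceased: float = 0.0
    frac_b948_history: float = 0.25
    coding_switch_date: str = "2021-10-01"
    index_window: tuple[str, str] = ("2021-10-01", "2022-05-26")
    window_days: int = 60
    n_zips: int = 300
    n_sites: int = 10
    n_failing_sites: int = 0
    sdoh_gradients: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SDOH_GRADIENTS))
    sdoh_skew: float = 0.0  # >0 over-samples low-poverty ZIPs
    procedure_rate: float = 0.06
    encounter_code_rate: float = 0.80
    drug_rate: float = 0.05
    frac_drug_with_prior: float = 0.30
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be non-negative")
        self._check_simplex("age_group_weights", self.age_group_weights)
        if len(self.age_group_weights) != 4:
            raise ConfigError("age_group_weights must have 4 entries")
        for subtype, profile in self.subtype_profiles.items():
            for cond, p in profile.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(
                        f"subtype_profiles[{subtype!r}][{cond!r}] not in [0, 1]")
        for group, mix in self.subtype_mixture_by_age.items():
            self._check_simplex(f"subtype_mixture_by_age[{group!r}]", mix.values())
            unknown = set(mix) - set(self.subtype_profiles)
            if unknown:
                raise ConfigError(
                    f"subtype_mixture_by_age[{group!r}] references unknown "
                    f"subtypes {sorted(unknown)}")
        for name in ("background_condition_rate", "frac_inpatient_index",
                     "frac_hospitalized_acute", "frac_severe_given_hospitalized",
                     "frac_missing_covid_index", "frac_deceased",
                     "frac_b948_history"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        start, end = (dt.date.fromisoformat(d) for d in self.index_window)
        if start > end:
            raise ConfigError("index_window start after end")

    @staticmethod
    def _check_simplex(name, values) -> None:
        values = list(values)
        if any(v < 0 for v in values):
            raise ConfigError(f"{name} has a negative entry")
        if abs(sum(values) - 1.0) > 1e-9:
            raise ConfigError(f"{name} must sum to 1 (got {sum(values)!r})")


@dataclass
class RawTables:
    """The generated OMOP-flavored extract plus the planted truth table."""

    persons: pd.DataFrame
    coded_events: pd.DataFrame
    visits: pd.DataFrame
    tests: pd.DataFrame
    site_metadata: pd.DataFrame
    sdoh_by_zip: pd.DataFrame
    truth: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}


_PERSON_COLS = ["person_id", "birth_date", "sex", "race", "ethnicity", "zip",
                "deceased", "site_id", "hospitalized_acute", "severe_acute"]
_EVENT_COLS = ["person_id", "code", "vocabulary", "date", "event_class", "inpatient"]
_VISIT_COLS = ["person_id", "start_date", "end_date", "inpatient"]
_TEST_COLS = ["person_id", "test_date", "result"]
_SITE_COLS = ["site_id", "lab_coverage", "valid_end_date_frac",
              "date_shift_days", "n_index_code"]

SEX_MARGINAL = {"Female": 0.665, "Male": 0.330, "Unknown": 0.005}
RACE_MARGINAL = {"White": 0.715, "Black": 0.138, "Asian": 0.022,
                 "American Indian or Alaska Native": 0.008,
                 "Hawaiian/Pac Isldr": 0.002, "Other": 0.010, "Unknown": 0.105}
ETHNICITY_MARGINAL = {"Hispanic/Latino": 0.105,
                      "Not Hispanic/Latino": 0.795, "Unknown": 0.100}


def _empty_tables() -> RawTables:
    return RawTables(
        persons=pd.DataFrame(columns=_PERSON_COLS),
        coded_events=pd.DataFrame(columns=_EVENT_COLS),
        visits=pd.DataFrame(columns=_VISIT_COLS),
        tests=pd.DataFrame(columns=_TEST_COLS),
        site_metadata=pd.DataFrame(columns=_SITE_COLS),
        sdoh_by_zip=pd.DataFrame(columns=["zip", *DEFAULT_SDOH_GRADIENTS]),
        truth=pd.DataFrame(columns=["person_id", "subtype"]),
    )


def _iso(dates: np.ndarray) -> np.ndarray:
    """datetime64[D] array -> ISO-8601 strings."""
    return np.datetime_as_string(dates, unit="D")


def _pick_exact(rng: np.random.Generator, candidates: np.ndarray, frac: float) -> np.ndarray:
    """Seeded choice of exactly round(frac * len(candidates)) items."""
    k = int(round(frac * len(candidates)))
    if k == 0:
        return candidates[:0]
    return rng.choice(candidates, size=k, replace=False)


def make_zips(n_zips: int, seed: int) -> list[str]:
    rng = _rng(seed, "zips")
    pool = rng.choice(np.arange(1000, 99999), size=n_zips, replace=False)
    return [f"{z:05d}" for z in np.sort(pool)]


def generate_sdoh_table(zips: list[str],
                        gradient_spec: dict[str, tuple[float, float]],
                        seed: int) -> pd.DataFrame:
    """One row per ZIP with percentage-valued area variables, drawn normal
    with the given (mean, sd) and clipped to [0, 100]."""
    if len(zips) == 0:
        raise ConfigError("zips must be non-empty")
    if len(set(zips)) != len(zips):
        raise ConfigError("duplicate ZIPs in input")
    rng = _rng(seed, "sdoh")
    out = {"zip": list(zips)}
    for var, (mean, sd) in gradient_spec.items():
        if sd < 0:
            raise ConfigError(f"gradient_spec[{var!r}] has negative sd")
        out[var] = np.clip(rng.normal(mean, sd, size=len(zips)), 0.0, 100.0)
    return pd.DataFrame(out)


def generate_population(config: GeneratorConfig) -> RawTables:
    """Draw the full synthetic extract. Deterministic given ``config.seed``."""
    config.validate()
    n = config.n_patients
    if n == 0:
        return _empty_tables()
    seed = config.seed

    win_start = np.datetime64(config.index_window[0])
    win_end = np.datetime64(config.index_window[1])
    n_index_days = int((win_end - win_start).astype(int)) + 1
    switch = np.datetime64(config.coding_switch_date)

    # --- persons -----------------------------------------------------------
    rng = _rng(seed, "persons")
    person_id = np.array([f"P{i:07d}" for i in range(n)])
    age_group_idx = rng.choice(4, size=n, p=np.asarray(config.age_group_weights))
    lo = np.array(AGE_BIN_EDGES[:-1])[age_group_idx]
    hi = np.array([21, 46, 66, 95])[age_group_idx]
    age_years = rng.uniform(lo, hi)

    sex = rng.choice(list(SEX_MARGINAL), size=n, p=list(SEX_MARGINAL.values()))
    race = rng.choice(list(RACE_MARGINAL), size=n, p=list(RACE_MARGINAL.values()))
    eth = rng.choice(list(ETHNICITY_MARGINAL), size=n,
                     p=list(ETHNICITY_MARGINAL.values()))
    deceased = np.zeros(n, dtype=int)
    deceased[_indices(_pick_exact(rng, np.arange(n), config.frac_deceased))] = 1

    zips = make_zips(config.n_zips, seed)
    sdoh = generate_sdoh_table(zips, config.sdoh_gradients, seed)
    if config.sdoh_skew > 0:
        pov_rank = sdoh["poverty_pct"].rank(pct=True).to_numpy()
        w = np.exp(-config.sdoh_skew * pov_rank)
        zip_p = w / w.sum()
    else:
        zip_p = np.full(len(zips), 1.0 / len(zips))
    person_zip = rng.choice(np.asarray(zips), size=n, p=zip_p)

    # --- index dates -------------------------------------------------------
    rng_idx = _rng(seed, "index")
    index_date = win_start + rng_idx.integers(0, n_index_days, size=n)
    birth_date = (index_date
                  - (age_years * 365.25).astype(int).astype("timedelta64[D]"))

    # exact-count class assignment: inpatient-index among all, then the
    # acute-infection classes among the expected post-exclusion base cohort
    alive = np.flatnonzero(deceased == 0)
    inpatient_index = np.zeros(n, dtype=bool)
    inpatient_index[_indices(_pick_exact(rng_idx, alive, config.frac_inpatient_index * n / max(len(alive), 1)))] = True
    base = np.flatnonzero(~inpatient_index & (deceased == 0))
    missing_covid = np.zeros(n, dtype=bool)
    missing_covid[_indices(_pick_exact(rng_idx, base, config.frac_missing_covid_index))] = True
    hosp_pool = np.flatnonzero(~inpatient_index & (deceased == 0) & ~missing_covid)
    k_hosp = int(round(config.frac_hospitalized_acute * len(base)))
    hosp_acute = np.zeros(n, dtype=bool)
    hosp_idx = rng_idx.choice(hosp_pool, size=min(k_hosp, len(hosp_pool)), replace=False)
    hosp_acute[hosp_idx] = True
    severe = np.zeros(n, dtype=bool)
    severe[_indices(_pick_exact(rng_idx, hosp_idx, config.frac_severe_given_hospitalized))] = True

    site_ids = np.array([f"S{i:02d}" for i in range(config.n_sites)])
    person_site = rng_idx.choice(site_ids, size=n)

    persons = pd.DataFrame({
        "person_id": person_id,
        "birth_date": _iso(birth_date),
        "sex": sex, "race": race, "ethnicity": eth,
        "zip": person_zip,
        "deceased": deceased,
        "site_id": person_site,
        "hospitalized_acute": hosp_acute.astype(int),
        "severe_acute": severe.astype(int),
    })

    # --- latent subtype and condition events -------------------------------
    rng_sub = _rng(seed, "subtype")
    subtype_names = list(config.subtype_profiles)
    subtype_idx = np.empty(n, dtype=int)
    for g, group in enumerate(AGE_GROUPS):
        mix = config.subtype_mixture_by_age[group]
        p = np.array([mix.get(s, 0.0) for s in subtype_names])
        members = np.flatnonzero(age_group_idx == g)
        subtype_idx[members] = rng_sub.choice(len(subtype_names), size=len(members), p=p)
    truth = pd.DataFrame({"person_id": person_id,
                          "subtype": np.array(subtype_names)[subtype_idx]})

    cond_names = vocab.CONDITION_NAMES
    emission = np.full((len(subtype_names), len(cond_names)),
                       config.background_condition_rate)
    for s, sname in enumerate(subtype_names):
        for c, cname in enumerate(cond_names):
            p = config.subtype_profiles[sname].get(cname, 0.0)
            emission[s, c] = min(1.0, p + config.background_condition_rate)

    rng_cond = _rng(seed, "conditions")
    hits = rng_cond.random((n, len(cond_names))) < emission[subtype_idx]
    pi, ci = np.nonzero(hits)
    offsets = rng_cond.integers(0, config.window_days + 1, size=len(pi))
    cond_dates = index_date[pi] + offsets.astype("timedelta64[D]")
    # choose one ICD-10-CM code per emitted condition (conditions may own >1)
    icd_codes = np.empty(len(pi), dtype=object)
    code_lists = [vocab.CONDITION_TO_ICD[c] for c in cond_names]
    pick = rng_cond.integers(0, 1 << 30, size=len(pi))
    for k in range(len(pi)):
        codes = code_lists[ci[k]]
        icd_codes[k] = codes[pick[k] % len(codes)]

    cond_events = pd.DataFrame({
        "person_id": person_id[pi],
        "code": icd_codes,
        "vocabulary": "ICD-10-CM",
        "date": _iso(cond_dates),
        "event_class": "condition",
        "inpatient": 0,
    })

    # index code events: one at index, occasionally repeated inside the window
    repeat = rng_cond.random(n) < 0.2
    idx_events = pd.DataFrame({
        "person_id": np.concatenate([person_id, person_id[repeat]]),
        "code": vocab.INDEX_CODE,
        "vocabulary": "ICD-10-CM",
        "date": np.concatenate([
            _iso(index_date),
            _iso(index_date[repeat]
                 + rng_cond.integers(1, config.window_days + 1,
                                     size=int(repeat.sum())).astype("timedelta64[D]")),
        ]),
        "event_class": "condition",
        "inpatient": np.concatenate([inpatient_index.astype(int),
                                     np.zeros(int(repeat.sum()), dtype=int)]),
    })

    # placeholder-code history before the coding switch date
    rng_hist = _rng(seed, "history")
    with_hist = _indices(_pick_exact(rng_hist, np.arange(n), config.frac_b948_history))
    hist_start = np.datetime64("2020-04-01")
    n_hist_days = int((switch - hist_start).astype(int))
    hist_events = pd.DataFrame({
        "person_id": person_id[with_hist],
        "code": vocab.PLACEHOLDER_CODE,
        "vocabulary": "ICD-10-CM",
        "date": _iso(hist_start + rng_hist.integers(0, max(n_hist_days, 1),
                                                    size=len(with_hist)).astype("timedelta64[D]")),
        "event_class": "condition",
        "inpatient": 0,
    })

    # --- procedures --------------------------------------------------------
    rng_proc = _rng(seed, "procedures")
    proc_codes = np.array(list(vocab.PROCEDURE_CATEGORY_OF))
    p_hits = rng_proc.random((n, len(proc_codes))) < config.procedure_rate
    ppi, pci = np.nonzero(p_hits)
    proc_events = pd.DataFrame({
        "person_id": person_id[ppi],
        "code": proc_codes[pci],
        "vocabulary": "CPT4",
        "date": _iso(index_date[ppi]
                     + rng_proc.integers(0, config.window_days + 1,
                                         size=len(ppi)).astype("timedelta64[D]")),
        "event_class": "procedure",
        "inpatient": 0,
    })
    enc = rng_proc.random(n) < config.encounter_code_rate
    enc_codes = rng_proc.choice(sorted(vocab.NONINFORMATIVE_PROCEDURE_CODES),
                                size=int(enc.sum()))
    enc_events = pd.DataFrame({
        "person_id": person_id[enc],
        "code": enc_codes,
        "vocabulary": "CPT4",
        "date": _iso(index_date[enc]
                     + rng_proc.integers(0, config.window_days + 1,
                                         size=int(enc.sum())).astype("timedelta64[D]")),
        "event_class": "procedure",
        "inpatient": 0,
    })

    # --- drugs -------------------------------------------------------------
    rng_drug = _rng(seed, "drugs")
    ingredients = np.array(vocab.INGREDIENTS)
    d_hits = rng_drug.random((n, len(ingredients))) < config.drug_rate
    dpi, dci = np.nonzero(d_hits)
    in_window_dates = index_date[dpi] + rng_drug.integers(
        0, config.window_days + 1, size=len(dpi)).astype("timedelta64[D]")
    drug_frames = [pd.DataFrame({
        "person_id": person_id[dpi],
        "code": ingredients[dci],
        "vocabulary": "RxNorm",
        "date": _iso(in_window_dates),
        "event_class": "drug",
        "inpatient": 0,
    })]
    # a seeded subset of in-window drugs also has a pre-index record, so the
    # new-medication rule has real traffic to filter out
    prior = rng_drug.random(len(dpi)) < config.frac_drug_with_prior
    if prior.any():
        prior_dates = index_date[dpi[prior]] - rng_drug.integers(
            10, 400, size=int(prior.sum())).astype("timedelta64[D]")
        drug_frames.append(pd.DataFrame({
            "person_id": person_id[dpi[prior]],
            "code": ingredients[dci[prior]],
            "vocabulary": "RxNorm",
            "date": _iso(prior_dates),
            "event_class": "drug",
            "inpatient": 0,
        }))

    coded_events = pd.concat(
        [idx_events, cond_events, hist_events, proc_events, enc_events,
         *drug_frames], ignore_index=True)

    # --- visits ------------------------------------------------------------
    rng_vis = _rng(seed, "visits")
    frames = [pd.DataFrame({
        "person_id": person_id,
        "start_date": _iso(index_date),
        "end_date": _iso(index_date),
        "inpatient": 0,
    })]
    inp = np.flatnonzero(inpatient_index)
    if len(inp):
        frames.append(pd.DataFrame({
            "person_id": person_id[inp],
            "start_date": _iso(index_date[inp] - np.timedelta64(2, "D")),
            "end_date": _iso(index_date[inp] + np.timedelta64(3, "D")),
            "inpatient": 1,
        }))

    # --- tests (SARS-CoV-2) ------------------------------------------------
    rng_test = _rng(seed, "tests")
    has_covid_idx = np.flatnonzero(~missing_covid & (deceased == 0))
    covid_dates = index_date[has_covid_idx] - rng_test.integers(
        30, 181, size=len(has_covid_idx)).astype("timedelta64[D]")
    tests = pd.DataFrame({
        "person_id": person_id[has_covid_idx],
        "test_date": _iso(covid_dates),
        "result": "positive",
    })
    hosp_with_idx = np.flatnonzero(hosp_acute)
    if len(hosp_with_idx):
        # acute-infection hospitalization around the COVID test date
        hosp_dates = pd.Series(_iso(covid_dates),
                               index=has_covid_idx).reindex(hosp_with_idx)
        start = hosp_dates.to_numpy().astype("datetime64[D]")
        frames.append(pd.DataFrame({
            "person_id": person_id[hosp_with_idx],
            "start_date": _iso(start),
            "end_date": _iso(start + np.timedelta64(7, "D")),
            "inpatient": 1,
        }))
    visits = pd.concat(frames, ignore_index=True)

    # --- site metadata -----------------------------------------------------
    rng_site = _rng(seed, "sites")
    n_sites = config.n_sites
    lab = rng_site.uniform(0.30, 0.90, size=n_sites)
    valid_end = rng_site.uniform(0.80, 1.00, size=n_sites)
    shift = rng_site.integers(0, 31, size=n_sites)
    for j in range(min(config.n_failing_sites, n_sites)):
        which = j % 3
        if which == 0:
            lab[j] = 0.10
        elif which == 1:
            valid_end[j] = 0.50
        else:
            shift[j] = 45
    n_index_code = pd.Series(person_site).value_counts().reindex(
        site_ids, fill_value=0).to_numpy()
    site_metadata = pd.DataFrame({
        "site_id": site_ids,
        "lab_coverage": np.round(lab, 3),
        "valid_end_date_frac": np.round(valid_end, 3),
        "date_shift_days": shift,
        "n_index_code": n_index_code,
    })

    return RawTables(persons=persons, coded_events=coded_events, visits=visits,
                     tests=tests, site_metadata=site_metadata,
                     sdoh_by_zip=sdoh, truth=truth)


def _indices(picked: np.ndarray) -> np.ndarray:
    return picked.astype(int) if len(picked) else np.array([], dtype=int)


def condition_block_labels(conditions: list[str]) -> dict[str, str]:
    """Planted block label for each condition name (ground truth for
    community-recovery checks)."""
    return {c: vocab.CONDITION_BLOCK_OF.get(c, "background") for c in conditions}
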