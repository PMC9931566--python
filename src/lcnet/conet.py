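"""Condition co-occurrence networks and their community structure.

The analytic core of the package: from windowed condition events, build the
top-K condition co-occurrence network (nodes = SNOMED-style condition
names, edge weight = number of distinct patients carrying both conditions
inside their analysis window) and detect communities with Louvain,
Girvan–Newman or Walktrap, scored by weighted modularity.

The modelling surface follows the statsmodels convention:

>>> model = CooccurrenceModel.from_events(windowed, k=30)
>>> res = model.fit(algorithm="louvain", seed=0)
>>> res.summary()          # community membership table
>>> res.stability(B=50)    # bootstrap adjusted-Rand stability
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import vocab
from .community import ari, detect, modularity


def map_conditions(events: pd.DataFrame,
                   crosswalk: dict[str, str] | None = None) -> pd.DataFrame:
    """Collapse ICD-10-CM codes onto SNOMED-style condition display names.

    Codes absent from the crosswalk pass through unchanged, so the function
    is total over arbitrary vocabularies.
    """
    crosswalk = vocab.ICD_TO_CONDITION if crosswalk is None else crosswalk
    out = events.copy()
    out["condition"] = out["code"].map(lambda c: crosswalk.get(c, c))
    return out


def top_conditions(windowed_events: pd.DataFrame, k: int = 30,
                   exclude: tuple[str, ...] = (vocab.INDEX_CODE,),
                   crosswalk: dict[str, str] | None = None) -> list[str]:
    """The K conditions with the largest unique-patient counts.

    A person contributes each condition at most once; the index code itself
    is never a candidate.  Ties break lexicographically on the condition
    name so the ranking is invariant to event order.
    """
    ev = windowed_events
    if "event_class" in ev.columns:
        ev = ev[ev["event_class"] == "condition"]
    ev = map_conditions(ev, crosswalk)
    ev = ev[~ev["condition"].isin(exclude)]
    counts = (ev.drop_duplicates(["person_id", "condition"])
              .groupby("condition").size())
    if len(counts) < k:
        warnings.warn(f"only {len(counts)} distinct conditions available "
                      f"(requested top {k})")
    ranked = counts.sort_index().sort_values(ascending=False, kind="stable")
    return ranked.index[:k].tolist()


@dataclass
class CooccurrenceNetwork:
    """Symmetric patient-count co-occurrence graph over an ordered node list.

    ``weights[i, j]`` counts distinct persons whose analysis window contains
    both condition i and condition j; the diagonal is zero and
    ``weights[i, j] <= min(node_freq[i], node_freq[j])``.
    """

    nodes: list[str]
    weights: np.ndarray
    node_freq: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights)
        if not np.array_equal(self.weights, self.weights.T):
            raise ValueError("co-occurrence matrix must be symmetric")

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum()) / 2.0

    def edge_list(self) -> pd.DataFrame:
        """Nonzero edges as (node_a, node_b, weight) rows, GraphML-style."""
        rows = []
        for i in range(len(self.nodes)):
            for j in range(i + 1, len(self.nodes)):
                if self.weights[i, j] > 0:
                    rows.append((self.nodes[i], self.nodes[j],
                                 int(self.weights[i, j])))
        return pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])

    def matrix_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.nodes, columns=self.nodes)


def incidence_matrix(windowed_events: pd.DataFrame, conditions: list[str],
                     crosswalk: dict[str, str] | None = None,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Binary person x condition incidence over ``conditions``.

    Returns (person ids, matrix); persons with no listed condition are
    absent (they contribute nothing to any pairwise count).
    """
    ev = windowed_events
    if "event_class" in ev.columns:
        ev = ev[ev["event_class"] == "condition"]
    ev = map_conditions(ev, crosswalk)
    ev = ev[ev["condition"].isin(conditions)]
    pairs = ev.drop_duplicates(["person_id", "condition"])
    col = {c: i for i, c in enumerate(conditions)}
    persons = pairs["person_id"].unique()
    row = {p: i for i, p in enumerate(persons)}
    incidence = np.zeros((len(persons), len(conditions)), dtype=np.int64)
    if len(pairs):
        incidence[pairs["person_id"].map(row).to_numpy(),
                  pairs["condition"].map(col).to_numpy()] = 1
    return persons, incidence


def _network_from_incidence(conditions: list[str],
                            incidence: np.ndarray) -> CooccurrenceNetwork:
    w = incidence.T @ incidence
    freq = np.diag(w).copy()
    np.fill_diagonal(w, 0)
    return CooccurrenceNetwork(nodes=list(conditions), weights=w,
                               node_freq=freq)


def cooccurrence(windowed_events: pd.DataFrame, conditions: list[str],
                 crosswalk: dict[str, str] | None = None) -> CooccurrenceNetwork:
    """Build the patient-count co-occurrence network over ``conditions``.

    Conditions absent from the events are retained as zero-frequency nodes.
    """
    if not conditions:
        raise ValueError("conditions list must be non-empty")
    _, incidence = incidence_matrix(windowed_events, conditions, crosswalk)
    return _network_from_incidence(conditions, incidence)


@dataclass
class StabilityReport:
    """Bootstrap stability of a partition: per-replicate adjusted Rand index
    against the full-data reference."""

    B: int
    ari_values: list[float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.ari_values))

    @property
    def min(self) -> float:
        return float(np.min(self.ari_values))


class CooccurrenceModel:
    """Community-structure model of a condition co-occurrence network.

    Built either from a prebuilt :class:`CooccurrenceNetwork` or directly
    from windowed condition events via :meth:`from_events` (which keeps the
    events so bootstrap stability can resample patients).
    """

    def __init__(self, network: CooccurrenceNetwork,
                 events: pd.DataFrame | None = None,
                 crosswalk: dict[str, str] | None = None):
        self.network = network
        self._events = events
        self._crosswalk = crosswalk

    @classmethod
    def from_events(cls, windowed_events: pd.DataFrame, k: int = 30,
                    crosswalk: dict[str, str] | None = None) -> "CooccurrenceModel":
        conditions = top_conditions(windowed_events, k=k, crosswalk=crosswalk)
        net = cooccurrence(windowed_events, conditions, crosswalk)
        return cls(net, events=windowed_events, crosswalk=crosswalk)

    def fit(self, algorithm: str = "louvain", resolution: float = 1.0,
            seed: int = 0, t: int = 4) -> "CommunityDetectionResults":
        labels = detect(self.network.weights, algorithm=algorithm,
                        resolution=resolution, seed=seed, t=t)
        q = modularity(self.network.weights, labels, resolution)
        return CommunityDetectionResults(
            model=self, algorithm=algorithm, resolution=resolution,
            seed=seed, labels=labels, Q=q)


@dataclass
class CommunityDetectionResults:
    """A fitted partition: community labels per node plus its modularity."""

    model: CooccurrenceModel
    algorithm: str
    resolution: float
    seed: int
    labels: np.ndarray
    Q: float

    @property
    def assignment(self) -> dict[str, int]:
        return dict(zip(self.model.network.nodes, (int(x) for x in self.labels)))

    @property
    def n_communities(self) -> int:
        return int(len(np.unique(self.labels)))

    def membership_frame(self) -> pd.DataFrame:
        net = self.model.network
        return pd.DataFrame({
            "node": net.nodes,
            "community": self.labels,
            "patient_count": net.node_freq,
        }).sort_values(["community", "patient_count"],
                       ascending=[True, False]).reset_index(drop=True)

    def summary(self) -> str:
        lines = [
            "Community detection on condition co-occurrence network",
            f"  algorithm:   {self.algorithm}"
            + (f" (resolution={self.resolution})"
               if self.algorithm == "louvain" else ""),
            f"  nodes:       {len(self.labels)}",
            f"  communities: {self.n_communities}",
            f"  modularity Q: {self.Q:.4f}",
            "",
        ]
        frame = self.membership_frame()
        for c, grp in frame.groupby("community"):
            lines.append(f"  community {c} ({len(grp)} conditions):")
            for _, r in grp.iterrows():
                lines.append(f"    {r['node']}  (n={r['patient_count']})")
        return "\n".join(lines)

    def stability(self, B: int = 50, seed: int = 0) -> StabilityReport:
        """Patient-bootstrap stability: resample patients with replacement,
        rebuild the network on the same node set, re-detect, and score the
        adjusted Rand index against this reference partition."""
        events = self.model._events
        if events is None:
            raise ValueError("model was not built from events; "
                             "stability needs patient-level data")
        return stability(events, self.model.network.nodes, self.algorithm,
                         B=B, seed=seed, resolution=self.resolution,
                         reference=self.labels, crosswalk=self.model._crosswalk)


def stability(windowed_events: pd.DataFrame, conditions: list[str],
              algorithm: str, B: int, seed: int = 0,
              resolution: float = 1.0,
              reference: np.ndarray | None = None,
              crosswalk: dict[str, str] | None = None) -> StabilityReport:
    """Bootstrap replicates of network construction + detection, scored by
    adjusted Rand index against the full-data reference partition."""
    if B < 1:
        raise ValueError("B must be >= 1")
    if len(windowed_events) == 0 or windowed_events["person_id"].nunique() == 0:
        raise ValueError("no patients in windowed events")
    persons, incidence = incidence_matrix(windowed_events, conditions,
                                          crosswalk)
    if reference is None:
        net = _network_from_incidence(conditions, incidence.copy())
        reference = detect(net.weights, algorithm=algorithm,
                           resolution=resolution, seed=seed)
    rng = np.random.default_rng(seed)
    aris = []
    for b in range(B):
        rows = rng.integers(0, len(persons), size=len(persons))
        net_b = _network_from_incidence(conditions, incidence[rows])
        if net_b.weights.sum() == 0:
            aris.append(0.0)
            continue
        labels_b = detect(net_b.weights, algorithm=algorithm,
                          resolution=resolution, seed=seed + b + 1)
        aris.append(ari(reference, labels_b))
    return StabilityReport(B=B, ari_values=aris)


def stratified_networks(cohort: pd.DataFrame, windowed_events: pd.DataFrame,
                        k: int = 30, algorithm: str = "louvain",
                        resolution: float = 1.0, seed: int = 0,
                        crosswalk: dict[str, str] | None = None,
                        ) -> dict[str, CommunityDetectionResults]:
    """Independent top-K network + detection inside each age stratum.

    The top-K condition lists may differ by stratum.  Strata with fewer than
    two distinct conditions (or no co-occurrence at all) are skipped with a
    warning; other strata are unaffected.
    """
    out: dict[str, CommunityDetectionResults] = {}
    from .cohort import included  # local import to avoid a cycle
    inc = included(cohort)
    for group, members in inc.groupby("age_group", sort=False):
        ev = windowed_events[
            windowed_events["person_id"].isin(members["person_id"])]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            conds = top_conditions(ev, k=k, crosswalk=crosswalk)
        if len(conds) < 2:
            warnings.warn(f"age group {group!r}: fewer than 2 conditions, "
                          "stratum skipped")
            continue
        net = cooccurrence(ev, conds, crosswalk)
        if net.weights.sum() == 0:
            warnings.warn(f"age group {group!r}: no co-occurrence, "
                          "stratum skipped")
            continue
        model = CooccurrenceModel(net, events=ev, crosswalk=crosswalk)
        out[str(group)] = model.fit(algorithm=algorithm,
                                    resolution=resolution, seed=seed)
    return out
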