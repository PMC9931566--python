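"""Network construction, the model surface, stability and stratification."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcnet.community import ari
from lcnet.conet import (CooccurrenceModel, cooccurrence, stability,
                         stratified_networks, top_conditions)
from lcnet.synth import GeneratorConfig, generate_population, \
    condition_block_labels
from lcnet.cohort import apply_exclusions, derive_index, window_events


def cond_events(rows):
    return pd.DataFrame(rows, columns=["person_id", "code"]).assign(
        vocabulary="ICD-10-CM", date="2022-01-10", event_class="condition",
        inpatient=0)


class TestTopConditions:
    def test_duplicate_events_collapse_per_patient(self):
        ev = cond_events([("P1", "A"), ("P1", "A"), ("P1", "B"), ("P2", "A")])
        assert top_conditions(ev, k=2, exclude=()) == ["A", "B"]

    def test_ties_break_lexicographically(self):
        ev = cond_events([("P1", "Y"), ("P2", "X")])
        assert top_conditions(ev, k=1, exclude=()) == ["X"]

    def test_ranking_invariant_to_event_permutation(self):
        rows = [("P1", "C"), ("P2", "C"), ("P1", "B"), ("P3", "B"),
                ("P2", "A"), ("P1", "A"), ("P3", "A")]
        base = top_conditions(cond_events(rows), k=3, exclude=())
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = [rows[i] for i in rng.permutation(len(rows))]
            assert top_conditions(cond_events(perm), k=3, exclude=()) == base

    def test_index_code_never_a_candidate(self):
        ev = cond_events([("P1", "U09.9"), ("P1", "R53.83"), ("P2", "U09.9")])
        with pytest.warns(UserWarning, match="distinct conditions"):
            assert top_conditions(ev, k=5) == ["Fatigue"]

    def test_exactly_k_from_generator_output(self, small_windowed):
        conds = top_conditions(small_windowed, k=30)
        assert len(conds) == 30

    def test_short_supply_warns_and_returns_all(self):
        ev = cond_events([("P1", "A"), ("P1", "B")])
        with pytest.warns(UserWarning, match="distinct conditions"):
            assert len(top_conditions(ev, k=30, exclude=())) == 2

    def test_icd_synonyms_collapse_to_one_condition(self):
        # R06.00 and R06.02 both mean dyspnea
        ev = cond_events([("P1", "R06.00"), ("P2", "R06.02")])
        with pytest.warns(UserWarning, match="distinct conditions"):
            conds = top_conditions(ev, k=5)
        assert conds == ["Dyspnea"]


class TestCooccurrence:
    def test_matches_brute_force_pair_enumeration(self):
        ev = cond_events([("P1", "A"), ("P1", "B"), ("P2", "A"), ("P2", "B"),
                          ("P3", "A"), ("P3", "C")])
        net = cooccurrence(ev, ["A", "B", "C"])
        w = net.matrix_frame()
        assert w.loc["A", "B"] == 2
        assert w.loc["A", "C"] == 1
        assert w.loc["B", "C"] == 0

    def test_single_patient_with_all_conditions_gives_complete_graph(self):
        conds = ["A", "B", "C", "D"]
        ev = cond_events([("P1", c) for c in conds])
        net = cooccurrence(ev, conds)
        off = ~np.eye(4, dtype=bool)
        assert (net.weights[off] == 1).all()

    def test_patient_order_invariance(self):
        rows = [("P1", "A"), ("P1", "B"), ("P2", "B"), ("P3", "A")]
        a = cooccurrence(cond_events(rows), ["A", "B"]).weights
        b = cooccurrence(cond_events(rows[::-1]), ["A", "B"]).weights
        assert np.array_equal(a, b)

    def test_absent_condition_kept_with_zero_frequency(self):
        net = cooccurrence(cond_events([("P1", "A")]), ["A", "Z"])
        assert net.node_freq[net.nodes.index("Z")] == 0

    def test_empty_condition_list_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            cooccurrence(cond_events([("P1", "A")]), [])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 9), st.integers(0, 4)),
                    min_size=1, max_size=60))
    def test_weight_bounded_by_node_frequencies(self, pairs):
        """w(i,j) <= min(freq_i, freq_j) on arbitrary random event sets."""
        ev = cond_events([(f"P{p}", f"C{c}") for p, c in pairs])
        conds = [f"C{c}" for c in range(5)]
        net = cooccurrence(ev, conds)
        for i, j in combinations(range(5), 2):
            assert net.weights[i, j] <= min(net.node_freq[i],
                                            net.node_freq[j])


class TestModelSurface:
    def test_fit_reports_consistent_modularity(self, small_windowed):
        model = CooccurrenceModel.from_events(small_windowed, k=30)
        res = model.fit(algorithm="louvain", seed=0)
        from lcnet.community import modularity
        assert res.Q == pytest.approx(
            modularity(model.network.weights, res.labels), abs=1e-12)
        assert set(res.assignment) == set(model.network.nodes)

    def test_summary_mentions_algorithm_and_q(self, small_windowed):
        res = CooccurrenceModel.from_events(small_windowed, k=10).fit()
        text = res.summary()
        assert "louvain" in text and "modularity" in text

    def test_edge_list_round_trips_matrix(self, small_windowed):
        model = CooccurrenceModel.from_events(small_windowed, k=10)
        edges = model.network.edge_list()
        total = edges["weight"].sum()
        assert total == model.network.weights.sum() / 2


class TestStability:
    def test_identical_partition_scores_one(self):
        assert ari([0, 1, 0, 1], [0, 1, 0, 1]) == 1.0

    def test_bootstrap_on_planted_blocks_is_stable(self):
        cfg = GeneratorConfig(
            n_patients=800, seed=5,
            subtype_profiles={
                "a": {"Fatigue": 0.5, "Headache": 0.5, "Dizziness": 0.5},
                "b": {"Nausea": 0.5, "Diarrhea": 0.5, "Vomiting": 0.5}},
            subtype_mixture_by_age={g: {"a": 0.5, "b": 0.5}
                                    for g in ("<21", "21–45", "46–65",
                                              "66+")})
        tabs = generate_population(cfg)
        cohort = apply_exclusions(tabs.persons, tabs.visits,
                                  derive_index(tabs.coded_events), tabs.tests)
        win = window_events(cohort, tabs.coded_events)
        conds = ["Fatigue", "Headache", "Dizziness", "Nausea", "Diarrhea",
                 "Vomiting"]
        report = stability(win, conds, "louvain", B=50, seed=0)
        assert report.B == 50 and len(report.ari_values) == 50
        assert all(-1 <= v <= 1 for v in report.ari_values)
        assert report.mean >= 0.8

    def test_empty_events_rejected(self):
        with pytest.raises(ValueError, match="no patients"):
            stability(cond_events([]).iloc[:0], ["A"], "louvain", B=2)

    def test_invalid_replicate_count_rejected(self, small_windowed):
        with pytest.raises(ValueError, match="B"):
            stability(small_windowed, ["Fatigue"], "louvain", B=0)


class TestStratifiedNetworks:
    def test_age_specific_block_appears_only_in_its_stratum(self):
        """A subtype planted only in the youngest mixture produces its block
        only in that stratum's network."""
        profiles = {
            "resp": {"Acute pharyngitis": 0.6,
                     "Acute upper respiratory infection": 0.6,
                     "Acute sinusitis": 0.6, "Otitis media": 0.6},
            "neuro": {"Fatigue": 0.6, "Headache": 0.6, "Dizziness": 0.6,
                      "Memory impairment": 0.6},
            "gi": {"Nausea": 0.6, "Diarrhea": 0.6, "Vomiting": 0.6,
                   "Abdominal pain": 0.6},
        }
        mixtures = {"<21": {"resp": 0.5, "neuro": 0.5},
                    "21–45": {"neuro": 0.5, "gi": 0.5},
                    "46–65": {"neuro": 0.5, "gi": 0.5},
                    "66+": {"neuro": 0.5, "gi": 0.5}}
        cfg = GeneratorConfig(n_patients=2500, seed=21,
                              age_group_weights=(0.4, 0.2, 0.2, 0.2),
                              subtype_profiles=profiles,
                              subtype_mixture_by_age=mixtures,
                              background_condition_rate=0.01)
        tabs = generate_population(cfg)
        cohort = apply_exclusions(tabs.persons, tabs.visits,
                                  derive_index(tabs.coded_events), tabs.tests)
        win = window_events(cohort, tabs.coded_events)
        results = stratified_networks(cohort, win, k=8, algorithm="louvain")
        resp = {"Acute pharyngitis", "Acute upper respiratory infection",
                "Acute sinusitis", "Otitis media"}
        # respiratory block forms exactly one community in the young stratum
        assign = results["<21"].assignment
        assert resp <= set(assign)
        resp_comms = {assign[c] for c in resp}
        assert len(resp_comms) == 1
        non_resp = set(assign) - resp
        assert resp_comms.isdisjoint({assign[c] for c in non_resp})
        # adult strata have planted neuro+gi traffic; respiratory codes stay
        # at background level and never reach their top-8
        for group in ("21–45", "46–65", "66+"):
            assert resp.isdisjoint(results[group].model.network.nodes)

    def test_identical_mixtures_give_matching_partitions(self):
        """With the same subtype mixture in every age group, the strata are
        exchangeable by construction and their partitions agree up to label
        permutation on the shared top conditions."""
        from itertools import combinations as combos
        cfg = GeneratorConfig(
            n_patients=4000, seed=8, age_group_weights=(0.25, 0.25, 0.25, 0.25),
            subtype_mixture_by_age={
                g: {"cardiopulmonary": 0.25, "neurological": 0.25,
                    "gastrointestinal": 0.25, "comorbid": 0.25}
                for g in ("<21", "21–45", "46–65", "66+")})
        tabs = generate_population(cfg)
        cohort = apply_exclusions(tabs.persons, tabs.visits,
                                  derive_index(tabs.coded_events), tabs.tests)
        win = window_events(cohort, tabs.coded_events)
        results = stratified_networks(cohort, win, k=30, algorithm="louvain")
        assert len(results) == 4
        for (ga, ra), (gb, rb) in combos(results.items(), 2):
            common = [n for n in ra.model.network.nodes
                      if n in rb.model.network.nodes]
            assert len(common) >= 20
            la = [ra.assignment[n] for n in common]
            lb = [rb.assignment[n] for n in common]
            assert ari(la, lb) >= 0.9, (ga, gb)

    def test_empty_stratum_skipped_without_harm(self, small_extract):
        tabs = small_extract
        cohort = apply_exclusions(tabs.persons, tabs.visits,
                                  derive_index(tabs.coded_events), tabs.tests)
        win = window_events(cohort, tabs.coded_events)
        # drop the youngest stratum entirely
        cohort = cohort[cohort["age_group"] != "<21"]
        results = stratified_networks(cohort, win, k=10)
        assert set(results) == {"21–45", "46–65", "66+"}
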