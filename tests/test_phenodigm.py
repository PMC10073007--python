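import math

import numpy as np
import pytest

from cardioko.errors import ReferentialError, UndefinedStatisticError
from cardioko.phenodigm import (
    AnnotationCorpus,
    OntologyGraph,
    mica,
    model_disease_score,
    pair_score,
    sim_j,
    summarize_positive,
    term_ic,
)
from cardioko.synthetic import random_dag


# ---------------------------------------------------------------- oracle
# an independent re-implementation used only for cross-checking: plain
# recursive ancestor traversal, entity counting by loop, exhaustive MICA scan

def oracle_ancestors(graph, term):
    out = {term}
    for p in graph.parents(term):
        out |= oracle_ancestors(graph, p)
    return out


def oracle_ic(graph, corpus, term):
    entities = list(corpus.disease_annotations.items()) + list(
        corpus.model_annotations.items()
    )
    k = 0
    for _, terms in entities:
        closure = set()
        for t in terms:
            closure |= oracle_ancestors(graph, t)
        if term in closure:
            k += 1
    n = len(entities)
    return -math.log(k / n) if k else -math.log(1 / n)


def oracle_pair_score(graph, corpus, t1, t2):
    a1, a2 = oracle_ancestors(graph, t1), oracle_ancestors(graph, t2)
    simj = len(a1 & a2) / len(a1 | a2)
    best_ic = max(oracle_ic(graph, corpus, t) for t in a1 & a2)
    return math.sqrt(simj * best_ic)


def oracle_percentage(graph, corpus, hpo, mp):
    hpo, mp = sorted(hpo), sorted(mp)
    matrix = np.array(
        [[oracle_pair_score(graph, corpus, h, m) for m in mp] for h in hpo]
    )
    theory = [math.sqrt(oracle_ic(graph, corpus, h)) for h in hpo]
    best = matrix.max()
    avg = np.concatenate([matrix.max(axis=1), matrix.max(axis=0)]).mean()
    pct = 50.0 * (best / max(theory) + avg / (sum(theory) / len(theory)))
    return min(max(pct, 0.0), 100.0)


def random_corpus(rng, graph, n_diseases=4, n_models=4, terms=3):
    hp = graph.terms_in_namespace("HP-like") or sorted(graph.terms)
    mp = graph.terms_in_namespace("MP-like") or sorted(graph.terms)
    disease = {
        f"D{i}": set(rng.choice(hp, size=min(terms, len(hp)), replace=False))
        for i in range(n_diseases)
    }
    model = {
        f"M{i}": set(rng.choice(mp, size=min(terms, len(mp)), replace=False))
        for i in range(n_models)
    }
    return AnnotationCorpus(disease, model, graph)


# ----------------------------------------------------------------- tests

class TestGraphBasics:
    def test_rejects_cycle(self):
        with pytest.raises(Exception):
            OntologyGraph([("A", "B"), ("B", "C"), ("C", "A"), ("B", "R")])

    def test_rejects_multiple_roots(self):
        with pytest.raises(Exception):
            OntologyGraph([("A", "R1"), ("B", "R2")])

    def test_ancestors_self_inclusive_and_reach_root(self, tiny_graph):
        anc = tiny_graph.ancestors("H:1")
        assert anc == {"H:1", "C:1", "R:0"}
        for t in tiny_graph.terms:
            assert tiny_graph.root in tiny_graph.ancestors(t)

    def test_unknown_term_lookup_error(self, tiny_graph):
        with pytest.raises(ReferentialError):
            tiny_graph.ancestors("X:404")


class TestSimJ:
    def test_identity(self, tiny_graph):
        assert sim_j(tiny_graph, "H:1", "H:1") == 1.0

    def test_siblings(self, tiny_graph):
        # ancestor sets {H:1, C:1, R:0} and {M:1, C:1, R:0}: 2 shared of 4
        assert sim_j(tiny_graph, "H:1", "M:1") == pytest.approx(0.5)

    def test_symmetry_and_range_on_random_dags(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            graph = random_dag(rng, int(rng.integers(5, 40)))
            terms = sorted(graph.terms)
            t1, t2 = rng.choice(terms, size=2, replace=False)
            s12, s21 = sim_j(graph, t1, t2), sim_j(graph, t2, t1)
            assert s12 == s21
            assert 0 < s12 <= 1  # root is always shared


class TestIC:
    def make(self, tiny_graph):
        corpus = AnnotationCorpus(
            {"D1": {"H:1"}, "D2": {"H:2"}},
            {"M1": {"M:1"}, "M2": {"M:2"}},
            tiny_graph,
        )
        return corpus

    def test_root_covers_everything(self, tiny_graph):
        corpus = self.make(tiny_graph)
        assert term_ic(tiny_graph, corpus, "R:0") == 0.0

    def test_direct_definition(self, tiny_graph):
        corpus = self.make(tiny_graph)
        # H:1 annotated by 1 of 4 entities
        assert term_ic(tiny_graph, corpus, "H:1") == pytest.approx(-math.log(0.25))
        # C:1 inherited from H:1 and M:1 -> 2 of 4
        assert term_ic(tiny_graph, corpus, "C:1") == pytest.approx(-math.log(0.5))

    def test_descendant_annotation_propagates(self, tiny_graph):
        base = self.make(tiny_graph)
        richer = AnnotationCorpus(
            {"D1": {"H:1"}, "D2": {"H:2"}, "D3": {"H:1"}},
            {"M1": {"M:1"}, "M2": {"M:2"}},
            tiny_graph,
        )
        k_base = base.term_entity_counts(tiny_graph)["C:1"]
        k_rich = richer.term_entity_counts(tiny_graph)["C:1"]
        assert k_rich == k_base + 1

    def test_never_observed_term_flagged(self, tiny_graph):
        corpus = AnnotationCorpus({"D1": {"H:1"}}, {"M1": {"M:1"}}, tiny_graph)
        with pytest.warns(UserWarning):
            ic = term_ic(tiny_graph, corpus, "H:2")
        assert ic == pytest.approx(-math.log(1 / 2))

    def test_ic_matches_oracle_on_random_graphs(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            graph = random_dag(rng, 25)
            corpus = random_corpus(rng, graph)
            for t in sorted(graph.terms)[::5]:
                assert corpus.ic_map(graph)[t] == pytest.approx(
                    oracle_ic(graph, corpus, t)
                )


class TestPairScore:
    def test_root_only_overlap_scores_zero(self, tiny_graph):
        corpus = AnnotationCorpus(
            {"D1": {"H:1"}, "D2": {"H:2"}}, {"M1": {"M:1"}, "M2": {"M:2"}}, tiny_graph
        )
        assert pair_score(tiny_graph, corpus, "H:1", "M:2") == 0.0

    def test_self_score_is_sqrt_ic(self, tiny_graph):
        corpus = AnnotationCorpus(
            {"D1": {"H:1"}, "D2": {"H:2"}}, {"M1": {"M:1"}, "M2": {"M:2"}}, tiny_graph
        )
        assert pair_score(tiny_graph, corpus, "H:1", "H:1") == pytest.approx(
            math.sqrt(term_ic(tiny_graph, corpus, "H:1"))
        )

    def test_mica_and_score_match_bruteforce_on_random_dags(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            graph = random_dag(rng, int(rng.integers(8, 50)))
            corpus = random_corpus(rng, graph)
            terms = sorted(graph.terms)
            t1, t2 = (str(x) for x in rng.choice(terms, size=2))
            _, ic_val = mica(graph, corpus, t1, t2)
            common = oracle_ancestors(graph, t1) & oracle_ancestors(graph, t2)
            assert ic_val == pytest.approx(
                max(oracle_ic(graph, corpus, t) for t in common)
            )
            assert pair_score(graph, corpus, t1, t2) == pytest.approx(
                oracle_pair_score(graph, corpus, t1, t2)
            )


class TestModelDiseaseScore:
    def corpus(self, tiny_graph):
        return AnnotationCorpus(
            {"D1": {"H:1"}, "D2": {"H:2"}}, {"M1": {"M:1"}, "M2": {"M:2"}}, tiny_graph
        )

    def test_perfect_model_scores_100(self, tiny_graph):
        corpus = self.corpus(tiny_graph)
        res = model_disease_score(tiny_graph, corpus, {"H:1"}, {"H:1"})
        assert res.percentage == pytest.approx(100.0)
        assert res.positive

    def test_root_only_model_scores_0(self, tiny_graph):
        corpus = self.corpus(tiny_graph)
        res = model_disease_score(tiny_graph, corpus, {"H:1"}, {"M:2"})
        assert res.percentage == 0.0
        assert not res.positive

    def test_empty_model_set_flagged_zero(self, tiny_graph):
        corpus = self.corpus(tiny_graph)
        with pytest.warns(UserWarning):
            res = model_disease_score(tiny_graph, corpus, {"H:1"}, set())
        assert res.percentage == 0.0 and "empty_model_terms" in res.flags

    def test_empty_disease_set_rejected(self, tiny_graph):
        with pytest.raises(ValueError):
            model_disease_score(tiny_graph, self.corpus(tiny_graph), set(), {"M:1"})

    def test_uninformative_disease_terms_rejected(self, tiny_graph):
        # every entity annotated below the root -> IC(root) = 0
        corpus = self.corpus(tiny_graph)
        with pytest.raises(UndefinedStatisticError):
            model_disease_score(tiny_graph, corpus, {"R:0"}, {"M:1"})

    def test_positive_iff_informative_match(self, tiny_graph):
        corpus = self.corpus(tiny_graph)
        res = model_disease_score(tiny_graph, corpus, {"H:1"}, {"M:1"})
        assert res.positive and res.percentage > 0
        assert res.pair_matrix.max() > 0

    def test_replacing_nonmatching_with_matching_term_cannot_decrease(self, tiny_graph):
        corpus = self.corpus(tiny_graph)
        weaker = model_disease_score(tiny_graph, corpus, {"H:1", "H:2"}, {"M:1", "M:2"})
        # M:2 (system 2, unrelated to H:1) -> replaced by the matching M:1 twin
        base = model_disease_score(tiny_graph, corpus, {"H:1"}, {"M:2"})
        better = model_disease_score(tiny_graph, corpus, {"H:1"}, {"M:1"})
        assert better.percentage >= base.percentage
        assert 0 <= weaker.percentage <= 100

    def test_full_scorer_matches_naive_reimplementation(self):
        rng = np.random.default_rng(41)
        checked = 0
        while checked < 40:
            graph = random_dag(rng, int(rng.integers(10, 50)))
            hp = graph.terms_in_namespace("HP-like")
            mp = graph.terms_in_namespace("MP-like")
            if len(hp) < 2 or len(mp) < 2:
                continue
            corpus = random_corpus(rng, graph)
            hpo = set(rng.choice(hp, size=2, replace=False))
            mps = set(rng.choice(mp, size=2, replace=False))
            res = model_disease_score(graph, corpus, hpo, mps)
            assert res.percentage == pytest.approx(
                oracle_percentage(graph, corpus, hpo, mps)
            )
            checked += 1

    def test_grand_mean_mode_differs_but_bounded(self, tiny_graph):
        corpus = self.corpus(tiny_graph)
        res = model_disease_score(
            tiny_graph, corpus, {"H:1", "H:2"}, {"M:1"}, avg_mode="grand"
        )
        assert 0 <= res.percentage <= 100


def test_summarize_positive_counts(tiny_graph):
    corpus = AnnotationCorpus(
        {"D1": {"H:1"}, "D2": {"H:2"}}, {"M1": {"M:1"}, "M2": {"M:2"}}, tiny_graph
    )
    pos = model_disease_score(tiny_graph, corpus, {"H:1"}, {"M:1"})
    neg = model_disease_score(tiny_graph, corpus, {"H:1"}, {"M:2"})
    assert summarize_positive([pos] * 18 + [neg] * 8) == 69.2
    assert summarize_positive([neg, neg]) == 0.0
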