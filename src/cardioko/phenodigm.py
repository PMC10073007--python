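"""Cross-species phenotype semantic similarity.

Implements the PhenoDigm-style scorer: pairwise term similarity is the
geometric mean of the Jaccard index of the two terms' self-inclusive ancestor
sets (simJ) and the information content (IC) of their most informative common
ancestor (MICA), where IC is computed from the observed annotation frequency
over the combined corpus of disease and mouse-model entities.  A disease /
model pair is summarised by comparing best and average pairwise scores against
the theoretical scores of a model perfectly mimicking the disease phenotypes
(the disease term set compared against itself), giving a percentage in
[0, 100].  A percentage greater than zero implies at least one informative
human–mouse phenotype match.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import DataError, ReferentialError, UndefinedStatisticError
from .utils import percent


class OntologyGraph:
    """A rooted, acyclic child→parent phenotype ontology.

    Terms carry a namespace label: ``HP-like`` (human vocabulary), ``MP-like``
    (mouse vocabulary) or ``bridge`` (shared cross-species ancestors).  The
    graph is validated at construction: exactly one root, no cycles, and —
    since every non-root term has at least one parent — every term reaches
    the root.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]],
        namespaces: Mapping[str, str] | None = None,
        names: Mapping[str, str] | None = None,
    ):
        parents: dict[str, set[str]] = {}
        terms: set[str] = set()
        for child, parent in edges:
            terms.add(child)
            terms.add(parent)
            parents.setdefault(child, set()).add(parent)
        if not terms:
            raise DataError("ontology has no terms")
        roots = sorted(t for t in terms if t not in parents)
        if len(roots) != 1:
            raise DataError(f"ontology must have exactly one root, found {roots}")
        g = nx.DiGraph((c, p) for c, ps in parents.items() for p in ps)
        if not nx.is_directed_acyclic_graph(g):
            raise DataError("ontology contains a cycle")
        self.root: str = roots[0]
        self.terms: frozenset[str] = frozenset(terms)
        self._parents: dict[str, tuple[str, ...]] = {
            t: tuple(sorted(ps)) for t, ps in parents.items()
        }
        self.namespace: dict[str, str] = {
            t: (namespaces or {}).get(t, "bridge") for t in terms
        }
        self.names: dict[str, str] = dict(names or {})
        self._anc_cache: dict[str, frozenset[str]] = {}

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def parents(self, term: str) -> tuple[str, ...]:
        self._check(term)
        return self._parents.get(term, ())

    def _check(self, term: str) -> None:
        if term not in self.terms:
            raise ReferentialError(f"unknown ontology term {term!r}")

    def ancestors(self, term: str) -> frozenset[str]:
        """Self-inclusive ancestor closure of ``term``."""
        self._check(term)
        cached = self._anc_cache.get(term)
        if cached is not None:
            return cached
        # iterative DFS with memoisation; closures of parents are reused
        stack = [term]
        while stack:
            t = stack[-1]
            if t in self._anc_cache:
                stack.pop()
                continue
            pending = [p for p in self._parents.get(t, ()) if p not in self._anc_cache]
            if pending:
                stack.extend(pending)
                continue
            closure = {t}
            for p in self._parents.get(t, ()):
                closure |= self._anc_cache[p]
            self._anc_cache[t] = frozenset(closure)
            stack.pop()
        return self._anc_cache[term]

    def terms_in_namespace(self, namespace: str) -> list[str]:
        return sorted(t for t in self.terms if self.namespace[t] == namespace)

    def edges(self) -> list[tuple[str, str]]:
        return sorted(
            (c, p) for c, ps in self._parents.items() for p in ps
        )


class AnnotationCorpus:
    """Disease→HP-like and model→MP-like term annotations.

    Information content is computed over the *combined* set of disease and
    model entities: an entity counts towards a term if it is annotated with
    the term or any of its descendants (i.e. the term lies in the ancestor
    closure of one of the entity's annotations).
    """

    def __init__(
        self,
        disease_annotations: Mapping[str, Iterable[str]],
        model_annotations: Mapping[str, Iterable[str]],
        graph: OntologyGraph | None = None,
    ):
        self.disease_annotations: dict[str, frozenset[str]] = {
            e: frozenset(ts) for e, ts in disease_annotations.items()
        }
        self.model_annotations: dict[str, frozenset[str]] = {
            e: frozenset(ts) for e, ts in model_annotations.items()
        }
        overlap = set(self.disease_annotations) & set(self.model_annotations)
        if overlap:
            raise DataError(f"entity ids used for both disease and model: {sorted(overlap)[:5]}")
        if graph is not None:
            self.validate(graph)
        self._ic_cache: dict[int, dict[str, float]] = {}

    @property
    def n_entities(self) -> int:
        return len(self.disease_annotations) + len(self.model_annotations)

    @property
    def empty_entities(self) -> list[str]:
        return sorted(
            e
            for e, ts in {**self.disease_annotations, **self.model_annotations}.items()
            if not ts
        )

    def validate(self, graph: OntologyGraph) -> None:
        for e, ts in list(self.disease_annotations.items()) + list(
            self.model_annotations.items()
        ):
            for t in ts:
                if t not in graph:
                    raise ReferentialError(
                        f"annotation term {t!r} of entity {e!r} absent from ontology"
                    )

    def term_entity_counts(self, graph: OntologyGraph) -> dict[str, int]:
        """k(term): number of entities annotated with the term or a descendant."""
        counts: dict[str, int] = {t: 0 for t in graph.terms}
        for annotations in (self.disease_annotations, self.model_annotations):
            for ts in annotations.values():
                closure: set[str] = set()
                for t in ts:
                    closure |= graph.ancestors(t)
                for t in closure:
                    counts[t] += 1
        return counts

    def ic_map(self, graph: OntologyGraph) -> dict[str, float]:
        """IC(term) = −ln(k/N) for every term; terms never observed (k = 0)
        are capped at −ln(1/N), the IC of a singleton annotation."""
        key = id(graph)
        cached = self._ic_cache.get(key)
        if cached is not None:
            return cached
        n = self.n_entities
        if n == 0:
            raise DataError("annotation corpus is empty")
        counts = self.term_entity_counts(graph)
        cap = -math.log(1.0 / n)
        ic = {t: (-math.log(k / n) if k > 0 else cap) for t, k in counts.items()}
        self._ic_cache[key] = ic
        return ic


def ancestors(graph: OntologyGraph, term: str) -> frozenset[str]:
    """Self-inclusive ancestor set of a term."""
    return graph.ancestors(term)


def sim_j(graph: OntologyGraph, t1: str, t2: str) -> float:
    """Jaccard index of the self-inclusive ancestor sets of two terms."""
    a1, a2 = graph.ancestors(t1), graph.ancestors(t2)
    return len(a1 & a2) / len(a1 | a2)


def term_ic(graph: OntologyGraph, corpus: AnnotationCorpus, term: str) -> float:
    graph._check(term)
    k = corpus.term_entity_counts(graph)[term]
    ic = corpus.ic_map(graph)[term]
    if k == 0:
        warnings.warn(
            f"term {term!r} is uninformative-by-absence (no annotated entity); "
            "IC capped at -ln(1/N)",
            stacklevel=2,
        )
    return ic


def mica(
    graph: OntologyGraph, corpus: AnnotationCorpus, t1: str, t2: str
) -> tuple[str, float]:
    """Most informative common ancestor and its IC.

    Ties on IC are broken by the lexicographically smallest term id so the
    result is deterministic.
    """
    common = graph.ancestors(t1) & graph.ancestors(t2)
    ic = corpus.ic_map(graph)
    best = max(sorted(common), key=lambda t: (ic[t], ), default=None)
    # max() keeps the first of equal keys; sorting first yields the smallest id
    assert best is not None  # root is always a common ancestor
    return best, ic[best]


def pair_score(
    graph: OntologyGraph, corpus: AnnotationCorpus, t1: str, t2: str
) -> float:
    """Geometric mean of simJ and the MICA information content."""
    _, ic_val = mica(graph, corpus, t1, t2)
    return math.sqrt(sim_j(graph, t1, t2) * ic_val)


@dataclass
class PhenoDigmResult:
    """Disease/model similarity summary.

    ``percentage`` is 100 · ½ · (max/max_theory + avg/avg_theory) clamped to
    [0, 100]; ``positive`` is True iff the percentage is strictly positive,
    i.e. at least one HP–MP pair shares an informative common ancestor.
    """

    pair_matrix: np.ndarray
    hpo_terms: tuple[str, ...]
    mp_terms: tuple[str, ...]
    max_score: float
    avg_score: float
    max_theory: float
    avg_theory: float
    percentage: float
    positive: bool
    flags: tuple[str, ...] = field(default_factory=tuple)


def model_disease_score(
    graph: OntologyGraph,
    corpus: AnnotationCorpus,
    hpo_set: Iterable[str],
    mp_set: Iterable[str],
    avg_mode: str = "bidirectional",
) -> PhenoDigmResult:
    """Score a mouse model (MP term set) against a disease (HP term set).

    ``avg_mode='bidirectional'`` (default) averages the best match of every
    disease term and every model term; ``avg_mode='grand'`` averages the full
    pairwise matrix instead.
    """
    hpo = tuple(sorted(set(hpo_set)))
    mp = tuple(sorted(set(mp_set)))
    if not hpo:
        raise ValueError("hpo_set must be non-empty")
    if avg_mode not in ("bidirectional", "grand"):
        raise ValueError(f"unknown avg_mode {avg_mode!r}")
    for t in hpo + mp:
        graph._check(t)
    ic = corpus.ic_map(graph)
    # a perfect model maps every disease term onto itself: simJ = 1 and the
    # MICA is the term itself (IC is monotone non-increasing towards the root)
    theory = np.array([math.sqrt(max(ic[t], 0.0)) for t in hpo])
    max_theory = float(theory.max())
    avg_theory = float(theory.mean())
    if avg_theory == 0.0:
        raise UndefinedStatisticError(
            "all disease terms are uninformative (IC 0); score undefined"
        )
    flags: list[str] = []
    if not mp:
        warnings.warn("empty model term set; similarity score is 0", stacklevel=2)
        return PhenoDigmResult(
            pair_matrix=np.zeros((len(hpo), 0)),
            hpo_terms=hpo,
            mp_terms=mp,
            max_score=0.0,
            avg_score=0.0,
            max_theory=max_theory,
            avg_theory=avg_theory,
            percentage=0.0,
            positive=False,
            flags=("empty_model_terms",),
        )
    matrix = np.zeros((len(hpo), len(mp)))
    for i, h in enumerate(hpo):
        for j, m in enumerate(mp):
            matrix[i, j] = pair_score(graph, corpus, h, m)
    max_score = float(matrix.max())
    if avg_mode == "bidirectional":
        avg_score = float(
            np.concatenate([matrix.max(axis=1), matrix.max(axis=0)]).mean()
        )
    else:
        avg_score = float(matrix.mean())
    pct = 100.0 * 0.5 * (max_score / max_theory + avg_score / avg_theory)
    pct = min(max(pct, 0.0), 100.0)
    return PhenoDigmResult(
        pair_matrix=matrix,
        hpo_terms=hpo,
        mp_terms=mp,
        max_score=max_score,
        avg_score=avg_score,
        max_theory=max_theory,
        avg_theory=avg_theory,
        percentage=pct,
        positive=pct > 0.0,
        flags=tuple(flags),
    )


def summarize_positive(results: Sequence[PhenoDigmResult]) -> float:
    """Percentage of results with a positive similarity score (1 dp)."""
    if not results:
        raise DataError("no similarity results to summarise")
    n_pos = sum(1 for r in results if r.positive)
    return percent(n_pos, len(results))
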