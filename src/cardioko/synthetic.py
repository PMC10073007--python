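"""Synthetic inputs with known ground truth.

Every file the pipeline consumes can be generated here, emulating the
statistical structure of the real study: a disease/non-disease gene universe
whose lethality odds differ by a configurable odds ratio, litter genotype
counts consistent with the viability category, a rooted cross-species
phenotype DAG with bridging ancestors, disease/model annotation corpora with
tunable human–mouse overlap, pathogenic-variant tables with a loss-of-function
mix that depends on viability, human early-lethality records, and per-gene
parameter p-value matrices with an enriched-small-p alternative for affected
genes.

Determinism: one RNG stream per output table, keyed by (seed, table name), so
identical seed + config yields byte-identical files and adding one table
never perturbs another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import ConfigError, DataError
from .phenodigm import AnnotationCorpus, OntologyGraph
from .utils import table_rng

VIABILITY_CATEGORIES = ("lethal", "subviable", "viable")
LETHALITY_CATEGORIES = ("prenatal", "neonatal", "infant", "child", "none")
LOF_CONSEQUENCES = ("frameshift", "nonsense", "splice_site")
NONLOF_CONSEQUENCES = (
    "missense",
    "ncRNA",
    "near_gene",
    "UTR",
    "synonymous",
    "in_frame",
)
PANELS = ("cardiomyopathy", "cardiac arrhythmia", "congenital heart disease")
MOI_CATEGORIES = ("biallelic", "monoallelic", "both", "x_linked")
SYSTEM_NAMES = (
    "cardiovascular system",
    "metabolism/homeostasis",
    "musculoskeletal system",
    "hematopoietic system",
    "nervous system",
    "growth/body size",
)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic universe.

    Defaults emulate a genome-wide knockout screen: a rare disease-gene class
    (~1% of lines) with 5.6-fold higher odds of being lethal/subviable than
    the ~35% background rate, panel ratings and modes of inheritance drawn
    with the observed frequencies, TTE covering about a third and ECG about
    two thirds of lines, and a Beta(0.2, 1) small-p alternative for affected
    gene–parameter pairs.
    """

    n_genes: int = 8000
    disease_fraction: float = 0.01
    true_or: float = 5.6
    base_nonviable_rate: float = 0.35
    lethal_given_nonviable: float = 0.714
    panel_rating_probs: tuple[float, float, float] = (0.44, 0.26, 0.30)
    moi_probs: tuple[float, float, float, float] = (0.35, 0.44, 0.14, 0.07)
    orthologue_one_to_one_rate: float = 0.987
    lof_fraction_by_viability: dict = field(
        default_factory=lambda: {"lethal": 0.70, "subviable": 0.70, "viable": 0.85}
    )
    pathogenic_fraction: float = 0.8
    mean_variants_per_gene: float = 4.0
    ontology_depth: int = 3
    ontology_branching: int = 3
    n_diseases: int = 60
    n_models: int = 60
    annotation_overlap: float = 0.6
    annotations_per_entity: int = 6
    params_per_gene: int = 10
    procedure_coverage: dict = field(
        default_factory=lambda: {"TTE": 0.333, "ECG": 0.667}
    )
    affected_gene_fraction: float = 0.1
    affected_param_effect: float = 0.5
    beta_a: float = 0.2
    pups_per_line: int = 28
    lethality_concordance: float = 0.465
    viable_early_rate: float = 0.285
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "disease_fraction",
            "base_nonviable_rate",
            "lethal_given_nonviable",
            "orthologue_one_to_one_rate",
            "annotation_overlap",
            "affected_gene_fraction",
            "affected_param_effect",
            "pathogenic_fraction",
            "lethality_concordance",
            "viable_early_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(name, f"proportion must be in [0, 1], got {v}")
        if self.true_or <= 0:
            raise ConfigError("true_or", "must be a positive odds ratio")
        for name in (
            "n_genes",
            "ontology_depth",
            "ontology_branching",
            "n_diseases",
            "n_models",
            "annotations_per_entity",
            "params_per_gene",
            "pups_per_line",
        ):
            if int(getattr(self, name)) < 1:
                raise ConfigError(name, "count must be >= 1")
        if self.ontology_depth < 2 or self.ontology_branching < 2:
            raise ConfigError(
                "ontology_depth" if self.ontology_depth < 2 else "ontology_branching",
                "ontology requires depth >= 2 and branching >= 2",
            )
        probs = np.asarray(self.panel_rating_probs, dtype=float)
        if probs.shape != (3,) or (probs < 0).any() or abs(probs.sum() - 1) > 1e-9:
            raise ConfigError("panel_rating_probs", "must be a 3-vector summing to 1")
        moi = np.asarray(self.moi_probs, dtype=float)
        if moi.shape != (4,) or (moi < 0).any() or abs(moi.sum() - 1) > 1e-9:
            raise ConfigError("moi_probs", "must be a 4-vector summing to 1")
        for cat, frac in self.lof_fraction_by_viability.items():
            if cat not in VIABILITY_CATEGORIES + ("all",):
                raise ConfigError(
                    "lof_fraction_by_viability", f"unknown viability category {cat!r}"
                )
            if not 0.0 <= frac <= 1.0:
                raise ConfigError("lof_fraction_by_viability", f"proportion {frac}")
        for proc, frac in self.procedure_coverage.items():
            if not 0.0 <= frac <= 1.0:
                raise ConfigError("procedure_coverage", f"{proc}: proportion {frac}")
        if not 0.0 < self.beta_a:
            raise ConfigError("beta_a", "Beta shape must be positive")

    def lof_fraction(self, category: str) -> float:
        if "all" in self.lof_fraction_by_viability:
            return self.lof_fraction_by_viability["all"]
        return self.lof_fraction_by_viability.get(category, 0.5)


def _gene_symbols(n: int) -> np.ndarray:
    return np.array([f"G{i:06d}" for i in range(n)])


def generate_universe(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene table and viability table with ground-truth disease labels.

    Viability is sampled so the population log-odds of being non-viable
    differ by ln(true_or) between disease and non-disease genes.
    """
    rng = table_rng(config.seed, "universe")
    n = config.n_genes
    symbols = _gene_symbols(n)
    is_disease = rng.random(n) < config.disease_fraction
    p0 = config.base_nonviable_rate
    p1 = float(expit(logit(p0) + np.log(config.true_or))) if 0 < p0 < 1 else p0
    p_nonviable = np.where(is_disease, p1, p0)
    nonviable = rng.random(n) < p_nonviable
    lethal = nonviable & (rng.random(n) < config.lethal_given_nonviable)
    category = np.where(lethal, "lethal", np.where(nonviable, "subviable", "viable"))
    one_to_one = rng.random(n) < config.orthologue_one_to_one_rate
    rating = rng.choice(["green", "amber", "red"], size=n, p=config.panel_rating_probs)
    moi = rng.choice(MOI_CATEGORIES, size=n, p=config.moi_probs)
    panel = rng.choice(PANELS, size=n)
    genes = pd.DataFrame(
        {
            "gene_symbol": symbols,
            "mouse_symbol": np.char.add("m", symbols.astype(str)),
            "orthologue_one_to_one": one_to_one,
            "panel_name": np.where(is_disease, panel, ""),
            "rating": np.where(is_disease, rating, ""),
            "mode_of_inheritance": np.where(is_disease, moi, "unknown"),
            "is_disease": is_disease,
        }
    )
    viability = pd.DataFrame(
        {"gene_symbol": symbols[one_to_one], "category": category[one_to_one]}
    ).reset_index(drop=True)
    return genes, viability


def generate_litters(
    viability: pd.DataFrame, pups_per_line: int = 28, seed: int = 0
) -> pd.DataFrame:
    """Litter genotype counts consistent with each line's viability category.

    Lethal lines produce zero live homozygotes; subviable lines realise a
    homozygote fraction strictly inside (0, 0.125); viable lines follow the
    Mendelian trinomial (1/4 hom, 1/2 het, 1/4 wt).
    """
    if pups_per_line < 1:
        raise ConfigError("pups_per_line", "must be >= 1")
    rng = table_rng(seed, "litters")
    rows = []
    max_sub_hom = int(np.ceil(0.125 * pups_per_line)) - 1
    for gene, category in zip(viability["gene_symbol"], viability["category"]):
        if category == "lethal":
            n_het = rng.binomial(pups_per_line, 2.0 / 3.0)
            n_hom, n_wt = 0, pups_per_line - n_het
        elif category == "subviable":
            frac = rng.uniform(np.nextafter(0.0, 1.0), 0.125)
            n_hom = int(np.floor(frac * pups_per_line))
            n_hom = min(max(n_hom, 1), max(max_sub_hom, 1))
            rest = pups_per_line - n_hom
            n_het = rng.binomial(rest, 2.0 / 3.0)
            n_wt = rest - n_het
        else:
            n_hom, n_het, n_wt = rng.multinomial(
                pups_per_line, [0.25, 0.5, 0.25]
            )
        rows.append((gene, int(n_hom), int(n_het), int(n_wt)))
    return pd.DataFrame(rows, columns=["gene_symbol", "n_hom", "n_het", "n_wt"])


def generate_ontology(config: SyntheticConfig) -> OntologyGraph:
    """Rooted cross-species DAG: root → system layer → bridge layers → leaves.

    Level k (k = 1..depth) holds branching**k bridge terms; level 1 is the
    physiological-system layer.  Each deepest bridge term gets one HP-like and
    one MP-like leaf child, so every matched human/mouse leaf pair shares an
    informative bridging ancestor and every leaf reaches the root.
    """
    depth, b = config.ontology_depth, config.ontology_branching
    root = "CP:0000000"
    edges: list[tuple[str, str]] = []
    namespaces = {root: "bridge"}
    names = {root: "phenotypic abnormality"}
    counter = 1
    level = [root]
    system_terms: list[str] = []
    for k in range(1, depth + 1):
        nxt = []
        for parent in level:
            for _ in range(b):
                term = f"CP:{counter:07d}"
                counter += 1
                edges.append((term, parent))
                namespaces[term] = "bridge"
                nxt.append(term)
        if k == 1:
            system_terms = list(nxt)
            for i, term in enumerate(nxt):
                names[term] = (
                    SYSTEM_NAMES[i] if i < len(SYSTEM_NAMES) else f"system {i}"
                )
        level = nxt
    for i, parent in enumerate(level):
        hp, mp = f"HP:{i:07d}", f"MP:{i:07d}"
        edges.append((hp, parent))
        edges.append((mp, parent))
        namespaces[hp] = "HP-like"
        namespaces[mp] = "MP-like"
    graph = OntologyGraph(edges, namespaces, names)
    graph.system_terms = tuple(system_terms)  # type: ignore[attr-defined]
    return graph


def matched_leaf_pairs(graph: OntologyGraph) -> list[tuple[str, str, str]]:
    """(hp_leaf, mp_leaf, shared_parent) triples for cross-species-matched
    leaves hanging off the same bridging term."""
    by_parent: dict[str, dict[str, str]] = {}
    for leaf in graph.terms:
        ns = graph.namespace[leaf]
        if ns in ("HP-like", "MP-like"):
            for parent in graph.parents(leaf):
                by_parent.setdefault(parent, {})[ns] = leaf
    pairs = [
        (d["HP-like"], d["MP-like"], parent)
        for parent, d in by_parent.items()
        if "HP-like" in d and "MP-like" in d
    ]
    return sorted(pairs)


def generate_annotations(
    graph: OntologyGraph,
    config: SyntheticConfig,
    genes: Sequence[str] | None = None,
) -> tuple[AnnotationCorpus, pd.DataFrame]:
    """Annotation corpus plus a disease↔model pairing table.

    The first min(n_diseases, n_models) disease/model entities are paired;
    for paired entities a fraction ``annotation_overlap`` of annotation slots
    are drawn from cross-species-matched leaf pairs (shared informative
    ancestor) and the rest from independent random branches.  When ``genes``
    is given, paired entities are linked to gene symbols in order.
    """
    rng = table_rng(config.seed, "annotations")
    pairs = matched_leaf_pairs(graph)
    if not pairs:
        raise DataError("ontology has no matched HP/MP leaf pairs")
    hp_leaves = sorted(graph.terms_in_namespace("HP-like"))
    mp_leaves = sorted(graph.terms_in_namespace("MP-like"))
    n_paired = min(config.n_diseases, config.n_models)
    disease_ann: dict[str, set[str]] = {}
    model_ann: dict[str, set[str]] = {}
    pair_rows = []
    for i in range(config.n_diseases):
        disease_ann[f"DIS:{i:04d}"] = set()
    for i in range(config.n_models):
        model_ann[f"MOD:{i:04d}"] = set()
    for i in range(n_paired):
        d_id, m_id = f"DIS:{i:04d}", f"MOD:{i:04d}"
        for _ in range(config.annotations_per_entity):
            if rng.random() < config.annotation_overlap:
                hp, mp, _parent = pairs[rng.integers(len(pairs))]
                disease_ann[d_id].add(hp)
                model_ann[m_id].add(mp)
            else:
                disease_ann[d_id].add(hp_leaves[rng.integers(len(hp_leaves))])
                model_ann[m_id].add(mp_leaves[rng.integers(len(mp_leaves))])
        gene = genes[i] if genes is not None and i < len(genes) else ""
        pair_rows.append((gene, d_id, m_id))
    for i in range(n_paired, config.n_diseases):
        d_id = f"DIS:{i:04d}"
        for _ in range(config.annotations_per_entity):
            disease_ann[d_id].add(hp_leaves[rng.integers(len(hp_leaves))])
    for i in range(n_paired, config.n_models):
        m_id = f"MOD:{i:04d}"
        for _ in range(config.annotations_per_entity):
            model_ann[m_id].add(mp_leaves[rng.integers(len(mp_leaves))])
    corpus = AnnotationCorpus(disease_ann, model_ann, graph)
    pairs_df = pd.DataFrame(pair_rows, columns=["gene_symbol", "disease_id", "model_id"])
    return corpus, pairs_df


def generate_matched_cohort(
    graph: OntologyGraph,
    n_positive: int,
    n_negative: int,
    terms_per_entity: int = 3,
    seed: int = 0,
    genes: Sequence[str] | None = None,
) -> tuple[AnnotationCorpus, pd.DataFrame]:
    """A cohort where exactly ``n_positive`` disease/model pairs share an
    informative (non-root) ancestor and ``n_negative`` pairs share only the
    root.

    Positive pairs annotate matched HP/MP leaves under the same physiological
    system; negative pairs take their HP terms from one system and their MP
    terms from a different one, so every common ancestor is the root (IC 0)
    and the similarity percentage is exactly zero.
    """
    systems = getattr(graph, "system_terms", None)
    if not systems or len(systems) < 2:
        raise DataError("matched cohort requires an ontology with >= 2 system terms")
    rng = np.random.default_rng(seed)
    pairs = matched_leaf_pairs(graph)
    by_system: dict[str, list[tuple[str, str, str]]] = {s: [] for s in systems}
    for hp, mp, parent in pairs:
        anc = graph.ancestors(parent)
        for s in systems:
            if s in anc:
                by_system[s].append((hp, mp, parent))
                break
    usable = [s for s in systems if by_system[s]]
    if len(usable) < 2:
        raise DataError("need matched leaf pairs under >= 2 distinct systems")
    n_total = n_positive + n_negative
    disease_ann: dict[str, set[str]] = {}
    model_ann: dict[str, set[str]] = {}
    rows = []
    for i in range(n_total):
        d_id, m_id = f"DIS:{i:04d}", f"MOD:{i:04d}"
        positive = i < n_positive
        s = usable[i % len(usable)]
        s_other = usable[(i + 1) % len(usable)]
        d_terms: set[str] = set()
        m_terms: set[str] = set()
        if positive:
            group = by_system[s]
            for _ in range(terms_per_entity):
                hp, mp, _parent = group[rng.integers(len(group))]
                d_terms.add(hp)
                m_terms.add(mp)
        else:
            g1, g2 = by_system[s], by_system[s_other]
            for _ in range(terms_per_entity):
                d_terms.add(g1[rng.integers(len(g1))][0])
                m_terms.add(g2[rng.integers(len(g2))][1])
        disease_ann[d_id] = d_terms
        model_ann[m_id] = m_terms
        gene = genes[i] if genes is not None and i < len(genes) else f"G{i:06d}"
        rows.append((gene, d_id, m_id, positive))
    corpus = AnnotationCorpus(disease_ann, model_ann, graph)
    cohort = pd.DataFrame(
        rows, columns=["gene_symbol", "disease_id", "model_id", "truth_positive"]
    )
    return corpus, cohort


def generate_pvalues(
    genes: Sequence[str], config: SyntheticConfig
) -> tuple[pd.DataFrame, set[str]]:
    """Per-gene parameter p-values for each phenotyping procedure.

    Unaffected gene–parameter pairs draw p ~ Uniform(0, 1); for affected
    genes a fraction ``affected_param_effect`` of parameters draw from
    Beta(beta_a, 1) with beta_a < 1, concentrating mass near zero.  Each
    procedure covers a configurable fraction of genes and contributes
    ``params_per_gene`` parameters per covered gene.  Returns the long-format
    table and the set of truly affected genes.
    """
    rng = table_rng(config.seed, "pvalues")
    genes = list(genes)
    affected = {
        g for g in genes if rng.random() < config.affected_gene_fraction
    }
    frames = []
    for proc in sorted(config.procedure_coverage):
        cov = config.procedure_coverage[proc]
        covered = [g for g in genes if rng.random() < cov]
        if not covered:
            continue
        k = config.params_per_gene
        n = len(covered)
        p = rng.random((n, k))
        is_affected = np.array([g in affected for g in covered])
        effect_mask = (rng.random((n, k)) < config.affected_param_effect) & (
            is_affected[:, None]
        )
        p = np.where(effect_mask, rng.beta(config.beta_a, 1.0, size=(n, k)), p)
        frames.append(
            pd.DataFrame(
                {
                    "gene_symbol": np.repeat(covered, k),
                    "procedure": proc,
                    "parameter": np.tile([f"{proc}_param_{j:02d}" for j in range(k)], n),
                    "p_value": p.ravel(),
                }
            )
        )
    if not frames:
        return (
            pd.DataFrame(columns=["gene_symbol", "procedure", "parameter", "p_value"]),
            affected,
        )
    return pd.concat(frames, ignore_index=True), affected


def generate_variants(
    gene_table: pd.DataFrame, config: SyntheticConfig
) -> pd.DataFrame:
    """ClinVar-like pathogenic-variant table.

    The per-variant probability of a loss-of-function consequence depends on
    the gene's viability category via ``lof_fraction_by_viability``; a
    fraction of records carry non-pathogenic clinical significance and must
    be filtered out downstream.
    """
    rng = table_rng(config.seed, "variants")
    rows = []
    categories = (
        gene_table["viability"]
        if "viability" in gene_table.columns
        else pd.Series(["viable"] * len(gene_table), index=gene_table.index)
    )
    for gene, category in zip(gene_table["gene_symbol"], categories):
        cat = category if category in VIABILITY_CATEGORIES else "viable"
        lof_p = config.lof_fraction(cat)
        n_var = 1 + rng.poisson(config.mean_variants_per_gene)
        for _ in range(n_var):
            if rng.random() < lof_p:
                consequence = LOF_CONSEQUENCES[rng.integers(len(LOF_CONSEQUENCES))]
            elif rng.random() < 0.7:
                consequence = "missense"
            else:
                consequence = NONLOF_CONSEQUENCES[
                    rng.integers(len(NONLOF_CONSEQUENCES))
                ]
            significance = (
                "pathogenic"
                if rng.random() < config.pathogenic_fraction
                else ("benign" if rng.random() < 0.5 else "uncertain_significance")
            )
            rows.append((gene, consequence, significance))
    return pd.DataFrame(
        rows, columns=["gene_symbol", "consequence", "clinical_significance"]
    )


def generate_human_lethality(
    viability: pd.DataFrame, config: SyntheticConfig
) -> pd.DataFrame:
    """Earliest-death records with a single mouse–human concordance knob.

    Mouse non-viable genes receive an early (prenatal/neonatal/infant) record
    with probability ``lethality_concordance``; viable genes with probability
    ``viable_early_rate``; everything else is childhood death or none.
    """
    rng = table_rng(config.seed, "human_lethality")
    rows = []
    early = ("prenatal", "neonatal", "infant")
    for gene, category in zip(viability["gene_symbol"], viability["category"]):
        p_early = (
            config.lethality_concordance
            if category in ("lethal", "subviable")
            else config.viable_early_rate
        )
        if rng.random() < p_early:
            cat = early[rng.integers(3)]
        else:
            cat = "child" if rng.random() < 0.2 else "none"
        rows.append((gene, cat))
    return pd.DataFrame(rows, columns=["gene_symbol", "category"])


def random_dag(
    rng: np.random.Generator,
    n_terms: int,
    max_parents: int = 3,
    hp_fraction: float = 0.3,
    mp_fraction: float = 0.3,
) -> OntologyGraph:
    """A random rooted DAG for property tests: term i draws 1..max_parents
    parents among terms 0..i-1; leaves are labelled HP-like/MP-like."""
    if n_terms < 2:
        raise ValueError("need at least 2 terms")
    ids = [f"T:{i:04d}" for i in range(n_terms)]
    edges = []
    has_child = set()
    for i in range(1, n_terms):
        k = int(rng.integers(1, max_parents + 1))
        parents = rng.choice(i, size=min(k, i), replace=False)
        for p in parents:
            edges.append((ids[i], ids[int(p)]))
            has_child.add(ids[int(p)])
    namespaces = {}
    for t in ids:
        if t in has_child or t == ids[0]:
            namespaces[t] = "bridge"
        else:
            u = rng.random()
            namespaces[t] = (
                "HP-like"
                if u < hp_fraction
                else ("MP-like" if u < hp_fraction + mp_fraction else "bridge")
            )
    return OntologyGraph(edges, namespaces)


def write_bundle(config: SyntheticConfig, outdir: str | Path) -> dict:
    """Generate every pipeline input and write it as TSV/JSON under outdir.

    Returns the manifest (also written as manifest.json) recording config and
    seed; ground-truth labels go to truth.tsv.
    """
    from . import ingest  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, viability = generate_universe(config)
    disease = genes[genes["is_disease"]]
    panels = pd.DataFrame(
        {
            "gene_symbol": disease["gene_symbol"],
            "panel_name": disease["panel_name"],
            "rating": disease["rating"],
            "mode_of_inheritance": disease["mode_of_inheritance"],
        }
    )
    orthologues = pd.DataFrame(
        {
            "gene_symbol": genes["gene_symbol"],
            "mouse_symbol": genes["mouse_symbol"],
        }
    )
    # break one-to-one status by duplicating the mouse partner of flagged genes
    dup = genes.loc[~genes["orthologue_one_to_one"]]
    if len(dup):
        extra = pd.DataFrame(
            {
                "gene_symbol": np.char.add(dup["gene_symbol"].to_numpy(str), "B"),
                "mouse_symbol": dup["mouse_symbol"],
            }
        )
        orthologues = pd.concat([orthologues, extra], ignore_index=True)
    litters = generate_litters(viability, config.pups_per_line, config.seed)
    graph = generate_ontology(config)
    disease_eligible = disease[
        disease["gene_symbol"].isin(viability["gene_symbol"])
    ]["gene_symbol"].tolist()
    corpus, pairs_df = generate_annotations(graph, config, genes=disease_eligible)
    pvalues, affected = generate_pvalues(viability["gene_symbol"].tolist(), config)
    gene_table_for_variants = genes.merge(viability, on="gene_symbol", how="left").rename(
        columns={"category": "viability"}
    )
    variants = generate_variants(
        gene_table_for_variants[gene_table_for_variants["is_disease"]], config
    )
    lethality = generate_human_lethality(viability, config)

    ingest.write_panels(panels, outdir / "panels.tsv")
    ingest.write_table(orthologues, outdir / "orthologues.tsv")
    ingest.write_table(viability, outdir / "viability.tsv")
    ingest.write_table(litters, outdir / "litters.tsv")
    ingest.write_table(variants, outdir / "variants.tsv")
    ingest.write_table(lethality, outdir / "human_lethality.tsv")
    ingest.write_table(pvalues, outdir / "pvalues.tsv")
    ingest.write_ontology(graph, outdir / "ontology_edges.tsv", outdir / "ontology_terms.tsv")
    ingest.write_annotations(corpus, outdir / "annotations.tsv")
    ingest.write_table(pairs_df, outdir / "pairs.tsv")
    truth = genes[["gene_symbol", "is_disease"]].copy()
    truth["affected_pvalues"] = truth["gene_symbol"].isin(affected)
    ingest.write_table(truth, outdir / "truth.tsv")
    manifest = {
        "generator": "cardioko.synthetic",
        "seed": config.seed,
        "config": asdict(config),
        "tables": sorted(p.name for p in outdir.glob("*.tsv")),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
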