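"""Readers, writers and validation for every pipeline input format.

All tabular inputs are plain TSV with a header row; panels may alternatively
be a JSON array of objects.  Ontologies are read either from an OBO 1.2
subset ([Term], id, name, is_a, namespace, is_obsolete) or from an edge-list
TSV (child_id, parent_id) plus a term table (id, name, namespace).  Malformed
rows are rejected with line-numbered messages; vocabulary tokens are
normalised to lower case before validation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import obonet
import pandas as pd

from .errors import ReferentialError, SchemaError, VocabularyError
from .phenodigm import AnnotationCorpus, OntologyGraph

RATINGS = ("green", "amber", "red")
RATING_RANK = {"green": 0, "amber": 1, "red": 2}
MOI = ("biallelic", "monoallelic", "both", "x_linked", "unknown")
VIABILITY = ("lethal", "subviable", "viable")
LETHALITY = ("prenatal", "neonatal", "infant", "child", "none", "unknown")
ENTITY_KINDS = ("disease", "model")
# canonical spellings keyed by lower-cased token
CONSEQUENCES = {
    c.lower(): c
    for c in (
        "frameshift",
        "nonsense",
        "splice_site",
        "missense",
        "ncRNA",
        "near_gene",
        "UTR",
        "synonymous",
        "in_frame",
    )
}


@dataclass
class GeneRecord:
    """One gene with its panel evidence and cross-species status."""

    gene_symbol: str
    panel_memberships: tuple[tuple[str, str], ...]
    resolved_rating: str
    mode_of_inheritance: str
    mouse_symbol: str | None
    orthologue_one_to_one: bool
    viability: str | None
    human_lethality: str


@dataclass
class VariantRecord:
    gene_symbol: str
    consequence: str
    clinical_significance: str


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    if df.empty:
        warnings.warn(f"{path.name}: no data rows", stacklevel=3)
    return df


def _check_vocab(
    df: pd.DataFrame, column: str, vocabulary: tuple[str, ...], path: Path
) -> pd.Series:
    """Lower-case the column and reject unknown tokens with line numbers
    (header is line 1, first data row line 2)."""
    values = df[column].str.strip().str.lower()
    bad = ~values.isin(vocabulary)
    if bad.any():
        lines = [
            f"line {i + 2}: {column}={df[column].iloc[i]!r}"
            for i in df.index[bad][:10]
        ]
        raise VocabularyError(
            f"{Path(path).name}: unknown {column} token(s): " + "; ".join(lines)
        )
    return values


def read_panels(path: str | Path) -> pd.DataFrame:
    """Panel entries: gene_symbol, panel_name, rating, mode_of_inheritance."""
    path = Path(path)
    if path.suffix == ".json":
        records = json.loads(path.read_text())
        df = pd.DataFrame.from_records(records).astype(str)
        missing = [
            c
            for c in ("gene_symbol", "panel_name", "rating", "mode_of_inheritance")
            if c not in df.columns
        ]
        if missing:
            raise SchemaError(f"{path.name}: missing column(s) {missing}")
        if df.empty:
            warnings.warn(f"{path.name}: no data rows", stacklevel=2)
    else:
        df = _read_tsv(path, ["gene_symbol", "panel_name", "rating", "mode_of_inheritance"])
    df = df.copy()
    df["gene_symbol"] = df["gene_symbol"].str.strip().str.upper()
    if len(df):
        df["rating"] = _check_vocab(df, "rating", RATINGS, path)
        df["mode_of_inheritance"] = _check_vocab(df, "mode_of_inheritance", MOI, path)
    dup = df.duplicated(subset=["gene_symbol", "panel_name"], keep=False)
    if dup.any():
        conflicting = (
            df[dup]
            .groupby(["gene_symbol", "panel_name"])["rating"]
            .nunique()
        )
        genes = sorted(conflicting[conflicting > 1].index.get_level_values(0).unique())
        if genes:
            raise VocabularyError(
                f"{path.name}: duplicate (gene, panel) rows with conflicting "
                f"ratings for gene(s): {genes}"
            )
        df = df.drop_duplicates(subset=["gene_symbol", "panel_name"])
    return df.reset_index(drop=True)


def read_orthologues(path: str | Path) -> pd.DataFrame:
    """Human↔mouse orthologue map; one-to-one status is inferred: a pair is
    one-to-one iff its human symbol and its mouse symbol each occur exactly
    once in the map."""
    df = _read_tsv(path, ["gene_symbol", "mouse_symbol"])
    df = df.copy()
    df["gene_symbol"] = df["gene_symbol"].str.strip().str.upper()
    human_counts = df["gene_symbol"].value_counts()
    mouse_counts = df["mouse_symbol"].value_counts()
    df["one_to_one"] = (
        df["gene_symbol"].map(human_counts).eq(1)
        & df["mouse_symbol"].map(mouse_counts).eq(1)
    )
    return df


def read_viability(path: str | Path) -> pd.DataFrame:
    """Either precomputed calls (gene_symbol, category) or litter counts
    (gene_symbol, n_hom, n_het, n_wt); the schema is detected from columns."""
    path = Path(path)
    head = pd.read_csv(path, sep="\t", nrows=0)
    if "category" in head.columns:
        df = _read_tsv(path, ["gene_symbol", "category"])
        df = df.copy()
        df["gene_symbol"] = df["gene_symbol"].str.strip().str.upper()
        if len(df):
            df["category"] = _check_vocab(df, "category", VIABILITY, path)
        return df.reset_index(drop=True)
    df = _read_tsv(path, ["gene_symbol", "n_hom", "n_het", "n_wt"])
    df = df.copy()
    df["gene_symbol"] = df["gene_symbol"].str.strip().str.upper()
    for col in ("n_hom", "n_het", "n_wt"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() | (values < 0) | (values % 1 != 0)
        if bad.any():
            lines = [f"line {i + 2}: {col}={df[col].iloc[i]!r}" for i in df.index[bad][:10]]
            raise SchemaError(f"{Path(path).name}: non-count values: " + "; ".join(lines))
        df[col] = values.astype(int)
    return df.reset_index(drop=True)


def read_variants(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, ["gene_symbol", "consequence", "clinical_significance"])
    df = df.copy()
    df["gene_symbol"] = df["gene_symbol"].str.strip().str.upper()
    if len(df):
        tokens = df["consequence"].str.strip().str.lower()
        bad = ~tokens.isin(CONSEQUENCES)
        if bad.any():
            lines = [
                f"line {i + 2}: consequence={df['consequence'].iloc[i]!r}"
                for i in df.index[bad][:10]
            ]
            raise VocabularyError(
                f"{Path(path).name}: unknown consequence token(s): " + "; ".join(lines)
            )
        df["consequence"] = tokens.map(CONSEQUENCES)
        df["clinical_significance"] = df["clinical_significance"].str.strip().str.lower()
    return df.reset_index(drop=True)


def read_human_lethality(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, ["gene_symbol", "category"])
    df = df.copy()
    df["gene_symbol"] = df["gene_symbol"].str.strip().str.upper()
    if len(df):
        df["category"] = _check_vocab(df, "category", LETHALITY, path)
    return df.reset_index(drop=True)


def read_pvalues(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, ["gene_symbol", "procedure", "parameter", "p_value"])
    df = df.copy()
    df["gene_symbol"] = df["gene_symbol"].str.strip().str.upper()
    p = pd.to_numeric(df["p_value"], errors="coerce")
    bad = p.isna() | (p < 0) | (p > 1)
    if bad.any():
        lines = [f"line {i + 2}: p_value={df['p_value'].iloc[i]!r}" for i in df.index[bad][:10]]
        raise SchemaError(f"{Path(path).name}: p-values outside [0, 1]: " + "; ".join(lines))
    df["p_value"] = p
    dup = df.duplicated(subset=["gene_symbol", "procedure", "parameter"], keep=False)
    if dup.any():
        genes = sorted(df.loc[dup, "gene_symbol"].unique()[:10])
        raise SchemaError(
            f"{Path(path).name}: duplicate (gene, procedure, parameter) rows for {genes}"
        )
    return df.reset_index(drop=True)


def read_annotations(path: str | Path, graph: OntologyGraph | None = None) -> AnnotationCorpus:
    df = _read_tsv(path, ["entity_id", "entity_kind", "term_id"])
    if len(df):
        df = df.copy()
        df["entity_kind"] = _check_vocab(df, "entity_kind", ENTITY_KINDS, path)
    disease: dict[str, set[str]] = {}
    model: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        target = disease if row["entity_kind"] == "disease" else model
        target.setdefault(row["entity_id"], set()).add(row["term_id"])
    corpus = AnnotationCorpus(disease, model)
    if graph is not None:
        corpus.validate(graph)
    return corpus


def read_ontology(path: str | Path, terms_path: str | Path | None = None) -> OntologyGraph:
    """OBO 1.2 subset (``.obo``) or edge-list TSV + term table."""
    path = Path(path)
    if path.suffix == ".obo":
        return _read_obo(path)
    if terms_path is None:
        raise SchemaError("edge-list ontologies need a term table (id, name, namespace)")
    edges = _read_tsv(path, ["child_id", "parent_id"])
    terms = _read_tsv(terms_path, ["id", "name", "namespace"])
    namespaces = dict(zip(terms["id"], terms["namespace"]))
    names = dict(zip(terms["id"], terms["name"]))
    graph = OntologyGraph(
        list(zip(edges["child_id"], edges["parent_id"])), namespaces, names
    )
    unknown = set(namespaces) - set(graph.terms)
    if unknown:
        raise ReferentialError(f"term table lists ids absent from edges: {sorted(unknown)[:5]}")
    _attach_systems(graph)
    return graph


def _read_obo(path: Path) -> OntologyGraph:
    g = obonet.read_obo(path, ignore_obsolete=True)
    edges = []
    namespaces = {}
    names = {}
    for node, data in g.nodes(data=True):
        names[node] = data.get("name", node)
        ns = data.get("namespace", "")
        if ns in ("HP-like", "MP-like", "bridge"):
            namespaces[node] = ns
        elif node.startswith("HP:"):
            namespaces[node] = "HP-like"
        elif node.startswith("MP:"):
            namespaces[node] = "MP-like"
        else:
            namespaces[node] = "bridge"
    for child, parent, key in g.edges(keys=True):
        if key == "is_a":
            edges.append((child, parent))
    graph = OntologyGraph(edges, namespaces, names)
    _attach_systems(graph)
    return graph


def _attach_systems(graph: OntologyGraph) -> None:
    """Declare the DAG layer directly below the root as the system layer."""
    systems = sorted(
        t for t in graph.terms if graph.root in graph.parents(t)
    )
    graph.system_terms = tuple(systems)  # type: ignore[attr-defined]


def build_gene_table(
    panels: pd.DataFrame,
    orthologues: pd.DataFrame,
    viability: pd.DataFrame | None = None,
    lethality: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per gene symbol with resolved panel evidence.

    The resolved rating is the most confident across panels (green > amber >
    red).  Mode of inheritance is 'both' when distinct panels disagree
    between biallelic and monoallelic, otherwise the best-rated panel's
    value.  Genes without a one-to-one orthologue are retained but carry no
    viability call (they are ineligible for mouse-side stages).
    """
    records = []
    ortho = orthologues.set_index("gene_symbol") if len(orthologues) else None
    via = (
        viability.set_index("gene_symbol")["category"]
        if viability is not None and len(viability)
        else None
    )
    leth = (
        lethality.set_index("gene_symbol")["category"]
        if lethality is not None and len(lethality)
        else None
    )
    for gene, group in panels.groupby("gene_symbol", sort=True):
        group = group.sort_values(["rating", "panel_name"], key=lambda s: (
            s.map(RATING_RANK) if s.name == "rating" else s
        ))
        memberships = tuple(
            sorted(zip(group["panel_name"], group["rating"]))
        )
        resolved = min(group["rating"], key=RATING_RANK.get)
        mois = set(group["mode_of_inheritance"]) - {"unknown"}
        if {"biallelic", "monoallelic"} <= mois or "both" in mois:
            moi = "both"
        elif mois:
            best = group.loc[group["rating"].map(RATING_RANK).idxmin()]
            moi = best["mode_of_inheritance"]
        else:
            moi = "unknown"
        mouse = None
        one_to_one = False
        if ortho is not None and gene in ortho.index:
            hit = ortho.loc[gene]
            if isinstance(hit, pd.DataFrame):
                hit = hit.iloc[0]
                one_to_one = False
            else:
                one_to_one = bool(hit["one_to_one"])
            mouse = hit["mouse_symbol"]
        viability_call = None
        if one_to_one and via is not None and gene in via.index:
            viability_call = via.loc[gene]
        human_lethality = "unknown"
        if leth is not None and gene in leth.index:
            human_lethality = leth.loc[gene]
        records.append(
            {
                "gene_symbol": gene,
                "panel_memberships": "|".join(f"{p}:{r}" for p, r in memberships),
                "resolved_rating": resolved,
                "mode_of_inheritance": moi,
                "mouse_symbol": mouse,
                "orthologue_one_to_one": one_to_one,
                "viability": viability_call,
                "human_lethality": human_lethality,
            }
        )
    return pd.DataFrame.from_records(records).sort_values("gene_symbol").reset_index(drop=True)


def gene_records(table: pd.DataFrame) -> list[GeneRecord]:
    """Typed view of a gene table."""
    out = []
    for _, row in table.iterrows():
        memberships = tuple(
            tuple(m.split(":", 1)) for m in row["panel_memberships"].split("|") if m
        )
        out.append(
            GeneRecord(
                gene_symbol=row["gene_symbol"],
                panel_memberships=memberships,  # type: ignore[arg-type]
                resolved_rating=row["resolved_rating"],
                mode_of_inheritance=row["mode_of_inheritance"],
                mouse_symbol=row["mouse_symbol"],
                orthologue_one_to_one=bool(row["orthologue_one_to_one"]),
                viability=row["viability"] if pd.notna(row["viability"]) else None,
                human_lethality=row["human_lethality"],
            )
        )
    return out


# ---------------------------------------------------------------------------
# writers (the synthetic generator emits the same dialects these readers read)

def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def write_panels(df: pd.DataFrame, path: str | Path) -> None:
    write_table(df, path)


def write_annotations(corpus: AnnotationCorpus, path: str | Path) -> None:
    rows = []
    for entity, terms in sorted(corpus.disease_annotations.items()):
        rows += [(entity, "disease", t) for t in sorted(terms)]
    for entity, terms in sorted(corpus.model_annotations.items()):
        rows += [(entity, "model", t) for t in sorted(terms)]
    write_table(pd.DataFrame(rows, columns=["entity_id", "entity_kind", "term_id"]), path)


def write_ontology(
    graph: OntologyGraph, edges_path: str | Path, terms_path: str | Path
) -> None:
    edges = pd.DataFrame(graph.edges(), columns=["child_id", "parent_id"])
    terms = pd.DataFrame(
        {
            "id": sorted(graph.terms),
            "name": [graph.names.get(t, t) for t in sorted(graph.terms)],
            "namespace": [graph.namespace[t] for t in sorted(graph.terms)],
        }
    )
    write_table(edges, edges_path)
    write_table(terms, terms_path)
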