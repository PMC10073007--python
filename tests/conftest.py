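"""Shared fixtures.

``paper_bundle`` builds, with fully deterministic counts, the reference
worked-example input directory: 153 panel genes of which
151 have one-to-one mouse orthologues, 57 with knockout data (34 lethal, 9
subviable, 14 viable), human early-death records for 20 (+4 child) of the 43
non-viable genes, TTE data for 19 genes (17 nominally significant) and ECG
for 38 (20 significant), and a 26-line cross-species similarity cohort in
which exactly 18 models share an informative ancestor with their disease.
"""

from __future__ import annotations

import itertools

import pandas as pd
import pytest

from cardioko import ingest, synthetic
from cardioko.phenodigm import AnnotationCorpus

PANEL_CYCLE = ("cardiomyopathy", "cardiac arrhythmia", "congenital heart disease")


def _moi_for(position_nonviable: dict[str, int]) -> dict[str, str]:
    """Mode-of-inheritance layout over the 57 genes with data: 24 biallelic
    (19 non-viable), 23 monoallelic (19 non-viable), 8 both, 2 X-linked."""
    nonviable = position_nonviable["nonviable"]
    viable = position_nonviable["viable"]
    moi = {}
    for g in nonviable[0:19] + viable[0:5]:
        moi[g] = "biallelic"
    for g in nonviable[19:38] + viable[5:9]:
        moi[g] = "monoallelic"
    for g in nonviable[38:42] + viable[9:13]:
        moi[g] = "both"
    for g in nonviable[42:43] + viable[13:14]:
        moi[g] = "x_linked"
    return moi


def build_paper_bundle(outdir) -> dict:
    """Write the worked-example input bundle; returns layout metadata."""
    genes = [f"CVD{i:03d}" for i in range(1, 154)]
    with_data = genes[:57]
    lethal = with_data[0:34]
    subviable = with_data[34:43]
    viable = with_data[43:57]
    nonviable = lethal + subviable

    moi = _moi_for({"nonviable": nonviable, "viable": viable})
    panel_rows = []
    for i, g in enumerate(genes):
        panel_rows.append(
            {
                "gene_symbol": g,
                "panel_name": PANEL_CYCLE[i % 3],
                "rating": "green",
                "mode_of_inheritance": moi.get(g, "biallelic"),
            }
        )
    # one gene rated green in one panel and red in another
    panel_rows.append(
        {
            "gene_symbol": "CVD001",
            "panel_name": "hypertrophic cardiomyopathy",
            "rating": "red",
            "mode_of_inheritance": moi["CVD001"],
        }
    )
    panels = pd.DataFrame(panel_rows)

    # two genes share one mouse orthologue -> not one-to-one; 151 remain
    ortho_rows = []
    for g in genes:
        mouse = "Sharedmouse" if g in ("CVD152", "CVD153") else g.capitalize()
        ortho_rows.append({"gene_symbol": g, "mouse_symbol": mouse})
    orthologues = pd.DataFrame(ortho_rows)

    viability = pd.DataFrame(
        {
            "gene_symbol": with_data,
            "category": ["lethal"] * 34 + ["subviable"] * 9 + ["viable"] * 14,
        }
    )

    lethality_rows = []
    early = itertools.cycle(["prenatal", "neonatal", "infant"])
    for g in nonviable[0:20]:
        lethality_rows.append({"gene_symbol": g, "category": next(early)})
    for g in nonviable[20:24]:
        lethality_rows.append({"gene_symbol": g, "category": "child"})
    for g in nonviable[24:]:
        lethality_rows.append({"gene_symbol": g, "category": "none"})
    for g in viable[0:4]:
        lethality_rows.append({"gene_symbol": g, "category": "neonatal"})
    for g in viable[4:]:
        lethality_rows.append({"gene_symbol": g, "category": "none"})
    human_lethality = pd.DataFrame(lethality_rows)

    # p-values: TTE covers 19 genes of interest (17 with p < 0.05) plus 81
    # background genes; ECG covers 38 (20 significant) plus 62 background
    pv_rows = []

    def pv_block(proc, covered, n_sig, bg_prefix, n_bg, n_bg_sig):
        for i, g in enumerate(covered):
            sig = i < n_sig
            pv_rows.append((g, proc, f"{proc}_p1", 0.01 if sig else 0.50))
            pv_rows.append((g, proc, f"{proc}_p2", 0.73))
        for i in range(n_bg):
            g = f"{bg_prefix}{i:03d}"
            pv_rows.append((g, proc, f"{proc}_p1", 0.01 if i < n_bg_sig else 0.50))
            pv_rows.append((g, proc, f"{proc}_p2", 0.64))

    pv_block("TTE", with_data[0:19], 17, "BGT", 81, 54)
    pv_block("ECG", with_data[0:38], 20, "BGE", 62, 30)
    pvalues = pd.DataFrame(
        pv_rows, columns=["gene_symbol", "procedure", "parameter", "p_value"]
    )

    # variants: every non-viable gene keeps at least one pathogenic record
    variant_rows = []
    for i, g in enumerate(with_data):
        variant_rows.append((g, "frameshift" if i % 4 else "missense", "pathogenic"))
        variant_rows.append((g, "missense", "benign"))
    variants = pd.DataFrame(
        variant_rows, columns=["gene_symbol", "consequence", "clinical_significance"]
    )

    # cross-species cohort: 26 lethal lines; leaf pair i sits under system i//3
    cfg = synthetic.SyntheticConfig(ontology_depth=2, ontology_branching=3)
    graph = synthetic.generate_ontology(cfg)
    cohort_genes = lethal[0:26]
    disease_ann: dict[str, set[str]] = {}
    model_ann: dict[str, set[str]] = {}
    pair_rows = []
    truth = []
    for k, g in enumerate(cohort_genes):
        d_id, m_id = f"DIS:{k:04d}", f"MOD:{k:04d}"
        a = k % 3  # an HP/MP leaf pair in system 0
        hpo = {f"HP:{a:07d}"}
        if k < 16:  # positive, multisystem model (systems 0 and 1)
            mp = {f"MP:{a:07d}", f"MP:{3 + a:07d}"}
            positive = True
        elif k < 18:  # positive, single-system model
            mp = {f"MP:{a:07d}", f"MP:{(a + 1) % 3:07d}"}
            positive = True
        elif k < 23:  # negative, multisystem model (systems 1 and 2)
            mp = {f"MP:{3 + a:07d}", f"MP:{6 + a:07d}"}
            positive = False
        else:  # negative, single-system model
            mp = {f"MP:{3 + a:07d}"}
            positive = False
        disease_ann[d_id] = hpo
        model_ann[m_id] = mp
        pair_rows.append({"gene_symbol": g, "disease_id": d_id, "model_id": m_id})
        truth.append(positive)
    corpus = AnnotationCorpus(disease_ann, model_ann, graph)
    pairs = pd.DataFrame(pair_rows)

    # mouse term sets for the 14 viable lines: 11 multisystem, 3 single
    viable_mouse_terms = {}
    for j, g in enumerate(viable):
        if j < 11:
            viable_mouse_terms[g] = {f"MP:{j % 3:07d}", f"MP:{3 + j % 3:07d}"}
        else:
            viable_mouse_terms[g] = {f"MP:{j % 3:07d}"}

    ingest.write_panels(panels, outdir / "panels.tsv")
    ingest.write_table(orthologues, outdir / "orthologues.tsv")
    ingest.write_table(viability, outdir / "viability.tsv")
    ingest.write_table(human_lethality, outdir / "human_lethality.tsv")
    ingest.write_table(pvalues, outdir / "pvalues.tsv")
    ingest.write_table(variants, outdir / "variants.tsv")
    ingest.write_ontology(
        graph, outdir / "ontology_edges.tsv", outdir / "ontology_terms.tsv"
    )
    ingest.write_annotations(corpus, outdir / "annotations.tsv")
    ingest.write_table(pairs, outdir / "pairs.tsv")

    return {
        "genes": genes,
        "with_data": with_data,
        "lethal": lethal,
        "subviable": subviable,
        "viable": viable,
        "cohort_genes": cohort_genes,
        "cohort_truth": truth,
        "graph": graph,
        "corpus": corpus,
        "viable_mouse_terms": viable_mouse_terms,
    }


@pytest.fixture(scope="session")
def paper_bundle(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("paper_bundle")
    meta = build_paper_bundle(outdir)
    return outdir, meta


@pytest.fixture()
def tiny_graph():
    """root -> {c1, c2}; c1 -> {h1 (HP), m1 (MP)}; c2 -> {h2 (HP), m2 (MP)}."""
    from cardioko.phenodigm import OntologyGraph

    edges = [
        ("C:1", "R:0"),
        ("C:2", "R:0"),
        ("H:1", "C:1"),
        ("M:1", "C:1"),
        ("H:2", "C:2"),
        ("M:2", "C:2"),
    ]
    ns = {
        "R:0": "bridge",
        "C:1": "bridge",
        "C:2": "bridge",
        "H:1": "HP-like",
        "H:2": "HP-like",
        "M:1": "MP-like",
        "M:2": "MP-like",
    }
    return OntologyGraph(edges, ns)
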