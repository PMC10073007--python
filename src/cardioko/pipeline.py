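"""End-to-end orchestration: ingest → viability → enrichment → phenotype
similarity → bootstrap → systems, plus rating-stratified summaries.

A run consumes either a directory of input files (see ``ingest``) or a
synthetic configuration, in which case the generator first writes a complete
input bundle under ``<outdir>/inputs`` and the pipeline ingests it like any
other data — so synthetic runs exercise exactly the same readers.  Stages
whose inputs are absent are skipped and logged in the manifest; every stage
failure is re-raised with the stage name attached.  All randomness derives
from the single run seed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bootstrap as bootstrap_mod
from . import enrichment, ingest, synthetic, systems, viability
from . import phenodigm as phenodigm_mod
from .errors import CardiokoError, ConfigError, DataError
from .utils import percent


@dataclass
class RunConfig:
    input_dir: str | Path | None = None
    synthetic: synthetic.SyntheticConfig | None = None
    outdir: str | Path = "cardioko_run"
    alpha: float = 0.05
    phenodeviant_threshold: float = 0.0001
    n_iter: int = 10000
    conf_level: float = 0.95
    seed: int = 0
    background: str = "complement"
    min_pups: int = viability.DEFAULT_MIN_PUPS

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.synthetic is None):
            raise ConfigError(
                "input_dir", "provide exactly one of input_dir or synthetic config"
            )
        for name in ("alpha", "phenodeviant_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(name, f"threshold must be in (0, 1), got {v}")
        if not 0 < self.conf_level < 1:
            raise ConfigError("conf_level", "must be in (0, 1)")
        if self.n_iter < 1:
            raise ConfigError("n_iter", "must be >= 1")


@dataclass
class ReportBundle:
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    summaries: dict[str, dict] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in sorted(self.tables.items()):
            ingest.write_table(df, outdir / f"{name}.tsv")
        for name, payload in sorted(self.summaries.items()):
            (outdir / f"{name}.json").write_text(
                json.dumps(payload, indent=2, sort_keys=True)
            )
        (outdir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True)
        )


@contextmanager
def _stage(name: str):
    try:
        yield
    except CardiokoError as exc:
        raise type(exc)(f"stage {name!r}: {exc}") from exc


def _config_hash(config: RunConfig) -> str:
    payload = {
        "input_dir": str(config.input_dir) if config.input_dir else None,
        "synthetic": (
            synthetic.asdict(config.synthetic) if config.synthetic else None
        ),
        "alpha": config.alpha,
        "phenodeviant_threshold": config.phenodeviant_threshold,
        "n_iter": config.n_iter,
        "conf_level": config.conf_level,
        "seed": config.seed,
        "background": config.background,
        "min_pups": config.min_pups,
    }
    blob = json.dumps(payload, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16], payload


def run(config: RunConfig) -> ReportBundle:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle()
    digest, payload = _config_hash(config)
    bundle.manifest = {"config": payload, "config_hash": digest, "seed": config.seed,
                       "stages_run": [], "stages_skipped": []}

    if config.synthetic is not None:
        with _stage("simulate"):
            input_dir = outdir / "inputs"
            synthetic.write_bundle(config.synthetic, input_dir)
    else:
        input_dir = Path(config.input_dir)

    def present(name: str) -> Path | None:
        p = input_dir / name
        return p if p.exists() else None

    # ------------------------------------------------------------------ ingest
    with _stage("ingest"):
        panels = ingest.read_panels(present("panels.tsv") or input_dir / "panels.tsv")
        orthologues = ingest.read_orthologues(input_dir / "orthologues.tsv")
        lethality = (
            ingest.read_human_lethality(present("human_lethality.tsv"))
            if present("human_lethality.tsv")
            else None
        )
    bundle.manifest["stages_run"].append("ingest")

    # --------------------------------------------------------------- viability
    calls = None
    if present("litters.tsv"):
        with _stage("viability"):
            litters = ingest.read_viability(input_dir / "litters.tsv")
            calls = viability.call_viability_frame(litters, config.min_pups)
    elif present("viability.tsv"):
        with _stage("viability"):
            calls = ingest.read_viability(input_dir / "viability.tsv")
            calls = calls.rename(columns={"category": "category"})
    if calls is not None:
        with _stage("viability"):
            bundle.tables["viability_calls"] = calls
            bundle.tables["viability_summary"] = viability.summarize_viability(calls)
        bundle.manifest["stages_run"].append("viability")
    else:
        bundle.manifest["stages_skipped"].append("viability")

    with _stage("gene_table"):
        gene_table = ingest.build_gene_table(
            panels,
            orthologues,
            calls[["gene_symbol", "category"]] if calls is not None else None,
            lethality,
        )
        bundle.tables["gene_table"] = gene_table
    disease_genes = set(gene_table["gene_symbol"])

    # ------------------------------------------------------------- concordance
    if calls is not None and lethality is not None:
        with _stage("concordance"):
            disease_calls = calls[calls["gene_symbol"].isin(disease_genes)]
            rows = []
            if (disease_calls["category"].isin(["lethal", "subviable"])).any():
                for window in (
                    ("prenatal", "neonatal", "infant"),
                    ("prenatal", "neonatal", "infant", "child"),
                ):
                    pct, k, n = viability.lethality_concordance(
                        disease_calls, lethality, frozenset(window)
                    )
                    rows.append(
                        {
                            "window": "+".join(window),
                            "n_concordant": k,
                            "n_nonviable": n,
                            "percent": pct,
                        }
                    )
                bundle.tables["lethality_concordance"] = pd.DataFrame(rows)
                bundle.manifest["stages_run"].append("concordance")
            else:
                bundle.manifest["stages_skipped"].append("concordance")
    else:
        bundle.manifest["stages_skipped"].append("concordance")

    # -------------------------------------------------------------- enrichment
    if calls is not None:
        with _stage("enrichment"):
            frame = calls[["gene_symbol", "category"]].copy()
            frame["nonviable"] = frame["category"].isin(["lethal", "subviable"])
            panel_of = (
                panels.drop_duplicates("gene_symbol").set_index("gene_symbol")[
                    "panel_name"
                ]
            )
            frame["group"] = frame["gene_symbol"].map(panel_of).fillna("")
            if (frame["group"] != "").any():
                bundle.tables["enrichment_viability"] = enrichment.compare_categories(
                    frame,
                    "group",
                    "nonviable",
                    conf_level=config.conf_level,
                    background=config.background,
                )
                bundle.manifest["stages_run"].append("enrichment")
            else:
                bundle.manifest["stages_skipped"].append("enrichment")

        # rating-stratified viability summaries
        with _stage("rating_stratified"):
            rating_of = gene_table.set_index("gene_symbol")["resolved_rating"]
            merged = calls[calls["gene_symbol"].isin(rating_of.index)].copy()
            merged["rating"] = merged["gene_symbol"].map(rating_of)
            strata = []
            for rating in ("green", "amber", "red"):
                sub = merged[merged["rating"] == rating]
                if not len(sub):
                    continue
                summary = viability.summarize_viability(sub)
                summary.insert(0, "rating", rating)
                strata.append(summary)
            if strata:
                bundle.tables["viability_by_rating"] = pd.concat(
                    strata, ignore_index=True
                )
    else:
        bundle.manifest["stages_skipped"].append("enrichment")

    # ---------------------------------------------------------------- variants
    if present("variants.tsv"):
        with _stage("variants"):
            variants = ingest.read_variants(input_dir / "variants.tsv")
            gene_classes = enrichment.classify_gene(variants)
            bundle.tables["variant_gene_classes"] = gene_classes
            if calls is not None and len(gene_classes):
                merged = gene_classes.merge(
                    calls[["gene_symbol", "category"]], on="gene_symbol"
                )
                if len(merged):
                    merged["nonviable"] = merged["category"].isin(
                        ["lethal", "subviable"]
                    )
                    merged["nonlof_only"] = merged["gene_class"] == "nonLoF_only"
                    counts = (
                        merged.groupby("category")
                        .agg(
                            n_genes=("gene_symbol", "size"),
                            n_nonlof_only=("nonlof_only", "sum"),
                        )
                        .reset_index()
                    )
                    counts["pct_nonlof_only"] = [
                        percent(int(k), int(n))
                        for k, n in zip(counts["n_nonlof_only"], counts["n_genes"])
                    ]
                    a = int((merged["nonviable"] & merged["nonlof_only"]).sum())
                    b = int((merged["nonviable"] & ~merged["nonlof_only"]).sum())
                    c = int((~merged["nonviable"] & merged["nonlof_only"]).sum())
                    d = int((~merged["nonviable"] & ~merged["nonlof_only"]).sum())
                    if min(a + b, c + d) > 0 and min(a + c, b + d) > 0:
                        table = enrichment.ContingencyTable2x2(a, b, c, d)
                        counts.attrs["fisher_p"] = enrichment.fisher_two_sided(table)
                        bundle.summaries["variant_class_test"] = {
                            "a": a,
                            "b": b,
                            "c": c,
                            "d": d,
                            "p_fisher": counts.attrs["fisher_p"],
                        }
                    bundle.tables["variant_class_by_viability"] = counts
        bundle.manifest["stages_run"].append("variants")
    else:
        bundle.manifest["stages_skipped"].append("variants")

    # --------------------------------------------------------------- phenodigm
    graph = None
    have_phenodigm = (
        present("ontology_edges.tsv")
        and present("ontology_terms.tsv")
        and present("annotations.tsv")
        and present("pairs.tsv")
    )
    if have_phenodigm:
        with _stage("phenodigm"):
            graph = ingest.read_ontology(
                input_dir / "ontology_edges.tsv", input_dir / "ontology_terms.tsv"
            )
            corpus = ingest.read_annotations(input_dir / "annotations.tsv", graph)
            pairs = pd.read_csv(input_dir / "pairs.tsv", sep="\t", dtype=str)
            rows = []
            results = []
            for _, row in pairs.iterrows():
                hpo = corpus.disease_annotations.get(row["disease_id"], frozenset())
                mp = corpus.model_annotations.get(row["model_id"], frozenset())
                if not hpo:
                    warnings.warn(
                        f"disease {row['disease_id']} has no annotations; skipped",
                        stacklevel=2,
                    )
                    continue
                res = phenodigm_mod.model_disease_score(graph, corpus, hpo, mp)
                results.append(res)
                rows.append(
                    {
                        "gene_symbol": row["gene_symbol"],
                        "disease_id": row["disease_id"],
                        "model_id": row["model_id"],
                        "max_score": res.max_score,
                        "avg_score": res.avg_score,
                        "percentage": res.percentage,
                        "positive": res.positive,
                    }
                )
            if rows:
                bundle.tables["phenodigm_scores"] = pd.DataFrame(rows)
                bundle.summaries["phenodigm_summary"] = {
                    "n_pairs": len(rows),
                    "n_positive": sum(r["positive"] for r in rows),
                    "pct_positive": phenodigm_mod.summarize_positive(results),
                }
        bundle.manifest["stages_run"].append("phenodigm")
    else:
        bundle.manifest["stages_skipped"].append("phenodigm")

    # ----------------------------------------------------------------- systems
    if have_phenodigm and graph is not None:
        with _stage("systems"):
            system_terms = getattr(graph, "system_terms", ())
            profiles_h, profiles_m, prof_rows = [], [], []
            for _, row in pairs.iterrows():
                hpo = corpus.disease_annotations.get(row["disease_id"], frozenset())
                mp = corpus.model_annotations.get(row["model_id"], frozenset())
                ph = systems.profile(graph, row["gene_symbol"], "human", hpo, system_terms)
                pm = systems.profile(graph, row["gene_symbol"], "mouse", mp, system_terms)
                shared = systems.shared_systems(ph, pm)
                profiles_h.append(ph)
                profiles_m.append(pm)
                prof_rows.append(
                    {
                        "gene_symbol": row["gene_symbol"],
                        "n_systems_human": ph.n_systems,
                        "n_systems_mouse": pm.n_systems,
                        "n_shared": len(shared),
                        "systems_human": ";".join(sorted(ph.systems)),
                        "systems_mouse": ";".join(sorted(pm.systems)),
                        "systems_shared": ";".join(sorted(shared)),
                    }
                )
            if prof_rows:
                bundle.tables["system_profiles"] = pd.DataFrame(prof_rows)
                bundle.summaries["multisystem_summary"] = {
                    "human": systems.multisystem_summary(profiles_h),
                    "mouse": systems.multisystem_summary(profiles_m),
                }
        bundle.manifest["stages_run"].append("systems")
    else:
        bundle.manifest["stages_skipped"].append("systems")

    # --------------------------------------------------------------- bootstrap
    if present("pvalues.tsv"):
        with _stage("bootstrap"):
            pvalues = ingest.read_pvalues(input_dir / "pvalues.tsv")
            # phenodeviant flag: any parameter under the screening threshold
            deviants = (
                pvalues.groupby("gene_symbol")["p_value"]
                .apply(lambda s: bool((s < config.phenodeviant_threshold).any()))
                .reset_index()
                .rename(columns={"p_value": "phenodeviant"})
            )
            bundle.tables["phenodeviants"] = deviants
            if calls is not None:
                bundle.tables["procedure_coverage"] = systems.coverage_summary(
                    calls["gene_symbol"],
                    pvalues[["gene_symbol", "procedure"]].drop_duplicates(),
                )
            boot_results = {}
            hist_frames = []
            interest = sorted(disease_genes)
            for i, proc in enumerate(sorted(pvalues["procedure"].unique())):
                pool_genes = set(pvalues.loc[pvalues["procedure"] == proc, "gene_symbol"])
                if not set(interest) & pool_genes:
                    bundle.manifest["stages_skipped"].append(f"bootstrap:{proc}")
                    continue
                res = bootstrap_mod.bootstrap_enrichment(
                    pvalues,
                    proc,
                    interest,
                    n_iter=config.n_iter,
                    alpha=config.alpha,
                    seed=int(np.random.SeedSequence([config.seed, 7, i]).generate_state(1)[0] % (2**31)),
                )
                boot_results[proc] = res.to_dict()
                hist = bootstrap_mod.null_histogram(res)
                hist.insert(0, "procedure", proc)
                hist_frames.append(hist)
            if boot_results:
                bundle.summaries["bootstrap_results"] = boot_results
                bundle.tables["bootstrap_null_histogram"] = pd.concat(
                    hist_frames, ignore_index=True
                )
                bundle.manifest["stages_run"].append("bootstrap")
    else:
        bundle.manifest["stages_skipped"].append("bootstrap")

    bundle.write(outdir)
    return bundle
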