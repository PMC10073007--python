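import math

import numpy as np
import pandas as pd
import pytest

from cardioko.errors import ConfigError
from cardioko.synthetic import (
    SyntheticConfig,
    generate_annotations,
    generate_human_lethality,
    generate_litters,
    generate_matched_cohort,
    generate_ontology,
    generate_pvalues,
    generate_universe,
    generate_variants,
    matched_leaf_pairs,
)
from cardioko.phenodigm import model_disease_score


def realized_or(genes, viability):
    merged = genes.merge(viability, on="gene_symbol")
    nonviable = merged["category"].isin(["lethal", "subviable"])
    disease = merged["is_disease"]
    a = int((disease & nonviable).sum())
    b = int((disease & ~nonviable).sum())
    c = int((~disease & nonviable).sum())
    d = int((~disease & ~nonviable).sum())
    return a, b, c, d


class TestConfig:
    def test_invalid_proportion_names_field(self):
        with pytest.raises(ConfigError, match="disease_fraction"):
            SyntheticConfig(disease_fraction=1.5)

    def test_invalid_or_and_counts(self):
        with pytest.raises(ConfigError, match="true_or"):
            SyntheticConfig(true_or=0)
        with pytest.raises(ConfigError, match="ontology_depth"):
            SyntheticConfig(ontology_depth=1)

    def test_rating_probs_must_sum_to_one(self):
        with pytest.raises(ConfigError, match="panel_rating_probs"):
            SyntheticConfig(panel_rating_probs=(0.5, 0.5, 0.5))


class TestUniverse:
    def test_determinism_same_seed_same_tables(self):
        cfg = SyntheticConfig(n_genes=2000, seed=11)
        g1, v1 = generate_universe(cfg)
        g2, v2 = generate_universe(cfg)
        assert g1.to_csv() == g2.to_csv()
        assert v1.to_csv() == v2.to_csv()

    def test_null_association_or_near_one(self):
        cfg = SyntheticConfig(
            n_genes=100_000, disease_fraction=0.5, true_or=1.0, seed=3
        )
        genes, viability = generate_universe(cfg)
        a, b, c, d = realized_or(genes, viability)
        assert 0.9 <= (a * d) / (b * c) <= 1.1

    def test_zero_disease_fraction_degenerate(self):
        cfg = SyntheticConfig(n_genes=500, disease_fraction=0.0, seed=1)
        genes, _ = generate_universe(cfg)
        assert genes["is_disease"].sum() == 0

    def test_wald_ci_covers_truth_across_replicates(self):
        """95% Wald CIs from the realised 2x2 contain the generating odds
        ratio in at least 94% of replicates."""
        from cardioko.enrichment import ContingencyTable2x2, odds_ratio_wald

        true_or = 5.6
        covered = 0
        n_rep = 500
        for rep in range(n_rep):
            cfg = SyntheticConfig(
                n_genes=20_000, disease_fraction=0.05, true_or=true_or, seed=10_000 + rep
            )
            genes, viability = generate_universe(cfg)
            res = odds_ratio_wald(ContingencyTable2x2(*realized_or(genes, viability)))
            covered += int(res.ci_low <= true_or <= res.ci_high)
        assert covered / n_rep >= 0.94


class TestLitters:
    def viability_frame(self, n_each):
        cats = ["lethal"] * n_each + ["subviable"] * n_each + ["viable"] * n_each
        return pd.DataFrame(
            {"gene_symbol": [f"G{i}" for i in range(len(cats))], "category": cats}
        )

    def test_lethal_lines_have_zero_homozygotes(self):
        litters = generate_litters(self.viability_frame(50), pups_per_line=28, seed=2)
        lethal = litters.iloc[:50]
        assert (lethal["n_hom"] == 0).all()

    def test_subviable_strictly_below_threshold(self):
        litters = generate_litters(self.viability_frame(50), pups_per_line=28, seed=2)
        sub = litters.iloc[50:100]
        frac = sub["n_hom"] / sub[["n_hom", "n_het", "n_wt"]].sum(axis=1)
        assert ((frac > 0) & (frac < 0.125)).all()

    def test_viable_mean_hom_fraction_mendelian(self):
        cats = pd.DataFrame(
            {"gene_symbol": [f"G{i}" for i in range(1000)], "category": "viable"}
        )
        litters = generate_litters(cats, pups_per_line=400, seed=4)
        frac = litters["n_hom"] / 400
        assert 0.24 <= frac.mean() <= 0.26


class TestOntology:
    def test_invariants_on_generated_graphs(self):
        for depth, branching in [(2, 2), (3, 3), (2, 5)]:
            cfg = SyntheticConfig(ontology_depth=depth, ontology_branching=branching)
            graph = generate_ontology(cfg)
            assert graph.root == "CP:0000000"
            for t in graph.terms:
                assert graph.root in graph.ancestors(t)

    def test_counting_rule_depth2_branching2(self):
        cfg = SyntheticConfig(ontology_depth=2, ontology_branching=2)
        graph = generate_ontology(cfg)
        bridges = graph.terms_in_namespace("bridge")
        hp = graph.terms_in_namespace("HP-like")
        mp = graph.terms_in_namespace("MP-like")
        # 1 root + 2 systems + 4 deep bridge terms; 4 leaves per species
        assert len(bridges) == 7
        assert len(graph.system_terms) == 2
        assert len(hp) == len(mp) == 4

    def test_every_cross_species_leaf_pair_shares_root(self):
        cfg = SyntheticConfig(ontology_depth=2, ontology_branching=2)
        graph = generate_ontology(cfg)
        for h in graph.terms_in_namespace("HP-like"):
            for m in graph.terms_in_namespace("MP-like"):
                assert graph.root in (graph.ancestors(h) & graph.ancestors(m))

    def test_matched_pairs_share_parent(self):
        graph = generate_ontology(SyntheticConfig(ontology_depth=2, ontology_branching=3))
        pairs = matched_leaf_pairs(graph)
        assert len(pairs) == 9
        for hp, mp, parent in pairs:
            assert parent in graph.ancestors(hp) and parent in graph.ancestors(mp)


class TestAnnotations:
    def test_full_overlap_gives_all_positive(self):
        cfg = SyntheticConfig(
            annotation_overlap=1.0, n_diseases=20, n_models=20, seed=6
        )
        graph = generate_ontology(cfg)
        corpus, pairs = generate_annotations(graph, cfg)
        for _, row in pairs.iterrows():
            res = model_disease_score(
                graph,
                corpus,
                corpus.disease_annotations[row["disease_id"]],
                corpus.model_annotations[row["model_id"]],
            )
            assert res.positive

    def test_overlap_monotonicity_of_scores(self):
        scores = {}
        for overlap in (0.0, 1.0):
            cfg = SyntheticConfig(
                annotation_overlap=overlap,
                n_diseases=100,
                n_models=100,
                ontology_depth=3,
                ontology_branching=3,
                seed=8,
            )
            graph = generate_ontology(cfg)
            corpus, pairs = generate_annotations(graph, cfg)
            vals = [
                model_disease_score(
                    graph,
                    corpus,
                    corpus.disease_annotations[r["disease_id"]],
                    corpus.model_annotations[r["model_id"]],
                ).percentage
                for _, r in pairs.iterrows()
            ]
            scores[overlap] = float(np.median(vals))
        assert scores[0.0] < scores[1.0]

    def test_matched_cohort_truth_labels_are_exact(self):
        graph = generate_ontology(SyntheticConfig(ontology_depth=3, ontology_branching=3))
        corpus, cohort = generate_matched_cohort(graph, 18, 8, seed=12)
        for _, row in cohort.iterrows():
            res = model_disease_score(
                graph,
                corpus,
                corpus.disease_annotations[row["disease_id"]],
                corpus.model_annotations[row["model_id"]],
            )
            assert res.positive == row["truth_positive"]


class TestPValuesVariantsLethality:
    def test_null_rate_matches_closed_form(self):
        cfg = SyntheticConfig(
            affected_gene_fraction=0.0,
            params_per_gene=5,
            procedure_coverage={"TTE": 1.0},
            seed=9,
        )
        genes = [f"G{i}" for i in range(10_000)]
        table, affected = generate_pvalues(genes, cfg)
        assert not affected
        any_sig = table.groupby("gene_symbol")["p_value"].apply(lambda s: (s < 0.05).any())
        expected = 1 - 0.95**5
        se = math.sqrt(expected * (1 - expected) / 10_000)
        assert abs(any_sig.mean() - expected) <= 2 * se

    def test_affected_genes_enriched_for_small_p(self):
        cfg = SyntheticConfig(
            affected_gene_fraction=0.5,
            affected_param_effect=0.8,
            procedure_coverage={"TTE": 1.0},
            seed=10,
        )
        genes = [f"G{i}" for i in range(2000)]
        table, affected = generate_pvalues(genes, cfg)
        sig = table.groupby("gene_symbol")["p_value"].apply(lambda s: (s < 0.05).any())
        rate_affected = sig.loc[sig.index.isin(affected)].mean()
        rate_null = sig.loc[~sig.index.isin(affected)].mean()
        assert rate_affected > rate_null + 0.2

    def test_all_lof_config_labels_every_gene_lof(self):
        from cardioko.enrichment import classify_gene

        cfg = SyntheticConfig(
            lof_fraction_by_viability={"all": 1.0}, pathogenic_fraction=1.0, seed=3
        )
        gene_table = pd.DataFrame(
            {"gene_symbol": [f"G{i}" for i in range(200)], "viability": "lethal"}
        )
        variants = generate_variants(gene_table, cfg)
        labels = classify_gene(variants)
        assert (labels["gene_class"] == "LoF").all()
        assert set(labels["gene_symbol"]) == set(gene_table["gene_symbol"])

    def test_unknown_lof_category_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(lof_fraction_by_viability={"zombie": 0.5})

    def test_lethality_categories_and_concordance_direction(self):
        cfg = SyntheticConfig(lethality_concordance=0.9, viable_early_rate=0.05, seed=5)
        viability = pd.DataFrame(
            {
                "gene_symbol": [f"G{i}" for i in range(2000)],
                "category": ["lethal"] * 1000 + ["viable"] * 1000,
            }
        )
        records = generate_human_lethality(viability, cfg)
        assert set(records["category"]) <= {"prenatal", "neonatal", "infant", "child", "none"}
        early = records["category"].isin(["prenatal", "neonatal", "infant"])
        assert early[:1000].mean() > 0.8
        assert early[1000:].mean() < 0.15
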