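# Methods

This note documents the models and procedures implemented in `cardioko`,
the defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions that matter for
reproducibility.

## Viability calling

A knockout line's primary viability is called from litter genotype counts
(`n_hom`, `n_het`, `n_wt` at weaning):

- **lethal** — `n_hom = 0`;
- **subviable** — homozygote fraction strictly below 0.125 (half the
  Mendelian expectation of 0.25 for a het × het cross);
- **viable** — otherwise. A fraction of exactly 0.125 is viable: the
  definition is a strict inequality.

Calls require at least `min_pups = 28` genotyped pups (a common screening
convention; the threshold is configurable and not derived from data).
Reported percentages are rounded half-away-from-zero to one decimal place
throughout the package, so 43/57 → 75.4 and 20/43 → 46.5.

Mouse–human lethality concordance is the share of mouse non-viable genes
with a human earliest-death record inside a window over the ordered
categories *prenatal < neonatal < infant < child*. Only windows that are
prefixes of that order are accepted — extending the window to later ages is
meaningful, skipping early ones is not.

## 2×2 enrichment statistics

Each comparison is a 2×2 table with exposure rows (e.g. disease-panel gene
vs background) and outcome columns (e.g. non-viable vs viable):

- **Odds ratio** — the unconditional sample estimate `ad/bc` with the Wald
  interval `exp(ln OR ± z_{1−α/2}·√(1/a+1/b+1/c+1/d))`. If any single cell
  is zero, 0.5 is added to all four cells and the result is flagged
  (`zero_cell_corrected`); clean tables are never altered. Two zero cells on
  a diagonal leave the OR undefined and raise an error.
- **Fisher exact test** — two-sided by the point-probability method: the sum
  of hypergeometric probabilities (margins fixed) of every table whose point
  probability does not exceed the observed one, with a ~1e-7 relative tie
  tolerance. The implementation delegates to `scipy.stats.fisher_exact`,
  which implements exactly this rule; the test suite checks it against an
  exact-rational enumeration oracle on every table with total ≤ 30.
- **Multiple testing** — Benjamini–Hochberg step-up adjustment
  (`statsmodels`), applied within one comparison family at a time (one call
  per figure-style panel), cross-checked against a direct implementation of
  the sorted step-up rule.
- **Background convention** — `compare_categories` defaults to group vs
  complement (all other genes in the table); a
  `background="outside_all_groups"` flag compares against genes belonging to
  no group instead, since either convention is defensible when disease
  categories overlap.

Variant classes: LoF = {frameshift, nonsense, splice_site}; non-LoF =
{missense, ncRNA, near_gene, UTR, synonymous, in_frame}. Only records with
clinical significance `pathogenic` count; a gene is `LoF` if it has at least
one pathogenic LoF variant and `nonLoF_only` otherwise.

## Cross-species phenotype similarity

The scorer follows the PhenoDigm construction over a merged cross-species
ontology (HP-like and MP-like vocabularies joined by bridging ancestors):

- `simJ(t1, t2)` — Jaccard index of the *self-inclusive* ancestor sets.
- `IC(t) = −ln(k/N)` — information content over the **combined** corpus of
  disease and model entities, where `k` counts entities annotated with `t`
  or any descendant. Terms never observed are capped at `−ln(1/N)` and
  flagged. The log base is irrelevant to the final percentage (it cancels in
  the normalisation by the perfect-model score) — natural log is used.
- `MICA(t1, t2)` — common ancestor with maximal IC; ties break to the
  lexicographically smallest id so results are deterministic.
- pair score — `√(simJ · IC(MICA))`, the geometric mean.
- set score — for disease HP set *H* and model MP set *M*, `max` is the best
  entry of the |H|×|M| matrix, and `avg` is the symmetric best-match mean
  (mean of all row maxima and all column maxima). The theoretical maxima
  come from comparing *H* with itself — a perfect model — for which the pair
  score of a term with itself reduces to `√IC(t)` (simJ = 1, and IC is
  monotone non-increasing towards the root so the MICA is the term itself).
  The percentage is `100 · ½ · (max/max_theory + avg/avg_theory)`, clamped
  to [0, 100] (the `avg` component can exceed its theory value when a small
  model set concentrates on the disease's most informative term).
- `positive ⇔ percentage > 0 ⇔` at least one HP–MP pair has an informative
  (IC > 0) common ancestor.

Design choices made where the construction is genuinely open: the symmetric
(bidirectional) best-match mean is the default and a grand mean of the whole
matrix is available via `avg_mode="grand"`; entities with empty annotation
sets score 0 with a flag rather than being dropped; an all-uninformative
disease set (avg_theory = 0) is an error rather than a silent 0/0.

## Bootstrap enrichment of nominal p-values

For one phenotyping procedure, the pool is every gene with at least one
parameter measured. The observed statistic is the fraction of interest genes
(intersected with the pool; genes without data are dropped with a logged
count) that have any parameter with p < α (strict, default α = 0.05). Each
of `n_iter = 10,000` iterations draws the same number of genes from the pool
without replacement, independently across iterations, and recomputes the
fraction. The empirical p is `#(iteration ≥ observed) / n_iter` with no +1
correction, so it is always a multiple of 1/n_iter; a value of 0 is flagged
as below the test's resolution. Ties are compared as integer counts (all
fractions share one denominator), never as floats. Because the null statistic
is discrete and ties count against rejection, the empirical p is
conservative (super-uniform) under a null interest set — the test suite
verifies this by simulation, and verifies the p-value itself against
exhaustive enumeration of all draws on small pools.

## System rollups

Top-level "physiological system" terms are *declared* (the DAG layer below
the root in generated and file-based ontologies), not inferred, because real
human and mouse top levels differ and curated system vocabularies are the
norm. A system is affected iff some annotated term has it in its ancestor
closure; multisystem means ≥ 2 systems. Human–mouse comparison goes through
an explicit mouse→human system map, defaulting to identity (exact for the
synthetic ontology, where systems are shared bridge terms); unmapped systems
are ignored with a warning.

## Synthetic data generator

The generator is first-class, tested code. Its defaults are the study
conditions the rest of the package is exercised under:

| parameter | default | rationale |
| --- | --- | --- |
| `n_genes` | 8000 | order of a genome-wide screen with viability data |
| `disease_fraction` | 0.01 | a small curated disease-gene class |
| `true_or` | 5.6 | lethality odds ratio of disease vs background genes |
| `base_nonviable_rate` | 0.35 | background non-viable rate (~35%) |
| `lethal_given_nonviable` | 0.714 | lethal ≈ 25% of all lines, subviable ≈ 10% |
| `panel_rating_probs` | (0.44, 0.26, 0.30) | green/amber/red mix of curated panels |
| `moi_probs` | (0.35, 0.44, 0.14, 0.07) | biallelic/monoallelic/both/X-linked mix |
| `lof_fraction_by_viability` | lethal 0.70, subviable 0.70, viable 0.85 | more non-LoF-only genes among mouse-lethal genes |
| `procedure_coverage` | TTE 0.333, ECG 0.667 | roughly a third/two-thirds of lines covered |
| `params_per_gene` | 10 per procedure | a typical parameter panel |
| `affected_param_effect`, `beta_a` | 0.5, 0.2 | Beta(0.2, 1) small-p alternative on half the parameters of affected genes |
| `annotation_overlap` | 0.6 | fraction of annotation slots drawn from matched cross-species branches |
| `lethality_concordance` | 0.465 | early-death rate among mouse non-viable genes |
| `viable_early_rate` | 0.285 | early-death rate among mouse-viable genes |

Key mechanisms:

- **Universe** — viability is Bernoulli with `logit(p) = logit(base) +
  ln(true_or)·disease`, so the population log-odds difference is exactly
  `ln(true_or)`; the enrichment stage recovers it within sampling error
  (verified at 100k genes).
- **Litters** — lethal lines have 0 homozygotes by construction; subviable
  lines realise a homozygote fraction drawn Uniform(0, 0.125) exclusive of
  both ends (clipped to keep the realised count strictly below 12.5% with at
  least one pup), matching the definitional band without inventing a
  biological model; viable lines are trinomial (¼, ½, ¼). A viable line can
  by chance realise < 12.5% homozygotes in a small litter — that is genuine
  misclassification noise, not a bug.
- **Ontology** — a rooted tree: root, `branching` system terms, further
  bridge layers down to depth, then one HP-like and one MP-like leaf per
  deepest bridge term. Matched leaf pairs share an informative parent;
  leaves from different systems share only the root. `random_dag` provides
  genuinely multi-parent random DAGs for property tests.
- **Human lethality** — the joint distribution of mouse viability and human
  early death is not specified beyond marginals in the literature this
  emulates, so a single concordance parameter (plus a viable-gene early
  rate) is exposed rather than guessing a mechanism.
- **Determinism** — one RNG stream per output table, keyed by
  `(seed, crc32(table name))`: identical config + seed gives byte-identical
  files, and adding a table never perturbs the others.

What the generator does **not** emulate: mixed-model phenotype statistics,
soft windowing, batch or litter pedigree structure, centre effects, linkage
between neighbouring genes, or realistic term-frequency distributions in
the ontology. Passing tests therefore demonstrate the correctness and
calibration of the statistical machinery under idealised sampling, not the
biases of real screen data.

## Problem sizes and numerical conventions

Test and script workloads are sized to run comfortably on one CPU: the
worked-example fixture (153 genes, 57 with data) runs in seconds; Wald
coverage uses 1,000 tables per odds ratio (plus 500 generator replicates at
20k genes for the end-to-end coverage check); bootstrap calibration uses
exhaustive enumeration on pools ≤ 8 and 500 null replicates at 2,000
iterations; similarity oracles use 100 random DAGs of ≤ 50 terms; parameter
recovery uses a single 100k-gene universe. Percent rounding is
half-away-from-zero to 1 dp. Bootstrap tie comparison is integer-exact.
MICA ties break lexicographically. The Fisher tie tolerance is the
conventional ~1e-7 relative band.

## Known limitations

- The Wald CI is a large-sample approximation; with expected cells below ~5
  its coverage degrades (the continuity-corrected zero-cell path keeps it
  defined, not well-calibrated).
- The similarity scorer's percentage depends on the annotation corpus
  through IC; scores from different corpora are not comparable.
- The pipeline consumes phenotype-significance p-values as given; it does
  not model the upstream test dependence between parameters of one
  procedure.
- `compare_categories` treats genes in multiple disease categories by their
  first panel membership when building groups; overlapping-category designs
  should use the explicit background flag.
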