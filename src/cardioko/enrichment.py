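"""2×2 enrichment statistics and variant-class comparisons.

The odds ratio is the unconditional (sample) estimate ad/bc with a Wald
confidence interval on the log scale; a 0.5 continuity correction is applied
to all four cells when any cell is zero (and the result is flagged).
Independence is tested with the two-sided Fisher exact test (point-
probability method) and families of tests are corrected with the
Benjamini–Hochberg step-up procedure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError, UndefinedStatisticError, VocabularyError

LOF_CONSEQUENCES = frozenset({"frameshift", "nonsense", "splice_site"})
NONLOF_CONSEQUENCES = frozenset(
    {"missense", "ncRNA", "near_gene", "UTR", "synonymous", "in_frame"}
)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = exposure (e.g. disease gene) and columns = outcome
    (e.g. non-viable): a = exposed & outcome, b = exposed & not, c =
    unexposed & outcome, d = unexposed & not."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise DataError("empty contingency table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class ORResult:
    or_estimate: float
    ci_low: float
    ci_high: float
    p_fisher: float | None = None
    p_adjusted: float | None = None
    zero_cell_corrected: bool = False


def odds_ratio_wald(table: ContingencyTable2x2, conf_level: float = 0.95) -> ORResult:
    """Sample odds ratio with a normal-approximation (Wald) CI on ln OR."""
    if not 0 < conf_level < 1:
        raise ValueError("conf_level must be in (0, 1)")
    a, b, c, d = table.a, table.b, table.c, table.d
    corrected = False
    if min(a, b, c, d) == 0:
        if (a == 0 and d == 0) or (b == 0 and c == 0):
            raise UndefinedStatisticError(
                "odds ratio undefined: two zero cells on a diagonal"
            )
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
        corrected = True
    or_est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - (1 - conf_level) / 2)
    log_or = math.log(or_est)
    return ORResult(
        or_estimate=or_est,
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        zero_cell_corrected=corrected,
    )


def fisher_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p: the sum of hypergeometric probabilities of
    all tables (margins fixed) whose point probability does not exceed the
    observed one (relative tie tolerance ~1e-7)."""
    _, p = stats.fisher_exact(table.as_array(), alternative="two-sided")
    return float(min(p, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_variant(consequence: str) -> str:
    """LoF (frameshift, nonsense, splice site) vs nonLoF (everything else in
    the controlled vocabulary)."""
    if consequence in LOF_CONSEQUENCES:
        return "LoF"
    if consequence in NONLOF_CONSEQUENCES:
        return "nonLoF"
    raise VocabularyError(f"unknown molecular consequence {consequence!r}")


def classify_gene(variants: pd.DataFrame) -> pd.DataFrame:
    """Gene-level labels from pathogenic variants only: a gene is LoF if at
    least one pathogenic LoF variant is reported, nonLoF_only otherwise."""
    pathogenic = variants[variants["clinical_significance"] == "pathogenic"]
    if not len(pathogenic):
        return pd.DataFrame(columns=["gene_symbol", "gene_class"])
    classes = pathogenic["consequence"].map(classify_variant)
    has_lof = (
        classes.eq("LoF").groupby(pathogenic["gene_symbol"]).any()
    )
    return (
        pd.DataFrame(
            {
                "gene_symbol": has_lof.index,
                "gene_class": np.where(has_lof, "LoF", "nonLoF_only"),
            }
        )
        .sort_values("gene_symbol")
        .reset_index(drop=True)
    )


def compare_categories(
    gene_table: pd.DataFrame,
    grouping: str,
    outcome: str,
    conf_level: float = 0.95,
    background: str = "complement",
) -> pd.DataFrame:
    """One enrichment test per group of ``grouping`` against the background.

    The outcome column must be boolean.  ``background='complement'`` compares
    each group against all other genes in the table;
    ``background='outside_all_groups'`` compares against genes belonging to
    no group (empty/NaN group label).  BH adjustment is applied across the
    groups of this one comparison family.
    """
    if background not in ("complement", "outside_all_groups"):
        raise ValueError(f"unknown background convention {background!r}")
    labels = gene_table[grouping].fillna("")
    out = gene_table[outcome].astype(bool)
    groups = sorted(x for x in labels.unique() if x != "")
    if not groups:
        raise DataError(f"no non-empty groups in column {grouping!r}")
    rows = []
    for group in groups:
        in_group = labels == group
        if background == "complement":
            in_background = ~in_group
        else:
            in_background = labels == ""
        if not in_group.any():
            warnings.warn(f"group {group!r} is empty; skipped", stacklevel=2)
            continue
        if not in_background.any():
            raise DataError(
                f"group {group!r} covers every gene; degenerate complement refused"
            )
        table = ContingencyTable2x2(
            a=int((in_group & out).sum()),
            b=int((in_group & ~out).sum()),
            c=int((in_background & out).sum()),
            d=int((in_background & ~out).sum()),
        )
        if (table.a + table.c == 0) or (table.b + table.d == 0):
            raise DataError(
                f"outcome margin is zero for group {group!r}; enrichment undefined"
            )
        try:
            orr = odds_ratio_wald(table, conf_level)
        except UndefinedStatisticError:
            warnings.warn(f"group {group!r}: OR undefined (double-zero diagonal)", stacklevel=2)
            continue
        rows.append(
            {
                "group": group,
                "a": table.a,
                "b": table.b,
                "c": table.c,
                "d": table.d,
                "odds_ratio": orr.or_estimate,
                "ci_low": orr.ci_low,
                "ci_high": orr.ci_high,
                "p_fisher": fisher_two_sided(table),
                "zero_cell_corrected": orr.zero_cell_corrected,
            }
        )
    if not rows:
        raise DataError("no testable groups")
    result = pd.DataFrame(rows)
    result["p_adjusted"] = bh_adjust(result["p_fisher"].to_numpy())
    return result
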