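"""Viability calling from litter genotype counts and mouse–human lethality
concordance.

A knockout line is *lethal* when no live homozygous pups are observed at
weaning, *subviable* when the homozygote fraction is strictly below 12.5%
(half the Mendelian expectation of 25%), and *viable* otherwise.  A boundary
fraction of exactly 12.5% is viable (the definition is a strict inequality).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .errors import DataError, InsufficientDataError
from .utils import percent

CATEGORIES = ("lethal", "subviable", "viable")
# earliest-death categories from conception onwards; "none" = no record
LETHALITY_ORDER = ("prenatal", "neonatal", "infant", "child")
SUBVIABLE_THRESHOLD = 0.125
DEFAULT_MIN_PUPS = 28  # screening convention; configurable


@dataclass(frozen=True)
class LitterCounts:
    gene_symbol: str
    n_hom: int
    n_het: int
    n_wt: int

    def __post_init__(self) -> None:
        if min(self.n_hom, self.n_het, self.n_wt) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_hom + self.n_het + self.n_wt


@dataclass(frozen=True)
class ViabilityCall:
    gene_symbol: str
    category: str
    hom_fraction: float


def call_viability(counts: LitterCounts, min_pups: int = DEFAULT_MIN_PUPS) -> ViabilityCall:
    """Categorise one line from its litter genotype counts."""
    if counts.total < min_pups:
        raise InsufficientDataError(
            f"{counts.gene_symbol}: {counts.total} pups < min_pups={min_pups}; no call"
        )
    fraction = counts.n_hom / counts.total
    if counts.n_hom == 0:
        category = "lethal"
    elif fraction < SUBVIABLE_THRESHOLD:
        category = "subviable"
    else:
        category = "viable"
    return ViabilityCall(counts.gene_symbol, category, fraction)


def call_viability_frame(
    litters: pd.DataFrame, min_pups: int = DEFAULT_MIN_PUPS
) -> pd.DataFrame:
    """Vectorised calls for a litter table; lines below min_pups are dropped
    with a warning rather than raising."""
    total = litters[["n_hom", "n_het", "n_wt"]].sum(axis=1)
    keep = total >= min_pups
    if (~keep).any():
        warnings.warn(
            f"{(~keep).sum()} line(s) below min_pups={min_pups} received no call",
            stacklevel=2,
        )
    sub = litters[keep]
    total = total[keep]
    fraction = sub["n_hom"] / total
    category = pd.Series("viable", index=sub.index)
    category[fraction < SUBVIABLE_THRESHOLD] = "subviable"
    category[sub["n_hom"] == 0] = "lethal"
    return pd.DataFrame(
        {
            "gene_symbol": sub["gene_symbol"],
            "category": category,
            "hom_fraction": fraction,
        }
    ).reset_index(drop=True)


def summarize_viability(calls: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages (1 dp) per category plus the non-viable total."""
    if calls is None or not len(calls):
        raise DataError("no viability calls to summarise")
    total = len(calls)
    counts = calls["category"].value_counts()
    rows = [
        {"category": c, "n": int(counts.get(c, 0)), "percent": percent(int(counts.get(c, 0)), total)}
        for c in CATEGORIES
    ]
    nonviable = int(counts.get("lethal", 0) + counts.get("subviable", 0))
    rows.append({"category": "non_viable", "n": nonviable, "percent": percent(nonviable, total)})
    rows.append({"category": "total", "n": total, "percent": 100.0})
    return pd.DataFrame(rows)


def lethality_concordance(
    calls: pd.DataFrame,
    human_records: pd.DataFrame,
    window: set[str] | frozenset[str] = frozenset({"prenatal", "neonatal", "infant"}),
) -> tuple[float, int, int]:
    """Percentage of mouse non-viable genes with a human death record inside
    the window.

    The window must be an upward-closed prefix of the ordered earliest-death
    categories (prenatal < neonatal < infant < child): you may extend it to
    later ages but not skip earlier ones.  Returns (percent, numerator,
    denominator) where the denominator is the number of mouse lethal +
    subviable genes.
    """
    window = frozenset(window)
    prefix_ok = any(
        window == frozenset(LETHALITY_ORDER[: k + 1]) for k in range(len(LETHALITY_ORDER))
    )
    if not prefix_ok:
        raise ValueError(
            f"window {sorted(window)} is not a prefix of {LETHALITY_ORDER}"
        )
    nonviable = calls.loc[calls["category"].isin(["lethal", "subviable"]), "gene_symbol"]
    denominator = len(nonviable)
    if denominator == 0:
        raise DataError("no mouse non-viable genes; concordance undefined")
    if human_records is None or not len(human_records):
        warnings.warn("no human lethality records; concordance is 0", stacklevel=2)
        return 0.0, 0, denominator
    in_window = human_records.loc[
        human_records["category"].isin(window), "gene_symbol"
    ]
    numerator = int(nonviable.isin(set(in_window)).sum())
    return percent(numerator, denominator), numerator, denominator
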