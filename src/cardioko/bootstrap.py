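"""Empirical bootstrap test for enrichment of nominally significant
parameters within a gene set, per phenotyping procedure.

The pool is the set of genes with at least one parameter measured for the
procedure.  The observed statistic is the fraction of interest genes (within
the pool) that have any parameter with p < alpha.  Each of n_iter iterations
draws the same number of genes from the pool without replacement and
recomputes the fraction; the empirical p-value is the share of iterations
whose fraction is greater than or equal to the observed one.  Counts are
compared as integers (all fractions share one denominator), so ties are
exact and the reported p is always a multiple of 1/n_iter with no +1
correction; a p of 0 is flagged as below the resolution of the test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DataError


@dataclass
class BootstrapResult:
    procedure: str
    n_pool: int
    n_interest: int
    observed_count: int
    observed_proportion: float
    n_iter: int
    empirical_p: float
    null_mean: float
    null_sd: float
    null_quantiles: dict = field(default_factory=dict)
    below_resolution: bool = False
    null_counts: np.ndarray | None = None

    def to_dict(self) -> dict:
        d = {
            "procedure": self.procedure,
            "n_pool": self.n_pool,
            "n_interest": self.n_interest,
            "observed_count": self.observed_count,
            "observed_proportion": self.observed_proportion,
            "n_iter": self.n_iter,
            "empirical_p": self.empirical_p,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "null_quantiles": self.null_quantiles,
            "below_resolution": self.below_resolution,
        }
        return d


def _pool_significance(
    table: pd.DataFrame, procedure: str, alpha: float
) -> pd.Series:
    """Boolean per pool gene: any parameter with p < alpha (strict)."""
    rows = table[table["procedure"] == procedure]
    if not len(rows):
        raise DataError(f"no p-value rows for procedure {procedure!r}")
    return rows.groupby("gene_symbol")["p_value"].apply(lambda s: bool((s < alpha).any()))


def observed_proportion(
    table: pd.DataFrame,
    procedure: str,
    genes_of_interest: Iterable[str],
    alpha: float = 0.05,
) -> float:
    """Fraction of interest genes in the procedure's pool with any p < alpha."""
    sig = _pool_significance(table, procedure, alpha)
    interest = sorted(set(genes_of_interest) & set(sig.index))
    if not interest:
        raise DataError(
            f"no genes of interest have data for procedure {procedure!r}"
        )
    return float(sig.loc[interest].sum() / len(interest))


def bootstrap_enrichment(
    table: pd.DataFrame,
    procedure: str,
    genes_of_interest: Iterable[str],
    n_iter: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
) -> BootstrapResult:
    """Run the resampling test for one procedure; reproducible given seed."""
    if n_iter < 1:
        raise DataError("n_iter must be >= 1")
    if not 0 < alpha < 1:
        raise DataError("alpha must be in (0, 1)")
    sig = _pool_significance(table, procedure, alpha)
    pool = sig.index.to_numpy()
    flags = sig.to_numpy(dtype=bool)
    interest_all = set(genes_of_interest)
    interest = sorted(interest_all & set(pool))
    dropped = len(interest_all) - len(interest)
    if dropped:
        warnings.warn(
            f"{dropped} gene(s) of interest have no {procedure} data and were dropped",
            stacklevel=2,
        )
    m = len(interest)
    if m == 0:
        raise DataError(f"no genes of interest have data for procedure {procedure!r}")
    n_pool = len(pool)
    if m > n_pool:
        raise DataError("sample size exceeds pool size")
    observed_count = int(sig.loc[interest].sum())
    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_iter, dtype=np.int64)
    # vectorised draws without replacement: rank random keys per iteration
    chunk = max(1, min(n_iter, int(4e7 // max(n_pool, 1))))
    done = 0
    while done < n_iter:
        size = min(chunk, n_iter - done)
        keys = rng.random((size, n_pool))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
        null_counts[done : done + size] = flags[idx].sum(axis=1)
        done += size
    empirical_count = int((null_counts >= observed_count).sum())
    empirical_p = empirical_count / n_iter
    below = empirical_count == 0
    if below:
        warnings.warn(
            f"empirical p below resolution (< 1/{n_iter}); reported as 0",
            stacklevel=2,
        )
    null_props = null_counts / m
    quantiles = {
        str(q): float(np.quantile(null_props, q))
        for q in (0.025, 0.25, 0.5, 0.75, 0.975)
    }
    return BootstrapResult(
        procedure=procedure,
        n_pool=n_pool,
        n_interest=m,
        observed_count=observed_count,
        observed_proportion=observed_count / m,
        n_iter=n_iter,
        empirical_p=empirical_p,
        null_mean=float(null_props.mean()),
        null_sd=float(null_props.std(ddof=1)) if n_iter > 1 else 0.0,
        null_quantiles=quantiles,
        below_resolution=below,
        null_counts=null_counts,
    )


def null_histogram(result: BootstrapResult) -> pd.DataFrame:
    """Counts of iterations per null proportion value (for plotting/export)."""
    if result.null_counts is None:
        raise DataError("result carries no null counts")
    values, counts = np.unique(result.null_counts, return_counts=True)
    return pd.DataFrame(
        {
            "proportion": values / result.n_interest,
            "n_iterations": counts,
        }
    )
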