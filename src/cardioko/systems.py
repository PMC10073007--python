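"""Physiological-system rollups and multisystem phenotype profiling.

Phenotype terms are rolled up to a declared set of top-level system terms (a
system is affected iff some annotated term has it in its ancestor closure).
Profiles are compared across species through an explicit human↔mouse system
map (defaulting to identity, which is exact for the synthetic cross-species
ontology where systems are shared bridge terms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .phenodigm import OntologyGraph
from .utils import percent


@dataclass(frozen=True)
class SystemProfile:
    gene_symbol: str
    species: str  # "human" or "mouse"
    systems: frozenset[str]

    @property
    def n_systems(self) -> int:
        return len(self.systems)


def rollup(
    graph: OntologyGraph, term_set: Iterable[str], system_terms: Iterable[str]
) -> frozenset[str]:
    """Top-level systems touched by a set of phenotype terms."""
    system_terms = frozenset(system_terms)
    terms = list(term_set)
    if not terms:
        warnings.warn("empty term set; empty system profile", stacklevel=2)
        return frozenset()
    hit: set[str] = set()
    for t in terms:
        hit |= graph.ancestors(t) & system_terms
    return frozenset(hit)


def profile(
    graph: OntologyGraph,
    gene_symbol: str,
    species: str,
    term_set: Iterable[str],
    system_terms: Iterable[str],
) -> SystemProfile:
    return SystemProfile(gene_symbol, species, rollup(graph, term_set, system_terms))


def shared_systems(
    human_profile: SystemProfile,
    mouse_profile: SystemProfile,
    system_map: Mapping[str, str] | None = None,
) -> frozenset[str]:
    """Systems affected in both species, after mapping mouse systems into the
    human vocabulary.  Unmapped mouse systems are ignored with a warning;
    a None map means name identity."""
    if system_map is None:
        mapped = set(mouse_profile.systems)
    else:
        mapped = set()
        for s in mouse_profile.systems:
            if s in system_map:
                mapped.add(system_map[s])
            else:
                warnings.warn(f"mouse system {s!r} has no human mapping; ignored", stacklevel=2)
    return frozenset(set(human_profile.systems) & mapped)


def multisystem_summary(profiles: Sequence[SystemProfile]) -> dict:
    """Counts/percentages of multisystem (>= 2 systems), single-system and
    no-phenotype genes, plus the median number of systems per gene."""
    if not profiles:
        raise DataError("no system profiles to summarise")
    n = len(profiles)
    n_sys = np.array([p.n_systems for p in profiles])
    multi = int((n_sys >= 2).sum())
    single = int((n_sys == 1).sum())
    none = int((n_sys == 0).sum())
    return {
        "n_genes": n,
        "n_multisystem": multi,
        "pct_multisystem": percent(multi, n),
        "n_single_system": single,
        "pct_single_system": percent(single, n),
        "n_no_phenotype": none,
        "pct_no_phenotype": percent(none, n),
        "median_n_systems": float(np.median(n_sys)),
    }


def coverage_summary(
    lines: Iterable[str], procedures_performed: pd.DataFrame
) -> pd.DataFrame:
    """Percentage of lines with data per procedure (1 dp).

    ``procedures_performed`` holds one row per (gene_symbol, procedure) with
    data; every procedure appearing there is reported.
    """
    lines = sorted(set(lines))
    if not lines:
        raise DataError("no phenotyping lines")
    rows = []
    for proc, group in procedures_performed.groupby("procedure", sort=True):
        covered = set(group["gene_symbol"]) & set(lines)
        rows.append(
            {
                "procedure": proc,
                "n_lines": len(lines),
                "n_with_data": len(covered),
                "percent": percent(len(covered), len(lines)),
            }
        )
    return pd.DataFrame(rows)
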