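"""Hypergeometric over-representation analysis against GMT gene sets.

Given a query gene list (e.g. the mediated genes) and a background universe
(by default every gene tested in the DE stage), each gene set's overlap with
the query is scored with the upper-tail hypergeometric probability
P(X >= k).  Raw p-values are reported (with a BH column for reference) and
records are kept when p <= threshold and the overlap has at least
``min_overlap`` genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom
from sklearn.base import BaseEstimator

from .de import bh_adjust

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "hypergeometric_enrichment",
    "HypergeometricEnrichment",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions, as parsed from a GMT file."""

    sets: dict[str, frozenset] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)
    source: str = ""

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, fields name / description / members.

    Lines with fewer than three tab-separated fields are skipped with a
    warning; duplicate member genes on a line are stored once; a duplicated
    set name is an error.
    """
    path = Path(path)
    sets: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                warnings.warn(f"{path.name}:{lineno}: fewer than 3 fields, line skipped", stacklevel=2)
                continue
            name, desc, *members = fields
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r} in {path}")
            members = frozenset(g for g in members if g)
            if not members:
                warnings.warn(f"{path.name}:{lineno}: set {name!r} has no members, line skipped", stacklevel=2)
                continue
            sets[name] = members
            descriptions[name] = desc
    if not sets:
        raise ValueError(f"no valid gene sets found in {path}")
    return GeneSetCollection(sets=sets, descriptions=descriptions, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def hypergeometric_enrichment(
    query,
    universe,
    sets: GeneSetCollection,
    p_threshold: float = 0.05,
    min_overlap: int = 2,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` within ``universe``.

    For each set: K = |set ∩ universe|, k = |set ∩ query|, and
    p = P(X >= k) for X hypergeometric(N=|universe|, K, n=|query|).  Query
    genes outside the universe are dropped with a warning.  Returns records
    with p <= ``p_threshold`` and k >= ``min_overlap`` sorted by p; the
    ``bh_p`` column is adjusted across all sets tested (before filtering).
    """
    universe = set(universe)
    query = set(query)
    if not universe or not query:
        raise ValueError("query and universe must be nonempty")
    stray = query - universe
    if stray:
        warnings.warn(f"{len(stray)} query gene(s) not in the universe were dropped", stacklevel=2)
        query &= universe
        if not query:
            raise ValueError("no query genes remain inside the universe")
    N, n = len(universe), len(query)

    rows = []
    for name, members in sets.sets.items():
        members_u = members & universe
        K = len(members_u)
        overlap = sorted(members_u & query)
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {
                "set_name": name,
                "description": sets.descriptions.get(name, ""),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": min(max(p, 0.0), 1.0),
                "overlap_genes": ",".join(overlap),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["bh_p"] = bh_adjust(table["p_value"].clip(lower=1e-300))
        table = table[(table["p_value"] <= p_threshold) & (table["k"] >= min_overlap)]
        table = table.sort_values("p_value", kind="stable").reset_index(drop=True)
    return table


class HypergeometricEnrichment(BaseEstimator):
    """Estimator wrapper: ``fit(query, universe=...)`` populates ``results_``."""

    def __init__(self, gene_sets: GeneSetCollection = None, p_threshold: float = 0.05, min_overlap: int = 2):
        self.gene_sets = gene_sets
        self.p_threshold = p_threshold
        self.min_overlap = min_overlap

    def fit(self, X, y=None, universe=None):
        if self.gene_sets is None or universe is None:
            raise ValueError("fit requires gene_sets at construction and a universe")
        self.results_ = hypergeometric_enrichment(
            X, universe, self.gene_sets, self.p_threshold, self.min_overlap
        )
        return self
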