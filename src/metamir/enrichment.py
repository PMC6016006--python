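"""Hypergeometric over-representation analysis against a gene-set collection.

For a list of ``n`` genes drawn from a universe of ``N``, a set of size
``K`` with ``x`` list members has upper-tail p-value ``P(X >= x)`` for
``X ~ Hypergeometric(N, K, n)``.  Raw p < 0.05 marks a set significant;
BH-adjusted p-values are reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import GeneSetCollection
from .meta_de import bh_adjust

__all__ = ["EnrichmentResult", "enrich", "enrichment_profile", "hypergeom_upper_tail"]

SIGNIFICANCE_CUTOFF = 0.05


@dataclass
class EnrichmentResult:
    """Per-set enrichment table, ordered by ascending p.

    Columns: ``set_name``, ``N``, ``set_size``, ``list_size``, ``overlap``,
    ``p``, ``adj_p``, ``significant``, ``overlap_genes`` (semicolon list).
    """

    table: pd.DataFrame

    def p_for(self, set_name: str) -> float:
        row = self.table[self.table["set_name"] == set_name]
        if row.empty:
            raise KeyError(set_name)
        return float(row["p"].iloc[0])

    def significant_sets(self) -> list[str]:
        return self.table.loc[self.table["significant"], "set_name"].tolist()


def hypergeom_upper_tail(N: int, K: int, n: int, x: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N, K, n)."""
    if x <= 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, N, K, n))


def enrich(gene_list: Iterable[str], genesets: GeneSetCollection) -> EnrichmentResult:
    """Test each gene set for over-representation in ``gene_list``.

    Genes outside the collection's universe are dropped with a warning.
    """
    universe = set(genesets.universe)
    if not universe:
        raise ValueError("empty gene universe")
    requested = list(dict.fromkeys(gene_list))
    if not requested:
        raise ValueError("empty gene list")
    genes = [g for g in requested if g in universe]
    dropped = len(requested) - len(genes)
    if dropped:
        warnings.warn(f"{dropped} genes outside the universe dropped", stacklevel=2)
    if not genes:
        raise ValueError("no gene in the list belongs to the universe")

    N = len(universe)
    n = len(genes)
    gene_set = set(genes)
    rows = []
    for name, members in genesets.sets.items():
        K = len(members)
        overlap = sorted(gene_set.intersection(members))
        x = len(overlap)
        p = hypergeom_upper_tail(N, K, n, x)
        rows.append(
            {
                "set_name": name,
                "N": N,
                "set_size": K,
                "list_size": n,
                "overlap": x,
                "p": p,
                "overlap_genes": ";".join(overlap),
            }
        )
    table = pd.DataFrame(rows)
    table["adj_p"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["p"] < SIGNIFICANCE_CUTOFF
    table = table.sort_values(["p", "set_name"], kind="stable").reset_index(drop=True)
    return EnrichmentResult(table=table)


def enrichment_profile(
    gene_lists: Mapping[str, Sequence[str]],
    genesets: GeneSetCollection,
    set_order: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Matrix of per-set p-values, one column per gene list.

    All lists are tested against the same universe; rows follow
    ``set_order`` (defaults to the collection's set order).
    """
    names = list(set_order) if set_order is not None else genesets.names
    columns = {}
    for list_name, genes in gene_lists.items():
        result = enrich(genes, genesets)
        lookup = result.table.set_index("set_name")["p"]
        columns[list_name] = [lookup[name] for name in names]
    return pd.DataFrame(columns, index=pd.Index(names, name="set_name"))
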