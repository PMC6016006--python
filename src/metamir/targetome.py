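"""Cross-source intersection of predicted miRNA targets.

Only records with a 3'-UTR target site contribute.  A miRNA's consensus
target set is the three-way intersection of its per-source gene sets; the
candidate gene set is the union of consensus sets over the selected miRNAs
intersected with the meta-DE gene list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .dataio import TargetRecord

__all__ = ["TargetMap", "CandidateGeneSet", "build_target_map", "candidate_genes", "pairing_table"]


@dataclass
class TargetMap:
    """Per-miRNA, per-source 3'-UTR target sets plus their consensus."""

    sources: list[str]
    per_source: dict[str, dict[str, set[str]]]  # mirna -> source -> genes
    consensus: dict[str, set[str]]  # mirna -> genes in all 3 sources

    def provenance_counts(self, mirna_id: str) -> dict[str, int]:
        """For each gene predicted for ``mirna_id``, in how many sources."""
        counts: dict[str, int] = {}
        for source in self.sources:
            for gene in self.per_source.get(mirna_id, {}).get(source, set()):
                counts[gene] = counts.get(gene, 0) + 1
        return counts


@dataclass
class CandidateGeneSet:
    """Union of consensus targets over selected miRNAs, cut to meta-DE genes."""

    genes: set[str]
    supporting_mirnas: dict[str, list[str]]  # gene -> sorted miRNA ids
    union_targets: set[str]  # union before the meta-DE intersection

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": gene,
                "supporting_mirnas": ";".join(self.supporting_mirnas[gene]),
                "n_supporting": len(self.supporting_mirnas[gene]),
            }
            for gene in sorted(self.genes)
        ]
        return pd.DataFrame(rows, columns=["gene_id", "supporting_mirnas", "n_supporting"])


def build_target_map(
    records: Sequence[TargetRecord],
    mirnas: Optional[Iterable[str]] = None,
) -> TargetMap:
    """Assemble per-source 3'-UTR target sets and their triple intersection.

    Parameters
    ----------
    records
        Target predictions spanning exactly three sources.
    mirnas
        Restrict the map to these miRNAs (default: all observed).  A
        requested miRNA absent from every source yields an empty consensus
        with a warning.
    """
    sources = sorted({r.source for r in records})
    if len(sources) != 3:
        raise ValueError(f"records must span exactly 3 sources, got {sources}")

    wanted = list(dict.fromkeys(mirnas)) if mirnas is not None else None
    per_source: dict[str, dict[str, set[str]]] = {}
    for rec in records:
        if rec.region != "3UTR":
            continue
        if wanted is not None and rec.mirna_id not in wanted:
            continue
        per_source.setdefault(rec.mirna_id, {s: set() for s in sources})
        per_source[rec.mirna_id][rec.source].add(rec.gene_id)

    if wanted is not None:
        for m in wanted:
            if m not in per_source:
                warnings.warn(f"miRNA {m!r} absent from all sources", stacklevel=2)
                per_source[m] = {s: set() for s in sources}

    consensus = {
        mirna: set.intersection(*(by_source[s] for s in sources))
        for mirna, by_source in per_source.items()
    }
    return TargetMap(sources=sources, per_source=per_source, consensus=consensus)


def candidate_genes(
    target_map: TargetMap,
    mirnas: Sequence[str],
    meta_genes: Iterable[str],
) -> CandidateGeneSet:
    """Union of consensus targets over ``mirnas``, intersected with ``meta_genes``."""
    meta = set(meta_genes)
    union: set[str] = set()
    supporting: dict[str, list[str]] = {}
    for mirna in mirnas:
        for gene in target_map.consensus.get(mirna, set()):
            union.add(gene)
            supporting.setdefault(gene, [])
            if mirna not in supporting[gene]:
                supporting[gene].append(mirna)
    genes = union & meta
    return CandidateGeneSet(
        genes=genes,
        supporting_mirnas={g: sorted(supporting[g]) for g in genes},
        union_targets=union,
    )


def pairing_table(candidates: CandidateGeneSet) -> list[tuple[str, str]]:
    """Explicit (miRNA, gene) edge list, miRNA-then-gene lexicographic."""
    pairs = {
        (mirna, gene)
        for gene in candidates.genes
        for mirna in candidates.supporting_mirnas[gene]
    }
    return sorted(pairs)
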