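"""Curated reference tables for structural checks of the miRNA and
target-integration stages.

These are small published-screen-style tables (miRNA ids with p-values and
fold changes, miRNA-gene pairings, a candidate gene list) used as fixed
inputs: the package never re-derives them, it only processes them.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .dataio import TargetRecord
from .mirna_de import MiRNADEResult

__all__ = [
    "MIRNA_SCREEN",
    "PAIRING",
    "CANDIDATE_GENES",
    "GENE_ALIASES",
    "mirna_screen_result",
    "pairing_pairs",
    "pairing_target_records",
    "write_reference_tables",
]

#: miRNA screen table: (mirna_id, mature_id, p, fold_change, sequence)
MIRNA_SCREEN: list[tuple[str, str, float, float, str]] = [
    ("miR-199b-3p", "miR-199b-3p", 3.14e-05, 2.18189, "UAGCACCAUUUGAAAUCGGUUA"),
    ("miR-126-5p", "miR-126-5p", 4.59e-05, 3.01653, "CAGUGGUUUUACCCUAUGGUAG"),
    ("miR-29a", "miR-29a-3p", 0.000180049, 2.01085, "UGAGGUAGUAGAUUGUAUAGUU"),
    ("miR-19b", "miR-19b-3p", 0.0001859, 2.4704, "UAUUGCACAUUACUAAGUUGCA"),
    ("miR-301a", "miR-301a-3p", 0.000211687, 2.47262, "UGAGGUAGUAGUUUGUGCUGUU"),
    ("miR-19a", "miR-19a-3p", 0.000280255, 2.60849, "UGUGCAAAUCUAUGCAAAACUGA"),
    ("miR-142-5p", "miR-142-5p", 0.000282505, 2.14868, "UGUAAACAUCCUUGACUGGAAG"),
    ("miR-101", "miR-101-3p", 0.000402333, 2.63582, "UAAGGUGCAUCUAGUGCAGUUAG"),
    ("miR-30e", "miR-30e-5p", 0.000508645, 2.82353, "UAAGGUGCAUCUAGUGCAGAUAG"),
    ("miR-140-5p", "miR-140-5p", 0.00069842, 2.20528, "UGUAGUGUUUCCUACUUUAUGGA"),
    ("let-7g", "let-7g-5p", 0.000811595, 2.22691, "CAUUAUUACUUUUGGUACGCG"),
    ("miR-142-3p", "miR-142-3p", 0.00086, 2.55601, "UAGCACCAUUUGAAAUCAGUGUU"),
    ("miR-105", "miR-105-5p", 0.000997507, 2.24747, "ACAGUAGUCUGCACAUUGGUUA"),
    ("let-7f", "let-7f-5p", 0.00123097, 2.06713, "UGAGGUAGUAGUUUGUACAGUU"),
    ("miR-32", "miR-32-5p", 0.00138919, 2.43632, "CAUAAAGUAGAAAGCACUACU"),
    ("miR-18b", "miR-18b-5p", 0.0014553, 2.15171, "UAGCUUAUCAGACUGAUGUUGA"),
    ("miR-18a", "miR-18a-5p", 0.00163672, 2.1271, "UCAAAUGCUCAGACUCCUGUGGU"),
    ("let-7i", "let-7i-5p", 0.00175562, 2.10813, "UACAGUACUGUGAUAACUGAA"),
    ("miR-21", "miR-21-5p", 0.00226262, 2.47414, "UGUGCAAAUCCAUGCAAAACUGA"),
]

#: reference miRNA -> gene pairings (mature ids)
PAIRING: dict[str, list[str]] = {
    "miR-126-5p": ["MTCH2", "VAPA", "SNCA", "NDUFS1"],
    "miR-29a-3p": ["CDC42", "TIMM8B", "SUB1"],
    "miR-19b-3p": ["MAPK8", "USP13", "KPNA6"],
}

#: candidate genes shared by the targetome union and the meta-DE list
CANDIDATE_GENES: frozenset[str] = frozenset(
    {
        "NDUFS1",
        "MAPK8",
        "CDC42",
        "SNCA",
        "VAPA",
        "USP13",
        "TIMM8B",
        "KIF3A",
        "KPNA6",
        "MTCH2",
        "SUB1",
    }
)

#: alternative spellings observed in the wild
GENE_ALIASES: dict[str, str] = {"VAVP": "VAPA"}

#: genes carried by the remaining candidate-list members without a pairing row
_EXTRA_CONSENSUS: dict[str, list[str]] = {
    "miR-199b-3p": ["SNCA", "KIF3A"],
    "miR-301a-3p": ["KIF3A"],
}

_SOURCES = ("alpha", "beta", "gamma")


def mirna_screen_result() -> MiRNADEResult:
    """The reference miRNA screen wrapped for top-k selection."""
    return MiRNADEResult.from_screen_table(
        mirna_ids=[row[0] for row in MIRNA_SCREEN],
        p=[row[2] for row in MIRNA_SCREEN],
        fold_change=[row[3] for row in MIRNA_SCREEN],
    )


def pairing_pairs() -> list[tuple[str, str]]:
    """The reference (miRNA, gene) edge list, deterministically ordered."""
    return sorted((m, g) for m, genes in PAIRING.items() for g in genes)


def pairing_target_records(include_extra: bool = True) -> list[TargetRecord]:
    """Three-source target records whose 3'-UTR consensus reproduces the
    reference pairings (plus the extra consensus rows completing the
    candidate gene list when ``include_extra``)."""
    mapping = dict(PAIRING)
    if include_extra:
        mapping = {**mapping, **_EXTRA_CONSENSUS}
    records = []
    for source in _SOURCES:
        for mirna, genes in mapping.items():
            for gene in genes:
                records.append(
                    TargetRecord(source=source, mirna_id=mirna, gene_id=gene, region="3UTR")
                )
    return records


def write_reference_tables(outdir) -> None:
    outdir = Path(outdir)
    screen = pd.DataFrame(
        MIRNA_SCREEN, columns=["mirna_id", "mature_id", "p", "fold_change", "sequence"]
    )
    screen.to_csv(outdir / "reference_mirna_screen.tsv", sep="\t", index=False, lineterminator="\n")
    pairs = pd.DataFrame(pairing_pairs(), columns=["mirna_id", "gene_id"])
    pairs.to_csv(outdir / "reference_pairing.tsv", sep="\t", index=False, lineterminator="\n")
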