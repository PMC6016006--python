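"""Synthetic multi-study expression data with planted, known ground truth.

Generative model for study ``k``, sample ``j``, gene ``g``::

    x_gjk = mu_g + a_gk + z_j * delta_g * s_g + eps_gjk

with ``mu_g ~ N(baseline_mean, baseline_sd^2)`` shared across studies,
``a_gk ~ N(0, study_batch_sd^2)`` a per-gene per-study batch offset,
``z_j = 1`` for cases and 0 for controls, ``s_g = -1`` for planted DE genes
(downregulation by default) and ``eps ~ N(0, sigma_g^2)`` with a gene-specific
noise sd.  An optional corrupted study is regenerated with no shared
structure, giving quality control an unambiguous target.

Everything is deterministic under ``SimParams.seed``; the mRNA, miRNA,
target-source, gene-set and interaction generators draw from independent
seed-derived streams so they can be called in any combination.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .dataio import (
    ExpressionStudy,
    GeneSetCollection,
    PPIEdge,
    StudyCollection,
    TargetRecord,
    write_expression,
    write_genesets,
    write_ppi,
    write_targets,
)

__all__ = [
    "SimParams",
    "TruthTable",
    "simulate_studies",
    "simulate_mirna_study",
    "simulate_target_sources",
    "simulate_genesets",
    "simulate_ppi",
    "write_fixture_bundle",
]

SOURCE_NAMES = ("alpha", "beta", "gamma")


@dataclass
class SimParams:
    """All knobs of the synthetic-data generators."""

    n_studies: int = 5
    genes_per_study: int = 2000
    n_cases: int = 8
    n_controls: int = 8
    de_fraction: float = 0.05
    effect_size_range: tuple[float, float] = (0.8, 1.2)
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    study_batch_sd: float = 0.3
    gene_noise_sd_range: tuple[float, float] = (0.2, 0.6)
    corrupt_study: Optional[int] = None
    dropout_fraction: float = 0.0
    sign_mode: str = "down"  # "down" (all planted effects negative) or "both"

    n_mirna: int = 150
    mirna_de_count: int = 5
    mirna_fc_min: float = 4.0
    mirna_n_cases: int = 19
    mirna_n_controls: int = 13
    mirna_noise_sd: float = 0.5

    targets_per_mirna: int = 8
    source_retention: tuple[float, float, float] = (0.9, 0.9, 0.9)
    decoys_per_source: int = 30

    n_genesets: int = 30
    geneset_size_range: tuple[int, int] = (20, 80)
    signal_ratio: float = 0.5

    ppi_de_density: float = 0.2
    ppi_background_edges: int = 200

    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_studies",
            "genes_per_study",
            "n_cases",
            "n_controls",
            "n_mirna",
            "mirna_n_cases",
            "mirna_n_controls",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.de_fraction > 0 and self.de_fraction * self.genes_per_study < 1:
            raise ValueError("de_fraction * genes_per_study must be >= 1 when positive")
        lo, hi = self.effect_size_range
        if lo > hi:
            raise ValueError("effect_size_range must satisfy lo <= hi")
        lo, hi = self.gene_noise_sd_range
        if lo > hi or lo <= 0:
            raise ValueError("gene_noise_sd_range must be positive with lo <= hi")
        if len(self.source_retention) != 3:
            raise ValueError("source_retention needs exactly 3 probabilities")
        for r in self.source_retention:
            if not 0.0 < r <= 1.0:
                raise ValueError("retention probabilities must lie in (0, 1]")
        if self.mirna_de_count > self.n_mirna:
            raise ValueError("mirna_de_count cannot exceed n_mirna")
        if self.mirna_fc_min <= 1.0:
            raise ValueError("mirna_fc_min must exceed 1 (linear fold change)")
        if self.corrupt_study is not None and not 0 <= self.corrupt_study < self.n_studies:
            raise ValueError("corrupt_study index out of range")
        if not 0.0 <= self.dropout_fraction < 1.0:
            raise ValueError("dropout_fraction must lie in [0, 1)")
        if self.sign_mode not in ("down", "both"):
            raise ValueError("sign_mode must be 'down' or 'both'")


@dataclass
class TruthTable:
    """Ground truth planted by the generators."""

    de_gene_ids: set[str] = field(default_factory=set)
    delta: dict[str, float] = field(default_factory=dict)  # signed log2 effect
    de_mirna_ids: set[str] = field(default_factory=set)
    true_target_pairs: set[tuple[str, str]] = field(default_factory=set)
    corrupted_study_id: Optional[str] = None
    gene_universe: list[str] = field(default_factory=list)
    mirna_universe: list[str] = field(default_factory=list)


def _rng(params: SimParams, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([params.seed, *stream]))


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _mirna_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"mir-{i:0{width}d}" for i in range(1, n + 1)]


def simulate_studies(params: SimParams) -> tuple[StudyCollection, TruthTable]:
    """Generate K concordant studies over a shared gene universe.

    Returns the collection together with a truth table recording the DE
    genes, their signed log2 effects and the corrupted study (if any).
    """
    rng = _rng(params, 0)
    G, K = params.genes_per_study, params.n_studies
    genes = _gene_ids(G)

    mu = rng.normal(params.baseline_mean, params.baseline_sd, size=G)
    sigma = rng.uniform(*params.gene_noise_sd_range, size=G)

    n_de = int(round(params.de_fraction * G))
    de_idx = np.sort(rng.choice(G, size=n_de, replace=False)) if n_de else np.array([], dtype=int)
    magnitude = rng.uniform(*params.effect_size_range, size=n_de)
    if params.sign_mode == "down":
        sign = -np.ones(n_de)
    else:
        sign = rng.choice([-1.0, 1.0], size=n_de)
    delta_signed = np.zeros(G)
    delta_signed[de_idx] = magnitude * sign

    truth = TruthTable(
        de_gene_ids={genes[i] for i in de_idx},
        delta={genes[i]: float(delta_signed[i]) for i in de_idx},
        gene_universe=list(genes),
    )

    studies = []
    for k in range(K):
        sid = f"study{k + 1}"
        n1, n2 = params.n_cases, params.n_controls
        z = np.r_[np.ones(n1), np.zeros(n2)]
        sample_ids = [f"{sid}_case{i + 1}" for i in range(n1)] + [
            f"{sid}_ctrl{i + 1}" for i in range(n2)
        ]
        group = ["case"] * n1 + ["control"] * n2

        if params.corrupt_study == k:
            # label-independent regeneration: nothing shared with mu/delta
            mu_bad = rng.normal(params.baseline_mean, params.baseline_sd, size=G)
            sigma_bad = rng.uniform(*params.gene_noise_sd_range, size=G)
            matrix = mu_bad[:, None] + rng.normal(0.0, 1.0, size=(G, n1 + n2)) * sigma_bad[:, None]
            truth.corrupted_study_id = sid
        else:
            batch = rng.normal(0.0, params.study_batch_sd, size=G)
            eps = rng.normal(0.0, 1.0, size=(G, n1 + n2)) * sigma[:, None]
            matrix = mu[:, None] + batch[:, None] + delta_signed[:, None] * z[None, :] + eps

        study_genes = list(genes)
        if params.dropout_fraction > 0:
            keep = rng.random(G) >= params.dropout_fraction
            matrix = matrix[keep, :]
            study_genes = [g for g, kflag in zip(genes, keep) if kflag]

        studies.append(
            ExpressionStudy(
                study_id=sid,
                matrix=matrix,
                gene_ids=study_genes,
                sample_ids=sample_ids,
                group=group,
            )
        )
    return StudyCollection(studies), truth


def simulate_mirna_study(
    params: SimParams, truth: Optional[TruthTable] = None
) -> tuple[ExpressionStudy, TruthTable]:
    """Generate a two-group miRNA study with planted fold changes.

    Planted miRNAs carry a population log2 case-control difference of
    ``-log2(mirna_fc_min)`` (downregulated).  When a truth table from
    :func:`simulate_studies` is supplied, true target pairs are drawn from
    its planted DE genes; otherwise a fresh gene universe is invented.
    """
    rng = _rng(params, 1)
    truth = truth if truth is not None else TruthTable()
    M = params.n_mirna
    mirnas = _mirna_ids(M)
    n1, n2 = params.mirna_n_cases, params.mirna_n_controls

    baseline = rng.normal(5.0, 1.0, size=M)
    de_idx = rng.choice(M, size=params.mirna_de_count, replace=False) if params.mirna_de_count else np.array([], dtype=int)
    effect = np.zeros(M)
    effect[de_idx] = -np.log2(params.mirna_fc_min)

    z = np.r_[np.ones(n1), np.zeros(n2)]
    matrix = (
        baseline[:, None]
        + effect[:, None] * z[None, :]
        + rng.normal(0.0, params.mirna_noise_sd, size=(M, n1 + n2))
    )
    sample_ids = [f"pb_case{i + 1}" for i in range(n1)] + [f"pb_ctrl{i + 1}" for i in range(n2)]
    study = ExpressionStudy(
        study_id="mirna_study",
        matrix=matrix,
        gene_ids=mirnas,
        sample_ids=sample_ids,
        group=["case"] * n1 + ["control"] * n2,
    )

    truth.de_mirna_ids = {mirnas[i] for i in de_idx}
    truth.mirna_universe = list(mirnas)

    target_pool = sorted(truth.de_gene_ids) if truth.de_gene_ids else _gene_ids(
        max(params.targets_per_mirna * max(params.mirna_de_count, 1) * 2, 50)
    )
    if not truth.gene_universe:
        truth.gene_universe = list(target_pool)
    pairs: set[tuple[str, str]] = set()
    for i in sorted(de_idx):
        n_targets = min(params.targets_per_mirna, len(target_pool))
        chosen = rng.choice(len(target_pool), size=n_targets, replace=False)
        for c in chosen:
            pairs.add((mirnas[i], target_pool[c]))
    truth.true_target_pairs = pairs
    return study, truth


def simulate_target_sources(
    params: SimParams, truth: TruthTable
) -> list[TargetRecord]:
    """Emit three target-prediction sources from the true pairs.

    Each true pair is reported by source ``s`` with probability
    ``source_retention[s]`` (always region 3UTR); each source additionally
    reports ``decoys_per_source`` random decoy pairs with random regions.
    """
    rng = _rng(params, 2)
    if not truth.true_target_pairs:
        raise ValueError("truth table has no true target pairs")
    mirna_pool = truth.mirna_universe or sorted({m for m, _ in truth.true_target_pairs})
    gene_pool = truth.gene_universe or sorted({g for _, g in truth.true_target_pairs})

    records: list[TargetRecord] = []
    true_pairs = sorted(truth.true_target_pairs)
    for source, retention in zip(SOURCE_NAMES, params.source_retention):
        for mirna, gene in true_pairs:
            if rng.random() <= retention:
                records.append(
                    TargetRecord(
                        source=source,
                        mirna_id=mirna,
                        gene_id=gene,
                        region="3UTR",
                        score=float(rng.uniform(0.5, 1.0)),
                    )
                )
        for _ in range(params.decoys_per_source):
            mirna = mirna_pool[rng.integers(len(mirna_pool))]
            gene = gene_pool[rng.integers(len(gene_pool))]
            if (mirna, gene) in truth.true_target_pairs:
                continue
            region = ("3UTR", "CDS", "5UTR")[rng.integers(3)]
            records.append(
                TargetRecord(
                    source=source,
                    mirna_id=mirna,
                    gene_id=gene,
                    region=region,
                    score=float(rng.uniform(0.0, 1.0)),
                )
            )
    return records


def simulate_genesets(params: SimParams, truth: TruthTable) -> GeneSetCollection:
    """Random gene sets plus one signal set enriched for the planted DE genes.

    The signal set draws a ``signal_ratio`` fraction of its members from the
    DE genes (all of them when the set would otherwise exhaust the list).
    """
    rng = _rng(params, 3)
    universe = list(truth.gene_universe)
    if not universe:
        raise ValueError("truth table has an empty gene universe")
    lo, hi = params.geneset_size_range
    if hi > len(universe):
        raise ValueError("geneset size range exceeds the universe")

    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}

    de = sorted(truth.de_gene_ids)
    non_de = [g for g in universe if g not in truth.de_gene_ids]
    if de:
        size = min(len(universe), max(lo, 2 * len(de)))
        n_signal = min(len(de), int(round(params.signal_ratio * size)))
        members = list(rng.choice(de, size=n_signal, replace=False))
        members += list(rng.choice(non_de, size=size - n_signal, replace=False))
        sets["signal_set"] = members
        descriptions["signal_set"] = "planted-signal gene set"

    for i in range(params.n_genesets - len(sets)):
        size = int(rng.integers(lo, hi + 1))
        members = list(rng.choice(universe, size=size, replace=False))
        sets[f"random_set_{i + 1:03d}"] = members
        descriptions[f"random_set_{i + 1:03d}"] = "random gene set"

    return GeneSetCollection(sets=sets, universe=universe, descriptions=descriptions)


def simulate_ppi(params: SimParams, truth: TruthTable) -> list[PPIEdge]:
    """Scored gene-gene interactions: a dense module on the planted DE genes
    plus random background edges over the universe."""
    rng = _rng(params, 4)
    universe = list(truth.gene_universe)
    if len(universe) < 2:
        raise ValueError("gene universe too small for interactions")
    edges: dict[tuple[str, str], float] = {}

    de = sorted(truth.de_gene_ids)
    for i in range(len(de)):
        for j in range(i + 1, len(de)):
            if rng.random() < params.ppi_de_density:
                edges[(de[i], de[j])] = float(rng.uniform(0.4, 1.0))

    n_bg = 0
    while n_bg < params.ppi_background_edges:
        a, b = rng.choice(len(universe), size=2, replace=False)
        key = tuple(sorted((universe[a], universe[b])))
        if key in edges:
            continue
        edges[key] = float(rng.uniform(0.0, 1.0))
        n_bg += 1

    return [PPIEdge(a, b, s) for (a, b), s in sorted(edges.items())]


def write_fixture_bundle(outdir, params: Optional[SimParams] = None) -> dict:
    """Generate every synthetic input and write it in the external formats.

    Also writes the curated reference tables (miRNA screen and miRNA-gene
    pairing fixtures) and a manifest JSON recording the seed and file list.
    Returns the manifest.
    """
    from . import fixtures

    params = params or SimParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    collection, truth = simulate_studies(params)
    mirna_study, truth = simulate_mirna_study(params, truth)
    targets = simulate_target_sources(params, truth)
    genesets = simulate_genesets(params, truth)
    ppi = simulate_ppi(params, truth)

    files: dict[str, str] = {}

    ann_rows = []
    for study in collection:
        path = outdir / f"expression_{study.study_id}.tsv"
        write_expression(study, path)
        files[f"expression_{study.study_id}"] = path.name
        ann_rows.extend(
            f"{s}\t{g}\t{study.study_id}" for s, g in zip(study.sample_ids, study.group)
        )
    ann_path = outdir / "annotation.tsv"
    ann_path.write_text(
        "sample_id\tgroup\tstudy_id\n" + "\n".join(ann_rows) + "\n", encoding="utf-8"
    )
    files["annotation"] = ann_path.name

    write_expression(
        mirna_study, outdir / "mirna_expression.tsv", outdir / "mirna_annotation.tsv"
    )
    files["mirna_expression"] = "mirna_expression.tsv"
    files["mirna_annotation"] = "mirna_annotation.tsv"

    for source in SOURCE_NAMES:
        recs = [r for r in targets if r.source == source]
        path = outdir / f"targets_{source}.tsv"
        write_targets(recs, path)
        files[f"targets_{source}"] = path.name

    write_genesets(genesets, outdir / "genesets.gmt")
    files["genesets"] = "genesets.gmt"
    write_ppi(ppi, outdir / "ppi.tsv")
    files["ppi"] = "ppi.tsv"

    fixtures.write_reference_tables(outdir)
    files["reference_mirna_screen"] = "reference_mirna_screen.tsv"
    files["reference_pairing"] = "reference_pairing.tsv"

    truth_path = outdir / "truth.json"
    truth_path.write_text(
        json.dumps(
            {
                "de_gene_ids": sorted(truth.de_gene_ids),
                "delta": {g: truth.delta[g] for g in sorted(truth.delta)},
                "de_mirna_ids": sorted(truth.de_mirna_ids),
                "true_target_pairs": sorted(list(p) for p in truth.true_target_pairs),
                "corrupted_study_id": truth.corrupted_study_id,
            },
            indent=2,
        )
        + "\n",
        encoding="utf-8",
    )
    files["truth"] = truth_path.name

    manifest = {"seed": params.seed, "files": files}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return manifest
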