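"""Readers and writers for every on-disk artifact.

Formats (all tab-delimited, UTF-8):

* Expression matrix: first column ``gene_id``, remaining columns are sample ids.
* Sample annotation: columns ``sample_id``, ``group`` (``case``/``control``),
  ``study_id``.
* Gene sets: standard GMT (name, description, members...).
* Scored gene-gene interactions: ``gene_a``, ``gene_b``, ``combined_score``
  on a 0-1 scale.
* miRNA target predictions: ``mirna_id``, ``gene_id``, ``region``
  (``3UTR``/``CDS``/``5UTR``), optional ``score``.

Expression values are assumed to be on the log2 scale; pass ``linear=True``
to :func:`read_expression` to apply ``log2(x + 1)`` on load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionStudy",
    "StudyCollection",
    "GeneSetCollection",
    "TargetRecord",
    "PPIEdge",
    "read_expression",
    "write_expression",
    "read_genesets",
    "write_genesets",
    "read_targets",
    "write_targets",
    "read_ppi",
    "write_ppi",
    "write_results",
]

GROUP_LABELS = ("case", "control")
REGION_VOCAB = ("3UTR", "CDS", "5UTR")

#: normalization map for region tokens (case-insensitive, punctuation-tolerant)
_REGION_ALIASES = {
    "3utr": "3UTR",
    "3'utr": "3UTR",
    "3-utr": "3UTR",
    "utr3": "3UTR",
    "cds": "CDS",
    "5utr": "5UTR",
    "5'utr": "5UTR",
    "5-utr": "5UTR",
    "utr5": "5UTR",
}


class DataIOError(ValueError):
    """Raised on malformed or inconsistent input files."""


def normalize_region(token: str) -> str:
    """Map a free-form region token onto the closed vocabulary."""
    key = str(token).strip().lower().replace("′", "'")
    if key in _REGION_ALIASES:
        return _REGION_ALIASES[key]
    raise DataIOError(f"unknown target region token: {token!r}")


@dataclass
class ExpressionStudy:
    """One study's log2 genes x samples matrix plus per-sample group labels."""

    study_id: str
    matrix: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    group: list[str]
    platform_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.group = [str(g) for g in self.group]
        if self.matrix.ndim != 2:
            raise DataIOError("expression matrix must be 2-dimensional")
        if self.matrix.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataIOError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataIOError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataIOError("duplicate sample ids")
        if len(self.group) != len(self.sample_ids):
            raise DataIOError("every sample needs a group label")
        bad = sorted(set(self.group) - set(GROUP_LABELS))
        if bad:
            raise DataIOError(f"unknown group labels: {bad}")
        for label in GROUP_LABELS:
            if self.group.count(label) < 2:
                raise DataIOError(
                    f"study {self.study_id}: need >= 2 samples per group, "
                    f"got {self.group.count(label)} {label!r}"
                )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def group_mask(self, label: str) -> np.ndarray:
        return np.asarray([g == label for g in self.group], dtype=bool)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionStudy":
        """Return a copy restricted to ``genes`` in the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise DataIOError(f"genes absent from study {self.study_id}: {missing[:5]}")
        rows = [index[g] for g in genes]
        return ExpressionStudy(
            study_id=self.study_id,
            matrix=self.matrix[rows, :].copy(),
            gene_ids=list(genes),
            sample_ids=list(self.sample_ids),
            group=list(self.group),
            platform_id=self.platform_id,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class StudyCollection:
    """Ordered list of studies sharing (part of) a gene universe."""

    studies: list[ExpressionStudy]

    def __post_init__(self) -> None:
        ids = [s.study_id for s in self.studies]
        if len(set(ids)) != len(ids):
            raise DataIOError("duplicate study ids in collection")

    @property
    def K(self) -> int:
        return len(self.studies)

    @property
    def common_genes(self) -> list[str]:
        """Genes present in every study, in first-study order."""
        if not self.studies:
            return []
        shared = set(self.studies[0].gene_ids)
        for s in self.studies[1:]:
            shared &= set(s.gene_ids)
        return [g for g in self.studies[0].gene_ids if g in shared]

    def study_ids(self) -> list[str]:
        return [s.study_id for s in self.studies]

    def __iter__(self):
        return iter(self.studies)

    def __getitem__(self, i: int) -> ExpressionStudy:
        return self.studies[i]

    def restrict_to_common(self) -> "StudyCollection":
        genes = self.common_genes
        if not genes:
            raise DataIOError("no genes shared by all studies")
        return StudyCollection([s.subset_genes(genes) for s in self.studies])


@dataclass
class GeneSetCollection:
    """Named gene sets over a declared universe."""

    sets: dict[str, list[str]]
    universe: list[str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.universe = [str(g) for g in self.universe]
        uni = set(self.universe)
        for name, members in self.sets.items():
            self.sets[name] = [m for m in dict.fromkeys(members)]
        if uni:
            for name, members in self.sets.items():
                extra = [m for m in members if m not in uni]
                if extra:
                    self.sets[name] = [m for m in members if m in uni]

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class TargetRecord:
    """One predicted miRNA -> gene interaction from one source."""

    source: str
    mirna_id: str
    gene_id: str
    region: str
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.region not in REGION_VOCAB:
            raise DataIOError(f"region {self.region!r} not in {REGION_VOCAB}")


@dataclass(frozen=True)
class PPIEdge:
    """Undirected scored gene-gene interaction, stored in canonical order."""

    gene_a: str
    gene_b: str
    combined_score: float

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise DataIOError(f"self-interaction not allowed: {self.gene_a}")
        if not 0.0 <= self.combined_score <= 1.0:
            raise DataIOError(f"combined_score out of [0,1]: {self.combined_score}")
        if self.gene_a > self.gene_b:
            a, b = self.gene_b, self.gene_a
            object.__setattr__(self, "gene_a", a)
            object.__setattr__(self, "gene_b", b)


# ---------------------------------------------------------------------------
# expression


def read_expression(
    matrix_path,
    annotation_path,
    *,
    study_id: Optional[str] = None,
    linear: bool = False,
    collapse: str = "max_mean",
) -> ExpressionStudy:
    """Read an expression matrix and its sample annotation into a study.

    Parameters
    ----------
    matrix_path, annotation_path
        TSV files in the formats documented in the module docstring.
    study_id
        Override the ``study_id`` column of the annotation; required when the
        annotation covers several studies.
    linear
        If true, values are linear-scale and are transformed to
        ``log2(x + 1)`` on load.
    collapse
        Rule for duplicate gene rows: ``max_mean`` keeps the row with the
        highest mean expression (default), ``mean`` averages duplicates.
    """
    mat = pd.read_csv(matrix_path, sep="\t", dtype={0: str}, float_precision="round_trip")
    if mat.columns[0] != "gene_id":
        raise DataIOError("expression matrix must start with a 'gene_id' column")
    ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in ann.columns:
            raise DataIOError(f"annotation missing column {col!r}")
    if ann["sample_id"].duplicated().any():
        raise DataIOError("duplicate sample id in annotation")
    if study_id is None:
        sids = ann["study_id"].unique() if "study_id" in ann.columns else ["study"]
        if len(sids) != 1:
            raise DataIOError("annotation covers several studies; pass study_id")
        study_id = str(sids[0])
    elif "study_id" in ann.columns:
        ann = ann[ann["study_id"] == study_id]

    sample_ids = [str(c) for c in mat.columns[1:]]
    ann = ann.set_index("sample_id")
    missing = [s for s in sample_ids if s not in ann.index]
    if missing:
        raise DataIOError(f"annotation missing samples: {missing}")
    groups = [str(ann.loc[s, "group"]) for s in sample_ids]

    values = mat.iloc[:, 1:].to_numpy(dtype=float)
    if linear:
        values = np.log2(values + 1.0)
    genes = mat["gene_id"].astype(str).tolist()

    if len(set(genes)) != len(genes):
        frame = pd.DataFrame(values, index=genes)
        if collapse == "max_mean":
            means = frame.mean(axis=1)
            order = np.argsort(-means.to_numpy(), kind="stable")
            frame = frame.iloc[order]
            frame = frame[~frame.index.duplicated(keep="first")]
            keep = [g for g in dict.fromkeys(genes)]
            frame = frame.loc[keep]
        elif collapse == "mean":
            frame = frame.groupby(level=0, sort=False).mean()
        else:
            raise DataIOError(f"unknown collapse rule {collapse!r}")
        genes = frame.index.tolist()
        values = frame.to_numpy()

    return ExpressionStudy(
        study_id=study_id,
        matrix=values,
        gene_ids=genes,
        sample_ids=sample_ids,
        group=groups,
    )


def write_expression(study: ExpressionStudy, matrix_path, annotation_path=None) -> None:
    frame = study.to_frame()
    frame.index.name = "gene_id"
    # repr gives the shortest exact decimal, so write->read round-trips bitwise
    frame.to_csv(
        matrix_path, sep="\t", lineterminator="\n", float_format=lambda v: repr(float(v))
    )
    if annotation_path is not None:
        ann = pd.DataFrame(
            {
                "sample_id": study.sample_ids,
                "group": study.group,
                "study_id": study.study_id,
            }
        )
        ann.to_csv(annotation_path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# gene sets


def read_genesets(gmt_path, universe: Optional[Iterable[str]] = None) -> GeneSetCollection:
    """Read a GMT file: one set per line as name, description, members..."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    members_seen: set[str] = set()
    with open(gmt_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataIOError(f"GMT line {lineno}: no members")
            name, desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise DataIOError(f"GMT line {lineno}: no members")
            if name in sets:
                raise DataIOError(f"duplicate set name {name!r}")
            sets[name] = list(dict.fromkeys(members))
            descriptions[name] = desc
            members_seen.update(sets[name])
    uni = list(universe) if universe is not None else sorted(members_seen)
    return GeneSetCollection(sets=sets, universe=uni, descriptions=descriptions)


def write_genesets(collection: GeneSetCollection, gmt_path) -> None:
    with open(gmt_path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# targets


def read_targets(
    paths_by_source: Mapping[str, object], *, assume_3utr: bool = False
) -> list[TargetRecord]:
    """Read target-prediction tables, one TSV per source.

    Exactly three sources are required; records are tagged with their source
    name and region tokens are normalized to the closed vocabulary.  Rows
    with an empty region are dropped with a warning, or treated as 3UTR when
    ``assume_3utr`` is set.
    """
    if len(paths_by_source) != 3:
        raise DataIOError(
            f"exactly 3 target sources required, got {len(paths_by_source)}"
        )
    records: list[TargetRecord] = []
    n_dropped = 0
    for source, path in paths_by_source.items():
        table = pd.read_csv(path, sep="\t", dtype={"mirna_id": str, "gene_id": str})
        for col in ("mirna_id", "gene_id", "region"):
            if col not in table.columns:
                raise DataIOError(f"target table {path}: missing column {col!r}")
        has_score = "score" in table.columns
        for row in table.itertuples(index=False):
            score = float(row.score) if has_score and pd.notna(row.score) else None
            if pd.isna(row.region) or str(row.region).strip() == "":
                if assume_3utr:
                    region = "3UTR"
                else:
                    n_dropped += 1
                    continue
            else:
                region = normalize_region(row.region)
            records.append(
                TargetRecord(
                    source=str(source),
                    mirna_id=str(row.mirna_id),
                    gene_id=str(row.gene_id),
                    region=region,
                    score=score,
                )
            )
    if n_dropped:
        warnings.warn(f"{n_dropped} target rows without a region dropped", stacklevel=2)
    return records


def write_targets(records: Sequence[TargetRecord], path) -> None:
    frame = pd.DataFrame(
        {
            "mirna_id": [r.mirna_id for r in records],
            "gene_id": [r.gene_id for r in records],
            "region": [r.region for r in records],
            "score": [r.score if r.score is not None else "" for r in records],
        }
    )
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# scored gene-gene interactions


def read_ppi(path) -> list[PPIEdge]:
    table = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    for col in ("gene_a", "gene_b", "combined_score"):
        if col not in table.columns:
            raise DataIOError(f"interaction table missing column {col!r}")
    return [
        PPIEdge(str(r.gene_a), str(r.gene_b), float(r.combined_score))
        for r in table.itertuples(index=False)
    ]


def write_ppi(edges: Sequence[PPIEdge], path) -> None:
    frame = pd.DataFrame(
        {
            "gene_a": [e.gene_a for e in edges],
            "gene_b": [e.gene_b for e in edges],
            "combined_score": [e.combined_score for e in edges],
        }
    )
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# results


def write_results(tables: Mapping[str, pd.DataFrame], network, outdir) -> dict:
    """Write result tables (TSV) and, optionally, a network (GraphML + SIF).

    Returns a manifest mapping logical names to written file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for name, table in tables.items():
        path = outdir / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False, lineterminator="\n")
        manifest[name] = str(path)
    if network is not None:
        from . import network as _network

        paths = _network.export(network, outdir)
        manifest.update(paths)
    return manifest
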