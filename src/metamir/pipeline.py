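"""End-to-end orchestration: QC -> meta-DE -> enrichment -> miRNA-DE ->
targetome -> network, with a machine-readable run report.

A run is driven by a :class:`RunConfig` (loadable from YAML or JSON).  Each
stage writes its tables into the output directory; a final ``report.json``
records the seed, per-stage counts and the file manifest (paths relative to
the output directory, so identical runs are byte-identical).
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import dataio, enrichment, meta_de, mirna_de, network, study_qc, targetome

logger = logging.getLogger("metamir")

__all__ = ["RunConfig", "PipelineError", "ValidationError", "run_all"]


class ValidationError(ValueError):
    """Configuration or input validation failed (exit code 2)."""


class PipelineError(RuntimeError):
    """A stage failed mid-run (exit code 3)."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths plus per-stage options for a full pipeline run."""

    expression: list[dict]  # [{"matrix": ..., "study_id": ...}, ...]
    annotation: str
    mirna_matrix: str
    mirna_annotation: str
    genesets: str
    ppi: str
    targets: dict[str, str]  # source name -> path (exactly 3)
    outdir: str = "results"
    seed: int = 0
    quantile_normalize: bool = False
    run_qc: bool = True
    score_min: float = network.DEFAULT_SCORE_MIN
    hub_count: int = network.DEFAULT_HUB_COUNT
    meta: meta_de.MetaDEConfig = field(default_factory=meta_de.MetaDEConfig)
    qc: study_qc.QCConfig = field(default_factory=study_qc.QCConfig)
    mirna: mirna_de.MiRNAFilterConfig = field(default_factory=mirna_de.MiRNAFilterConfig)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        return cls.from_dict(raw, base=path.parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Optional[Path] = None) -> "RunConfig":
        raw = dict(raw)

        def resolve(p):
            p = Path(p)
            return str(p if p.is_absolute() or base is None else base / p)

        expression = [
            {"matrix": resolve(e["matrix"]), "study_id": e.get("study_id")}
            for e in raw.pop("expression")
        ]
        targets = {k: resolve(v) for k, v in raw.pop("targets").items()}
        sub = {}
        for name, cls_ in (("meta", meta_de.MetaDEConfig), ("qc", study_qc.QCConfig), ("mirna", mirna_de.MiRNAFilterConfig)):
            sub[name] = cls_(**raw.pop(name, {}))
        for key in ("annotation", "mirna_matrix", "mirna_annotation", "genesets", "ppi"):
            raw[key] = resolve(raw[key])
        return cls(expression=expression, targets=targets, **sub, **raw)

    @classmethod
    def from_bundle(cls, bundle_dir, outdir="results", seed: int = 0, **overrides) -> "RunConfig":
        """Build a config pointing at a :func:`synthetic.write_fixture_bundle` dir."""
        bundle_dir = Path(bundle_dir)
        manifest = json.loads((bundle_dir / "manifest.json").read_text(encoding="utf-8"))
        files = manifest["files"]
        expression = [
            {"matrix": str(bundle_dir / v), "study_id": k.removeprefix("expression_")}
            for k, v in sorted(files.items())
            if k.startswith("expression_")
        ]
        targets = {
            k.removeprefix("targets_"): str(bundle_dir / v)
            for k, v in sorted(files.items())
            if k.startswith("targets_")
        }
        return cls(
            expression=expression,
            annotation=str(bundle_dir / files["annotation"]),
            mirna_matrix=str(bundle_dir / files["mirna_expression"]),
            mirna_annotation=str(bundle_dir / files["mirna_annotation"]),
            genesets=str(bundle_dir / files["genesets"]),
            ppi=str(bundle_dir / files["ppi"]),
            targets=targets,
            outdir=str(outdir),
            seed=seed,
            **overrides,
        )

    def validate(self) -> None:
        if len(self.targets) != 3:
            raise ValidationError(f"exactly 3 target sources required, got {len(self.targets)}")
        paths = [e["matrix"] for e in self.expression] + [
            self.annotation,
            self.mirna_matrix,
            self.mirna_annotation,
            self.genesets,
            self.ppi,
            *self.targets.values(),
        ]
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise ValidationError(f"missing input files: {missing}")
        if self.run_qc and len(self.expression) < 3:
            raise ValidationError("quality control needs at least 3 studies")


def _stage(name):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except (ValidationError, PipelineError):
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineError(name, str(exc)) from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return result

        return wrapper

    return decorator


@_stage("load")
def _load(config: RunConfig):
    studies = [
        dataio.read_expression(e["matrix"], config.annotation, study_id=e["study_id"])
        for e in config.expression
    ]
    collection = dataio.StudyCollection(studies)
    mirna_study = dataio.read_expression(config.mirna_matrix, config.mirna_annotation)
    genesets = dataio.read_genesets(config.genesets, universe=collection.common_genes)
    ppi = dataio.read_ppi(config.ppi)
    records = dataio.read_targets(config.targets)
    return collection, mirna_study, genesets, ppi, records


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order and write tables plus ``report.json``.

    Returns the report dictionary.  Raises :class:`ValidationError` before
    any computation for bad configs and :class:`PipelineError` (carrying the
    stage name) when a stage fails.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    collection, mirna_study, genesets, ppi, records = _load(config)
    tables: dict[str, pd.DataFrame] = {}
    counts: dict[str, object] = {"studies_loaded": collection.K}

    if config.quantile_normalize:
        collection = _quantile(collection)

    if config.run_qc:
        report = _qc(collection, genesets, config)
        tables["qc_report"] = report.table
        collection = study_qc.apply_exclusions(collection, report)
        counts["studies_excluded"] = report.excluded_study_ids()
    counts["studies_retained"] = collection.K

    per_study, meta = _meta(collection, config)
    for res in per_study:
        tables[f"de_{res.study_id}"] = res.table
    tables["meta_de"] = meta.table
    overlap = meta_de.overlap_de_genes(per_study, config.meta)
    counts["overlap_de_genes"] = len(overlap)
    counts["meta_de_genes"] = len(meta.meta_de_gene_ids)
    tables["overlap_de_genes"] = pd.DataFrame({"gene_id": sorted(overlap)})

    enr = _enrich(meta, genesets)
    if enr is not None:
        tables["enrichment"] = enr.table
        counts["significant_sets"] = len(enr.significant_sets())

    mirna_result, top_mirnas = _mirna(mirna_study, config)
    tables["mirna_de"] = mirna_result.table
    counts["de_mirnas"] = int(mirna_result.table["is_de"].sum())
    counts["top_mirnas"] = top_mirnas

    candidates, pairs = _targets(records, top_mirnas, meta)
    tables["candidate_genes"] = candidates.to_frame()
    tables["mirna_gene_pairs"] = pd.DataFrame(pairs, columns=["mirna_id", "gene_id"])
    counts["candidate_genes"] = len(candidates.genes)

    net, hub_report = _network(ppi, pairs, meta, config)
    if hub_report is not None:
        tables["hub_report"] = hub_report.to_frame()
        counts["hubs"] = hub_report.hub_ids
    tables["network_nodes"] = net.node_table()

    manifest = dataio.write_results(tables, net, outdir)
    manifest = {k: str(Path(v).name) for k, v in manifest.items()}

    report_dict = {"seed": config.seed, "counts": counts, "files": manifest}
    (outdir / "report.json").write_text(
        json.dumps(report_dict, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return report_dict


@_stage("quantile_normalize")
def _quantile(collection):
    return meta_de.quantile_normalize(collection)


@_stage("qc")
def _qc(collection, genesets, config: RunConfig):
    return study_qc.compute_qc_indices(collection, genesets, config.qc, config.meta)


@_stage("meta_de")
def _meta(collection, config: RunConfig):
    return meta_de.meta_analyze(collection, config.meta)


@_stage("enrichment")
def _enrich(meta, genesets):
    genes = meta.meta_de_gene_ids
    if not genes:
        warnings.warn("no meta-DE genes; enrichment skipped", stacklevel=2)
        return None
    return enrichment.enrich(genes, genesets)


@_stage("mirna_de")
def _mirna(mirna_study, config: RunConfig):
    result = mirna_de.test_mirnas(mirna_study, config.mirna)
    return result, mirna_de.top_k_mirnas(result, config.mirna)


@_stage("targetome")
def _targets(records, top_mirnas, meta):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        target_map = targetome.build_target_map(records, top_mirnas)
    candidates = targetome.candidate_genes(target_map, top_mirnas, meta.meta_de_gene_ids)
    return candidates, targetome.pairing_table(candidates)


@_stage("network")
def _network(ppi, pairs, meta, config: RunConfig):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net = network.build_network(
            ppi, pairs, genes_of_interest=meta.meta_de_gene_ids, score_min=config.score_min
        )
    hub_report = None
    if net.n_nodes > config.hub_count:
        hub_report = network.hubs(net, config.hub_count)
    return net, hub_report
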