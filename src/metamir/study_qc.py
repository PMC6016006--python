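"""Multi-study quality control with six concordance indices.

Each index is ``-log10`` of a permutation (or hypergeometric) p-value of a
concordance statistic computed on the ``n_qc_genes`` most variable genes
shared by all studies:

* ``IQC``  - study-vs-other-studies co-expression concordance.
* ``EQC``  - study co-expression vs gene-set co-membership concordance.
* ``AQCg`` - overlap of the study's top DE genes with the leave-one-out
  meta-analysis top genes (hypergeometric).
* ``CQCg`` - rank correlation of study p-values with leave-one-out meta
  p-values (permutation).
* ``AQCp``/``CQCp`` - the same two ideas on per-gene-set enrichment
  p-values instead of gene p-values.

Studies are ranked per index, the ranks averaged and standardized, and a
study whose standardized mean rank falls below ``exclusion_threshold``
standard deviations is flagged for exclusion.  All permutation streams are
keyed by ``(seed, study_id)`` so the report does not depend on study order.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import GeneSetCollection, StudyCollection
from .enrichment import enrich
from .meta_de import MetaDEConfig, fisher_combine, penalized_t

__all__ = ["QCConfig", "QCReport", "compute_qc_indices", "qc_pca", "apply_exclusions"]

INDEX_COLUMNS = ["IQC", "EQC", "AQCg", "AQCp", "CQCg", "CQCp"]


@dataclass
class QCConfig:
    n_qc_genes: int = 500
    n_perm: int = 500
    seed: int = 0
    correlation_kind: str = "spearman"
    top_m: int = 100
    exclusion_threshold: float = -1.0

    def __post_init__(self) -> None:
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.correlation_kind not in ("spearman", "pearson"):
            raise ValueError("correlation_kind must be spearman or pearson")
        if self.top_m < 1 or self.n_qc_genes < 2:
            raise ValueError("top_m >= 1 and n_qc_genes >= 2 required")


@dataclass
class QCReport:
    """Per-study quality indices, ranks, PCA coordinates and exclusions.

    ``table`` columns: ``study_id``, the six index columns, ``mean_rank``,
    ``std_mean_rank``, ``pc1``, ``pc2``, ``excluded``.
    """

    table: pd.DataFrame
    explained_variance: Optional[np.ndarray] = None

    def excluded_study_ids(self) -> list[str]:
        return self.table.loc[self.table["excluded"], "study_id"].tolist()


def _study_stream(seed: int, study_id: str, salt: int) -> np.random.Generator:
    key = zlib.crc32(study_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([seed, key, salt]))


def _coexpression(matrix: np.ndarray, kind: str) -> np.ndarray:
    """Gene x gene correlation across samples; zero-variance rows give 0."""
    if kind == "spearman":
        data = stats.rankdata(matrix, axis=1)
    else:
        data = matrix
    sd = data.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data)
    corr = np.nan_to_num(corr, nan=0.0)
    corr[sd == 0, :] = 0.0
    corr[:, sd == 0] = 0.0
    return corr


def _standardized_matrix(corr: np.ndarray, iu, kind: str) -> np.ndarray:
    """Symmetric matrix of standardized (optionally rank-transformed)
    upper-triangle values.

    Under a gene-label permutation the upper triangle of the permuted matrix
    is a permutation of the original entries, so ranks, means and sds
    computed once stay valid for every permutation; vector correlations then
    reduce to dot products of the standardized entries.
    """
    values = corr[iu].astype(float)
    if kind == "spearman":
        values = stats.rankdata(values)
    sd = values.std()
    values = (values - values.mean()) / sd if sd > 0 else np.zeros_like(values)
    out = np.zeros_like(corr, dtype=float)
    out[iu] = values
    out[iu[1], iu[0]] = values
    return out


def _perm_corr(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation with degenerate inputs mapped to 0."""
    us, vs = u.std(), v.std()
    if us == 0 or vs == 0:
        return 0.0
    return float((u @ v / u.size - u.mean() * v.mean()) / (us * vs))


def compute_qc_indices(
    collection: StudyCollection,
    genesets: Optional[GeneSetCollection],
    config: Optional[QCConfig] = None,
    meta_config: Optional[MetaDEConfig] = None,
) -> QCReport:
    """Compute the six quality indices and the exclusion flags.

    Requires K >= 3 (the leave-one-out indices need at least two remaining
    studies).  With an empty gene-set collection the pathway-level indices
    (EQC, AQCp, CQCp) are reported missing with a warning.
    """
    config = config or QCConfig()
    meta_config = meta_config or MetaDEConfig()
    if collection.K < 3:
        raise ValueError("quality control needs at least 3 studies")

    common = collection.common_genes
    if len(common) < 2:
        raise ValueError("studies share too few genes")
    studies = [s.subset_genes(common) for s in collection]
    study_ids = [s.study_id for s in studies]
    K = len(studies)

    # most variable common genes (mean within-study variance)
    variances = np.mean([s.matrix.var(axis=1, ddof=1) for s in studies], axis=0)
    n_qc = min(config.n_qc_genes, len(common))
    top = np.sort(np.argsort(-variances, kind="stable")[:n_qc])
    qc_matrices = [s.matrix[top, :] for s in studies]
    qc_genes = [common[i] for i in top]

    iu = np.triu_indices(n_qc, k=1)
    corr = [_coexpression(m, config.correlation_kind) for m in qc_matrices]
    # standardized symmetric rank matrices: means and sds of the upper
    # triangle are permutation-invariant, so correlations between permuted
    # vectors reduce to plain dot products
    zmats = [
        _standardized_matrix(c, iu, config.correlation_kind).astype(np.float32)
        for c in corr
    ]
    vectors = [zm[iu] for zm in zmats]
    P = vectors[0].size

    have_sets = genesets is not None and len(genesets) > 0
    if not have_sets:
        warnings.warn("no gene sets: EQC, AQCp and CQCp reported missing", stacklevel=2)

    co_vec = None
    if have_sets:
        member = np.zeros((len(genesets.sets), n_qc))
        gene_pos = {g: i for i, g in enumerate(qc_genes)}
        for row, members in enumerate(genesets.sets.values()):
            for g in members:
                if g in gene_pos:
                    member[row, gene_pos[g]] = 1.0
        co_member = (member.T @ member > 0).astype(float)
        co_vec = _standardized_matrix(co_member, iu, config.correlation_kind)[iu].astype(np.float32)
        if not co_vec.any():
            warnings.warn("degenerate co-membership matrix; EQC missing", stacklevel=2)
            co_vec = None

    def pair_corr(u: np.ndarray, v: np.ndarray) -> float:
        # inputs are standardized, so the correlation is a plain dot product
        return float(u @ v) / P

    iqc_stat = np.array(
        [
            np.mean([pair_corr(vectors[s], vectors[t]) for t in range(K) if t != s])
            for s in range(K)
        ]
    )
    eqc_stat = (
        np.array([pair_corr(vectors[s], co_vec) for s in range(K)])
        if co_vec is not None
        else None
    )

    iqc_count = np.zeros(K)
    eqc_count = np.zeros(K)
    perm_streams = [_study_stream(config.seed, sid, 11) for sid in study_ids]
    B = config.n_perm
    i_arr, j_arr = iu
    for _ in range(B):
        permuted = []
        for s in range(K):
            pi = perm_streams[s].permutation(n_qc)
            permuted.append(zmats[s][pi[i_arr], pi[j_arr]])
        pair = np.zeros((K, K))
        for s in range(K):
            for t in range(s + 1, K):
                pair[s, t] = pair[t, s] = pair_corr(permuted[s], permuted[t])
        stat = (pair.sum(axis=1)) / (K - 1)
        iqc_count += stat >= iqc_stat
        if co_vec is not None:
            eqc_perm = np.array([pair_corr(permuted[s], co_vec) for s in range(K)])
            eqc_count += eqc_perm >= eqc_stat

    iqc = -np.log10((iqc_count + 1.0) / (B + 1.0))
    eqc = -np.log10((eqc_count + 1.0) / (B + 1.0)) if co_vec is not None else np.full(K, np.nan)

    # --- accuracy / consistency indices on DE evidence -----------------
    de_results = [penalized_t(s, meta_config) for s in studies]
    p_vectors = [
        r.table.set_index("gene_id").loc[common, "p"].to_numpy() for r in de_results
    ]
    p_matrix = np.column_stack(p_vectors)
    G = len(common)
    top_m = min(config.top_m, G)

    def top_genes(p: np.ndarray) -> set[int]:
        return set(np.argsort(p, kind="stable")[:top_m])

    aqcg = np.zeros(K)
    cqcg = np.zeros(K)
    loo_p = []
    for s in range(K):
        others = [t for t in range(K) if t != s]
        _, meta_p = fisher_combine(p_matrix[:, others])
        loo_p.append(meta_p)
        overlap = len(top_genes(p_vectors[s]) & top_genes(meta_p))
        aqcg[s] = -np.log10(max(stats.hypergeom.sf(overlap - 1, G, top_m, top_m), 1e-320))

        cqcg[s] = _perm_rank_corr_index(
            p_vectors[s], meta_p, _study_stream(config.seed, study_ids[s], 23), B
        )

    # --- pathway-level versions ----------------------------------------
    aqcp = np.full(K, np.nan)
    cqcp = np.full(K, np.nan)
    if have_sets:
        qc_sets = GeneSetCollection(
            sets={k: list(v) for k, v in genesets.sets.items()},
            universe=list(common),
            descriptions=dict(genesets.descriptions),
        )
        qc_sets = GeneSetCollection(
            sets={k: v for k, v in qc_sets.sets.items() if v},
            universe=qc_sets.universe,
            descriptions=qc_sets.descriptions,
        )
        if len(qc_sets) >= 2:
            n_sets = len(qc_sets)
            top_sets_m = max(1, min(top_m, n_sets // 3 or 1))

            def set_p_vector(gene_idx: set[int]) -> np.ndarray:
                genes = [common[i] for i in gene_idx]
                table = enrich(genes, qc_sets).table.set_index("set_name")
                return np.array([table.loc[name, "p"] for name in qc_sets.names])

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                loo_set_p = [set_p_vector(top_genes(loo_p[s])) for s in range(K)]
                study_set_p = [set_p_vector(top_genes(p_vectors[s])) for s in range(K)]
            for s in range(K):
                top_a = set(np.argsort(study_set_p[s], kind="stable")[:top_sets_m])
                top_b = set(np.argsort(loo_set_p[s], kind="stable")[:top_sets_m])
                overlap = len(top_a & top_b)
                aqcp[s] = -np.log10(
                    max(stats.hypergeom.sf(overlap - 1, n_sets, top_sets_m, top_sets_m), 1e-320)
                )
                cqcp[s] = _perm_rank_corr_index(
                    study_set_p[s],
                    loo_set_p[s],
                    _study_stream(config.seed, study_ids[s], 29),
                    B,
                )

    table = pd.DataFrame(
        {
            "study_id": study_ids,
            "IQC": iqc,
            "EQC": eqc,
            "AQCg": aqcg,
            "AQCp": aqcp,
            "CQCg": cqcg,
            "CQCp": cqcp,
        }
    )
    table = _aggregate(table, config)
    report = QCReport(table=table)
    coords, frac = qc_pca(report)
    report.table["pc1"] = coords[:, 0]
    report.table["pc2"] = coords[:, 1] if coords.shape[1] > 1 else 0.0
    report.explained_variance = frac
    return report


def _perm_rank_corr_index(
    a: np.ndarray, b: np.ndarray, rng: np.random.Generator, B: int
) -> float:
    """-log10 permutation p of the Spearman correlation between a and b."""
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    obs = _perm_corr(ra, rb)
    count = 0
    for _ in range(B):
        if _perm_corr(ra, rng.permutation(rb)) >= obs:
            count += 1
    return float(-np.log10((count + 1.0) / (B + 1.0)))


def _aggregate(table: pd.DataFrame, config: QCConfig) -> pd.DataFrame:
    """Rank each index across studies, standardize per index, average, flag.

    Standardizing each rank column separately and averaging the z-scores
    damps Monte-Carlo jitter (a noise column contributes ~1/sqrt(6) to the
    mean) while a genuinely poor study scores low on every column.
    """
    available = [c for c in INDEX_COLUMNS if table[c].notna().all()]
    ranks = pd.DataFrame(
        {c: stats.rankdata(table[c].to_numpy()) for c in available}, index=table.index
    )
    mean_rank = ranks.mean(axis=1).to_numpy()
    z_cols = []
    for c in available:
        col = ranks[c].to_numpy(dtype=float)
        sd = col.std()
        z_cols.append((col - col.mean()) / sd if sd > 0 else np.zeros_like(col))
    z = np.mean(z_cols, axis=0) if z_cols else np.zeros(len(table))
    out = table.copy()
    out["mean_rank"] = mean_rank
    out["std_mean_rank"] = z
    out["excluded"] = z < config.exclusion_threshold
    return out


def qc_pca(report: QCReport) -> tuple[np.ndarray, np.ndarray]:
    """Principal components of the centered, unit-scaled study x index matrix.

    Returns (coordinates, explained-variance fractions).  The fractions sum
    to 1 over all components.
    """
    cols = [c for c in INDEX_COLUMNS if report.table[c].notna().all()]
    X = report.table[cols].to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    X = X / np.where(sd > 0, sd, 1.0)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    coords = u * s
    total = float((s ** 2).sum())
    frac = (s ** 2) / total if total > 0 else np.zeros_like(s)
    if not np.isfinite(coords).all():
        raise ValueError("non-finite PCA coordinates")
    return coords, frac


def apply_exclusions(collection: StudyCollection, report: QCReport) -> StudyCollection:
    """Drop the studies flagged by the report; refuse to go below K = 2."""
    excluded = set(report.excluded_study_ids())
    kept = [s for s in collection if s.study_id not in excluded]
    if len(kept) < 2:
        raise ValueError("exclusions would leave fewer than 2 studies")
    return StudyCollection(kept)
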