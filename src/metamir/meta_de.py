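"""Per-study differential expression and cross-study p-value combination.

The per-study statistic is a penalized two-sample t: the ordinary pooled-t
denominator is inflated by a fudge constant ``s0`` so that genes with tiny
variance cannot dominate the ranking.  Per-gene p-values are then combined
across studies with Fisher's method (``-2 * sum(log p)``, chi-square with
``2K`` df) and/or the maxP statistic (``max_k p``, null p-value ``maxP**K``),
followed by Benjamini-Hochberg adjustment and a cross-study sign-consistency
filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import ExpressionStudy, StudyCollection

__all__ = [
    "MetaDEConfig",
    "StudyDEResult",
    "MetaDEResult",
    "penalized_t",
    "fisher_combine",
    "maxp_combine",
    "bh_adjust",
    "overlap_de_genes",
    "meta_de_genes",
    "meta_analyze",
    "quantile_normalize",
]

P_FLOOR = 1e-300


@dataclass
class MetaDEConfig:
    """Knobs for per-study testing and cross-study combination."""

    s0_rule: Literal["median_se", "fixed", "none"] = "median_se"
    s0: float = 0.0
    p_method: Literal["t_reference", "permutation"] = "t_reference"
    n_perm: int = 1000
    seed: int = 0
    combine: Literal["fisher", "maxp", "both"] = "both"
    meta_alpha: float = 0.05
    heatmap_fdr: float = 1e-4
    per_study_alpha: float = 0.05
    direction_rule: Literal["all_same_sign", "majority", "off"] = "all_same_sign"

    def __post_init__(self) -> None:
        for name in ("meta_alpha", "heatmap_fdr", "per_study_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.s0_rule == "fixed" and self.s0 < 0:
            raise ValueError("fixed s0 must be >= 0")
        if self.p_method == "permutation" and self.n_perm < 100:
            raise ValueError("n_perm must be >= 100 for permutation p-values")


@dataclass
class StudyDEResult:
    """Penalized-t differential expression for one study.

    ``table`` columns: ``gene_id``, ``logFC`` (case - control), ``se``
    (pooled standard error), ``t`` (penalized), ``p``, ``adj_p``,
    ``zero_variance``.
    """

    study_id: str
    table: pd.DataFrame
    s0: float

    def significant_genes(self, alpha: float) -> set[str]:
        mask = self.table["adj_p"] < alpha
        return set(self.table.loc[mask, "gene_id"])


@dataclass
class MetaDEResult:
    """Combined meta-analysis over a study collection.

    ``table`` columns: ``gene_id``, one ``p_<study>`` and ``d_<study>`` pair
    per study, ``fisher_S``, ``fisher_p``, ``maxp_stat``, ``maxp_p``,
    ``fisher_fdr``, ``maxp_fdr``, ``direction_consistent``, ``is_meta_de``,
    ``is_heatmap``.
    """

    table: pd.DataFrame
    study_ids: list[str]
    config: MetaDEConfig

    @property
    def meta_de_gene_ids(self) -> list[str]:
        return self.table.loc[self.table["is_meta_de"], "gene_id"].tolist()

    @property
    def heatmap_gene_ids(self) -> list[str]:
        return self.table.loc[self.table["is_heatmap"], "gene_id"].tolist()


def _pooled_stats(matrix: np.ndarray, case: np.ndarray, control: np.ndarray):
    x1 = matrix[:, case]
    x2 = matrix[:, control]
    n1, n2 = x1.shape[1], x2.shape[1]
    d = x1.mean(axis=1) - x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return d, se, n1, n2


def resolve_s0(se: np.ndarray, config: MetaDEConfig) -> float:
    if config.s0_rule == "none":
        return 0.0
    if config.s0_rule == "fixed":
        return float(config.s0)
    return float(np.median(se))


def penalized_t(study: ExpressionStudy, config: Optional[MetaDEConfig] = None) -> StudyDEResult:
    """Two-sample differential expression with a variance fudge constant.

    ``t_g = d_g / (se_g + s0)`` with ``d_g`` the case-minus-control log2
    difference and ``se_g`` the pooled standard error.  ``s0`` defaults to
    the median of the gene-wise standard errors.  p-values come from the t
    reference distribution with ``n1 + n2 - 2`` df, or from group-label
    permutation when ``config.p_method == "permutation"``.
    """
    config = config or MetaDEConfig()
    case = study.group_mask("case")
    control = study.group_mask("control")
    d, se, n1, n2 = _pooled_stats(study.matrix, case, control)
    s0 = resolve_s0(se, config)
    denom = se + s0
    zero_var = denom == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero_var, np.where(d == 0, 0.0, np.sign(d) * np.inf), d / denom)
    # d == 0 with zero denominator: no evidence either way
    t = np.where(zero_var & (d == 0), 0.0, t)

    df = n1 + n2 - 2
    if config.p_method == "t_reference":
        p = 2.0 * stats.t.sf(np.abs(t), df=df)
        p = np.where(np.isinf(t), 0.0, p)
        p = np.where(zero_var & (d == 0), 1.0, p)
        if zero_var.any() and (d[zero_var] != 0).any():
            warnings.warn(
                "zero within-group variance with s0 = 0; p reported as limit 0",
                RuntimeWarning,
                stacklevel=2,
            )
    else:
        p = _permutation_p(study.matrix, case, control, t, s0, config)

    table = pd.DataFrame(
        {
            "gene_id": study.gene_ids,
            "logFC": d,
            "se": se,
            "t": t,
            "p": p,
            "adj_p": bh_adjust(p),
            "zero_variance": zero_var,
        }
    )
    return StudyDEResult(study_id=study.study_id, table=table, s0=s0)


def _permutation_p(
    matrix: np.ndarray,
    case: np.ndarray,
    control: np.ndarray,
    t_obs: np.ndarray,
    s0: float,
    config: MetaDEConfig,
) -> np.ndarray:
    """Group-label permutation p for the penalized t, s0 held fixed."""
    rng = np.random.default_rng(config.seed)
    labels = np.where(case, 1, 0)
    count = np.zeros(matrix.shape[0], dtype=np.int64)
    for _ in range(config.n_perm):
        perm = rng.permutation(labels).astype(bool)
        d, se, _, _ = _pooled_stats(matrix, perm, ~perm)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = d / (se + s0)
        t_perm = np.nan_to_num(t_perm, nan=0.0, posinf=np.inf, neginf=-np.inf)
        count += np.abs(t_perm) >= np.abs(t_obs)
    return (count + 1.0) / (config.n_perm + 1.0)


def fisher_combine(p_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fisher's p-value combination across the columns of ``p_matrix``.

    Returns ``(S, meta_p)`` with ``S = -2 * sum(log p)`` and ``meta_p`` the
    upper tail of chi-square with ``2K`` degrees of freedom.  Zero p-values
    are clamped to 1e-300 with a warning; missing values are not allowed.
    """
    p = _validated_p_matrix(p_matrix)
    S = -2.0 * np.sum(np.log(p), axis=1)
    meta_p = stats.chi2.sf(S, df=2 * p.shape[1])
    return S, meta_p


def maxp_combine(p_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """maxP combination: statistic ``max_k p``; null p-value ``maxP**K``."""
    p = _validated_p_matrix(p_matrix)
    stat = np.max(p, axis=1)
    return stat, stat ** p.shape[1]


def _validated_p_matrix(p_matrix: np.ndarray) -> np.ndarray:
    p = np.asarray(p_matrix, dtype=float)
    if p.ndim != 2 or p.shape[1] < 2:
        raise ValueError("p_matrix must be 2-d with K >= 2 columns")
    if np.isnan(p).any():
        raise ValueError("missing p-values are not allowed (complete-case only)")
    if (p > 1).any() or (p < 0).any():
        raise ValueError("p-values must lie in [0, 1]")
    if (p == 0).any():
        warnings.warn(
            f"{int((p == 0).sum())} zero p-values clamped to {P_FLOOR}",
            RuntimeWarning,
            stacklevel=3,
        )
        p = np.clip(p, P_FLOOR, 1.0)
    return p


def bh_adjust(p_vector: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_vector, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def overlap_de_genes(
    results: Sequence[StudyDEResult], config: Optional[MetaDEConfig] = None
) -> set[str]:
    """Genes significant (BH-adjusted) in every study."""
    config = config or MetaDEConfig()
    if not results:
        return set()
    sets = [r.significant_genes(config.per_study_alpha) for r in results]
    return set.intersection(*sets)


def _direction_consistent(d_matrix: np.ndarray, rule: str) -> np.ndarray:
    signs = np.sign(d_matrix)
    if rule == "off":
        return np.ones(d_matrix.shape[0], dtype=bool)
    if rule == "all_same_sign":
        return (np.all(signs > 0, axis=1)) | (np.all(signs < 0, axis=1))
    if rule == "majority":
        k = d_matrix.shape[1]
        pos = (signs > 0).sum(axis=1)
        neg = (signs < 0).sum(axis=1)
        return (pos > k / 2) | (neg > k / 2)
    raise ValueError(f"unknown direction rule {rule!r}")


def meta_de_genes(meta: MetaDEResult, config: Optional[MetaDEConfig] = None) -> MetaDEResult:
    """(Re-)annotate a MetaDEResult with is_meta_de / is_heatmap flags."""
    config = config or meta.config
    t = meta.table
    fisher_ok = t["fisher_fdr"] < config.meta_alpha
    maxp_ok = t["maxp_fdr"] < config.meta_alpha
    if config.combine == "fisher":
        combined = fisher_ok
    elif config.combine == "maxp":
        combined = maxp_ok
    else:
        combined = fisher_ok & maxp_ok
    t = t.copy()
    t["is_meta_de"] = combined & t["direction_consistent"]
    t["is_heatmap"] = t["fisher_fdr"] < config.heatmap_fdr
    return MetaDEResult(table=t, study_ids=meta.study_ids, config=config)


def meta_analyze(
    collection: StudyCollection, config: Optional[MetaDEConfig] = None
) -> tuple[list[StudyDEResult], MetaDEResult]:
    """Run per-study penalized-t DE and combine p-values across studies.

    Only genes present in every study enter the combination (complete-case).
    """
    config = config or MetaDEConfig()
    if collection.K < 2:
        raise ValueError("meta-analysis needs at least 2 studies")
    genes = collection.common_genes
    if not genes:
        raise ValueError("studies share no genes")
    per_study = [penalized_t(s, config) for s in collection]

    p_cols, d_cols = {}, {}
    for res in per_study:
        sub = res.table.set_index("gene_id").loc[genes]
        p_cols[res.study_id] = sub["p"].to_numpy()
        d_cols[res.study_id] = sub["logFC"].to_numpy()
    p_matrix = np.column_stack([p_cols[s] for s in collection.study_ids()])
    d_matrix = np.column_stack([d_cols[s] for s in collection.study_ids()])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        S, fisher_p = fisher_combine(p_matrix)
        maxp_stat, maxp_p = maxp_combine(p_matrix)

    table = pd.DataFrame({"gene_id": genes})
    for i, sid in enumerate(collection.study_ids()):
        table[f"p_{sid}"] = p_matrix[:, i]
        table[f"d_{sid}"] = d_matrix[:, i]
    table["fisher_S"] = S
    table["fisher_p"] = fisher_p
    table["maxp_stat"] = maxp_stat
    table["maxp_p"] = maxp_p
    table["fisher_fdr"] = bh_adjust(fisher_p)
    table["maxp_fdr"] = bh_adjust(maxp_p)
    table["direction_consistent"] = _direction_consistent(d_matrix, config.direction_rule)

    meta = MetaDEResult(table=table, study_ids=collection.study_ids(), config=config)
    return per_study, meta_de_genes(meta, config)


def quantile_normalize(collection: StudyCollection) -> StudyCollection:
    """Within-study quantile normalization to the mean-of-order-statistics.

    After normalization every column of a study shares the identical sorted
    value profile; rank ties receive the average of the reference values at
    the tied positions.
    """
    out = []
    for study in collection:
        out.append(
            ExpressionStudy(
                study_id=study.study_id,
                matrix=_quantile_normalize_matrix(study.matrix),
                gene_ids=list(study.gene_ids),
                sample_ids=list(study.sample_ids),
                group=list(study.group),
                platform_id=study.platform_id,
            )
        )
    return StudyCollection(out)


def _quantile_normalize_matrix(matrix: np.ndarray) -> np.ndarray:
    reference = np.sort(matrix, axis=0).mean(axis=1)
    out = np.empty_like(matrix, dtype=float)
    n = matrix.shape[0]
    for j in range(matrix.shape[1]):
        col = matrix[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n)
        assigned[order] = reference
        # ties share the average of the reference values they span
        out[:, j] = pd.Series(assigned).groupby(pd.Series(col)).transform("mean").to_numpy()
    return out
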