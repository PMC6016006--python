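"""Two-group miRNA differential expression with variance pre-filtering.

Workflow: per-row standardization is available for visualization parity,
but the sd-ratio filter and the t-test both run on the original log2
values (standardizing first would force every sd to 1 and distort the
test).  A miRNA is called DE when p < p_threshold, BH q < q_threshold and
linear fold change > fc_threshold simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import ExpressionStudy
from .meta_de import bh_adjust

__all__ = [
    "MiRNAFilterConfig",
    "MiRNADEResult",
    "standardize",
    "variance_filter",
    "test_mirnas",
    "top_k_mirnas",
]


@dataclass
class MiRNAFilterConfig:
    sd_ratio_threshold: float = 0.1
    p_threshold: float = 0.001
    q_threshold: float = 0.01
    fc_threshold: float = 2.0
    top_k: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.sd_ratio_threshold < 1.0:
            raise ValueError("sd_ratio_threshold must be in [0, 1)")
        for name in ("p_threshold", "q_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1)")
        if self.fc_threshold <= 1.0:
            raise ValueError("fc_threshold must exceed 1 (linear scale)")
        if self.top_k < 0:
            raise ValueError("top_k must be >= 0")


@dataclass
class MiRNADEResult:
    """Per-miRNA filter and test results.

    ``table`` columns: ``mirna_id``, ``sigma`` (pre-standardization sd),
    ``sigma_ratio``, ``passed_filter``, ``log2fc`` (signed case - control),
    ``direction`` (+1/-1/0), ``fold_change`` (``2**|log2fc|``, >= 1),
    ``t``, ``p``, ``q``, ``is_de``, ``rank`` (ascending p among DE calls).
    """

    table: pd.DataFrame

    @classmethod
    def from_screen_table(
        cls,
        mirna_ids: Sequence[str],
        p: Sequence[float],
        fold_change: Sequence[float],
        direction: Optional[Sequence[int]] = None,
    ) -> "MiRNADEResult":
        """Wrap an externally produced (id, p, fold-change) screen.

        All rows are treated as having passed filtering and thresholds,
        so top-k selection can be applied to published screen tables.
        """
        n = len(mirna_ids)
        fc = np.asarray(fold_change, dtype=float)
        table = pd.DataFrame(
            {
                "mirna_id": list(mirna_ids),
                "sigma": np.nan,
                "sigma_ratio": np.nan,
                "passed_filter": True,
                "log2fc": np.log2(fc)
                * (np.asarray(direction) if direction is not None else 1),
                "direction": list(direction) if direction is not None else [1] * n,
                "fold_change": fc,
                "t": np.nan,
                "p": np.asarray(p, dtype=float),
                "q": np.asarray(p, dtype=float),
                "is_de": True,
            }
        )
        table["rank"] = _rank_de(table)
        return cls(table=table)

    def de_mirna_ids(self) -> list[str]:
        sub = self.table[self.table["is_de"]].sort_values("rank")
        return sub["mirna_id"].tolist()


def standardize(study: ExpressionStudy) -> ExpressionStudy:
    """Center each row to mean 0 and scale to sd 1 (sample sd, ddof=1).

    Zero-variance rows are left centered only.  Idempotent up to floating
    point on rows that already have unit sd.
    """
    matrix = study.matrix
    mean = matrix.mean(axis=1, keepdims=True)
    sd = matrix.std(axis=1, ddof=1, keepdims=True)
    scale = np.where(sd > 0, sd, 1.0)
    return ExpressionStudy(
        study_id=study.study_id,
        matrix=(matrix - mean) / scale,
        gene_ids=list(study.gene_ids),
        sample_ids=list(study.sample_ids),
        group=list(study.group),
        platform_id=study.platform_id,
    )


def variance_filter(
    study: ExpressionStudy, config: Optional[MiRNAFilterConfig] = None
) -> set[str]:
    """Retain miRNAs whose sd is at least ``tau`` times the maximum sd.

    The sd is computed on the raw (pre-standardization) values.
    """
    config = config or MiRNAFilterConfig()
    sigma = study.matrix.std(axis=1, ddof=1)
    sigma_max = sigma.max() if sigma.size else 0.0
    if sigma_max == 0.0:
        raise ValueError("all rows are constant; sd ratio undefined")
    keep = sigma / sigma_max >= config.sd_ratio_threshold
    return {g for g, k in zip(study.gene_ids, keep) if k}


def _rank_de(table: pd.DataFrame) -> np.ndarray:
    """Rank DE rows by ascending p, ties by descending FC then id."""
    rank = np.full(len(table), -1, dtype=int)
    de = table[table["is_de"]]
    ordered = de.sort_values(
        ["p", "fold_change", "mirna_id"],
        ascending=[True, False, True],
        kind="stable",
    )
    for r, idx in enumerate(ordered.index, start=1):
        rank[table.index.get_loc(idx)] = r
    return rank


def test_mirnas(
    study: ExpressionStudy, config: Optional[MiRNAFilterConfig] = None
) -> MiRNADEResult:
    """Pooled-variance two-sided t-test per retained miRNA on log2 values."""
    config = config or MiRNAFilterConfig()
    retained = variance_filter(study, config)

    case = study.group_mask("case")
    control = study.group_mask("control")
    n1, n2 = int(case.sum()), int(control.sum())
    df = n1 + n2 - 2

    sigma = study.matrix.std(axis=1, ddof=1)
    sigma_max = sigma.max()
    passed = np.asarray([g in retained for g in study.gene_ids], dtype=bool)

    x1 = study.matrix[:, case]
    x2 = study.matrix[:, control]
    d = x1.mean(axis=1) - x2.mean(axis=1)
    sp2 = ((n1 - 1) * x1.var(axis=1, ddof=1) + (n2 - 1) * x2.var(axis=1, ddof=1)) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, d / se, np.where(d == 0, 0.0, np.sign(d) * np.inf))
    p = 2.0 * stats.t.sf(np.abs(t), df=df)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where((se == 0) & (d == 0), 1.0, p)

    q = np.full_like(p, np.nan)
    q[passed] = bh_adjust(p[passed])

    direction = np.sign(d).astype(int)
    fold_change = 2.0 ** np.abs(d)
    is_de = (
        passed
        & (p < config.p_threshold)
        & (q < config.q_threshold)
        & (fold_change > config.fc_threshold)
    )

    table = pd.DataFrame(
        {
            "mirna_id": study.gene_ids,
            "sigma": sigma,
            "sigma_ratio": sigma / sigma_max,
            "passed_filter": passed,
            "log2fc": d,
            "direction": direction,
            "fold_change": fold_change,
            "t": t,
            "p": p,
            "q": q,
            "is_de": is_de,
        }
    )
    table["rank"] = _rank_de(table)
    return MiRNADEResult(table=table)


def top_k_mirnas(
    result: MiRNADEResult, config: Optional[MiRNAFilterConfig] = None
) -> list[str]:
    """First ``top_k`` DE miRNAs by ascending p (ties: descending FC, id)."""
    config = config or MiRNAFilterConfig()
    return result.de_mirna_ids()[: config.top_k]
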