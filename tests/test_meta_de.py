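import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_study
from metamir.dataio import ExpressionStudy, StudyCollection
from metamir.meta_de import (
    MetaDEConfig,
    bh_adjust,
    fisher_combine,
    maxp_combine,
    meta_analyze,
    meta_de_genes,
    overlap_de_genes,
    penalized_t,
    quantile_normalize,
)
from metamir.synthetic import SimParams, simulate_studies

# ---------------------------------------------------------------------------
# independent oracles


def bh_oracle(p):
    """Literal step-up definition: adj p_(i) = min_{j>=i} min(1, m p_(j)/j)."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    for rank_i, idx in enumerate(order, start=1):
        best = min(
            min(1.0, m * p[order[j - 1]] / j) for j in range(rank_i, m + 1)
        )
        adj[idx] = best
    return adj


def chi2_upper_tail_even_df(s, k):
    """Closed form for chi-square upper tail with 2k df (k integer):
    exp(-s/2) * sum_{i<k} (s/2)^i / i!"""
    half = s / 2.0
    return math.exp(-half) * math.fsum(half**i / math.factorial(i) for i in range(k))


def quantile_normalize_oracle(matrix):
    """Brute-force per-column rank/average implementation."""
    matrix = np.asarray(matrix, dtype=float)
    n, m = matrix.shape
    reference = np.mean(np.sort(matrix, axis=0), axis=1)
    out = np.zeros_like(matrix)
    for j in range(m):
        col = matrix[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n)
        assigned[order] = reference
        for value in np.unique(col):
            mask = col == value
            out[mask, j] = assigned[mask].mean()
    return out


def two_group_study(group1, group2):
    values = np.array([list(group1) + list(group2)], dtype=float)
    return ExpressionStudy(
        study_id="two",
        matrix=values,
        gene_ids=["g"],
        sample_ids=[f"x{i}" for i in range(values.shape[1])],
        group=["case"] * len(group1) + ["control"] * len(group2),
    )


# ---------------------------------------------------------------------------
# penalized t


class TestPenalizedT:
    def test_hand_derived_s0_zero(self):
        study = two_group_study((1, 2, 3), (4, 5, 6))
        res = penalized_t(study, MetaDEConfig(s0_rule="fixed", s0=0.0))
        row = res.table.iloc[0]
        assert row["logFC"] == pytest.approx(-3.0)
        assert row["se"] == pytest.approx(0.8165, abs=1e-4)
        assert row["t"] == pytest.approx(-3.6742, abs=1e-4)

    def test_hand_derived_s0_half(self):
        study = two_group_study((1, 2, 3), (4, 5, 6))
        res = penalized_t(study, MetaDEConfig(s0_rule="fixed", s0=0.5))
        assert res.table["t"].iloc[0] == pytest.approx(-2.2788, abs=1e-4)

    def test_identical_groups(self):
        study = two_group_study((1.0, 2.0, 3.0), (1.0, 2.0, 3.0))
        res = penalized_t(study, MetaDEConfig(s0_rule="none"))
        row = res.table.iloc[0]
        assert row["logFC"] == 0.0
        assert row["t"] == 0.0
        assert row["p"] == pytest.approx(1.0)

    def test_reduction_to_classical_t(self, rng):
        # s0 = 0 penalized t == classical pooled two-sample t to 1e-12
        for _ in range(25):
            n1, n2 = rng.integers(2, 9, size=2)
            study = make_study(rng, n_genes=30, n_cases=int(n1), n_controls=int(n2))
            res = penalized_t(study, MetaDEConfig(s0_rule="none"))
            ref_t, ref_p = stats.ttest_ind(
                study.matrix[:, study.group_mask("case")],
                study.matrix[:, study.group_mask("control")],
                axis=1,
                equal_var=True,
            )
            np.testing.assert_allclose(res.table["t"], ref_t, rtol=1e-12, atol=1e-12)
            np.testing.assert_allclose(res.table["p"], ref_p, rtol=1e-12, atol=1e-12)

    def test_sign_matches_logfc(self, rng):
        study = make_study(rng, n_genes=50)
        res = penalized_t(study)
        nz = res.table[res.table["logFC"] != 0]
        assert (np.sign(nz["t"]) == np.sign(nz["logFC"])).all()

    def test_zero_variance_with_s0_zero_warns(self):
        study = two_group_study((1.0, 1.0), (2.0, 2.0))
        with pytest.warns(RuntimeWarning, match="zero within-group variance"):
            res = penalized_t(study, MetaDEConfig(s0_rule="none"))
        assert res.table["p"].iloc[0] == 0.0
        assert bool(res.table["zero_variance"].iloc[0])

    def test_permutation_p_method(self):
        study = two_group_study((1, 2, 3, 2.5), (4, 5, 6, 5.5))
        res = penalized_t(
            study, MetaDEConfig(p_method="permutation", n_perm=200, seed=1, s0_rule="none")
        )
        p = res.table["p"].iloc[0]
        assert 1 / 201 <= p < 0.2

    def test_default_s0_is_median_se(self, rng):
        study = make_study(rng, n_genes=31)
        res = penalized_t(study)
        assert res.s0 == pytest.approx(np.median(res.table["se"]))


# ---------------------------------------------------------------------------
# combination


class TestFisherCombine:
    def test_hand_derived(self):
        S, p = fisher_combine(np.array([[0.01, 0.05]]))
        assert S[0] == pytest.approx(15.2018, abs=1e-4)

    def test_all_ones(self):
        S, p = fisher_combine(np.array([[1.0, 1.0, 1.0]]))
        assert S[0] == 0.0
        assert p[0] == pytest.approx(1.0)

    def test_matches_closed_form_oracle(self, rng):
        for _ in range(100):
            k = int(rng.integers(2, 7))
            pvec = rng.uniform(1e-6, 1.0, size=(1, k))
            S, meta_p = fisher_combine(pvec)
            expected = chi2_upper_tail_even_df(S[0], k)
            assert meta_p[0] == pytest.approx(expected, rel=1e-10)

    def test_zero_p_clamped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clamped"):
            S, p = fisher_combine(np.array([[0.0, 0.5]]))
        assert np.isfinite(S).all()

    def test_rejects_missing(self):
        with pytest.raises(ValueError, match="missing"):
            fisher_combine(np.array([[0.1, np.nan]]))

    def test_rejects_single_column(self):
        with pytest.raises(ValueError):
            fisher_combine(np.array([[0.1]]))


class TestMaxPCombine:
    def test_closed_form(self):
        stat, p = maxp_combine(np.array([[0.2, 0.3]]))
        assert stat[0] == pytest.approx(0.3)
        assert p[0] == pytest.approx(0.09)

    def test_boundary(self):
        _, p = maxp_combine(np.array([[1.0, 0.5]]))
        assert p[0] == pytest.approx(1.0)

    def test_uniform_under_null(self, rng):
        pvec = rng.uniform(size=(4000, 3))
        _, meta_p = maxp_combine(pvec)
        assert stats.kstest(meta_p, "uniform").pvalue > 0.01


class TestBHAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_value_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_and_dominates_raw(self, p):
        adjusted = bh_adjust(p)
        np.testing.assert_allclose(adjusted, bh_oracle(p), rtol=1e-12, atol=1e-12)
        assert (adjusted >= np.asarray(p) - 1e-15).all()

    def test_empty(self):
        assert bh_adjust([]).size == 0


# ---------------------------------------------------------------------------
# gene-list construction


class TestOverlapDEGenes:
    def _results(self, rng, planted):
        genes = [f"g{i}" for i in range(40)]
        studies = []
        for k in range(3):
            study = make_study(rng, f"s{k}", gene_ids=genes, n_cases=6, n_controls=6)
            rows = [genes.index(g) for g in planted[k]]
            if rows:
                study.matrix[np.ix_(rows, study.group_mask("case"))] -= 10.0
            studies.append(study)
        return [penalized_t(s) for s in studies]

    def test_matches_brute_force_intersection(self, rng):
        config = MetaDEConfig()
        planted = [{"g1", "g2", "g3"}, {"g2", "g3", "g5"}, {"g3", "g2", "g9"}]
        results = self._results(rng, planted)
        observed = overlap_de_genes(results, config)
        expected = set.intersection(
            *(r.significant_genes(config.per_study_alpha) for r in results)
        )
        assert observed == expected
        assert {"g2", "g3"} <= observed

    def test_significant_in_all_but_one_excluded(self, rng):
        results = self._results(rng, [{"g1"}, {"g1"}, {"g7"}])
        assert "g1" not in overlap_de_genes(results)

    def test_empty_when_no_signal(self, rng):
        results = self._results(rng, [set(), set(), set()])
        assert overlap_de_genes(results) == set()


class TestMetaDEGenes:
    def _meta_with(self, d_rows, p=1e-8):
        genes = [f"g{i}" for i in range(len(d_rows))]
        table = pd.DataFrame({"gene_id": genes})
        for k in range(len(d_rows[0])):
            table[f"p_s{k}"] = p
            table[f"d_s{k}"] = [row[k] for row in d_rows]
        K = len(d_rows[0])
        pm = np.full((len(d_rows), K), p)
        from metamir.meta_de import MetaDEResult, _direction_consistent

        S, fisher_p = fisher_combine(pm)
        mstat, maxp_p = maxp_combine(pm)
        table["fisher_S"] = S
        table["fisher_p"] = fisher_p
        table["maxp_stat"] = mstat
        table["maxp_p"] = maxp_p
        table["fisher_fdr"] = bh_adjust(fisher_p)
        table["maxp_fdr"] = bh_adjust(maxp_p)
        dmat = np.array(d_rows, dtype=float)
        config = MetaDEConfig()
        table["direction_consistent"] = _direction_consistent(dmat, config.direction_rule)
        return MetaDEResult(table=table, study_ids=[f"s{k}" for k in range(K)], config=config)

    def test_opposite_signs_rejected(self):
        meta = self._meta_with([[-1.0, 1.0, -1.0], [-1.0, -1.0, -1.0]])
        annotated = meta_de_genes(meta)
        flags = dict(zip(annotated.table["gene_id"], annotated.table["is_meta_de"]))
        assert not flags["g0"]
        assert flags["g1"]

    def test_heatmap_subset_of_meta_de(self):
        meta = self._meta_with([[-1.0, -1.0, -1.0], [-0.5, -0.5, -0.5]], p=1e-9)
        annotated = meta_de_genes(meta)
        t = annotated.table
        assert set(t.loc[t["is_heatmap"], "gene_id"]) <= set(t.loc[t["is_meta_de"], "gene_id"])

    def test_planted_gene_recovery_rate(self):
        # delta = 1.2, n = 8/8, K = 5: planted genes flagged in >= 90% of 20 seeds
        hits = total = 0
        for seed in range(20):
            params = SimParams(
                seed=seed, n_studies=5, genes_per_study=500, de_fraction=0.05,
                effect_size_range=(1.2, 1.2), n_cases=8, n_controls=8,
            )
            collection, truth = simulate_studies(params)
            _, meta = meta_analyze(collection)
            found = set(meta.meta_de_gene_ids)
            hits += len(found & truth.de_gene_ids)
            total += len(truth.de_gene_ids)
        assert hits / total >= 0.9


class TestMetaAnalyze:
    def test_complete_case_only(self, rng):
        genes = [f"g{i}" for i in range(20)]
        s1 = make_study(rng, "s1", gene_ids=genes)
        s2 = make_study(rng, "s2", gene_ids=genes[:15])
        _, meta = meta_analyze(StudyCollection([s1, s2]))
        assert list(meta.table["gene_id"]) == genes[:15]

    def test_needs_two_studies(self, rng):
        with pytest.raises(ValueError):
            meta_analyze(StudyCollection([make_study(rng, "s1")]))

    def test_null_calibration(self):
        # pi = 0 with the classical t (s0 = 0): fraction of raw Fisher meta-p
        # < alpha within the binomial 99% interval around alpha
        params = SimParams(seed=11, n_studies=5, genes_per_study=2000, de_fraction=0.0)
        collection, _ = simulate_studies(params)
        _, meta = meta_analyze(collection, MetaDEConfig(s0_rule="none"))
        frac = float((meta.table["fisher_p"] < 0.05).mean())
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / 2000)
        assert abs(frac - 0.05) <= half_width

    def test_null_conservative_with_fudge(self):
        # the s0 penalty makes reference-distribution p-values conservative:
        # the null flag rate can only fall below alpha, never above
        params = SimParams(seed=11, n_studies=5, genes_per_study=2000, de_fraction=0.0)
        collection, _ = simulate_studies(params)
        _, meta = meta_analyze(collection)
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / 2000)
        assert float((meta.table["fisher_p"] < 0.05).mean()) <= 0.05 + half_width

    def test_monotone_in_effect_size(self):
        # same seed, growing delta: true-positive count never decreases
        for seed in (0, 1, 2):
            tps = []
            for delta in (0.5, 1.0, 1.5):
                params = SimParams(
                    seed=seed, n_studies=5, genes_per_study=500, de_fraction=0.1,
                    effect_size_range=(delta, delta),
                )
                collection, truth = simulate_studies(params)
                _, meta = meta_analyze(collection)
                tps.append(len(set(meta.meta_de_gene_ids) & truth.de_gene_ids))
            assert tps == sorted(tps)

    def test_combine_both_is_intersection(self):
        params = SimParams(seed=4, n_studies=4, genes_per_study=400, de_fraction=0.1)
        collection, _ = simulate_studies(params)
        counts = {}
        for combine in ("fisher", "maxp", "both"):
            _, meta = meta_analyze(collection, MetaDEConfig(combine=combine))
            counts[combine] = set(meta.meta_de_gene_ids)
        assert counts["both"] == counts["fisher"] & counts["maxp"]


# ---------------------------------------------------------------------------
# quantile normalization


class TestQuantileNormalize:
    def _collection(self, matrix):
        matrix = np.asarray(matrix, dtype=float)
        study = ExpressionStudy(
            study_id="s1",
            matrix=matrix,
            gene_ids=[f"g{i}" for i in range(matrix.shape[0])],
            sample_ids=[f"x{i}" for i in range(matrix.shape[1])],
            group=["case", "case", "control", "control"][: matrix.shape[1]],
        )
        other = study.subset_genes(study.gene_ids)
        other.study_id = "s2"
        return StudyCollection([study, other])

    def test_identical_columns_unchanged(self):
        col = [1.0, 3.0, 2.0, 5.0, 4.0]
        matrix = np.column_stack([col] * 4)
        out = quantile_normalize(self._collection(matrix))
        np.testing.assert_allclose(out[0].matrix, matrix)

    def test_column_means_equal(self, rng):
        matrix = rng.normal(size=(50, 4))
        out = quantile_normalize(self._collection(matrix))
        means = out[0].matrix.mean(axis=0)
        np.testing.assert_allclose(means, means[0], atol=1e-9)

    def test_matches_brute_force_oracle_with_ties(self):
        matrix = np.array(
            [
                [2.0, 4.0, 4.0, 5.0],
                [5.0, 14.0, 4.0, 7.0],
                [4.0, 8.0, 6.0, 9.0],
                [3.0, 8.0, 5.0, 8.0],
                [3.0, 9.0, 3.0, 5.0],
            ]
        )
        out = quantile_normalize(self._collection(matrix))
        np.testing.assert_allclose(out[0].matrix, quantile_normalize_oracle(matrix), rtol=1e-12)

    def test_matches_oracle_random(self, rng):
        for _ in range(20):
            matrix = rng.integers(0, 6, size=(8, 4)).astype(float)
            out = quantile_normalize(self._collection(matrix))
            np.testing.assert_allclose(
                out[0].matrix, quantile_normalize_oracle(matrix), rtol=1e-12
            )
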