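"""ssGSEA scoring, normalization, cytolytic activity and feature assembly."""

import numpy as np
import pandas as pd
import pytest

from immunemap import panels
from immunemap.scoring import (
    FeatureMatrix,
    SsgseaParams,
    assemble_features,
    cytolytic_activity,
    normalize_scores,
    poplar_panel,
    ssgsea_matrix,
    ssgsea_score,
)
from immunemap.types import ExpressionMatrix, GeneSetCollection, ValidationError
from conftest import random_expression


def oracle_ssgsea(values: np.ndarray, genes: list, gene_set: set, alpha: float) -> float:
    """Definitional running-sum ES for one sample, coded as explicit loops."""
    n = len(genes)
    # average-rank ties, rank n = highest expression
    order_asc = sorted(range(n), key=lambda i: (values[i], i))
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order_asc[j + 1]] == values[order_asc[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order_asc[k]] = avg
        i = j + 1
    order_desc = sorted(range(n), key=lambda i: (-values[i], i))
    in_flags = [genes[i] in gene_set for i in order_desc]
    weights = [abs(ranks[i]) ** alpha for i in order_desc]
    denom = sum(w for w, f in zip(weights, in_flags) if f)
    n_out = sum(1 for f in in_flags if not f)
    es = 0.0
    cum_in = cum_out = 0.0
    for w, f in zip(weights, in_flags):
        if f:
            cum_in += w / denom
        else:
            cum_out += 1.0 / n_out
        es += cum_in - cum_out
    return es


class TestSsgsea:
    def test_matches_oracle_on_random_matrices(self, rng):
        for _ in range(10):
            expr = random_expression(rng, 200, 8)
            members = list(rng.choice(expr.genes, size=15, replace=False))
            scores = ssgsea_score(expr, members, SsgseaParams(alpha=0.25))
            for j, sid in enumerate(expr.samples):
                expected = oracle_ssgsea(
                    expr.df.to_numpy()[:, j], expr.genes, set(members), 0.25
                )
                assert scores[sid] == pytest.approx(expected, abs=1e-9)

    def test_rank_invariance_under_monotone_transform(self, rng):
        expr = random_expression(rng, 150, 4)
        members = list(rng.choice(expr.genes, size=12, replace=False))
        base = ssgsea_score(expr, members)
        transformed = ExpressionMatrix(np.exp(expr.df / expr.df.max().max() * 3))
        again = ssgsea_score(transformed, members)
        assert np.allclose(base.to_numpy(), again.to_numpy(), atol=1e-9)

    def test_top_ranked_set_is_extremal(self, rng):
        # the set occupying the highest expression ranks beats random sets
        n = 100
        genes = [f"G{i}" for i in range(n)]
        vals = np.sort(rng.lognormal(1, 1, size=n))[::-1]
        expr = ExpressionMatrix(pd.DataFrame({"S1": vals}, index=genes))
        top = ssgsea_score(expr, genes[:10])["S1"]
        for _ in range(20):
            members = list(rng.choice(genes, size=10, replace=False))
            assert ssgsea_score(expr, members)["S1"] <= top + 1e-12

    def test_empty_overlap_names_set(self, rng):
        expr = random_expression(rng, 30, 3)
        coll = GeneSetCollection({"MYSET": ["NOT_A_GENE"]})
        with pytest.raises(ValidationError, match="MYSET"):
            ssgsea_matrix(expr, coll)


class TestNormalize:
    def test_unity_hand_case(self):
        raw = pd.DataFrame([[2.0, 4.0, 6.0]], index=["f"], columns=list("abc"))
        out = normalize_scores(raw, "unity")
        assert out.loc["f"].tolist() == [0.0, 0.5, 1.0]

    def test_unity_affine_invariance(self, rng):
        raw = pd.DataFrame(rng.normal(size=(5, 8)))
        rescaled = raw * 3.7 - 11.0
        pd.testing.assert_frame_equal(
            normalize_scores(raw, "unity"), normalize_scores(rescaled, "unity")
        )

    def test_zscore_moments(self, rng):
        raw = pd.DataFrame(rng.normal(size=(6, 20)))
        out = normalize_scores(raw, "zscore")
        assert np.allclose(out.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(out.std(axis=1, ddof=0), 1.0, atol=1e-12)

    def test_constant_feature_conventions(self):
        raw = pd.DataFrame([[3.0, 3.0, 3.0]], index=["f"], columns=list("abc"))
        assert normalize_scores(raw, "unity").loc["f"].tolist() == [0.5] * 3
        assert normalize_scores(raw, "zscore").loc["f"].tolist() == [0.0] * 3

    def test_unity_bounded(self, rng):
        out = normalize_scores(pd.DataFrame(rng.normal(size=(7, 9))), "unity")
        assert ((out >= 0) & (out <= 1)).all().all()


class TestCytolytic:
    def _expr(self, gzma, prf1):
        return ExpressionMatrix(
            pd.DataFrame({"S1": [gzma, prf1]}, index=["GZMA", "PRF1"])
        )

    def test_geometric_mean(self):
        assert cytolytic_activity(self._expr(4.0, 9.0), "S1", eps=0.0) == pytest.approx(6.0)

    def test_idempotent_on_equal_inputs(self):
        assert cytolytic_activity(self._expr(7.0, 7.0), "S1", eps=0.0) == pytest.approx(7.0)

    def test_product_form_rank_equivalent(self, rng):
        vals = pd.DataFrame(
            rng.lognormal(2, 1, size=(2, 12)),
            index=["GZMA", "PRF1"],
            columns=[f"S{i}" for i in range(12)],
        )
        expr = ExpressionMatrix(vals)
        geo = cytolytic_activity(expr, form="geometric").rank()
        prod = cytolytic_activity(expr, form="product").rank()
        pd.testing.assert_series_equal(geo, prod, check_names=False)

    def test_missing_gene_raises(self):
        expr = ExpressionMatrix(pd.DataFrame({"S1": [1.0]}, index=["GZMA"]))
        with pytest.raises(ValidationError, match="PRF1"):
            cytolytic_activity(expr)


class TestPoplar:
    def test_all_ones(self):
        df = pd.DataFrame(
            {"S1": [1.0] * 8}, index=list(panels.POPLAR_GENES)
        )
        out = poplar_panel(ExpressionMatrix(df), "S1")
        assert len(out) == 8
        assert np.allclose(out.to_numpy(), 1.0)

    def test_missing_gene_named(self):
        df = pd.DataFrame({"S1": [1.0]}, index=["CD8A"])
        with pytest.raises(ValidationError, match="CXCL9"):
            poplar_panel(ExpressionMatrix(df), "S1")


class TestAssembly:
    def test_278_columns_and_block_sizes(self, small_cohort):
        from immunemap.pipeline import PipelineConfig, per_locus_metrics

        metrics = per_locus_metrics(small_cohort, PipelineConfig())
        fm = assemble_features(
            small_cohort.expression,
            metrics["neoantigen_load"].astype(float),
            metrics["clonality"],
            panels.default_immune_gene_panel(),
            panels.default_pathway_sets(),
            panels.default_cell_type_sets(),
        )
        assert fm.df.shape == (len(small_cohort.expression.samples), 278)
        assert [len(v) for v in fm.blocks.values()] == [1, 1, 31, 217, 28]
        assert not fm.df.isna().any().any()

    def test_wrong_pathway_count_rejected(self, small_cohort):
        pw = panels.default_pathway_sets()
        truncated = GeneSetCollection(
            {k: v for k, v in list(pw.sets.items())[:216]}
        )
        dummy = pd.Series(0.0, index=small_cohort.expression.samples)
        with pytest.raises(ValidationError, match="217"):
            assemble_features(
                small_cohort.expression, dummy, dummy,
                panels.default_immune_gene_panel(), truncated,
                panels.default_cell_type_sets(),
            )

    def test_sample_mismatch_rejected(self, small_cohort):
        dummy = pd.Series(0.0, index=small_cohort.expression.samples[:-1])
        with pytest.raises(ValidationError, match="missing sample"):
            assemble_features(
                small_cohort.expression, dummy, dummy,
                panels.default_immune_gene_panel(),
                panels.default_pathway_sets(),
                panels.default_cell_type_sets(),
            )

    def test_block_order_deterministic(self, small_cohort):
        from immunemap.pipeline import PipelineConfig, per_locus_metrics

        metrics = per_locus_metrics(small_cohort, PipelineConfig())
        args = (
            small_cohort.expression,
            metrics["neoantigen_load"].astype(float),
            metrics["clonality"],
            panels.default_immune_gene_panel(),
            panels.default_pathway_sets(),
            panels.default_cell_type_sets(),
        )
        a, b = assemble_features(*args), assemble_features(*args)
        assert list(a.df.columns) == list(b.df.columns)
        assert (a.df.to_numpy() == b.df.to_numpy()).all()
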