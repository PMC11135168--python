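import numpy as np
import pytest
from scipy import stats

from radpath.activity import (
    SIGMA_FLOOR,
    aggregated_differential_score,
    compute_llr,
    fit_gene_gaussians,
    normalize_llr,
    orient_llr_by_class,
    pathway_activity_scores,
    rank_pathways,
    score_contrast,
)
from radpath.io import (
    DoseClass,
    ExpressionMatrix,
    GeneSetCollection,
    SampleAnnotation,
    assign_dose_class,
)

from conftest import make_study

CONTRAST = (DoseClass.ZERO, DoseClass.LOW)


def _ann(doses):
    return [assign_dose_class(SampleAnnotation(f"s{i}", "d", d)) for i, d in enumerate(doses)]


def _matrix(values, genes=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or tuple(f"g{i}" for i in range(values.shape[0]))
    return ExpressionMatrix(tuple(genes), tuple(f"s{j}" for j in range(values.shape[1])), values)


class TestFitGeneGaussians:
    def test_population_moments_per_class(self):
        m = _matrix([[0.0, 2.0, 5.0, 9.0]])
        ann = _ann([0.0, 0.0, 0.05, 0.05])
        model = fit_gene_gaussians(m, ann, CONTRAST)
        assert model.mu1[0] == pytest.approx(1.0)
        assert model.sd1[0] == pytest.approx(1.0)  # population sd of [0, 2]
        assert model.mu2[0] == pytest.approx(7.0)
        assert model.sd2[0] == pytest.approx(2.0)

    def test_constant_gene_floored_no_nan(self):
        m = _matrix([[5.0, 5.0, 5.0, 5.0]])
        ann = _ann([0.0, 0.0, 0.05, 0.05])
        model = fit_gene_gaussians(m, ann, CONTRAST)
        assert model.sd1[0] == SIGMA_FLOOR
        llr = normalize_llr(compute_llr(model, m), model)
        assert np.all(np.isfinite(llr.values))

    def test_norm_mean_near_zero_for_identical_distributions(self):
        rng = np.random.default_rng(0)
        n = 5000
        m = _matrix(rng.normal(3.0, 1.0, size=(1, 2 * n)))
        ann = _ann([0.0] * n + [0.05] * n)
        model = fit_gene_gaussians(m, ann, CONTRAST)
        assert abs(model.norm_mean[0]) < 0.05

    def test_small_class_rejected(self):
        m = _matrix([[1.0, 2.0, 3.0]])
        ann = _ann([0.0, 0.05, 0.05])
        with pytest.raises(ValueError, match="need >= 2"):
            fit_gene_gaussians(m, ann, CONTRAST)


class TestComputeLLR:
    def _unit_model(self):
        m = _matrix([[0.0]])
        # construct directly: f1 = N(0,1), f2 = N(1,1)
        from radpath.activity import GeneLLRModel

        return GeneLLRModel(
            gene_ids=("g0",), contrast=CONTRAST,
            mu1=np.array([0.0]), sd1=np.array([1.0]),
            mu2=np.array([1.0]), sd2=np.array([1.0]),
            norm_mean=np.array([0.0]), norm_sd=np.array([1.0]),
        )

    @pytest.mark.parametrize("x, expected", [(0.5, 0.0), (0.0, 0.5), (1.0, -0.5)])
    def test_closed_form_and_density_oracle(self, x, expected):
        model = self._unit_model()
        llr = compute_llr(model, _matrix([[x]]))
        assert llr.values[0, 0] == pytest.approx(expected, abs=1e-12)
        oracle = stats.norm.logpdf(x, 0, 1) - stats.norm.logpdf(x, 1, 1)
        assert llr.values[0, 0] == pytest.approx(oracle, abs=1e-12)

    def test_identical_densities_give_zero(self):
        m = _matrix([[1.0, 2.0, 3.0, 4.0]])
        ann = _ann([0.0, 0.0, 0.05, 0.05])
        # both classes share values -> equal fits
        m.values[0, 2:] = m.values[0, :2]
        model = fit_gene_gaussians(m, ann, CONTRAST)
        llr = compute_llr(model, m)
        np.testing.assert_allclose(llr.values, 0.0, atol=1e-12)

    def test_unmodelled_gene_omitted_with_warning(self):
        model = self._unit_model()
        m = _matrix([[0.0], [1.0]], genes=("g0", "gX"))
        with pytest.warns(UserWarning, match="omitted"):
            llr = compute_llr(model, m)
        assert llr.gene_ids == ("g0",)


class TestNormalizeLLR:
    def test_population_moment_normalization(self):
        # gene row [1, 2, 3]: mean 2, population sd sqrt(2/3)
        from radpath.activity import GeneLLRModel, LLRMatrix

        raw = LLRMatrix(("g0",), ("s0", "s1", "s2"), np.array([[1.0, 2.0, 3.0]]))
        model = GeneLLRModel(
            gene_ids=("g0",), contrast=CONTRAST,
            mu1=np.zeros(1), sd1=np.ones(1), mu2=np.zeros(1), sd2=np.ones(1),
            norm_mean=np.array([2.0]), norm_sd=np.array([np.sqrt(2.0 / 3.0)]),
        )
        out = normalize_llr(raw, model)
        np.testing.assert_allclose(out.values, [[-1.2247, 0.0, 1.2247]], atol=1e-4)

    def test_training_moments_zero_mean_unit_power(self, small_study):
        _, gs, m, ann, _ = small_study
        from radpath.activity import contrast_samples

        ids1, ids2 = contrast_samples(ann, CONTRAST)
        sub = m.subset_samples(ids1 + ids2)
        model = fit_gene_gaussians(sub, ann, CONTRAST)
        llr = normalize_llr(compute_llr(model, sub), model)
        np.testing.assert_allclose(llr.values.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose((llr.values**2).mean(axis=1), 1.0, atol=1e-10)

    def test_double_normalization_rejected(self):
        m = _matrix([[1.0, 2.0, 3.0, 4.0]])
        ann = _ann([0.0, 0.0, 0.05, 0.05])
        model = fit_gene_gaussians(m, ann, CONTRAST)
        out = normalize_llr(compute_llr(model, m), model)
        with pytest.raises(ValueError):
            normalize_llr(out, model)

    def test_scale_invariance(self):
        """Scaling a gene's expression by a positive constant leaves
        standardised LLRs unchanged."""
        rng = np.random.default_rng(5)
        vals = rng.normal(0, 1, size=(1, 12))
        vals[0, 6:] += 1.0
        ann = _ann([0.0] * 6 + [0.05] * 6)
        m1 = _matrix(vals)
        m2 = _matrix(vals * 37.5)
        out = []
        for m in (m1, m2):
            model = fit_gene_gaussians(m, ann, CONTRAST)
            out.append(normalize_llr(compute_llr(model, m), model).values)
        np.testing.assert_allclose(out[0], out[1], atol=1e-8)


class TestOrientation:
    def test_sign_flip_only_for_class2(self):
        m = _matrix([[0.7, 0.7, 0.7, 0.7]])
        ann = _ann([0.0, 0.0, 0.05, 0.05])
        model = fit_gene_gaussians(m, ann, CONTRAST)
        from radpath.activity import LLRMatrix

        llr = LLRMatrix(("g0",), tuple(f"s{i}" for i in range(4)), np.full((1, 4), 0.7))
        out = orient_llr_by_class(llr, ann, CONTRAST)
        np.testing.assert_allclose(out.values, [[0.7, 0.7, -0.7, -0.7]])
        again = orient_llr_by_class(out, ann, CONTRAST)
        np.testing.assert_allclose(again.values, llr.values)
        assert not again.class_oriented

    def test_unlabeled_sample_rejected(self):
        from radpath.activity import LLRMatrix

        llr = LLRMatrix(("g0",), ("s0", "sX"), np.zeros((1, 2)))
        ann = _ann([0.0, 0.0])
        with pytest.raises(ValueError, match="sX"):
            orient_llr_by_class(llr, ann, CONTRAST)


class TestPathwayScores:
    def _llr(self, rows, genes):
        from radpath.activity import LLRMatrix

        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        return LLRMatrix(tuple(genes), tuple(f"s{j}" for j in range(rows.shape[1])), rows)

    def test_cancellation_singleton_and_sum(self):
        gs = GeneSetCollection()
        gs.add("pair", "d", ["g0", "g1"])
        gs.add("single", "d", ["g0"])
        llr = self._llr([[0.5], [-0.5]], ["g0", "g1"])
        scores = pathway_activity_scores(llr, gs)
        assert scores.loc["pair", "s0"] == pytest.approx(0.0)
        assert scores.loc["single", "s0"] == pytest.approx(0.5)

    def test_twenty_genes_loop_oracle(self):
        genes = [f"g{i}" for i in range(20)]
        gs = GeneSetCollection()
        gs.add("pw", "d", genes)
        llr = self._llr(np.full((20, 1), 0.1), genes)
        scores = pathway_activity_scores(llr, gs)
        explicit = sum(llr.values[i, 0] for i in range(20))
        assert scores.loc["pw", "s0"] == pytest.approx(2.0) == pytest.approx(explicit)


class TestAggregatedScore:
    def test_textbook_t_statistic(self):
        from radpath.activity import LLRMatrix

        gs = GeneSetCollection()
        gs.add("pw", "d", ["g0"])
        llr = LLRMatrix(("g0",), ("s0", "s1", "s2"), np.array([[1.0, 2.0, 3.0]]))
        table = aggregated_differential_score(llr, gs)
        # mean 2, sample sd 1, n 3 -> t = 2 * sqrt(3)
        assert table.loc["pw", "aggregated_score"] == pytest.approx(3.4641, abs=1e-3)
        oracle = stats.ttest_1samp([1.0, 2.0, 3.0], 0.0).statistic
        assert table.loc["pw", "aggregated_score"] == pytest.approx(oracle)

    def test_zero_llrs_give_zero_score(self):
        from radpath.activity import LLRMatrix

        gs = GeneSetCollection()
        gs.add("pw", "d", ["g0", "g1"])
        with pytest.warns(UserWarning, match="floored"):
            table = aggregated_differential_score(
                LLRMatrix(("g0", "g1"), ("s0", "s1"), np.zeros((2, 2))), gs
            )
        assert table.loc["pw", "aggregated_score"] == 0.0

    def test_absolute_values_average(self):
        from radpath.activity import LLRMatrix

        gs = GeneSetCollection()
        gs.add("pw", "d", ["g0", "g1"])
        # g0: [1,2,3] -> t = +3.46; g1: [-1,-2,-3] -> t = -3.46
        llr = LLRMatrix(("g0", "g1"), ("s0", "s1", "s2"),
                        np.array([[1.0, 2.0, 3.0], [-1.0, -2.0, -3.0]]))
        table = aggregated_differential_score(llr, gs)
        assert table.loc["pw", "aggregated_score"] == pytest.approx(2.0 * np.sqrt(3.0))
        assert table.loc["pw", "pathway_t"] == pytest.approx(0.0)  # S_j cancels

    def test_subset_too_small(self):
        from radpath.activity import LLRMatrix

        gs = GeneSetCollection()
        gs.add("pw", "d", ["g0"])
        llr = LLRMatrix(("g0",), ("s0", "s1"), np.zeros((1, 2)))
        with pytest.raises(ValueError):
            aggregated_differential_score(llr, gs, sample_subset=["s0"])


class TestRankPathways:
    def _table(self, scores, t=None, n=10):
        import pandas as pd

        t = t if t is not None else [1.0] * len(scores)
        return pd.DataFrame(
            {
                "name": ["x"] * len(scores),
                "n_members": [2] * len(scores),
                "aggregated_score": list(scores.values()),
                "pathway_t": t,
                "n_samples": [n] * len(scores),
            },
            index=pd.Index(list(scores), name="pathway_id"),
        )

    def test_descending_sort(self):
        out = rank_pathways(self._table({"A": 2.0, "B": 3.0, "C": 1.0}))
        assert list(out.index) == ["B", "A", "C"]
        assert list(out["rank"]) == [1, 2, 3]

    def test_tie_break_lexicographic(self):
        out = rank_pathways(self._table({"B": 1.0, "A": 1.0}))
        assert list(out.index) == ["A", "B"]

    def test_null_center_p_value_one(self):
        out = rank_pathways(self._table({"A": 1.0}, t=[0.0], n=10))
        assert out.loc["A", "p_value"] == pytest.approx(1.0)

    def test_p_values_match_student_t(self):
        out = rank_pathways(self._table({"A": 1.0}, t=[2.5], n=10))
        assert out.loc["A", "p_value"] == pytest.approx(2 * stats.t.sf(2.5, 9))


class TestNaiveBayesEquivalence:
    def test_unnormalized_summed_llr_matches_nbm(self):
        """The sign of the raw summed LLR equals the decision of an
        equal-prior Gaussian naive Bayes classifier."""
        rng = np.random.default_rng(123)
        for _ in range(50):
            n_genes, n1, n2 = 5, 5, 5
            x1 = rng.normal(0, 1, size=(n_genes, n1))
            x2 = rng.normal(rng.normal(0, 1, size=(n_genes, 1)), 1, size=(n_genes, n2))
            m = _matrix(np.hstack([x1, x2]))
            ann = _ann([0.0] * n1 + [0.05] * n2)
            model = fit_gene_gaussians(m, ann, CONTRAST)
            llr = compute_llr(model, m)  # raw: no normalization, no orientation
            s = llr.values.sum(axis=0)

            # independent oracle: explicit naive Bayes with equal priors
            log_post1 = stats.norm.logpdf(m.values, model.mu1[:, None], model.sd1[:, None]).sum(axis=0)
            log_post2 = stats.norm.logpdf(m.values, model.mu2[:, None], model.sd2[:, None]).sum(axis=0)
            nbm_choice = log_post1 > log_post2
            np.testing.assert_array_equal(s > 0, nbm_choice)


class TestScoreContrast:
    def test_planted_pathways_rank_top(self, small_study):
        _, gs, m, ann, truth = small_study
        table = score_contrast(m, ann, gs, CONTRAST)
        top = set(table.index[: len(truth.low_responsive)])
        assert top == set(truth.low_responsive)

    def test_permutation_null_is_calibrated(self):
        """With permuted labels, planted and background pathways have
        indistinguishable aggregated scores."""
        rng = np.random.default_rng(9)
        _, gs, m, ann, truth = make_study(n_genes=300, n_pathways=20, seed=11)
        doses = np.array([a.dose_gy for a in ann])
        resp_scores, null_scores = [], []
        for _ in range(8):
            perm = rng.permutation(len(ann))
            shuffled = [
                type(a)(a.sample_id, a.donor_id, float(doses[perm[i]]), None)
                for i, a in enumerate(ann)
            ]
            from radpath.io import assign_dose_class

            shuffled = [assign_dose_class(a) for a in shuffled]
            table = score_contrast(m, shuffled, gs, CONTRAST)
            resp = truth.low_responsive
            resp_scores.extend(table.loc[list(resp), "aggregated_score"])
            null_scores.extend(
                table.loc[[p for p in table.index if p not in resp], "aggregated_score"]
            )
        ks = stats.ks_2samp(resp_scores, null_scores)
        assert ks.pvalue > 0.01
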