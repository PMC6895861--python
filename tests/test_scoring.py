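import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from sigscore import (
    CohortZScorer,
    GeneSet,
    SignatureDefinition,
    SignatureScorer,
    compute_zscores,
    dichotomize_gene,
    rank_and_segregate,
    score_all,
    score_signature,
)


def make_zres(values: np.ndarray, genes=None, samples=None):
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    expr = pd.DataFrame(values, index=genes, columns=samples)
    return compute_zscores(expr, log_transform=False)


class TestCohortZScores:
    def test_simple_row_standardizes_to_unit_steps(self):
        zres = make_zres(np.array([[1.0, 2.0, 3.0]]))
        # mean 2, sample sd (n-1) = 1
        assert np.allclose(zres.z.to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_constant_row_is_flagged_degenerate_and_zero(self):
        zres = make_zres(np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]]))
        assert bool(zres.degenerate.iloc[0])
        assert np.all(zres.z.iloc[0].to_numpy() == 0.0)
        assert not bool(zres.degenerate.iloc[1])

    def test_random_matrix_rows_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        zres = make_zres(rng.lognormal(size=(50, 20)))
        z = zres.z.to_numpy()
        assert np.abs(z.mean(axis=1)).max() < 1e-10
        assert np.abs(z.std(axis=1, ddof=1) - 1).max() < 1e-8

    def test_log_transform_changes_standardization_scale(self):
        expr = pd.DataFrame([[1.0, 3.0, 7.0]], index=["g"], columns=list("abc"))
        with_log = compute_zscores(expr, log_transform=True)
        manual = np.log2(expr.to_numpy() + 1)
        expected = (manual - manual.mean()) / manual.std(ddof=1)
        assert np.allclose(with_log.z.to_numpy(), expected)

    def test_single_sample_rejected(self):
        expr = pd.DataFrame([[1.0]], index=["g"], columns=["s"])
        with pytest.raises(ValueError, match="2 samples"):
            compute_zscores(expr)

    def test_sklearn_estimator_round_trip_and_out_of_cohort_guard(self, tiny_expr):
        X = tiny_expr.T  # samples x genes
        scorer = CohortZScorer(log_transform=False).fit(X)
        z = scorer.transform(X)
        assert z.shape == X.shape
        held_out = X.iloc[:2].rename(index={"s1": "new1", "s2": "new2"})
        with pytest.raises(ValueError, match="outside the fitted cohort"):
            scorer.transform(held_out)
        scorer_ok = CohortZScorer(log_transform=False, allow_out_of_cohort=True).fit(X)
        assert scorer_ok.transform(held_out).shape == (2, 3)

    def test_get_params_round_trip(self):
        scorer = CohortZScorer(log_transform=False, ddof=0)
        clone = CohortZScorer(**scorer.get_params())
        assert clone.get_params() == scorer.get_params()


class TestSignatureScores:
    def test_up_minus_down_on_known_z(self):
        zres = make_zres(np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]]))
        sig = SignatureDefinition(
            "s", GeneSet("u", ("g0",)), GeneSet("d", ("g1",))
        )
        score, cov = score_signature(zres, sig)
        # z(g0) = [-1,0,1], z(g1) = [1,0,-1] -> score = [-2, 0, 2]
        assert np.allclose(score.to_numpy(), [-2.0, 0.0, 2.0])
        assert cov == 1.0

    def test_one_sided_signature_is_plain_z_sum(self, small_cohort):
        zres = compute_zscores(small_cohort.expression)
        stat3 = next(s for s in small_cohort.signatures if s.name == "STAT3")
        assert stat3.down_set is None
        score, cov = score_signature(zres, stat3)
        expected = zres.z.loc[list(stat3.up_set.genes)].sum(axis=0)
        assert np.allclose(score.to_numpy(), expected.to_numpy())
        assert cov == 1.0

    def test_swapping_up_and_down_negates_scores(self, small_cohort):
        zres = compute_zscores(small_cohort.expression)
        sig = next(s for s in small_cohort.signatures if s.name == "SLUG_OE")
        swapped = SignatureDefinition(
            name="swapped", up_set=sig.down_set, down_set=sig.up_set
        )
        s1, _ = score_signature(zres, sig)
        s2, _ = score_signature(zres, swapped)
        assert np.allclose(s1.to_numpy(), -s2.to_numpy())

    def test_zero_overlap_raises_naming_signature(self, small_cohort):
        zres = compute_zscores(small_cohort.expression)
        sig = SignatureDefinition("ghost", GeneSet("u", ("NOPE1", "NOPE2")))
        with pytest.raises(ValueError, match="ghost"):
            score_signature(zres, sig)

    def test_missing_genes_reduce_coverage_not_crash(self, small_cohort):
        zres = compute_zscores(small_cohort.expression)
        stat3 = next(s for s in small_cohort.signatures if s.name == "STAT3")
        padded = SignatureDefinition(
            "padded", GeneSet("u", stat3.up_set.genes + ("ABSENT",))
        )
        score, cov = score_signature(zres, padded)
        base, _ = score_signature(zres, stat3)
        assert np.allclose(score.to_numpy(), base.to_numpy())
        assert cov == pytest.approx(len(stat3.up_set) / (len(stat3.up_set) + 1))

    def test_score_table_columns_sum_to_zero_on_cohort(self, small_cohort):
        zres = compute_zscores(small_cohort.expression)
        table = score_all(zres, small_cohort.signatures)
        assert list(table.scores.columns) == [s.name for s in small_cohort.signatures]
        n = small_cohort.expression.shape[1]
        for sig in small_cohort.signatures:
            tol = 1e-8 * len(sig) * n
            assert abs(table.scores[sig.name].sum()) < tol

    def test_degenerate_gene_insertion_is_a_noop(self):
        rng = np.random.default_rng(3)
        values = rng.lognormal(size=(6, 8))
        zres = make_zres(values)
        sig = SignatureDefinition(
            "s", GeneSet("u", ("g0", "g1")), GeneSet("d", ("g2",))
        )
        base, _ = score_signature(zres, sig)
        with_const = np.vstack([values, np.full((1, 8), 7.0)])
        zres2 = make_zres(with_const, genes=[f"g{i}" for i in range(7)])
        sig2 = SignatureDefinition(
            "s", GeneSet("u", ("g0", "g1", "g6")), GeneSet("d", ("g2",))
        )
        augmented, _ = score_signature(zres2, sig2)
        assert np.allclose(base.to_numpy(), augmented.to_numpy())

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        values=arrays(
            float,
            (5, 6),
            elements=st.floats(0.1, 1e4, allow_nan=False),
        ),
        perm_seed=st.integers(0, 2**16),
    )
    def test_scores_invariant_to_gene_and_sample_permutation(self, values, perm_seed):
        zres = make_zres(values)
        sig = SignatureDefinition(
            "s", GeneSet("u", ("g0", "g3")), GeneSet("d", ("g1", "g4"))
        )
        base, _ = score_signature(zres, sig)
        rng = np.random.default_rng(perm_seed)
        gperm = rng.permutation(5)
        sperm = rng.permutation(6)
        permuted = pd.DataFrame(
            values[np.ix_(gperm, sperm)],
            index=[f"g{i}" for i in gperm],
            columns=[f"s{j}" for j in sperm],
        )
        zperm = compute_zscores(permuted, log_transform=False)
        permuted_score, _ = score_signature(zperm, sig)
        assert np.allclose(
            base.loc[permuted_score.index].to_numpy(), permuted_score.to_numpy()
        )

    def test_increasing_an_up_gene_strictly_increases_that_sample_score(self):
        rng = np.random.default_rng(11)
        values = rng.lognormal(size=(4, 6))
        sig = SignatureDefinition("s", GeneSet("u", ("g0",)), GeneSet("d", ("g2",)))
        base, _ = score_signature(make_zres(values), sig)
        bumped = values.copy()
        bumped[0, 2] *= 4.0  # raise one up-set gene in sample s2
        bumped_score, _ = score_signature(make_zres(bumped), sig)
        assert bumped_score.iloc[2] > base.iloc[2]

    def test_signature_scorer_estimator_matches_function_layer(self, small_cohort):
        X = small_cohort.expression.T
        est = SignatureScorer(signatures=small_cohort.signatures).fit(X)
        scores = est.transform(X)
        zres = compute_zscores(small_cohort.expression)
        table = score_all(zres, small_cohort.signatures)
        pd.testing.assert_frame_equal(scores, table.scores)
        assert (est.coverage_ == 1.0).all()


class TestRankingAndDichotomization:
    def test_ranking_and_threshold_labels(self):
        scores = pd.Series([3.0, -1.0, 0.5], index=["s1", "s2", "s3"])
        order, labels = rank_and_segregate(scores, threshold=0.0)
        assert order == ["s1", "s3", "s2"]
        assert labels.tolist() == ["high", "low", "high"]

    def test_all_negative_scores_all_low(self):
        scores = pd.Series([-3.0, -0.1], index=["a", "b"])
        _, labels = rank_and_segregate(scores)
        assert (labels == "low").all()

    def test_tie_at_threshold_goes_low(self):
        scores = pd.Series([0.0, 1.0], index=["a", "b"])
        _, labels = rank_and_segregate(scores, threshold=0.0)
        assert labels["a"] == "low"

    def test_dichotomize_gene_threshold(self):
        expr = pd.DataFrame(
            [np.array([-2.0, 0.0, 1.5]) + 10.0], index=["g"], columns=list("abc")
        )
        zres = compute_zscores(expr, log_transform=False)
        # choose the threshold matching the constructed z values
        z = zres.z.loc["g"]
        labels = dichotomize_gene(zres, "g", z_threshold=float(z["c"]) - 1e-9)
        assert labels.tolist() == ["low", "low", "high"]

    def test_very_low_threshold_marks_everything_high(self, small_cohort):
        zres = compute_zscores(small_cohort.expression)
        gene = small_cohort.expression.index[0]
        labels = dichotomize_gene(zres, gene, z_threshold=-1e6)
        assert (labels == "high").all()

    def test_degenerate_gene_rejected(self):
        expr = pd.DataFrame(
            [[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]], index=["flat", "ok"], columns=list("abc")
        )
        zres = compute_zscores(expr, log_transform=False)
        with pytest.raises(ValueError, match="zero cohort variance"):
            dichotomize_gene(zres, "flat")

    def test_normal_tail_fraction_above_one_sd(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(
            rng.normal(size=(1, 10_000)) + 100.0,
            index=["g"],
            columns=[f"s{i}" for i in range(10_000)],
        )
        zres = compute_zscores(expr, log_transform=False)
        labels = dichotomize_gene(zres, "g", z_threshold=1.0)
        frac = (labels == "high").mean()
        assert frac == pytest.approx(0.159, abs=0.01)
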