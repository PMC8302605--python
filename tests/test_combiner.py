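import numpy as np
import pandas as pd
import pytest
from scipy import stats

from deconsensus import (
    CombineConfig,
    DEResult,
    NOT_DEG,
    POSSIBLE,
    PREVALENT,
    combine_results,
    fisher_combine,
    fisher_combine_matrix,
    mean_logfc,
    nb_train,
    vote_tag,
)
from deconsensus.combine import NBModel, nb_features


def chi2_sf_even_df(x, k):
    """Chi-square survival for even df 2k via the closed-form Poisson series."""
    half = x / 2.0
    term, total = 1.0, 1.0
    for j in range(1, k):
        term *= half / j
        total += term
    return np.exp(-half) * total


def _result(name, genes, logfc, fdr, pvalue=None):
    return DEResult(name, pd.DataFrame({
        "logfc": logfc,
        "pvalue": pvalue if pvalue is not None else fdr,
        "fdr": fdr,
    }, index=genes))


class TestVoteTag:
    GENES = ["G1", "G2", "G3"]

    def _methods(self, call_matrix):
        # call -> fdr 0.001 & |logfc| 2 ; no-call -> fdr 0.9 & logfc 0
        out = []
        for i, calls in enumerate(call_matrix):
            out.append(_result(
                f"m{i}", self.GENES,
                [2.0 if c else 0.0 for c in calls],
                [0.001 if c else 0.9 for c in calls],
            ))
        return out

    def test_prevalent_when_votes_reach_threshold(self):
        # G1 called by 3 of 4 methods, min_votes 2 -> PREVALENT
        methods = self._methods([[1, 0, 0], [1, 0, 0], [1, 0, 0], [0, 0, 0]])
        tags = vote_tag(methods, CombineConfig(min_votes=2))
        assert tags.loc["G1", "votes"] == 3
        assert tags.loc["G1", "tag"] == PREVALENT

    def test_possible_when_below_threshold(self):
        methods = self._methods([[1, 0, 0], [0, 0, 0], [0, 0, 0]])
        tags = vote_tag(methods, CombineConfig(min_votes=3))
        assert tags.loc["G1", "tag"] == POSSIBLE
        assert tags.loc["G2", "tag"] == NOT_DEG

    def test_call_requires_both_criteria(self):
        # significant FDR but |logfc| below the cutoff -> not a call
        methods = [_result("m0", self.GENES, [0.5, 0.5, 0.5], [0.01, 0.01, 0.01])]
        tags = vote_tag(methods, CombineConfig(min_votes=1))
        assert (tags["votes"] == 0).all()
        assert (tags["tag"] == NOT_DEG).all()

    def test_mismatched_gene_sets_rejected(self):
        a = _result("a", ["G1", "G2"], [1, 1], [0.5, 0.5])
        b = _result("b", ["G1", "G3"], [1, 1], [0.5, 0.5])
        with pytest.raises(ValueError, match="symmetric difference"):
            vote_tag([a, b], CombineConfig())

    def test_min_votes_above_method_count_warns(self):
        methods = self._methods([[1, 0, 0]])
        with pytest.warns(UserWarning, match="PREVALENT"):
            vote_tag(methods, CombineConfig(min_votes=5))

    def test_prevalent_sets_nested_in_threshold(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(200)]
        methods = [
            _result(f"m{i}", genes,
                    rng.uniform(-3, 3, 200), rng.uniform(0, 1, 200))
            for i in range(4)
        ]
        prev = []
        for t in range(1, 5):
            tags = vote_tag(methods, CombineConfig(min_votes=t))
            prev.append(set(tags.index[tags["tag"] == PREVALENT]))
        for lo, hi in zip(prev[1:], prev[:-1]):
            assert lo <= hi


class TestFisherCombine:
    def test_all_ones(self):
        assert fisher_combine([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_single_value_identity(self):
        assert fisher_combine([0.05]) == pytest.approx(0.05)

    def test_three_value_example(self):
        # X^2 = -2(ln .01 + ln .02 + ln .03) = 24.048, df 6
        expected = chi2_sf_even_df(
            -2 * (np.log(0.01) + np.log(0.02) + np.log(0.03)), 3
        )
        assert expected == pytest.approx(5.12e-4, rel=0.01)
        assert fisher_combine([0.01, 0.02, 0.03]) == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_inputs(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            v = rng.uniform(0.01, 1.0, size=4)
            base = fisher_combine(v)
            w = v.copy()
            w[rng.integers(4)] *= 0.5
            assert fisher_combine(w) <= base + 1e-15

    def test_matches_series_oracle_random(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            k = int(rng.integers(1, 6))
            v = rng.uniform(1e-6, 1.0, size=k)
            ours = fisher_combine(v)
            oracle = chi2_sf_even_df(-2 * np.log(v).sum(), k)
            assert ours == pytest.approx(oracle, abs=1e-10)

    def test_matrix_form_agrees(self):
        rng = np.random.default_rng(3)
        fdr = pd.DataFrame(rng.uniform(0.001, 1, size=(50, 3)),
                           index=[f"G{i}" for i in range(50)])
        rowwise = fisher_combine_matrix(fdr)
        for g in fdr.index[:10]:
            assert rowwise[g] == pytest.approx(fisher_combine(fdr.loc[g]), abs=1e-12)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            fisher_combine([])
        with pytest.raises(ValueError):
            fisher_combine([0.5, 1.5])


class TestMeanLogfc:
    @pytest.mark.parametrize("values, expected", [
        ((2.0, 2.0, 2.0), 2.0),
        ((1.0, -1.0), 0.0),
        # the published outlier gene: three methods reported -23.5, -8.8, -2.6
        ((-23.5, -8.8, -2.6), -11.633333333333333),
    ])
    def test_examples(self, values, expected):
        assert mean_logfc(values) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_logfc([])


def _separable_training(n=200, methods=("a", "b", "c")):
    genes = [f"G{i}" for i in range(n)]
    is_deg = pd.Series([i < n // 4 for i in range(n)], index=genes)
    p = pd.DataFrame(
        {m: np.where(is_deg, 1e-6, 0.5) for m in methods}, index=genes
    )
    # tiny jitter so class variances are nonzero
    rng = np.random.default_rng(0)
    p = p * rng.uniform(0.9, 1.1, size=p.shape)
    return p, is_deg


class TestNaiveBayes:
    def test_separable_training_classified_correctly(self):
        t1 = _separable_training()
        t2 = _separable_training(100)
        model = nb_train([t1, t2])
        post, call = model.predict(t1[0])
        assert (call == t1[1]).all()
        assert (post[t1[1]] > 0.99).all()

    def test_uninformative_features_posterior_near_prior(self):
        rng = np.random.default_rng(4)
        genes = [f"G{i}" for i in range(400)]
        labels = pd.Series(rng.uniform(size=400) < 0.3, index=genes)
        p = pd.DataFrame({m: rng.uniform(size=400) for m in ("a", "b")},
                         index=genes)
        model = nb_train([(p, labels), (p, labels)])
        post, _ = model.predict(p)
        assert post.mean() == pytest.approx(model.prior_deg, abs=0.1)

    def test_feature_order_is_supplied_order(self):
        t = _separable_training(methods=("z", "a", "m"))
        model = nb_train([t, t])
        assert model.method_names == ["z", "a", "m"]

    def test_method_mismatch_rejected(self):
        t = _separable_training()
        model = nb_train([t, t])
        bad = t[0].rename(columns={"a": "x"})
        with pytest.raises(ValueError, match="expects"):
            model.predict(bad)

    def test_single_class_rejected(self):
        p, labels = _separable_training()
        all_true = pd.Series(True, index=labels.index)
        with pytest.raises(ValueError, match="both"):
            nb_train([(p, all_true), (p, all_true)])

    def test_needs_two_datasets(self):
        t = _separable_training()
        with pytest.raises(ValueError, match=">= 2"):
            nb_train([t])

    def test_midpoint_of_symmetric_classes(self):
        model = NBModel(
            method_names=["a"], prior_deg=0.5, prior_non=0.5,
            mean_deg=np.array([4.0]), var_deg=np.array([1.0]),
            mean_non=np.array([2.0]), var_non=np.array([1.0]),
        )
        # feature 3.0 is the midpoint: p = 10**-3
        post, _ = model.predict(pd.DataFrame({"a": [1e-3]}, index=["G1"]))
        assert post.iloc[0] == pytest.approx(0.5, abs=1e-9)

    def test_posterior_monotone_when_means_ordered(self):
        t1 = _separable_training()
        model = nb_train([t1, _separable_training(100)])
        assert (model.mean_deg > model.mean_non).all()
        ps = np.logspace(-8, -0.1, 25)
        for m_idx, name in enumerate(model.method_names):
            frame = pd.DataFrame(
                {m: np.full(25, 0.3) for m in model.method_names},
                index=[f"G{i}" for i in range(25)],
            )
            frame[name] = ps
            post, _ = model.predict(frame)
            assert (np.diff(post.to_numpy()) <= 1e-12).all()

    def test_matches_sklearn_gaussian_nb(self):
        """Independent oracle: sklearn GaussianNB on the same features."""
        from sklearn.naive_bayes import GaussianNB

        rng = np.random.default_rng(5)
        genes = [f"G{i}" for i in range(500)]
        labels = pd.Series(rng.uniform(size=500) < 0.2, index=genes)
        p = pd.DataFrame(
            {m: np.where(labels, rng.uniform(1e-8, 1e-2, 500),
                         rng.uniform(0.01, 1.0, 500)) for m in ("a", "b", "c")},
            index=genes,
        )
        model = nb_train([(p, labels), (p, labels)])
        post, _ = model.predict(p)
        x = nb_features(p.to_numpy())
        clf = GaussianNB(var_smoothing=0.0).fit(np.vstack([x, x]),
                                                np.concatenate([labels, labels]))
        ref = clf.predict_proba(x)[:, list(clf.classes_).index(True)]
        assert np.allclose(post, ref, atol=1e-6)

    def test_serialization_round_trip(self, tmp_path):
        t = _separable_training()
        model = nb_train([t, t], metadata={"evidence": "pvalue"})
        path = tmp_path / "model.tsv"
        model.to_file(path)
        back = NBModel.from_file(path)
        assert back.method_names == model.method_names
        assert back.metadata["evidence"] == "pvalue"
        assert np.allclose(back.mean_deg, model.mean_deg)
        post_a, _ = model.predict(t[0])
        post_b, _ = back.predict(t[0])
        assert np.allclose(post_a, post_b)


class TestCombineResults:
    def test_full_table_fields(self):
        genes = ["G1", "G2"]
        a = _result("a", genes, [2.0, 0.1], [0.001, 0.8])
        b = _result("b", genes, [1.0, -0.1], [0.02, 0.9])
        out = combine_results([a, b], CombineConfig(min_votes=2))
        assert out.loc["G1", "votes"] == 2
        assert out.loc["G1", "combined_logfc"] == pytest.approx(1.5)
        assert out.loc["G1", "combined_fdr"] == pytest.approx(
            fisher_combine([0.001, 0.02]))
        assert bool(out.loc["G1", "combined_call"])
        assert not bool(out.loc["G2", "combined_call"])
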