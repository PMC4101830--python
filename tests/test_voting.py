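"""Weighted-voting gene signature: statistics, model building, classification."""

import numpy as np
import pandas as pd
import pytest

from prosmark.synthetic import ExpressionSimConfig, ExpressionStudy, simulate_expression_studies
from prosmark.voting import (
    VotingModel,
    build_model,
    classify,
    collapse_probes,
    compute_sx,
    evaluate_models,
    normalize_study,
    rank_genes,
    select_top_informative,
    train_voting_model,
    weighted_average_sx,
)


def _study(matrix, labels, name="s"):
    cols = list(matrix.columns)
    return ExpressionStudy(name=name, matrix=matrix,
                           labels=pd.Series(labels, index=cols))


def _toy_study(name="toy"):
    # 3 genes x 6 samples: first 3 aggressive, last 3 non-aggressive
    data = pd.DataFrame(
        {
            "a1": [0.0, 1.0, 5.0], "a2": [-1.0, 1.5, 5.0], "a3": [1.0, 0.5, 5.0],
            "n1": [2.0, 1.2, 5.0], "n2": [3.0, 0.8, 5.0], "n3": [1.0, 1.0, 5.0],
        },
        index=["g1", "g2", "g3"],
    )
    labels = ["aggressive"] * 3 + ["non_aggressive"] * 3
    return _study(data, labels, name)


class TestSx:
    def test_direct_arithmetic(self):
        # mu_NA=2, mu_A=0, sd_NA=sd_A=1 -> sx = 1.0
        m = pd.DataFrame(
            {"a1": [-1.0], "a2": [1.0], "n1": [1.0], "n2": [3.0]}, index=["g"]
        )
        st = _study(m, ["aggressive", "aggressive", "non_aggressive",
                        "non_aggressive"])
        sx = compute_sx(st)
        sd = np.std([-1.0, 1.0], ddof=1)
        assert sx["g"] == pytest.approx((2.0 - 0.0) / (sd + sd))

    def test_antisymmetry_under_label_swap(self):
        st = _toy_study()
        swapped = _study(
            st.matrix,
            ["non_aggressive" if l == "aggressive" else "aggressive"
             for l in st.labels],
        )
        assert np.allclose(compute_sx(st).values, -compute_sx(swapped).values)

    def test_constant_gene_zero_with_warning(self):
        st = _toy_study()
        with pytest.warns(UserWarning, match="zero pooled SD"):
            sx = compute_sx(st)
        assert sx["g3"] == 0.0


class TestProbesAndSelection:
    def test_collapse_identity_and_mean(self):
        m = pd.DataFrame({"s1": [1.0, 3.0, 5.0]}, index=["p1", "p2", "p3"])
        out = collapse_probes(m, {"p1": "gA", "p2": "gA", "p3": "gB"})
        assert out.loc["gA", "s1"] == 2.0
        assert out.loc["gB", "s1"] == 5.0
        perm = collapse_probes(m.iloc[::-1], {"p1": "gA", "p2": "gA", "p3": "gB"})
        pd.testing.assert_frame_equal(out.sort_index(), perm.sort_index())

    def test_unmapped_probe_raises(self):
        m = pd.DataFrame({"s1": [1.0]}, index=["p1"])
        with pytest.raises(ValueError, match="without gene mapping"):
            collapse_probes(m, {})

    def test_top_informative_extremes(self):
        sx = pd.Series([2.0, 1.0, -1.0, -3.0], index=["gA", "gB", "gC", "gD"])
        assert select_top_informative(sx, n_each=1) == {"gA", "gD"}
        assert len(select_top_informative(sx, n_each=2)) == 4
        with pytest.raises(ValueError, match="genes"):
            select_top_informative(sx, n_each=3)


class TestWeightedAverage:
    def test_quoted_arithmetic(self):
        sx = {"A": pd.Series({"g": 1.0}), "B": pd.Series({"g": 0.5})}
        w = weighted_average_sx(sx, {"A": 21, "B": 58})
        assert w["g"] == pytest.approx((21 * 1.0 + 58 * 0.5) / 79)

    def test_equal_values_fixed_point(self):
        sx = {"A": pd.Series({"g": 0.7}), "B": pd.Series({"g": 0.7})}
        assert weighted_average_sx(sx, {"A": 10, "B": 30})["g"] == pytest.approx(0.7)

    def test_single_study_reduces_to_sx(self):
        st = _toy_study()
        sx = compute_sx(st)
        w = weighted_average_sx({st.name: sx}, {st.name: st.n_samples})
        assert np.allclose(w.loc[sx.index].values, sx.values)

    def test_zero_sample_size_rejected(self):
        sx = {"A": pd.Series({"g": 1.0}), "B": pd.Series({"g": 0.5})}
        with pytest.raises(ValueError, match="sample size"):
            weighted_average_sx(sx, {"A": 21, "B": 0})


class TestModelAndClassify:
    def test_single_gene_vote(self):
        model = VotingModel(
            genes=["g"], weighted_sx=pd.Series({"g": 1.0}),
            boundaries=pd.Series({"g": 1.0}),
        )
        res = classify(model, pd.Series({"g": 2.0}))
        assert res["votes"]["g"] == pytest.approx(1.0)
        assert res["V"] == pytest.approx(1.0)
        assert res["label"] == "non_aggressive"

    def test_sign_rule_and_indeterminate(self):
        model = VotingModel(
            genes=["g1", "g2"],
            weighted_sx=pd.Series({"g1": 1.0, "g2": -0.4}),
            boundaries=pd.Series({"g1": 0.0, "g2": 0.0}),
        )
        res = classify(model, pd.Series({"g1": 1.0, "g2": 1.0}))
        assert res["V"] == pytest.approx(0.6)
        assert res["label"] == "non_aggressive"
        res0 = classify(model, pd.Series({"g1": 0.0, "g2": 0.0}))
        assert res0["label"] == "indeterminate"

    def test_double_negation_invariance(self):
        model = VotingModel(
            genes=["g"], weighted_sx=pd.Series({"g": -0.8}),
            boundaries=pd.Series({"g": 0.2}),
        )
        flipped = VotingModel(
            genes=["g"], weighted_sx=pd.Series({"g": 0.8}),
            boundaries=pd.Series({"g": -0.2}),
        )
        assert classify(model, pd.Series({"g": 0.9}))["V"] == pytest.approx(
            classify(flipped, pd.Series({"g": -0.9}))["V"]
        )

    def test_gene_order_invariance(self):
        wsx = pd.Series({"g1": 0.5, "g2": -0.3})
        b = pd.Series({"g1": 0.0, "g2": 0.0})
        m1 = VotingModel(genes=["g1", "g2"], weighted_sx=wsx, boundaries=b)
        m2 = VotingModel(genes=["g2", "g1"], weighted_sx=wsx, boundaries=b)
        sample = pd.Series({"g1": 1.1, "g2": 0.4})
        assert classify(m1, sample)["V"] == pytest.approx(classify(m2, sample)["V"])

    def test_missing_genes_skipped_or_error(self):
        model = VotingModel(
            genes=["g1", "g2"],
            weighted_sx=pd.Series({"g1": 1.0, "g2": 1.0}),
            boundaries=pd.Series({"g1": 0.0, "g2": 0.0}),
        )
        res = classify(model, pd.Series({"g1": 2.0}))
        assert res["skipped_genes"] == ["g2"]
        with pytest.raises(ValueError, match="no model genes"):
            classify(model, pd.Series({"other": 1.0}))

    def test_build_model_sizes_and_bounds(self):
        ranked = rank_genes(pd.Series({"g1": 1.0, "g2": -2.0, "g3": 0.5}))
        assert list(ranked.index) == ["g2", "g1", "g3"]
        m = build_model(ranked, 1)
        assert m.genes == ["g2"]
        with pytest.raises(ValueError, match="exceeds"):
            build_model(ranked, 7)


class TestEvaluate:
    def test_perfect_separation_accuracy_one(self):
        cfg = ExpressionSimConfig(seed=2, n_genes=60, effect_size=8.0,
                                  n_signal_genes=5, train_sizes=(20,),
                                  validation_size=12)
        studies, _ = simulate_expression_studies(cfg)
        model, ranked = train_voting_model(
            [s for s in studies if s.role == "training"], n_each=30, n_genes=5
        )
        out = evaluate_models([normalize_study(s) for s in studies], ranked,
                              n_range=[5])
        assert (out["accuracy"] == 1.0).all()

    def test_permuted_labels_near_chance(self):
        cfg = ExpressionSimConfig(seed=3, n_genes=200, effect_size=2.0,
                                  n_signal_genes=8, train_sizes=(30, 30),
                                  validation_size=40)
        studies, _ = simulate_expression_studies(cfg)
        rng = np.random.default_rng(0)
        val = studies[-1]
        permuted = ExpressionStudy(
            name=val.name,
            matrix=val.matrix,
            labels=pd.Series(rng.permutation(val.labels.values),
                             index=val.labels.index),
            role="validation",
        )
        model, ranked = train_voting_model(studies[:-1], n_each=100, n_genes=8)
        out = evaluate_models([normalize_study(permuted)], ranked, n_range=[8])
        assert 0.2 <= out["accuracy"].iloc[0] <= 0.8
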