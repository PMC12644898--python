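"""Shapley attribution correctness: the efficiency, dummy and symmetry
axioms, and agreement between tree explanations and the brute-force
subset-enumeration oracle."""

import numpy as np
import pandas as pd
import pytest
import xgboost as xgb

from motifbag.gbt_models import TrainConfig, predict, train
from motifbag.shap_interpret import (exact_shapley, explain, local_explanation,
                                     rank_motifs, ExplanationMatrix)


def margin_fn(bundle, key="model"):
    booster = bundle.boosters[key]
    best = bundle.best_iterations.get(key)
    it = (0, best + 1) if best is not None else None

    def f(z):
        d = xgb.DMatrix(np.asarray(z, dtype=np.float32).reshape(1, -1),
                        feature_names=bundle.feature_names)
        return float(booster.predict(d, output_margin=True, iteration_range=it)[0])

    return f


class TestExactShapley:
    def test_additive_model(self):
        phi = exact_shapley(lambda z: 2 * z[0] + 3 * z[1], [1.0, 1.0], [0.0, 0.0])
        assert np.allclose(phi, [2.0, 3.0], atol=1e-12)

    def test_constant_model(self):
        phi = exact_shapley(lambda z: 7.0, [1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert np.allclose(phi, 0.0)

    def test_stump_game(self):
        # margin 2 iff count(M1) >= 1; second feature is a dummy
        phi = exact_shapley(lambda z: 2.0 if z[0] >= 1 else 0.0,
                            [3.0, 5.0], [0.0, 0.0])
        assert np.allclose(phi, [2.0, 0.0], atol=1e-12)

    def test_refuses_above_12_features(self):
        with pytest.raises(ValueError):
            exact_shapley(lambda z: 0.0, np.zeros(13), np.zeros(13))

    def test_interaction_game_efficiency_and_symmetry(self):
        f = lambda z: float(z[0] * z[1] + 0.5 * z[2])
        x, r = np.array([1.0, 1.0, 1.0]), np.zeros(3)
        phi = exact_shapley(f, x, r)
        assert abs(phi.sum() - (f(x) - f(r))) < 1e-12
        assert abs(phi[0] - phi[1]) < 1e-12  # interchangeable features


class TestTreeExplanations:
    def test_efficiency_default_background(self, separable_model,
                                           count_matrix_factory):
        bundle, tr, va, _ = separable_model
        expl = explain(bundle, va)
        margins = predict(bundle, va, output_margin=True)["score"].to_numpy()
        total = expl.values.sum(axis=1) + float(expl.base_values)
        assert np.allclose(total, margins, atol=1e-4)

    def test_efficiency_zero_reference(self, separable_model):
        bundle, tr, _, _ = separable_model
        sub = tr.subset(tr.row_ids[:10])
        expl = explain(bundle, sub, reference=np.zeros(8))
        margins = predict(bundle, sub, output_margin=True)["score"].to_numpy()
        total = expl.values.sum(axis=1) + float(expl.base_values)
        assert np.allclose(total, margins, atol=1e-6)

    def test_oracle_agreement_zero_reference(self, separable_model):
        bundle, tr, _, _ = separable_model
        sub = tr.subset(tr.row_ids[:5])
        expl = explain(bundle, sub, reference=np.zeros(8))
        f = margin_fn(bundle)
        for i, row in enumerate(sub.counts.to_numpy(dtype=float)):
            oracle = exact_shapley(f, row, np.zeros(8))
            assert np.allclose(expl.values[i], oracle, atol=1e-6)

    def test_dummy_feature_gets_zero(self, count_matrix_factory):
        rng = np.random.default_rng(8)
        X = rng.integers(0, 4, size=(120, 4))
        y = (X[:, 0] >= 2).astype(int)
        X[:, 3] = 5  # constant -> never a split candidate
        m = count_matrix_factory(X)
        bundle = train(m, y, m, y, TrainConfig(rounds=40, learning_rate=0.3))
        expl = explain(bundle, m)
        assert np.allclose(expl.values[:, 3], 0.0, atol=1e-7)

    def test_multiclass_per_class_slices_and_efficiency(self, count_matrix_factory):
        rng = np.random.default_rng(9)
        X = rng.integers(0, 6, size=(120, 5))
        y = pd.Series([("a", "b", "c")[int(v % 3)] for v in X[:, 0]])
        m = count_matrix_factory(X)
        y.index = m.row_ids
        bundle = train(m, y, m, y, TrainConfig(mode="multiclass", rounds=25,
                                               learning_rate=0.3))
        expl = explain(bundle, m)
        assert expl.values.shape == (120, 3, 5)
        margins = predict(bundle, m, output_margin=True)[bundle.class_names].to_numpy()
        total = expl.values.sum(axis=2) + expl.base_values[None, :]
        assert np.allclose(total, margins, atol=1e-4)


class TestRanking:
    def _expl(self, phi, motifs=("M1", "M2")):
        return ExplanationMatrix(np.asarray(phi, dtype=float),
                                 np.asarray(0.0),
                                 [f"r{i}" for i in range(len(phi))], list(motifs))

    def test_sum_abs_ordering(self):
        ranking = rank_motifs(self._expl([[1, -0.5], [1, 0]]))
        assert ranking.motif_order == ["M1", "M2"]
        assert np.allclose(ranking.table["sum_abs"], [2.0, 0.5])

    def test_all_zero_lexicographic(self):
        ranking = rank_motifs(self._expl([[0, 0], [0, 0]], motifs=("Mb", "Ma")))
        assert ranking.motif_order == ["Ma", "Mb"]

    def test_row_order_invariance(self):
        phi = [[1.0, -0.5], [0.2, 0.9], [-0.3, 0.1]]
        a = rank_motifs(self._expl(phi)).motif_order
        b = rank_motifs(self._expl(phi[::-1])).motif_order
        assert a == b

    def test_local_explanation(self, count_matrix_factory):
        phi = [[0.9, -0.4, 0.1]]
        expl = ExplanationMatrix(np.asarray(phi), np.asarray(0.0), ["r0"],
                                 ["M0", "M1", "M2"])
        m = count_matrix_factory(np.array([[3, 1, 7]]))
        top = local_explanation(expl, m, "r0", top_k=2)
        assert top == [("M0", 0.9, 3), ("M1", -0.4, 1)]
        assert len(local_explanation(expl, m, "r0", top_k=10)) == 3
        with pytest.raises(KeyError):
            local_explanation(expl, m, "nope")

    def test_implanted_motifs_dominate_ranking(self, recovery):
        top10 = recovery.ranking.motif_order[:10]
        assert all(m in top10 for m in recovery.discriminative_ids)
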