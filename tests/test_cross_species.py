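import numpy as np
import pandas as pd
import pytest

from motifbag.cross_species import (CellAccessibility, aggregate_cell_shap,
                                    assign_cell_types, downsample_cells)
from motifbag.shap_interpret import ExplanationMatrix
from motifbag.synthetic import simulate_cell_accessibility


def _expl(n_peaks, n_motifs, classes, fill):
    """Explanation where peak i of class k has phi = fill(i, k) per slice."""
    values = np.zeros((n_peaks, len(classes), n_motifs))
    for i in range(n_peaks):
        for k in range(len(classes)):
            values[i, k, :] = fill(i, k)
    return ExplanationMatrix(values, np.zeros(len(classes)),
                             [f"p{i}" for i in range(n_peaks)],
                             [f"M{j}" for j in range(n_motifs)], list(classes))


def _access(matrix, peak_class, types=None):
    df = pd.DataFrame(matrix, index=[f"c{i}" for i in range(len(matrix))],
                      columns=list(peak_class))
    ct = None if types is None else pd.Series(types, index=df.index)
    return CellAccessibility(df, peak_class, ct)


class TestAggregate:
    def test_mean_of_two_peaks(self):
        classes = ["A", "B"]
        phi = {("p0", "A"): 0.2, ("p1", "A"): 0.4}
        expl = _expl(2, 1, classes,
                     lambda i, k: phi.get((f"p{i}", classes[k]), 0.0))
        access = _access(np.ones((1, 2)), {"p0": "A", "p1": "A"})
        agg = aggregate_cell_shap(expl, access, min_peaks=1)
        # mean 0.3 under A, 0 under B, then normalized by sum |.| = 0.3
        assert np.isclose(agg.loc["c0", ("A", "M0")], 1.0)
        assert np.isclose(agg.loc["c0", ("B", "M0")], 0.0)

    def test_min_peaks_filter_excludes_cell(self):
        expl = _expl(25, 2, ["A", "B"], lambda i, k: 0.1)
        peak_class = {f"p{i}": "A" for i in range(25)}
        rows = np.zeros((2, 25))
        rows[0, :20] = 1   # exactly 20 accessible -> kept
        rows[1, :19] = 1   # 19 -> excluded
        agg = aggregate_cell_shap(expl, _access(rows, peak_class), min_peaks=20)
        assert list(agg.index) == ["c0"]
        assert agg.attrs["filter_counts"]["excluded_min_peaks"] == 1

    def test_excluded_training_peaks_dropped(self):
        expl = _expl(4, 1, ["A", "B"], lambda i, k: (1.0 if i < 2 else -1.0))
        peak_class = {f"p{i}": "A" for i in range(4)}
        access = _access(np.ones((1, 4)), peak_class)
        agg_all = aggregate_cell_shap(expl, access, min_peaks=1)
        agg_excl = aggregate_cell_shap(expl, access, min_peaks=1,
                                       exclude_peaks={"p2", "p3"})
        assert np.isclose(agg_all.loc["c0", ("A", "M0")], 0.0)
        assert np.isclose(agg_excl.loc["c0", ("A", "M0")], 1.0)

    def test_no_surviving_cells_errors_with_counts(self):
        expl = _expl(5, 1, ["A", "B"], lambda i, k: 0.1)
        access = _access(np.zeros((3, 5)), {f"p{i}": "A" for i in range(5)})
        with pytest.raises(ValueError, match="3"):
            aggregate_cell_shap(expl, access, min_peaks=2)


class TestAssign:
    def test_worked_zscore_example(self):
        r = pd.DataFrame([[1.0, 0.2], [0.4, 0.8], [0.9, 0.3]],
                         index=["c0", "c1", "c2"], columns=["class1", "class2"])
        # feed ratios through a degenerate aggregate: one motif, phi = r mass
        cols = pd.MultiIndex.from_product([["class1", "class2"], ["M0", "M1"]],
                                          names=["class", "motif"])
        # construct aggregates whose positive/absolute ratio reproduces r
        data = np.zeros((3, 4))
        for i in range(3):
            for k, cls in enumerate(["class1", "class2"]):
                data[i, 2 * k] = r.iloc[i, k]          # positive mass
                data[i, 2 * k + 1] = -(1 - r.iloc[i, k])  # negative mass
        agg = pd.DataFrame(data, index=r.index, columns=cols)
        score = assign_cell_types(agg)
        assert np.allclose(score.ratios.to_numpy(), r.to_numpy())
        assert np.allclose(score.zscores["class1"], [0.726, -1.141, 0.415],
                           atol=1e-3)
        assert np.allclose(score.zscores["class2"], [-0.726, 1.141, -0.415],
                           atol=1e-3)
        assert list(score.predicted) == ["class1", "class2", "class1"]

    def test_degenerate_sd_falls_back_to_raw_ratio(self):
        cols = pd.MultiIndex.from_product([["A", "B"], ["M0"]],
                                          names=["class", "motif"])
        agg = pd.DataFrame([[0.6, -0.4], [0.6, -0.4]], index=["c0", "c1"],
                           columns=cols)
        score = assign_cell_types(agg)
        assert list(score.predicted) == ["A", "A"]

    def test_single_cell_warns(self):
        cols = pd.MultiIndex.from_product([["A", "B"], ["M0"]],
                                          names=["class", "motif"])
        agg = pd.DataFrame([[0.9, -0.1]], index=["c0"], columns=cols)
        with pytest.warns(UserWarning):
            score = assign_cell_types(agg)
        assert list(score.predicted) == ["A"]

    def test_ratio_invariant_to_positive_rescaling(self):
        cols = pd.MultiIndex.from_product([["A", "B"], ["M0", "M1"]],
                                          names=["class", "motif"])
        base = np.array([[0.5, -0.2, 0.1, -0.6], [0.3, 0.3, -0.4, 0.2]])
        r1 = assign_cell_types(pd.DataFrame(base, columns=cols)).ratios
        r2 = assign_cell_types(pd.DataFrame(base * 7.3, columns=cols)).ratios
        assert np.allclose(r1.to_numpy(), r2.to_numpy())


class TestDownsample:
    def test_cap_applied(self):
        access = simulate_cell_accessibility(["T1", "T2"], cells_per_type=40,
                                             marker_peaks_per_type=5, seed=0)
        capped = downsample_cells(access, cap_per_type=25, seed=1)
        counts = capped.cell_types.value_counts()
        assert counts["T1"] == 25 and counts["T2"] == 25

    def test_types_below_cap_untouched(self):
        access = simulate_cell_accessibility(["T1"], 30, 5, seed=0)
        assert len(downsample_cells(access, cap_per_type=100, seed=0).cell_ids) == 30

    def test_deterministic(self):
        access = simulate_cell_accessibility(["T1"], 50, 5, seed=2)
        a = downsample_cells(access, 20, seed=9).cell_ids
        b = downsample_cells(access, 20, seed=9).cell_ids
        assert a == b

    def test_missing_annotation_errors(self):
        access = simulate_cell_accessibility(["T1"], 10, 5, seed=0)
        access.cell_types = None
        with pytest.raises(ValueError):
            downsample_cells(access, 5)


class TestEndToEndAssignment:
    def test_block_diagonal_gives_perfect_assignment(self):
        types = ["T1", "T2", "T3"]
        access = simulate_cell_accessibility(types, cells_per_type=30,
                                             marker_peaks_per_type=25,
                                             contamination=0.0, dropout=0.0,
                                             seed=4)
        rng = np.random.default_rng(5)
        n_peaks = len(access.peak_ids)
        values = np.zeros((n_peaks, 3, 6))
        for i, p in enumerate(access.peak_ids):
            for k, t in enumerate(types):
                mag = np.abs(rng.normal(size=6))
                values[i, k] = mag if access.peak_class_map[p] == t else -mag
        expl = ExplanationMatrix(values, np.zeros(3), list(access.peak_ids),
                                 [f"M{j}" for j in range(6)], types)
        agg = aggregate_cell_shap(expl, access, min_peaks=20)
        score = assign_cell_types(agg)
        truth = access.cell_types.loc[score.predicted.index]
        assert (score.predicted == truth).all()

    def test_contamination_degrades_accuracy_monotonically(self):
        types = ["T1", "T2"]
        rng = np.random.default_rng(6)
        accs = []
        for contamination in (0.0, 0.5, 1.0):
            access = simulate_cell_accessibility(types, 40, 25,
                                                 contamination=contamination,
                                                 dropout=0.0, seed=7)
            n_peaks = len(access.peak_ids)
            values = np.zeros((n_peaks, 2, 4))
            for i, p in enumerate(access.peak_ids):
                for k, t in enumerate(types):
                    mag = np.abs(rng.normal(size=4)) + 0.1
                    values[i, k] = mag if access.peak_class_map[p] == t else -mag
            expl = ExplanationMatrix(values, np.zeros(2), list(access.peak_ids),
                                     [f"M{j}" for j in range(4)], types)
            score = assign_cell_types(aggregate_cell_shap(expl, access, min_peaks=10))
            truth = access.cell_types.loc[score.predicted.index]
            accs.append(float((score.predicted == truth).mean()))
        assert accs[0] == 1.0
        assert accs[0] >= accs[1] - 0.1
        assert accs[1] >= accs[2] - 0.1
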