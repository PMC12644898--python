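"""Shapley-value attributions of motif contributions per CRE.

Attributions are reported in model-margin units (log-odds for
classifiers) so that the efficiency axiom is exact: per row, the
attributions plus the base value sum to the margin prediction.

Two routes are provided.  The default uses the tree-path (cover-
weighted) TreeSHAP built into the boosting library, whose implicit
background is the training-data distribution.  Passing an explicit
reference vector switches to interventional Shapley values computed
exactly per tree: a leaf's path constraints partition features into a
"must take the instance's value" set A and a "must take the
reference's value" set B, and the leaf contributes its value times the
closed-form Shapley weight of the corresponding unanimity game.  A
brute-force subset-enumeration oracle (<= 12 features) verifies both.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb

from .bag_matrix import MotifCountMatrix
from .gbt_models import ModelBundle, _align_columns


@dataclass
class ExplanationMatrix:
    """Per-row, per-motif (optionally per-class) Shapley values."""

    values: np.ndarray              # (rows, motifs) or (rows, classes, motifs)
    base_values: np.ndarray         # scalar array () or (classes,)
    row_ids: list[str]
    motif_ids: list[str]
    class_names: list[str] = field(default_factory=list)

    def phi(self, class_name: str | None = None) -> np.ndarray:
        """The (rows x motifs) slice for one class (or the only slice)."""
        if self.values.ndim == 2:
            return self.values
        if class_name is None:
            raise ValueError("class_name required for per-class explanations")
        k = self.class_names.index(class_name)
        return self.values[:, k, :]

    def frame(self, class_name: str | None = None) -> pd.DataFrame:
        return pd.DataFrame(self.phi(class_name), index=self.row_ids,
                            columns=self.motif_ids)


@dataclass
class ImportanceRanking:
    table: pd.DataFrame  # motif, sum_abs, mean_abs, mean_signed, rank

    @property
    def motif_order(self) -> list[str]:
        return list(self.table["motif"])


# --- exact oracle -------------------------------------------------------

def exact_shapley(model_fn, instance, reference) -> np.ndarray:
    """Shapley values by full subset enumeration (<= 12 features).

    v(S) evaluates `model_fn` on the instance with features outside S
    replaced by the reference values; phi_j is the classical weighted
    average of marginal contributions over all subsets.
    """
    x = np.asarray(instance, dtype=float)
    r = np.asarray(reference, dtype=float)
    n = len(x)
    if n > 12:
        raise ValueError(f"{n} features: subset enumeration refused above 12")
    cache: dict[frozenset, float] = {}

    def v(subset: frozenset) -> float:
        if subset not in cache:
            z = r.copy()
            idx = list(subset)
            z[idx] = x[idx]
            cache[subset] = float(model_fn(z))
        return cache[subset]

    phi = np.zeros(n)
    others = list(range(n))
    for j in range(n):
        rest = [k for k in others if k != j]
        for size in range(n):
            weight = (math.factorial(size) * math.factorial(n - size - 1)
                      / math.factorial(n))
            for subset in itertools.combinations(rest, size):
                s = frozenset(subset)
                phi[j] += weight * (v(s | {j}) - v(s))
    return phi


# --- interventional tree Shapley (explicit reference) -------------------

def _tree_nodes(tree_frame: pd.DataFrame) -> dict:
    return {row.ID: row for row in tree_frame.itertuples(index=False)}


def _single_tree_reference_shapley(tree_frame: pd.DataFrame, x: np.ndarray,
                                   r: np.ndarray, feat_index: dict[str, int],
                                   phi: np.ndarray) -> None:
    """Accumulate one tree's exact Shapley values for one (x, r) pair."""
    nodes = _tree_nodes(tree_frame)
    root_id = tree_frame.iloc[0].ID

    def descend(node_id: str, constraints: dict[int, tuple[bool, bool]]) -> None:
        node = nodes[node_id]
        if node.Feature == "Leaf":
            value = float(node.Gain)
            a_set = [f for f, (ci, co) in constraints.items() if ci and not co]
            b_set = [f for f, (ci, co) in constraints.items() if co and not ci]
            a, b = len(a_set), len(b_set)
            if a + b == 0:
                return
            denom = math.factorial(a + b)
            if a:
                w_in = value * math.factorial(a - 1) * math.factorial(b) / denom
                for f in a_set:
                    phi[f] += w_in
            if b:
                w_out = value * math.factorial(a) * math.factorial(b - 1) / denom
                for f in b_set:
                    phi[f] -= w_out
            return
        f = feat_index[node.Feature]
        split = float(node.Split)
        x_yes = x[f] < split
        r_yes = r[f] < split
        for child, toward_yes in ((node.Yes, True), (node.No, False)):
            x_ok = x_yes == toward_yes
            r_ok = r_yes == toward_yes
            ci_prev, co_prev = constraints.get(f, (True, True))
            ci, co = ci_prev and x_ok, co_prev and r_ok
            if not ci and not co:
                continue  # unreachable under any coalition
            nxt = dict(constraints)
            nxt[f] = (ci, co)
            descend(child, nxt)

    descend(root_id, {})


def _reference_shapley(booster: xgb.Booster, X: np.ndarray,
                       reference: np.ndarray, feature_names: list[str],
                       best_iteration: int | None = None,
                       num_class: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Exact interventional Shapley values for every row against references.

    Returns (phi, base) where phi has shape (rows, num_class, features)
    and base is the mean margin of the reference rows per class.
    """
    trees = booster.trees_to_dataframe()
    if best_iteration is not None:
        n_rounds = best_iteration + 1
        trees = trees[trees["Tree"] < n_rounds * num_class]
    feat_index = {name: i for i, name in enumerate(feature_names)}
    refs = np.atleast_2d(np.asarray(reference, dtype=float))
    n, p = X.shape
    phi = np.zeros((n, num_class, p))
    grouped = {t: g for t, g in trees.groupby("Tree")}
    for t, g in grouped.items():
        k = t % num_class
        for i in range(n):
            for rref in refs:
                tree_phi = np.zeros(p)
                _single_tree_reference_shapley(g, X[i], rref, feat_index, tree_phi)
                phi[i, k] += tree_phi / len(refs)
    dref = xgb.DMatrix(refs.astype(np.float32), feature_names=feature_names)
    it = (0, best_iteration + 1) if best_iteration is not None else None
    base_margin = booster.predict(dref, output_margin=True, iteration_range=it)
    base_margin = np.atleast_2d(base_margin.reshape(len(refs), -1)).mean(axis=0)
    return phi, base_margin


# --- public API ---------------------------------------------------------

def explain(bundle: ModelBundle, matrix: MotifCountMatrix,
            reference: np.ndarray | None = None,
            strict: bool = True) -> ExplanationMatrix:
    """Per-row, per-motif Shapley attributions in margin units.

    With `reference=None` (default) the training distribution is the
    implicit background (tree-path TreeSHAP); an explicit reference
    vector or matrix switches to exact interventional attributions.
    """
    counts = _align_columns(matrix, bundle.feature_names, strict=strict)
    X = counts.to_numpy(dtype=np.float32)
    features = bundle.feature_names
    mode = bundle.mode

    def _contribs(key: str) -> tuple[np.ndarray, np.ndarray]:
        booster = bundle.boosters[key]
        best = bundle.best_iterations.get(key)
        num_class = len(bundle.class_names) if mode == "multiclass" else 1
        if reference is not None:
            phi, base = _reference_shapley(
                booster, X.astype(float), reference, features,
                best_iteration=best, num_class=num_class)
            return phi, base
        dmat = xgb.DMatrix(X, feature_names=features)
        it = (0, best + 1) if best is not None else None
        contribs = booster.predict(dmat, pred_contribs=True, iteration_range=it)
        if contribs.ndim == 2:  # (rows, features + bias)
            return contribs[:, None, :-1], contribs[:1, -1]
        return contribs[:, :, :-1], contribs[0, :, -1]  # multiclass

    row_ids = list(counts.index)
    if mode == "multiclass":
        phi, base = _contribs("model")
        return ExplanationMatrix(phi, np.asarray(base), row_ids, features,
                                 list(bundle.class_names))
    if mode == "multilabel":
        slices, bases = [], []
        for cls in bundle.class_names:
            phi, base = _contribs(cls)
            slices.append(phi[:, 0, :])
            bases.append(float(np.ravel(base)[0]))
        return ExplanationMatrix(np.stack(slices, axis=1), np.asarray(bases),
                                 row_ids, features, list(bundle.class_names))
    phi, base = _contribs("model")
    return ExplanationMatrix(phi[:, 0, :], np.asarray(float(np.ravel(base)[0])),
                             row_ids, features)


def rank_motifs(expl: ExplanationMatrix, signed: bool = False,
                class_name: str | None = None) -> ImportanceRanking:
    """Global motif importance: descending sum of |phi| across rows.

    Mean |phi| and the signed mean (direction of effect) are reported
    alongside; exact ties break lexicographically by motif id.  With
    `signed=True` the ordering uses the signed mean instead.
    """
    if expl.values.size == 0:
        raise ValueError("empty explanation")
    if expl.values.ndim == 3 and class_name is None:
        phi = expl.values.reshape(-1, len(expl.motif_ids))
    else:
        phi = expl.phi(class_name)
    sum_abs = np.abs(phi).sum(axis=0)
    mean_abs = np.abs(phi).mean(axis=0)
    mean_signed = phi.mean(axis=0)
    df = pd.DataFrame({"motif": expl.motif_ids, "sum_abs": sum_abs,
                       "mean_abs": mean_abs, "mean_signed": mean_signed})
    key = "mean_signed" if signed else "sum_abs"
    df = df.sort_values([key, "motif"], ascending=[False, True],
                        kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return ImportanceRanking(df)


def local_explanation(expl: ExplanationMatrix, matrix: MotifCountMatrix,
                      row_id: str, top_k: int = 4,
                      class_name: str | None = None) -> list[tuple[str, float, int]]:
    """Top motifs for one CRE by |phi|, with signed phi and raw count."""
    if row_id not in expl.row_ids:
        raise KeyError(f"row {row_id!r} not in explanation")
    i = expl.row_ids.index(row_id)
    phi = expl.phi(class_name)[i]
    order = np.argsort(-np.abs(phi), kind="stable")[:top_k]
    counts = matrix.counts.loc[row_id]
    return [(expl.motif_ids[j], float(phi[j]), int(counts[expl.motif_ids[j]]))
            for j in order]


def write_ranking_tsv(ranking: ImportanceRanking, path: str,
                      tf_annotation: dict[str, str] | None = None) -> None:
    df = ranking.table.copy()
    if tf_annotation:
        df["tf"] = df["motif"].map(tf_annotation)
    df.to_csv(path, sep="\t", index=False)
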