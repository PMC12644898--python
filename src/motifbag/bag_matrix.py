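"""CRE x motif count matrices and class-balanced dataset assembly.

The bag-of-motifs representation: each candidate regulatory element is
a vector of motif occurrence counts, discarding order, spacing and
orientation.  Binary classification datasets pair a positive class
against a background balanced by stratified sampling so that every
non-target class contributes (near-)equally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scan import MotifHit


@dataclass
class MotifCountMatrix:
    """Integer count matrix (rows = CREs, columns = motifs) with labels."""

    counts: pd.DataFrame
    labels: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("row and column ids must be unique")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def row_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.counts.columns)

    def label_series(self) -> pd.Series:
        """Single-label view; raises if any row is multilabel."""
        vals = {}
        for name in self.counts.index:
            labs = self.labels.get(name, [])
            if len(labs) != 1:
                raise ValueError(f"row {name} has {len(labs)} labels; expected 1")
            vals[name] = labs[0]
        return pd.Series(vals).loc[self.counts.index]

    def subset(self, row_ids: list[str]) -> "MotifCountMatrix":
        return MotifCountMatrix(self.counts.loc[row_ids].copy(),
                                {r: list(self.labels.get(r, [])) for r in row_ids})

    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


@dataclass
class BalancedDataset:
    matrix: MotifCountMatrix
    positive_class: str
    negative_composition: dict[str, int]
    seed: int

    def binary_labels(self) -> pd.Series:
        """1 for the positive class, 0 for background rows."""
        return pd.Series(
            {r: int(self.positive_class in self.matrix.labels.get(r, []))
             for r in self.matrix.row_ids}).loc[self.matrix.row_ids]


@dataclass
class DatasetSplit:
    train: list[str]
    validation: list[str]
    test: list[str]
    fractions: tuple[float, float, float]
    seed: int


def build_count_matrix(hits: list[MotifHit], cre_ids: list[str],
                       motif_ids: list[str],
                       labels: dict[str, list[str]] | None = None) -> MotifCountMatrix:
    """Count retained hits per (CRE, motif); zero-hit CREs keep all-zero rows."""
    cre_index = {c: i for i, c in enumerate(cre_ids)}
    motif_index = {m: j for j, m in enumerate(motif_ids)}
    counts = np.zeros((len(cre_ids), len(motif_ids)), dtype=np.int64)
    for h in hits:
        if h.seq_id not in cre_index:
            raise KeyError(f"hit references unknown sequence {h.seq_id!r}")
        if h.motif_id not in motif_index:
            raise KeyError(f"hit references unknown motif {h.motif_id!r}")
        counts[cre_index[h.seq_id], motif_index[h.motif_id]] += 1
    df = pd.DataFrame(counts, index=list(cre_ids), columns=list(motif_ids))
    return MotifCountMatrix(df, {c: list((labels or {}).get(c, [])) for c in cre_ids})


def assemble_balanced(matrix: MotifCountMatrix, positive_class: str,
                      min_peaks: int = 100, seed: int = 0) -> BalancedDataset:
    """Positive class vs an equal-size background stratified over other classes.

    Each background class contributes k = floor(n_pos / n_classes) rows
    (remainder round-robin from the largest classes).  If some class
    has fewer than k rows, k drops to the smallest background class
    size and the positives are downsampled to k * n_classes so the
    dataset stays balanced.
    """
    rng = np.random.default_rng(seed)
    pos_rows = [r for r in matrix.row_ids if positive_class in matrix.labels.get(r, [])]
    if len(pos_rows) < min_peaks:
        raise ValueError(
            f"class {positive_class!r} has {len(pos_rows)} rows; "
            f"at least {min_peaks} are required")
    bg_classes: dict[str, list[str]] = {}
    for r in matrix.row_ids:
        labs = matrix.labels.get(r, [])
        if positive_class in labs:
            continue
        if labs:  # multilabel rows stratify under their first label
            bg_classes.setdefault(labs[0], []).append(r)
    if not bg_classes:
        raise ValueError("no background classes available")

    n_pos = len(pos_rows)
    n_bg = len(bg_classes)
    k = n_pos // n_bg
    min_size = min(len(v) for v in bg_classes.values())
    if min_size < k:
        k = min_size
        quota = {c: k for c in bg_classes}
    else:
        quota = {c: k for c in bg_classes}
        remainder = n_pos - k * n_bg
        # one extra row each from the largest background classes (keeps the
        # per-class spread at <= 1); any unfillable remainder instead shrinks
        # the positive set below
        for c in sorted(bg_classes, key=lambda c: (-len(bg_classes[c]), c)):
            if remainder == 0:
                break
            if len(bg_classes[c]) > k:
                quota[c] += 1
                remainder -= 1
    n_neg = sum(quota.values())
    if n_neg < n_pos:  # downsample positives to keep the dataset balanced
        pos_rows = sorted(pos_rows)
        idx = rng.choice(len(pos_rows), size=n_neg, replace=False)
        pos_rows = [pos_rows[i] for i in sorted(idx)]

    neg_rows: list[str] = []
    composition: dict[str, int] = {}
    for c in sorted(bg_classes):
        rows = sorted(bg_classes[c])
        take = quota[c]
        idx = rng.choice(len(rows), size=take, replace=False)
        neg_rows.extend(rows[i] for i in sorted(idx))
        composition[c] = take

    sub = matrix.subset(pos_rows + neg_rows)
    return BalancedDataset(sub, positive_class, composition, seed)


def split_dataset(row_ids: list[str], labels: pd.Series | None = None,
                  fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
                  seed: int = 0, stratify_by_label: bool = True) -> DatasetSplit:
    """Seeded train/validation/test partition, stratified per label.

    Sizes follow the fractions by largest-remainder rounding within
    each stratum; partitions are disjoint and jointly exhaustive.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    if labels is None or not stratify_by_label:
        strata = {"__all__": list(row_ids)}
    else:
        strata = {}
        for r in row_ids:
            strata.setdefault(str(labels.loc[r]), []).append(r)

    parts: tuple[list[str], list[str], list[str]] = ([], [], [])
    for key in sorted(strata):
        rows = strata[key]
        perm = rng.permutation(len(rows))
        shuffled = [rows[i] for i in perm]
        n = len(rows)
        ideal = [f * n for f in fractions]
        sizes = [int(x) for x in ideal]
        # largest remainder fills the leftover slots
        rema = sorted(range(3), key=lambda i: (ideal[i] - sizes[i]), reverse=True)
        for i in rema[: n - sum(sizes)]:
            sizes[i] += 1
        a, b = sizes[0], sizes[0] + sizes[1]
        parts[0].extend(shuffled[:a])
        parts[1].extend(shuffled[a:b])
        parts[2].extend(shuffled[b:])
    if any(len(p) == 0 for p in parts):
        raise ValueError("a split partition is empty; need more rows")
    return DatasetSplit(parts[0], parts[1], parts[2], tuple(fractions), seed)


def subsample_counts(matrix: MotifCountMatrix, remove_fraction: float,
                     seed: int = 0) -> MotifCountMatrix:
    """Remove floor(remove_fraction * total) hit-units uniformly at random.

    Models a perturbation of the motif annotation: individual motif
    occurrences are dropped without replacement across all cells.
    """
    if not (0 <= remove_fraction < 1):
        raise ValueError("remove_fraction must be in [0, 1)")
    counts = matrix.counts.to_numpy().copy()
    total = int(counts.sum())
    n_remove = int(remove_fraction * total)
    if n_remove == 0:
        return MotifCountMatrix(matrix.counts.copy(),
                                {k: list(v) for k, v in matrix.labels.items()})
    rng = np.random.default_rng(seed)
    flat = counts.ravel()
    # sample hit-units without replacement via a weighted multivariate draw
    chosen = rng.choice(total, size=n_remove, replace=False)
    boundaries = np.cumsum(flat)
    cells = np.searchsorted(boundaries, chosen, side="right")
    dec = np.bincount(cells, minlength=flat.size)
    flat -= dec
    df = pd.DataFrame(counts, index=matrix.counts.index, columns=matrix.counts.columns)
    return MotifCountMatrix(df, {k: list(v) for k, v in matrix.labels.items()})


def minmax_normalize(values) -> np.ndarray:
    """(x - min) / (max - min); constant vectors map to all-zeros."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)] if arr.ndim == 1 and not np.all(np.isfinite(arr)) else arr
    if arr.size == 0:
        raise ValueError("cannot normalize an empty vector")
    lo, hi = np.nanmin(arr), np.nanmax(arr)
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


# --- persistence --------------------------------------------------------

def write_count_matrix_tsv(matrix: MotifCountMatrix, path: str) -> None:
    matrix.counts.to_csv(path, sep="\t")


def read_count_matrix_tsv(path: str, labels: dict[str, list[str]] | None = None
                          ) -> MotifCountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return MotifCountMatrix(df.astype(np.int64),
                            {r: list((labels or {}).get(r, [])) for r in df.index})


def write_count_matrix_mtx(matrix: MotifCountMatrix, prefix: str) -> None:
    """MatrixMarket triplet + row/column name sidecars (<prefix>.mtx/.rows/.cols)."""
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    mmwrite(f"{prefix}.mtx", csr_matrix(matrix.counts.to_numpy()))
    with open(f"{prefix}.rows", "w") as fh:
        fh.write("\n".join(matrix.row_ids) + "\n")
    with open(f"{prefix}.cols", "w") as fh:
        fh.write("\n".join(matrix.col_ids) + "\n")


def write_manifest(dataset: BalancedDataset, path: str) -> None:
    with open(path, "w") as fh:
        json.dump({"positive_class": dataset.positive_class,
                   "negative_composition": dataset.negative_composition,
                   "n_rows": len(dataset.matrix.row_ids),
                   "seed": dataset.seed}, fh, indent=2)
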