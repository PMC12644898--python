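"""Cell-type assignment from aggregated per-peak motif attributions.

Because the bag-of-motifs vocabulary is shared across genomes, a model
trained on one species' cell-type-specific CREs can score another
species' accessible peaks.  Each single cell is then summarized by the
mean attribution over its accessible marker peaks (per motif and model
class), normalized per cell, and assigned to the class whose
attributions are most consistently positive: the z-score-transformed
ratio of positive to absolute attribution mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .shap_interpret import ExplanationMatrix


@dataclass
class CellAccessibility:
    """Cells x peaks accessibility with a marker-peak-to-class map."""

    matrix: pd.DataFrame                 # rows cells, columns peaks; counts or 0/1
    peak_class_map: dict[str, str]       # marker peak -> model class
    cell_types: pd.Series | None = None  # optional truth annotation per cell

    def __post_init__(self) -> None:
        missing = set(self.peak_class_map) - set(self.matrix.columns)
        if missing:
            raise ValueError(f"peaks in class map absent from matrix: {sorted(missing)[:5]}")
        if self.cell_types is not None:
            self.cell_types = pd.Series(self.cell_types).loc[self.matrix.index]

    @property
    def cell_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def peak_ids(self) -> list[str]:
        return list(self.matrix.columns)


@dataclass
class CellClassScore:
    ratios: pd.DataFrame       # cells x classes, r in [0, 1]
    zscores: pd.DataFrame      # cells x classes
    predicted: pd.Series       # cell -> class
    filter_counts: dict[str, int] = field(default_factory=dict)


def downsample_cells(access: CellAccessibility, cap_per_type: int = 1000,
                     seed: int = 0) -> CellAccessibility:
    """Cap each annotated cell type at `cap_per_type` cells (seeded uniform)."""
    if access.cell_types is None:
        raise ValueError("downsampling requires per-cell type annotation")
    rng = np.random.default_rng(seed)
    keep: list[str] = []
    for ctype in sorted(access.cell_types.unique()):
        cells = sorted(access.cell_types.index[access.cell_types == ctype])
        if len(cells) > cap_per_type:
            idx = rng.choice(len(cells), size=cap_per_type, replace=False)
            cells = [cells[i] for i in sorted(idx)]
        keep.extend(cells)
    keep = [c for c in access.cell_ids if c in set(keep)]
    return CellAccessibility(access.matrix.loc[keep], dict(access.peak_class_map),
                             access.cell_types.loc[keep])


def aggregate_cell_shap(expl: ExplanationMatrix, access: CellAccessibility,
                        min_peaks: int = 20,
                        exclude_peaks: set[str] | None = None,
                        own_class_only: bool = True) -> pd.DataFrame:
    """Mean attribution over each cell's accessible marker peaks.

    A peak is accessible when its entry is > 0 (equivalently exactly 1
    for binary matrices).  Peaks used in model training/validation are
    passed in `exclude_peaks` and dropped first; cells with fewer than
    `min_peaks` accessible marker peaks are excluded.  By default each
    marker peak contributes only under its own class's attribution
    slice.  The result (cells x (class, motif)) is normalized per cell
    by the sum of absolute values.
    """
    exclude_peaks = exclude_peaks or set()
    classes = expl.class_names or ["model"]
    marker_peaks = [p for p in access.peak_ids
                    if p in access.peak_class_map and p not in exclude_peaks
                    and p in set(expl.row_ids)]
    if not marker_peaks:
        raise ValueError("no usable marker peaks after exclusion/reconciliation")

    peak_pos = {p: expl.row_ids.index(p) for p in marker_peaks}
    acc = (access.matrix[marker_peaks].to_numpy() > 0)
    n_cells = acc.shape[0]
    accessible_counts = acc.sum(axis=1)
    keep_mask = accessible_counts >= min_peaks
    n_dropped = int((~keep_mask).sum())
    if not keep_mask.any():
        raise ValueError(
            f"no cells survive: {n_dropped} of {n_cells} cells have fewer than "
            f"{min_peaks} accessible marker peaks")

    phi_by_class = {}
    for k, cls in enumerate(classes):
        phi = expl.values if expl.values.ndim == 2 else expl.values[:, k, :]
        phi_by_class[cls] = phi

    motifs = expl.motif_ids
    cols = pd.MultiIndex.from_product([classes, motifs], names=["class", "motif"])
    cells = [c for c, ok in zip(access.cell_ids, keep_mask) if ok]
    out = np.zeros((len(cells), len(classes) * len(motifs)))

    peak_class = np.array([access.peak_class_map[p] for p in marker_peaks])
    peak_rows = np.array([peak_pos[p] for p in marker_peaks])
    acc_kept = acc[keep_mask]
    for k, cls in enumerate(classes):
        in_class = (peak_class == cls) if own_class_only else np.ones(len(marker_peaks), bool)
        phi = phi_by_class[cls][peak_rows[in_class]]
        sub_acc = acc_kept[:, in_class].astype(float)
        n_acc = sub_acc.sum(axis=1)
        with np.errstate(invalid="ignore"):
            means = (sub_acc @ phi) / n_acc[:, None]
        means[n_acc == 0] = 0.0
        out[:, k * len(motifs):(k + 1) * len(motifs)] = means

    df = pd.DataFrame(out, index=cells, columns=cols)
    norms = df.abs().sum(axis=1)
    norms = norms.replace(0, 1.0)
    df = df.div(norms, axis=0)
    df.attrs["filter_counts"] = {"input_cells": n_cells,
                                 "excluded_min_peaks": n_dropped,
                                 "scored": len(cells)}
    return df


def assign_cell_types(aggregates: pd.DataFrame, use_zscore: bool = True,
                      zscore_axis: str = "cells") -> CellClassScore:
    """Assign each cell to the class with the highest aggregated score.

    Per cell and class, r = sum of positive attributions divided by
    the sum of absolute attributions (0 when the class carries no
    attribution mass).  r columns are z-scored across cells per class
    (degenerate SD falls back to raw r); the predicted label is the
    argmax.  `zscore_axis="classes"` standardizes within each cell
    instead.
    """
    classes = list(aggregates.columns.get_level_values("class").unique())
    if len(classes) < 2:
        raise ValueError("need at least two classes to assign cells")
    cells = list(aggregates.index)
    ratios = pd.DataFrame(index=cells, columns=classes, dtype=float)
    for cls in classes:
        block = aggregates[cls].to_numpy()
        pos = np.clip(block, 0, None).sum(axis=1)
        tot = np.abs(block).sum(axis=1)
        with np.errstate(invalid="ignore"):
            r = np.where(tot > 0, pos / np.where(tot > 0, tot, 1.0), 0.0)
        ratios[cls] = r

    if not use_zscore or len(cells) < 2:
        if use_zscore and len(cells) < 2:
            warnings.warn("single cell: falling back to raw-ratio argmax")
        z = ratios.copy()
    elif zscore_axis == "cells":
        z = ratios.copy()
        for cls in classes:
            sd = ratios[cls].std(ddof=1)
            z[cls] = (ratios[cls] - ratios[cls].mean()) / sd if sd > 0 else ratios[cls]
    elif zscore_axis == "classes":
        mu = ratios.mean(axis=1)
        sd = ratios.std(axis=1, ddof=1)
        z = ratios.sub(mu, axis=0).div(sd.replace(0, 1.0), axis=0)
    else:
        raise ValueError("zscore_axis must be 'cells' or 'classes'")

    predicted = z.idxmax(axis=1)
    counts = dict(aggregates.attrs.get("filter_counts", {}))
    return CellClassScore(ratios, z, predicted, counts)


def write_assignment_tsv(score: CellClassScore, path: str) -> None:
    df = pd.concat([score.ratios.add_prefix("r_"),
                    score.zscores.add_prefix("z_")], axis=1)
    df["predicted"] = score.predicted
    df.to_csv(path, sep="\t", index_label="cell")
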