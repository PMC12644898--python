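"""Synthetic fixtures emulating the pipeline's inputs.

Generates random motif sets, class-labeled CRE sequence sets whose
classes differ in the implant rates of known motifs, and toy
cell x peak accessibility matrices — everything needed to exercise
scanning, training, interpretation and cell assignment offline, with
full per-seed determinism.

The flagship recovery design: two classes of 500-bp CREs where five
discriminative motifs are implanted at rate 0.8 in the positive class
versus 0.05 in the background, on top of shared decoy motifs, so a
trained classifier must rediscover the implanted vocabulary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cross_species import CellAccessibility
from .genome_io import GenomicInterval, LabeledCRESet, write_bed, write_fasta, write_label_tsv
from .motifs import ALPHABET, BackgroundModel, PWM, write_meme


@dataclass
class SimulationDesign:
    classes: list[str] = field(default_factory=lambda: ["classA", "classB"])
    n_per_class: int = 500
    cre_width: int = 500
    # implant_rate[class][motif_id] -> Bernoulli probability of one implant
    implant_rate: dict[str, dict[str, float]] = field(default_factory=dict)
    gc_fraction: float = 0.41
    seed: int = 0

    def __post_init__(self) -> None:
        for cls, rates in self.implant_rate.items():
            for motif, rate in rates.items():
                if not (0 <= rate <= 1):
                    raise ValueError(f"rate {rate} for {cls}/{motif} outside [0, 1]")


def make_motif_set(n_motifs: int, width_range: tuple[int, int] = (8, 12),
                   concentration: float = 50.0, seed: int = 0,
                   prefix: str = "M") -> list[PWM]:
    """Seeded random PWMs with tunable information content.

    Each column is a Dirichlet draw with the consensus base's
    concentration boosted by `concentration`; large values give
    near-delta columns (consensus probability -> 1).
    """
    if n_motifs < 1:
        raise ValueError("need at least one motif")
    rng = np.random.default_rng(seed)
    motifs = []
    lo, hi = width_range
    for i in range(n_motifs):
        w = int(rng.integers(lo, hi + 1))
        rows = []
        for _ in range(w):
            consensus = int(rng.integers(0, 4))
            alpha = np.ones(4)
            alpha[consensus] += concentration
            rows.append(rng.dirichlet(alpha))
        motifs.append(PWM(id=f"{prefix}{i:03d}", probs=np.array(rows)))
    return motifs


def _random_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = BackgroundModel.from_gc(gc).freqs
    return rng.choice(4, size=length, p=probs)


def _sample_instance(rng: np.random.Generator, pwm: PWM) -> np.ndarray:
    return np.array([rng.choice(4, p=row) for row in pwm.probs])


def simulate_cre_dataset(design: SimulationDesign, motifs: list[PWM],
                         out_dir: str | None = None, spacer: int = 100,
                         max_retries: int = 1000):
    """Labeled CRE sequences with per-class Bernoulli motif implants.

    Each CRE is i.i.d. background; per motif, with the class's implant
    rate, one PWM-sampled instance replaces bases at a uniformly
    chosen position that overlaps no earlier implant.  All CREs are
    laid out on one synthetic chromosome separated by spacer bases.

    Returns (genome: dict, cre_set: LabeledCRESet, truth: DataFrame);
    with `out_dir` also writes FASTA/BED/labels TSV/truth TSV.
    """
    rng = np.random.default_rng(design.seed)
    motif_by_id = {m.id: m for m in motifs}
    chrom_parts: list[np.ndarray] = []
    intervals: list[GenomicInterval] = []
    labels: dict[str, list[str]] = {}
    truth_rows = []
    offset = 0
    for cls in design.classes:
        rates = design.implant_rate.get(cls, {})
        for i in range(design.n_per_class):
            name = f"{cls}_cre{i:04d}"
            seq = _random_background(rng, design.cre_width, design.gc_fraction)
            occupied: list[tuple[int, int]] = []
            for motif_id in sorted(rates):
                if rng.random() >= rates[motif_id]:
                    continue
                pwm = motif_by_id[motif_id]
                w = pwm.width
                inst = _sample_instance(rng, pwm)
                for _ in range(max_retries):
                    start = int(rng.integers(0, design.cre_width - w + 1))
                    if all(start + w <= s or start >= e for s, e in occupied):
                        break
                else:
                    raise RuntimeError(f"{name}: cannot place implant of {motif_id}")
                occupied.append((start, start + w))
                seq[start:start + w] = inst
                truth_rows.append({"cre": name, "motif": motif_id, "start": start,
                                   "instance": "".join(ALPHABET[b] for b in inst)})
            chrom_parts.append(seq)
            chrom_parts.append(_random_background(rng, spacer, design.gc_fraction))
            intervals.append(GenomicInterval("chrS", offset, offset + design.cre_width, name))
            labels[name] = [cls]
            offset += design.cre_width + spacer

    chrom = "".join(ALPHABET[b] for b in np.concatenate(chrom_parts))
    genome = {"chrS": chrom}
    cre_set = LabeledCRESet(intervals, labels, list(design.classes))
    truth = pd.DataFrame(truth_rows, columns=["cre", "motif", "start", "instance"])

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_fasta(genome, os.path.join(out_dir, "genome.fa"))
        write_bed(intervals, os.path.join(out_dir, "cres.bed"))
        write_label_tsv(labels, os.path.join(out_dir, "labels.tsv"))
        truth.to_csv(os.path.join(out_dir, "implants.tsv"), sep="\t", index=False)
        write_meme(motifs, BackgroundModel.from_gc(design.gc_fraction),
                   os.path.join(out_dir, "motifs.meme"))
    return genome, cre_set, truth


def recovery_design(seed: int = 0, n_per_class: int = 500,
                    n_discriminative: int = 5, n_decoys: int = 20,
                    rate_pos: float = 0.8, rate_neg: float = 0.05,
                    decoy_rate: float = 0.3):
    """The standard two-class motif-recovery benchmark.

    Five discriminative motifs are implanted at `rate_pos` in classA
    and `rate_neg` in classB; decoys appear at `decoy_rate` in both.
    Returns (design, motifs, discriminative_ids).
    """
    motifs = make_motif_set(n_discriminative, seed=seed, prefix="D")
    decoys = make_motif_set(n_decoys, seed=seed + 1, prefix="X")
    disc_ids = [m.id for m in motifs]
    rates_a = {m.id: rate_pos for m in motifs}
    rates_b = {m.id: rate_neg for m in motifs}
    for m in decoys:
        rates_a[m.id] = decoy_rate
        rates_b[m.id] = decoy_rate
    design = SimulationDesign(classes=["classA", "classB"], n_per_class=n_per_class,
                              implant_rate={"classA": rates_a, "classB": rates_b},
                              seed=seed)
    return design, motifs + decoys, disc_ids


def simulate_cell_accessibility(types: list[str], cells_per_type: int,
                                marker_peaks_per_type: int,
                                contamination: float = 0.0,
                                dropout: float = 0.0,
                                seed: int = 0) -> CellAccessibility:
    """Toy binary cell x peak matrix with block structure plus noise.

    A cell accesses its own type's marker peaks with probability
    1 - dropout and every other type's peaks with probability
    `contamination`; truth annotation is attached.
    """
    for p, name in ((contamination, "contamination"), (dropout, "dropout")):
        if not (0 <= p <= 1):
            raise ValueError(f"{name} must be a probability")
    rng = np.random.default_rng(seed)
    peak_ids, peak_class = [], {}
    for t in types:
        for j in range(marker_peaks_per_type):
            pid = f"{t}_peak{j:03d}"
            peak_ids.append(pid)
            peak_class[pid] = t
    cell_ids, cell_types = [], []
    rows = []
    for t in types:
        for c in range(cells_per_type):
            cell_ids.append(f"{t}_cell{c:04d}")
            cell_types.append(t)
            probs = np.where(np.array([peak_class[p] for p in peak_ids]) == t,
                             1.0 - dropout, contamination)
            rows.append((rng.random(len(peak_ids)) < probs).astype(np.int64))
    matrix = pd.DataFrame(np.array(rows), index=cell_ids, columns=peak_ids)
    return CellAccessibility(matrix, peak_class, pd.Series(cell_types, index=cell_ids))
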