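"""Genomic intervals, distal CRE definition, and sequence extraction.

Coordinates are 0-based half-open throughout (BED convention); GTF
input (1-based inclusive) is converted on read.  Candidate CREs are
restricted to distal, non-exonic fixed-width windows: every window
base must lie more than `min_tss_distance` from every transcription
start site, and windows may not overlap any annotated exon.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field

import numpy as np
from pyfaidx import Fasta


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: str
    summit: int | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.name}: invalid interval [{self.start}, {self.end})")
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValueError(f"{self.name}: summit {self.summit} outside interval")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


@dataclass
class LabeledCRESet:
    """CRE intervals with one or more class labels each (multilabel allowed)."""

    intervals: list[GenomicInterval]
    labels: dict[str, list[str]]
    label_vocabulary: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [iv.name for iv in self.intervals]
        if len(set(names)) != len(names):
            raise ValueError("interval names must be unique")
        if not self.label_vocabulary:
            seen: list[str] = []
            for labs in self.labels.values():
                for lab in labs:
                    if lab not in seen:
                        seen.append(lab)
            self.label_vocabulary = seen
        vocab = set(self.label_vocabulary)
        for name, labs in self.labels.items():
            bad = set(labs) - vocab
            if bad:
                raise ValueError(f"{name}: labels {sorted(bad)} not in vocabulary")

    def __len__(self) -> int:
        return len(self.intervals)

    def by_name(self) -> dict[str, GenomicInterval]:
        return {iv.name: iv for iv in self.intervals}


@dataclass
class GeneAnnotation:
    """Per-chromosome TSS positions and exon intervals for the distal filter."""

    tss_positions: dict[str, list[int]]
    exon_intervals: dict[str, list[tuple[int, int]]]

    def __post_init__(self) -> None:
        self.tss_positions = {c: sorted(p) for c, p in self.tss_positions.items()}
        self.exon_intervals = {c: sorted(e) for c, e in self.exon_intervals.items()}

    def nearest_tss_distance(self, chrom: str, start: int, end: int) -> float:
        """Min over TSSs of the distance to the closest window base."""
        tss = self.tss_positions.get(chrom, [])
        if not tss:
            return float("inf")
        i = bisect.bisect_left(tss, start)
        best = float("inf")
        for j in (i - 1, i, bisect.bisect_right(tss, end - 1)):
            if 0 <= j < len(tss):
                t = tss[j]
                if t < start:
                    d = start - t
                elif t > end - 1:
                    d = t - (end - 1)
                else:
                    d = 0
                best = min(best, d)
        return best

    def overlaps_exon(self, chrom: str, start: int, end: int) -> bool:
        exons = self.exon_intervals.get(chrom, [])
        for es, ee in exons:
            if es >= end:
                break
            if ee > start:
                return True
        return False


def load_sequences(genome, intervals: list[GenomicInterval]) -> dict[str, str]:
    """Extract uppercase sequences for intervals from a FASTA genome.

    `genome` is a FASTA path, an open pyfaidx.Fasta, or a plain
    dict of chromosome name -> sequence.
    """
    if isinstance(genome, dict):
        chroms = {k: str(v).upper() for k, v in genome.items()}
        getter = lambda c, s, e: chroms[c][s:e]
        length = lambda c: len(chroms[c])
        names = set(chroms)
    else:
        fa = genome if isinstance(genome, Fasta) else Fasta(str(genome))
        getter = lambda c, s, e: str(fa[c][s:e]).upper()
        length = lambda c: len(fa[c])
        names = set(fa.keys())

    out: dict[str, str] = {}
    for iv in intervals:
        if iv.chrom not in names:
            raise KeyError(f"chromosome {iv.chrom!r} not present in genome")
        if iv.end > length(iv.chrom):
            raise ValueError(
                f"interval {iv.name} ({iv.chrom}:{iv.start}-{iv.end}) exceeds "
                f"chromosome length {length(iv.chrom)}")
        seq = getter(iv.chrom, iv.start, iv.end).upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            seq = "".join(c if c in "ACGTN" else "N" for c in seq)
        out[iv.name] = seq
    return out


def define_cres(cres: LabeledCRESet, annotation: GeneAnnotation,
                min_tss_distance: int = 1000, width: int = 500,
                chrom_sizes: dict[str, int] | None = None) -> LabeledCRESet:
    """Trim/center peaks to fixed-width windows and apply the distal filter.

    Windows are centered on the summit when present, else the peak
    midpoint.  Windows closer than `min_tss_distance` to any TSS (edge
    distance), overlapping any exon, or extending past chromosome ends
    are dropped.
    """
    half = width // 2
    kept: list[GenomicInterval] = []
    labels: dict[str, list[str]] = {}
    for iv in cres.intervals:
        center = iv.summit if iv.summit is not None else (iv.start + iv.end) // 2
        start = center - half
        end = start + width
        if start < 0:
            continue
        if chrom_sizes is not None and end > chrom_sizes.get(iv.chrom, np.inf):
            continue
        if annotation.nearest_tss_distance(iv.chrom, start, end) <= min_tss_distance:
            continue
        if annotation.overlaps_exon(iv.chrom, start, end):
            continue
        kept.append(GenomicInterval(iv.chrom, start, end, iv.name, strand=iv.strand))
        labels[iv.name] = list(cres.labels.get(iv.name, []))
    if not kept:
        warnings.warn("define_cres: no CREs survived the distal/non-exonic filters")
    return LabeledCRESet(kept, labels, list(cres.label_vocabulary))


def flanking_negatives(cres: LabeledCRESet, span: int = 2000, width: int = 500,
                       stride: int = 50) -> list[GenomicInterval]:
    """Tile fixed-width windows through +-span of each CRE, excluding overlaps.

    Windows tile [start - span, start) and [end, end + span) of each
    CRE; any window overlapping ANY CRE in the input set is excluded.
    """
    if span < width:
        raise ValueError(f"span ({span}) must be >= width ({width})")
    out: list[GenomicInterval] = []
    for iv in cres.intervals:
        candidates: list[tuple[str, int]] = []
        for s in range(iv.start - span, iv.start - width + 1, stride):
            candidates.append(("up", s))
        for s in range(iv.end, iv.end + span - width + 1, stride):
            candidates.append(("down", s))
        for side, s in candidates:
            if s < 0:
                continue
            window = GenomicInterval(iv.chrom, s, s + width,
                                     f"{iv.name}_flank_{side}_{s}")
            if any(window.overlaps(other) for other in cres.intervals):
                continue
            out.append(window)
    return out


# --- file I/O -----------------------------------------------------------

def read_bed(path: str) -> list[GenomicInterval]:
    """Read BED (>=3 columns); column 4 is the name, column 7 (if present)
    a summit offset relative to start, BED6 strand respected."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for k, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else f"region_{k}"
            strand = f[5] if len(f) > 5 and f[5] in "+-" else "."
            summit = None
            if len(f) > 6 and f[6] not in (".", "", "-1"):
                summit = int(f[1]) + int(f[6])
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), name,
                                       summit=summit, strand=strand))
    return out


def write_bed(intervals: list[GenomicInterval], path: str) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


def read_label_tsv(path: str) -> dict[str, list[str]]:
    """Two-column name -> label TSV; repeated names accumulate labels."""
    labels: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, label = line.split("\t")[:2]
            labels.setdefault(name, []).append(label)
    return labels


def write_label_tsv(labels: dict[str, list[str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, labs in labels.items():
            for lab in labs:
                fh.write(f"{name}\t{lab}\n")


def read_cre_set(bed_path: str, label_path: str) -> LabeledCRESet:
    intervals = read_bed(bed_path)
    labels = read_label_tsv(label_path)
    return LabeledCRESet(intervals, {iv.name: labels.get(iv.name, []) for iv in intervals})


def write_fasta(sequences: dict[str, str], path: str, line_width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i:i + line_width] + "\n")


def read_gene_annotation(path: str) -> GeneAnnotation:
    """Build TSS/exon annotation from GTF or GFF3.

    TSSs come from transcript/mRNA features (gene features where no
    transcripts exist), strand-aware; exons from exon features.
    1-based inclusive coordinates are converted to 0-based half-open.
    """
    tss: dict[str, set[int]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8:
                continue
            chrom, _, feature, start1, end1, _, strand = f[:7]
            start, end = int(start1) - 1, int(end1)
            if feature in ("transcript", "mRNA", "gene"):
                pos = start if strand != "-" else end - 1
                tss.setdefault(chrom, set()).add(pos)
            elif feature == "exon":
                exons.setdefault(chrom, []).append((start, end))
    return GeneAnnotation({c: sorted(v) for c, v in tss.items()}, exons)
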