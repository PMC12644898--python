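"""Synthetic regulatory element (SRE) design by motif implantation.

Top-ranked motifs from a trained model's global importance ranking are
implanted into a fixed-length template sequence: a seeded random
permutation of (motif x copy) instances is placed at random
non-overlapping positions, replacing template bases so the final
length is unchanged.  The designs can be scanned back to confirm each
implant is recoverable at its recorded coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motifs import ALPHABET, PWM
from .shap_interpret import ImportanceRanking


@dataclass
class SRESpec:
    template: str
    motifs: list[PWM]
    copies_per_motif: int = 2
    n_designs: int = 5
    target_length: int | None = None
    sample_instances: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.template = self.template.upper()
        if self.target_length is None:
            self.target_length = len(self.template)
        if len(self.template) != self.target_length:
            raise ValueError("template length must equal target_length")
        need = self.copies_per_motif * sum(m.width for m in self.motifs)
        if need > self.target_length:
            raise ValueError(
                f"implants need {need} bases but the template has only "
                f"{self.target_length}")


@dataclass
class SyntheticElement:
    name: str
    sequence: str
    implants: list[tuple[str, int, str, str]]  # motif_id, start, strand, instance
    seed: int


def select_top_motifs(ranking: ImportanceRanking, k: int = 5) -> list[str]:
    """First k motif ids of the global importance ranking."""
    order = ranking.motif_order
    if k > len(order):
        raise ValueError(f"requested top {k} of {len(order)} ranked motifs")
    return order[:k]


def consensus(pwm: PWM) -> str:
    """Per-position argmax base, ties broken in A<C<G<T order."""
    return pwm.consensus()


def _sample_instance(pwm: PWM, rng: np.random.Generator) -> str:
    draws = [rng.choice(4, p=row) for row in pwm.probs]
    return "".join(ALPHABET[i] for i in draws)


def design_sres(spec: SRESpec, max_retries: int = 1000) -> list[SyntheticElement]:
    """Generate `n_designs` elements with non-overlapping implants.

    Instances are PWM consensus strings by default (seeded PWM samples
    with `sample_instances=True`); placement order is a seeded random
    permutation, positions are uniform with rejection of overlaps.
    """
    rng = np.random.default_rng(spec.seed)
    designs: list[SyntheticElement] = []
    L = spec.target_length
    for d in range(spec.n_designs):
        instances = []
        for pwm in spec.motifs:
            for _ in range(spec.copies_per_motif):
                inst = _sample_instance(pwm, rng) if spec.sample_instances else pwm.consensus()
                instances.append((pwm.id, inst))
        order = rng.permutation(len(instances))
        placed: list[tuple[str, int, str, str]] = []
        occupied: list[tuple[int, int]] = []
        seq = list(spec.template)
        failed = False
        for idx in order:
            motif_id, inst = instances[idx]
            w = len(inst)
            for _ in range(max_retries):
                start = int(rng.integers(0, L - w + 1))
                if all(start + w <= s or start >= e for s, e in occupied):
                    break
            else:
                failed = True
                break
            occupied.append((start, start + w))
            seq[start:start + w] = list(inst)
            placed.append((motif_id, start, "+", inst))
        if failed:
            raise RuntimeError(
                f"design {d}: could not place {sum(len(i[1]) for i in instances)} "
                f"implant bases into {L} after {max_retries} retries")
        placed.sort(key=lambda t: t[1])
        designs.append(SyntheticElement(f"sre_{d}", "".join(seq), placed, spec.seed))
    return designs


def write_designs(designs: list[SyntheticElement], fasta_path: str,
                  table_path: str) -> None:
    with open(fasta_path, "w") as fh:
        for d in designs:
            fh.write(f">{d.name}\n{d.sequence}\n")
    with open(table_path, "w") as fh:
        fh.write("design\tmotif\tstart\tstrand\tinstance\n")
        for d in designs:
            for motif_id, start, strand, inst in d.implants:
                fh.write(f"{d.name}\t{motif_id}\t{start}\t{strand}\t{inst}\n")
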