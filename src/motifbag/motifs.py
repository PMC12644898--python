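"""Position weight matrices and MEME minimal-format I/O.

A PWM is a per-position probability model of a transcription-factor
binding site over the DNA alphabet A, C, G, T.  Motif databases
(GimmeMotifs clusters, Cis-BP, JASPAR exports) distribute these as
MEME minimal text files, which is the interchange format here.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
# reverse complement permutation of the column order A,C,G,T
RC_PERM = np.array([3, 2, 1, 0])

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class MEMEParseError(ValueError):
    pass


@dataclass
class BackgroundModel:
    """0-order background nucleotide frequencies (A, C, G, T)."""

    freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (4,):
            raise ValueError("background requires exactly 4 frequencies")
        if np.any(self.freqs <= 0):
            raise ValueError("background frequencies must be positive")
        if abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls(np.full(4, 0.25))

    @classmethod
    def from_gc(cls, gc: float) -> "BackgroundModel":
        at = (1.0 - gc) / 2.0
        return cls(np.array([at, gc / 2.0, gc / 2.0, at]))


@dataclass
class PWM:
    """A motif as a width x 4 matrix of per-position base probabilities."""

    id: str
    probs: np.ndarray
    name: str | None = None
    nsites: int | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise ValueError(f"motif {self.id}: probs must be w x 4 with w >= 1")
        if np.any(self.probs < 0):
            raise ValueError(f"motif {self.id}: negative probabilities")
        sums = self.probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-3 + 1e-9):
            raise ValueError(f"motif {self.id}: rows do not sum to 1")
        # renormalize small drift so downstream arithmetic sees exact rows
        self.probs = self.probs / sums[:, None]

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def log_odds(self, background: BackgroundModel, pseudocount: float = 0.1) -> np.ndarray:
        """Log2 odds matrix with a background-proportional pseudocount.

        score(base b at position i) =
            log2((p[i,b] + pseudocount * bg[b]) / ((1 + pseudocount) * bg[b]))
        """
        bg = background.freqs
        num = self.probs + pseudocount * bg[None, :]
        den = (1.0 + pseudocount) * bg[None, :]
        return np.log2(num / den)

    def reverse_complement(self) -> "PWM":
        return PWM(id=self.id, name=self.name, nsites=self.nsites,
                   probs=self.probs[::-1, RC_PERM].copy())

    def consensus(self) -> str:
        """Per-position argmax base; ties break in A<C<G<T order."""
        return "".join(ALPHABET[i] for i in np.argmax(self.probs, axis=1))


def parse_meme(source: str | io.TextIOBase) -> tuple[list[PWM], BackgroundModel]:
    """Parse a MEME minimal motif file into PWMs and a background model.

    Accepts a path, raw text, or an open text handle.  Rows off unity by
    up to 1e-3 are renormalized; the background block is optional
    (uniform if absent).
    """
    if isinstance(source, io.TextIOBase):
        text = source.read()
    elif "\n" in source or source.strip().upper().startswith("MEME VERSION"):
        text = source
    else:
        with open(source) as fh:
            text = fh.read()

    lines = text.splitlines()
    background = BackgroundModel.uniform()
    motifs: list[PWM] = []
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if line.lower().startswith("background letter frequencies"):
            i += 1
            tokens: list[str] = []
            while i < n and lines[i].strip() and not lines[i].startswith("MOTIF"):
                tokens.extend(lines[i].split())
                i += 1
            freq_map = {tokens[j].upper(): float(tokens[j + 1]) for j in range(0, len(tokens), 2)}
            freqs = np.array([freq_map.get(b, 0.25) for b in ALPHABET])
            background = BackgroundModel(freqs / freqs.sum())
            continue
        if line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise MEMEParseError(f"line {i + 1}: MOTIF line lacks an identifier")
            motif_id = parts[1]
            motif_name = parts[2] if len(parts) > 2 else None
            i += 1
            # seek the letter-probability header
            width = None
            nsites = None
            while i < n:
                header = lines[i].strip()
                if header.startswith("letter-probability matrix"):
                    m = re.search(r"w\s*=\s*(\d+)", header)
                    width = int(m.group(1)) if m else None
                    m = re.search(r"nsites\s*=\s*(\d+)", header)
                    nsites = int(m.group(1)) if m else None
                    i += 1
                    break
                if header.startswith("MOTIF"):
                    raise MEMEParseError(f"motif {motif_id}: no letter-probability matrix")
                i += 1
            rows: list[list[float]] = []
            while i < n:
                row = lines[i].strip()
                if not row or row.startswith(("MOTIF", "URL", "letter-probability")):
                    break
                fields = row.split()
                try:
                    values = [float(v) for v in fields]
                except ValueError as exc:
                    raise MEMEParseError(
                        f"motif {motif_id}, line {i + 1}: non-numeric matrix row") from exc
                if len(values) != 4:
                    raise MEMEParseError(
                        f"motif {motif_id}, line {i + 1}: expected 4 columns, got {len(values)}")
                rows.append(values)
                i += 1
            if width is not None and len(rows) != width:
                raise MEMEParseError(
                    f"motif {motif_id}: header says w={width} but {len(rows)} rows found")
            if not rows:
                raise MEMEParseError(f"motif {motif_id}: empty matrix")
            motifs.append(PWM(id=motif_id, name=motif_name, nsites=nsites, probs=np.array(rows)))
            continue
        i += 1
    return motifs, background


def write_meme(motifs: list[PWM], background: BackgroundModel | None = None,
               path: str | None = None) -> str:
    """Serialize motifs to MEME minimal format; returns the text."""
    background = background or BackgroundModel.uniform()
    out = io.StringIO()
    out.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
    out.write("Background letter frequencies\n")
    out.write(" ".join(f"{b} {f:.6f}" for b, f in zip(ALPHABET, background.freqs)) + "\n\n")
    for pwm in motifs:
        title = pwm.id if pwm.name is None else f"{pwm.id} {pwm.name}"
        out.write(f"MOTIF {title}\n")
        nsites = pwm.nsites if pwm.nsites is not None else 20
        out.write(f"letter-probability matrix: alength= 4 w= {pwm.width} "
                  f"nsites= {nsites} E= 0\n")
        for row in pwm.probs:
            out.write(" ".join(f"{v:.6f}" for v in row) + "\n")
        out.write("\n")
    text = out.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
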