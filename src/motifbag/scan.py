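"""PWM scanning with exact p-values and FDR filtering.

Sequences are scored on both strands with log-odds matrices.  Window
p-values come from the exact null distribution of the discretized
score under a 0-order background, computed by dynamic programming over
motif positions (the same construction FIMO uses).  Hits passing the
p-value threshold are FDR-adjusted per motif with Benjamini-Hochberg
and retained at a lenient q-value cutoff, reflecting the observation
that degenerate, low-affinity motif matches carry predictive signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .motifs import ALPHABET, RC_PERM, BackgroundModel, PWM, reverse_complement

HIT_COLUMNS = ["seq_id", "motif_id", "start", "end", "strand",
               "score", "p_value", "q_value", "matched"]


@dataclass
class MotifHit:
    """One scored motif occurrence (forward-strand, 0-based half-open)."""

    seq_id: str
    motif_id: str
    start: int
    end: int
    strand: str
    score: float
    p_value: float
    q_value: float | None = None
    matched: str = ""


class ScoreDistribution:
    """Exact discretized null distribution of a log-odds score.

    Per-position scores are rounded to a shared integer grid
    (`resolution` bins across the motif's achievable score range); the
    distribution of the integer total under the background is then
    exact by convolution.  Window scores must be discretized with the
    same grid (`int_matrix`) for tail lookups to be exact.
    """

    def __init__(self, log_odds: np.ndarray, background: BackgroundModel,
                 resolution: int = 1000):
        log_odds = np.asarray(log_odds, dtype=float)
        if not np.all(np.isfinite(log_odds)):
            raise ValueError("log-odds matrix contains non-finite entries")
        self.log_odds = log_odds
        w = log_odds.shape[0]
        lo = float(log_odds.min(axis=1).sum())
        hi = float(log_odds.max(axis=1).sum())
        span = hi - lo
        self.scale = (resolution - 1) / span if span > 0 else 1.0
        self.offsets = log_odds.min(axis=1)  # per-position shift to >= 0
        self.int_matrix = np.rint((log_odds - self.offsets[:, None]) * self.scale).astype(np.int64)

        max_total = int(self.int_matrix.max(axis=1).sum())
        pdf = np.zeros(max_total + 1)
        pdf[0] = 1.0
        bg = background.freqs
        for i in range(w):
            step = np.zeros(int(self.int_matrix[i].max()) + 1)
            for b in range(4):
                step[self.int_matrix[i, b]] += bg[b]
            pdf = np.convolve(pdf, step)
        self.pdf = pdf
        # tail[t] = P(integer score >= t)
        self.tail = np.concatenate([np.cumsum(pdf[::-1])[::-1], [0.0]])
        self.max_total = max_total

    def int_score(self, encoded_window: np.ndarray) -> int:
        return int(self.int_matrix[np.arange(len(encoded_window)), encoded_window].sum())

    def pvalue_of_int(self, t: int) -> float:
        t = max(0, min(t, self.max_total))
        return float(min(1.0, self.tail[t]))

    def pvalue(self, score: float) -> float:
        """Tail probability of a raw log-odds score (discretized lookup)."""
        t = int(np.rint((score - self.offsets.sum()) * self.scale))
        if t < 0:
            return 1.0
        if t > self.max_total:
            return self.pvalue_of_int(self.max_total)
        return self.pvalue_of_int(t)

    def min_int_for_pvalue(self, p_threshold: float) -> int:
        """Smallest integer score whose tail probability is <= p_threshold."""
        idx = np.nonzero(self.tail[: self.max_total + 1] <= p_threshold)[0]
        return int(idx[0]) if len(idx) else self.max_total + 1


def score_pvalue(log_odds: np.ndarray, background: BackgroundModel,
                 resolution: int = 1000) -> ScoreDistribution:
    """Monotone score -> p-value map via the exact discretized DP."""
    return ScoreDistribution(log_odds, background, resolution=resolution)


def encode(seq: str) -> np.ndarray:
    """Map ACGT to 0..3; anything else (N) to -1."""
    table = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(ALPHABET):
        table[ord(b)] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].astype(np.int64)


def _window_scores(enc: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Sum matrix[j, enc[i+j]] over j for every window start i (vectorized)."""
    w = matrix.shape[0]
    n_windows = len(enc) - w + 1
    safe = np.where(enc < 0, 0, enc)
    total = np.zeros(n_windows, dtype=matrix.dtype)
    for j in range(w):
        total += matrix[j, safe[j:j + n_windows]]
    return total


def scan_motifs(sequences: dict[str, str], motifs: list[PWM],
                background: BackgroundModel | None = None,
                p_threshold: float = 1e-4, pseudocount: float = 0.1,
                resolution: int = 1000) -> list[MotifHit]:
    """Scan sequences on both strands; report windows with p <= p_threshold.

    Windows containing N are skipped.  Reverse-strand hits are reported
    in forward coordinates with the matched subsequence as read on the
    hit strand.  q-values are left unset (see :func:`qvalue_filter`).
    """
    background = background or BackgroundModel.uniform()
    encoded = {name: encode(seq) for name, seq in sequences.items()}

    hits: list[MotifHit] = []
    for pwm in motifs:
        w = pwm.width
        fwd = pwm.log_odds(background, pseudocount)
        dist = ScoreDistribution(fwd, background, resolution=resolution)
        min_int = dist.min_int_for_pvalue(p_threshold)
        # reverse-strand matrix in forward coordinates
        rev_float = fwd[::-1][:, RC_PERM]
        rev_int = dist.int_matrix[::-1][:, RC_PERM]
        for name, enc in encoded.items():
            if len(enc) < w:
                continue
            n_windows = len(enc) - w + 1
            has_n = np.convolve((enc < 0).astype(np.int64), np.ones(w, dtype=np.int64),
                                mode="valid") > 0
            for strand, fmat, imat in (("+", fwd, dist.int_matrix),
                                       ("-", rev_float, rev_int)):
                ints = _window_scores(enc, imat)
                ok = np.nonzero((ints >= min_int) & ~has_n)[0]
                if len(ok) == 0:
                    continue
                floats = _window_scores(enc, fmat)
                seq = sequences[name]
                for i in ok:
                    sub = seq[i:i + w]
                    hits.append(MotifHit(
                        seq_id=name, motif_id=pwm.id, start=int(i), end=int(i + w),
                        strand=strand, score=float(floats[i]),
                        p_value=dist.pvalue_of_int(int(ints[i])),
                        matched=sub if strand == "+" else reverse_complement(sub)))
    return hits


def qvalue_filter(hits: list[MotifHit], q_cutoff: float = 0.5) -> list[MotifHit]:
    """Benjamini-Hochberg per motif across the whole run; keep q <= cutoff."""
    if not hits:
        return []
    by_motif: dict[str, list[MotifHit]] = {}
    for h in hits:
        by_motif.setdefault(h.motif_id, []).append(h)
    kept: list[MotifHit] = []
    for group in by_motif.values():
        pvals = np.array([h.p_value for h in group])
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for h, q in zip(group, qvals):
            h.q_value = float(q)
            if h.q_value <= q_cutoff:
                kept.append(h)
    return kept


def remove_overlapping_hits(hits: list[MotifHit], seed: int = 0) -> list[MotifHit]:
    """Greedily resolve overlapping hits per sequence, keeping higher scores.

    While any two retained hits on a sequence overlap (strand-agnostic
    interval intersection), the lowest-scoring hit involved in an
    overlap is removed; exact score ties are broken by a seeded uniform
    choice.  The survivors are pairwise non-overlapping.
    """
    rng = np.random.default_rng(seed)
    by_seq: dict[str, list[MotifHit]] = {}
    for h in hits:
        by_seq.setdefault(h.seq_id, []).append(h)

    kept: list[MotifHit] = []
    for seq_id in sorted(by_seq):
        group = sorted(by_seq[seq_id], key=lambda h: (h.start, h.end))
        alive = list(group)
        while True:
            overlapped = set()
            for i in range(len(alive)):
                for j in range(i + 1, len(alive)):
                    if alive[j].start >= alive[i].end:
                        break
                    overlapped.update((i, j))
            if not overlapped:
                break
            min_score = min(alive[i].score for i in overlapped)
            lowest = [i for i in overlapped if alive[i].score == min_score]
            drop = lowest[0] if len(lowest) == 1 else int(rng.choice(lowest))
            alive.pop(drop)
        kept.extend(alive)
    return kept


def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(h, c) for c in HIT_COLUMNS} for h in hits],
                        columns=HIT_COLUMNS)


def write_hits_tsv(hits: list[MotifHit], path: str) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def read_hits_tsv(path: str) -> list[MotifHit]:
    """Read a hit table (internal or FIMO-style column names)."""
    df = pd.read_csv(path, sep="\t")
    renames = {"sequence_name": "seq_id", "sequence": "seq_id", "motif": "motif_id",
               "stop": "end", "p-value": "p_value", "q-value": "q_value",
               "matched_sequence": "matched"}
    df = df.rename(columns=renames)
    out = []
    for row in df.itertuples(index=False):
        q = getattr(row, "q_value", None)
        out.append(MotifHit(seq_id=str(row.seq_id), motif_id=str(row.motif_id),
                            start=int(row.start), end=int(row.end), strand=str(row.strand),
                            score=float(row.score), p_value=float(row.p_value),
                            q_value=None if q is None or pd.isna(q) else float(q),
                            matched=str(getattr(row, "matched", ""))))
    return out
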