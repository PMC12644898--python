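"""Independent reference implementations used to verify the package.

These deliberately avoid the library's vectorized code paths: plain
Python loops over every window/word/pair, so that agreement with the
implementation is evidence rather than tautology.
"""

import numpy as np

from motifbag.motifs import ALPHABET, reverse_complement
from motifbag.scan import ScoreDistribution


def random_sequences(n, length, seed):
    rng = np.random.default_rng(seed)
    return {f"s{i}": "".join(ALPHABET[b] for b in rng.integers(0, 4, size=length))
            for i in range(n)}


def brute_force_hits(sequences, motifs, background, p_threshold, pseudocount=0.1):
    """Score every window on both strands directly; threshold on p-value.

    Reverse-strand windows are scored by reverse-complementing the
    window text and applying the forward-strand matrices.
    """
    out = []
    for pwm in motifs:
        lo = pwm.log_odds(background, pseudocount)
        dist = ScoreDistribution(lo, background)
        for name, seq in sequences.items():
            w = pwm.width
            for start in range(len(seq) - w + 1):
                window = seq[start:start + w]
                if "N" in window:
                    continue
                for strand in "+-":
                    text = window if strand == "+" else reverse_complement(window)
                    idx = [ALPHABET.index(c) for c in text]
                    int_score = sum(dist.int_matrix[j, b] for j, b in enumerate(idx))
                    if dist.pvalue_of_int(int_score) <= p_threshold:
                        score = sum(lo[j, b] for j, b in enumerate(idx))
                        out.append((name, pwm.id, start, strand, score))
    return out


def oracle_overlap_removal(hits):
    """Literal rule: drop the lowest-scoring overlapped hit until clean."""
    alive = list(hits)
    while True:
        overlapped = [h for h in alive
                      if any(o is not h and o.seq_id == h.seq_id
                             and h.start < o.end and o.start < h.end for o in alive)]
        if not overlapped:
            return alive
        alive.remove(min(overlapped, key=lambda h: h.score))
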