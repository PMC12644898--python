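"""Classify cell-type-specific CREs from motif counts.

Simulates two classes of 500-bp regulatory sequences (five
discriminative motifs implanted at 0.8 vs 0.05, twenty shared decoys),
scans them into a bag-of-motifs count matrix, trains a boosted-tree
classifier on a balanced dataset and reports held-out performance.
"""

from motifbag.pipeline import run_recovery

res = run_recovery(seed=1, n_per_class=200)

print("held-out test metrics (200 CREs/class, balanced 1:1):")
for key in ("accuracy", "precision", "recall", "f1", "mcc", "auroc", "aupr"):
    print(f"  {key:10s} {res.metrics[key]:.3f}")
print()
print("The model separates the two classes almost perfectly (auROC near 1)")
print("because class membership is encoded in the implanted motif counts;")
print("decoy motifs occur equally in both classes and carry no signal.")
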