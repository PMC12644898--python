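"""Define distal non-exonic CRE windows and flanking negatives.

Builds a toy annotation, applies the >1-kb-from-TSS and non-exonic
filters while trimming peaks to fixed 500-bp windows, and tiles
flanking negative windows around a surviving CRE.
"""

from motifbag.genome_io import (GeneAnnotation, GenomicInterval, LabeledCRESet,
                                define_cres, flanking_negatives)

peaks = LabeledCRESet(
    [GenomicInterval("chr1", 5800, 6300, "near_tss"),
     GenomicInterval("chr1", 20100, 20600, "in_exon"),
     GenomicInterval("chr1", 52000, 52800, "good_distal", summit=52300)],
    {"near_tss": ["heart"], "in_exon": ["heart"], "good_distal": ["heart"]})

annotation = GeneAnnotation(tss_positions={"chr1": [5000, 40000]},
                            exon_intervals={"chr1": [(20000, 21000)]})

cres = define_cres(peaks, annotation, min_tss_distance=1000, width=500)
print("surviving CREs after distal/non-exonic filtering:")
for iv in cres.intervals:
    print(f"  {iv.name}: {iv.chrom}:{iv.start}-{iv.end} ({iv.width} bp)")

flanks = flanking_negatives(cres, span=2000, width=500, stride=50)
print(f"flanking negatives: {len(flanks)} windows of 500 bp at 50-bp stride")
print()
print("'near_tss' fails the edge-distance rule (800 bp < 1 kb), 'in_exon'")
print("overlaps an exon; the survivor is centered on its summit and then")
print("surrounded by +-2-kb sliding negatives that avoid every input CRE.")
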