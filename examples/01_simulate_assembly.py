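"""Generate a synthetic redundant assembly and inspect its composition.

The generator fragments each reference gene into one near-full-length
contig plus several partial contigs (the redundancy de novo assemblers
produce from incomplete read coverage) and adds erroneous contigs with
no gene of origin.
"""

from contigdedup.metrics import summarize_lengths
from contigdedup.synthetic import generate_dataset

ds = generate_dataset(seed=0)

n_error = len(ds.truth.error_contig_ids(ds.contigs))
genes_stats = summarize_lengths(ds.genes)
contig_stats = summarize_lengths(ds.contigs)

print(f"reference genes : {len(ds.genes)} (N50 {genes_stats.n50} b, mean {genes_stats.mean_len:.0f} b)")
print(f"raw contigs     : {len(ds.contigs)} (N50 {contig_stats.n50} b, mean {contig_stats.mean_len:.0f} b)")
print(f"  of gene origin: {len(ds.truth.contig_to_gene)}")
print(f"  erroneous     : {n_error}")
print(f"homology hits   : {len(ds.hits)} HSP rows")

# The assembly holds ~3x more contigs than genes, and the contigs are
# shorter on average than the genes they derive from — the redundancy
# and fragmentation that removal methods must undo.
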