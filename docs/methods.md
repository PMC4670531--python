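# Methods

## Scope and model

The package operates downstream of a de novo transcriptome assembly.
Its inputs are the assembly (FASTA with assembler-structured IDs),
homology hits of those contigs against a reference gene or protein set
(BLAST tabular format 6), optional cluster membership (CD-HIT `.clstr`),
per-feature read counts for two conditions (2-column TSV or SAM/BAM),
and a flat gene-to-GO-slim annotation table. Nothing in the package runs
an assembler, aligner, BLAST or clustering tool; it consumes their
standard output formats.

The underlying picture: each expressed gene gives rise to one or more
contigs — ideally one near-complete contig, in practice several partial
overlapping ones when read coverage is uneven — plus a background of
erroneous contigs assembled from mis-read or chimeric reads. Redundancy
removal tries to recover a one-contig-per-gene reference.

## Gene assignment and classification

HSP rows are aggregated per (contig, gene) pair by the **maximum**
single-HSP bit score (not the sum); each contig is assigned the gene
with the highest aggregated score. Ties break by lower e-value, then
lexicographically smaller gene ID. Deliberately, no e-value or identity
cut-off is applied — weak hits still anchor a contig to a gene.

Classification is defined on these one-per-contig assignments, which
makes the three categories a partition: a contig is *unique-hit* when it
is the only contig assigned to its gene, *multiple-hit* when the gene is
shared, *no-hit* when it has no hits at all. The alternative reading
(classify on all hits rather than the best one) makes the categories
overlap and cannot yield the structural 100%-unique outcome that
best-bit-score selection guarantees, so it was rejected.

## The three removal methods

* **Longest per subcomponent.** The subcomponent key is parsed from the
  contig ID by stripping the isoform suffix; both the classic
  `comp<i>_c<j>_seq<k>` and the newer `TRINITY_DN<i>_c<j>_g<k>_i<l>`
  dialects are recognized, and anything else forms a singleton
  subcomponent. Failure mode: when the assembler builds two
  subcomponents from one gene, both survive.
* **Cluster representative.** The `*`-marked representative of each
  cluster is kept; clusters without a mark fall back to the longest
  member. Contigs outside every cluster pass through (kept) with a
  warning tally. Failure mode: partial contigs of one gene that share no
  sequence overlap never cluster together.
* **Annotated best hit.** For each gene, the contig assigned to it with
  the highest bit score is kept; ties break by longer contig, then
  smaller ID. The selection pool is "contigs whose own best hit is g",
  not "contigs with any hit to g" — this guarantees each contig competes
  for at most one gene, so the kept set is a bijection with the covered
  genes and re-classifies as entirely unique-hit. All no-hit contigs are
  removed.

Tie-breaking everywhere is primary criterion → longer contig → smaller
ID, purely for determinism; the underlying method statements are silent
on ties.

The built-in `greedy_cluster` is a desk-scale clusterer so the
cluster-representative path runs self-contained: longest-first greedy
assignment by exact 16-mer containment of the shorter sequence against
the cluster representative (default threshold 0.9). It mirrors the
incremental scheme of CD-HIT-like tools but is *not* claimed to
reproduce their output; note that k-mer containment is conservative
under substitutions (a 1% substitution rate destroys ~15% of 16-mers),
so clusters are tighter than alignment-based ones.

## Expression and differential calling

RPKM = C·10⁹/(N·L) with C the feature count, L the feature length and N
the library's total mapped reads. For SAM input, a record counts when it
is mapped, primary and non-supplementary; each mate of a pair counts
once (the per-mate convention is a documented choice, not derivable from
the method statement). A pseudocount of 1 is added to each RPKM before
the log2 ratio, so absent features stay finite. Features with
|log₂FC| > 1 — strictly greater, i.e. more than 2-fold in either
direction — are called differential. The threshold is a parameter;
reading the cut-off as a raw (not log) fold change of 1 would call half
of everything and is therefore not the default.

For the gene/contig scatter, every contig pairs with its assigned gene's
fold change (several contigs of one gene each pair with it); genes with
no contig and contigs with no gene sit on the axes at 0. The headline
Pearson correlation includes those axis-aligned rows — removing
erroneous contigs moves points off the Y axis, which is precisely the
mechanism by which redundancy removal improves the correlation. A
matched-rows-only correlation is also computed and reported alongside.

## Co-identity and GO comparison

A DEC is co-identical when its assigned gene ID is in the DEG set;
unassigned DECs are nonidentical. Two ratios are emitted: the DEC-based
percentage (identical DECs over all DECs) and the distinct-DEG coverage
(distinct DEGs hit over all DEGs); they differ when DECs are redundant.

GO slim comparison treats the per-term annotation counts of the two
differential sets as two samples with one observation per term (the
quantile–quantile view) and applies the asymptotic two-sample
Kolmogorov–Smirnov test; the statistic is invariant under permuting the
term universe. Per term, a two-sided Fisher exact test is run on the 2×2
table [features with term / without term] × [DEG set / DEC set], and the
count of terms with p < 0.05 is reported without multiple-testing
correction (the comparison metric is that raw count). GO graph
propagation and slimming from the full ontology are out of scope;
annotations arrive as a flat table.

## Synthetic data generator

The generator emulates the generative claims the methods rest on:
fragmentation of genes into redundant partial contigs, occasional
splitting of one gene across two subcomponents, and erroneous no-origin
contigs. Defaults (the conditions all end-to-end tests use): 100 genes
of 300–3000 nt (uniform), K = 1 + Poisson(2) contigs per gene of which
one is near-full-length (90–100% of the gene) and the rest are 20–70%
fragments, 1% point substitutions, 15% of multi-contig genes split
across two subcomponents, 10 error contigs of 120–1000 nt, 10%
cross-hit probability.

Simulated hit rows use the bit-score surrogate **2 × matched bases** —
monotone in alignment quality, which is the only property selection
uses; it is not a BLAST score model. Error contigs get no rows.

Counts: per-gene base expression is log-uniform on [5, 500] (arbitrary
transcripts-per-unit scale spanning two decades); expected reads are
expression × length(kb) × depth (default depth 50) and realised counts
are Poisson. Twenty planted genes change 4-fold in condition B, half up
and half down. The up/down split is chosen to approximately conserve
total transcriptional output (low-expression-mass genes up, refined by
deterministic pairwise swaps): an unconstrained split can shift the
library total several-fold, which moves every null gene's RPKM ratio —
a real compositional pathology of total-count normalisation that would
make "recover exactly the planted set" ill-posed. Conserved total output
is the same invariance assumption global normalisation methods make.

Contig counts follow the true gene's expression scaled by the
contig/gene length ratio. Partial fragments carry extra multiplicative
lognormal noise (σ = 0.5 on the natural-log scale), modelling ambiguous
read assignment among overlapping partials; each gene's near-full-length
contig is quantified cleanly. Error contigs draw independent expression
per condition, so their apparent fold changes are artifacts — as for
real mis-assembled contigs. All randomness flows from one top-level seed
through named substreams (`genes`, `fragment`, `blast`, `counts`, `go`),
so every artifact is reproducible file for file.

What the generator does **not** model: read-level simulation and actual
alignment (counts are drawn, not mapped), splice variants, multi-mapping
between gene paralogs, library-preparation biases, and biological
replicate variance. Passing end-to-end tests therefore demonstrates the
selection and evaluation logic under the stated generative model, not
performance on real libraries.

## Evaluation pipeline conventions

When a removal method keeps a subset of contigs, the contig count tables
are restricted to the kept contigs and the mapped-read total is
recomputed over them — emulating a re-mapping of the libraries against
the reduced reference. (In a real re-mapping, reads from removed contigs
would partially re-map to kept ones; the subset approximation ignores
that gain.)

Problem sizes throughout tests and examples are desk-scale (100 genes,
~300 contigs, 20-seed sweeps for structural and recovery properties);
the structural guarantees checked are size-independent.

## Numerical choices

* N50 uses the cumulative convention: the length at which the
  descending-sorted cumulative sum first reaches ≥ half of total bases.
  Median is the lower middle value for even n, so every reported
  statistic is an attained length.
* KS uses the asymptotic p-value (`scipy.stats.ks_2samp`,
  `method="asymp"`); Fisher uses `scipy.stats.fisher_exact`, two-sided.
* Pearson correlation is reported as missing (None/NA) below 2 rows or
  at zero variance on either axis.
* Defaults: fold-change threshold 1 (log2), significance level 0.05,
  cluster identity threshold 0.9.

## Known limitations

* The greedy clusterer is not CD-HIT; cluster-method results on real
  data should use a real `.clstr` file.
* The annotated method inherits the reference's completeness: genes
  missing from the reference lose their contigs entirely (they become
  no-hit and are removed).
* Single-replicate threshold calling has no error model; the framework
  deliberately mirrors that simplicity rather than adding one.
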