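"""End-to-end study orchestration.

Given one dataset (synthetic or loaded from files), run every
redundancy-removal method, re-classify each resulting contig set, call
DECs against the gene gold standard, and evaluate co-identity,
fold-change correlation and GO-distribution distance per method — the
structure of a full comparison of raw vs redundancy-removed references.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from contigdedup.classify import (
    ClassificationSummary,
    GeneAssignment,
    best_hit_per_contig,
    classify_contigs,
)
from contigdedup.dedup import (
    DedupResult,
    greedy_cluster,
    select_annotated,
    select_cluster_representatives,
    select_longest_per_subcomponent,
)
from contigdedup.evaluation import (
    CoIdentityReport,
    GoComparisonReport,
    co_identity,
    compare_go_distributions,
)
from contigdedup.expression import (
    build_expression_table,
    call_differential,
    pair_fold_changes,
    pearson,
)
from contigdedup.io import BlastHit, ContigRecord, CountTable, GoAnnotationMap
from contigdedup.metrics import LengthSummary, summarize_lengths
from contigdedup.synthetic import SyntheticDataset

METHODS = ("raw", "longest", "clustered", "annotated")


@dataclass
class MethodReport:
    """Everything measured for one contig set (one method's output)."""

    method: str
    n_kept: int
    lengths: LengthSummary
    classification: ClassificationSummary
    n_dec: int
    correlation: Optional[float]
    correlation_matched_only: Optional[float]
    co_identity: CoIdentityReport
    go: Optional[GoComparisonReport]


def apply_method(
    method: str,
    contigs: Sequence[ContigRecord],
    hits: Sequence[BlastHit],
    identity_threshold: float = 0.9,
) -> DedupResult:
    """Run one named method; 'raw' keeps everything."""
    if method == "raw":
        return DedupResult("longest_subcomponent", {c.contig_id for c in contigs}, set())
    if method == "longest":
        return select_longest_per_subcomponent(contigs)
    if method == "clustered":
        clusters = greedy_cluster(contigs, identity_threshold=identity_threshold)
        return select_cluster_representatives(contigs, clusters)
    if method == "annotated":
        return select_annotated(contigs, hits)
    raise ValueError(f"unknown method {method!r}")


def _subset_counts(table: CountTable, ids: set[str]) -> CountTable:
    sub = {fid: c for fid, c in table.feature_counts.items() if fid in ids}
    return CountTable(sub, sum(sub.values()))


def evaluate_contig_set(
    method: str,
    kept: Sequence[ContigRecord],
    hits: Sequence[BlastHit],
    gene_lengths: dict[str, int],
    gene_counts_a: CountTable,
    gene_counts_b: CountTable,
    contig_counts_a: CountTable,
    contig_counts_b: CountTable,
    go_map: Optional[GoAnnotationMap] = None,
    fc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> MethodReport:
    """Measure one contig set against the gene gold standard.

    Count tables for the contig set are restricted to the kept contigs
    with the mapped-read total recomputed over them, emulating a
    re-mapping of the libraries against the reduced reference.
    """
    kept_ids = {c.contig_id for c in kept}
    set_hits = [h for h in hits if h.query_id in kept_ids]
    assignments: dict[str, GeneAssignment] = best_hit_per_contig(set_hits)
    _, classification = classify_contigs(kept, assignments)

    gene_records = build_expression_table(
        gene_counts_a, gene_counts_b, gene_lengths, fc_threshold
    )
    deg_ids = call_differential(gene_records, fc_threshold)

    contig_lengths = {c.contig_id: c.length for c in kept}
    cca = _subset_counts(contig_counts_a, kept_ids)
    ccb = _subset_counts(contig_counts_b, kept_ids)
    contig_records = build_expression_table(cca, ccb, contig_lengths, fc_threshold)
    dec_ids = call_differential(contig_records, fc_threshold)

    pairs = pair_fold_changes(gene_records, contig_records, assignments)
    coid = co_identity(dec_ids, deg_ids, assignments)

    go_report = None
    if go_map is not None:
        dec_genes = {
            assignments[cid].gene_id for cid in dec_ids if cid in assignments
        }
        go_report = compare_go_distributions(deg_ids, dec_genes, go_map, alpha=alpha)

    return MethodReport(
        method=method,
        n_kept=len(kept),
        lengths=summarize_lengths(list(kept)),
        classification=classification,
        n_dec=len(dec_ids),
        correlation=pearson(pairs),
        correlation_matched_only=pearson(pairs, matched_only=True),
        co_identity=coid,
        go=go_report,
    )


def run_study(
    dataset: SyntheticDataset,
    methods: Sequence[str] = METHODS,
    identity_threshold: float = 0.9,
    fc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> dict[str, MethodReport]:
    """Run every method on one dataset and evaluate each contig set."""
    by_id = {c.contig_id: c for c in dataset.contigs}
    gene_lengths = {g.contig_id: g.length for g in dataset.genes}
    reports: dict[str, MethodReport] = {}
    for method in methods:
        result = apply_method(
            method, dataset.contigs, dataset.hits, identity_threshold=identity_threshold
        )
        kept = [by_id[cid] for cid in sorted(result.kept_ids)]
        reports[method] = evaluate_contig_set(
            method,
            kept,
            dataset.hits,
            gene_lengths,
            dataset.gene_counts_a,
            dataset.gene_counts_b,
            dataset.contig_counts_a,
            dataset.contig_counts_b,
            go_map=dataset.go_map,
            fc_threshold=fc_threshold,
            alpha=alpha,
        )
    return reports


def study_summary_tsv(reports: dict[str, MethodReport]) -> str:
    """A combined per-method summary table (counts, lengths, DE metrics)."""
    lines = [
        "method\tn_kept\tn50\tmean_len\tn_unique_hit\tn_multiple_hit\tn_no_hit\t"
        "n_dec\tcorrelation\tn_dec_identical\tn_dec_nonidentical\t"
        "ks_statistic\tks_pvalue\tn_significant_go_terms"
    ]
    for method, r in reports.items():
        corr = f"{r.correlation:.4f}" if r.correlation is not None else "NA"
        ks_s = f"{r.go.ks_statistic:.4f}" if r.go else "NA"
        ks_p = f"{r.go.ks_pvalue:.4g}" if r.go else "NA"
        n_sig = str(r.go.n_significant_terms) if r.go else "NA"
        lines.append(
            f"{method}\t{r.n_kept}\t{r.lengths.n50}\t{round(r.lengths.mean_len)}\t"
            f"{r.classification.n_unique_hit}\t{r.classification.n_multiple_hit}\t"
            f"{r.classification.n_no_hit}\t{r.n_dec}\t{corr}\t"
            f"{r.co_identity.n_dec_identical}\t{r.co_identity.n_dec_nonidentical}\t"
            f"{ks_s}\t{ks_p}\t{n_sig}"
        )
    return "\n".join(lines) + "\n"
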