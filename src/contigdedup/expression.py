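"""RPKM quantification, pseudocounted log2 fold change, and DEC/DEG calling.

Expression of each feature (gene or contig) is measured as RPKM — reads
per kilobase of feature per million mapped reads.  A pseudocount of 1 is
added to each RPKM before taking the log2 ratio between the two
conditions, so features absent from one library still receive a finite
fold change.  Features whose absolute log2 fold change exceeds the
threshold (default 1, i.e. more than 2-fold in either direction) are
called differentially expressed: DEGs for the gene gold standard, DECs
for a contig set.  Contig fold changes are paired with their assigned
gene's fold change for the scatter correlation; unmatched features sit
on the axes (gene axis = genes no contig hit, contig axis = contigs
with no assigned gene).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

from scipy import stats

from contigdedup.classify import GeneAssignment
from contigdedup.io import CountTable

PairingStatus = Literal["matched", "gene_only", "contig_only"]


@dataclass(frozen=True)
class ExpressionRecord:
    feature_id: str
    count_a: int
    count_b: int
    rpkm_a: float
    rpkm_b: float
    log2fc: float
    is_differential: bool


@dataclass(frozen=True)
class PairedFoldChange:
    """One point of the gene-vs-contig fold-change scatter.

    ``gene_only`` rows have ``contig_log2fc == 0`` (gene axis);
    ``contig_only`` rows have ``gene_log2fc == 0`` (contig axis).
    """

    gene_id: str
    gene_log2fc: float
    contig_log2fc: float
    pairing_status: PairingStatus


def rpkm(count: int, length: int, total_mapped: int) -> float:
    """Reads per kilobase of feature per million mapped reads.

    ``count * 1e9 / (total_mapped * length)``.
    """
    if length < 1:
        raise ValueError("feature length must be >= 1")
    if total_mapped < 1:
        raise ValueError("total_mapped must be >= 1")
    return count * 1e9 / (total_mapped * length)


def log2_fold_change(rpkm_a: float, rpkm_b: float) -> float:
    """log2((rpkm_b + 1) / (rpkm_a + 1)) — pseudocounted, B over A."""
    if rpkm_a < 0 or rpkm_b < 0:
        raise ValueError("RPKM values must be >= 0")
    return math.log2((rpkm_b + 1.0) / (rpkm_a + 1.0))


def build_expression_table(
    counts_a: CountTable,
    counts_b: CountTable,
    lengths: Mapping[str, int],
    fc_threshold: float = 1.0,
) -> list[ExpressionRecord]:
    """Quantify every feature in ``lengths`` across the two conditions.

    Features missing from a count table get count 0 in that condition.
    """
    if fc_threshold <= 0:
        raise ValueError("fc_threshold must be > 0")
    records = []
    for fid in sorted(lengths):
        ca = counts_a.feature_counts.get(fid, 0)
        cb = counts_b.feature_counts.get(fid, 0)
        ra = rpkm(ca, lengths[fid], counts_a.total_mapped)
        rb = rpkm(cb, lengths[fid], counts_b.total_mapped)
        fc = log2_fold_change(ra, rb)
        records.append(
            ExpressionRecord(fid, ca, cb, ra, rb, fc, abs(fc) > fc_threshold)
        )
    return records


def call_differential(
    records: Sequence[ExpressionRecord], threshold: float = 1.0
) -> set[str]:
    """IDs of features with |log2fc| strictly greater than ``threshold``."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return {r.feature_id for r in records if abs(r.log2fc) > threshold}


def pair_fold_changes(
    gene_records: Sequence[ExpressionRecord],
    contig_records: Sequence[ExpressionRecord],
    assignments: Mapping[str, GeneAssignment],
) -> list[PairedFoldChange]:
    """Pair each contig's fold change with its assigned gene's.

    Several contigs assigned to one gene (non-deduplicated sets) each
    yield their own row against that gene's fold change.  Genes with no
    assigned contig become gene-axis rows; contigs with no assignment
    become contig-axis rows.
    """
    gene_fc = {r.feature_id: r.log2fc for r in gene_records}
    pairs: list[PairedFoldChange] = []
    covered_genes: set[str] = set()
    for r in contig_records:
        a = assignments.get(r.feature_id)
        if a is not None and a.gene_id in gene_fc:
            pairs.append(
                PairedFoldChange(a.gene_id, gene_fc[a.gene_id], r.log2fc, "matched")
            )
            covered_genes.add(a.gene_id)
        else:
            pairs.append(PairedFoldChange("", 0.0, r.log2fc, "contig_only"))
    for gid, fc in gene_fc.items():
        if gid not in covered_genes:
            pairs.append(PairedFoldChange(gid, fc, 0.0, "gene_only"))
    return pairs


def pearson(
    pairs: Sequence[PairedFoldChange], matched_only: bool = False
) -> Optional[float]:
    """Pearson correlation of gene vs contig log2 fold changes.

    By default all rows enter, including the axis-aligned unmatched ones
    — erroneous and missing features are what degrade the correlation,
    and removing them is the effect under evaluation.  Returns None when
    the correlation is undefined (fewer than 2 rows or zero variance on
    either axis).
    """
    rows = [p for p in pairs if p.pairing_status == "matched"] if matched_only else pairs
    if len(rows) < 2:
        return None
    x = [p.gene_log2fc for p in rows]
    y = [p.contig_log2fc for p in rows]
    if len(set(x)) == 1 or len(set(y)) == 1:
        return None
    r, _ = stats.pearsonr(x, y)
    return float(r)


def expression_table_tsv(records: Sequence[ExpressionRecord]) -> str:
    lines = ["feature_id\tcount_a\tcount_b\trpkm_a\trpkm_b\tlog2fc\tis_differential"]
    for r in records:
        lines.append(
            f"{r.feature_id}\t{r.count_a}\t{r.count_b}\t{r.rpkm_a:.4f}\t"
            f"{r.rpkm_b:.4f}\t{r.log2fc:.4f}\t{int(r.is_differential)}"
        )
    return "\n".join(lines) + "\n"
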