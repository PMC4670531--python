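"""Per-contig gene assignment and three-way contig classification.

HSP-level homology hits are reduced to at most one gene per contig: HSPs
are aggregated per (contig, gene) pair by maximum bit score, and the
contig is assigned the gene with the highest aggregated score.  No
e-value or identity cut-off is applied.  Contigs are then classified as
*unique hit* (their assigned gene is shared with no other contig),
*multiple hit* (the gene is shared, i.e. the contigs are redundant), or
*no hit* (no homology to any reference gene — presumed erroneous).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

from contigdedup.io import BlastHit, ContigRecord

Label = Literal["unique", "multiple", "no_hit"]


@dataclass(frozen=True)
class GeneAssignment:
    """The best-hit gene of one contig, with its winning scores."""

    contig_id: str
    gene_id: str
    best_bitscore: float
    best_evalue: float


@dataclass(frozen=True)
class ClassificationSummary:
    """Counts and percentages of the three contig categories.

    ``n_hit = n_unique_hit + n_multiple_hit`` and
    ``n_total = n_hit + n_no_hit``; percentages are relative to
    ``n_total``.
    """

    n_total: int
    n_hit: int
    n_unique_hit: int
    n_multiple_hit: int
    n_no_hit: int

    def _pct(self, n: int) -> float:
        return 100.0 * n / self.n_total if self.n_total else 0.0

    @property
    def pct_hit(self) -> float:
        return self._pct(self.n_hit)

    @property
    def pct_unique_hit(self) -> float:
        return self._pct(self.n_unique_hit)

    @property
    def pct_multiple_hit(self) -> float:
        return self._pct(self.n_multiple_hit)

    @property
    def pct_no_hit(self) -> float:
        return self._pct(self.n_no_hit)


def best_hit_per_contig(hits: Iterable[BlastHit]) -> dict[str, GeneAssignment]:
    """Assign each query contig its best-hit gene.

    HSPs are aggregated per (query, subject) pair by maximum single-HSP
    bit score (the lowest e-value over those HSPs is carried alongside);
    the subject with the highest aggregated score wins.  Ties are broken
    by lower e-value, then lexicographically smaller subject ID.  No
    filtering by e-value or identity is applied.
    """
    # (query, subject) -> (max bitscore, min evalue)
    pair_best: dict[tuple[str, str], tuple[float, float]] = {}
    for h in hits:
        key = (h.query_id, h.subject_id)
        cur = pair_best.get(key)
        if cur is None:
            pair_best[key] = (h.bitscore, h.evalue)
        else:
            pair_best[key] = (max(cur[0], h.bitscore), min(cur[1], h.evalue))

    per_query: dict[str, list[tuple[str, float, float]]] = {}
    for (query, subject), (score, evalue) in pair_best.items():
        per_query.setdefault(query, []).append((subject, score, evalue))

    assignments: dict[str, GeneAssignment] = {}
    for query, candidates in per_query.items():
        # highest bitscore, then lowest evalue, then smallest subject ID
        subject, score, evalue = min(candidates, key=lambda c: (-c[1], c[2], c[0]))
        assignments[query] = GeneAssignment(query, subject, score, evalue)
    return assignments


def classify_contigs(
    contigs: Sequence[ContigRecord],
    assignments: Mapping[str, GeneAssignment],
) -> tuple[dict[str, Label], ClassificationSummary]:
    """Label every contig unique / multiple / no_hit and summarise.

    Contigs absent from ``assignments`` are *no_hit*.  Assigned contigs
    are grouped by their gene: a gene with exactly one assigned contig
    makes that contig *unique*; a gene shared by two or more contigs
    makes every member *multiple*.  The labels partition the input.
    """
    contig_ids = {c.contig_id for c in contigs}
    extraneous = set(assignments) - contig_ids
    if extraneous:
        raise ValueError(
            f"assignments reference contigs not in the input set: {sorted(extraneous)[:5]}"
        )

    gene_groups: dict[str, list[str]] = {}
    for cid in contig_ids:
        a = assignments.get(cid)
        if a is not None:
            gene_groups.setdefault(a.gene_id, []).append(cid)

    labels: dict[str, Label] = {}
    for c in contigs:
        a = assignments.get(c.contig_id)
        if a is None:
            labels[c.contig_id] = "no_hit"
        elif len(gene_groups[a.gene_id]) == 1:
            labels[c.contig_id] = "unique"
        else:
            labels[c.contig_id] = "multiple"

    n_total = len(contigs)
    n_unique = sum(1 for v in labels.values() if v == "unique")
    n_multiple = sum(1 for v in labels.values() if v == "multiple")
    n_no_hit = n_total - n_unique - n_multiple
    summary = ClassificationSummary(
        n_total=n_total,
        n_hit=n_unique + n_multiple,
        n_unique_hit=n_unique,
        n_multiple_hit=n_multiple,
        n_no_hit=n_no_hit,
    )
    return labels, summary


def summary_table(summary: ClassificationSummary) -> str:
    """Render a classification summary as a TSV block.

    Rows are hit / unique hit / multiple hit / no hit / total, with
    counts and percentages (2 decimal places) of all contigs.
    """
    rows = [
        ("hit", summary.n_hit, summary.pct_hit),
        ("unique_hit", summary.n_unique_hit, summary.pct_unique_hit),
        ("multiple_hit", summary.n_multiple_hit, summary.pct_multiple_hit),
        ("no_hit", summary.n_no_hit, summary.pct_no_hit),
        ("total", summary.n_total, 100.0 if summary.n_total else 0.0),
    ]
    lines = ["category\tcount\tpercentage"]
    lines += [f"{name}\t{n}\t{pct:.2f}" for name, n, pct in rows]
    return "\n".join(lines) + "\n"
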