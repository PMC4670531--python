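"""The three redundancy-removal strategies.

1. *Longest per subcomponent*: keep the longest contig of each assembler
   subcomponent (isoform group).
2. *Cluster representative*: keep one contig per sequence-identity
   cluster (CD-HIT-style membership, or the built-in greedy k-mer
   clusterer for self-contained runs).
3. *Annotated best hit*: assign each contig its best-hit reference gene
   and keep, per gene, the contig with the highest bit score.  No-hit
   contigs are dropped entirely — this is the homology-search method and
   the only one of the three that removes both redundant and erroneous
   contigs by construction.

Tie-breaking everywhere is: primary criterion, then longer contig, then
lexicographically smaller contig ID, so every method is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

from contigdedup.classify import best_hit_per_contig
from contigdedup.io import BlastHit, ClusterSet, ContigRecord

logger = logging.getLogger(__name__)

Method = Literal["longest_subcomponent", "cluster_representative", "annotated_best_hit"]


@dataclass
class DedupResult:
    """Outcome of one redundancy-removal method.

    ``kept_ids`` and ``removed_ids`` partition the input contig IDs.
    For the annotated method, ``gene_to_contig`` records the one kept
    contig per covered gene (injective both ways).
    ``n_unclustered_passthrough`` counts contigs outside every cluster
    that the cluster method passed through unchanged.
    """

    method: Method
    kept_ids: set[str]
    removed_ids: set[str]
    gene_to_contig: Optional[dict[str, str]] = None
    n_unclustered_passthrough: int = 0

    def __post_init__(self) -> None:
        if self.kept_ids & self.removed_ids:
            raise ValueError("kept and removed sets overlap")
        if self.gene_to_contig is not None:
            contigs = list(self.gene_to_contig.values())
            if len(set(contigs)) != len(contigs):
                raise ValueError("gene_to_contig must be injective")


def _pick(candidates: Iterable[ContigRecord]) -> ContigRecord:
    """Longest contig; ties go to the lexicographically smallest ID."""
    return min(candidates, key=lambda c: (-c.length, c.contig_id))


def select_longest_per_subcomponent(contigs: Sequence[ContigRecord]) -> DedupResult:
    """Keep exactly one contig per subcomponent: the longest.

    Contigs whose IDs carry no recognizable isoform suffix form
    singleton subcomponents and are always kept.
    """
    groups: dict[str, list[ContigRecord]] = {}
    for c in contigs:
        key = c.subcomponent_key if c.subcomponent_key is not None else c.contig_id
        groups.setdefault(key, []).append(c)
    kept = {_pick(members).contig_id for members in groups.values()}
    removed = {c.contig_id for c in contigs} - kept
    return DedupResult("longest_subcomponent", kept, removed)


def select_cluster_representatives(
    contigs: Sequence[ContigRecord], clusters: ClusterSet
) -> DedupResult:
    """Keep one contig per cluster: the marked representative, else the
    longest member.  Contigs in no cluster pass through (kept) and are
    tallied as a warning.
    """
    by_id = {c.contig_id: c for c in contigs}
    unknown = clusters.member_ids() - set(by_id)
    if unknown:
        raise ValueError(f"cluster members not in contig set: {sorted(unknown)[:5]}")

    kept: set[str] = set()
    for members, rep in clusters.clusters:
        if rep is not None:
            kept.add(rep)
        else:
            kept.add(_pick(by_id[m] for m in members).contig_id)

    clustered = clusters.member_ids()
    passthrough = {cid for cid in by_id if cid not in clustered}
    if passthrough:
        logger.warning("%d contigs outside all clusters kept as pass-through", len(passthrough))
    kept |= passthrough
    removed = set(by_id) - kept
    return DedupResult(
        "cluster_representative", kept, removed, n_unclustered_passthrough=len(passthrough)
    )


def select_annotated(
    contigs: Sequence[ContigRecord], hits: Sequence[BlastHit]
) -> DedupResult:
    """Keep, per reference gene, the assigned contig with the highest
    bit score (ties: longer contig, then smaller ID); drop every no-hit
    contig.

    The selection pool for gene *g* is the set of contigs whose own
    best hit is *g*, so each contig competes for at most one gene and
    the kept set is a bijection with the covered genes.
    """
    by_id = {c.contig_id: c for c in contigs}
    assignments = best_hit_per_contig(h for h in hits if h.query_id in by_id)

    per_gene: dict[str, list[str]] = {}
    for cid, a in assignments.items():
        per_gene.setdefault(a.gene_id, []).append(cid)

    gene_to_contig: dict[str, str] = {}
    for gene, cids in per_gene.items():
        winner = min(
            cids,
            key=lambda cid: (
                -assignments[cid].best_bitscore,
                -by_id[cid].length,
                cid,
            ),
        )
        gene_to_contig[gene] = winner

    kept = set(gene_to_contig.values())
    removed = set(by_id) - kept
    return DedupResult("annotated_best_hit", kept, removed, gene_to_contig=gene_to_contig)


def greedy_cluster(
    contigs: Sequence[ContigRecord], identity_threshold: float = 0.9, k: int = 16
) -> ClusterSet:
    """Greedy incremental clustering by exact k-mer containment.

    Contigs are visited in decreasing length order (ties: smaller ID);
    each joins the first existing cluster whose representative shares at
    least ``identity_threshold`` of the shorter sequence's k-mers, else
    founds a new cluster as its representative.  This mirrors the
    incremental longest-first scheme of CD-HIT-style tools but scores by
    k-mer containment rather than banded alignment; a desk-scale
    clusterer, not a reimplementation of any external tool.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")

    def kmers(seq: str) -> set[str]:
        if len(seq) < k:
            return {seq}
        return {seq[i : i + k] for i in range(len(seq) - k + 1)}

    ordered = sorted(contigs, key=lambda c: (-c.length, c.contig_id))
    reps: list[tuple[str, set[str]]] = []  # (rep_id, rep kmers)
    clusters: list[list[str]] = []
    for c in ordered:
        ck = kmers(c.sequence)
        placed = False
        for idx, (rep_id, rk) in enumerate(reps):
            smaller = ck if len(ck) <= len(rk) else rk
            larger = rk if smaller is ck else ck
            if not smaller:
                continue
            containment = len(smaller & larger) / len(smaller)
            if containment >= identity_threshold:
                clusters[idx].append(c.contig_id)
                placed = True
                break
        if not placed:
            reps.append((c.contig_id, ck))
            clusters.append([c.contig_id])
    return ClusterSet(
        [(members, reps[i][0]) for i, members in enumerate(clusters)]
    )
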