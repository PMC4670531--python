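"""Co-identity of DECs with gold-standard DEGs and GO-distribution tests.

A differentially expressed contig (DEC) exhibits *co-identity* when its
assigned gene ID is itself a differentially expressed gene (DEG) in the
gold standard.  Beyond ID agreement, the functional profile of the two
differential sets is compared over a GO slim term universe: per-term
annotation counts form the two samples of a two-sample
Kolmogorov-Smirnov test (distribution-level distance, one observation
per term as in a quantile-quantile plot), and each term gets a 2x2
Fisher exact test on with/without-term margins (raw p-values; the
headline statistic is the count of terms significant at alpha).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from scipy import stats

from contigdedup.classify import GeneAssignment
from contigdedup.io import GoAnnotationMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoIdentityReport:
    """DEC/DEG identifier agreement.

    ``n_dec_identical + n_dec_nonidentical == n_dec_total``.  Coverage
    counts distinct DEGs (several DECs hitting one DEG count once), so
    ``pct_of_degs_covered`` and the DEC-based ratio
    ``pct_identical`` can differ when DECs are redundant.
    """

    n_dec_total: int
    n_dec_identical: int
    n_dec_nonidentical: int
    n_degs_covered: int
    n_degs_total: int

    @property
    def pct_identical(self) -> float:
        return 100.0 * self.n_dec_identical / self.n_dec_total if self.n_dec_total else 0.0

    @property
    def pct_nonidentical(self) -> float:
        return 100.0 * self.n_dec_nonidentical / self.n_dec_total if self.n_dec_total else 0.0

    @property
    def pct_of_degs_covered(self) -> float:
        return 100.0 * self.n_degs_covered / self.n_degs_total if self.n_degs_total else 0.0


@dataclass(frozen=True)
class GoComparisonReport:
    per_term_counts_deg: dict[str, int]
    per_term_counts_dec: dict[str, int]
    ks_statistic: float
    ks_pvalue: float
    fisher_pvalues: dict[str, float]
    n_significant_terms: int


def co_identity(
    dec_ids: Iterable[str],
    deg_ids: Iterable[str],
    assignments: Mapping[str, GeneAssignment],
) -> CoIdentityReport:
    """Partition DECs into identical / nonidentical against the DEG set.

    A DEC is identical iff its assigned gene ID is in ``deg_ids``; DECs
    with no assignment at all are nonidentical.  Coverage is over
    distinct DEG IDs hit.
    """
    decs = set(dec_ids)
    degs = set(deg_ids)
    identical = 0
    covered: set[str] = set()
    for cid in decs:
        a = assignments.get(cid)
        if a is not None and a.gene_id in degs:
            identical += 1
            covered.add(a.gene_id)
    return CoIdentityReport(
        n_dec_total=len(decs),
        n_dec_identical=identical,
        n_dec_nonidentical=len(decs) - identical,
        n_degs_covered=len(covered),
        n_degs_total=len(degs),
    )


def go_term_counts(
    gene_ids: Iterable[str], go_map: GoAnnotationMap
) -> dict[str, int]:
    """Per-term annotation counts over the map's full term universe.

    ``count(t)`` = number of input genes annotated with term *t*.
    Input IDs must already be gene IDs (translate DEC contig IDs via
    their assignments first).  Genes absent from the map contribute
    nothing and are tallied in a log message.
    """
    counts = {t: 0 for t in go_map.term_universe()}
    unannotated = 0
    for gid in set(gene_ids):
        terms = go_map.gene_to_terms.get(gid)
        if terms is None:
            unannotated += 1
            continue
        for t in terms:
            counts[t] += 1
    if unannotated:
        logger.info("%d genes had no GO annotation and were skipped", unannotated)
    return counts


def ks_distribution_test(
    counts_a: Mapping[str, int], counts_b: Mapping[str, int]
) -> tuple[float, float]:
    """Two-sample KS test on per-term annotation counts.

    The two samples are the count vectors over the shared term universe
    (one observation per term); the asymptotic p-value is returned.
    The statistic is therefore invariant under permutation of terms.
    """
    if set(counts_a) != set(counts_b):
        raise ValueError("count maps must cover the same term universe")
    if not counts_a:
        raise ValueError("empty term universe")
    a = [counts_a[t] for t in counts_a]
    b = [counts_b[t] for t in counts_b]
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def fisher_per_term(
    deg_counts: Mapping[str, int],
    n_deg: int,
    dec_counts: Mapping[str, int],
    n_dec: int,
    alpha: float = 0.05,
) -> tuple[dict[str, float], int]:
    """Two-sided Fisher exact test per GO term, uncorrected.

    The 2x2 table for term *t* is
    ``[[deg_counts[t], n_deg - deg_counts[t]], [dec_counts[t], n_dec - dec_counts[t]]]``
    (features with / without the term in each set).  Returns the p-value
    map and the number of terms with p < ``alpha``; no multiple-testing
    correction is applied.
    """
    if set(deg_counts) != set(dec_counts):
        raise ValueError("count maps must cover the same term universe")
    pvalues: dict[str, float] = {}
    for term in deg_counts:
        a, c = deg_counts[term], dec_counts[term]
        if a > n_deg or c > n_dec:
            raise ValueError(f"term {term!r}: count exceeds set size")
        table = [[a, n_deg - a], [c, n_dec - c]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        pvalues[term] = float(p)
    n_sig = sum(1 for p in pvalues.values() if p < alpha)
    return pvalues, n_sig


def compare_go_distributions(
    deg_gene_ids: Iterable[str],
    dec_gene_ids: Iterable[str],
    go_map: GoAnnotationMap,
    alpha: float = 0.05,
) -> GoComparisonReport:
    """Full GO-slim comparison of a DEG set vs a (gene-translated) DEC set."""
    deg_ids = set(deg_gene_ids)
    dec_ids = set(dec_gene_ids)
    deg_counts = go_term_counts(deg_ids, go_map)
    dec_counts = go_term_counts(dec_ids, go_map)
    ks_stat, ks_p = ks_distribution_test(deg_counts, dec_counts)
    fisher_p, n_sig = fisher_per_term(
        deg_counts, len(deg_ids), dec_counts, len(dec_ids), alpha=alpha
    )
    return GoComparisonReport(
        per_term_counts_deg=deg_counts,
        per_term_counts_dec=dec_counts,
        ks_statistic=ks_stat,
        ks_pvalue=ks_p,
        fisher_pvalues=fisher_p,
        n_significant_terms=n_sig,
    )


def go_comparison_tsv(report: GoComparisonReport, alpha: float = 0.05) -> str:
    lines = ["term\tdeg_count\tdec_count\tfisher_p\tsignificant"]
    for term in sorted(report.per_term_counts_deg):
        p = report.fisher_pvalues[term]
        lines.append(
            f"{term}\t{report.per_term_counts_deg[term]}\t"
            f"{report.per_term_counts_dec[term]}\t{p:.4g}\t{int(p < alpha)}"
        )
    return "\n".join(lines) + "\n"
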