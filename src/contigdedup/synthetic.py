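"""Synthetic redundant-assembly generator with known truth.

Emulates the failure modes of de novo transcriptome assembly that
redundancy removal targets: each reference gene is fragmented into one
near-full-length contig plus a random number of partial contigs
(redundancy from incomplete read coverage), a gene's contigs are
occasionally split across two assembler subcomponents (which defeats
longest-per-subcomponent selection), and a handful of erroneous contigs
with no gene of origin are added (mis-assembly).  Homology hits, cluster
files, GO annotations and two-condition count tables with planted fold
changes are all derived from the same truth, so every downstream module
can be tested end to end with no external tool.

All randomness flows from one top-level seed through named substreams,
so every artifact is reproducible file for file.

Default parameters model a desk-scale study: 100 genes of 300-3000 nt,
on average 3 contigs per gene, 10 erroneous contigs, 1% point
substitutions, 20 genes differentially expressed at 4-fold, sequencing
depth giving a few thousand reads per moderately expressed gene.
Partial fragments carry extra multiplicative count noise (ambiguous
read assignment to overlapping partial contigs); the near-full-length
contig of each gene is quantified cleanly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from contigdedup.io import BlastHit, ContigRecord, CountTable, GoAnnotationMap

_BASES = np.array(list("ACGT"))


def substream(seed: int, name: str) -> np.random.Generator:
    """A named, independent random stream derived from the top seed."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


@dataclass
class ContigOrigin:
    """Provenance of one simulated contig."""

    gene_id: str
    start: int  # 0-based offset in the gene
    n_substitutions: int
    is_designated_best: bool  # the near-full-length contig of its gene


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated assembly."""

    gene_ids: list[str]
    contig_to_gene: dict[str, str]  # absent keys = error contigs
    planted_deg_ids: set[str]
    rng_seed: int
    origins: dict[str, ContigOrigin] = field(default_factory=dict)

    def error_contig_ids(self, contigs: Sequence[ContigRecord]) -> set[str]:
        return {c.contig_id for c in contigs if c.contig_id not in self.contig_to_gene}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _substitute(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, int]:
    """Apply point substitutions at the given per-base rate."""
    if rate <= 0:
        return seq, 0
    arr = np.array(list(seq))
    mask = rng.random(len(arr)) < rate
    n = int(mask.sum())
    if n:
        # replace with a different base
        offsets = rng.integers(1, 4, size=n)
        idx = np.flatnonzero(mask)
        base_idx = np.searchsorted(_BASES, arr[idx])
        arr[idx] = _BASES[(base_idx + offsets) % 4]
    return "".join(arr), n


def generate_reference_genes(
    n_genes: int,
    min_len: int = 300,
    max_len: int = 3000,
    seed: int = 0,
) -> list[ContigRecord]:
    """Random nucleotide reference genes, lengths uniform on [min, max]."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 1 <= min_len <= max_len:
        raise ValueError("need 1 <= min_len <= max_len")
    rng = substream(seed, "genes")
    genes = []
    for i in range(n_genes):
        length = int(rng.integers(min_len, max_len + 1))
        genes.append(ContigRecord(f"gene{i:04d}", _random_seq(rng, length)))
    return genes


def fragment_into_contigs(
    genes: Sequence[ContigRecord],
    mean_frags_per_gene: float = 3.0,
    truncation_dist: tuple[float, float] = (0.2, 0.7),
    n_error_contigs: int = 10,
    subst_rate: float = 0.01,
    seed: int = 0,
    split_prob: float = 0.15,
) -> tuple[list[ContigRecord], SyntheticTruth]:
    """Fragment each gene into redundant contigs plus error contigs.

    Each gene yields ``K = 1 + Poisson(mean - 1)`` contigs: one
    designated near-full-length contig (90-100% of the gene) and ``K-1``
    partial fragments with lengths drawn from ``truncation_dist``
    (fractions of the gene length), all with point substitutions at
    ``subst_rate``.  With probability ``split_prob`` a gene's contigs
    are split across two subcomponents, reproducing the case where the
    assembler builds two or more subcomponents from one gene.  Error
    contigs are random sequences with no gene of origin.

    Contig IDs follow the ``comp<i>_c<j>_seq<k>`` scheme with one
    component per gene (two when split).
    """
    if mean_frags_per_gene < 1:
        raise ValueError("mean_frags_per_gene must be >= 1")
    if not 0 <= subst_rate <= 0.2:
        raise ValueError("subst_rate must be in [0, 0.2]")
    lo, hi = truncation_dist
    if not 0 < lo <= hi <= 1:
        raise ValueError("truncation_dist fractions must satisfy 0 < lo <= hi <= 1")

    rng = substream(seed, "fragment")
    contigs: list[ContigRecord] = []
    truth = SyntheticTruth(
        gene_ids=[g.contig_id for g in genes],
        contig_to_gene={},
        planted_deg_ids=set(),
        rng_seed=seed,
    )

    comp = 0
    for gene in genes:
        k = 1 + int(rng.poisson(max(mean_frags_per_gene - 1.0, 0.0)))
        split = k >= 2 and rng.random() < split_prob
        comps = [comp, comp + 1] if split else [comp]
        comp += len(comps)
        seq_counters = {c: 0 for c in comps}
        for j in range(k):
            glen = gene.length
            if j == 0:  # designated near-full-length contig
                frac = rng.uniform(0.9, 1.0)
            else:
                frac = rng.uniform(lo, hi)
            flen = max(100, int(round(frac * glen)))
            flen = min(flen, glen)
            start = int(rng.integers(0, glen - flen + 1))
            raw = gene.sequence[start : start + flen]
            seq, nsub = _substitute(rng, raw, subst_rate)
            # fragments after the first may land in the second subcomponent
            c = comps[0] if (j == 0 or not split) else comps[j % len(comps)]
            seq_counters[c] += 1
            cid = f"comp{c}_c0_seq{seq_counters[c]}"
            contigs.append(ContigRecord(cid, seq, subcomponent_key=f"comp{c}_c0"))
            truth.contig_to_gene[cid] = gene.contig_id
            truth.origins[cid] = ContigOrigin(
                gene.contig_id, start, nsub, is_designated_best=(j == 0)
            )

    for _ in range(n_error_contigs):
        length = int(rng.integers(120, 1001))
        cid = f"comp{comp}_c0_seq1"
        comp += 1
        contigs.append(
            ContigRecord(cid, _random_seq(rng, length), subcomponent_key=cid[: -len("_seq1")])
        )
    return contigs, truth


def simulate_blast_hits(
    contigs: Sequence[ContigRecord],
    genes: Sequence[ContigRecord],
    truth: SyntheticTruth,
    cross_hit_prob: float = 0.1,
    seed: Optional[int] = None,
) -> list[BlastHit]:
    """One HSP per non-error contig to its true gene; no rows for errors.

    The bit score surrogate is ``2 x matched bases`` — monotone in
    alignment quality, which is the only property downstream selection
    uses; it is not a BLAST score reimplementation.  With probability
    ``cross_hit_prob`` a contig gains a weaker cross-hit to another gene
    (20-60% of its primary score) to exercise best-hit tie logic.
    """
    rng = substream(seed if seed is not None else truth.rng_seed, "blast")
    gene_ids = [g.contig_id for g in genes]
    hits: list[BlastHit] = []
    for c in contigs:
        origin = truth.origins.get(c.contig_id)
        if origin is None:
            continue  # error contig: no homology
        matched = c.length - origin.n_substitutions
        bitscore = 2.0 * matched
        identity = 100.0 * matched / c.length
        evalue = 10.0 ** -min(bitscore / 10.0, 300.0)
        hits.append(
            BlastHit(
                query_id=c.contig_id,
                subject_id=origin.gene_id,
                pct_identity=round(identity, 2),
                aln_length=c.length,
                mismatches=origin.n_substitutions,
                gap_opens=0,
                q_start=1,
                q_end=c.length,
                s_start=origin.start + 1,
                s_end=origin.start + c.length,
                evalue=evalue,
                bitscore=bitscore,
            )
        )
        if len(gene_ids) > 1 and rng.random() < cross_hit_prob:
            other = origin.gene_id
            while other == origin.gene_id:
                other = gene_ids[int(rng.integers(0, len(gene_ids)))]
            frac = rng.uniform(0.2, 0.6)
            xscore = round(bitscore * frac, 1)
            xlen = max(30, int(c.length * frac / 2.0))
            hits.append(
                BlastHit(
                    query_id=c.contig_id,
                    subject_id=other,
                    pct_identity=70.0,
                    aln_length=xlen,
                    mismatches=int(xlen * 0.3),
                    gap_opens=0,
                    q_start=1,
                    q_end=xlen,
                    s_start=1,
                    s_end=xlen,
                    evalue=10.0 ** -min(xscore / 10.0, 300.0),
                    bitscore=xscore,
                )
            )
    return hits


def _balanced_up_assignment(
    planted: list[str], mass: dict[str, float], fc: float
) -> set[str]:
    """Split planted DEGs into up/down halves preserving total output.

    Up-regulation adds ``(fc - 1) x mass`` expected reads and
    down-regulation removes ``(1 - 1/fc) x mass``, so a random split
    shifts the library total — and with it every null gene's RPKM ratio.
    Real between-library normalization assumes total transcriptional
    output is roughly conserved; this emulates that by choosing the
    up/down split (half the genes each) that minimizes the expected
    change in total output: low-mass genes seeded as up, then improved
    by deterministic pairwise swaps.
    """
    n_up = len(planted) // 2
    if n_up == 0 or fc == 1:
        return set(planted[:n_up])
    gain = fc - 1.0
    loss = 1.0 - 1.0 / fc
    order = sorted(planted, key=lambda g: (mass[g], g))
    up = order[:n_up]
    down = order[n_up:]

    def imbalance(u: list[str], d: list[str]) -> float:
        return abs(gain * sum(mass[g] for g in u) - loss * sum(mass[g] for g in d))

    improved = True
    while improved:
        improved = False
        best = imbalance(up, down)
        for i in range(len(up)):
            for j in range(len(down)):
                up[i], down[j] = down[j], up[i]
                cand = imbalance(up, down)
                if cand < best:
                    best = cand
                    improved = True
                else:
                    up[i], down[j] = down[j], up[i]
    return set(up)


def simulate_counts(
    genes: Sequence[ContigRecord],
    contigs: Sequence[ContigRecord],
    truth: SyntheticTruth,
    n_deg: int = 20,
    fc: float = 4.0,
    depth: float = 50.0,
    seed: Optional[int] = None,
    expr_range: tuple[float, float] = (5.0, 500.0),
    fragment_noise_sd: float = 0.5,
) -> tuple[CountTable, CountTable, CountTable, CountTable, set[str]]:
    """Two-condition counts for genes and contigs with planted DEGs.

    Per-gene base expression is log-uniform on ``expr_range``; in
    condition B the ``n_deg`` planted genes change ``fc``-fold (half up,
    half down).  Expected counts are ``expression x length_kb x depth``
    and realised counts are Poisson.  Contig counts derive from the true
    gene's expression scaled by the contig/gene length ratio; partial
    fragments additionally carry multiplicative lognormal noise
    (``fragment_noise_sd`` on the natural-log scale) modelling ambiguous
    read assignment among overlapping partials, while each gene's
    near-full-length contig is quantified cleanly.  Error contigs draw
    independent expression in each condition (their apparent fold
    changes are artifacts, as for real mis-assembled contigs).

    Returns (gene counts A, gene counts B, contig counts A, contig
    counts B, planted DEG IDs); also records the planted set on
    ``truth``.
    """
    if n_deg > len(genes):
        raise ValueError("n_deg cannot exceed the number of genes")
    if fc < 1:
        raise ValueError("fc must be >= 1")
    rng = substream(seed if seed is not None else truth.rng_seed, "counts")
    lo, hi = expr_range
    gene_list = list(genes)

    base = {
        g.contig_id: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        for g in gene_list
    }
    deg_idx = rng.choice(len(gene_list), size=n_deg, replace=False)
    planted = {gene_list[int(i)].contig_id for i in deg_idx}
    lengths = {g.contig_id: g.length for g in gene_list}
    up = _balanced_up_assignment(
        sorted(planted), {gid: base[gid] * lengths[gid] for gid in planted}, fc
    )

    expr_a = dict(base)
    expr_b = {
        gid: (e * fc if gid in up else e / fc) if gid in planted else e
        for gid, e in base.items()
    }

    def poisson_counts(expr: dict[str, float], feats: Sequence[ContigRecord]) -> dict[str, int]:
        return {
            f.contig_id: int(rng.poisson(expr[f.contig_id] * f.length / 1000.0 * depth))
            for f in feats
        }

    gene_counts_a = poisson_counts(expr_a, gene_list)
    gene_counts_b = poisson_counts(expr_b, gene_list)

    # contig expression follows the true gene; error contigs are artifacts
    contig_expr_a: dict[str, float] = {}
    contig_expr_b: dict[str, float] = {}
    for c in contigs:
        gid = truth.contig_to_gene.get(c.contig_id)
        if gid is None:
            contig_expr_a[c.contig_id] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            contig_expr_b[c.contig_id] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            continue
        noisy = not truth.origins[c.contig_id].is_designated_best
        for expr_src, dst in ((expr_a, contig_expr_a), (expr_b, contig_expr_b)):
            e = expr_src[gid]
            if noisy and fragment_noise_sd > 0:
                e *= float(np.exp(rng.normal(0.0, fragment_noise_sd)))
            dst[c.contig_id] = e

    contig_counts_a = {
        c.contig_id: int(rng.poisson(contig_expr_a[c.contig_id] * c.length / 1000.0 * depth))
        for c in contigs
    }
    contig_counts_b = {
        c.contig_id: int(rng.poisson(contig_expr_b[c.contig_id] * c.length / 1000.0 * depth))
        for c in contigs
    }

    truth.planted_deg_ids = planted
    return (
        CountTable(gene_counts_a, sum(gene_counts_a.values())),
        CountTable(gene_counts_b, sum(gene_counts_b.values())),
        CountTable(contig_counts_a, sum(contig_counts_a.values())),
        CountTable(contig_counts_b, sum(contig_counts_b.values())),
        planted,
    )


def simulate_go_annotations(
    gene_ids: Sequence[str],
    n_terms: int = 15,
    max_terms_per_gene: int = 4,
    seed: int = 0,
) -> GoAnnotationMap:
    """Random GO-slim-style annotation: 1..max terms per gene from a
    fixed universe of ``n_terms`` terms."""
    rng = substream(seed, "go")
    universe = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
    gene_to_terms = {
        gid: set(
            rng.choice(universe, size=int(rng.integers(1, max_terms_per_gene + 1)), replace=False)
        )
        for gid in gene_ids
    }
    return GoAnnotationMap({g: {str(t) for t in ts} for g, ts in gene_to_terms.items()})


@dataclass
class SyntheticDataset:
    """Everything one simulated study needs, generated from one seed."""

    genes: list[ContigRecord]
    contigs: list[ContigRecord]
    hits: list[BlastHit]
    truth: SyntheticTruth
    go_map: GoAnnotationMap
    gene_counts_a: CountTable
    gene_counts_b: CountTable
    contig_counts_a: CountTable
    contig_counts_b: CountTable


def generate_dataset(
    seed: int = 0,
    n_genes: int = 100,
    mean_frags_per_gene: float = 3.0,
    n_error_contigs: int = 10,
    subst_rate: float = 0.01,
    split_prob: float = 0.15,
    cross_hit_prob: float = 0.1,
    n_deg: int = 20,
    fc: float = 4.0,
    depth: float = 50.0,
    fragment_noise_sd: float = 0.5,
) -> SyntheticDataset:
    """Generate a complete default-preset study from one seed."""
    genes = generate_reference_genes(n_genes, seed=seed)
    contigs, truth = fragment_into_contigs(
        genes,
        mean_frags_per_gene=mean_frags_per_gene,
        n_error_contigs=n_error_contigs,
        subst_rate=subst_rate,
        seed=seed,
        split_prob=split_prob,
    )
    hits = simulate_blast_hits(contigs, genes, truth, cross_hit_prob=cross_hit_prob)
    gca, gcb, cca, ccb, _ = simulate_counts(
        genes,
        contigs,
        truth,
        n_deg=n_deg,
        fc=fc,
        depth=depth,
        fragment_noise_sd=fragment_noise_sd,
    )
    go_map = simulate_go_annotations([g.contig_id for g in genes], seed=seed)
    return SyntheticDataset(genes, contigs, hits, truth, go_map, gca, gcb, cca, ccb)
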