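"""The synthetic redundant-assembly generator and its truth tables."""

import numpy as np
import pytest

from contigdedup.classify import best_hit_per_contig, classify_contigs
from contigdedup.dedup import select_annotated
from contigdedup.evaluation import co_identity
from contigdedup.expression import build_expression_table, call_differential, pair_fold_changes, pearson
from contigdedup.synthetic import (
    SyntheticTruth,
    fragment_into_contigs,
    generate_dataset,
    generate_reference_genes,
    simulate_blast_hits,
    simulate_counts,
)


class TestReferenceGenes:
    def test_deterministic_for_fixed_seed(self):
        a = generate_reference_genes(5, 500, 1500, seed=7)
        b = generate_reference_genes(5, 500, 1500, seed=7)
        assert [(g.contig_id, g.sequence) for g in a] == [
            (g.contig_id, g.sequence) for g in b
        ]

    def test_exact_length_when_range_collapses(self):
        (g,) = generate_reference_genes(1, 100, 100, seed=3)
        assert g.length == 100

    def test_uniform_length_mean(self):
        genes = generate_reference_genes(1000, 200, 3000, seed=1)
        mean = np.mean([g.length for g in genes])
        assert abs(mean - 1600) / 1600 < 0.05


class TestFragmentation:
    def test_single_clean_fragment_is_exact_substring(self):
        genes = generate_reference_genes(10, 400, 800, seed=5)
        contigs, truth = fragment_into_contigs(
            genes, mean_frags_per_gene=1.0, n_error_contigs=0, subst_rate=0.0, seed=5
        )
        assert len(contigs) == 10
        by_gene = {g.contig_id: g.sequence for g in genes}
        for c in contigs:
            assert c.sequence in by_gene[truth.contig_to_gene[c.contig_id]]

    def test_error_contigs_have_no_origin(self):
        genes = generate_reference_genes(5, 400, 800, seed=5)
        contigs, truth = fragment_into_contigs(genes, n_error_contigs=10, seed=5)
        errors = truth.error_contig_ids(contigs)
        assert len(errors) == 10
        assert all(cid not in truth.contig_to_gene for cid in errors)

    def test_truth_rows_match_contig_count(self):
        genes = generate_reference_genes(100, 300, 3000, seed=3)
        contigs, truth = fragment_into_contigs(
            genes, mean_frags_per_gene=3.0, n_error_contigs=0, seed=3
        )
        assert len(contigs) == len(truth.contig_to_gene) == len(truth.origins)

    def test_every_gene_has_a_designated_best_contig(self):
        genes = generate_reference_genes(50, 300, 3000, seed=9)
        contigs, truth = fragment_into_contigs(genes, seed=9)
        designated = {
            o.gene_id for o in truth.origins.values() if o.is_designated_best
        }
        assert designated == set(truth.gene_ids)

    def test_ids_follow_assembler_scheme(self):
        genes = generate_reference_genes(5, 300, 600, seed=2)
        contigs, _ = fragment_into_contigs(genes, seed=2)
        for c in contigs:
            assert c.contig_id.startswith("comp")
            assert "_seq" in c.contig_id
            assert c.subcomponent_key == c.contig_id.rsplit("_seq", 1)[0]


class TestSimulatedHits:
    def test_bitscore_is_twice_matched_bases(self):
        genes = generate_reference_genes(5, 1000, 1000, seed=4)
        contigs, truth = fragment_into_contigs(
            genes, mean_frags_per_gene=1.0, n_error_contigs=0, subst_rate=0.0, seed=4
        )
        hits = simulate_blast_hits(contigs, genes, truth, cross_hit_prob=0.0)
        for h in hits:
            c = next(c for c in contigs if c.contig_id == h.query_id)
            assert h.bitscore == 2.0 * c.length
            assert h.pct_identity == 100.0

    def test_error_contigs_get_no_rows(self):
        genes = generate_reference_genes(5, 500, 800, seed=4)
        contigs, truth = fragment_into_contigs(genes, n_error_contigs=8, seed=4)
        hits = simulate_blast_hits(contigs, genes, truth)
        queried = {h.query_id for h in hits}
        assert queried.isdisjoint(truth.error_contig_ids(contigs))

    def test_annotated_selection_keeps_longest_fragment(self):
        """The near-full-length contig outscores partial fragments of the
        same gene, so best-bit-score selection keeps it."""
        genes = generate_reference_genes(20, 800, 2000, seed=6)
        contigs, truth = fragment_into_contigs(
            genes, mean_frags_per_gene=3.0, n_error_contigs=5, seed=6
        )
        hits = simulate_blast_hits(contigs, genes, truth, cross_hit_prob=0.0)
        result = select_annotated(contigs, hits)
        for cid in result.kept_ids:
            assert truth.origins[cid].is_designated_best


class TestSimulatedCounts:
    def test_same_seed_gives_identical_tables(self):
        genes = generate_reference_genes(30, 300, 2000, seed=8)
        contigs, truth = fragment_into_contigs(genes, seed=8)
        out1 = simulate_counts(genes, contigs, truth, seed=8)
        out2 = simulate_counts(genes, contigs, truth, seed=8)
        for t1, t2 in zip(out1[:4], out2[:4]):
            assert t1.feature_counts == t2.feature_counts
        assert out1[4] == out2[4]

    def test_null_fold_change_plants_no_recoverable_degs(self):
        genes = generate_reference_genes(40, 500, 2000, seed=9)
        truth = SyntheticTruth([g.contig_id for g in genes], {}, set(), 9)
        gca, gcb, _, _, _ = simulate_counts(
            genes, [], truth, n_deg=10, fc=1.0, depth=500.0, seed=9
        )
        lengths = {g.contig_id: g.length for g in genes}
        records = build_expression_table(gca, gcb, lengths)
        assert call_differential(records) == set()

    def test_eightfold_changes_recovered_exactly(self):
        genes = generate_reference_genes(50, 300, 2000, seed=10)
        truth = SyntheticTruth([g.contig_id for g in genes], {}, set(), 10)
        gca, gcb, _, _, planted = simulate_counts(
            genes, [], truth, n_deg=10, fc=8.0, depth=200.0, seed=10
        )
        lengths = {g.contig_id: g.length for g in genes}
        records = build_expression_table(gca, gcb, lengths)
        assert call_differential(records) == planted


class TestEndToEnd:
    def test_annotated_reclassification_is_clean(self, dataset):
        result = select_annotated(dataset.contigs, dataset.hits)
        kept = [c for c in dataset.contigs if c.contig_id in result.kept_ids]
        assignments = best_hit_per_contig(
            h for h in dataset.hits if h.query_id in result.kept_ids
        )
        _, summary = classify_contigs(kept, assignments)
        assert summary.n_multiple_hit == 0
        assert summary.n_no_hit == 0

    def test_redundancy_removal_reduces_nonidentical_decs(self, dataset):
        """The headline direction: best-bit-score selection leaves fewer
        DECs without a DEG counterpart than the raw assembly."""
        from contigdedup.pipeline import run_study

        reports = run_study(dataset, methods=("raw", "annotated"))
        raw, anno = reports["raw"], reports["annotated"]
        assert anno.co_identity.n_dec_nonidentical < raw.co_identity.n_dec_nonidentical
        assert anno.correlation > raw.correlation
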