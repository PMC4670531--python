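"""The three redundancy-removal strategies and the greedy clusterer."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contigdedup.classify import best_hit_per_contig, classify_contigs
from contigdedup.dedup import (
    greedy_cluster,
    select_annotated,
    select_cluster_representatives,
    select_longest_per_subcomponent,
)
from contigdedup.io import BlastHit, ClusterSet, ContigRecord, parse_trinity_id


def contig(cid, length=100, seq=None):
    return ContigRecord(cid, seq or ("ACGT" * (length // 4 + 1))[:length],
                        subcomponent_key=parse_trinity_id(cid))


def hit(query, subject, bitscore, evalue=1e-50):
    return BlastHit(query, subject, 95.0, 100, 5, 0, 1, 100, 1, 100, evalue, bitscore)


class TestLongestPerSubcomponent:
    def test_longer_isoform_wins(self):
        r = select_longest_per_subcomponent(
            [contig("comp0_c0_seq1", 300), contig("comp0_c0_seq2", 500)]
        )
        assert r.kept_ids == {"comp0_c0_seq2"}
        assert r.removed_ids == {"comp0_c0_seq1"}

    def test_one_kept_per_subcomponent(self):
        r = select_longest_per_subcomponent(
            [
                contig("comp0_c0_seq1", 300),
                contig("comp0_c0_seq2", 500),
                contig("comp1_c0_seq1", 200),
            ]
        )
        assert r.kept_ids == {"comp0_c0_seq2", "comp1_c0_seq1"}

    @pytest.mark.parametrize("order", [(1, 2), (2, 1)])
    def test_length_tie_keeps_smaller_id(self, order):
        contigs = [contig(f"comp0_c0_seq{k}", 400) for k in order]
        r = select_longest_per_subcomponent(contigs)
        assert r.kept_ids == {"comp0_c0_seq1"}

    def test_unparseable_ids_are_singletons(self):
        r = select_longest_per_subcomponent([contig("weird_a", 10), contig("weird_b", 20)])
        assert r.kept_ids == {"weird_a", "weird_b"}


class TestClusterRepresentatives:
    def test_marked_representative_kept(self):
        contigs = [contig("a", 800), contig("b", 200)]
        r = select_cluster_representatives(contigs, ClusterSet([(["a", "b"], "a")]))
        assert r.kept_ids == {"a"}

    def test_one_kept_per_cluster(self):
        contigs = [contig(f"c{i}", 100 + i) for i in range(7)]
        clusters = ClusterSet(
            [(["c0", "c1", "c2"], "c2"), (["c3", "c4"], "c4"), (["c5", "c6"], "c6")]
        )
        r = select_cluster_representatives(contigs, clusters)
        assert len(r.kept_ids) == 3

    def test_missing_representative_falls_back_to_longest(self):
        contigs = [contig("a", 200), contig("b", 800)]
        r = select_cluster_representatives(contigs, ClusterSet([(["a", "b"], None)]))
        assert r.kept_ids == {"b"}

    def test_unclustered_contigs_pass_through(self):
        contigs = [contig("a", 800), contig("b", 200), contig("loner", 50)]
        r = select_cluster_representatives(contigs, ClusterSet([(["a", "b"], "a")]))
        assert r.kept_ids == {"a", "loner"}
        assert r.n_unclustered_passthrough == 1

    def test_unknown_member_is_error(self):
        with pytest.raises(ValueError, match="ghost"):
            select_cluster_representatives([contig("a")], ClusterSet([(["ghost"], None)]))


class TestSelectAnnotated:
    def test_per_gene_argmax(self):
        contigs = [contig(c) for c in ("c1", "c2", "c3", "c4")]
        hits = [hit("c1", "g1", 900), hit("c2", "g1", 400), hit("c3", "g2", 500)]
        r = select_annotated(contigs, hits)
        assert r.kept_ids == {"c1", "c3"}
        assert r.removed_ids == {"c2", "c4"}
        assert r.gene_to_contig == {"g1": "c1", "g2": "c3"}

    def test_distinct_genes_keep_all_hit_contigs(self):
        contigs = [contig(f"c{i}") for i in range(4)]
        hits = [hit(f"c{i}", f"g{i}", 100 + i) for i in range(3)]
        r = select_annotated(contigs, hits)
        assert r.kept_ids == {"c0", "c1", "c2"}
        assert r.removed_ids == {"c3"}

    def test_bitscore_tie_keeps_longer_then_smaller_id(self):
        contigs = [contig("cB", 300), contig("cA", 200)]
        r = select_annotated(contigs, [hit("cA", "g1", 500), hit("cB", "g1", 500)])
        assert r.kept_ids == {"cB"}  # longer wins the tie
        contigs = [contig("cB", 300), contig("cA", 300)]
        r = select_annotated(contigs, [hit("cA", "g1", 500), hit("cB", "g1", 500)])
        assert r.kept_ids == {"cA"}  # full tie: smaller ID

    def test_reclassified_kept_set_is_all_unique(self, dataset):
        """After best-bit-score selection, every kept contig is the sole
        contig of its gene: re-classification gives 0 multiple, 0 no-hit."""
        r = select_annotated(dataset.contigs, dataset.hits)
        kept = [c for c in dataset.contigs if c.contig_id in r.kept_ids]
        kept_ids = r.kept_ids
        assignments = best_hit_per_contig(h for h in dataset.hits if h.query_id in kept_ids)
        _, summary = classify_contigs(kept, assignments)
        assert summary.n_multiple_hit == 0
        assert summary.n_no_hit == 0
        assert summary.n_unique_hit == len(kept)

    def test_bijection_between_kept_and_covered_genes(self, dataset):
        r = select_annotated(dataset.contigs, dataset.hits)
        assignments = best_hit_per_contig(dataset.hits)
        covered = {a.gene_id for a in assignments.values()}
        assert set(r.gene_to_contig) == covered
        assert len(set(r.gene_to_contig.values())) == len(r.gene_to_contig)
        assert r.kept_ids == set(r.gene_to_contig.values())


class TestGreedyCluster:
    def test_identical_sequences_cluster_together(self):
        seq = "ACGTTGCA" * 10
        cs = greedy_cluster([ContigRecord("a", seq), ContigRecord("b", seq)])
        assert len(cs.clusters) == 1
        assert sorted(cs.clusters[0][0]) == ["a", "b"]

    def test_disjoint_sequences_stay_separate(self):
        cs = greedy_cluster([ContigRecord("a", "A" * 100), ContigRecord("b", "C" * 100)])
        assert len(cs.clusters) == 2

    def test_contained_substring_joins_cluster(self):
        import numpy as np

        rng = np.random.default_rng(42)
        full = "".join(rng.choice(list("ACGT"), size=400))
        sub = full[100:300]
        cs = greedy_cluster(
            [ContigRecord("full", full), ContigRecord("sub", sub)], identity_threshold=0.9
        )
        assert len(cs.clusters) == 1
        assert cs.clusters[0][1] == "full"  # longest founds the cluster

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            greedy_cluster([ContigRecord("a", "ACGT")], identity_threshold=0.0)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_every_method_is_idempotent(seed):
    """Applying any dedup method to its own output changes nothing."""
    import numpy as np

    rng = np.random.default_rng(seed)
    contigs = []
    for i in range(rng.integers(3, 12)):
        for k in range(1, rng.integers(2, 4)):
            length = int(rng.integers(100, 600))
            seq = "".join(rng.choice(list("ACGT"), size=length))
            contigs.append(
                ContigRecord(f"comp{i}_c0_seq{k}", seq, subcomponent_key=f"comp{i}_c0")
            )
    hits = [
        hit(c.contig_id, f"g{rng.integers(0, 5)}", float(rng.integers(50, 900)))
        for c in contigs
        if rng.random() < 0.8
    ]

    first = select_longest_per_subcomponent(contigs)
    kept = [c for c in contigs if c.contig_id in first.kept_ids]
    assert select_longest_per_subcomponent(kept).kept_ids == first.kept_ids

    first = select_annotated(contigs, hits)
    kept = [c for c in contigs if c.contig_id in first.kept_ids]
    assert select_annotated(kept, hits).kept_ids == first.kept_ids

    clusters = greedy_cluster(contigs)
    first = select_cluster_representatives(contigs, clusters)
    kept = [c for c in contigs if c.contig_id in first.kept_ids]
    reclusters = greedy_cluster(kept)
    assert select_cluster_representatives(kept, reclusters).kept_ids == first.kept_ids
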