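import itertools

import networkx as nx
import pytest

from anxtools.duplication import (
    annotate_segmental,
    chromosome_distribution,
    detect_tandem,
    round_percent,
    summarize_duplication,
)
from anxtools.io_formats import CollinearPairTable, FormatError
from anxtools.synthetic_data import gen_genome_orders
from conftest import build_genome


def brute_force_clusters(loci, genome, max_intervening):
    """Independent oracle: union-find over all family pairs via networkx."""
    family = {l.gene_id for l in loci}
    g = nx.Graph()
    g.add_nodes_from(family)
    for a, b in itertools.combinations(loci, 2):
        if a.chromosome != b.chromosome:
            continue
        ia = genome.order_index(a.chromosome, a.gene_id)
        ib = genome.order_index(b.chromosome, b.gene_id)
        lo, hi = sorted((ia, ib))
        between = [
            gid for gid, _ in genome.by_chromosome[a.chromosome][lo + 1:hi]
            if gid not in family
        ]
        if len(between) <= max_intervening:
            g.add_edge(a.gene_id, b.gene_id)
    return {frozenset(c) for c in nx.connected_components(g) if len(c) >= 2}


class TestDetectTandem:
    def test_adjacent_pair_clusters(self):
        genome, loci = build_genome({"chr1": [5, "f1", "f2", 5]})
        (cluster,) = detect_tandem(loci, genome, max_intervening=5)
        assert cluster.members == ("f1", "f2")
        assert cluster.max_intervening_observed == 0

    def test_boundary_spacing_inclusive_and_exclusive(self):
        genome5, loci5 = build_genome({"chr1": [3, "f1", 5, "f2", 3]})
        assert len(detect_tandem(loci5, genome5, 5)) == 1
        genome6, loci6 = build_genome({"chr1": [3, "f1", 6, "f2", 3]})
        assert detect_tandem(loci6, genome6, 5) == []

    def test_chaining_matches_union_find_oracle(self):
        genome, loci = build_genome({"chr1": [5, "f1", 2, "f2", 2, "f3", 10]})
        clusters = detect_tandem(loci, genome, 5)
        assert [c.members for c in clusters] == [("f1", "f2", "f3")]
        assert {frozenset(c.members) for c in clusters} == brute_force_clusters(
            loci, genome, 5)

    def test_random_layouts_match_oracle(self):
        for seed in range(6):
            genome, loci, _, _ = gen_genome_orders(
                seed, genes_per_chrom=160,
                planted_tandem=((1, 2, 0), (1, 2, 5), (2, 4, 3), (3, 2, 6)))
            for k in (0, 3, 5):
                got = {frozenset(c.members) for c in detect_tandem(loci, genome, k)}
                assert got == brute_force_clusters(loci, genome, k)

    def test_monotone_in_threshold(self):
        genome, loci = build_genome(
            {"chr1": [2, "f1", 3, "f2", 5, "f3", 8, "f4", 2]})
        sizes = []
        for k in range(0, 10):
            clusters = detect_tandem(loci, genome, k)
            sizes.append(sum(len(c.members) for c in clusters))
        assert sizes == sorted(sizes)

    def test_missing_gene_raises(self):
        genome, loci = build_genome({"chr1": [2, "f1", 2]})
        from anxtools.duplication import GeneLocus

        loci.append(GeneLocus("ghost", "chr1", 1, 2))
        with pytest.raises(FormatError, match="ghost"):
            detect_tandem(loci, genome, 5)


class TestSegmental:
    def test_one_to_many_pairs_kept(self, poplar_like):
        _, loci, pairs = poplar_like
        seg = annotate_segmental([l.gene_id for l in loci], pairs)
        partners = [p for p in seg
                    if "Pt02g09420" in (p.gene_id_a, p.gene_id_b)]
        assert len(partners) == 2
        distinct = {g for p in seg for g in (p.gene_id_a, p.gene_id_b)}
        assert len(seg) == 5 and len(distinct) == 9

    def test_empty_table(self):
        assert annotate_segmental(["a"], CollinearPairTable()) == []

    def test_pair_with_non_family_gene_excluded(self):
        pairs = CollinearPairTable.from_rows([("a", "zz", "b1"), ("a", "b", "b2")])
        seg = annotate_segmental(["a", "b"], pairs)
        assert [(p.gene_id_a, p.gene_id_b) for p in seg] == [("a", "b")]


class TestSummary:
    def test_eight_gene_family_fifty_twentyfive(self, arabidopsis_like):
        genome, loci, pairs = arabidopsis_like
        clusters = detect_tandem(loci, genome, 5)
        seg = annotate_segmental([l.gene_id for l in loci], pairs)
        summary = summarize_duplication(loci, clusters, seg)
        assert (summary.tandem_pct, summary.segmental_pct) == (50, 25)
        assert summary.combined_pct == 75

    def test_ten_gene_family_twenty_forty(self, rice_like):
        genome, loci, pairs = rice_like
        clusters = detect_tandem(loci, genome, 5)
        seg = annotate_segmental([l.gene_id for l in loci], pairs)
        summary = summarize_duplication(loci, clusters, seg)
        assert (summary.tandem_pct, summary.segmental_pct) == (20, 40)
        assert summary.combined_pct == 60

    def test_no_duplicates(self):
        _, loci = build_genome({"chr1": [2, "f1", 10, "f2", 2]})
        summary = summarize_duplication(loci, [], [])
        assert (summary.tandem_pct, summary.segmental_pct,
                summary.combined_pct) == (0, 0, 0)

    def test_empty_family_raises(self):
        with pytest.raises(FormatError):
            summarize_duplication([], [], [])

    def test_rounding_half_up(self):
        assert round_percent(100 * 2 / 12) == 17  # 16.67 rounds up
        assert round_percent(12.5) == 13
        assert round_percent(12.49) == 12


class TestChromosomeDistribution:
    def test_arabidopsis_shape(self, arabidopsis_like):
        _, loci, _ = arabidopsis_like
        counts, top = chromosome_distribution(loci)
        assert counts == {"chr1": 2, "chr2": 2, "chr5": 4}
        assert top == ["chr5"]

    def test_single_chromosome(self):
        _, loci = build_genome({"chrX": [1, "f1", 1, "f2", 1, "f3", 1]})
        counts, top = chromosome_distribution(loci)
        assert counts == {"chrX": 3} and top == ["chrX"]

    def test_empty_family(self):
        assert chromosome_distribution([]) == ({}, [])


class TestPlantedTruth:
    def test_precision_and_recall_on_generator_output(self):
        for seed in (0, 1):
            genome, loci, pairs, truth = gen_genome_orders(seed)
            clusters = detect_tandem(loci, genome, 5)
            got_tandem = {frozenset(c.members) for c in clusters}
            assert got_tandem == {frozenset(t) for t in truth["tandem_clusters"]}
            seg = annotate_segmental([l.gene_id for l in loci], pairs)
            got_pairs = {frozenset((p.gene_id_a, p.gene_id_b)) for p in seg}
            assert got_pairs == {
                frozenset((a, b)) for a, b, _ in truth["segmental_pairs"]}
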