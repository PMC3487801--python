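import pytest

from anxtools.domain_motif import AnnexinDomainSet, classify_domain_cbs, scan_protein
from anxtools.gene_structure import phase_string
from anxtools.io_formats import read_gff3, write_gff3
from anxtools.kaks_dating import CodonAlignment, ng86
from anxtools.synthetic_data import (
    DEFAULT_TEMPLATES,
    DomainPlan,
    evolve_codon_pair,
    gen_gene_models,
    gen_genome_orders,
    gen_proteins,
)


class TestGenProteins:
    def test_two_cbs_plan_scans_to_count_two(self):
        plan = DomainPlan(cbs=("canonical", "absent", "absent", "canonical"))
        records, domains, _ = gen_proteins(seed=3, n=10, domain_plan=plan)
        for rec in records:
            dset = AnnexinDomainSet.from_annotation(
                rec.id, rec.residues, domains.by_protein[rec.id])
            statuses, count = classify_domain_cbs(dset, scan_protein(dset))
            assert count == 2
            assert statuses == {1: "present", 2: "absent", 3: "absent",
                                4: "present"}

    def test_all_absent_plan_scans_clean(self):
        plan = DomainPlan(cbs=("absent",) * 4)
        records, domains, truth = gen_proteins(seed=3, n=10, domain_plan=plan)
        for rec in records:
            dset = AnnexinDomainSet.from_annotation(
                rec.id, rec.residues, domains.by_protein[rec.id])
            assert scan_protein(dset) == []

    def test_mixed_plans_recall_precision_exact(self):
        plans = [
            DomainPlan(("canonical", "degenerate", "absent", "canonical"),
                       tripeptides=((2, "KGD", "adjacent"),)),
            DomainPlan(("canonical",) * 4,
                       tripeptides=((1, "RGD", "overlapping"), (3, "HGD", "none"))),
            DomainPlan(("degenerate", "absent", "absent", "degenerate")),
        ]
        records, domains, truth = gen_proteins(seed=4, n=30, domain_plan=plans)
        for rec in records:
            dset = AnnexinDomainSet.from_annotation(
                rec.id, rec.residues, domains.by_protein[rec.id])
            got = {
                (h.domain_index, h.kind, h.start, h.status, h.cbs_relation)
                for h in scan_protein(dset)
                if h.kind in ("CBS", "KGD", "RGD", "HGD")
            }
            expected = {
                (r["domain_index"], r["kind"], r["start"], r["status"],
                 r["relation"])
                for r in truth if r["protein_id"] == rec.id and r["kind"]
            }
            assert got == expected

    def test_determinism(self):
        plan = DomainPlan(cbs=("canonical", "absent", "degenerate", "canonical"))
        r1, d1, t1 = gen_proteins(seed=9, n=5, domain_plan=plan)
        r2, d2, t2 = gen_proteins(seed=9, n=5, domain_plan=plan)
        assert r1 == r2 and d1 == d2 and t1 == t2
        r3, _, _ = gen_proteins(seed=10, n=5, domain_plan=plan)
        assert r1 != r3

    def test_invalid_plan_raises(self):
        with pytest.raises(ValueError):
            DomainPlan(cbs=("canonical", "absent", "absent", "weird"))
        with pytest.raises(ValueError):
            DomainPlan(cbs=("absent",) * 4,
                       tripeptides=((1, "KGD", "overlapping"),))


class TestGenGeneModels:
    def test_templates_round_trip_through_gff3(self, tmp_path):
        models, _ = gen_gene_models(seed=2, n_per_template=1)
        path = tmp_path / "x.gff3"
        write_gff3(models, path)
        back = read_gff3(path)
        assert sorted(back, key=lambda m: m.gene_id) == sorted(
            models, key=lambda m: m.gene_id)

    def test_truth_phase_strings_match_models(self):
        models, truth = gen_gene_models(seed=2, n_per_template=2)
        by_id = {m.gene_id: m for m in models}
        for row in truth:
            assert phase_string(by_id[row["gene_id"]]) == row["phase_string"]

    def test_strand_flip_preserves_phase_string(self):
        models, truth = gen_gene_models(seed=6, n_per_template=6)
        by_template = {}
        for m, row in zip(models, truth):
            by_template.setdefault(row["template"], []).append(m)
        saw_both = 0
        for tmpl, group in by_template.items():
            strands = {m.strand for m in group}
            phases = {phase_string(m) for m in group}
            assert len(phases) == 1
            if strands == {"+", "-"}:
                saw_both += 1
        assert saw_both > 0

    def test_bad_template_raises(self):
        with pytest.raises(ValueError, match="divisible"):
            gen_gene_models(seed=1, templates=[(100, 100)])

    def test_intronless_template_has_empty_phase_string(self):
        models, truth = gen_gene_models(seed=1, templates=[(600,)],
                                        n_per_template=2)
        assert all(row["phase_string"] == "" for row in truth)


class TestGenGenomeOrders:
    def test_boundary_spacing_at_threshold_detected(self):
        from anxtools.duplication import detect_tandem

        genome, loci, _, truth = gen_genome_orders(
            seed=1, planted_tandem=((1, 2, 5),), planted_segmental=0,
            n_singletons=0)
        clusters = detect_tandem(loci, genome, max_intervening=5)
        assert [set(c.members) for c in clusters] == [
            set(truth["tandem_clusters"][0])]

    def test_spacing_just_beyond_threshold_not_detected(self):
        from anxtools.duplication import detect_tandem

        genome, loci, _, _ = gen_genome_orders(
            seed=1, planted_tandem=((1, 2, 6),), planted_segmental=0,
            n_singletons=0)
        assert detect_tandem(loci, genome, max_intervening=5) == []

    def test_overpacked_chromosome_raises(self):
        with pytest.raises(ValueError, match="over-packed"):
            gen_genome_orders(seed=1, genes_per_chrom=10)

    def test_determinism(self):
        g1 = gen_genome_orders(seed=5)
        g2 = gen_genome_orders(seed=5)
        assert g1[0] == g2[0] and g1[1] == g2[1] and g1[3] == g2[3]


class TestEvolveCodonPair:
    def test_zero_targets_identity(self):
        a, b, truth = evolve_codon_pair(seed=1, n_codons=50,
                                        target_syn_events=0,
                                        target_nonsyn_events=0)
        assert a == b
        res = ng86(CodonAlignment.from_sequences(a, b))
        assert res.Ks == 0 and res.Ka == 0

    def test_same_seed_is_byte_identical(self):
        p1 = evolve_codon_pair(seed=7, n_codons=100, target_syn_events=10,
                               target_nonsyn_events=5)
        p2 = evolve_codon_pair(seed=7, n_codons=100, target_syn_events=10,
                               target_nonsyn_events=5)
        assert p1 == p2

    def test_event_counts_exact(self):
        _, _, truth = evolve_codon_pair(seed=3, n_codons=200,
                                        target_syn_events=12,
                                        target_nonsyn_events=7)
        assert truth["syn_events"] == 12 and truth["nonsyn_events"] == 7
        assert len(truth["events"]) == 19

    def test_synonymous_only_evolution_gives_zero_ka(self):
        for seed in range(5):
            a, b, _ = evolve_codon_pair(seed=seed, n_codons=300,
                                        target_syn_events=30,
                                        target_nonsyn_events=0)
            res = ng86(CodonAlignment.from_sequences(a, b))
            assert res.Ka == 0.0 and res.Nd == 0.0

    def test_unreachable_target_raises(self):
        # seed 12 draws a single-codon ancestor of ATG (Met), which has no
        # synonymous neighbour, so a synonymous-only target cannot be met
        with pytest.raises(RuntimeError, match="unreachable"):
            evolve_codon_pair(seed=12, n_codons=1, target_syn_events=1,
                              target_nonsyn_events=0, max_attempts=500)
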