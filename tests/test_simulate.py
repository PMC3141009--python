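"""Simulator: ancestor construction, event algebra, schedules, fixtures."""

import pickle

import numpy as np
import pytest

from karyevo import (
    ConfigError,
    RearrangementEvent,
    RejectedEventError,
    ScheduleError,
    SimConfig,
    apply_event,
    evolve,
    make_ancestor,
    make_reuse_fixture,
    random_history,
)
from karyevo.simulate import CDE3_CCGAA_OFFSET, synthesize_sequences


def _state(genome):
    return pickle.dumps([
        (c.chrom_id, [(g.gene_id, g.pillar_id, g.orientation) for g in c.genes],
         (c.centromere.intergenic_position, c.centromere.strand,
          c.centromere.cde1_seq, c.centromere.cde2_seq, c.centromere.cde3_seq)
         if c.centromere else None)
        for c in genome.chromosomes])


class TestAncestor:
    def test_default_conditions(self, default_ancestor):
        genome, _ = default_ancestor
        assert genome.n_chromosomes() == 8
        assert len(genome.centromeres()) == 8
        ends = [e for c in genome.chromosomes
                for e in (c.left_telomere, c.right_telomere)]
        assert len(ends) == 16 and all(e is not None for e in ends)

    def test_cde_sequence_structure(self, default_ancestor):
        genome, _ = default_ancestor
        for cen in genome.centromeres():
            cde1 = cen.cde1_seq
            assert (cde1[2], cde1[3], cde1[6], cde1[7]) == ("C", "A", "T", "G")
            assert cde1[4] in "ACG" and cde1[5] in "CGT"
            assert len(cen.cde3_seq) == 26
            assert cen.cde3_seq[CDE3_CCGAA_OFFSET:CDE3_CCGAA_OFFSET + 5] == "CCGAA"

    def test_cde2_at_fraction_in_configured_range(self, default_ancestor):
        genome, _ = default_ancestor
        lo, hi = SimConfig(seed=0).cde2_at_fraction_range
        for cen in genome.centromeres():
            at = sum(1 for b in cen.cde2_seq if b in "AT") / len(cen.cde2_seq)
            assert lo <= at <= hi

    def test_seed_determinism(self):
        a1, _ = make_ancestor(SimConfig(seed=5))
        a2, _ = make_ancestor(SimConfig(seed=5))
        a3, _ = make_ancestor(SimConfig(seed=6))
        assert _state(a1) == _state(a2)
        assert _state(a1) != _state(a3)

    def test_too_small_config_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(seed=1, genes_per_chromosome=10, subtelomeric_zone=4)

    def test_seed_is_mandatory(self):
        with pytest.raises(ConfigError, match="seed"):
            SimConfig()


class TestApplyEvent:
    def test_wgd_doubles_chromosomes_and_centromeres(self, ancestor):
        g = apply_event(ancestor, RearrangementEvent("WGD"))
        g.validate()
        assert g.n_chromosomes() == 16
        assert len(g.centromeres()) == 16
        assert g.wgd_status == "post-WGD"
        assert all(n == 2 for n in g.pillar_counts().values())

    def test_fusion_conserves_genes_and_drops_one_centromere(self, ancestor):
        before_genes = sorted(g.gene_id for g in ancestor.iter_genes())
        ev = RearrangementEvent(
            "telomere_fusion_cen_loss", lost_centromere="CEN2",
            participants={"chrom_a": "Anc1", "end_a": "R",
                          "chrom_b": "Anc2", "end_b": "L"})
        g = apply_event(ancestor, ev)
        g.validate()
        assert g.n_chromosomes() == 7
        assert len(g.centromeres()) == 7
        assert sorted(x.gene_id for x in g.iter_genes()) == before_genes
        assert "CEN2" not in {c.ancestral_label for c in g.centromeres()}

    def test_fusion_requires_participant_centromere(self, ancestor):
        ev = RearrangementEvent(
            "telomere_fusion_cen_loss", lost_centromere="CEN5",
            participants={"chrom_a": "Anc1", "end_a": "R",
                          "chrom_b": "Anc2", "end_b": "L"})
        with pytest.raises(RejectedEventError, match="must name a centromere"):
            apply_event(ancestor, ev)

    def test_inversion_is_an_involution(self, ancestor):
        ev = RearrangementEvent("inversion",
                                participants={"chrom": "Anc1", "start": 8, "end": 19})
        once = apply_event(ancestor, ev)
        twice = apply_event(once, ev)
        assert _state(twice) == _state(ancestor)
        assert _state(once) != _state(ancestor)

    def test_inversion_spanning_centromere_moves_and_flips_it(self, ancestor):
        cen = ancestor.chromosome("Anc1").centromere
        pos, strand = cen.intergenic_position, cen.strand
        ev = RearrangementEvent("inversion", participants={
            "chrom": "Anc1", "start": pos - 3, "end": pos + 5})
        g = apply_event(ancestor, ev)
        new_cen = g.chromosome("Anc1").centromere
        assert new_cen.strand != strand
        assert new_cen.intergenic_position == (pos - 3) + (pos + 5) - pos
        assert _state(apply_event(g, ev)) == _state(ancestor)

    def test_translocation_rejects_acentric_or_dicentric_products(self, ancestor):
        cen1 = ancestor.chromosome("Anc1").centromere.intergenic_position
        cen2 = ancestor.chromosome("Anc2").centromere.intergenic_position
        ev = RearrangementEvent("reciprocal_translocation", participants={
            "chrom_a": "Anc1", "pos_a": cen1 - 5,
            "chrom_b": "Anc2", "pos_b": cen2 + 5})
        with pytest.raises(RejectedEventError):
            apply_event(ancestor, ev)

    def test_pure_input_untouched(self, ancestor):
        before = _state(ancestor)
        apply_event(ancestor, RearrangementEvent("WGD"))
        assert _state(ancestor) == before

    @pytest.mark.parametrize("kind,participants,dchrom,dcen", [
        ("reciprocal_translocation",
         {"chrom_a": "Anc1", "pos_a": 12, "chrom_b": "Anc2", "pos_b": 15}, 0, 0),
        ("telomeric_translocation",
         {"donor": "Anc1", "pos": 38, "donor_side": "R",
          "acceptor": "Anc3", "acceptor_end": "R"}, 0, 0),
        ("centromere_fission",
         {"chrom": "Anc3", "acceptor_left": ["Anc4", "R"],
          "acceptor_right": ["Anc5", "L"]}, -1, -1),
    ])
    def test_conservation_laws(self, ancestor, kind, participants, dchrom, dcen):
        """Pillar multiset preserved; chromosome/centromere deltas as defined."""
        ev = RearrangementEvent(kind, participants=participants,
                                lost_centromere="CEN3" if dcen else None)
        g = apply_event(ancestor, ev)
        g.validate()
        assert g.n_chromosomes() - ancestor.n_chromosomes() == dchrom
        assert len(g.centromeres()) - len(ancestor.centromeres()) == dcen
        assert g.pillar_counts() == ancestor.pillar_counts()


class TestEvolve:
    def test_post_wgd_lineage_with_three_fusions_has_13(self, ancestor,
                                                        species_tree):
        schedule = {"WGD": {"WGD": 1},
                    "Candida_glabrata": {"telomere_fusion_cen_loss": 3}}
        leaves, log = evolve(ancestor, species_tree, schedule, seed=3)
        assert leaves["Candida_glabrata"].n_chromosomes() == 13
        assert leaves["Saccharomyces_cerevisiae"].n_chromosomes() == 16
        for g in leaves.values():
            g.validate()

    def test_non_wgd_lineage_with_two_fusions_has_6(self, ancestor, species_tree):
        schedule = {"Kluyveromyces_lactis": {"telomere_fusion_cen_loss": 2}}
        leaves, _ = evolve(ancestor, species_tree, schedule, seed=3)
        assert leaves["Kluyveromyces_lactis"].n_chromosomes() == 6

    def test_empty_schedule_returns_ancestor_everywhere(self, ancestor,
                                                        species_tree):
        leaves, log = evolve(ancestor, species_tree, {})
        assert log == []
        for g in leaves.values():
            assert _state(g) == _state(ancestor)

    def test_unsatisfiable_schedule_fails_before_application(self, ancestor,
                                                             species_tree):
        schedule = {"Kluyveromyces_lactis": {"telomere_fusion_cen_loss": 9}}
        with pytest.raises(ScheduleError, match="chromosomes"):
            evolve(ancestor, species_tree, schedule, seed=1)

    def test_unknown_branch_rejected(self, ancestor, species_tree):
        with pytest.raises(ScheduleError, match="not in tree"):
            evolve(ancestor, species_tree, {"no_such_branch": {"inversion": 1}},
                   seed=1)

    def test_post_wgd_gene_loss_reaches_single_copy_fraction(self, ancestor,
                                                             species_tree):
        cfg = SimConfig(seed=4)
        leaves, log = evolve(ancestor, species_tree, {"WGD": {"WGD": 1}},
                             config=cfg)
        g = leaves["Saccharomyces_cerevisiae"]
        counts = g.pillar_counts()
        single = sum(1 for v in counts.values() if v == 1) / len(counts)
        assert abs(single - cfg.post_wgd_single_copy_fraction) < 0.01
        assert all(v >= 1 for v in counts.values())  # never lose both copies

    def test_random_mode_without_seed_is_an_error(self, ancestor, species_tree):
        with pytest.raises(ScheduleError, match="seed"):
            evolve(ancestor, species_tree,
                   {"Kluyveromyces_lactis": {"inversion": 1}})


class TestNoReuseHistories:
    def test_every_product_stays_valid(self, ancestor):
        kinds = ["reciprocal_translocation"] * 4 + ["inversion"] * 3
        genome, log = random_history(ancestor, kinds, seed=9)
        genome.validate()
        assert len(log) == 7

    def test_identical_seed_identical_history(self, ancestor):
        kinds = ["reciprocal_translocation"] * 3
        g1, l1 = random_history(ancestor, kinds, seed=5)
        g2, l2 = random_history(ancestor, kinds, seed=5)
        assert _state(g1) == _state(g2)
        assert [e.participants for e in l1] == [e.participants for e in l2]


class TestReuseFixtures:
    def test_klactis_cycle_event_structure(self):
        _, genome, log = make_reuse_fixture("klactis_cycle", seed=5)
        assert len(log) == 4
        assert all(e.kind == "reciprocal_translocation" for e in log)
        assert sum(e.participants["centromeric_breakpoint"] for e in log) == 3
        assert sum(e.participants["reused_junction"] for e in log) == 3
        genome.validate()

    def test_cen9_pathway_event_structure(self):
        _, genome, log = make_reuse_fixture("cen9_pathway", seed=5)
        assert len(log) == 9
        assert all(e.kind == "reciprocal_translocation" for e in log)
        assert sum(e.participants["reused_junction"] for e in log) == 8
        genome.validate()

    def test_fixture_products_have_one_centromere_each(self):
        for style in ("klactis_cycle", "cen9_pathway"):
            _, genome, _ = make_reuse_fixture(style, seed=2)
            for chrom in genome.chromosomes:
                assert chrom.centromere is not None


def test_synthesized_sequences_carry_planted_cassette(ancestor):
    cfg = SimConfig(seed=1)
    rng = np.random.default_rng(1)
    seqs, spans, coords = synthesize_sequences(ancestor, cfg, rng)
    for chrom in ancestor.chromosomes:
        start, end, strand = spans[chrom.chrom_id]
        cassette = seqs[chrom.chrom_id][start:end]
        cen = chrom.centromere
        expected = cen.cde1_seq + cen.cde2_seq + cen.cde3_seq
        if strand == "-":
            from karyevo.simulate import revcomp
            expected = revcomp(expected)
        assert cassette == expected
        assert len(coords[chrom.chrom_id]) == len(chrom.genes)
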