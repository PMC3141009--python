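"""Centromere/telomere fate mapping and parsimony inference."""

import pytest

from karyevo import (
    RearrangementEvent,
    SimConfig,
    ValidationError,
    apply_event,
    assign_events_to_branches,
    centromere_loci,
    evolve,
    infer_ancestral_presence,
    make_ancestor,
    map_all_centromeres,
    map_all_telomeres,
    map_centromere,
)


def _fates(assignments):
    return {a.label: a for a in assignments if a.label is not None}


class TestCentromereMapping:
    def test_unrearranged_lineage_full_flank_evidence_no_flags(self, ancestor):
        g = ancestor.copy()
        g.species = "sp"
        for a in map_all_centromeres(g, ancestor):
            assert a.status == "mapped"
            assert not a.flags
            assert len(a.evidence["left"]) == 5
            assert len(a.evidence["right"]) == 5

    @pytest.mark.parametrize("seed", range(50))
    def test_fusion_lineage_loses_exactly_the_named_centromere(self, seed):
        anc, _ = make_ancestor(SimConfig(seed=400 + seed))
        import numpy as np
        rng = np.random.default_rng(seed)
        ids = list(rng.choice([c.chrom_id for c in anc.chromosomes], 2,
                              replace=False))
        lost = anc.chromosome(ids[1]).centromere.ancestral_label
        ev = RearrangementEvent(
            "telomere_fusion_cen_loss", lost_centromere=lost,
            participants={"chrom_a": ids[0], "end_a": "R",
                          "chrom_b": ids[1], "end_b": "L"})
        g = apply_event(anc, ev)
        g.species = "sp"
        lost_labels = [a.label for a in map_all_centromeres(g, anc)
                       if a.status == "LOST"]
        assert lost_labels == [lost]

    def test_translocation_at_centromeres_flags_both_loci(self, ancestor):
        cen1 = ancestor.chromosome("Anc1").centromere.intergenic_position
        cen2 = ancestor.chromosome("Anc2").centromere.intergenic_position
        ev = RearrangementEvent("reciprocal_translocation", participants={
            "chrom_a": "Anc1", "pos_a": cen1, "chrom_b": "Anc2", "pos_b": cen2})
        g = apply_event(ancestor, ev)
        g.species = "sp"
        fates = _fates(map_all_centromeres(g, ancestor))
        assert "translocation_at_locus" in fates["CEN1"].flags
        assert "translocation_at_locus" in fates["CEN2"].flags
        assert fates["CEN1"].status == "mapped"

    def test_inversion_spanning_centromere_flags_inversion(self, ancestor):
        cen = ancestor.chromosome("Anc1").centromere.intergenic_position
        ev = RearrangementEvent("inversion", participants={
            "chrom": "Anc1", "start": cen - 2, "end": cen + 3})
        g = apply_event(ancestor, ev)
        g.species = "sp"
        fates = _fates(map_all_centromeres(g, ancestor))
        assert fates["CEN1"].status == "mapped"
        assert {"inversion_at_locus", "orientation_change"} & fates["CEN1"].flags

    def test_whole_chromosome_flip_keeps_assignment(self, ancestor):
        from karyevo.genome import reverse_chromosome_in_place
        g = ancestor.copy()
        g.species = "sp"
        reverse_chromosome_in_place(g.chromosome("Anc1"))
        fates = _fates(map_all_centromeres(g, ancestor))
        assert fates["CEN1"].status == "mapped"

    def test_single_locus_wrapper(self, ancestor):
        g = ancestor.copy()
        g.species = "sp"
        locus = centromere_loci(ancestor)[0]
        (a,) = map_centromere(g, ancestor, locus)
        assert a.label == locus.label and a.status == "mapped"

    def test_unannotated_centromeres_without_sequences_error(self, ancestor):
        g = ancestor.copy()
        g.species = "sp"
        g.chromosomes[0].centromere = None
        with pytest.raises(ValidationError, match="unannotated"):
            map_all_centromeres(g, ancestor)


class TestTelomereMapping:
    def test_unrearranged_lineage_all_ends_conserved(self, ancestor):
        g = ancestor.copy()
        g.species = "sp"
        asg = map_all_telomeres(g, ancestor)
        conserved = [a for a in asg if a.fate == "conserved"]
        assert len(conserved) == 16
        assert not [a for a in asg if a.fate == "novel_site"]

    def test_fusion_reports_both_ends_fused_to_each_other(self, ancestor):
        ev = RearrangementEvent(
            "telomere_fusion_cen_loss", lost_centromere="CEN2",
            participants={"chrom_a": "Anc1", "end_a": "R",
                          "chrom_b": "Anc2", "end_b": "L"})
        g = apply_event(ancestor, ev)
        g.species = "sp"
        fates = _fates(map_all_telomeres(g, ancestor))
        assert fates["Anc1-R"].fate == "fused"
        assert fates["Anc1-R"].partner == "Anc2-L"
        assert fates["Anc2-L"].fate == "fused"
        assert fates["Anc2-L"].partner == "Anc1-R"
        assert "internalized_genes" in fates["Anc1-R"].flags

    def test_telomeric_translocation_loss_and_novel_site(self, ancestor):
        ev = RearrangementEvent("telomeric_translocation", participants={
            "donor": "Anc1", "pos": 35, "donor_side": "R",
            "acceptor": "Anc2", "acceptor_end": "R"})
        g = apply_event(ancestor, ev)
        g.species = "sp"
        asg = map_all_telomeres(g, ancestor)
        fates = _fates(asg)
        assert fates["Anc2-R"].fate == "lost_by_translocation"
        novel = [a for a in asg if a.fate == "novel_site"]
        assert len(novel) == 1
        assert novel[0].new_site == ("Anc1", "R")
        # the moved terminal keeps its ancestral identity on the acceptor
        assert fates["Anc1-R"].fate == "conserved"
        assert fates["Anc1-R"].chrom_id == "Anc2"

    def test_terminal_inversion_reports_loss_by_inversion(self, ancestor):
        n = len(ancestor.chromosome("Anc1").genes)
        ev = RearrangementEvent("inversion", participants={
            "chrom": "Anc1", "start": 20, "end": n})
        g = apply_event(ancestor, ev)
        g.species = "sp"
        asg = map_all_telomeres(g, ancestor)
        fates = _fates(asg)
        assert fates["Anc1-R"].fate == "lost_by_inversion"
        assert [a for a in asg if a.fate == "novel_site"]

    def test_fission_both_arms_reported(self, ancestor):
        ev = RearrangementEvent(
            "centromere_fission", lost_centromere="CEN3",
            participants={"chrom": "Anc3", "acceptor_left": ["Anc4", "R"],
                          "acceptor_right": ["Anc5", "L"]})
        g = apply_event(ancestor, ev)
        g.species = "sp"
        fates = _fates(map_all_telomeres(g, ancestor))
        assert fates["Anc4-R"].fate == "fission_fusion"
        assert fates["Anc4-R"].partner == "CEN3"
        assert fates["Anc5-L"].fate == "fission_fusion"
        # the split chromosome's own outer ends survive on the acceptors
        assert fates["Anc3-L"].fate == "conserved"
        assert fates["Anc3-R"].fate == "conserved"


class TestAncestralPresence:
    def test_locus_in_all_species_is_present(self, species_tree):
        presence = {sp: {"CEN1": 1} for sp in species_tree.leaf_names}
        out = infer_ancestral_presence(presence, species_tree)
        assert out["CEN1"]["wgd_node"] and out["CEN1"]["node_b"]

    def test_loss_in_one_post_wgd_leaf_still_ancestral(self, species_tree):
        presence = {sp: {"CEN2": 1} for sp in species_tree.leaf_names}
        presence["Candida_glabrata"] = {"CEN2": 0}
        out = infer_ancestral_presence(presence, species_tree)
        assert out["CEN2"]["wgd_node"]

    def test_sister_region_clause(self, species_tree):
        presence = {sp: {} for sp in species_tree.leaf_names}
        presence["Vanderwaltozyma_polyspora"] = {"CEN3": 2}
        out = infer_ancestral_presence(presence, species_tree)
        assert out["CEN3"]["wgd_node"]
        assert not out["CEN3"]["node_b"]  # no non-WGD support

    def test_never_present_when_absent_from_all_leaves(self, species_tree):
        presence = {sp: {"CEN4": 0} for sp in species_tree.leaf_names}
        out = infer_ancestral_presence(presence, species_tree)
        assert not out["CEN4"]["wgd_node"] and not out["CEN4"]["node_b"]

    def test_post_wgd_only_dataset_warns(self, species_tree):
        presence = {sp: {"CEN5": 1} for sp in species_tree.post_wgd_species}
        with pytest.warns(UserWarning, match="sister-region"):
            infer_ancestral_presence(presence, species_tree)


class TestBranchAssignment:
    def test_single_leaf_event_on_terminal_branch(self, species_tree):
        out = assign_events_to_branches(
            {"e": {"Kluyveromyces_lactis"}}, species_tree)
        assert out["e"] == {"branch": "Kluyveromyces_lactis", "conflict": False}

    def test_genus_wide_event_on_stem_branch(self, species_tree):
        carriers = {"Lachancea_kluyveri", "Lachancea_thermotolerans",
                    "Lachancea_waltii"}
        out = assign_events_to_branches({"e": carriers}, species_tree)
        assert out["e"] == {"branch": "Lachancea", "conflict": False}

    def test_non_monophyletic_carriers_flagged(self, species_tree):
        carriers = {"Kluyveromyces_lactis", "Lachancea_waltii"}
        out = assign_events_to_branches({"e": carriers}, species_tree)
        assert out["e"]["conflict"]

    @pytest.mark.parametrize("seed", range(20))
    def test_scheduled_branches_recovered_from_simulated_leaves(
            self, species_tree, seed):
        """Events scheduled on a branch are carried by exactly that clade."""
        anc, _ = make_ancestor(SimConfig(seed=500 + seed))
        schedule = {
            "Lachancea": {"reciprocal_translocation": 1},
            "Kluyveromyces_lactis": {"inversion": 1},
            "KLE": {"reciprocal_translocation": 1},
        }
        leaves, log = evolve(anc, species_tree, schedule, seed=seed)
        # derive carrier sets from the leaf genomes via a junction signature
        def junctions(genome):
            out = set()
            for chrom in genome.chromosomes:
                pillars = [g.pillar_id for g in chrom.genes if g.pillar_id]
                out.update(frozenset(p) for p in zip(pillars, pillars[1:]))
            return out
        anc_j = junctions(anc)
        leaf_j = {sp: junctions(g) - anc_j for sp, g in leaves.items()}
        novel = set().union(*leaf_j.values())
        carriers = {str(j): {sp for sp, js in leaf_j.items() if j in js}
                    for j in novel}
        placed = assign_events_to_branches(carriers, species_tree)
        scheduled = set(schedule)
        recovered = {v["branch"] for v in placed.values() if not v["conflict"]}
        assert scheduled <= recovered
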