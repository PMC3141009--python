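"""Mapping extant centromeres and telomere locations to ancestral loci.

Each ancestral centromere and chromosome end is characterized by its
flanking pillars (window ``w`` per side).  An extant centromere maps to an
ancestral centromere when flank pillars from the ancestral locus lie beside
it in a consistent layout; disrupted sides are flagged as translocation or
inversion breakpoints at the locus.  Telomeres are treated as locations:
an ancestral chromosome end is conserved when its flank still sits at an
extant chromosome end, fused when it now abuts another ancestral end
inside a chromosome, and otherwise lost to a translocation or inversion
(with novel telomere sites reported for extant ends matching no ancestral
end).

Ancestral presence follows a parsimony rule: a locus present in an
orthologous region of at least one pre-duplication and one post-duplication
species — or in both paralogous sister regions of a post-duplication
species — is inferred present in the ancestor; presence at the older node B
additionally requires support across the pre-duplication genera.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .genome import Genome, SpeciesTree, ValidationError
from .cenfind import ConsensusModel, scan_centromeres

DEFAULT_FLANK_WINDOW = 5


# ---------------------------------------------------------------------------
# loci and assignments
# ---------------------------------------------------------------------------


@dataclass
class AncestralLocus:
    """An ancestral centromere or chromosome end with its flank pillars.

    Flanks are ordered nearest-first.  Centromere loci have both flanks;
    telomere ends only the inward one.
    """

    kind: str  # 'centromere' | 'telomere_end'
    label: str
    ancestral_chrom: str
    left_flank: list[str] = field(default_factory=list)
    right_flank: list[str] = field(default_factory=list)

    @property
    def inward_flank(self) -> list[str]:
        return self.right_flank if self.kind == "telomere_end" else []


@dataclass
class LocusAssignment:
    species: str
    label: str | None
    status: str  # 'mapped' | 'LOST' | 'UNMAPPED'
    chrom_id: str | None = None
    position: int | None = None
    evidence: dict[str, list[str]] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)
    fate: str | None = None  # telomere ends: conserved/fused/lost_by_*/fission_fusion
    partner: str | None = None  # fused-to ancestral end or fission cen locus
    new_site: tuple[str, str] | None = None
    candidates: list[str] = field(default_factory=list)


def centromere_loci(ancestral: Genome, w: int = DEFAULT_FLANK_WINDOW) -> list[AncestralLocus]:
    loci = []
    for chrom in ancestral.chromosomes:
        cen = chrom.centromere
        if cen is None:
            continue
        left = [g.pillar_id for g in chrom.genes[:cen.intergenic_position]
                if g.pillar_id is not None][-w:][::-1]
        right = [g.pillar_id for g in chrom.genes[cen.intergenic_position:]
                 if g.pillar_id is not None][:w]
        loci.append(AncestralLocus(
            "centromere", cen.ancestral_label or f"CEN_{chrom.chrom_id}",
            chrom.chrom_id, left, right))
    return loci


def telomere_loci(ancestral: Genome, w: int = DEFAULT_FLANK_WINDOW) -> list[AncestralLocus]:
    loci = []
    for chrom in ancestral.chromosomes:
        pillars = [g.pillar_id for g in chrom.genes if g.pillar_id is not None]
        for side, flank in (("L", pillars[:w]), ("R", pillars[::-1][:w])):
            end = chrom.left_telomere if side == "L" else chrom.right_telomere
            label = (end.ancestral_label if end and end.ancestral_label
                     else f"{chrom.chrom_id}-{side}")
            loci.append(AncestralLocus("telomere_end", label, chrom.chrom_id,
                                       [], list(flank)))
    return loci


# ---------------------------------------------------------------------------
# centromere mapping
# ---------------------------------------------------------------------------


def _extant_cen_flanks(extant: Genome, w: int):
    """(chrom_id, position, left flank genes, right flank genes) per
    annotated extant centromere; flanks nearest-first, pillar genes only."""
    out = []
    for chrom in extant.chromosomes:
        cen = chrom.centromere
        if cen is None:
            continue
        left = [g for g in chrom.genes[:cen.intergenic_position]
                if g.pillar_id is not None][-w:][::-1]
        right = [g for g in chrom.genes[cen.intergenic_position:]
                 if g.pillar_id is not None][:w]
        out.append((chrom.chrom_id, cen.intergenic_position, left, right))
    return out


def map_all_centromeres(
    extant: Genome, ancestral: Genome,
    w: int = DEFAULT_FLANK_WINDOW,
    model: ConsensusModel | None = None,
    allow_missing: bool = False,
) -> list[LocusAssignment]:
    """Assign every ancestral centromere a fate in one extant genome.

    Returns one assignment per (locus, matching extant centromere), plus a
    LOST assignment per unmatched locus track and an UNMAPPED entry (with
    LOST candidates) for extant centromeres whose flanks match no ancestral
    locus.  ``allow_missing`` treats chromosomes without a centromere
    annotation as genuinely acentric instead of raising.
    """
    if not allow_missing:
        _ensure_annotated(extant, model)
    loci = centromere_loci(ancestral, w)
    anc_orient = {g.pillar_id: g.orientation for g in ancestral.iter_genes()
                  if g.pillar_id is not None}
    side_of: dict[str, tuple[str, str]] = {}
    for locus in loci:
        for p in locus.left_flank:
            side_of[p] = (locus.label, "L")
        for p in locus.right_flank:
            side_of[p] = (locus.label, "R")
    by_label = {l.label: l for l in loci}
    n_tracks = 2 if extant.wgd_status == "post-WGD" else 1

    assignments: list[LocusAssignment] = []
    matched_counts: dict[str, int] = {l.label: 0 for l in loci}
    for chrom_id, pos, left, right in _extant_cen_flanks(extant, w):
        votes: dict[str, dict[str, list]] = {}
        for ext_side, genes in (("EL", left), ("ER", right)):
            for g in genes:
                hit = side_of.get(g.pillar_id)
                if hit is None:
                    continue
                label, anc_side = hit
                votes.setdefault(label, {}).setdefault(ext_side + anc_side, []).append(g)
        if not votes:
            assignments.append(LocusAssignment(
                extant.species, None, "UNMAPPED", chrom_id, pos,
                candidates=[]))
            continue
        involved = sorted(votes)
        for label in involved:
            v = votes[label]
            same = ("ELL" in v and "ERR" in v)
            swapped = ("ELR" in v and "ERL" in v)
            one_sided = not same and not swapped
            flags: set[str] = set()
            evidence = {"left": [], "right": []}
            matched_genes: list = []
            if same:
                evidence = {"left": [g.gene_id for g in v["ELL"]],
                            "right": [g.gene_id for g in v["ERR"]]}
                matched_genes = v["ELL"] + v["ERR"]
            elif swapped:
                evidence = {"left": [g.gene_id for g in v["ELR"]],
                            "right": [g.gene_id for g in v["ERL"]]}
                matched_genes = v["ELR"] + v["ERL"]
                flags.add("orientation_change")
            else:
                evidence = {"left": [g.gene_id for gs in v.values() for g in gs],
                            "right": []}
                matched_genes = [g for gs in v.values() for g in gs]
                flags.add("translocation_at_locus")
            if len(involved) > 1:
                flags.add("translocation_at_locus")
            if same and swapped:
                # both layouts supported at once: an inversion breakpoint
                # sits inside the flank window at this locus
                flags.add("inversion_at_locus")
            if same or swapped:
                rels = {side: _consensus_rel(v[key], anc_orient)
                        for side, key in (("L", "ELL" if same else "ELR"),
                                          ("R", "ERR" if same else "ERL"))}
                if rels["L"] != rels["R"]:
                    flags.add("inversion_at_locus")
                elif rels["L"] == -1 and not swapped:
                    flags.add("orientation_change")
            matched_counts[label] += 1
            assignments.append(LocusAssignment(
                extant.species, label, "mapped", chrom_id, pos,
                evidence, flags))
    for label, count in matched_counts.items():
        for _ in range(max(0, n_tracks - count)):
            assignments.append(LocusAssignment(extant.species, label, "LOST"))
    lost_labels = [a.label for a in assignments if a.status == "LOST"]
    for a in assignments:
        if a.status == "UNMAPPED":
            a.candidates = sorted(set(lost_labels))
    return assignments


def _consensus_rel(genes, anc_orient) -> int:
    score = sum(1 if g.orientation == anc_orient.get(g.pillar_id) else -1
                for g in genes)
    return 1 if score >= 0 else -1


def map_centromere(extant: Genome, ancestral: Genome, locus: AncestralLocus,
                   w: int = DEFAULT_FLANK_WINDOW,
                   model: ConsensusModel | None = None) -> list[LocusAssignment]:
    """Assignments for a single ancestral centromere locus."""
    return [a for a in map_all_centromeres(extant, ancestral, w, model)
            if a.label == locus.label]


def _ensure_annotated(extant: Genome, model: ConsensusModel | None) -> None:
    missing = [c.chrom_id for c in extant.chromosomes if c.centromere is None]
    if not missing:
        return
    if extant.sequences is None or model is None:
        raise ValidationError(
            f"{extant.species}: unannotated centromeres on {missing} and no "
            "sequences/model available to scan them")
    for chrom_id in missing:
        cands = scan_centromeres(extant.sequences[chrom_id], model,
                                 chrom_id=chrom_id)
        if not cands:
            raise ValidationError(
                f"{extant.species}: no centromere detected on {chrom_id}")
    raise ValidationError(
        f"{extant.species}: centromeres detected on {missing} but gene "
        "coordinates are needed to place them; annotate via the pipeline")


# ---------------------------------------------------------------------------
# telomere mapping
# ---------------------------------------------------------------------------


def _extant_end_flanks(extant: Genome, w: int):
    """(chrom_id, side, flank genes nearest-terminal-first) per extant end."""
    out = []
    for chrom in extant.chromosomes:
        pillars = [g for g in chrom.genes if g.pillar_id is not None]
        out.append((chrom.chrom_id, "L", pillars[:w]))
        out.append((chrom.chrom_id, "R", pillars[::-1][:w]))
    return out


class _AncGeography:
    """Rank geography of the ancestor restricted to surviving pillars.

    Distances are measured in *surviving* pillar steps (pillars with no
    extant copy are skipped), which keeps flank reasoning stable in
    heavily gene-depleted post-WGD genomes.
    """

    def __init__(self, ancestral: Genome, extant: Genome) -> None:
        present = {g.pillar_id for g in extant.iter_genes() if g.pillar_id}
        self.rank: dict[str, tuple[str, int]] = {}
        self.survivors: dict[str, list[str]] = {}
        self.full_rank: dict[str, tuple[str, int]] = {}
        self.n_full: dict[str, int] = {}
        self.cen_gap_index: dict[str, int | None] = {}
        self.cen_gap_full: dict[str, int | None] = {}
        self.cen_label: dict[str, str] = {}
        self.end_labels: dict[str, dict[str, str]] = {}
        for chrom in ancestral.chromosomes:
            all_pillars = [g.pillar_id for g in chrom.genes if g.pillar_id is not None]
            self.n_full[chrom.chrom_id] = len(all_pillars)
            for i, p in enumerate(all_pillars):
                self.full_rank[p] = (chrom.chrom_id, i)
            surv = [g.pillar_id for g in chrom.genes if g.pillar_id in present]
            self.survivors[chrom.chrom_id] = surv
            for i, p in enumerate(surv):
                self.rank[p] = (chrom.chrom_id, i)
            cen = chrom.centromere
            if cen is not None:
                before = sum(1 for g in chrom.genes[:cen.intergenic_position]
                             if g.pillar_id in present)
                self.cen_gap_index[chrom.chrom_id] = before
                self.cen_gap_full[chrom.chrom_id] = sum(
                    1 for g in chrom.genes[:cen.intergenic_position]
                    if g.pillar_id is not None)
                self.cen_label[chrom.chrom_id] = (cen.ancestral_label
                                                  or f"CEN_{chrom.chrom_id}")
            else:
                self.cen_gap_index[chrom.chrom_id] = None
                self.cen_gap_full[chrom.chrom_id] = None
            labels = {}
            for side, end in (("L", chrom.left_telomere), ("R", chrom.right_telomere)):
                labels[side] = (end.ancestral_label if end and end.ancestral_label
                                else f"{chrom.chrom_id}-{side}")
            self.end_labels[chrom.chrom_id] = labels

    def dist_from_end(self, pillar: str, side: str) -> tuple[str, int] | None:
        loc = self.rank.get(pillar)
        if loc is None:
            return None
        chrom, i = loc
        n = len(self.survivors[chrom])
        return chrom, (i if side == "L" else n - 1 - i)

    def end_of(self, chrom: str, side: str) -> str:
        return self.end_labels[chrom][side]

    def dist_from_cen(self, pillar: str) -> int | None:
        loc = self.rank.get(pillar)
        if loc is None:
            return None
        chrom, i = loc
        gap = self.cen_gap_index.get(chrom)
        if gap is None:
            return None
        # survivors gap..  are right of the centromere, gap-1 left of it
        return i - gap if i >= gap else gap - 1 - i



def map_all_telomeres(
    extant: Genome, ancestral: Genome, w: int = DEFAULT_FLANK_WINDOW,
) -> list[LocusAssignment]:
    """Fates of every ancestral chromosome end in one extant genome,
    plus novel-telomere-site reports for unmatched extant ends."""
    loci = telomere_loci(ancestral, w)
    geo = _AncGeography(ancestral, extant)
    n_tracks = 2 if extant.wgd_status == "post-WGD" else 1
    ends = _extant_end_flanks(extant, w)

    # match extant ends to ancestral ends: >=2 flank genes within 3w
    # surviving-pillar steps of the ancestral terminal
    ext_assign: dict[tuple[str, str], str] = {}
    scored: dict[str, list] = {l.label: [] for l in loci}
    label_side = {geo.end_of(c, s): (c, s) for c in geo.survivors for s in "LR"}
    for chrom_id, side, genes in ends:
        best, best_score = None, None
        for label, (anc_chrom, anc_side) in label_side.items():
            dists = []
            for g in genes:
                d = geo.dist_from_end(g.pillar_id, anc_side)
                if d is not None and d[0] == anc_chrom and d[1] <= 3 * w:
                    dists.append(d[1])
            # ranking: ends whose outermost genes sit closest to the
            # ancestral terminal win; track capping below discards relic
            # matches (e.g. a donor chromosome's residual end after a
            # telomeric translocation loses to the moved true terminal)
            if len(dists) >= 2:
                score = (len(dists), -min(dists))
                if best_score is None or score > best_score:
                    best, best_score = label, score
        if best is not None:
            ext_assign[(chrom_id, side)] = best
            scored[best].append((best_score, (chrom_id, side)))
    matches = {label: [loc for _, loc in sorted(entries, reverse=True)]
               for label, entries in scored.items()}

    pillar_occurrences: dict[str, list] = {}
    for g in extant.iter_genes():
        if g.pillar_id is not None:
            pillar_occurrences.setdefault(g.pillar_id, []).append(g)

    assignments: list[LocusAssignment] = []
    flank_by_end = {(c, s): f for c, s, f in ends}
    for locus in loci:
        anc_chrom = locus.ancestral_chrom
        anc_side = "L" if locus.label.endswith("L") else "R"
        conserved_ends = matches[locus.label][:n_tracks]
        for chrom_id, side in conserved_ends:
            a = LocusAssignment(
                extant.species, locus.label, "mapped", chrom_id,
                fate="conserved",
                evidence={"flank": [g.gene_id for g in flank_by_end[(chrom_id, side)]]})
            a.flags.add(f"end_{side}")
            assignments.append(a)
        remaining = n_tracks - len(conserved_ends)
        if remaining <= 0:
            continue
        internal = _internal_locations(
            extant, geo, anc_chrom, anc_side, pillar_occurrences,
            conserved_ends, w)
        for loc in internal[:remaining]:
            assignments.append(_classify_internal_end(
                extant, geo, locus, anc_chrom, anc_side, loc, w))
            remaining -= 1
        for _ in range(remaining):
            assignments.append(LocusAssignment(
                extant.species, locus.label, "LOST", fate="missing"))
    # novel telomere sites: extant ends not kept as a conserved location
    kept = {loc for label, locs in matches.items() for loc in locs[:n_tracks]}
    for chrom_id, side, genes in ends:
        if (chrom_id, side) not in kept and genes:
            assignments.append(LocusAssignment(
                extant.species, None, "UNMAPPED", chrom_id,
                fate="novel_site", new_site=(chrom_id, side)))
    return assignments


def _internal_locations(extant, geo, anc_chrom, anc_side, pillar_occurrences,
                        conserved_ends, w):
    """One representative occurrence per non-conserved track of the locus's
    outermost surviving flank pillars, outermost-first."""
    conserved_genes: set[str] = set()
    for chrom_id, side in conserved_ends:
        chrom = extant.chromosome(chrom_id)
        pillars = [g for g in chrom.genes if g.pillar_id is not None]
        flank = pillars[:2 * w] if side == "L" else pillars[::-1][:2 * w]
        conserved_genes.update(g.gene_id for g in flank)
    surv = geo.survivors[anc_chrom]
    flank_pillars = surv[:2 * w] if anc_side == "L" else surv[::-1][:2 * w]
    found: list = []
    for pillar in flank_pillars:  # nearest-terminal first
        for g in pillar_occurrences.get(pillar, []):
            if g.gene_id in conserved_genes:
                continue
            # one representative per junction region: chained fusions can
            # put two tracks of the same end on one chromosome
            if any(g.chrom_id == f.chrom_id and abs(g.index - f.index) <= 3 * w
                   for f in found):
                continue
            found.append(g)
    return found


def _classify_internal_end(extant, geo: _AncGeography, locus, anc_chrom,
                           anc_side, gene, w):
    """Decide the fate of an ancestral end whose flank is now internal."""
    chrom = extant.chromosome(gene.chrom_id)
    # distal direction: the locus flank continues on whichever side the
    # adjacent gene continues this occurrence's own ancestral run; distal
    # is the other side.  (Pillar-set voting fails for sister-track
    # fusions, where both sides carry copies of the flank pillars.)
    own = geo.full_rank.get(gene.pillar_id)

    def continues(genes_iter) -> bool:
        for g in genes_iter:
            if g.pillar_id is None:
                continue
            loc = geo.full_rank.get(g.pillar_id)
            return (loc is not None and own is not None
                    and loc[0] == own[0] and abs(loc[1] - own[1]) <= w)
        return False

    right_genes = chrom.genes[gene.index + 1:gene.index + 1 + 2 * w]
    left_genes = chrom.genes[max(0, gene.index - 2 * w):gene.index][::-1]
    right_cont = continues(right_genes)
    left_cont = continues(left_genes)

    def subtel_adjacent(genes_iter) -> bool:
        for g in genes_iter:
            if g.pillar_id is not None:
                return False
            if g.subtelomeric:
                return True
        return False

    if right_cont and not left_cont:
        distal_dir = -1
    elif left_cont and not right_cont:
        distal_dir = 1
    elif subtel_adjacent(right_genes) and not subtel_adjacent(left_genes):
        distal_dir = 1  # internalized subtelomeric zone marks the junction
    elif subtel_adjacent(left_genes) and not subtel_adjacent(right_genes):
        distal_dir = -1
    else:
        # last resort: away from the bulk of the locus flank
        flank_rest = (set(geo.survivors[anc_chrom][:2 * w]) if anc_side == "L"
                      else set(geo.survivors[anc_chrom][-2 * w:])) - {gene.pillar_id}
        right_p = {g.pillar_id for g in chrom.genes[gene.index + 1:] if g.pillar_id}
        left_p = {g.pillar_id for g in chrom.genes[:gene.index] if g.pillar_id}
        distal_dir = -1 if len(flank_rest & right_p) >= len(flank_rest & left_p) else 1
    if distal_dir == 1:
        distal_genes = list(chrom.genes[gene.index + 1:])[:4 * w]
    else:
        distal_genes = list(chrom.genes[:gene.index])[::-1][:4 * w]
    distal = [g for g in distal_genes if g.pillar_id is not None][:w]
    internalized = any(g.subtelomeric for g in distal_genes[:2 * w]
                       if g.pillar_id is None)
    assignment = LocusAssignment(
        extant.species, locus.label, "mapped", gene.chrom_id,
        evidence={"boundary": [gene.gene_id]})
    if internalized:
        assignment.flags.add("internalized_genes")
    if not distal:
        assignment.fate = "lost_by_translocation"
        assignment.flags.add("translocation")
        return assignment
    ranked = [(geo.full_rank[g.pillar_id], g) for g in distal
              if g.pillar_id in geo.full_rank]
    if len(ranked) >= 2 and ranked[0][0][0] == ranked[1][0][0]:
        d_chrom = ranked[0][0][0]
        rs = [r for (c, r), _ in ranked if c == d_chrom]
        n = geo.n_full[d_chrom]
        slack = 2 * w - 2  # tolerated track-specific losses at an anchor
        # fused: distal run starts at the partner's terminal (within the
        # loss slack) and walks inward, away from that terminal
        for side, anchored, inward in (
                ("L", rs[0] <= slack, rs[0] == min(rs)),
                ("R", rs[0] >= n - 1 - slack, rs[0] == max(rs))):
            partner = geo.end_of(d_chrom, side)
            if partner != locus.label and anchored and inward:
                assignment.fate = "fused"
                assignment.partner = partner
                assignment.flags.add("fusion")
                return assignment
        # fission: distal run starts beside the partner's centromeric
        # intergenic and walks outward along one arm
        gap = geo.cen_gap_full.get(d_chrom)
        if gap is not None and d_chrom != anc_chrom:
            right_arm = gap <= rs[0] <= gap + slack and rs[0] == min(rs)
            left_arm = gap - 1 - slack <= rs[0] <= gap - 1 and rs[0] == max(rs)
            if right_arm or left_arm:
                assignment.fate = "fission_fusion"
                assignment.partner = geo.cen_label[d_chrom]
                assignment.flags.add("fission_fusion")
                return assignment
        if d_chrom == anc_chrom:
            assignment.fate = "lost_by_inversion"
            assignment.flags.add("inversion")
            return assignment
    assignment.fate = "lost_by_translocation"
    assignment.flags.add("translocation")
    return assignment


def map_telomere_end(extant: Genome, ancestral: Genome, locus: AncestralLocus,
                     w: int = DEFAULT_FLANK_WINDOW) -> list[LocusAssignment]:
    return [a for a in map_all_telomeres(extant, ancestral, w)
            if a.label == locus.label]


# ---------------------------------------------------------------------------
# ancestral presence by parsimony
# ---------------------------------------------------------------------------


def infer_ancestral_presence(
    presence_counts: dict[str, dict[str, int]],
    tree: SpeciesTree,
) -> dict[str, dict[str, bool]]:
    """Parsimony presence at the WGD node and node B per locus.

    ``presence_counts[species][label]`` is the number of orthologous copies
    of the locus found in that species (0 if absent; up to 2 for
    post-duplication species).  A locus is ancestral (WGD node) when found
    in at least one non-WGD and one post-WGD species, or in both sister
    regions of one post-WGD species.  Node B presence further requires
    support from at least two non-WGD genera, or one non-WGD genus plus
    WGD-node presence.
    """
    post = tree.post_wgd_species & set(presence_counts)
    non = set(presence_counts) - post
    if not non:
        warnings.warn("no non-WGD species in dataset; ancestral presence "
                      "degenerates to the sister-region clause")
    labels = sorted({lab for d in presence_counts.values() for lab in d})
    out: dict[str, dict[str, bool]] = {}
    for label in labels:
        in_non = [s for s in non if presence_counts[s].get(label, 0) >= 1]
        in_post = [s for s in post if presence_counts[s].get(label, 0) >= 1]
        sister = any(presence_counts[s].get(label, 0) >= 2 for s in post)
        at_wgd = (bool(in_non) and bool(in_post)) or sister
        genera = {s.split("_")[0].split(" ")[0] for s in in_non}
        at_b = len(genera) >= 2 or (len(genera) >= 1 and at_wgd)
        out[label] = {"wgd_node": at_wgd, "node_b": at_b,
                      "n_supporting_genera": len(genera)}
    return out


def assign_events_to_branches(
    carriers_by_event: dict[str, set[str]],
    tree: SpeciesTree,
) -> dict[str, dict]:
    """Dollo-style single-origin placement of derived states on the tree.

    Each event goes on the edge above the smallest clade containing exactly
    its carrier species; non-monophyletic carrier sets are flagged as
    conflicting rather than forced.
    """
    out = {}
    for event_id, carriers in carriers_by_event.items():
        if not carriers:
            out[event_id] = {"branch": None, "conflict": False}
            continue
        node = tree.mrca(carriers)
        clade = tree.leaves_under(node)
        conflict = clade != set(carriers)
        out[event_id] = {"branch": tree.branch_of(node), "conflict": conflict}
    return out
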