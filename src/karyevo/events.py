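"""Chromosome-number mechanisms, fate tables, and derived-gene bookkeeping.

Only two mechanisms reduce chromosome number in these yeasts: telomere-to-
telomere fusion of two chromosomes with concomitant death of one
centromere, and (once) breakage of a chromosome at its centromere with both
arms fusing to other chromosomes' telomeres.  The only increase mechanism
is whole-genome duplication.  This module calls those mechanisms from
mapper output, tallies centromere/telomere fate tables (including the
packaged transcriptions of the published mapping tables), predicts
chromosome numbers from lineage calls, and reports internalized
subtelomeric genes and ancestrally present but missing pillars.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .genome import Genome, KaryevoError, SpeciesTree
from .mapping import (
    LocusAssignment,
    assign_events_to_branches,
    map_all_centromeres,
    map_all_telomeres,
)


class FateTableError(KaryevoError):
    """A fate table leaves ancestral loci uncovered."""


@dataclass
class MechanismCall:
    """One chromosome-number-changing event on a lineage.

    Fusion calls name exactly one lost centromere and the two fused
    ancestral ends.  The relative order of fusion and centromere death is
    not knowable from synteny, so every call carries ``order_unknown``.
    """

    kind: str  # telomere_fusion_cen_loss | centromere_fission | WGD | unexplained_loss
    species: str
    participants: dict = field(default_factory=dict)
    lost_centromere: str | None = None
    branch: str | None = None
    order_unknown: bool = True


# ---------------------------------------------------------------------------
# mechanism classification
# ---------------------------------------------------------------------------


def two_to_one_fraction(genome: Genome, ancestral: Genome,
                        window: int = 10) -> float:
    """Fraction of ancestral pillar positions mapping 2-to-1 into the genome.

    Post-duplication genomes are mostly single-copy, so raw duplicate-gene
    counts cannot detect a WGD; what persists is double conserved synteny:
    around any ancestral position, gene copies fall on two distinct extant
    chromosomes, each spanning both sides of the position.  A position
    counts as 2-to-1 when at least two extant chromosomes carry copies on
    both sides of it within ``window`` ancestral ranks.
    """
    occurrences: dict[str, list[str]] = {}
    for g in genome.iter_genes():
        if g.pillar_id is not None:
            occurrences.setdefault(g.pillar_id, []).append(g.chrom_id)
    total = 0
    hits = 0
    for chrom in ancestral.chromosomes:
        pillars = [g.pillar_id for g in chrom.genes if g.pillar_id is not None]
        for r in range(len(pillars)):
            total += 1
            left = pillars[max(0, r - window):r]
            right = pillars[r + 1:r + 1 + window]
            if not left or not right:
                # near ancestral ends: one-sided window
                left = left or pillars[r:r + 1]
                right = right or pillars[r:r + 1]
            chrom_sides: dict[str, set[str]] = {}
            for side, ps in (("L", left), ("R", right)):
                for p in ps:
                    for c in occurrences.get(p, []):
                        chrom_sides.setdefault(c, set()).add(side)
            tracks = sum(1 for sides in chrom_sides.values()
                         if sides == {"L", "R"})
            if tracks >= 2:
                hits += 1
    return hits / total if total else 0.0


def classify_mechanisms(
    genomes: dict[str, Genome],
    ancestral: Genome,
    tree: SpeciesTree | None = None,
    w: int = 5,
    wgd_fraction: float = 0.5,
    assignments: dict[str, tuple[list[LocusAssignment], list[LocusAssignment]]] | None = None,
) -> tuple[list[MechanismCall], pd.DataFrame, pd.DataFrame]:
    """Mechanism calls plus centromere and telomere fate tables.

    A fusion is called when two ancestral ends are reported fused to each
    other on one extant chromosome and exactly one of the two chromosomes'
    centromeres is lost; a fission when both centromere-flanking arms of
    one ancestral chromosome sit at former telomere ends of two other
    chromosomes with the centromere lost; a WGD when at least
    ``wgd_fraction`` of ancestral pillars map two-to-one.  Lost centromeres
    matching neither pattern are first-class ``unexplained_loss`` calls.
    """
    cen_of_chrom = {c.chrom_id: c.centromere.ancestral_label
                    for c in ancestral.chromosomes if c.centromere}
    end_chrom = {}
    for chrom in ancestral.chromosomes:
        for side, end in (("L", chrom.left_telomere), ("R", chrom.right_telomere)):
            if end is not None and end.ancestral_label:
                end_chrom[end.ancestral_label] = chrom.chrom_id

    calls: list[MechanismCall] = []
    cen_rows, telo_rows = [], []
    carriers: dict[str, set[str]] = {}

    for species, genome in sorted(genomes.items()):
        if assignments is not None:
            cen_asg, telo_asg = assignments[species]
        else:
            # a resolved dataset's missing centromere IS the signal here
            cen_asg = map_all_centromeres(genome, ancestral, w,
                                          allow_missing=True)
            telo_asg = map_all_telomeres(genome, ancestral, w)
        for a in cen_asg:
            cen_rows.append({
                "species": species, "label": a.label, "status": a.status,
                "chrom": a.chrom_id, "flags": ",".join(sorted(a.flags)) or "-"})
        for a in telo_asg:
            telo_rows.append({
                "species": species, "label": a.label, "fate": a.fate,
                "chrom": a.chrom_id, "partner": a.partner,
                "flags": ",".join(sorted(a.flags)) or "-"})

        # multiset: post-WGD genomes can lose both sister copies of a label
        lost_cens: dict[str, int] = {}
        for a in cen_asg:
            if a.status == "LOST":
                lost_cens[a.label] = lost_cens.get(a.label, 0) + 1

        def claim(label: str | None) -> None:
            if label and lost_cens.get(label, 0) > 0:
                lost_cens[label] -= 1

        if two_to_one_fraction(genome, ancestral) >= wgd_fraction:
            calls.append(MechanismCall("WGD", species, order_unknown=False))
            carriers.setdefault("WGD", set()).add(species)

        # fissions first: a fission pattern pins its lost centromere, which
        # disambiguates fusions sharing a chromosome with it
        fission_targets: dict[str, list[LocusAssignment]] = {}
        for a in telo_asg:
            if a.fate == "fission_fusion" and a.partner:
                fission_targets.setdefault(a.partner, []).append(a)
        for cen_label, ends in sorted(fission_targets.items()):
            if lost_cens.get(cen_label, 0) > 0 and len(ends) >= 2:
                split_chrom = next((c for c, lab in cen_of_chrom.items()
                                    if lab == cen_label), None)
                call = MechanismCall(
                    "centromere_fission", species,
                    participants={
                        "split_chrom": split_chrom,
                        "acceptor_ends": sorted(e.label for e in ends)},
                    lost_centromere=cen_label)
                calls.append(call)
                claim(cen_label)
                carriers.setdefault(f"fission:{cen_label}", set()).add(species)

        # fusions: mutually fused ancestral end pairs
        fused: dict[str, list[LocusAssignment]] = {}
        for a in telo_asg:
            if a.fate == "fused":
                fused.setdefault(a.label, []).append(a)
        pairs = set()
        for label, asgs in sorted(fused.items()):
            for a in asgs:
                partner = a.partner
                if partner in fused and any(b.partner == label
                                            for b in fused[partner]):
                    pairs.add(tuple(sorted((label, partner))))
        # resolve lost centromeres jointly: repeatedly claim any fusion whose
        # candidate set shrank to one available centromere; fusion chains
        # that remain symmetric are attributed greedily and marked ambiguous
        def candidates(pair):
            labels = {cen_of_chrom.get(end_chrom.get(e)) for e in pair}
            return sorted(l for l in labels if l and lost_cens.get(l, 0) > 0)

        pending = set(pairs)
        resolved: dict[tuple, tuple[str | None, bool]] = {}
        while pending:
            unique = next((p for p in sorted(pending)
                           if len(candidates(p)) <= 1), None)
            if unique is not None:
                cands = candidates(unique)
                cen = cands[0] if cands else None
                resolved[unique] = (cen, False)
                claim(cen)
                pending.discard(unique)
                continue
            pair = min(pending)  # ambiguous chain: attribute deterministically
            cen = candidates(pair)[0]
            resolved[pair] = (cen, True)
            claim(cen)
            pending.discard(pair)
        for pair in sorted(pairs):
            chrom_a, chrom_b = end_chrom.get(pair[0]), end_chrom.get(pair[1])
            cen, ambiguous = resolved.get(pair, (None, False))
            call = MechanismCall(
                "telomere_fusion_cen_loss", species,
                participants={"fused_ends": list(pair),
                              "ancestral_chroms": [chrom_a, chrom_b]},
                lost_centromere=cen)
            if ambiguous:
                call.participants["cen_attribution"] = "ambiguous"
            calls.append(call)
            carriers.setdefault(f"fusion:{pair[0]}+{pair[1]}", set()).add(species)

        for label, count in sorted(lost_cens.items()):
            for _ in range(count):
                calls.append(MechanismCall("unexplained_loss", species,
                                           lost_centromere=label,
                                           order_unknown=False))

    if tree is not None:
        placements = assign_events_to_branches(carriers, tree)
        for call in calls:
            key = None
            if call.kind == "WGD":
                key = "WGD"
            elif call.kind == "telomere_fusion_cen_loss":
                key = "fusion:" + "+".join(call.participants["fused_ends"])
            elif call.kind == "centromere_fission":
                key = f"fission:{call.lost_centromere}"
            if key is not None and key in placements:
                call.branch = placements[key]["branch"]
                if placements[key]["conflict"]:
                    call.participants["branch_conflict"] = True
    return calls, pd.DataFrame(cen_rows), pd.DataFrame(telo_rows)


# ---------------------------------------------------------------------------
# fate-table counting
# ---------------------------------------------------------------------------


def count_fates(
    cen_table: pd.DataFrame | None = None,
    telo_table: pd.DataFrame | None = None,
) -> dict:
    """Exact integer tallies over centromere/telomere fate tables.

    Centromere tables need columns ``species, label, status`` (status
    ``LOST`` marks a loss; each species must cover every ancestral label).
    Telomere tables need ``species, label, fate`` with fates in
    {conserved, lost, fused, fission_fusion} plus optional ``flags`` and
    ``new_sites``.  Counts are invariant to row order and to L/R
    relabelling of ancestral ends.
    """
    summary: dict = {}
    if cen_table is not None:
        labels = sorted(x for x in cen_table["label"].unique() if x is not None)
        per_species: dict[str, int] = {}
        for species, sub in cen_table.groupby("species"):
            covered = set(sub["label"].dropna())
            missing = set(labels) - covered
            if missing:
                raise FateTableError(
                    f"{species}: centromere fate table leaves loci uncovered: "
                    f"{sorted(missing)}")
            per_species[species] = int((sub["status"] == "LOST").sum())
        summary["centromere_losses_total"] = sum(per_species.values())
        summary["centromere_losses_by_species"] = per_species
        summary["n_centromere_loci"] = len(labels)
    if telo_table is not None:
        labels = sorted(x for x in telo_table["label"].unique() if x is not None)
        species_list = sorted(telo_table["species"].unique())
        for species in species_list:
            sub = telo_table[telo_table["species"] == species]
            missing = set(labels) - set(sub["label"].dropna())
            if missing:
                raise FateTableError(
                    f"{species}: telomere fate table leaves ends uncovered: "
                    f"{sorted(missing)}")
        real = telo_table[telo_table["label"].notna()]
        fused = int((real["fate"] == "fused").sum())
        fission = int((real["fate"] == "fission_fusion").sum())
        lost = real[real["fate"].isin(["lost", "lost_by_translocation",
                                       "lost_by_inversion"])]
        flags = lost.get("flags", pd.Series("", index=lost.index)).fillna("")
        by_transloc = int(((lost["fate"] == "lost_by_translocation")
                           | flags.str.contains("translocation")).sum())
        by_inv = int(((lost["fate"] == "lost_by_inversion")
                      | flags.str.contains("inversion")).sum())
        novel = 0
        if "new_sites" in telo_table.columns:
            novel = int(telo_table["new_sites"].fillna("").astype(str)
                        .str.split(";").apply(
                            lambda xs: sum(1 for x in xs if x and x != "-")).sum())
        novel += int((telo_table["fate"] == "novel_site").sum())
        summary.update({
            "n_telomere_locations": len(labels) * len(species_list),
            "ends_lost_by_fusion": fused,
            "ends_in_fission_fusion": fission,
            "ends_lost_by_translocation_or_inversion": int(len(lost)),
            "ends_lost_by_translocation": by_transloc,
            "ends_lost_by_inversion": by_inv,
            "novel_telomere_sites": novel,
        })
    return summary


# ---------------------------------------------------------------------------
# chromosome-number arithmetic
# ---------------------------------------------------------------------------


def predict_chromosome_number(ancestral_n: int, calls: list) -> int:
    """Chromosome count after a lineage's ordered mechanism calls.

    Doubles per WGD, minus one per fusion or fission call.
    """
    n = ancestral_n
    for call in calls:
        kind = call.kind if hasattr(call, "kind") else str(call)
        if kind == "WGD":
            n *= 2
        elif kind in ("telomere_fusion_cen_loss", "centromere_fission"):
            n -= 1
        if n < 1:
            raise KaryevoError(
                f"lineage calls drive chromosome number to {n} (< 1)")
    return n


# ---------------------------------------------------------------------------
# internalized subtelomeric genes & absent pillars
# ---------------------------------------------------------------------------


def find_internalized_genes(
    extant: Genome, ancestral: Genome | None = None,
) -> list[dict]:
    """Ancestrally subtelomeric genes now internal to a chromosome.

    A gene is internal when it sits strictly between the outermost
    pillar-bearing genes of its chromosome.  Consecutive internal
    subtelomeric genes are grouped into one junction location, keyed by the
    flanking pillar-bearing genes.  Returns ``[{chrom, flanking, genes}]``.
    """
    locations = []
    for chrom in extant.chromosomes:
        pillars = [g.index for g in chrom.genes if g.pillar_id is not None]
        if len(pillars) < 2:
            continue
        lo, hi = pillars[0], pillars[-1]
        run: list = []
        for g in chrom.genes[lo + 1:hi]:
            if g.pillar_id is None and g.subtelomeric:
                run.append(g)
            else:
                if run:
                    locations.append(_junction_record(chrom, run))
                    run = []
        if run:
            locations.append(_junction_record(chrom, run))
    return locations


def _junction_record(chrom, run) -> dict:
    first, last = run[0].index, run[-1].index
    left = next((g.gene_id for g in reversed(chrom.genes[:first])
                 if g.pillar_id is not None), None)
    right = next((g.gene_id for g in chrom.genes[last + 1:]
                  if g.pillar_id is not None), None)
    return {"chrom": chrom.chrom_id, "flanking": (left, right),
            "genes": [g.gene_id for g in run]}


def absent_pillars(genome: Genome, ancestral: Genome) -> list[str]:
    """Ancestral pillars with no surviving copy, in ancestral order."""
    present = {g.pillar_id for g in genome.iter_genes() if g.pillar_id}
    out = []
    for chrom in ancestral.chromosomes:
        for g in chrom.genes:
            if g.pillar_id is not None and g.pillar_id not in present:
                out.append(g.pillar_id)
    return out


# ---------------------------------------------------------------------------
# packaged transcriptions of the published fate tables
# ---------------------------------------------------------------------------


def load_table1() -> pd.DataFrame:
    """Machine-readable transcription of the published ancestral-centromere
    mapping table (one row per ancestral centromere x species x copy)."""
    with resources.files("karyevo.data").joinpath("table1.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    df = df.rename(columns={"centromere": "label"})
    df["status"] = df["chrom"].apply(lambda c: "LOST" if c == "-" else "mapped")
    return df


def load_table2() -> pd.DataFrame:
    """Machine-readable transcription of the published ancestral-telomere
    mapping table (one row per ancestral end x species x copy)."""
    with resources.files("karyevo.data").joinpath("table2.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    return df.rename(columns={"anc_end": "label"})
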