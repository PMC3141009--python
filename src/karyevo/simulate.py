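"""Karyotype-evolution simulator.

Generates an 8-chromosome pre-duplication ancestor with point centromeres
(CDEI--CDEII--CDEIII cassettes sampled from a generating consensus),
subtelomeric gene zones, and then evolves it along a species tree under a
schedule of rearrangement events: whole-genome duplication, reciprocal and
telomeric translocations, inversions, telomere-to-telomere fusions with
concomitant centromere loss, centromere fission, and post-duplication gene
loss.  Every applied event is logged with its branch, giving ground truth
for the inference stages.

Random event placement runs in *no-reuse* mode by default: breakpoints are
only placed at ancestral gene adjacencies well clear of previous junctions,
so scheduled event counts are exactly recoverable from the breakpoint-cycle
analysis.  Deliberate breakpoint-reuse histories are built by
:func:`make_reuse_fixture`.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, replace

import numpy as np

from .genome import (
    CentromereLocus,
    Chromosome,
    ConfigError,
    Gene,
    Genome,
    RearrangementEvent,
    RejectedEventError,
    ScheduleError,
    SpeciesTree,
    build_chromosome,
)
from .cenfind import ConsensusModel

BASES = "ACGT"

#: Degenerate-consensus column for CDEI, "NNCAVBTG": four invariant sites
#: (positions 3,4,7,8, 1-based) and two partially constrained ones.
CDE1_TEMPLATE = "NNCAVBTG"

#: Reference CDEIII used to seed the generating profile: 26 bp with the
#: invariant CCGAA core at offset 11 (0-based).  Within a species, point
#: centromeres carry further invariant sites beyond the cross-species core;
#: the generating profile therefore fixes ten additional positions (chosen
#: so that no run of invariant sites other than CCGAA reaches length 5 and
#: the positions flanking the core stay variable) and samples the remaining
#: eleven positions from a sharp two-allele distribution.
CDE3_REFERENCE = "TGTTTATGATTCCGAATAAAAATTTG"
CDE3_CCGAA_OFFSET = 11
CDE3_INVARIANT_EXTRA = (1, 2, 4, 6, 8, 18, 20, 21, 23, 25)

_IUPAC_SETS = {
    "N": "ACGT", "V": "ACG", "B": "CGT", "H": "ACT", "D": "AGT",
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
}


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults emulate the reconstructed yeast ancestor: 8 chromosomes, a few
    dozen ancestrally ordered genes each, subtelomeric zones of
    ancestor-less genes, a genome that is ~60% AT, CDEII spacers that are
    76–98% AT with a species-characteristic mean length spanning a twofold
    range across species, and post-duplication loss back to mostly
    single-copy gene content.
    """

    n_ancestral_chromosomes: int = 8
    genes_per_chromosome: int = 50
    subtelomeric_zone: int = 4
    intergenic_length: tuple[int, int] = (200, 600)
    genome_at_fraction: float = 0.60
    cde2_species_mean_range: tuple[float, float] = (40.0, 90.0)
    cde2_within_species_sd: float = 2.0
    cde2_at_fraction_range: tuple[float, float] = (0.76, 0.98)
    post_wgd_single_copy_fraction: float = 0.85
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("SimConfig.seed is required (no default)")
        if self.genes_per_chromosome < 2 * self.subtelomeric_zone + 3:
            raise ConfigError(
                "genes_per_chromosome must be >= 2*subtelomeric_zone + 3 "
                f"({self.genes_per_chromosome} < {2 * self.subtelomeric_zone + 3})")
        for lo, hi, name in [
            (*self.intergenic_length, "intergenic_length"),
            (*self.cde2_species_mean_range, "cde2_species_mean_range"),
            (*self.cde2_at_fraction_range, "cde2_at_fraction_range"),
        ]:
            if lo > hi:
                raise ConfigError(f"{name}: empty range ({lo}, {hi})")
        for frac, name in [
            (self.genome_at_fraction, "genome_at_fraction"),
            (self.post_wgd_single_copy_fraction, "post_wgd_single_copy_fraction"),
            (self.cde2_at_fraction_range[0], "cde2_at_fraction_range[0]"),
            (self.cde2_at_fraction_range[1], "cde2_at_fraction_range[1]"),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {frac}")


# ---------------------------------------------------------------------------
# generating centromere model
# ---------------------------------------------------------------------------


def _template_probs(template: str) -> np.ndarray:
    probs = np.zeros((len(template), 4))
    for i, sym in enumerate(template):
        allowed = _IUPAC_SETS[sym]
        for b in allowed:
            probs[i, BASES.index(b)] = 1.0 / len(allowed)
    return probs


_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _biased_probs(reference: str, invariant: set[int],
                  dominant: float = 0.8) -> np.ndarray:
    """Per-position base probabilities: invariant positions are fixed to the
    reference base, the rest are two-allele (reference base vs its
    complement) at ``dominant`` : 1-dominant."""
    probs = np.zeros((len(reference), 4))
    for i, b in enumerate(reference):
        if i in invariant:
            probs[i, BASES.index(b)] = 1.0
        else:
            probs[i, BASES.index(b)] = dominant
            probs[i, BASES.index(_COMPLEMENT[b])] = 1.0 - dominant
    return probs


@dataclass
class GeneratingCDEModel:
    """The ground-truth distribution centromere cassettes are drawn from."""

    cde1_probs: np.ndarray
    cde3_probs: np.ndarray
    cde2_mean: float
    cde2_sd: float
    cde2_at_range: tuple[float, float]

    def sample_cde1(self, rng: np.random.Generator) -> str:
        return _sample_pfm(self.cde1_probs, rng)

    def sample_cde3(self, rng: np.random.Generator) -> str:
        return _sample_pfm(self.cde3_probs, rng)

    def sample_cde2(self, rng: np.random.Generator) -> str:
        length = max(10, int(round(rng.normal(self.cde2_mean, self.cde2_sd))))
        lo, hi = self.cde2_at_range
        target = rng.uniform(lo, hi)
        k = int(round(target * length))
        k = min(max(k, int(np.ceil(lo * length))), int(np.floor(hi * length)))
        bases = [rng.choice(["A", "T"]) for _ in range(k)]
        bases += [rng.choice(["G", "C"]) for _ in range(length - k)]
        rng.shuffle(bases)
        return "".join(bases)

    def to_consensus_model(self) -> ConsensusModel:
        lo = max(5, int(round(self.cde2_mean - 4 * self.cde2_sd)))
        hi = int(round(self.cde2_mean + 4 * self.cde2_sd))
        return ConsensusModel(
            pfm_cde1=np.round(self.cde1_probs * 1000).astype(float),
            pfm_cde3=np.round(self.cde3_probs * 1000).astype(float),
            cde2_length_window=(lo, hi),
            cde2_min_at=self.cde2_at_range[0],
            background=np.full(4, 0.25),
            pseudocount=1.0,
        )


def _sample_pfm(probs: np.ndarray, rng: np.random.Generator) -> str:
    out = []
    for row in probs:
        out.append(BASES[rng.choice(4, p=row / row.sum())])
    return "".join(out)


def make_generating_model(config: SimConfig, rng: np.random.Generator) -> GeneratingCDEModel:
    mean = rng.uniform(*config.cde2_species_mean_range)
    return GeneratingCDEModel(
        cde1_probs=_template_probs(CDE1_TEMPLATE),
        cde3_probs=_biased_probs(
            CDE3_REFERENCE,
            set(range(CDE3_CCGAA_OFFSET, CDE3_CCGAA_OFFSET + 5))
            | set(CDE3_INVARIANT_EXTRA)),
        cde2_mean=mean,
        cde2_sd=config.cde2_within_species_sd,
        cde2_at_range=config.cde2_at_fraction_range,
    )


# ---------------------------------------------------------------------------
# ancestor construction
# ---------------------------------------------------------------------------


def make_ancestor(config: SimConfig) -> tuple[Genome, ConsensusModel]:
    """Build the ancestral genome plus the consensus model it was drawn from.

    Each chromosome gets ``genes_per_chromosome`` genes, the outer
    ``subtelomeric_zone`` on each side flagged subtelomeric and pillar-less,
    a mid-chromosome point centromere with sampled CDEI/CDEII/CDEIII
    sequences, and Anc-style telomere end labels.
    """
    rng = np.random.default_rng(config.seed)
    gen_model = make_generating_model(config, rng)
    chroms = []
    for ci in range(1, config.n_ancestral_chromosomes + 1):
        chrom_id = f"Anc{ci}"
        genes = []
        n = config.genes_per_chromosome
        z = config.subtelomeric_zone
        for gi in range(n):
            subtel = gi < z or gi >= n - z
            pillar = None if subtel else f"P{ci:02d}.{gi:03d}"
            orient = "+" if rng.random() < 0.5 else "-"
            gid = f"{chrom_id}.g{gi:03d}"
            genes.append(Gene(gid, chrom_id, gi, orient, pillar, subtel))
        cen = CentromereLocus(
            chrom_id, n // 2,
            strand="+" if rng.random() < 0.5 else "-",
            cde1_seq=gen_model.sample_cde1(rng),
            cde2_seq=gen_model.sample_cde2(rng),
            cde3_seq=gen_model.sample_cde3(rng),
            ancestral_label=f"CEN{ci}")
        chroms.append(build_chromosome(chrom_id, genes, cen,
                                       left_label=f"Anc{ci}-L",
                                       right_label=f"Anc{ci}-R"))
    genome = Genome("Ancestor", "non-WGD", chroms)
    genome.validate()
    return genome, gen_model.to_consensus_model()


# ---------------------------------------------------------------------------
# sequence synthesis
# ---------------------------------------------------------------------------


def _random_dna(length: int, at_fraction: float, rng: np.random.Generator) -> str:
    p = np.array([at_fraction / 2, (1 - at_fraction) / 2,
                  (1 - at_fraction) / 2, at_fraction / 2])
    return "".join(BASES[i] for i in rng.choice(4, size=length, p=p))


_RC = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def planted_intergenic(
    cde1: str, cde2: str, cde3: str, strand: str,
    rng: np.random.Generator,
    flank: tuple[int, int] = (60, 200),
    at_fraction: float = 0.60,
) -> tuple[str, tuple[int, int], str]:
    """An intergenic region with one centromere cassette planted in it.

    Returns ``(sequence, (start, end), strand)`` where the half-open span
    covers CDEI..CDEIII on the forward coordinates of the returned sequence.
    """
    cassette = cde1 + cde2 + cde3
    if strand == "-":
        cassette = revcomp(cassette)
    left = _random_dna(int(rng.integers(*flank)), at_fraction, rng)
    right = _random_dna(int(rng.integers(*flank)), at_fraction, rng)
    seq = left + cassette + right
    return seq, (len(left), len(left) + len(cassette)), strand


def synthesize_sequences(
    genome: Genome, config: SimConfig, rng: np.random.Generator,
    gene_length: int = 300,
) -> tuple[dict[str, str], dict[str, tuple[int, int, str]],
           dict[str, list[tuple[str, int, int]]]]:
    """Emit per-chromosome DNA with the centromere cassette planted at its
    intergenic.  Returns ``(sequences, cen_spans, gene_coords)`` with DNA
    spans 0-based half-open; ``gene_coords`` maps chromosome id to
    ``(gene_id, start, end)`` triples in order.  Composition-only model:
    gene bodies and intergenics are random DNA at the configured AT
    fraction.
    """
    sequences: dict[str, str] = {}
    cen_spans: dict[str, tuple[int, int, str]] = {}
    gene_coords: dict[str, list[tuple[str, int, int]]] = {}
    lo, hi = config.intergenic_length
    for chrom in genome.chromosomes:
        parts: list[str] = []
        coords: list[tuple[str, int, int]] = []
        pos = 0
        cen = chrom.centromere
        for i in range(len(chrom.genes) + 1):
            ig_len = int(rng.integers(lo, hi + 1))
            if cen is not None and i == cen.intergenic_position:
                cassette = (cen.cde1_seq or "") + (cen.cde2_seq or "") + (cen.cde3_seq or "")
                if cen.strand == "-":
                    cassette = revcomp(cassette)
                pad = max(40, (ig_len - len(cassette)) // 2)
                leftpad = _random_dna(pad, config.genome_at_fraction, rng)
                rightpad = _random_dna(pad, config.genome_at_fraction, rng)
                parts.append(leftpad)
                pos += pad
                cen_spans[chrom.chrom_id] = (pos, pos + len(cassette), cen.strand)
                parts.append(cassette)
                pos += len(cassette)
                parts.append(rightpad)
                pos += pad
            else:
                parts.append(_random_dna(ig_len, config.genome_at_fraction, rng))
                pos += ig_len
            if i < len(chrom.genes):
                parts.append(_random_dna(gene_length, config.genome_at_fraction, rng))
                coords.append((chrom.genes[i].gene_id, pos, pos + gene_length))
                pos += gene_length
        sequences[chrom.chrom_id] = "".join(parts)
        gene_coords[chrom.chrom_id] = coords
    return sequences, cen_spans, gene_coords


# ---------------------------------------------------------------------------
# segments: the cut/join algebra behind every event
# ---------------------------------------------------------------------------


@dataclass
class _Segment:
    genes: list[Gene]
    cen: CentromereLocus | None  # intergenic position relative to segment
    left_label: str | None
    right_label: str | None


def _chrom_to_segment(chrom: Chromosome) -> _Segment:
    return _Segment(
        [replace(g) for g in chrom.genes],
        replace(chrom.centromere) if chrom.centromere else None,
        chrom.left_telomere.ancestral_label if chrom.left_telomere else None,
        chrom.right_telomere.ancestral_label if chrom.right_telomere else None,
    )


def _cut(seg: _Segment, pos: int) -> tuple[_Segment, _Segment]:
    """Split between gene pos-1 and pos.  A centromere sitting exactly at the
    cut intergenic stays with the left piece (its right edge)."""
    if not 0 < pos < len(seg.genes):
        raise RejectedEventError(f"cut position {pos} not internal (0..{len(seg.genes)})")
    left_cen = right_cen = None
    if seg.cen is not None:
        if seg.cen.intergenic_position <= pos:
            left_cen = replace(seg.cen)
        else:
            right_cen = replace(seg.cen, intergenic_position=seg.cen.intergenic_position - pos)
    return (
        _Segment(seg.genes[:pos], left_cen, seg.left_label, None),
        _Segment(seg.genes[pos:], right_cen, None, seg.right_label),
    )


def _reverse(seg: _Segment) -> _Segment:
    n = len(seg.genes)
    cen = None
    if seg.cen is not None:
        cen = replace(seg.cen.flipped_strand(),
                      intergenic_position=n - seg.cen.intergenic_position)
    return _Segment([g.flipped() for g in reversed(seg.genes)], cen,
                    seg.right_label, seg.left_label)


def _join(a: _Segment, b: _Segment) -> _Segment:
    cen = None
    if a.cen is not None and b.cen is not None:
        raise RejectedEventError("join would create a dicentric chromosome")
    if a.cen is not None:
        cen = replace(a.cen)
    elif b.cen is not None:
        cen = replace(b.cen, intergenic_position=b.cen.intergenic_position + len(a.genes))
    return _Segment(a.genes + b.genes, cen, a.left_label, b.right_label)


def _segment_to_chrom(seg: _Segment, chrom_id: str) -> Chromosome:
    cen = replace(seg.cen, chrom_id=chrom_id) if seg.cen else None
    return build_chromosome(chrom_id, seg.genes, cen, seg.left_label, seg.right_label)


def _require_one_cen(seg: _Segment, context: str) -> None:
    if seg.cen is None:
        raise RejectedEventError(f"{context}: product would have no centromere")


# ---------------------------------------------------------------------------
# apply_event
# ---------------------------------------------------------------------------


def apply_event(genome: Genome, event: RearrangementEvent) -> Genome:
    """Apply one rearrangement, returning a new genome (input untouched)."""
    g = genome.copy()
    p = event.participants
    kind = event.kind

    if kind == "WGD":
        new_chroms = []
        for chrom in g.chromosomes:
            for copy_tag in ("A", "B"):
                seg = _chrom_to_segment(chrom)
                if copy_tag == "B":
                    for gene in seg.genes:
                        gene.gene_id = gene.gene_id + "~w2"
                new_chroms.append(_segment_to_chrom(seg, f"{chrom.chrom_id}_{copy_tag}"))
        g.chromosomes = new_chroms
        g.wgd_status = "post-WGD"
        return g

    if kind == "reciprocal_translocation":
        ca, cb = g.chromosome(p["chrom_a"]), g.chromosome(p["chrom_b"])
        if ca is cb:
            raise RejectedEventError("reciprocal translocation needs two chromosomes")
        la, ra = _cut(_chrom_to_segment(ca), p["pos_a"])
        lb, rb = _cut(_chrom_to_segment(cb), p["pos_b"])
        prod_a, prod_b = _join(la, rb), _join(lb, ra)
        for seg in (prod_a, prod_b):
            _require_one_cen(seg, "reciprocal translocation")
        _replace_chroms(g, {ca.chrom_id: prod_a, cb.chrom_id: prod_b})
        return g

    if kind == "inversion":
        chrom = g.chromosome(p["chrom"])
        start, end = p["start"], p["end"]
        if not (0 <= start < end <= len(chrom.genes)):
            raise RejectedEventError(f"inversion interval [{start},{end}) invalid")
        seg = _chrom_to_segment(chrom)
        mid = _Segment(seg.genes[start:end], None, None, None)
        if seg.cen is not None and start < seg.cen.intergenic_position < end:
            mid.cen = replace(seg.cen, intergenic_position=seg.cen.intergenic_position - start)
            seg.cen = None
        rmid = _reverse(mid)
        out = _Segment(seg.genes[:start], seg.cen if seg.cen and
                       seg.cen.intergenic_position <= start else None,
                       seg.left_label, None)
        out = _join(out, rmid)
        tail_cen = None
        if seg.cen is not None and seg.cen.intergenic_position >= end:
            tail_cen = replace(seg.cen, intergenic_position=seg.cen.intergenic_position - end)
        out = _join(out, _Segment(seg.genes[end:], tail_cen, None, seg.right_label))
        _replace_chroms(g, {chrom.chrom_id: out})
        return g

    if kind == "telomeric_translocation":
        donor = g.chromosome(p["donor"])
        acceptor = g.chromosome(p["acceptor"])
        if donor is acceptor:
            raise RejectedEventError("telomeric translocation needs two chromosomes")
        dseg = _chrom_to_segment(donor)
        if p.get("donor_side", "R") == "R":
            keep, moved = _cut(dseg, p["pos"])  # broken edge already leftward
        else:
            moved, keep = _cut(dseg, p["pos"])
            moved = _reverse(moved)  # normalize: broken edge leftward
        if moved.cen is not None:
            raise RejectedEventError("moved terminal segment carries the centromere")
        aseg = _chrom_to_segment(acceptor)
        if p.get("acceptor_end", "R") == "L":
            aseg = _reverse(aseg)
        new_acceptor = _join(aseg, moved)
        if p.get("acceptor_end", "R") == "L":
            new_acceptor = _reverse(new_acceptor)
        _require_one_cen(keep, "telomeric translocation donor")
        _replace_chroms(g, {donor.chrom_id: keep, acceptor.chrom_id: new_acceptor})
        return g

    if kind == "telomere_fusion_cen_loss":
        ca, cb = g.chromosome(p["chrom_a"]), g.chromosome(p["chrom_b"])
        if ca is cb:
            raise RejectedEventError("fusion needs two distinct chromosomes")
        sa, sb = _chrom_to_segment(ca), _chrom_to_segment(cb)
        if p.get("end_a", "R") == "L":
            sa = _reverse(sa)
        if p.get("end_b", "L") == "R":
            sb = _reverse(sb)
        labels = {s.cen.ancestral_label for s in (sa, sb) if s.cen is not None}
        lost = event.lost_centromere
        if lost is None or lost not in labels:
            raise RejectedEventError(
                f"fusion must name a centromere on a participant (got {lost!r}, "
                f"have {sorted(l for l in labels if l)})")
        # delete exactly one centromere (sister copies share their label)
        for s in (sa, sb):
            if s.cen is not None and s.cen.ancestral_label == lost:
                s.cen = None
                break
        fused = _join(sa, sb)
        _require_one_cen(fused, "telomere fusion")
        new_id = p.get("product_id", ca.chrom_id)
        g.chromosomes = [c for c in g.chromosomes if c.chrom_id not in
                         (ca.chrom_id, cb.chrom_id)]
        g.chromosomes.append(_segment_to_chrom(fused, new_id))
        return g

    if kind == "centromere_fission":
        src = g.chromosome(p["chrom"])
        if src.centromere is None:
            raise RejectedEventError(f"{src.chrom_id} has no centromere to split at")
        seg = _chrom_to_segment(src)
        cut_at = seg.cen.intergenic_position
        left_arm, right_arm = _cut(seg, cut_at)
        # the centromere is destroyed with the breakage
        left_arm.cen = right_arm.cen = None
        acc_l_id, acc_l_end = p["acceptor_left"]
        acc_r_id, acc_r_end = p["acceptor_right"]
        if acc_l_id == acc_r_id or src.chrom_id in (acc_l_id, acc_r_id):
            raise RejectedEventError("fission acceptors must be two other chromosomes")
        g.chromosomes = [c for c in g.chromosomes if c.chrom_id != src.chrom_id]
        for arm, acc_id, acc_end, broken_left in (
                (left_arm, acc_l_id, acc_l_end, False),
                (right_arm, acc_r_id, acc_r_end, True)):
            acc = g.chromosome(acc_id)
            aseg = _chrom_to_segment(acc)
            if acc_end == "L":
                aseg = _reverse(aseg)
            piece = arm if broken_left else _reverse(arm)  # broken edge leftward
            joined = _join(aseg, piece)
            if acc_end == "L":
                joined = _reverse(joined)
            _require_one_cen(joined, "centromere fission")
            _replace_chroms(g, {acc_id: joined})
        return g

    if kind == "gene_loss":
        gid = p["gene_id"]
        for chrom in g.chromosomes:
            for i, gene in enumerate(chrom.genes):
                if gene.gene_id == gid:
                    del chrom.genes[i]
                    if chrom.centromere is not None and \
                            chrom.centromere.intergenic_position > i:
                        chrom.centromere.intergenic_position -= 1
                    chrom.reindex()
                    chrom.recompute_telomeres()
                    return g
        raise RejectedEventError(f"gene_loss: gene {gid!r} not found")

    if kind == "centromere_loss":
        chrom = g.chromosome(p["chrom"])
        if chrom.centromere is None:
            raise RejectedEventError(f"{chrom.chrom_id} has no centromere")
        chrom.centromere = None
        return g

    raise RejectedEventError(f"unhandled event kind {kind!r}")


def _replace_chroms(g: Genome, updates: dict[str, _Segment]) -> None:
    new = []
    for c in g.chromosomes:
        if c.chrom_id in updates:
            new.append(_segment_to_chrom(updates[c.chrom_id], c.chrom_id))
        else:
            new.append(c)
    g.chromosomes = new


# ---------------------------------------------------------------------------
# random event placement (no-reuse mode)
# ---------------------------------------------------------------------------


class _NoReuseTracker:
    """Blocks pillar neighbourhoods around every placed breakpoint.

    A candidate cut must fall at an adjacency of two pillar-bearing genes
    that are ancestrally consecutive, with no blocked pillar within
    ``min_spacing`` genes on either side; accepted cuts block their
    ancestral neighbourhood.  This keeps every junction clean (no reuse) and
    every inter-breakpoint run long enough to form a synteny block.
    """

    def __init__(self, ancestral: Genome, min_spacing: int = 3) -> None:
        self.min_spacing = min_spacing
        self.anc_pos: dict[str, tuple[str, int]] = {}
        self.anc_order: dict[str, list[str | None]] = {}
        for c in ancestral.chromosomes:
            order: list[str | None] = [g.pillar_id for g in c.genes]
            self.anc_order[c.chrom_id] = order
            for g in c.genes:
                if g.pillar_id is not None:
                    self.anc_pos[g.pillar_id] = (c.chrom_id, g.index)
        self.blocked: set[str] = set()

    def copy(self) -> "_NoReuseTracker":
        t = _copy.copy(self)
        t.blocked = set(self.blocked)
        return t

    def is_ancestral_adjacency(self, left: Gene, right: Gene) -> bool:
        if left.pillar_id is None or right.pillar_id is None:
            return False
        a = self.anc_pos.get(left.pillar_id)
        b = self.anc_pos.get(right.pillar_id)
        if a is None or b is None or a[0] != b[0]:
            return False
        return abs(a[1] - b[1]) == 1

    def cut_allowed(self, chrom: Chromosome, pos: int) -> bool:
        if not 0 < pos < len(chrom.genes):
            return False
        left, right = chrom.genes[pos - 1], chrom.genes[pos]
        if not self.is_ancestral_adjacency(left, right):
            return False
        # keep cuts clear of chromosome ends so terminal junctions can only
        # come from genuinely telomeric events
        pillar_idx = [g.index for g in chrom.genes if g.pillar_id is not None]
        if pos - pillar_idx[0] < self.min_spacing or \
                pillar_idx[-1] + 1 - pos < self.min_spacing:
            return False
        lo = max(0, pos - self.min_spacing)
        hi = min(len(chrom.genes), pos + self.min_spacing)
        for g in chrom.genes[lo:hi]:
            if g.pillar_id is not None and g.pillar_id in self.blocked:
                return False
        return True

    def block_cut(self, chrom: Chromosome, pos: int) -> None:
        for g in chrom.genes[max(0, pos - self.min_spacing):pos + self.min_spacing]:
            if g.pillar_id is not None:
                self.blocked.add(g.pillar_id)

    def block_pillar(self, pillar: str | None) -> None:
        if pillar is None:
            return
        chrom_id, idx = self.anc_pos[pillar]
        order = self.anc_order[chrom_id]
        for i in range(max(0, idx - self.min_spacing),
                       min(len(order), idx + self.min_spacing + 1)):
            if order[i] is not None:
                self.blocked.add(order[i])


def _end_available(chrom: Chromosome, end: str, tracker: _NoReuseTracker) -> bool:
    """True when the chromosome end's boundary pillar is unblocked, so
    telomeric events never stack on an end already used by a prior event."""
    endo = chrom.left_telomere if end == "L" else chrom.right_telomere
    if endo is None or endo.boundary_gene is None:
        return False
    bg = next(g for g in chrom.genes if g.gene_id == endo.boundary_gene)
    return bg.pillar_id is not None and bg.pillar_id not in tracker.blocked


def _sample_cut(genome: Genome, chrom: Chromosome, tracker: _NoReuseTracker,
                rng: np.random.Generator, side_of_cen: str | None = None,
                tries: int = 100) -> int | None:
    cen_pos = chrom.centromere.intergenic_position if chrom.centromere else None
    positions = list(range(1, len(chrom.genes)))
    for _ in range(tries):
        pos = int(rng.choice(positions))
        if pos == cen_pos:  # random mode never cuts the centromeric intergenic
            continue
        if side_of_cen == "L" and (cen_pos is None or pos >= cen_pos):
            continue
        if side_of_cen == "R" and (cen_pos is None or pos <= cen_pos):
            continue
        if tracker.cut_allowed(chrom, pos):
            return pos
    return None


def place_random_event(
    genome: Genome, kind: str, rng: np.random.Generator,
    tracker: _NoReuseTracker, tries: int = 200,
) -> RearrangementEvent:
    """Draw a valid no-reuse placement for ``kind`` on ``genome``."""
    if kind == "WGD":
        return RearrangementEvent("WGD")
    for _ in range(tries):
        if kind == "reciprocal_translocation":
            if genome.n_chromosomes() < 2:
                break
            ids = rng.choice([c.chrom_id for c in genome.chromosomes], 2, replace=False)
            ca, cb = genome.chromosome(ids[0]), genome.chromosome(ids[1])
            side = "L" if rng.random() < 0.5 else "R"
            pa = _sample_cut(genome, ca, tracker, rng, side)
            pb = _sample_cut(genome, cb, tracker, rng, side)
            if pa is None or pb is None:
                continue
            tracker.block_cut(ca, pa)
            tracker.block_cut(cb, pb)
            return RearrangementEvent(kind, participants={
                "chrom_a": ca.chrom_id, "pos_a": pa,
                "chrom_b": cb.chrom_id, "pos_b": pb})
        if kind == "inversion":
            chrom = genome.chromosome(
                str(rng.choice([c.chrom_id for c in genome.chromosomes])))
            start = _sample_cut(genome, chrom, tracker, rng)
            if start is None:
                continue
            length = int(rng.integers(2, 7))
            end = start + length
            cen_pos = chrom.centromere.intergenic_position if chrom.centromere else None
            if end >= len(chrom.genes) or end == cen_pos \
                    or not tracker.cut_allowed(chrom, end):
                continue
            tracker.block_cut(chrom, start)
            tracker.block_cut(chrom, end)
            return RearrangementEvent(kind, participants={
                "chrom": chrom.chrom_id, "start": start, "end": end,
                "spans_centromere": bool(cen_pos is not None and start < cen_pos < end)})
        if kind == "telomeric_translocation":
            if genome.n_chromosomes() < 2:
                break
            ids = rng.choice([c.chrom_id for c in genome.chromosomes], 2, replace=False)
            donor, acceptor = genome.chromosome(ids[0]), genome.chromosome(ids[1])
            donor_side = "L" if rng.random() < 0.5 else "R"
            pos = _sample_cut(genome, donor, tracker, rng,
                              side_of_cen="R" if donor_side == "R" else "L")
            if pos is None:
                continue
            # moved-segment junctions must not masquerade as terminal or
            # centromeric anchors: keep the cut >= 10 pillar genes from the
            # donor's ends and from its centromeric intergenic
            pidx = [g.index for g in donor.genes if g.pillar_id is not None]
            cen_pos = donor.centromere.intergenic_position
            n_left = sum(1 for i in pidx if i < pos)
            n_right = len(pidx) - n_left
            if min(n_left, n_right) < 10 or abs(pos - cen_pos) < 10:
                continue
            acceptor_end = "L" if rng.random() < 0.5 else "R"
            if not _end_available(acceptor, acceptor_end, tracker):
                continue
            acc_end_obj = (acceptor.left_telomere if acceptor_end == "L"
                           else acceptor.right_telomere)
            tracker.block_cut(donor, pos)
            if acc_end_obj is not None and acc_end_obj.boundary_gene is not None:
                bg = next(g for g in acceptor.genes
                          if g.gene_id == acc_end_obj.boundary_gene)
                tracker.block_pillar(bg.pillar_id)
            return RearrangementEvent(kind, participants={
                "donor": donor.chrom_id, "pos": pos, "donor_side": donor_side,
                "acceptor": acceptor.chrom_id, "acceptor_end": acceptor_end,
                "acceptor_anc_end": acc_end_obj.ancestral_label if acc_end_obj else None})
        if kind == "telomere_fusion_cen_loss":
            if genome.n_chromosomes() < 2:
                break
            ids = rng.choice([c.chrom_id for c in genome.chromosomes], 2, replace=False)
            ca, cb = genome.chromosome(ids[0]), genome.chromosome(ids[1])
            if ca.centromere is None or cb.centromere is None:
                continue
            end_a, end_b = "R", "L"
            if not (_end_available(ca, end_a, tracker)
                    and _end_available(cb, end_b, tracker)):
                continue
            lost_of = ca if rng.random() < 0.5 else cb
            lost = lost_of.centromere.ancestral_label
            for chrom, end in ((ca, end_a), (cb, end_b)):
                endo = chrom.left_telomere if end == "L" else chrom.right_telomere
                if endo is not None and endo.boundary_gene is not None:
                    bg = next(g for g in chrom.genes if g.gene_id == endo.boundary_gene)
                    tracker.block_pillar(bg.pillar_id)
            return RearrangementEvent(
                kind, lost_centromere=lost,
                participants={
                    "chrom_a": ca.chrom_id, "end_a": end_a,
                    "chrom_b": cb.chrom_id, "end_b": end_b,
                    "anc_end_a": (ca.right_telomere.ancestral_label
                                  if end_a == "R" else ca.left_telomere.ancestral_label),
                    "anc_end_b": (cb.left_telomere.ancestral_label
                                  if end_b == "L" else cb.right_telomere.ancestral_label)})
        if kind == "centromere_fission":
            if genome.n_chromosomes() < 3:
                break
            ids = rng.choice([c.chrom_id for c in genome.chromosomes], 3, replace=False)
            src = genome.chromosome(ids[0])
            if src.centromere is None:
                continue
            acc_l, acc_r = genome.chromosome(ids[1]), genome.chromosome(ids[2])
            end_l = "L" if rng.random() < 0.5 else "R"
            end_r = "L" if rng.random() < 0.5 else "R"
            if not (_end_available(acc_l, end_l, tracker)
                    and _end_available(acc_r, end_r, tracker)):
                continue
            cen_pos = src.centromere.intergenic_position
            tracker.block_cut(src, cen_pos)
            for chrom, end in ((acc_l, end_l), (acc_r, end_r)):
                endo = chrom.left_telomere if end == "L" else chrom.right_telomere
                if endo is not None and endo.boundary_gene is not None:
                    bg = next(g for g in chrom.genes if g.gene_id == endo.boundary_gene)
                    tracker.block_pillar(bg.pillar_id)
            return RearrangementEvent(
                kind, lost_centromere=src.centromere.ancestral_label,
                participants={
                    "chrom": src.chrom_id,
                    "acceptor_left": [acc_l.chrom_id, end_l],
                    "acceptor_right": [acc_r.chrom_id, end_r],
                    "anc_end_left": (acc_l.left_telomere.ancestral_label if end_l == "L"
                                     else acc_l.right_telomere.ancestral_label),
                    "anc_end_right": (acc_r.left_telomere.ancestral_label if end_r == "L"
                                      else acc_r.right_telomere.ancestral_label)})
        if kind == "gene_loss":
            two_copy = [pid for pid, n in genome.pillar_counts().items() if n == 2]
            candidates = [pid for pid in two_copy if pid not in tracker.blocked]
            if not candidates:
                break
            pid = str(rng.choice(sorted(candidates)))
            copies = [g for g in genome.iter_genes() if g.pillar_id == pid]
            gene = copies[int(rng.integers(len(copies)))]
            return RearrangementEvent(kind, participants={
                "gene_id": gene.gene_id, "pillar": pid})
        raise ScheduleError(f"cannot place random event of kind {kind!r}")
    raise ScheduleError(f"no valid no-reuse placement found for {kind!r}")


# ---------------------------------------------------------------------------
# evolve along a tree
# ---------------------------------------------------------------------------


def _validate_schedule(ancestor: Genome, stree: SpeciesTree, schedule: dict) -> None:
    known = {stree.node_label(n) for n in stree.tree.preorder_node_iter()}
    for branch in schedule:
        if branch not in known:
            raise ScheduleError(f"schedule branch {branch!r} not in tree")
    # per-leaf chromosome arithmetic must stay >= 1 and fusions feasible
    for leaf in stree.leaf_names:
        n = ancestor.n_chromosomes()
        for branch in stree.path_branches(leaf):
            for item in _branch_items(schedule.get(branch, [])):
                kind = item if isinstance(item, str) else item.kind
                if kind == "WGD":
                    n *= 2
                elif kind in ("telomere_fusion_cen_loss", "centromere_fission"):
                    n -= 1
                    if n < 1:
                        raise ScheduleError(
                            f"schedule leaves {leaf} with {n} chromosomes "
                            f"(more fusions than chromosomes - 1)")


def _branch_items(entry) -> list:
    """Normalize a schedule entry to a flat list of events / kind strings."""
    if isinstance(entry, dict):  # {"kind": count}
        items: list[str] = []
        for kind, count in entry.items():
            items.extend([kind] * int(count))
        return items
    return list(entry)


def evolve(
    ancestor: Genome,
    stree: SpeciesTree,
    schedule: dict,
    config: SimConfig | None = None,
    seed: int | None = None,
) -> tuple[dict[str, Genome], list[RearrangementEvent]]:
    """Evolve leaf genomes along root-to-leaf paths.

    ``schedule`` maps branch identifiers to either a list of fully specified
    :class:`RearrangementEvent` or a ``{kind: count}`` dict, in which case
    placements are drawn randomly in no-reuse mode (requires ``seed`` or
    ``config.seed``).  Post-WGD lineages additionally receive gene-loss
    events immediately after the WGD until the configured single-copy
    fraction is reached.  Returns leaf genomes plus the ground-truth log.
    """
    needs_rng = any(
        isinstance(entry, dict) or any(isinstance(i, str) for i in _branch_items(entry))
        for entry in schedule.values())
    has_wgd = any(
        (i if isinstance(i, str) else i.kind) == "WGD"
        for entry in schedule.values() for i in _branch_items(entry))
    if seed is None and config is not None:
        seed = config.seed
    if (needs_rng or has_wgd) and seed is None:
        raise ScheduleError("random schedule mode requires a seed")
    rng = np.random.default_rng(seed) if seed is not None else None
    single_copy_frac = (config.post_wgd_single_copy_fraction if config is not None
                        else SimConfig(seed=0).post_wgd_single_copy_fraction)
    _validate_schedule(ancestor, stree, schedule)

    log: list[RearrangementEvent] = []
    leaves: dict[str, Genome] = {}

    def walk(node, genome: Genome, tracker: _NoReuseTracker) -> None:
        branch = stree.branch_of(node) if node.parent_node is not None else None
        if branch is not None:
            for item in _branch_items(schedule.get(branch, [])):
                if isinstance(item, str):
                    event = place_random_event(genome, item, rng, tracker)
                else:
                    event = replace(item, participants=dict(item.participants))
                event.branch = branch
                genome = apply_event(genome, event)
                log.append(event)
                if event.kind == "WGD":
                    genome = _post_wgd_losses(genome, single_copy_frac, rng,
                                              tracker, branch, log)
        if node.is_leaf():
            leaf_genome = genome.copy()
            leaf_genome.species = node.taxon.label
            leaves[leaf_genome.species] = leaf_genome
            return
        for child in node.child_nodes():
            walk(child, genome, tracker.copy())

    walk(stree.tree.seed_node, ancestor.copy(), _NoReuseTracker(ancestor))
    return leaves, log


def _post_wgd_losses(genome: Genome, single_copy_fraction: float,
                     rng: np.random.Generator | None,
                     tracker: _NoReuseTracker, branch: str,
                     log: list[RearrangementEvent]) -> Genome:
    if rng is None:
        raise ScheduleError("post-WGD gene loss requires a seed")
    counts = genome.pillar_counts()
    n_pillars = len(counts)
    target_single = int(round(single_copy_fraction * n_pillars))
    n_single = sum(1 for v in counts.values() if v == 1)
    while n_single < target_single:
        event = place_random_event(genome, "gene_loss", rng, tracker)
        event.branch = branch
        genome = apply_event(genome, event)
        log.append(event)
        n_single += 1
    return genome


def random_history(
    ancestor: Genome, kinds: list[str], seed: int,
    min_spacing: int = 3,
) -> tuple[Genome, list[RearrangementEvent]]:
    """Apply a sequence of randomly placed no-reuse events to a genome.

    ``kinds`` lists the event kinds in application order (e.g. ten
    ``reciprocal_translocation`` and five ``inversion`` entries).  Returns
    the derived genome and the concrete event log.
    """
    rng = np.random.default_rng(seed)
    tracker = _NoReuseTracker(ancestor, min_spacing)
    genome = ancestor.copy()
    log: list[RearrangementEvent] = []
    for kind in kinds:
        event = place_random_event(genome, kind, rng, tracker)
        genome = apply_event(genome, event)
        log.append(event)
    return genome, log


# ---------------------------------------------------------------------------
# deliberate breakpoint-reuse fixtures
# ---------------------------------------------------------------------------


def make_reuse_fixture(style: str, seed: int,
                       config: SimConfig | None = None
                       ) -> tuple[Genome, Genome, list[RearrangementEvent]]:
    """Construct a genome with a deliberately chained rearrangement history.

    ``cen9_pathway`` chains nine reciprocal translocations so that eight
    breakpoints are reused: every event after the first cuts the junction
    created by the previous one, repeatedly replacing the left flank of one
    focal centromere.  ``klactis_cycle`` chains four reciprocal
    translocations, three of them cutting at ancestral centromeric
    intergenics, closing into a single breakpoint-edge cycle.

    Returns ``(ancestor, derived_genome, event_log)``.  Events carry
    ``participants["reused_junction"]`` and
    ``participants["centromeric_breakpoint"]`` metadata.
    """
    cfg = config or SimConfig(seed=seed)
    ancestor, _ = make_ancestor(cfg)
    if style == "klactis_cycle":
        genome, log = _klactis_cycle(ancestor)
    elif style == "cen9_pathway":
        genome, log = _cen9_pathway(ancestor)
    else:
        raise ConfigError(f"unknown fixture style {style!r}")
    genome.validate()
    return ancestor, genome, log


def _apply_logged(genome: Genome, log: list[RearrangementEvent],
                  **kwargs) -> Genome:
    event = RearrangementEvent("reciprocal_translocation", participants=kwargs)
    out = apply_event(genome, event)
    log.append(event)
    return out


def _check_fixture_room(ancestor: Genome, margin: int = 10) -> None:
    for chrom in ancestor.chromosomes:
        cen = chrom.centromere.intergenic_position
        pillars = chrom.pillar_genes()
        lo, hi = pillars[0].index, pillars[-1].index
        if cen - margin < lo or cen + margin > hi:
            raise ConfigError(
                "reuse fixtures need >= 10 pillar-bearing genes on each side "
                f"of every centromere ({chrom.chrom_id} is too short)")


def _klactis_cycle(ancestor: Genome) -> tuple[Genome, list[RearrangementEvent]]:
    g = ancestor
    _check_fixture_room(ancestor)
    ids = [c.chrom_id for c in ancestor.chromosomes[:4]]
    cen = {cid: ancestor.chromosome(cid).centromere.intergenic_position for cid in ids}
    log: list[RearrangementEvent] = []
    c1, c2, c3, c4 = ids
    b1 = cen[c1] + 4  # non-centromeric cut on the focal partner
    # E1: fresh cut on c1, centromeric cut on c2
    g = _apply_logged(g, log, chrom_a=c1, pos_a=b1, chrom_b=c2, pos_b=cen[c2],
                      reused_junction=False, centromeric_breakpoint=True)
    # E2/E3: cut the running junction + the next centromeric intergenic
    g = _apply_logged(g, log, chrom_a=c2, pos_a=cen[c2], chrom_b=c3, pos_b=cen[c3],
                      reused_junction=True, centromeric_breakpoint=True)
    g = _apply_logged(g, log, chrom_a=c3, pos_a=cen[c3], chrom_b=c4, pos_b=cen[c4],
                      reused_junction=True, centromeric_breakpoint=True)
    # E4: cut the last junction + a fresh non-centromeric site inside the
    # first finished product, closing the cycle
    b5 = b1 + 3
    g = _apply_logged(g, log, chrom_a=c4, pos_a=cen[c4], chrom_b=c1, pos_b=b5,
                      reused_junction=True, centromeric_breakpoint=False)
    return g, log


def _cen9_pathway(ancestor: Genome) -> tuple[Genome, list[RearrangementEvent]]:
    ids = [c.chrom_id for c in ancestor.chromosomes]
    if len(ids) < 8:
        raise ConfigError("cen9_pathway needs at least 8 ancestral chromosomes")
    _check_fixture_room(ancestor)
    cen = {cid: ancestor.chromosome(cid).centromere.intergenic_position for cid in ids}
    focal, partners = ids[0], ids[1:8]
    g = ancestor
    log: list[RearrangementEvent] = []
    # E1: cut 6 genes left of the focal centromere and 6 genes left of the
    # first partner's centromere
    g = _apply_logged(g, log, chrom_a=focal, pos_a=cen[focal] - 6,
                      chrom_b=partners[0], pos_b=cen[partners[0]] - 6,
                      reused_junction=False, centromeric_breakpoint=False)
    # the unfinished product is the partner-id chromosome carrying the focal
    # centromere; its junction sits at the partner's cut position
    running, junction = partners[0], cen[partners[0]] - 6
    # E2..E7: recut the running junction, fresh partner each time
    for nxt in partners[1:7]:
        g = _apply_logged(g, log, chrom_a=running, pos_a=junction,
                          chrom_b=nxt, pos_b=cen[nxt] - 6,
                          reused_junction=True, centromeric_breakpoint=False)
        running, junction = nxt, cen[nxt] - 6
    # E8/E9: recut the running junction against fresh sites inside the first
    # two finished products (3 genes past their junctions)
    for finished in (focal, partners[0]):
        fresh = _junction_offset_cut(g, finished, 3)
        g = _apply_logged(g, log, chrom_a=running, pos_a=junction,
                          chrom_b=finished, pos_b=fresh,
                          reused_junction=True, centromeric_breakpoint=False)
        running, junction = finished, fresh
    return g, log


def _junction_offset_cut(genome: Genome, chrom_id: str, offset: int) -> int:
    """Position ``offset`` genes to the right of the first junction (first
    position where consecutive genes come from different source chromosomes,
    judged by gene-id prefix)."""
    chrom = genome.chromosome(chrom_id)
    prefix = lambda g: g.gene_id.split(".")[0]
    for i in range(1, len(chrom.genes)):
        if prefix(chrom.genes[i - 1]) != prefix(chrom.genes[i]):
            return i + offset
    raise RejectedEventError(f"{chrom_id}: no junction found")
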