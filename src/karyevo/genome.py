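"""Core domain model for yeast karyotype evolution analyses.

Gene orders are compared across species through *pillars*: ortholog/paralog
columns that link each extant gene to a position in the reconstructed
pre-duplication ancestral genome.  A genome here is an ordered collection of
chromosomes, each carrying an ordered gene list, at most one point centromere
(located in an intergenic, i.e. *between* two gene indices) and two telomere
ends.  Telomeres are treated as locations rather than sequences: the telomere
location of a chromosome is the position beside the outermost gene that still
has an ancestral ortholog, and anything beyond it is subtelomeric.

Coordinate conventions used throughout the package:

* gene order: 0-based indices ``0..n-1`` per chromosome;
* intergenic loci: integers ``0..n`` meaning "before gene i" (``0`` = before
  the first gene, ``n`` = after the last);
* DNA: 0-based half-open intervals.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import yaml

#: sentinel written to gene-order files for genes without an ancestral pillar.
#: An explicit token (never an empty field) so that "no ortholog" cannot be
#: confused with a truncated row.
ABSENT = "ABSENT"

ORIENTATIONS = ("+", "-")


class KaryevoError(Exception):
    """Base class for all package errors."""


class MalformedInputError(KaryevoError):
    """An input file violates the documented format."""


class ValidationError(KaryevoError):
    """An object violates a model invariant."""


class ConfigError(KaryevoError):
    """A configuration value is out of range or inconsistent."""


class RejectedEventError(KaryevoError):
    """A rearrangement event would produce an invalid karyotype.

    Raised e.g. for a translocation whose products would carry zero or two
    centromeres; callers that place events randomly may catch this and
    resample.
    """


class ScheduleError(KaryevoError):
    """An event schedule cannot be satisfied on the given genome/tree."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Gene:
    """A single gene in a gene-order table.

    ``pillar_id`` is the ancestral ortholog-column identifier, or ``None``
    for genes (typically subtelomeric) with no ancestral counterpart.
    ``subtelomeric`` records whether the gene originated in a subtelomeric
    zone; the flag travels with the gene through rearrangements, which is
    what makes internalized-gene detection possible.
    """

    gene_id: str
    chrom_id: str
    index: int
    orientation: str
    pillar_id: str | None = None
    subtelomeric: bool = False

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise MalformedInputError(
                f"gene {self.gene_id!r}: unknown orientation {self.orientation!r}"
            )

    def flipped(self) -> "Gene":
        return replace(self, orientation="+" if self.orientation == "-" else "-")


@dataclass
class CentromereLocus:
    """A point centromere located in an intergenic.

    ``intergenic_position`` i means "between gene index i-1 and i" on the
    chromosome (0 = before the first gene).  CDE sequences are optional;
    when present CDEI must be 8 bp and CDEIII 26 bp.
    """

    chrom_id: str
    intergenic_position: int
    strand: str = "+"
    cde1_seq: str | None = None
    cde2_seq: str | None = None
    cde3_seq: str | None = None
    ancestral_label: str | None = None

    def __post_init__(self) -> None:
        if self.cde1_seq is not None and len(self.cde1_seq) != 8:
            raise ValidationError(
                f"centromere on {self.chrom_id}: CDEI must be 8 bp, got {len(self.cde1_seq)}"
            )
        if self.cde3_seq is not None and len(self.cde3_seq) != 26:
            raise ValidationError(
                f"centromere on {self.chrom_id}: CDEIII must be 26 bp, got {len(self.cde3_seq)}"
            )

    def flipped_strand(self) -> "CentromereLocus":
        return replace(self, strand="+" if self.strand == "-" else "-")


@dataclass
class TelomereEnd:
    """One end (L or R) of a chromosome, viewed as a location.

    ``boundary_gene`` is the outermost gene that carries a pillar id;
    ``subtelomeric_genes`` are gene ids beyond it.  ``ancestral_label`` names
    the ancestral chromosome end this end corresponds to (e.g. ``"Anc3-L"``),
    or ``None`` for a novel telomere site created by rearrangement.
    """

    chrom_id: str
    side: str  # 'L' or 'R'
    boundary_gene: str | None = None
    subtelomeric_genes: frozenset[str] = frozenset()
    ancestral_label: str | None = None


@dataclass
class Chromosome:
    chrom_id: str
    genes: list[Gene] = field(default_factory=list)
    centromere: CentromereLocus | None = None
    left_telomere: TelomereEnd | None = None
    right_telomere: TelomereEnd | None = None

    def __len__(self) -> int:
        return len(self.genes)

    def pillar_genes(self) -> list[Gene]:
        return [g for g in self.genes if g.pillar_id is not None]

    def recompute_telomeres(self) -> None:
        """Recompute boundary genes and subtelomeric sets from the gene order.

        Idempotent, and independent of how the gene list was assembled.
        Existing ancestral labels on the ends are preserved.
        """
        pg = self.pillar_genes()
        left_label = self.left_telomere.ancestral_label if self.left_telomere else None
        right_label = self.right_telomere.ancestral_label if self.right_telomere else None
        if not pg:
            self.left_telomere = TelomereEnd(self.chrom_id, "L", None, frozenset(), left_label)
            self.right_telomere = TelomereEnd(self.chrom_id, "R", None, frozenset(), right_label)
            return
        lo, hi = pg[0].index, pg[-1].index
        self.left_telomere = TelomereEnd(
            self.chrom_id, "L", pg[0].gene_id,
            frozenset(g.gene_id for g in self.genes[:lo]), left_label)
        self.right_telomere = TelomereEnd(
            self.chrom_id, "R", pg[-1].gene_id,
            frozenset(g.gene_id for g in self.genes[hi + 1:]), right_label)

    def reindex(self) -> None:
        for i, g in enumerate(self.genes):
            g.index = i
            g.chrom_id = self.chrom_id

    def validate(self) -> None:
        for i, g in enumerate(self.genes):
            if g.index != i:
                raise ValidationError(
                    f"{self.chrom_id}: gene {g.gene_id} has index {g.index}, expected {i}")
        if self.centromere is not None:
            if not 0 <= self.centromere.intergenic_position <= len(self.genes):
                raise ValidationError(
                    f"{self.chrom_id}: centromere position "
                    f"{self.centromere.intergenic_position} outside 0..{len(self.genes)}")


def build_chromosome(
    chrom_id: str,
    genes: Sequence[Gene],
    centromere: CentromereLocus | None = None,
    left_label: str | None = None,
    right_label: str | None = None,
) -> Chromosome:
    """Assemble a chromosome, reindexing genes and recomputing telomeres."""
    chrom = Chromosome(chrom_id, list(genes), centromere)
    chrom.reindex()
    if centromere is not None:
        centromere.chrom_id = chrom_id
    chrom.left_telomere = TelomereEnd(chrom_id, "L", ancestral_label=left_label)
    chrom.right_telomere = TelomereEnd(chrom_id, "R", ancestral_label=right_label)
    chrom.recompute_telomeres()
    return chrom


@dataclass
class Genome:
    species: str
    wgd_status: str = "non-WGD"  # or "post-WGD"
    chromosomes: list[Chromosome] = field(default_factory=list)
    sequences: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.wgd_status not in ("non-WGD", "post-WGD"):
            raise ValidationError(f"unknown wgd_status {self.wgd_status!r}")

    # -- access helpers ----------------------------------------------------
    def chromosome(self, chrom_id: str) -> Chromosome:
        for c in self.chromosomes:
            if c.chrom_id == chrom_id:
                return c
        raise KeyError(chrom_id)

    def iter_genes(self) -> Iterator[Gene]:
        for c in self.chromosomes:
            yield from c.genes

    def pillar_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for g in self.iter_genes():
            if g.pillar_id is not None:
                counts[g.pillar_id] = counts.get(g.pillar_id, 0) + 1
        return counts

    def centromeres(self) -> list[CentromereLocus]:
        return [c.centromere for c in self.chromosomes if c.centromere is not None]

    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    def validate(self, resolved: bool = True) -> None:
        """Check model invariants.

        With ``resolved=True`` (the post-event-resolution state) every
        chromosome must carry exactly one centromere and two telomere ends.
        """
        seen: set[str] = set()
        for c in self.chromosomes:
            c.validate()
            for g in c.genes:
                if g.gene_id in seen:
                    raise ValidationError(f"duplicate gene id {g.gene_id}")
                seen.add(g.gene_id)
            if resolved:
                if c.centromere is None:
                    raise ValidationError(f"{c.chrom_id}: no centromere")
                if c.left_telomere is None or c.right_telomere is None:
                    raise ValidationError(f"{c.chrom_id}: missing telomere end")
        max_copies = 2 if self.wgd_status == "post-WGD" else 1
        for pid, n in self.pillar_counts().items():
            if n > max_copies:
                raise ValidationError(
                    f"pillar {pid} has {n} copies in {self.wgd_status} genome {self.species}")

    def copy(self) -> "Genome":
        chroms = []
        for c in self.chromosomes:
            cc = Chromosome(
                c.chrom_id,
                [replace(g) for g in c.genes],
                replace(c.centromere) if c.centromere else None,
                replace(c.left_telomere) if c.left_telomere else None,
                replace(c.right_telomere) if c.right_telomere else None,
            )
            chroms.append(cc)
        return Genome(self.species, self.wgd_status, chroms,
                      dict(self.sequences) if self.sequences else None)


# ---------------------------------------------------------------------------
# rearrangement events (shared by the simulator and the classifier)
# ---------------------------------------------------------------------------

EVENT_KINDS = (
    "WGD",
    "reciprocal_translocation",
    "inversion",
    "telomeric_translocation",
    "telomere_fusion_cen_loss",
    "centromere_fission",
    "gene_loss",
    "centromere_loss",
)


@dataclass
class RearrangementEvent:
    """A typed rearrangement with its participants and tree branch.

    ``participants`` is a kind-specific mapping of chromosome ids, intergenic
    positions and ancestral end labels.  ``lost_centromere`` names the
    ancestral centromere removed by a fusion/fission/loss event.
    """

    kind: str
    branch: str | None = None
    participants: dict = field(default_factory=dict)
    lost_centromere: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValidationError(f"unknown event kind {self.kind!r}")


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------


@dataclass
class SpeciesTree:
    """A rooted species tree with a marked whole-genome-duplication node.

    Branches are identified by the label of the edge's child node; internal
    nodes without labels are auto-labelled on load.  Leaves below the WGD
    node are the post-WGD species.
    """

    tree: dendropy.Tree
    wgd_node: dendropy.Node | None = None

    @property
    def leaf_names(self) -> list[str]:
        return [l.taxon.label for l in self.tree.leaf_node_iter()]

    @property
    def post_wgd_species(self) -> set[str]:
        if self.wgd_node is None:
            return set()
        return {l.taxon.label for l in self.wgd_node.leaf_iter()}

    @property
    def non_wgd_species(self) -> set[str]:
        return set(self.leaf_names) - self.post_wgd_species

    def node_label(self, node: dendropy.Node) -> str:
        if node.is_leaf():
            return node.taxon.label
        return node.label

    def branch_of(self, node: dendropy.Node) -> str:
        """Identifier of the edge above ``node``."""
        return self.node_label(node)

    def find_node(self, label: str) -> dendropy.Node:
        for node in self.tree.preorder_node_iter():
            if self.node_label(node) == label:
                return node
        raise KeyError(label)

    def path_branches(self, species: str) -> list[str]:
        """Branch identifiers from the root down to a leaf, in order."""
        leaf = self.find_node(species)
        path = []
        node = leaf
        while node.parent_node is not None:
            path.append(self.branch_of(node))
            node = node.parent_node
        return list(reversed(path))

    def mrca(self, species: Iterable[str]) -> dendropy.Node:
        taxa = [self.tree.taxon_namespace.get_taxon(s) for s in species]
        if any(t is None for t in taxa):
            raise KeyError(f"species not in tree: {set(species) - set(self.leaf_names)}")
        if len(taxa) == 1:
            return self.find_node(taxa[0].label)
        return self.tree.mrca(taxa=taxa)

    def leaves_under(self, node: dendropy.Node) -> set[str]:
        return {l.taxon.label for l in node.leaf_iter()}

    def validate_genomes(self, genomes: Iterable[Genome]) -> None:
        """Check that genome WGD statuses match the tree's WGD annotation."""
        genomes = list(genomes)
        if self.wgd_node is None:
            post = [g.species for g in genomes if g.wgd_status == "post-WGD"]
            if post:
                raise ValidationError(
                    f"tree has no WGD-annotated node but post-WGD species present: {post}")
            return
        post_leaves = self.post_wgd_species
        for g in genomes:
            if g.species not in self.leaf_names:
                raise ValidationError(f"species {g.species} not a leaf of the tree")
            expected = "post-WGD" if g.species in post_leaves else "non-WGD"
            if g.wgd_status != expected:
                raise ValidationError(
                    f"{g.species}: wgd_status {g.wgd_status} conflicts with tree ({expected})")


WGD_LABEL = "WGD"


def read_newick(path: str | os.PathLike) -> SpeciesTree:
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             suppress_internal_node_taxa=False,
                             preserve_underscores=True)
    tree.is_rooted = True
    # dendropy may attach internal labels as taxa; normalize to .label
    counter = 0
    wgd_node = None
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            if node.label is None and node.taxon is not None:
                node.label = node.taxon.label
            if node.label is None:
                counter += 1
                node.label = f"N{counter}"
            if node.label == WGD_LABEL:
                wgd_node = node
    return SpeciesTree(tree, wgd_node)


def write_newick(stree: SpeciesTree, path: str | os.PathLike) -> None:
    stree.tree.write(path=str(path), schema="newick",
                     suppress_rooting=True, unquoted_underscores=True)


# ---------------------------------------------------------------------------
# gene-order tables
# ---------------------------------------------------------------------------

_GENE_ORDER_COLUMNS = ["gene_id", "chrom_id", "index", "orientation",
                       "pillar_id", "subtelomeric"]


def write_gene_order(genome: Genome, path: str | os.PathLike) -> None:
    """Write a genome as a tab-separated gene-order table.

    Two comment lines record the species name and WGD status; centromere
    loci are encoded as ``#centromere`` comment lines so that a single file
    round-trips the full gene-space model.
    """
    with open(path, "w") as fh:
        fh.write(f"#species\t{genome.species}\n")
        fh.write(f"#wgd_status\t{genome.wgd_status}\n")
        for c in genome.chromosomes:
            if c.centromere is not None:
                cen = c.centromere
                fh.write("#centromere\t{}\t{}\t{}\t{}\t{}\t{}\t{}\n".format(
                    c.chrom_id, cen.intergenic_position, cen.strand,
                    cen.cde1_seq or ABSENT, cen.cde2_seq or ABSENT,
                    cen.cde3_seq or ABSENT, cen.ancestral_label or ABSENT))
            for side, end in (("L", c.left_telomere), ("R", c.right_telomere)):
                if end is not None and end.ancestral_label:
                    fh.write(f"#telomere\t{c.chrom_id}\t{side}\t{end.ancestral_label}\n")
        fh.write("\t".join(_GENE_ORDER_COLUMNS) + "\n")
        for c in genome.chromosomes:
            for g in c.genes:
                fh.write("\t".join([
                    g.gene_id, g.chrom_id, str(g.index), g.orientation,
                    g.pillar_id if g.pillar_id is not None else ABSENT,
                    "1" if g.subtelomeric else "0",
                ]) + "\n")


def read_gene_order(path: str | os.PathLike, ancestral: Genome | None = None) -> Genome:
    """Read a gene-order table back into a :class:`Genome`.

    Chromosomes are assembled in index order and telomere boundary genes
    recomputed.  When an ancestral genome is supplied, chromosome
    orientations are normalized against it (see
    :func:`normalize_orientations`).
    """
    species = "unknown"
    wgd_status = "non-WGD"
    cen_rows: list[list[str]] = []
    telo_rows: list[list[str]] = []
    genes_by_chrom: dict[str, dict[int, Gene]] = {}
    chrom_order: list[str] = []
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split("\t")
                if parts[0] == "species":
                    species = parts[1]
                elif parts[0] == "wgd_status":
                    wgd_status = parts[1]
                elif parts[0] == "centromere":
                    cen_rows.append(parts[1:])
                elif parts[0] == "telomere":
                    telo_rows.append(parts[1:])
                continue
            fields = line.split("\t")
            if not header_seen:
                if fields != _GENE_ORDER_COLUMNS:
                    raise MalformedInputError(
                        f"{path}: line {lineno}: expected header "
                        f"{_GENE_ORDER_COLUMNS}, got {fields}")
                header_seen = True
                continue
            if len(fields) != len(_GENE_ORDER_COLUMNS):
                raise MalformedInputError(f"{path}: line {lineno}: wrong column count")
            gene_id, chrom_id, idx_s, orient, pillar, subtel = fields
            try:
                idx = int(idx_s)
            except ValueError:
                raise MalformedInputError(
                    f"{path}: line {lineno}: bad index {idx_s!r}") from None
            if orient not in ORIENTATIONS:
                raise MalformedInputError(
                    f"{path}: line {lineno}: unknown orientation symbol {orient!r}")
            bucket = genes_by_chrom.setdefault(chrom_id, {})
            if chrom_id not in chrom_order:
                chrom_order.append(chrom_id)
            if idx in bucket:
                raise MalformedInputError(
                    f"{path}: line {lineno}: duplicate index {idx} on {chrom_id} "
                    f"(gene {gene_id!r})")
            bucket[idx] = Gene(
                gene_id, chrom_id, idx, orient,
                None if pillar == ABSENT else pillar,
                subtel == "1")
    if not header_seen:
        raise MalformedInputError(f"{path}: missing header line")
    chroms = []
    for chrom_id in chrom_order:
        bucket = genes_by_chrom[chrom_id]
        n = len(bucket)
        if sorted(bucket) != list(range(n)):
            missing = sorted(set(range(n)) - set(bucket))
            raise MalformedInputError(
                f"{path}: chromosome {chrom_id} has gapped indices (missing {missing})")
        chroms.append(build_chromosome(chrom_id, [bucket[i] for i in range(n)]))
    genome = Genome(species, wgd_status, chroms)
    for row in cen_rows:
        chrom_id, pos, strand, cde1, cde2, cde3, label = row
        genome.chromosome(chrom_id).centromere = CentromereLocus(
            chrom_id, int(pos), strand,
            None if cde1 == ABSENT else cde1,
            None if cde2 == ABSENT else cde2,
            None if cde3 == ABSENT else cde3,
            None if label == ABSENT else label)
    for row in telo_rows:
        chrom_id, side, label = row
        chrom = genome.chromosome(chrom_id)
        end = chrom.left_telomere if side == "L" else chrom.right_telomere
        end.ancestral_label = label
    if ancestral is not None:
        genome = normalize_orientations(genome, ancestral)
    return genome


def normalize_orientations(genome: Genome, ancestral: Genome) -> Genome:
    """Flip chromosomes so ancestral coordinates run left to right.

    A chromosome mapping entirely to a single ancestral chromosome is
    stored with the lower ancestral pillar positions leftward; chromosomes
    spanning several ancestral chromosomes keep their stored orientation.
    This gives Table-style L/R bookkeeping a deterministic convention.
    """
    anc_pos: dict[str, tuple[str, int]] = {}
    for c in ancestral.chromosomes:
        for g in c.genes:
            if g.pillar_id is not None:
                anc_pos[g.pillar_id] = (c.chrom_id, g.index)
    out = genome.copy()
    for c in out.chromosomes:
        hits = [anc_pos[g.pillar_id] for g in c.genes
                if g.pillar_id is not None and g.pillar_id in anc_pos]
        if not hits:
            continue
        anc_chroms = {h[0] for h in hits}
        if len(anc_chroms) != 1:
            continue
        idxs = [h[1] for h in hits]
        # direction by endpoint comparison; ties keep stored orientation
        if idxs[0] > idxs[-1]:
            reverse_chromosome_in_place(c)
    return out


def reverse_chromosome_in_place(chrom: Chromosome) -> None:
    n = len(chrom.genes)
    chrom.genes = [g.flipped() for g in reversed(chrom.genes)]
    chrom.reindex()
    if chrom.centromere is not None:
        chrom.centromere = replace(
            chrom.centromere.flipped_strand(),
            intergenic_position=n - chrom.centromere.intergenic_position)
    left_label = chrom.left_telomere.ancestral_label if chrom.left_telomere else None
    right_label = chrom.right_telomere.ancestral_label if chrom.right_telomere else None
    chrom.left_telomere = TelomereEnd(chrom.chrom_id, "L", ancestral_label=right_label)
    chrom.right_telomere = TelomereEnd(chrom.chrom_id, "R", ancestral_label=left_label)
    chrom.recompute_telomeres()


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read FASTA sequences, uppercasing bases."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# centromere annotation tables (BED-like)
# ---------------------------------------------------------------------------

_CEN_COLUMNS = ["chrom_id", "intergenic_position", "strand",
                "cde1_seq", "cde2_seq", "cde3_seq", "ancestral_label"]


def write_centromere_annotations(loci: Iterable[CentromereLocus],
                                 path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_CEN_COLUMNS) + "\n")
        for cen in loci:
            fh.write("\t".join([
                cen.chrom_id, str(cen.intergenic_position), cen.strand,
                cen.cde1_seq or ABSENT, cen.cde2_seq or ABSENT,
                cen.cde3_seq or ABSENT, cen.ancestral_label or ABSENT]) + "\n")


def read_centromere_annotations(path: str | os.PathLike) -> list[CentromereLocus]:
    loci = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _CEN_COLUMNS:
            raise MalformedInputError(f"{path}: bad centromere table header {header}")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != len(_CEN_COLUMNS):
                raise MalformedInputError(f"{path}: line {lineno}: wrong column count")
            loci.append(CentromereLocus(
                f[0], int(f[1]), f[2],
                None if f[3] == ABSENT else f[3],
                None if f[4] == ABSENT else f[4],
                None if f[5] == ABSENT else f[5],
                None if f[6] == ABSENT else f[6]))
    return loci


# ---------------------------------------------------------------------------
# event logs
# ---------------------------------------------------------------------------


def write_event_log(events: Sequence[RearrangementEvent],
                    path: str | os.PathLike | io.TextIOBase) -> None:
    """Serialize events as a structured-text (YAML) log."""
    payload = [
        {
            "kind": e.kind,
            "branch": e.branch,
            "participants": e.participants,
            "lost_centromere": e.lost_centromere,
        }
        for e in events
    ]
    if isinstance(path, io.TextIOBase):
        yaml.safe_dump(payload, path, sort_keys=False)
    else:
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def read_event_log(path: str | os.PathLike) -> list[RearrangementEvent]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if payload is None:
        return []
    events = []
    for i, item in enumerate(payload):
        try:
            events.append(RearrangementEvent(
                kind=item["kind"], branch=item.get("branch"),
                participants=item.get("participants") or {},
                lost_centromere=item.get("lost_centromere")))
        except (KeyError, TypeError) as exc:
            raise MalformedInputError(f"{path}: event #{i}: {exc}") from None
    return events
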