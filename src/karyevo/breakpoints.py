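"""Synteny blocks, breakpoint edges, and reuse-cycle tracing.

An extant genome is decomposed into synteny blocks against the ancestral
gene order: maximal runs of genes whose pillars are consecutive in the
ancestor (up to orientation), tolerating small gaps from gene loss and
recording single-gene strand flips as within-block inversions (which never
count as rearrangements).  Each inter-block junction — and each chromosome
end whose terminal block stops short of an ancestral chromosome end — is a
*breakpoint edge* carrying "dangling" ancestral neighbours: the pillar that
ancestrally followed the left-hand gene and the one that preceded the
right-hand gene.

Cycle tracing walks these dangling links: from one edge of a breakpoint
(A|B) to the reciprocal edge where B now sits (B'|C), then to C's partner
(C'|D), and so on until the walk returns to the original breakpoint.  A
clean reciprocal translocation closes after two edges; chained breakpoint
reuse closes after more.  A closed cycle of k edges is counted as k-1
events (1 for the two-edge case); cycles that close through telomeres
(telomeric translocations, fusions, fissions) count as max(k-1, 1).  The
per-cycle count is a documented heuristic, exact on chained-reciprocal and
telomeric cycle classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome import Genome

#: sentinel dangling neighbour: the adjacency runs off an ancestral
#: chromosome end.
TELOMERE = "<telomere>"


# ---------------------------------------------------------------------------
# ancestral index
# ---------------------------------------------------------------------------


class AncestralIndex:
    """Rank positions of pillars along ancestral chromosomes."""

    def __init__(self, ancestral: Genome) -> None:
        self.rank: dict[str, tuple[str, int]] = {}
        self.orient: dict[str, str] = {}
        self.order: dict[str, list[str]] = {}
        self.cen_flank_ranks: dict[str, tuple[int, int] | None] = {}
        for chrom in ancestral.chromosomes:
            pillars = [g for g in chrom.genes if g.pillar_id is not None]
            self.order[chrom.chrom_id] = [g.pillar_id for g in pillars]
            for r, g in enumerate(pillars):
                self.rank[g.pillar_id] = (chrom.chrom_id, r)
                self.orient[g.pillar_id] = g.orientation
            cen = chrom.centromere
            flank = None
            if cen is not None:
                left = [r for r, g in enumerate(pillars) if g.index < cen.intergenic_position]
                right = [r for r, g in enumerate(pillars) if g.index >= cen.intergenic_position]
                if left and right:
                    flank = (left[-1], right[0])
            self.cen_flank_ranks[chrom.chrom_id] = flank

    def neighbour(self, pillar: str, step: int) -> str:
        """Pillar ``step`` ranks away on the same ancestral chromosome, or
        :data:`TELOMERE` when the step runs off the end."""
        chrom, r = self.rank[pillar]
        j = r + step
        order = self.order[chrom]
        if 0 <= j < len(order):
            return order[j]
        return TELOMERE

    def is_centromeric_adjacency(self, a: str, b: str) -> bool:
        """True when the ancestral centromere sits between pillars a and b."""
        if a == TELOMERE or b == TELOMERE:
            return False
        ca, ra = self.rank[a]
        cb, rb = self.rank[b]
        if ca != cb:
            return False
        flank = self.cen_flank_ranks.get(ca)
        return flank is not None and {ra, rb} == set(flank)


# ---------------------------------------------------------------------------
# synteny blocks
# ---------------------------------------------------------------------------


@dataclass
class SyntenyBlock:
    extant_chrom: str
    gene_ids: list[str]
    extant_interval: tuple[int, int]  # gene indices, inclusive
    anc_chrom: str
    anc_interval: tuple[int, int]  # pillar ranks, low..high inclusive
    direction: int  # +1 same, -1 inverted
    within_block_inversions: list[str] = field(default_factory=list)

    @property
    def orientation(self) -> str:
        return "same" if self.direction > 0 else "inverted"

    def __len__(self) -> int:
        return len(self.gene_ids)


def find_synteny_blocks(
    extant: Genome, ancestral: Genome,
    min_block_len: int = 2, max_gap: int = 1,
    index: AncestralIndex | None = None,
) -> list[SyntenyBlock]:
    """Maximal ancestrally consecutive runs per extant chromosome.

    Runs extend while the next gene's pillar continues on the same ancestral
    chromosome in the same direction with at most ``max_gap`` missing
    pillars.  A gene whose strand disagrees with the block direction but
    whose rank continues the run is kept and recorded as a within-block
    inversion.  Blocks shorter than ``min_block_len`` can only arise from
    real breakpoint clustering and are returned like any other block.
    """
    idx = index or AncestralIndex(ancestral)
    extant_pos: dict[str, list[tuple[str, int]]] = {}
    for g in extant.iter_genes():
        if g.pillar_id is not None:
            extant_pos.setdefault(g.pillar_id, []).append((g.chrom_id, g.index))

    def gap_is_real(prev_item, item) -> bool:
        """A rank gap only counts as gene loss if none of the skipped
        pillars sits nearby on the same extant chromosome (otherwise the
        'gap' is really a local rearrangement boundary)."""
        anc_chrom = prev_item[1]
        lo, hi = sorted((prev_item[2], item[2]))
        order = idx.order[anc_chrom]
        window = max_gap + 3
        for r in range(lo + 1, hi):
            for chrom_id, pos in extant_pos.get(order[r], []):
                if chrom_id == prev_item[0].chrom_id and \
                        abs(pos - prev_item[0].index) <= window:
                    return False
        return True

    blocks: list[SyntenyBlock] = []
    for chrom in extant.chromosomes:
        items = []
        for g in chrom.genes:
            if g.pillar_id is None or g.pillar_id not in idx.rank:
                continue
            anc_chrom, rank = idx.rank[g.pillar_id]
            rel = 1 if g.orientation == idx.orient[g.pillar_id] else -1
            items.append((g, anc_chrom, rank, rel))
        if not items:
            continue
        run = [items[0]]
        direction = 0
        for item in items[1:]:
            prev = run[-1]
            step = item[2] - prev[2]
            same_chrom = item[1] == prev[1]
            ok = same_chrom and 1 <= abs(step) <= max_gap + 1 and (
                direction == 0 or (step > 0) == (direction > 0))
            if ok and abs(step) > 1 and not gap_is_real(prev, item):
                ok = False
            if ok:
                if direction == 0:
                    direction = 1 if step > 0 else -1
                run.append(item)
            else:
                blocks.append(_close_run(chrom.chrom_id, run, direction))
                run = [item]
                direction = 0
        blocks.append(_close_run(chrom.chrom_id, run, direction))
    return blocks


def _close_run(chrom_id: str, run: list, direction: int) -> SyntenyBlock:
    if direction == 0:  # singleton: direction from the gene's own strand
        direction = run[0][3]
    ranks = [item[2] for item in run]
    wbi = [item[0].gene_id for item in run if item[3] != direction]
    return SyntenyBlock(
        extant_chrom=chrom_id,
        gene_ids=[item[0].gene_id for item in run],
        extant_interval=(run[0][0].index, run[-1][0].index),
        anc_chrom=run[0][1],
        anc_interval=(min(ranks), max(ranks)),
        direction=direction,
        within_block_inversions=wbi,
    )


# ---------------------------------------------------------------------------
# breakpoint edges
# ---------------------------------------------------------------------------


@dataclass
class EdgeSide:
    gene_id: str
    pillar: str
    dangle: str  # pillar id or TELOMERE
    position: int  # extant gene index


@dataclass
class BreakpointEdge:
    """A novel extant adjacency absent from the ancestral gene order.

    ``left``/``right`` are the junction genes with their dangling ancestral
    neighbours; chromosome-end edges have one physical side only (the other
    is an extant telomere).
    """

    chrom_id: str
    left: EdgeSide | None
    right: EdgeSide | None

    @property
    def key(self) -> tuple:
        pos = self.left.position if self.left else self.right.position
        return (self.chrom_id, pos)

    def sides(self):
        for side in (self.left, self.right):
            if side is not None:
                yield side


def extract_edges(
    blocks: list[SyntenyBlock], extant: Genome, ancestral: Genome,
    index: AncestralIndex | None = None,
) -> list[BreakpointEdge]:
    """One edge per inter-block junction plus chromosome-end junctions
    where the terminal block stops short of an ancestral chromosome end."""
    idx = index or AncestralIndex(ancestral)
    by_chrom: dict[str, list[SyntenyBlock]] = {}
    for b in blocks:
        by_chrom.setdefault(b.extant_chrom, []).append(b)
    gene_lookup = {g.gene_id: g for g in extant.iter_genes()}
    edges: list[BreakpointEdge] = []
    for chrom_id, chrom_blocks in by_chrom.items():
        chrom_blocks.sort(key=lambda b: b.extant_interval[0])
        for left_block, right_block in zip(chrom_blocks, chrom_blocks[1:]):
            lg = gene_lookup[left_block.gene_ids[-1]]
            rg = gene_lookup[right_block.gene_ids[0]]
            edges.append(BreakpointEdge(
                chrom_id,
                EdgeSide(lg.gene_id, lg.pillar_id,
                         idx.neighbour(lg.pillar_id, left_block.direction),
                         lg.index),
                EdgeSide(rg.gene_id, rg.pillar_id,
                         idx.neighbour(rg.pillar_id, -right_block.direction),
                         rg.index)))
        first, last = chrom_blocks[0], chrom_blocks[-1]
        fg = gene_lookup[first.gene_ids[0]]
        before = idx.neighbour(fg.pillar_id, -first.direction)
        if before != TELOMERE:
            edges.append(BreakpointEdge(
                chrom_id, None,
                EdgeSide(fg.gene_id, fg.pillar_id, before, fg.index)))
        lg = gene_lookup[last.gene_ids[-1]]
        after = idx.neighbour(lg.pillar_id, last.direction)
        if after != TELOMERE:
            edges.append(BreakpointEdge(
                chrom_id,
                EdgeSide(lg.gene_id, lg.pillar_id, after, lg.index),
                None))
    edges.sort(key=lambda e: e.key)
    return edges


# ---------------------------------------------------------------------------
# cycle tracing
# ---------------------------------------------------------------------------


@dataclass
class Cycle:
    """A connected set of breakpoint edges linked by reciprocal dangles."""

    edges: list[BreakpointEdge]
    event_count: int
    closed: bool  # all endpoints resolved (possibly through telomeres)
    telomeric: bool  # closure involves an ancestral or extant telomere
    centromeric_loci: list[str]  # ancestral chroms whose centromeric intergenic is cut
    gap_bridged: bool = False  # pairing needed a gene-loss gap bridge
    ambiguities: list[str] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


class _Pairing:
    """Reciprocal matching of edge endpoints across the genome."""

    def __init__(self, edges: list[BreakpointEdge], idx: AncestralIndex,
                 max_gap: int = 1) -> None:
        self.edges = edges
        self.idx = idx
        self.max_gap = max_gap
        self.endpoints: list[tuple[int, str]] = []  # (edge index, 'L'/'R')
        self.by_pd: dict[tuple[str, str], list[tuple[int, str]]] = {}
        for i, edge in enumerate(edges):
            for name, side in (("L", edge.left), ("R", edge.right)):
                if side is None:
                    continue
                self.endpoints.append((i, name))
                self.by_pd.setdefault((side.pillar, side.dangle), []).append((i, name))
        self.partner: dict[tuple[int, str], tuple[int, str] | None] = {}
        self.flags: dict[tuple[int, str], str] = {}
        self.ambiguous: set[tuple[int, str]] = set()
        self._pair_all()

    def _side(self, ep: tuple[int, str]) -> EdgeSide:
        edge = self.edges[ep[0]]
        return edge.left if ep[1] == "L" else edge.right

    def _pair_all(self) -> None:
        for ep in self.endpoints:
            if ep in self.partner:
                continue
            side = self._side(ep)
            if side.dangle == TELOMERE:
                self.partner[ep] = None
                self.flags[ep] = "telomere"
                continue
            mates = [m for m in self.by_pd.get((side.dangle, side.pillar), [])
                     if m != ep and m not in self.partner]
            if not mates:
                mates = self._widened(ep)
                if mates:
                    self.flags[ep] = "gap_bridged"
            if not mates:
                self.partner[ep] = None
                self.flags[ep] = "open"
                continue
            if len(mates) > 1:
                self.ambiguous.add(ep)
                mates.sort(key=lambda m: self.edges[m[0]].key)
            mate = mates[0]
            self.partner[ep] = mate
            self.partner[mate] = ep
            if self.flags.get(ep) == "gap_bridged":
                self.flags[mate] = "gap_bridged"

    def _widened(self, ep: tuple[int, str]) -> list[tuple[int, str]]:
        """Search within ``max_gap`` ancestral ranks of the expected
        reciprocal, to bridge gene losses at junctions."""
        side = self._side(ep)
        found = []
        for (pillar, dangle), eps in self.by_pd.items():
            if pillar == TELOMERE or dangle == TELOMERE:
                continue
            if self._near(pillar, side.dangle) and self._near(dangle, side.pillar):
                found.extend(m for m in eps if m != ep and m not in self.partner)
        return found

    def _near(self, a: str, b: str) -> bool:
        ca, ra = self.idx.rank[a]
        cb, rb = self.idx.rank[b]
        return ca == cb and abs(ra - rb) <= self.max_gap


def _components(pairing: _Pairing) -> list[list[int]]:
    n = len(pairing.edges)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for ep, mate in pairing.partner.items():
        if mate is not None:
            a, b = find(ep[0]), find(mate[0])
            if a != b:
                parent[a] = b
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    return [sorted(v) for v in sorted(comps.values(), key=lambda v: v[0])]


def _build_cycle(edge_idx: list[int], pairing: _Pairing) -> Cycle:
    edges = [pairing.edges[i] for i in edge_idx]
    flags = [pairing.flags.get((i, s)) for i in edge_idx for s in ("L", "R")
             if (i, s) in pairing.flags]
    open_chain = "open" in flags
    telomeric = "telomere" in flags or any(
        e.left is None or e.right is None for e in edges)
    gap = "gap_bridged" in flags
    cen_loci = []
    seen_adj = set()
    for i in edge_idx:
        for side in pairing.edges[i].sides():
            if side.dangle == TELOMERE:
                continue
            adj = frozenset((side.pillar, side.dangle))
            if adj in seen_adj:
                continue
            seen_adj.add(adj)
            if pairing.idx.is_centromeric_adjacency(side.pillar, side.dangle):
                cen_loci.append(pairing.idx.rank[side.pillar][0])
    k = len(edges)
    if open_chain:
        count = k  # lower bound
    else:
        count = max(k - 1, 1)
    ambiguities = sorted({pairing.edges[i].key[0] for i, s in pairing.ambiguous
                          if i in edge_idx} if pairing.ambiguous else set())
    return Cycle(edges, count, not open_chain, telomeric,
                 sorted(set(cen_loci)), gap, list(ambiguities))


def all_cycles(
    extant: Genome, ancestral: Genome,
    min_block_len: int = 2, max_gap: int = 1,
) -> list[Cycle]:
    """Partition every breakpoint edge into reciprocal-link cycles/chains."""
    idx = AncestralIndex(ancestral)
    blocks = find_synteny_blocks(extant, ancestral, min_block_len, max_gap, idx)
    edges = extract_edges(blocks, extant, ancestral, idx)
    pairing = _Pairing(edges, idx, max_gap)
    return [_build_cycle(comp, pairing) for comp in _components(pairing)]


def trace_cycle(
    start: BreakpointEdge, edges: list[BreakpointEdge],
    ancestral: Genome, max_gap: int = 1,
) -> Cycle:
    """The cycle containing ``start``, walking reciprocal dangling links.

    Start-point invariant: any edge of a cycle yields the same edge set and
    event count.
    """
    idx = AncestralIndex(ancestral)
    pairing = _Pairing(edges, idx, max_gap)
    try:
        start_idx = next(i for i, e in enumerate(edges) if e is start
                         or e.key == start.key)
    except StopIteration:
        raise ValueError("start edge not among extracted edges") from None
    for comp in _components(pairing):
        if start_idx in comp:
            return _build_cycle(comp, pairing)
    raise AssertionError("unreachable")


def count_rearrangements(
    extant: Genome, ancestral: Genome,
    min_block_len: int = 2, max_gap: int = 1,
) -> tuple[int, list[Cycle]]:
    """Total rearrangements between an extant genome and the ancestor.

    Sum of per-cycle event counts; within-block single-gene inversions are
    excluded by construction.  Open chains (unresolvable dangles) contribute
    their edge count as a flagged lower bound.
    """
    cycles = all_cycles(extant, ancestral, min_block_len, max_gap)
    return sum(c.event_count for c in cycles), cycles
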