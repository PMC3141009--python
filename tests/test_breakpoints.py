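"""Synteny blocks, breakpoint edges, cycle tracing, rearrangement counts."""

from collections import deque

import numpy as np
import pytest

from karyevo import (
    RearrangementEvent,
    SimConfig,
    apply_event,
    count_rearrangements,
    extract_edges,
    find_synteny_blocks,
    make_ancestor,
    make_reuse_fixture,
    random_history,
    trace_cycle,
)
from karyevo.breakpoints import AncestralIndex


class TestSyntenyBlocks:
    def test_unrearranged_chromosome_is_one_same_block(self, ancestor):
        blocks = [b for b in find_synteny_blocks(ancestor, ancestor)
                  if b.extant_chrom == "Anc1"]
        assert len(blocks) == 1
        assert blocks[0].orientation == "same"
        assert len(blocks[0]) == 42  # 50 genes minus 2x4 subtelomeric

    def test_one_inversion_gives_three_blocks_middle_inverted(self, ancestor):
        ev = RearrangementEvent("inversion",
                                participants={"chrom": "Anc1", "start": 10,
                                              "end": 16})
        g = apply_event(ancestor, ev)
        blocks = [b for b in find_synteny_blocks(g, ancestor)
                  if b.extant_chrom == "Anc1"]
        assert [b.orientation for b in blocks] == ["same", "inverted", "same"]
        assert len(blocks[1]) == 6

    def test_blocks_match_quadratic_oracle(self):
        """Greedy block boundaries equal an independent quadratic-time
        longest-run search on 50 random simulated genomes."""
        for seed in range(50):
            anc, _ = make_ancestor(SimConfig(seed=300 + seed))
            kinds = (["reciprocal_translocation"] * (1 + seed % 3)
                     + ["inversion"] * (seed % 2))
            g, _ = random_history(anc, kinds, seed=seed)
            got = [(b.extant_chrom, b.extant_interval, b.direction)
                   for b in find_synteny_blocks(g, anc)]
            assert got == _oracle_blocks(g, anc)

    def test_single_gene_flip_stays_within_block(self, ancestor):
        g = ancestor.copy()
        gene = g.chromosome("Anc1").genes[15]
        gene.orientation = "+" if gene.orientation == "-" else "-"
        blocks = [b for b in find_synteny_blocks(g, ancestor)
                  if b.extant_chrom == "Anc1"]
        assert len(blocks) == 1
        assert blocks[0].within_block_inversions == [gene.gene_id]
        assert count_rearrangements(g, ancestor)[0] == 0


def _oracle_blocks(extant, ancestral):
    """Brute-force: for each start gene, extend the longest valid run."""
    rank, orient = {}, {}
    for chrom in ancestral.chromosomes:
        pillars = [g for g in chrom.genes if g.pillar_id is not None]
        for r, g in enumerate(pillars):
            rank[g.pillar_id] = (chrom.chrom_id, r)
            orient[g.pillar_id] = g.orientation
    pos = {}
    for g in extant.iter_genes():
        if g.pillar_id is not None:
            pos.setdefault(g.pillar_id, []).append((g.chrom_id, g.index))
    out = []
    for chrom in extant.chromosomes:
        items = [g for g in chrom.genes if g.pillar_id in rank]
        i = 0
        while i < len(items):
            j, direction = i, 0
            while j + 1 < len(items):
                a, b = items[j], items[j + 1]
                ca, ra = rank[a.pillar_id]
                cb, rb = rank[b.pillar_id]
                step = rb - ra
                if ca != cb or not 1 <= abs(step) <= 2:
                    break
                if direction and (step > 0) != (direction > 0):
                    break
                if abs(step) > 1:
                    # the gap must be real gene loss, not a nearby boundary
                    lo, hi = sorted((ra, rb))
                    order = [p for p, (c, _) in rank.items() if c == ca]
                    order.sort(key=lambda p: rank[p][1])
                    bad = False
                    for r in range(lo + 1, hi):
                        for c2, i2 in pos.get(order[r], []):
                            if c2 == chrom.chrom_id and abs(i2 - a.index) <= 4:
                                bad = True
                    if bad:
                        break
                direction = direction or (1 if step > 0 else -1)
                j += 1
            if direction == 0:
                g0 = items[i]
                direction = 1 if g0.orientation == orient[g0.pillar_id] else -1
            out.append((chrom.chrom_id,
                        (items[i].index, items[j].index), direction))
            i = j + 1
    return out


class TestEdgesAndCycles:
    def test_unrearranged_genome_has_no_edges(self, ancestor):
        blocks = find_synteny_blocks(ancestor, ancestor)
        assert extract_edges(blocks, ancestor, ancestor) == []
        assert count_rearrangements(ancestor, ancestor)[0] == 0

    def test_single_translocation_two_reciprocal_edges_one_event(self, ancestor):
        ev = RearrangementEvent("reciprocal_translocation", participants={
            "chrom_a": "Anc1", "pos_a": 12, "chrom_b": "Anc2", "pos_b": 15})
        g = apply_event(ancestor, ev)
        blocks = find_synteny_blocks(g, ancestor)
        edges = extract_edges(blocks, g, ancestor)
        assert len(edges) == 2
        cycle = trace_cycle(edges[0], edges, ancestor)
        assert cycle.n_edges == 2 and cycle.event_count == 1 and cycle.closed

    def test_telomere_fusion_single_internal_edge(self, ancestor):
        ev = RearrangementEvent(
            "telomere_fusion_cen_loss", lost_centromere="CEN2",
            participants={"chrom_a": "Anc1", "end_a": "R",
                          "chrom_b": "Anc2", "end_b": "L"})
        g = apply_event(ancestor, ev)
        n, cycles = count_rearrangements(g, ancestor)
        assert n == 1
        assert len(cycles) == 1
        assert cycles[0].n_edges == 1 and cycles[0].telomeric

    def test_cycle_partition_each_edge_in_exactly_one_cycle(self, ancestor):
        kinds = ["reciprocal_translocation"] * 5 + ["inversion"] * 3
        g, _ = random_history(ancestor, kinds, seed=21)
        blocks = find_synteny_blocks(g, ancestor)
        edges = extract_edges(blocks, g, ancestor)
        _, cycles = count_rearrangements(g, ancestor)
        seen = [e.key for c in cycles for e in c.edges]
        assert sorted(seen) == sorted(e.key for e in edges)
        assert len(seen) == len(set(seen))

    def test_trace_is_start_point_invariant(self, ancestor):
        _, genome, _ = make_reuse_fixture("klactis_cycle", seed=5)
        anc, genome, _ = make_reuse_fixture("klactis_cycle", seed=5)
        blocks = find_synteny_blocks(genome, anc)
        edges = extract_edges(blocks, genome, anc)
        results = {
            (c.event_count, tuple(sorted(e.key for e in c.edges)))
            for c in (trace_cycle(e, edges, anc) for e in edges)}
        assert len(results) == 1

    def test_gene_loss_at_junction_is_bridged(self, ancestor):
        ev = RearrangementEvent("reciprocal_translocation", participants={
            "chrom_a": "Anc1", "pos_a": 15, "chrom_b": "Anc2", "pos_b": 12})
        g = apply_event(ancestor, ev)
        gid = g.chromosome("Anc1").genes[14].gene_id
        g.wgd_status = "post-WGD"  # permit a missing pillar copy
        g2 = apply_event(g, RearrangementEvent("gene_loss",
                                               participants={"gene_id": gid}))
        n, cycles = count_rearrangements(g2, ancestor)
        assert n == 1
        assert cycles[0].closed and cycles[0].gap_bridged


class TestCounts:
    def test_monotone_in_added_translocations(self, ancestor):
        for k in range(1, 6):
            g, _ = random_history(ancestor,
                                  ["reciprocal_translocation"] * k, seed=7)
            assert count_rearrangements(g, ancestor)[0] == k

    def test_random_no_reuse_schedules_counted_exactly(self, ancestor):
        """100 random mixed schedules recover the scheduled event count."""
        rng = np.random.default_rng(99)
        for trial in range(100):
            k = int(rng.integers(1, 16))
            kinds = ["reciprocal_translocation" if rng.random() < 0.6
                     else "inversion" for _ in range(k)]
            g, _ = random_history(ancestor, kinds, seed=1000 + trial)
            n, cycles = count_rearrangements(g, ancestor)
            assert n == k
            assert all(c.closed for c in cycles)

    def test_small_instances_match_exhaustive_minimal_scripts(self):
        """Counts equal brute-force minimal translocation scripts (<=3 events)
        on tiny genomes."""
        cfg = SimConfig(seed=2, n_ancestral_chromosomes=3,
                        genes_per_chromosome=9, subtelomeric_zone=1)
        anc, _ = make_ancestor(cfg)
        rng = np.random.default_rng(5)
        for k in (1, 2, 3):
            genome = _apply_k_translocations(anc, k, rng)
            if genome is None:
                continue
            n, _ = count_rearrangements(genome, anc)
            assert n == _bfs_min_translocations(anc, genome, max_depth=3)


def _chrom_signature(chrom):
    fwd = tuple((g.pillar_id, g.orientation) for g in chrom.genes)
    rev = tuple((p, "+" if o == "-" else "-") for p, o in reversed(fwd))
    return min(fwd, rev)


def _genome_signature(genome):
    return frozenset(_chrom_signature(c) for c in genome.chromosomes)


def _all_translocations(genome):
    ids = [c.chrom_id for c in genome.chromosomes]
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            na = len(genome.chromosome(a).genes)
            nb = len(genome.chromosome(b).genes)
            for pa in range(1, na):
                for pb in range(1, nb):
                    yield RearrangementEvent(
                        "reciprocal_translocation",
                        participants={"chrom_a": a, "pos_a": pa,
                                      "chrom_b": b, "pos_b": pb})


def _apply_k_translocations(anc, k, rng, tries=50):
    from karyevo import RejectedEventError
    for _ in range(tries):
        g = anc.copy()
        used = set()
        ok = True
        for _ in range(k):
            for _ in range(100):
                ev = None
                candidates = list(_all_translocations(g))
                ev = candidates[int(rng.integers(len(candidates)))]
                key = (ev.participants["chrom_a"], ev.participants["pos_a"],
                       ev.participants["chrom_b"], ev.participants["pos_b"])
                # keep breakpoints 2+ genes apart for clean blocks
                if any(key[0] == u[0] and abs(key[1] - u[1]) < 3 for u in used) or \
                   any(key[2] == u[2] and abs(key[3] - u[3]) < 3 for u in used):
                    continue
                try:
                    g = apply_event(g, ev)
                    used.add(key)
                    break
                except RejectedEventError:
                    continue
            else:
                ok = False
                break
        if ok and _genome_signature(g) != _genome_signature(anc):
            return g
    return None


def _bfs_min_translocations(anc, target, max_depth=3):
    from karyevo import RejectedEventError
    target_sig = _genome_signature(target)
    start_sig = _genome_signature(anc)
    if start_sig == target_sig:
        return 0
    frontier = deque([(anc, 0)])
    seen = {start_sig}
    while frontier:
        genome, depth = frontier.popleft()
        if depth >= max_depth:
            continue
        for ev in _all_translocations(genome):
            try:
                nxt = apply_event(genome, ev)
            except RejectedEventError:
                continue
            sig = _genome_signature(nxt)
            if sig == target_sig:
                return depth + 1
            if sig not in seen and depth + 1 < max_depth:
                seen.add(sig)
                frontier.append((nxt, depth + 1))
    raise AssertionError(f"target not reachable within {max_depth} events")


class TestReuseCycles:
    def test_klactis_cycle_is_one_four_event_cycle(self):
        anc, genome, _ = make_reuse_fixture("klactis_cycle", seed=5)
        n, cycles = count_rearrangements(genome, anc)
        assert n == 4
        assert len(cycles) == 1
        assert cycles[0].n_edges == 5
        assert len(cycles[0].centromeric_loci) == 3

    def test_cen9_pathway_resolves_nine_events(self):
        anc, genome, _ = make_reuse_fixture("cen9_pathway", seed=5)
        n, cycles = count_rearrangements(genome, anc)
        assert n == 9
        assert len(cycles) == 1 and cycles[0].n_edges == 10
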