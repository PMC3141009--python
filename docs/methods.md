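# Methods

This note records the models, conventions and design choices behind
`karyevo`, in the order the pipeline runs them.

## Coordinates and core objects

Gene orders use 0-based indices per chromosome; intergenic loci are
integers `0..n` meaning "before gene i"; DNA intervals are 0-based
half-open. A genome is an ordered set of chromosomes, each with an ordered
gene list, at most one point centromere (an intergenic position plus
optional CDEI/CDEII/CDEIII sequences and strand) and two telomere ends.
Genes carry a *pillar* id — the ortholog/paralog column linking them to a
position in the ancestral gene order — or an explicit `ABSENT` sentinel
(never an empty field, so "no ortholog" is distinguishable from a parse
failure). Telomeres are locations, not sequences: the boundary gene of an
end is the outermost gene with a pillar, and everything beyond it is
subtelomeric. The subtelomeric flag travels with a gene through
rearrangements, which is what makes internalized-gene detection a pure
bookkeeping operation.

Chromosome orientation is normalized against the ancestor
(`normalize_orientations`) so that a chromosome mapping entirely to one
ancestral chromosome stores lower ancestral coordinates leftward; L/R
labelling is otherwise an assembly convention with no biological content.
Normalization is an explicit step (invoked by the pipeline after loading)
because a bare gene-order file carries no ancestral frame of its own.

## The simulator and what it emulates

`SimConfig` defaults define the study conditions: 8 ancestral chromosomes
of 50 genes, 4 subtelomeric (pillar-less) genes per end, one mid-chromosome
point centromere each, intergenics of 200–600 bp at 60% AT, CDEII spacers
76–98% AT with a per-species mean length drawn from 40–90 bp (spanning the
observed twofold between-species range) and ±2 bp within-species scatter,
and post-WGD gene loss down to 85% single-copy pillars (never removing the
last copy, so pillar presence stays meaningful).

Centromere cassettes are sampled from a generating consensus. CDEI follows
`NNCAVBTG`: positions 3, 4, 7, 8 (1-based) invariant, `V`/`B` positions
uniform over their three bases, `N` positions uniform over four. CDEIII is
26 bp with the invariant `CCGAA` core at 0-based offset 11. Within a
species, point centromeres carry additional invariant sites beyond the
cross-species core, so the generating profile fixes ten further positions
— chosen so that no invariant run other than `CCGAA` reaches length 5 and
the core's immediate neighbours stay variable — and samples the remaining
eleven positions from a sharp two-allele (reference vs complement, 0.8/0.2)
distribution. This gives the scanner a realistic, information-rich motif:
a diffuse profile would make the fraction-of-maximum score threshold
unattainable for true sites, which is a property of real point centromeres
(deeply conserved cores), not a tuning of the scanner.

The event engine is a cut/join algebra on chromosome segments. Every event
is pure (input genome untouched) and validity-checked: a reciprocal
translocation whose products would carry zero or two centromeres raises a
rejected-event error; fusions must name a centromere present on a
participant (exactly one copy is deleted — sister copies share their
label); fissions split at the centromeric intergenic and immediately fuse
both arms to telomere ends of two other chromosomes, logged as one event,
because the relative timing of breakage and centromere death is not
observable from synteny.

Random event placement is *no-reuse* by default: cuts fall only at
adjacencies of two ancestrally consecutive pillar-bearing genes, at least
3 genes from any previous breakpoint and from the chromosome ends, and
never at a centromeric intergenic; telomeric-translocation cuts
additionally stay ≥ 10 pillar genes from the donor's ends and centromere so
that a moved segment's junction can never masquerade as a terminal or
centromeric anchor. Telomeric events (fusion, fission, telomeric
translocation) never stack on a chromosome end already used along the same
lineage. These placement rules are what make scheduled event counts exactly
recoverable; deliberate breakpoint-reuse histories are built separately by
`make_reuse_fixture` (nine chained translocations reusing eight
breakpoints; four translocations, three at centromeric intergenics, closing
one cycle).

What the generator does **not** emulate: nucleotide substitution outside
centromeres (sequence is composition-only), within-population fixation
dynamics, unfinished/scaffold assemblies, and segmental duplications other
than the WGD. Passing tests therefore demonstrate correctness of the
inference logic under clean synteny signal with realistic gene loss — not
robustness to assembly error or to saturation-level rearrangement.

## Centromere scanning and consensus building

Position-frequency models hold per-position base counts (widths fixed at
8 and 26 throughout; published boundary choices differ slightly between
sequencing groups, and a fixed width is the only convention that makes
cross-species counting well defined). Scoring adds a pseudocount of 1.0
per base per position — appropriate for the 8–16 centromeres available per
species — against a uniform background by default. Non-ACGT characters
score zero. A candidate needs CDEI and CDEIII windows each reaching 60% of
that matrix's maximum achievable bits (`min_score_fraction`, calibrated by
the false-positive example: 0 hits in 500 random 60%-AT sequences, with
100% recall on unmutated planted sites), a spacer within the model's CDEII
length window at or above the model's minimum AT fraction, and all three
elements collinear on one strand; both strands are scanned and overlapping
candidates resolve to the best scorer (ties to the leftmost — one
centromere per locus). A position is called invariant only when a single
base carries 100% of the pre-pseudocount counts; IUPAC letters cover the
smallest base set reaching 95% of count mass.

## Ancestral mapping

Each ancestral centromere is characterized by `w = 5` flanking pillars per
side; each ancestral end by its `w` terminal pillars. An extant centromere
maps to a locus when flank pillars appear beside it in a consistent layout;
one-sided evidence still maps but is flagged `translocation_at_locus`
(the published table maps all translocation-disrupted centromeres rather
than declaring them lost), simultaneous support for both layouts flags
`inversion_at_locus`, and flanks of two different ancestral centromeres
beside one extant centromere flag both loci. A locus matched by no extant
centromere is LOST; an extant centromere matching no locus is reported
UNMAPPED with the current LOST loci as candidates (the
synteny-fully-erased case is resolved through the breakpoint module, never
auto-assigned).

Telomere fates are decided on *surviving-pillar geography*: distances are
measured in ancestral ranks, skipping pillars with no extant copy, which
keeps flank logic stable in post-WGD genomes where each synteny track has
lost ~40% of its genes. An extant end matches an ancestral end when ≥ 2 of
its flank genes lie within 3w surviving ranks of the ancestral terminal;
ends are ranked by support and each locus keeps at most one match per track
(two for post-WGD), so the residual end a telomeric translocation leaves on
its donor loses to the moved true terminal and surfaces as a novel site.
For a locus flank that is now internal, the distal side of the junction is
identified by run continuity (the flank continues where the adjacent gene
continues the occurrence's own ancestral run; ties break toward an
adjacent internalized subtelomeric zone). The distal run then classifies
the fate: anchored at another end's terminal and walking inward → fused;
anchored beside another chromosome's centromeric intergenic and walking
outward along one arm → fission; otherwise lost by inversion (same
ancestral chromosome) or translocation. Anchoring tolerates `2w−2`
leading track-specific losses.

Ancestral presence is the literal parsimony rule (≥ 1 non-WGD and ≥ 1
post-WGD species, or both sister regions of one post-WGD species); node-B
presence additionally requires two non-WGD genera, or one plus WGD-node
presence, and reports the number of supporting genera as an evidence score
since the older node's telomere inference is intrinsically weaker. Derived
states are placed on the tree Dollo-style — the edge above the smallest
clade containing exactly the carriers — and non-monophyletic carrier sets
are flagged as conflicts, never forced.

## Breakpoint edges and cycle counting

Synteny blocks are maximal runs of pillars consecutive in the ancestor (up
to orientation), tolerating `max_gap = 1` missing pillars so post-WGD
single-gene losses do not fragment blocks, and keeping single-gene strand
flips inside a block as within-block inversions excluded from event
counts. A rank gap only counts as gene loss when none of the skipped
pillars sits nearby on the same extant chromosome — otherwise the "gap" is
a local rearrangement boundary (a short inversion) and must break the
block. `min_block_len = 2` is the smallest run the no-reuse placement
rules can produce between adjacent breakpoints.

Every junction yields an edge with two dangling ancestral neighbours; a
chromosome end whose terminal block stops short of an ancestral end yields
a one-sided edge. Endpoint (p → d) pairs with endpoint (d → p); a missing
reciprocal is retried within `max_gap` ranks (gene loss at the junction,
flagged `gap_bridged`), and an endpoint whose dangle runs off an ancestral
chromosome closes through a telomere pseudo-edge. Connected components are
cycles; a closed k-edge cycle counts k−1 events, telomere-closed
components count max(k−1, 1), and open chains contribute their edge count
as a flagged lower bound. The k−1 formula is a heuristic validated on the
chained-reciprocal and telomeric fixture classes (it is exact there, and on
every no-reuse schedule class the simulator produces); no general
minimal-rearrangement solver is attempted. When a dangle matches several
candidate endpoints (true reuse ambiguity) the tie breaks lexicographically
by chromosome and position and is recorded on the cycle, since event order
inside a reuse pathway is only one permutation of many.

Rearrangement counting is designed for the non-WGD comparison the count
was published for; against post-WGD genomes the same machinery returns a
number dominated by loss-induced block fragmentation and should be read as
an upper bound, not an event count.

## Mechanism calls

Fissions are called first (two fission-fusion ends naming the same lost
centromere pin it uniquely), then fusions from mutually fused end pairs.
Lost centromeres are attributed to fusions by fixpoint elimination over
the per-species multiset of losses (a label can be lost twice post-WGD);
chains that remain symmetric after elimination are attributed
deterministically and marked `cen_attribution: ambiguous` — the synteny
data genuinely cannot order them. Every call carries `order_unknown`
because fusion-then-loss and loss-then-rescue are indistinguishable.
Losses explained by neither pattern are first-class `unexplained_loss`
calls, never dropped.

WGD is detected by double conserved synteny rather than duplicate-gene
counting: a post-WGD genome is ~85% single-copy, so the persistent signal
is that ancestral positions are flanked on both sides (window 10 ranks) by
gene copies on two distinct extant chromosomes. A genome is called WGD
when ≥ 50% of ancestral positions are two-tracked; simulated post-WGD
genomes score > 0.8 and non-WGD genomes ~0 regardless of rearrangement
load, because translocation breakpoints produce one-sided, not two-sided,
second tracks.

## Numerical and degenerate-input conventions

Empty sequence input to the scanner returns an empty candidate list, not
an error. A dataset with only post-WGD species degenerates the presence
rule to the sister-region clause and warns. Fate tables leaving ancestral
loci uncovered raise with the missing loci named. All randomness flows
from explicit integer seeds through `numpy.random.default_rng`; identical
(config, schedule, seed) reproduce byte-identical outputs, including the
report bundle.

## Problem sizes used by the tests

The default 8×50-gene ancestor is used throughout. Recovery sweeps run 50
simulated histories for mechanism classification and mapping, 100 random
schedules for rearrangement counting, 200 planted sites plus 500 negative
sequences for scanner calibration, and exhaustive ≤ 3-event script
enumeration on 3×9-gene genomes for the small-instance equivalence check.

## Known limitations

* Fate classification assumes junctions separated by more than the flank
  window; events stacked within ~2w genes of each other can shadow one
  another (the simulator's no-reuse mode avoids this by construction, and
  deliberately chained histories are handled by the breakpoint cycles, not
  the fate mapper).
* The per-cycle event-count formula is exact on the fixture classes above
  but is not a minimal-distance estimator for arbitrary reuse tangles.
* Centromeres detectable only by sequence require the CDE structure; taxa
  that have lost point centromeres are out of scope by design.
* Branch assignment treats each derived adjacency as single-origin; the
  same fusion arising independently on two lineages is reported as a
  conflict rather than resolved.
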