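# karyevo

Chromosome-number evolution in budding yeasts (Saccharomycetaceae),
analysed through the fates of centromeres and telomeres.

Yeast chromosome numbers range from 6 to 16 across the family, yet every
chromosome needs exactly one centromere and two telomeres. Comparing extant
gene orders with the reconstructed 8-chromosome pre-duplication ancestor
shows that only two mechanisms have reduced chromosome number — both marked
by the death of a centromere:

* **telomere-to-telomere fusion** of two chromosomes with concomitant loss
  of one of their centromeres (the dominant route), and
* **centromere fission**, where a chromosome breaks at its centromeric
  intergenic and both arms fuse to the telomeres of other chromosomes.

The only increase mechanism is **whole-genome duplication (WGD)**.
`karyevo` implements this analysis as a reusable pipeline, together with a
karyotype-evolution simulator that supplies ground-truth histories for
validating every inference stage.

## What the package does

**Point-centromere detection** (`karyevo.cenfind`). Saccharomycetaceae
centromeres are short sequence-defined elements: an 8 bp CDEI motif
(consensus `NNCAVBTG`, four invariant sites), an AT-rich CDEII spacer
(76–98% AT, species-characteristic length varying twofold between species),
and a 26 bp CDEIII motif containing an invariant `CCGAA` core. The scanner
scores CDEI/CDEIII windows by log-odds against position-frequency models,
`score(w) = Σᵢ log₂[(cᵢ(wᵢ)+p)/(Σb cᵢ(b)+4p) / q(wᵢ)]`,
and accepts collinear CDEI–CDEII–CDEIII structures on either strand. A
consensus builder reports IUPAC strings, invariant positions, and per-species
CDEII length/AT statistics.

**Ancestral mapping** (`karyevo.mapping`). Extant centromeres and telomere
locations are assigned to ancestral loci through shared flanking ortholog
"pillars" (window *w* = 5 per side). Telomeres are treated as locations:
the position beside the outermost gene with an ancestral ortholog. Fates
mirror the published bookkeeping — conserved, fused to another ancestral
end, lost to a translocation or inversion (with novel telomere sites
reported), or joined to a fission arm. Ancestral presence follows the
parsimony rule: a locus found in at least one non-WGD and one post-WGD
species, or in both paralogous sister regions of a post-WGD species, was
present in the ancestor.

**Breakpoint-reuse cycles** (`karyevo.breakpoints`). Genomes are decomposed
into synteny blocks against the ancestor; every novel adjacency becomes a
breakpoint edge carrying "dangling" ancestral neighbours. When a reciprocal
breakpoint is missing (breakpoint reuse), the tracer follows one edge of
the breakpoint (A|B) to the reciprocal edge (B′|C), then to (C′|D), and so
on until the walk closes. A closed cycle of *k* edges decomposes into
*k*−1 events (one for the simple two-edge case); cycles closing through
telomeres count max(*k*−1, 1).

**Mechanism classification** (`karyevo.events`). Fusions, fissions and WGD
are called from the fate tables; WGD is detected by double conserved
synteny (ancestral positions flanked on both sides by two distinct extant
chromosomes). `predict_chromosome_number` applies the karyotype arithmetic
n → 2n per WGD and n → n−1 per fusion/fission. Machine-readable
transcriptions of the published centromere- and telomere-fate tables are
packaged (`load_table1`, `load_table2`) and tallied by `count_fates`.

**Simulator** (`karyevo.simulate`). Generates the 8-chromosome ancestor
with sampled CDE cassettes and subtelomeric zones, evolves it along a
species tree under scheduled or randomly placed events (WGD, reciprocal and
telomeric translocations, inversions, fusions, fissions, post-WGD gene
loss), and logs every event. Random placement is no-reuse by default;
deliberate reuse histories (a nine-translocation pathway erasing synteny
around one centromere; a four-translocation cycle through three centromeric
intergenics) come from `make_reuse_fixture`.

## Worked example

Simulate a WGD clade plus two reduced lineages, then recover the mechanisms
from the leaf genomes alone:

```python
from importlib import resources
from karyevo import (SimConfig, make_ancestor, evolve, classify_mechanisms,
                     count_rearrangements, predict_chromosome_number, read_newick)

tree = read_newick(str(resources.files("karyevo.data") / "species_tree.nwk"))
cfg = SimConfig(seed=11)
ancestor, cen_model = make_ancestor(cfg)

schedule = {
    "WGD": {"WGD": 1},
    "Candida_glabrata": {"telomere_fusion_cen_loss": 3},
    "Kluyveromyces_lactis": {"telomere_fusion_cen_loss": 2},
}
leaves, truth = evolve(ancestor, tree, schedule, config=cfg)

calls, cen_fates, telo_fates = classify_mechanisms(leaves, ancestor, tree)
for call in calls:
    if call.kind != "WGD":
        print(call.species, call.kind, call.lost_centromere,
              call.participants["fused_ends"], "on branch", call.branch)
```

prints the recovered fusions with the centromere each one killed:

```
Candida_glabrata telomere_fusion_cen_loss CEN1 ['Anc1-L', 'Anc5-R'] on branch Candida_glabrata
Candida_glabrata telomere_fusion_cen_loss CEN6 ['Anc2-R', 'Anc6-L'] on branch Candida_glabrata
Candida_glabrata telomere_fusion_cen_loss CEN4 ['Anc4-R', 'Anc5-L'] on branch Candida_glabrata
Kluyveromyces_lactis telomere_fusion_cen_loss CEN3 ['Anc3-L', 'Anc7-R'] on branch Kluyveromyces_lactis
Kluyveromyces_lactis telomere_fusion_cen_loss CEN8 ['Anc5-L', 'Anc8-R'] on branch Kluyveromyces_lactis
```

and the karyotype arithmetic closes against the simulated truth — doubling
to 16 at the WGD, minus one chromosome per fusion:

```python
for sp in ("Candida_glabrata", "Kluyveromyces_lactis", "Saccharomyces_cerevisiae"):
    lineage = [c for c in calls if c.species == sp]
    print(sp, "predicted", predict_chromosome_number(8, lineage),
          "observed", leaves[sp].n_chromosomes())
```

```
Candida_glabrata predicted 13 observed 13
Kluyveromyces_lactis predicted 6 observed 6
Saccharomyces_cerevisiae predicted 16 observed 16
```

The fate tables behave like the published ones:

```python
from karyevo import load_table1, count_fates
count_fates(cen_table=load_table1())["centromere_losses_total"]   # 9
```

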