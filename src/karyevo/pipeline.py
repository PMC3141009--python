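"""End-to-end orchestration: scan -> map -> trace -> classify -> report.

The pipeline consumes a directory of gene-order tables (one per species),
an ancestral gene-order table, and a species tree; it writes fate tables in
the published two-table layout (ancestral centromeres x species, ancestral
ends x species), breakpoint cycles, mechanism calls with branches, a
consensus report (IUPAC strings, invariant positions, CDEII statistics) and
a run log echoing parameters and seed.  Given identical inputs, config and
seed the report bundle is byte-identical.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .breakpoints import count_rearrangements
from .cenfind import build_consensus, cde2_stats, consensus_string, invariant_runs
from .events import classify_mechanisms, count_fates, predict_chromosome_number
from .genome import (
    ConfigError,
    Genome,
    KaryevoError,
    normalize_orientations,
    read_gene_order,
    read_newick,
)
from .mapping import infer_ancestral_presence, map_all_centromeres, map_all_telomeres

#: glyphs used in the human-readable fate tables, mirrored by a
#: machine-readable enum column
FATE_GLYPHS = {
    "lost": "X", "orientation_change": "*", "translocation_at_locus": "r",
    "inversion_at_locus": "i", "fusion": "‡", "fission_fusion": "•",
    "translocation": "*", "inversion": "i", "internalized_genes": "†",
}


@dataclass
class PipelineConfig:
    genomes_dir: str
    ancestor: str
    tree: str
    out_dir: str
    flank_window: int = 5
    min_block_len: int = 2
    max_gap: int = 1
    min_score_fraction: float = 0.6
    seed: int | None = None

    def validate(self, need_seed: bool = False) -> None:
        for name in ("genomes_dir", "ancestor", "tree"):
            if not Path(getattr(self, name)).exists():
                raise ConfigError(f"{name} path does not exist: {getattr(self, name)}")
        if need_seed and self.seed is None:
            raise ConfigError("seed is mandatory for any stochastic step")


def load_config(path: str) -> PipelineConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    try:
        return PipelineConfig(**payload)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from None


def run_pipeline(config: PipelineConfig, log_stream=None) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns a summary dictionary (also written as ``summary.json``).
    Any stage failure aborts with the stage name and offending input.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = log_stream or sys.stderr

    def say(msg: str) -> None:
        print(f"[karyevo] {msg}", file=log)

    say(f"version {__version__}; config: {asdict(config)}")

    ancestor = read_gene_order(config.ancestor)
    stree = read_newick(config.tree)
    genomes: dict[str, Genome] = {}
    for path in sorted(Path(config.genomes_dir).glob("*.tsv")):
        g = read_gene_order(path)
        if g.species == ancestor.species:
            continue
        g = normalize_orientations(g, ancestor)
        genomes[g.species] = g
    if not genomes:
        raise KaryevoError(f"stage 'load' failed: no gene-order tables in "
                           f"{config.genomes_dir}")
    stree.validate_genomes(genomes.values())
    say(f"loaded ancestor + {len(genomes)} genomes")

    # map
    assignments = {}
    for species, genome in sorted(genomes.items()):
        cen = map_all_centromeres(genome, ancestor, config.flank_window)
        telo = map_all_telomeres(genome, ancestor, config.flank_window)
        assignments[species] = (cen, telo)
    say("mapped centromeres and telomere locations")

    # trace
    cycle_report = {}
    total_rearrangements = {}
    for species, genome in sorted(genomes.items()):
        n, cycles = count_rearrangements(
            genome, ancestor, config.min_block_len, config.max_gap)
        total_rearrangements[species] = n
        cycle_report[species] = [
            {"n_edges": c.n_edges, "events": c.event_count, "closed": c.closed,
             "telomeric": c.telomeric, "centromeric_loci": c.centromeric_loci,
             "edges": [{"chrom": e.chrom_id,
                        "left": e.left.gene_id if e.left else None,
                        "right": e.right.gene_id if e.right else None}
                       for e in c.edges]}
            for c in cycles]
    (out / "cycles.json").write_text(json.dumps(cycle_report, indent=1))
    say(f"traced breakpoint cycles: {total_rearrangements}")

    # classify
    calls, cen_table, telo_table = classify_mechanisms(
        genomes, ancestor, stree, config.flank_window, assignments=assignments)
    cen_table.to_csv(out / "centromere_fates.tsv", sep="\t", index=False)
    telo_table.to_csv(out / "telomere_fates.tsv", sep="\t", index=False)
    calls_payload = [
        {"kind": c.kind, "species": c.species, "branch": c.branch,
         "lost_centromere": c.lost_centromere,
         "order_unknown": c.order_unknown, "participants": c.participants}
        for c in calls]
    (out / "calls.json").write_text(json.dumps(calls_payload, indent=1))
    say(f"classified {len(calls)} mechanism calls")

    # ancestral presence
    presence = {}
    for species, (cen_asg, _) in assignments.items():
        counts: dict[str, int] = {}
        for a in cen_asg:
            if a.label is not None and a.status == "mapped":
                counts[a.label] = counts.get(a.label, 0) + 1
        presence[species] = counts
    ancestral_presence = infer_ancestral_presence(presence, stree)

    # consensus report from annotated centromere sequences
    annotations, cde2_by_species = [], {}
    for species, genome in sorted(genomes.items()):
        for cen in genome.centromeres():
            if cen.cde1_seq and cen.cde3_seq:
                annotations.append((cen.cde1_seq, cen.cde3_seq))
            if cen.cde2_seq:
                cde2_by_species.setdefault(species, []).append(cen.cde2_seq)
    consensus_report = None
    if len(annotations) >= 2:
        model = build_consensus(annotations,
                                [s for seqs in cde2_by_species.values()
                                 for s in seqs] or None)
        c1, c3, inv1, inv3 = consensus_string(model)
        stats, ratio = (cde2_stats(cde2_by_species)
                        if cde2_by_species else (None, None))
        consensus_report = {
            "n_centromeres": len(annotations),
            "cde1_consensus": c1, "cde3_consensus": c3,
            "cde1_invariant_positions": sorted(inv1),
            "cde3_invariant_positions": sorted(inv3),
            "cde3_invariant_runs": invariant_runs(inv3),
            "cde2_length_ratio": ratio,
        }
        with open(out / "consensus_report.txt", "w") as fh:
            fh.write(f"centromeres analysed: {len(annotations)}\n")
            fh.write(f"CDEI consensus : {c1}\n")
            fh.write(f"CDEIII consensus: {c3}\n")
            fh.write(f"CDEI invariant positions (0-based): {sorted(inv1)}\n")
            fh.write(f"CDEIII invariant runs (start, length): {invariant_runs(inv3)}\n")
            if stats is not None:
                fh.write(f"cross-species CDEII length ratio: {ratio:.2f}\n\n")
                fh.write(stats.to_string() + "\n")
        say("built consensus report")

    # summary
    fate_summary = count_fates(cen_table, _telo_for_counting(telo_table))
    chromosome_numbers = {}
    for species, genome in sorted(genomes.items()):
        lineage = [c for c in calls if c.species == species]
        chromosome_numbers[species] = {
            "observed": genome.n_chromosomes(),
            "predicted": predict_chromosome_number(
                ancestor.n_chromosomes(), lineage),
        }
    summary = {
        "version": __version__,
        "seed": config.seed,
        "species": sorted(genomes),
        "chromosome_numbers": chromosome_numbers,
        "rearrangements_vs_ancestor": total_rearrangements,
        "fate_summary": fate_summary,
        "ancestral_presence": ancestral_presence,
        "consensus": consensus_report,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    _write_fate_grid(out, cen_table, telo_table)
    say("report bundle written")
    return summary


def _telo_for_counting(telo_table):
    df = telo_table.copy()
    df["fate"] = df["fate"].fillna("conserved")
    return df


def _write_fate_grid(out: Path, cen_table, telo_table) -> None:
    """Human-readable grid: loci as rows, species as columns, glyph-coded
    entries plus the machine-readable tables written alongside."""
    with open(out / "fate_grid.txt", "w") as fh:
        for name, table, key in (("centromeres", cen_table, "status"),
                                 ("telomere ends", telo_table, "fate")):
            fh.write(f"== ancestral {name} x species ==\n")
            species = sorted(table["species"].unique())
            labels = sorted(l for l in table["label"].unique() if l is not None)
            fh.write("locus\t" + "\t".join(species) + "\n")
            for label in labels:
                row = [label]
                for sp in species:
                    sub = table[(table["species"] == sp) & (table["label"] == label)]
                    cells = []
                    for _, rec in sub.iterrows():
                        val = rec.get("chrom") or ""
                        state = rec[key]
                        if state in ("LOST", "lost", "missing"):
                            cells.append("X")
                        elif state == "fused":
                            cells.append(f"{rec.get('partner')}‡")
                        elif state == "fission_fusion":
                            cells.append(f"{rec.get('partner')}•")
                        else:
                            glyphs = "".join(
                                FATE_GLYPHS.get(f, "") for f in
                                str(rec.get("flags") or "").split(",") if f != "-")
                            cells.append(f"{val}{glyphs}" if val else state or "")
                    row.append("/".join(c for c in cells if c) or "-")
                fh.write("\t".join(row) + "\n")
            fh.write("\n")
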