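"""Point-centromere detection and consensus building.

Budding-yeast point centromeres are short sequence-defined elements: an
8 bp CDEI motif, an AT-rich CDEII spacer of species-characteristic length,
and a 26 bp CDEIII motif containing an invariant CCGAA core.  This module
builds position-frequency models from annotated centromeres, renders IUPAC
consensus strings with invariant-site calls, scores windows by log-odds,
and scans DNA for the full CDEI--CDEII--CDEIII structure on both strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import MalformedInputError, ValidationError

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_RC = str.maketrans("ACGT", "TGCA")

CDE1_WIDTH = 8
CDE3_WIDTH = 26

# minimal base set -> IUPAC letter
_IUPAC_BY_SET = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def at_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return sum(1 for b in seq if b in "ATat") / len(seq)


@dataclass
class ConsensusModel:
    """Frequency model of the CDEI/CDEIII motifs plus CDEII constraints.

    ``pfm_cde1`` and ``pfm_cde3`` hold per-position base counts (widths 8
    and 26, base order ACGT).  Scoring adds ``pseudocount`` per base per
    position and compares against ``background`` (a composition summing to
    one).  ``cde2_length_window`` and ``cde2_min_at`` constrain the spacer.
    """

    pfm_cde1: np.ndarray
    pfm_cde3: np.ndarray
    cde2_length_window: tuple[int, int]
    cde2_min_at: float
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.pfm_cde1 = np.asarray(self.pfm_cde1, dtype=float)
        self.pfm_cde3 = np.asarray(self.pfm_cde3, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.pfm_cde1.shape != (CDE1_WIDTH, 4):
            raise ValidationError(f"CDEI matrix must be {CDE1_WIDTH}x4")
        if self.pfm_cde3.shape != (CDE3_WIDTH, 4):
            raise ValidationError(f"CDEIII matrix must be {CDE3_WIDTH}x4")
        if (self.pfm_cde1 < 0).any() or (self.pfm_cde3 < 0).any():
            raise ValidationError("negative counts in frequency matrix")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValidationError("background composition must sum to 1")
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be nonnegative")

    def _pfm(self, which: str) -> np.ndarray:
        if which == "cde1":
            return self.pfm_cde1
        if which == "cde3":
            return self.pfm_cde3
        raise ValueError(f"unknown matrix {which!r}")

    def log_odds(self, which: str) -> np.ndarray:
        """Per-position log2-odds, with pseudocounts, vs the background."""
        pfm = self._pfm(which)
        totals = pfm.sum(axis=1, keepdims=True)
        probs = (pfm + self.pseudocount) / (totals + 4 * self.pseudocount)
        return np.log2(probs / self.background[None, :])

    def max_score(self, which: str) -> float:
        return float(self.log_odds(which).max(axis=1).sum())


def build_consensus(
    annotations: list[tuple[str, str]],
    cde2_seqs: list[str] | None = None,
    length_slack: int = 4,
    at_slack: float = 0.02,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
) -> ConsensusModel:
    """Count-matrix consensus from (CDEI, CDEIII) sequence pairs.

    CDEII constraints are taken from the observed spacer lengths and AT
    fractions (plus slack) when ``cde2_seqs`` is given, else set to a
    permissive default window.
    """
    if len(annotations) < 2:
        raise MalformedInputError("need at least 2 centromere annotations")
    pfm1 = np.zeros((CDE1_WIDTH, 4))
    pfm3 = np.zeros((CDE3_WIDTH, 4))
    for rec_no, (cde1, cde3) in enumerate(annotations):
        if len(cde1) != CDE1_WIDTH or len(cde3) != CDE3_WIDTH:
            raise MalformedInputError(
                f"annotation #{rec_no}: CDEI/CDEIII must be {CDE1_WIDTH}/{CDE3_WIDTH} bp, "
                f"got {len(cde1)}/{len(cde3)}")
        for i, b in enumerate(cde1.upper()):
            if b in _BASE_INDEX:
                pfm1[i, _BASE_INDEX[b]] += 1
        for i, b in enumerate(cde3.upper()):
            if b in _BASE_INDEX:
                pfm3[i, _BASE_INDEX[b]] += 1
    if cde2_seqs:
        lengths = [len(s) for s in cde2_seqs]
        ats = [at_fraction(s) for s in cde2_seqs]
        window = (max(1, min(lengths) - length_slack), max(lengths) + length_slack)
        min_at = max(0.0, min(ats) - at_slack)
    else:
        window, min_at = (10, 200), 0.5
    return ConsensusModel(
        pfm1, pfm3, window, min_at,
        background if background is not None else np.full(4, 0.25),
        pseudocount)


def consensus_string(
    model: ConsensusModel, iupac_threshold: float = 0.95,
) -> tuple[str, str, set[int], set[int]]:
    """IUPAC consensus strings and invariant-position sets (0-based).

    A position is invariant iff a single base carries 100% of the
    pre-pseudocount counts; the IUPAC letter is the smallest base set
    covering at least ``iupac_threshold`` of the count mass.
    """
    out = []
    for which in ("cde1", "cde3"):
        pfm = model._pfm(which)
        letters = []
        invariant: set[int] = set()
        for i, row in enumerate(pfm):
            total = row.sum()
            if total == 0:
                letters.append("N")
                continue
            nonzero = row > 0
            if nonzero.sum() == 1:
                invariant.add(i)
            frac = row / total
            order = np.argsort(-frac, kind="stable")
            chosen: list[str] = []
            mass = 0.0
            for j in order:
                chosen.append(BASES[j])
                mass += frac[j]
                if mass >= iupac_threshold:
                    break
            letters.append(_IUPAC_BY_SET[frozenset(chosen)])
        out.append(("".join(letters), invariant))
    (c1, inv1), (c3, inv3) = out
    return c1, c3, inv1, inv3


def invariant_runs(invariant: set[int]) -> list[tuple[int, int]]:
    """Maximal runs of consecutive invariant positions as (start, length)."""
    runs = []
    for pos in sorted(invariant):
        if runs and pos == runs[-1][0] + runs[-1][1]:
            runs[-1] = (runs[-1][0], runs[-1][1] + 1)
        else:
            runs.append((pos, 1))
    return runs


def _encode(seq: str) -> np.ndarray:
    """Map to base indices; non-ACGT becomes 4 (scores as background, 0)."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    codes = np.full(arr.shape, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        codes[arr == ord(b)] = i
    return codes


def score_window(model: ConsensusModel, seq: str, which: str) -> float:
    """Total log2-odds of one window against the model.

    Non-ACGT characters contribute zero (treated as background).
    """
    pfm = model._pfm(which)
    if len(seq) != pfm.shape[0]:
        raise ValidationError(
            f"window length {len(seq)} != matrix width {pfm.shape[0]}")
    lom = np.hstack([model.log_odds(which), np.zeros((pfm.shape[0], 1))])
    codes = _encode(seq)
    return float(lom[np.arange(len(seq)), codes].sum())


def _scores_along(model: ConsensusModel, codes: np.ndarray, which: str) -> np.ndarray:
    """Window scores at every start position (vectorized sliding sum)."""
    lom = np.hstack([model.log_odds(which), np.zeros((model._pfm(which).shape[0], 1))])
    width = lom.shape[0]
    n = len(codes) - width + 1
    if n <= 0:
        return np.empty(0)
    total = np.zeros(n)
    for k in range(width):
        total += lom[k, codes[k:k + n]]
    return total


@dataclass
class CentromereCandidate:
    """One scanned centromere structure on a chromosome sequence.

    Spans are 0-based half-open on the forward strand; on the minus strand
    CDEI..CDEIII read right to left, but ``cde1_span`` etc. always store
    forward coordinates with cde1_span.start < cde3_span.end ordering
    following the strand.
    """

    chrom_id: str
    cde1_span: tuple[int, int]
    cde2_span: tuple[int, int]
    cde3_span: tuple[int, int]
    strand: str
    score: float

    @property
    def span(self) -> tuple[int, int]:
        lo = min(self.cde1_span[0], self.cde3_span[0])
        hi = max(self.cde1_span[1], self.cde3_span[1])
        return lo, hi

    def sequences(self, seq: str) -> tuple[str, str, str]:
        """(cde1, cde2, cde3) in motif orientation."""
        s1 = seq[slice(*self.cde1_span)]
        s2 = seq[slice(*self.cde2_span)]
        s3 = seq[slice(*self.cde3_span)]
        if self.strand == "-":
            s1, s2, s3 = revcomp(s1), revcomp(s2), revcomp(s3)
        return s1, s2, s3


def scan_centromeres(
    seq: str,
    model: ConsensusModel,
    min_score_fraction: float = 0.6,
    chrom_id: str = "seq",
) -> list[CentromereCandidate]:
    """Scan both strands for CDEI--CDEII--CDEIII structures.

    A candidate needs CDEI and CDEIII windows each scoring at least
    ``min_score_fraction`` of that matrix's maximum achievable bits, on a
    common strand, separated by a spacer within the model's CDEII length
    window with AT fraction >= the model minimum.  Overlapping candidates
    are resolved to the best scorer (ties to the leftmost).  Empty or
    too-short input yields an empty list.
    """
    lo_len, hi_len = model.cde2_length_window
    if len(seq) < CDE1_WIDTH + lo_len + CDE3_WIDTH:
        return []
    raw: list[CentromereCandidate] = []
    max1 = model.max_score("cde1")
    max3 = model.max_score("cde3")
    thr1, thr3 = min_score_fraction * max1, min_score_fraction * max3
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        codes = _encode(s)
        at_cum = np.concatenate([[0], np.cumsum((codes == 0) | (codes == 3))])
        sc1 = _scores_along(model, codes, "cde1")
        sc3 = _scores_along(model, codes, "cde3")
        hits1 = np.nonzero(sc1 >= thr1)[0]
        hits3set = np.nonzero(sc3 >= thr3)[0]
        hits3 = set(hits3set.tolist())
        for p1 in hits1:
            for spacer in range(lo_len, hi_len + 1):
                p3 = p1 + CDE1_WIDTH + spacer
                if p3 not in hits3:
                    continue
                s2_start, s2_end = p1 + CDE1_WIDTH, p3
                at = (at_cum[s2_end] - at_cum[s2_start]) / max(1, spacer)
                if at < model.cde2_min_at:
                    continue
                score = float(sc1[p1] + sc3[p3])
                if strand == "+":
                    spans = ((p1, p1 + CDE1_WIDTH), (s2_start, s2_end),
                             (p3, p3 + CDE3_WIDTH))
                else:
                    n = len(seq)
                    flip = lambda a, b: (n - b, n - a)
                    spans = (flip(p1, p1 + CDE1_WIDTH), flip(s2_start, s2_end),
                             flip(p3, p3 + CDE3_WIDTH))
                raw.append(CentromereCandidate(
                    chrom_id, spans[0], spans[1], spans[2], strand, score))
    return _resolve_overlaps(raw)


def _resolve_overlaps(candidates: list[CentromereCandidate]) -> list[CentromereCandidate]:
    """Keep the single best candidate in every overlapping set (>=1 bp)."""
    ordered = sorted(candidates, key=lambda c: (-c.score, c.span[0]))
    kept: list[CentromereCandidate] = []
    for cand in ordered:
        lo, hi = cand.span
        if any(lo < k.span[1] and k.span[0] < hi for k in kept):
            continue
        kept.append(cand)
    return sorted(kept, key=lambda c: c.span[0])


def cde2_stats(annotations_by_species: dict[str, list[str]]):
    """Per-species CDEII length/AT summary plus the cross-species ratio.

    Returns ``(table, ratio)`` where ``table`` is a pandas DataFrame with
    one row per species (n, mean, sd, min/max length, AT range) and
    ``ratio`` = max species mean / min species mean.
    """
    import pandas as pd

    rows = []
    for species, seqs in annotations_by_species.items():
        if not seqs:
            raise MalformedInputError(f"species {species}: no CDEII annotations")
        lengths = np.array([len(s) for s in seqs], dtype=float)
        ats = np.array([at_fraction(s) for s in seqs])
        rows.append({
            "species": species,
            "n": len(seqs),
            "mean_length": float(lengths.mean()),
            "sd_length": float(lengths.std(ddof=1)) if len(seqs) > 1 else 0.0,
            "min_length": int(lengths.min()),
            "max_length": int(lengths.max()),
            "min_at": float(ats.min()),
            "max_at": float(ats.max()),
        })
    table = pd.DataFrame(rows).set_index("species")
    means = table["mean_length"]
    ratio = float(means.max() / means.min())
    return table, ratio


# ---------------------------------------------------------------------------
# model serialization (structured text)
# ---------------------------------------------------------------------------


def write_model(model: ConsensusModel, path) -> None:
    import yaml

    payload = {
        "pfm_cde1": model.pfm_cde1.tolist(),
        "pfm_cde3": model.pfm_cde3.tolist(),
        "cde2_length_window": list(model.cde2_length_window),
        "cde2_min_at": float(model.cde2_min_at),
        "background": model.background.tolist(),
        "pseudocount": float(model.pseudocount),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh)


def read_model(path) -> ConsensusModel:
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return ConsensusModel(
        np.array(payload["pfm_cde1"]), np.array(payload["pfm_cde3"]),
        tuple(payload["cde2_length_window"]), payload["cde2_min_at"],
        np.array(payload["background"]), payload["pseudocount"])


def write_candidates(candidates: list[CentromereCandidate], path) -> None:
    """BED-like TSV of scanned candidates with per-CDE spans."""
    cols = ["chrom", "start", "end", "strand", "score",
            "cde1_start", "cde1_end", "cde2_start", "cde2_end",
            "cde3_start", "cde3_end"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in candidates:
            lo, hi = c.span
            fh.write("\t".join(str(x) for x in [
                c.chrom_id, lo, hi, c.strand, f"{c.score:.3f}",
                *c.cde1_span, *c.cde2_span, *c.cde3_span]) + "\n")
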