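"""Divergent gene-pair detection and bidirectional-promoter features.

A bidirectional promoter is the short intergenic spacer of a
head-to-head (divergent) gene pair: the two 5' ends face each other
across < 1 kb of sequence, and the spacer is typically CpG-rich and
TATA-less. This module classifies the orientation of coordinate-adjacent
gene pairs, extracts their intergenic intervals, and annotates candidate
spacers with CpG-island, TATA-consensus and PWM-motif content.

The TSS convention under half-open coordinates: interval start for "+"
genes, interval end for "-" genes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import motifs as bio_motifs

from .model import GeneAnnotation, GeneRecord, GenomicInterval, ValidationError

__all__ = [
    "Orientation",
    "PromoterPair",
    "CpGIsland",
    "Pwm",
    "MotifHit",
    "classify_orientation",
    "intergenic_interval",
    "find_bidirectional_pairs",
    "cpg_island_scan",
    "tata_scan",
    "pwm_scan",
    "read_jaspar_pwms",
    "reverse_complement",
]

DIVERGENT = "divergent_head_to_head"
CONVERGENT = "convergent_tail_to_tail"
TANDEM = "tandem"
Orientation = str

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


# ----------------------------------------------------------------- gene pairs


def classify_orientation(a: GeneRecord, b: GeneRecord) -> Orientation:
    """Orientation of a coordinate-ordered gene pair from its strands.

    left "-" / right "+" means both 5' ends face the intergenic gap
    (divergent, head-to-head); left "+" / right "-" points both 3' ends
    inward (convergent); equal strands are tandem.
    """
    if a.interval.chrom != b.interval.chrom:
        raise ValidationError("genes on different chromosomes")
    if a.interval.start > b.interval.start:
        a, b = b, a
    sa, sb = a.interval.strand, b.interval.strand
    if "." in (sa, sb):
        raise ValidationError(
            f"unstranded gene in pair ({a.gene_id}, {b.gene_id}); "
            f"orientation undefined"
        )
    if sa == sb:
        return TANDEM
    return DIVERGENT if sa == "-" else CONVERGENT


def intergenic_interval(
    a: GeneRecord, b: GeneRecord
) -> tuple[GenomicInterval, int, bool]:
    """Intergenic interval [left.end, right.start) and its length in bp.

    Overlapping or abutting genes yield an empty interval at the right
    gene's start; the boolean marks a genuine overlap.
    """
    if a.interval.chrom != b.interval.chrom:
        raise ValidationError("genes on different chromosomes")
    if a.interval.start > b.interval.start:
        a, b = b, a
    left, right = a.interval, b.interval
    overlap = left.end > right.start
    if overlap:
        iv = GenomicInterval(left.chrom, right.start, right.start)
    else:
        iv = GenomicInterval(left.chrom, left.end, right.start)
    return iv, iv.length, overlap


@dataclass
class PromoterPair:
    gene_left: str
    gene_right: str
    orientation: Orientation
    intergenic: GenomicInterval
    distance_bp: int
    overlap: bool
    bidirectional_flag: bool


def find_bidirectional_pairs(
    annotation: GeneAnnotation, max_dist: int = 1000
) -> list[PromoterPair]:
    """Classify all coordinate-adjacent gene pairs on each chromosome.

    A pair is flagged bidirectional when it is divergent and its
    intergenic distance is strictly less than ``max_dist``. Overlapping
    pairs are reported but never flagged.
    """
    by_chrom: dict[str, list[GeneRecord]] = {}
    for rec in annotation:
        by_chrom.setdefault(rec.interval.chrom, []).append(rec)
    pairs: list[PromoterPair] = []
    for recs in by_chrom.values():
        for a, b in zip(recs, recs[1:]):
            orientation = classify_orientation(a, b)
            iv, dist, overlap = intergenic_interval(a, b)
            flag = orientation == DIVERGENT and dist < max_dist and not overlap
            pairs.append(
                PromoterPair(
                    gene_left=a.gene_id,
                    gene_right=b.gene_id,
                    orientation=orientation,
                    intergenic=iv,
                    distance_bp=dist,
                    overlap=overlap,
                    bidirectional_flag=flag,
                )
            )
    return pairs


# ---------------------------------------------------------------- CpG islands


@dataclass
class CpGIsland:
    start: int  # 0-based offset within the scanned sequence
    end: int
    gc_fraction: float
    obs_exp_cpg: float

    @property
    def length(self) -> int:
        return self.end - self.start


def _cpg_stats(seq: str) -> tuple[float, float]:
    """GC fraction and observed/expected CpG of a sequence (N excluded)."""
    n_c = seq.count("C")
    n_g = seq.count("G")
    n_cpg = seq.count("CG")
    length = len(seq) - seq.count("N")
    if length == 0:
        return 0.0, 0.0
    gc = (n_c + n_g) / length
    oe = (n_cpg * length) / (n_c * n_g) if n_c and n_g else 0.0
    return gc, oe


def cpg_island_scan(
    seq: str,
    len_min: int = 200,
    gc_min: float = 0.5,
    oe_min: float = 0.6,
    window: int = 100,
    step: int = 1,
) -> list[CpGIsland]:
    """Sliding-window CpG-island screen (Gardiner-Garden/Frommer criteria).

    Windows passing GC >= ``gc_min`` and observed/expected CpG >=
    ``oe_min`` are merged when they overlap; each merged region is then
    re-checked against all three thresholds (including ``len_min``)
    before being reported. Sequences shorter than the window yield no
    islands.
    """
    seq = seq.upper()
    L = len(seq)
    if L < window:
        return []
    qualifying: list[tuple[int, int]] = []
    for off in range(0, L - window + 1, step):
        gc, oe = _cpg_stats(seq[off : off + window])
        if gc >= gc_min and oe >= oe_min:
            qualifying.append((off, off + window))
    if not qualifying:
        return []
    merged: list[list[int]] = [list(qualifying[0])]
    for s, e in qualifying[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    islands = []
    for s, e in merged:
        gc, oe = _cpg_stats(seq[s:e])
        if (e - s) >= len_min and gc >= gc_min and oe >= oe_min:
            islands.append(CpGIsland(start=s, end=e, gc_fraction=gc, obs_exp_cpg=oe))
    return islands


# ----------------------------------------------------------------- TATA boxes

# TATAWAW consensus, W = A or T
_TATA_RE = re.compile("TATA[AT]A[AT]")


def tata_scan(seq: str) -> tuple[bool, list[tuple[int, str]]]:
    """Find TATAWAW consensus occurrences on either strand.

    Offsets are 0-based positions of the match start on the forward
    sequence; for "-" hits, the offset of the forward-strand window
    whose reverse complement matches.
    """
    seq = seq.upper()
    hits: list[tuple[int, str]] = []
    for m in _TATA_RE.finditer(seq):
        hits.append((m.start(), "+"))
    rc = reverse_complement(seq)
    for m in _TATA_RE.finditer(rc):
        hits.append((len(seq) - m.end(), "-"))
    hits.sort()
    return bool(hits), hits


# ----------------------------------------------------------------- PWM scans

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class Pwm:
    """Position frequency model of a TF binding motif.

    ``matrix`` is width x 4 (A, C, G, T) base frequencies; rows are
    normalised to sum to 1. Scores are log-odds in bits against a
    uniform 0.25 background, with pseudocount added to both numerator
    and background.
    """

    motif_id: str
    matrix: np.ndarray
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or self.matrix.shape[0] == 0:
            raise ValidationError(
                f"PWM {self.motif_id!r}: need a non-empty width x 4 matrix"
            )
        sums = self.matrix.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise ValidationError(f"PWM {self.motif_id!r}: zero column sum")
        self.matrix = self.matrix / sums

    @property
    def width(self) -> int:
        return int(self.matrix.shape[0])

    def log_odds(self) -> np.ndarray:
        eps = self.pseudocount
        with np.errstate(divide="ignore"):  # zero freq at eps=0 -> -inf, fine
            return np.log2((self.matrix + eps) / (0.25 + eps))

    @property
    def max_score(self) -> float:
        return float(self.log_odds().max(axis=1).sum())

    def reverse_complement(self) -> "Pwm":
        return Pwm(self.motif_id, self.matrix[::-1, ::-1], self.pseudocount)


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    offset: int  # 0-based start of the hit window on the forward sequence
    strand: str
    score_bits: float


def _scan_one_strand(seq: str, lo: np.ndarray, width: int) -> np.ndarray:
    idx = np.array([_BASE_INDEX.get(c, -1) for c in seq])
    n = len(seq) - width + 1
    scores = np.full(max(n, 0), -np.inf)
    for off in range(max(n, 0)):
        window = idx[off : off + width]
        if np.any(window < 0):  # N anywhere in the window disqualifies it
            continue
        scores[off] = lo[np.arange(width), window].sum()
    return scores


def pwm_scan(seq: str, pwm: Pwm, threshold_bits: float) -> list[MotifHit]:
    """Log-odds scan of both strands; hits at score >= threshold.

    The reverse strand is scored by scanning with the
    reverse-complemented matrix, which equals scoring the reverse
    complement of each window; offsets always refer to the forward
    sequence.
    """
    seq = seq.upper()
    if len(seq) < pwm.width:
        return []
    hits: list[MotifHit] = []
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        scores = _scan_one_strand(seq, mat.log_odds(), pwm.width)
        for off in np.nonzero(scores >= threshold_bits)[0]:
            hits.append(
                MotifHit(
                    motif_id=pwm.motif_id,
                    offset=int(off),
                    strand=strand,
                    score_bits=float(scores[off]),
                )
            )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def read_jaspar_pwms(path: str | Path, pseudocount: float = 0.01) -> list[Pwm]:
    """Read JASPAR plain-text PFMs into frequency PWMs."""
    pwms = []
    with open(path) as fh:
        for motif in bio_motifs.parse(fh, "jaspar"):
            counts = np.array(
                [[motif.counts[b][i] for b in "ACGT"] for i in range(motif.length)],
                dtype=float,
            )
            name = motif.matrix_id or motif.name
            pwms.append(Pwm(motif_id=name, matrix=counts, pseudocount=pseudocount))
    return pwms
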