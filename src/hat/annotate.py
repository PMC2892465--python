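"""Sequence-of-interest scanning and nearest-TSS gene mapping.

A detected region can be corroborated by sequence content: a transcription
factor's binding word (e.g. CCAAT) should occur inside a binding region, and
a restriction-enzyme site (e.g. the palindromic GATC of DpnII) must flank any
fragment produced by that enzyme.  Both strands are scanned by exact match:
the motif on the forward sequence reports a + hit, its reverse complement a
- hit; palindromic motifs therefore produce paired hits at identical
positions.  Regions are also mapped to the nearest 5' transcriptional start
sites, separately upstream/downstream and per gene strand, within a distance
cap (default 300 kb in each direction).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Mapping, Sequence

from .io import GeneModel

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceHit:
    """An exact motif match; position is the 1-based start on forward coordinates."""

    motif: str
    chromosome: str
    position: int
    strand: str


@dataclass(frozen=True)
class FlankingGene:
    """A nearby gene: distance from the nearer region boundary to its TSS."""

    gene: GeneModel
    distance_bp: int
    direction: str  # upstream/downstream in chromosome coordinates


def _fetch(genome, chrom: str, start1: int, end1: int) -> str:
    """Extract [start1, end1] (1-based inclusive) from a dict of strings or a
    pyfaidx.Fasta."""
    try:
        record = genome[chrom]
    except KeyError:
        raise ValueError(f"chromosome {chrom!r} absent from the genome")
    piece = record[start1 - 1 : end1]
    return piece if isinstance(piece, str) else str(piece)


def _chrom_length(genome, chrom: str) -> int:
    try:
        return len(genome[chrom])
    except KeyError:
        raise ValueError(f"chromosome {chrom!r} absent from the genome")


def scan_sequence(
    region, genome, motif: str, flank_bp: int = 0
) -> List[SequenceHit]:
    """Scan region +/- flank for exact occurrences of ``motif`` on both strands.

    Case-insensitive; overlapping matches are all reported; flanks are
    clipped to chromosome bounds.  Motifs are restricted to unambiguous
    A/C/G/T strings.
    """
    motif = motif.upper()
    if len(motif) < 1 or set(motif) - set("ACGT"):
        raise ValueError(
            f"motif must be a non-empty unambiguous A/C/G/T string, got {motif!r}"
        )
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    chrom = region.chromosome
    L = _chrom_length(genome, chrom)
    start = max(1, region.start_bp - flank_bp)
    end = min(L, region.end_bp + flank_bp)
    seq = _fetch(genome, chrom, start, end).upper()

    hits: List[SequenceHit] = []
    for strand, pattern in (("+", motif), ("-", reverse_complement(motif))):
        i = seq.find(pattern)
        while i != -1:
            hits.append(SequenceHit(motif, chrom, start + i, strand))
            i = seq.find(pattern, i + 1)
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def map_nearest_tss(
    region, genes: Iterable[GeneModel], max_distance_bp: int = 300_000
) -> List[FlankingGene]:
    """Nearest 5' TSS up- and downstream of the region, per gene strand.

    Returns up to four entries (upstream/downstream x +/- strand).  Distance
    is measured from the nearer region boundary to the TSS and is 0 when the
    TSS lies inside the region; entries farther than ``max_distance_bp`` are
    omitted; ties break by lexicographic gene name.  The result does not
    depend on the input order of ``genes``.
    """
    out: List[FlankingGene] = []
    for strand in ("+", "-"):
        best: dict[str, tuple[int, GeneModel]] = {}
        for g in genes:
            if g.chromosome != region.chromosome or g.strand != strand:
                continue
            if g.tss < region.start_bp:
                direction, dist = "upstream", region.start_bp - g.tss
            elif g.tss > region.end_bp:
                direction, dist = "downstream", g.tss - region.end_bp
            else:
                # TSS inside the region: distance 0, nearer-boundary side
                dist = 0
                direction = (
                    "upstream"
                    if g.tss - region.start_bp <= region.end_bp - g.tss
                    else "downstream"
                )
            if dist > max_distance_bp:
                continue
            cur = best.get(direction)
            if cur is None or (dist, g.gene_name) < (cur[0], cur[1].gene_name):
                best[direction] = (dist, g)
        for direction in ("upstream", "downstream"):
            if direction in best:
                dist, g = best[direction]
                out.append(FlankingGene(gene=g, distance_bp=dist, direction=direction))
    out.sort(key=lambda f: (f.direction, f.gene.strand, f.gene.gene_name))
    return out
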