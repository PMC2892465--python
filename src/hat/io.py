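"""Reading and writing probe tracks, gene models and region calls.

Coordinates are 1-based inclusive everywhere inside the package; BED files
are read and written in the standard 0-based half-open convention.
Chromosome names are compared as exact strings -- no "chr" prefix stripping
is performed, so tracks, genomes and gene models must come from the same
assembly naming scheme.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

log = logging.getLogger("hat")


class ParseError(ValueError):
    """A malformed line in an input file (message names the line number)."""


class DuplicatePositionError(ValueError):
    """Two probes at the same genomic position on the same chromosome."""


# ---------------------------------------------------------------------------
# Probe tracks
# ---------------------------------------------------------------------------

@dataclass
class ProbeTrack:
    """One sample's probe grid: sorted positions plus normalized intensities.

    ``positions`` and ``intensities`` map chromosome name to parallel arrays;
    positions are 1-based, strictly increasing within a chromosome.  ``K``
    is the chip-wide probe count (all chromosomes pooled), the fixed
    population size of the hypergeometric test.
    """

    sample_id: str
    positions: Dict[str, np.ndarray]
    intensities: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if set(self.positions) != set(self.intensities):
            raise ValueError("positions and intensities cover different chromosomes")
        for chrom in self.positions:
            pos = np.asarray(self.positions[chrom], dtype=np.int64)
            val = np.asarray(self.intensities[chrom], dtype=np.float64)
            if pos.size != val.size:
                raise ValueError(f"{chrom}: positions and intensities differ in length")
            d = np.diff(pos)
            if np.any(d == 0):
                at = int(pos[np.nonzero(d == 0)[0][0]])
                raise DuplicatePositionError(
                    f"duplicate probe position {at} on {chrom}"
                )
            if np.any(d < 0):
                raise ValueError(f"{chrom}: probe positions are not sorted")
            self.positions[chrom] = pos
            self.intensities[chrom] = val

    @property
    def K(self) -> int:
        return int(sum(v.size for v in self.positions.values()))

    def chromosomes(self) -> List[str]:
        return sorted(self.positions)

    def all_intensities(self) -> np.ndarray:
        """All intensities pooled, in sorted-chromosome order."""
        chroms = self.chromosomes()
        if not chroms:
            return np.empty(0, dtype=np.float64)
        return np.concatenate([self.intensities[c] for c in chroms])

    def with_intensities(self, new: Mapping[str, np.ndarray]) -> "ProbeTrack":
        return ProbeTrack(
            self.sample_id,
            {c: self.positions[c].copy() for c in self.positions},
            {c: np.asarray(new[c], dtype=np.float64) for c in self.positions},
        )


def _split(line: str) -> List[str]:
    return line.split("\t") if "\t" in line else line.split()


_SKIP_PREFIXES = ("#", "track", "browser")


def _parse_track_rows(path: Path, dialect: str) -> List[Tuple[str, int, float]]:
    rows: List[Tuple[str, int, float]] = []
    if dialect == "wig-fixed":
        chrom, pos, step = None, None, None
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                s = raw.strip()
                if not s or s.startswith(("#", "track", "browser")):
                    continue
                if s.startswith("fixedStep"):
                    kv = dict(tok.split("=", 1) for tok in s.split()[1:])
                    try:
                        chrom = kv["chrom"]
                        pos = int(kv["start"])
                        step = int(kv["step"])
                    except (KeyError, ValueError):
                        raise ParseError(f"{path}: line {lineno}: bad fixedStep header")
                    continue
                if s.startswith("variableStep"):
                    raise ParseError(
                        f"{path}: line {lineno}: variableStep WIG is not supported; "
                        "use the tsv dialect"
                    )
                if chrom is None:
                    raise ParseError(f"{path}: line {lineno}: value before fixedStep header")
                try:
                    val = float(s)
                except ValueError:
                    raise ParseError(f"{path}: line {lineno}: expected a numeric value")
                rows.append((chrom, pos, val))
                pos += step
        return rows

    if dialect not in ("bedgraph", "tsv"):
        raise ValueError(f"unknown probe-track dialect: {dialect!r}")
    ncol = 4 if dialect == "bedgraph" else 3
    first_data_line = True
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            s = raw.strip()
            if not s or s.startswith(_SKIP_PREFIXES):
                continue
            f = _split(s)
            if len(f) < ncol:
                raise ParseError(
                    f"{path}: line {lineno}: expected {ncol} columns, got {len(f)}"
                )
            try:
                if dialect == "bedgraph":
                    # probe anchored at the interval start, converted to 1-based
                    row = (f[0], int(f[1]) + 1, float(f[3]))
                else:
                    row = (f[0], int(f[1]), float(f[2]))
            except ValueError:
                if first_data_line:  # tolerate a single header row
                    first_data_line = False
                    continue
                raise ParseError(f"{path}: line {lineno}: non-numeric field")
            first_data_line = False
            rows.append(row)
    return rows


def read_probe_track(
    path: str | Path, dialect: str = "tsv", sample_id: Optional[str] = None
) -> ProbeTrack:
    """Read a probe track file into a :class:`ProbeTrack`.

    Supported dialects: ``bedgraph`` (4-column, probe anchored at interval
    start), ``wig-fixed`` (fixedStep WIG) and ``tsv`` (chrom, 1-based
    position, intensity).  Unsorted input is sorted with a logged notice;
    duplicated positions on one chromosome are a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sample_id is None:
        sample_id = path.stem
    rows = _parse_track_rows(path, dialect)
    by_chrom: Dict[str, List[Tuple[int, float]]] = {}
    for chrom, pos, val in rows:
        by_chrom.setdefault(chrom, []).append((pos, val))

    positions: Dict[str, np.ndarray] = {}
    intensities: Dict[str, np.ndarray] = {}
    for chrom, pairs in by_chrom.items():
        pos = np.array([p for p, _ in pairs], dtype=np.int64)
        val = np.array([v for _, v in pairs], dtype=np.float64)
        order = np.argsort(pos, kind="stable")
        if not np.array_equal(order, np.arange(pos.size)):
            log.info("%s: probes on %s were unsorted; sorted by position", path, chrom)
            pos, val = pos[order], val[order]
        dup = np.nonzero(np.diff(pos) == 0)[0]
        if dup.size:
            raise DuplicatePositionError(
                f"{path}: duplicate probe position {int(pos[dup[0]])} on {chrom}"
            )
        positions[chrom] = pos
        intensities[chrom] = val
    return ProbeTrack(sample_id, positions, intensities)


def write_probe_track_tsv(track: ProbeTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tposition\tintensity\n")
        for chrom in track.chromosomes():
            for p, v in zip(track.positions[chrom], track.intensities[chrom]):
                fh.write(f"{chrom}\t{int(p)}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its 5' transcriptional start site.

    For minus-strand genes the TSS is the larger coordinate of the gene body.
    """

    gene_name: str
    chromosome: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand symbol: {self.strand!r}")


def read_gene_models(path: str | Path, dialect: str = "bed6") -> List[GeneModel]:
    """Read gene models from BED6 or refFlat text.

    The 5' TSS is the 1-based start coordinate for + strand genes and the
    end coordinate for - strand genes.  Duplicate (name, chromosome, strand)
    entries are collapsed to the first occurrence.
    """
    path = Path(path)
    genes: List[GeneModel] = []
    seen: Dict[Tuple[str, str, str], int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            s = raw.strip()
            if not s or s.startswith(_SKIP_PREFIXES):
                continue
            f = _split(s)
            try:
                if dialect == "bed6":
                    if len(f) < 6:
                        raise ParseError(
                            f"{path}: line {lineno}: BED6 needs 6 columns"
                        )
                    chrom, start, end, name, strand = f[0], int(f[1]), int(f[2]), f[3], f[5]
                elif dialect == "refflat":
                    if len(f) < 6:
                        raise ParseError(
                            f"{path}: line {lineno}: refFlat needs >= 6 columns"
                        )
                    name, chrom, strand, start, end = f[0], f[2], f[3], int(f[4]), int(f[5])
                else:
                    raise ValueError(f"unknown gene-model dialect: {dialect!r}")
            except ValueError as exc:
                if isinstance(exc, (ParseError,)):
                    raise
                raise ParseError(f"{path}: line {lineno}: non-numeric coordinate")
            if strand not in ("+", "-"):
                raise ValueError(
                    f"{path}: line {lineno}: unknown strand symbol {strand!r}"
                )
            tss = start + 1 if strand == "+" else end
            key = (name, chrom, strand)
            if key in seen:
                if genes[seen[key]].tss != tss:
                    log.info(
                        "%s: line %d: duplicate gene %s with different TSS; keeping first",
                        path, lineno, name,
                    )
                continue
            seen[key] = len(genes)
            genes.append(GeneModel(name, chrom, strand, tss))
    return genes


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Region output
# ---------------------------------------------------------------------------

def _bed_score(min_p_adj: float) -> float:
    if min_p_adj <= 0:
        return 1000.0
    return min(1000.0, -np.log10(min_p_adj))


_TSV_HEADER = (
    "chrom\tstart\tend\twidth_bp\tn_probes\tmin_p_adj\tn_contributing\t"
    "q_peak_position\tn_sequence_hits\tsequence_hits\tflanking_genes\n"
)


def write_regions(
    regions: Sequence,
    bed_path: str | Path,
    tsv_path: str | Path,
    hits: Optional[Sequence[Sequence]] = None,
    flanking: Optional[Sequence[Sequence]] = None,
) -> None:
    """Write region calls as a sorted BED file plus a detailed TSV report.

    ``hits`` and ``flanking`` are optional per-region sequences of
    :class:`~hat.annotate.SequenceHit` and :class:`~hat.annotate.FlankingGene`
    aligned with ``regions``.  BED scores are ``-log10(min adjusted p)``
    capped at 1000.
    """
    order = sorted(
        range(len(regions)),
        key=lambda i: (regions[i].chromosome, regions[i].start_bp, regions[i].end_bp),
    )
    with open(bed_path, "w") as bed, open(tsv_path, "w") as tsv:
        tsv.write(_TSV_HEADER)
        for rank, i in enumerate(order, 1):
            r = regions[i]
            name = f"region_{rank:05d}"
            score = _bed_score(r.min_p_adj)
            bed.write(
                f"{r.chromosome}\t{r.start_bp - 1}\t{r.end_bp}\t{name}\t{score:.6g}\t.\n"
            )
            rhits = list(hits[i]) if hits is not None else []
            rflank = list(flanking[i]) if flanking is not None else []
            hit_str = ";".join(
                f"{h.motif}:{h.strand}:{h.position}" for h in rhits
            )
            flank_str = ";".join(
                f"{f.gene.gene_name}:{f.gene.strand}:{f.direction}:{f.distance_bp}"
                for f in rflank
            )
            q_peak = getattr(r, "q_peak_position", lambda: r.start_bp)
            q_peak_pos = q_peak() if callable(q_peak) else q_peak
            n_probes = getattr(r, "n_probes", r.end_bp - r.start_bp + 1)
            tsv.write(
                f"{r.chromosome}\t{r.start_bp}\t{r.end_bp}\t"
                f"{r.end_bp - r.start_bp + 1}\t{n_probes}\t{r.min_p_adj:.6g}\t"
                f"{r.n_contributing}\t{q_peak_pos}\t{len(rhits)}\t"
                f"{hit_str}\t{flank_str}\n"
            )


@dataclass
class BedRegion:
    """A region read back from a BED file (1-based inclusive internally)."""

    chromosome: str
    start_bp: int
    end_bp: int
    name: str = ""
    score: float = 0.0
    sample_id: str = ""


def read_regions_bed(path: str | Path, sample_id: Optional[str] = None) -> List[BedRegion]:
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    out: List[BedRegion] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            s = raw.strip()
            if not s or s.startswith(_SKIP_PREFIXES):
                continue
            f = _split(s)
            if len(f) < 3:
                raise ParseError(f"{path}: line {lineno}: BED needs >= 3 columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-numeric coordinate")
            name = f[3] if len(f) > 3 else ""
            score = float(f[4]) if len(f) > 4 else 0.0
            out.append(BedRegion(f[0], start + 1, end, name, score, sample_id))
    return out


def write_gene_models_bed(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as BED6 with a 1 bp feature at the TSS."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chromosome}\t{g.tss - 1}\t{g.tss}\t{g.gene_name}\t0\t{g.strand}\n")
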