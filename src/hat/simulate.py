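"""Synthetic fixtures with known ground truth.

Emulates promoter tiling-array data after normalization: a probe grid with
~35 bp typical spacing (optionally jittered or mixed-resolution), background
intensities drawn from a normal distribution with a negative mean, and
enriched fragments ("spikes") of configurable width and additive effect on
the normalized scale.  Matching genomes with planted motifs and gene models
with TSSs at known offsets from the spikes support end-to-end annotation
tests.  Everything is reproducible from (spec, seed).

What this generator does not emulate: probe-sequence-dependent hybridization
bias, spatial array artifacts, replicate correlation, or copy-number
structure.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io import GeneModel, ProbeTrack


@dataclass(frozen=True)
class SpikeSpec:
    """One class of enriched fragments to plant."""

    width_bp: int
    effect: float   # additive intensity shift on the normalized scale
    n: int


@dataclass(frozen=True)
class TruthInterval:
    """A planted enrichment, 1-based inclusive."""

    chromosome: str
    start_bp: int
    end_bp: int


@dataclass(frozen=True)
class MotifPlant:
    motif: str
    chromosome: str
    position: int   # 1-based start of the planted copy
    where: str      # "in-spike" or "background"


@dataclass
class SimulationSpec:
    """Study conditions for a synthetic sample.

    Defaults mirror a promoter array after normalization: ~35 bp probe
    spacing, background N(-0.5, 1) so ~31% of probes are positive, one
    chromosome.  ``spacing_model`` is ``fixed``, ``jittered`` (uniform
    +/- 40% around the mean) or ``mixed-resolution`` (each gap drawn from
    ``spacing_modes``, default 25/50 bp).
    """

    n_probes: int = 10_000
    spacing_model: str = "jittered"
    spacing_bp: int = 35
    spacing_modes: Tuple[int, int] = (25, 50)
    background_mean: float = -0.5
    background_sd: float = 1.0
    spikes: List[SpikeSpec] = field(default_factory=list)
    motif_plants: List[Tuple[str, str]] = field(default_factory=list)  # (motif, where)
    seed: int = 0
    chromosome: str = "chr1"
    sample_id: str = "sim"
    min_spike_separation_bp: int = 2000
    tss_offset_bp: int = 500
    edge_softening: float = 0.0  # fraction of the effect on boundary probes

    def __post_init__(self) -> None:
        if self.background_mean >= 0:
            raise ValueError("background mean must be negative (normalized regime)")
        if self.spacing_model not in ("fixed", "jittered", "mixed-resolution"):
            raise ValueError(f"unknown spacing model: {self.spacing_model!r}")
        if not 0.0 <= self.edge_softening <= 1.0:
            raise ValueError("edge_softening must be in [0, 1]")


@dataclass
class SimGenome:
    """A synthetic genome consistent with a spiked track."""

    sequences: Dict[str, str]
    genes: List[GeneModel]
    motif_plants: List[MotifPlant]

    def fasta_text(self, width: int = 70) -> str:
        lines = []
        for name, seq in self.sequences.items():
            lines.append(f">{name}")
            lines.extend(seq[i : i + width] for i in range(0, len(seq), width))
        return "\n".join(lines) + "\n"


def _rng(spec: SimulationSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def generate_null_track(spec: SimulationSpec) -> ProbeTrack:
    """Background-only probe track: i.i.d. normal intensities on a probe grid."""
    rng = _rng(spec, 0)
    n = spec.n_probes
    if spec.spacing_model == "fixed":
        gaps = np.full(n - 1, spec.spacing_bp, dtype=np.int64)
    elif spec.spacing_model == "jittered":
        lo = max(1, int(round(spec.spacing_bp * 0.6)))
        hi = int(round(spec.spacing_bp * 1.4))
        gaps = rng.integers(lo, hi + 1, size=n - 1)
    else:  # mixed-resolution
        gaps = rng.choice(np.asarray(spec.spacing_modes, dtype=np.int64), size=n - 1)
    positions = np.concatenate(([1], 1 + np.cumsum(gaps)))
    intensities = rng.normal(spec.background_mean, spec.background_sd, size=n)
    return ProbeTrack(
        spec.sample_id,
        {spec.chromosome: positions},
        {spec.chromosome: intensities},
    )


def spike_track(
    track: ProbeTrack, spec: SimulationSpec, max_tries: int = 1000
) -> Tuple[ProbeTrack, List[TruthInterval]]:
    """Add enriched fragments at random non-overlapping locations.

    Probes inside each planted interval get ``effect`` added to their
    intensity (optionally softened on the boundary probes).  Returns the
    spiked track plus the exact truth intervals.
    """
    rng = _rng(spec, 1)
    chrom = spec.chromosome
    positions = track.positions[chrom]
    lo, hi = int(positions[0]), int(positions[-1])
    placed: List[Tuple[int, int]] = []
    truth: List[TruthInterval] = []
    for sp in spec.spikes:
        if sp.width_bp > hi - lo + 1:
            raise ValueError("spike width exceeds the simulated chromosome length")
        for _ in range(sp.n):
            for attempt in range(max_tries):
                start = int(rng.integers(lo, hi - sp.width_bp + 2))
                end = start + sp.width_bp - 1
                pad = spec.min_spike_separation_bp
                if all(e + pad < start or s - pad > end for s, e in placed):
                    placed.append((start, end))
                    truth.append(TruthInterval(chrom, start, end))
                    break
            else:
                raise RuntimeError(
                    "could not place spikes without overlap; reduce n or width"
                )
    new = {c: track.intensities[c].copy() for c in track.positions}
    vals = new[chrom]
    for iv, sp in zip(truth, _expand_specs(spec.spikes)):
        inside = np.nonzero((positions >= iv.start_bp) & (positions <= iv.end_bp))[0]
        if inside.size == 0:
            continue
        vals[inside] += sp.effect
        if spec.edge_softening > 0 and inside.size >= 2:
            soften = sp.effect * spec.edge_softening
            vals[inside[0]] -= soften
            vals[inside[-1]] -= soften
    return track.with_intensities(new), truth


def _expand_specs(spikes: Sequence[SpikeSpec]) -> List[SpikeSpec]:
    out: List[SpikeSpec] = []
    for sp in spikes:
        out.extend([sp] * sp.n)
    return out


_BASES = np.array(list("ACGT"))


def generate_genome_and_genes(
    spec: SimulationSpec,
    truth: Sequence[TruthInterval],
    genome_length: Optional[int] = None,
) -> SimGenome:
    """Random genome plus gene models consistent with the truth intervals.

    Requested motifs are planted at recorded positions (centre of each spike
    for ``in-spike``; random positions clear of all spikes for
    ``background``), and one gene TSS is placed ``tss_offset_bp`` downstream
    of each spike, alternating gene strands, for nearest-TSS mapping tests.
    """
    rng = _rng(spec, 2)
    if genome_length is None:
        approx = spec.n_probes * spec.spacing_bp + 2000
        if truth:
            approx = max(approx, max(iv.end_bp for iv in truth) + 2000)
        genome_length = approx
    for iv in truth:
        if iv.end_bp > genome_length:
            raise ValueError("truth interval outside the genome length")

    seq = rng.choice(_BASES, size=genome_length)
    plants: List[MotifPlant] = []
    for motif, where in spec.motif_plants:
        motif = motif.upper()
        mlen = len(motif)
        if where == "in-spike":
            sites = [
                (iv.start_bp + iv.end_bp) // 2 - mlen // 2 for iv in truth
            ]
        elif where == "background":
            sites = []
            for _ in range(max(1, len(truth))):
                for _try in range(1000):
                    p = int(rng.integers(1, genome_length - mlen + 1))
                    clear = all(
                        p + mlen - 1 < iv.start_bp - 100 or p > iv.end_bp + 100
                        for iv in truth
                    )
                    if clear:
                        sites.append(p)
                        break
        else:
            raise ValueError(f"unknown plant location: {where!r}")
        for p in sites:
            p = max(1, min(p, genome_length - mlen + 1))
            seq[p - 1 : p - 1 + mlen] = list(motif)
            plants.append(MotifPlant(motif, spec.chromosome, p, where))

    genes: List[GeneModel] = []
    for i, iv in enumerate(truth):
        strand = "+" if i % 2 == 0 else "-"
        tss = min(iv.end_bp + spec.tss_offset_bp, genome_length)
        genes.append(GeneModel(f"gene{i:03d}", spec.chromosome, strand, tss))

    return SimGenome(
        sequences={spec.chromosome: "".join(seq.tolist())},
        genes=genes,
        motif_plants=plants,
    )
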