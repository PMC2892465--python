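"""Cross-sample operations: common regions-of-interest and control subtraction.

Recurrence of a region across independent samples raises confidence that it
is real.  Regions from multiple samples are clustered by single linkage with
a base-pair radius: two regions link when the gap between them (negative if
they overlap, zero if they touch) is at most the radius.  The default radius
of zero therefore demands overlap or direct adjacency.  Clusters containing
regions from at least two distinct samples become common regions.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Mapping, Sequence, Tuple


@dataclass
class CommonRegion:
    """A cross-sample cluster: envelope coordinates plus member regions."""

    chromosome: str
    start_bp: int
    end_bp: int
    members: List  # regions with .sample_id
    n_samples: int

    @property
    def sample_ids(self) -> List[str]:
        return sorted({m.sample_id for m in self.members})


def _flatten(region_sets) -> List:
    if isinstance(region_sets, Mapping):
        out = []
        for sample_id, regions in region_sets.items():
            for r in regions:
                if getattr(r, "sample_id", "") != sample_id:
                    r = _with_sample(r, sample_id)
                out.append(r)
        return out
    return [r for regions in region_sets for r in regions]


def _with_sample(region, sample_id: str):
    import copy

    r = copy.copy(region)
    r.sample_id = sample_id
    return r


def gap_bp(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap between two 1-based inclusive intervals.

    Zero when they touch, negative when they overlap, positive otherwise.
    """
    if a_start > b_start:
        a_start, a_end, b_start, b_end = b_start, b_end, a_start, a_end
    return b_start - a_end - 1


def find_common_regions(region_sets, radius: int = 0) -> List[CommonRegion]:
    """Single-linkage clustering of per-sample regions within a bp radius.

    ``region_sets`` is either a mapping sample_id -> regions or an iterable
    of per-sample region collections (regions carry ``sample_id``).  Clusters
    whose members come from >= 2 distinct samples are returned as
    :class:`CommonRegion` with envelope = min start, max end.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    regions = _flatten(region_sets)
    regions.sort(key=lambda r: (r.chromosome, r.start_bp, r.end_bp, r.sample_id))

    out: List[CommonRegion] = []
    cluster: List = []
    cur_chrom, cur_end = None, None

    def close() -> None:
        if not cluster:
            return
        samples = {m.sample_id for m in cluster}
        if len(samples) >= 2:
            out.append(
                CommonRegion(
                    chromosome=cluster[0].chromosome,
                    start_bp=min(m.start_bp for m in cluster),
                    end_bp=max(m.end_bp for m in cluster),
                    members=list(cluster),
                    n_samples=len(samples),
                )
            )

    for r in regions:
        if (
            cur_chrom == r.chromosome
            and cur_end is not None
            and r.start_bp - cur_end - 1 <= radius
        ):
            cluster.append(r)
            cur_end = max(cur_end, r.end_bp)
        else:
            close()
            cluster = [r]
            cur_chrom, cur_end = r.chromosome, r.end_bp
    close()
    return out


def subtract_controls(
    case_region_sets: Sequence[Sequence],
    control_region_sets: Sequence[Sequence],
    radius: int = 0,
) -> List[List]:
    """Drop case regions lying within ``radius`` bp of any control region.

    Returns the case collections in their input structure with linked
    regions removed; provenance (sample_id) is untouched.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    controls: dict[str, List[Tuple[int, int]]] = {}
    for regions in control_region_sets:
        for r in regions:
            controls.setdefault(r.chromosome, []).append((r.start_bp, r.end_bp))
    for v in controls.values():
        v.sort()

    def linked(region) -> bool:
        for s, e in controls.get(region.chromosome, ()):
            if s > region.end_bp + radius + 1:
                break
            if gap_bp(region.start_bp, region.end_bp, s, e) <= radius:
                return True
        return False

    return [[r for r in regions if not linked(r)] for regions in case_region_sets]
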