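"""Collapse significant windows into regions-of-interest and score probes.

Windows surviving the per-threshold Bonferroni filter are merged in two
stages: first windows sharing at least one probe at the same threshold level
join into fragments, then fragments from all threshold levels join by the
same shared-probe rule into the final regions.  The join criterion is shared
probe indices, not bp overlap, which keeps merging independent of probe
spacing.  Each region carries a probe-significance profile Q(g): how often
each probe sat inside a significant window across all (threshold, width,
position) settings, normalized so the best-supported probe reads 1.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .detect import WindowTest
from .io import ProbeTrack


@dataclass
class RegionFragment:
    """A maximal set of probe-overlapping windows (intermediate merge unit)."""

    chromosome: str
    probe_start: int
    probe_end: int   # inclusive
    windows: List[WindowTest]
    t_indices: frozenset

    @property
    def min_p_adj(self) -> float:
        return min(w.p_adj for w in self.windows)


@dataclass
class Region:
    """A final region-of-interest.

    ``start_bp``/``end_bp`` are the genomic positions of the first and last
    member probe (1-based inclusive).  ``q_profile`` holds one score in
    [0, 1] per member probe; ``n_contributing`` counts the significant
    (threshold, width, position) windows that built the region.
    """

    chromosome: str
    start_bp: int
    end_bp: int
    probe_start: int
    probe_end: int
    positions: np.ndarray
    q_profile: np.ndarray
    min_p_adj: float
    n_contributing: int
    sample_id: str = ""
    t_indices: frozenset = field(default_factory=frozenset)
    windows: List[WindowTest] = field(default_factory=list)

    @property
    def n_probes(self) -> int:
        return self.probe_end - self.probe_start + 1

    def q_peak_position(self) -> int:
        """Genomic position of the probe with the highest significance score."""
        return int(self.positions[int(np.argmax(self.q_profile))])


def _merge_interval_items(
    items: Sequence[Tuple[str, int, int, List[WindowTest], frozenset]]
) -> List[RegionFragment]:
    """Single sweep merging items that share >= 1 probe index per chromosome."""
    out: List[RegionFragment] = []
    for chrom in sorted({it[0] for it in items}):
        rows = sorted(
            (it for it in items if it[0] == chrom), key=lambda it: (it[1], it[2])
        )
        cur: RegionFragment | None = None
        for _, s, e, ws, ts in rows:
            if cur is not None and s <= cur.probe_end:
                cur.probe_end = max(cur.probe_end, e)
                cur.windows.extend(ws)
                cur.t_indices = cur.t_indices | ts
            else:
                if cur is not None:
                    out.append(cur)
                cur = RegionFragment(chrom, s, e, list(ws), frozenset(ts))
        if cur is not None:
            out.append(cur)
    return out


def merge_windows_per_threshold(windows: Sequence[WindowTest]) -> List[RegionFragment]:
    """Join windows of one threshold level that share at least one probe.

    Adjacent but disjoint windows (no common probe index) stay separate;
    windows never join across chromosomes.
    """
    t_set = {w.t_index for w in windows}
    if len(t_set) > 1:
        raise ValueError("merge_windows_per_threshold expects a single threshold level")
    items = [
        (w.chromosome, w.g, w.g + w.N - 1, [w], frozenset({w.t_index}))
        for w in windows
    ]
    return _merge_interval_items(items)


def merge_across_thresholds(fragments: Sequence[RegionFragment]) -> List[RegionFragment]:
    """Apply the shared-probe join across fragments from all threshold levels."""
    items = [
        (f.chromosome, f.probe_start, f.probe_end, list(f.windows), f.t_indices)
        for f in fragments
    ]
    return _merge_interval_items(items)


def probe_significance(
    probe_start: int,
    probe_end: int,
    windows: Sequence[WindowTest],
    mode: str = "max",
) -> np.ndarray:
    """Per-probe significance profile Q(g) over [probe_start, probe_end].

    The raw score of a probe is the number of significant (threshold, width,
    position) windows covering it.  ``mode='max'`` (default) normalizes by the
    within-region maximum so the peak reads 1; ``mode='global'`` normalizes by
    the total number of contributing windows, giving the fraction of the
    region's windows covering each probe.
    """
    if mode not in ("max", "global"):
        raise ValueError(f"unknown q normalization mode: {mode!r}")
    n = probe_end - probe_start + 1
    diff = np.zeros(n + 1, dtype=np.int64)
    for w in windows:
        a = max(w.g, probe_start) - probe_start
        b = min(w.g + w.N - 1, probe_end) - probe_start
        if b >= a:
            diff[a] += 1
            diff[b + 1] -= 1
    counts = np.cumsum(diff[:-1]).astype(np.float64)
    denom = counts.max() if mode == "max" else float(len(windows))
    if denom <= 0:
        return np.zeros(n, dtype=np.float64)
    return counts / denom


def assemble_regions(
    track: ProbeTrack,
    windows: Sequence[WindowTest],
    sample_id: str | None = None,
    q_mode: str = "max",
) -> List[Region]:
    """Two-stage merge of significant windows into final scored regions."""
    if sample_id is None:
        sample_id = track.sample_id
    by_t: Dict[int, List[WindowTest]] = {}
    for w in windows:
        by_t.setdefault(w.t_index, []).append(w)
    fragments: List[RegionFragment] = []
    for t in sorted(by_t):
        fragments.extend(merge_windows_per_threshold(by_t[t]))
    merged = merge_across_thresholds(fragments)

    regions: List[Region] = []
    for frag in merged:
        pos = track.positions[frag.chromosome]
        q = probe_significance(frag.probe_start, frag.probe_end, frag.windows, q_mode)
        regions.append(
            Region(
                chromosome=frag.chromosome,
                start_bp=int(pos[frag.probe_start]),
                end_bp=int(pos[frag.probe_end]),
                probe_start=frag.probe_start,
                probe_end=frag.probe_end,
                positions=pos[frag.probe_start : frag.probe_end + 1].copy(),
                q_profile=q,
                min_p_adj=frag.min_p_adj,
                n_contributing=len(frag.windows),
                sample_id=sample_id,
                t_indices=frag.t_indices,
                windows=sorted(
                    frag.windows, key=lambda w: (w.t_index, w.g, w.N)
                ),
            )
        )
    regions.sort(key=lambda r: (r.chromosome, r.start_bp, r.end_bp))
    return regions
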