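"""Per-region graphical reports.

Panel A shows the probe intensities as lollipops with the probe-significance
curve Q(g) on a second axis, green strand-oriented bars for sequence hits
(upward = forward strand, downward = reverse) and arrows to flanking-gene
TSSs with their bp distances.  Panel B maps which (threshold, window-width)
settings produced a significant window overlapping the region.
"""
from __future__ import annotations

from typing import Optional, Sequence, Tuple

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .detect import WindowTest
from .io import ProbeTrack
from .merge import Region


def significance_grid(
    region: Region, windows: Optional[Sequence[WindowTest]] = None
) -> Tuple[Sequence[int], Sequence[int], np.ndarray]:
    """Binary (threshold, width) matrix of significant windows in the region."""
    ws = list(windows) if windows is not None else list(region.windows)
    ws = [
        w
        for w in ws
        if w.chromosome == region.chromosome
        and w.g <= region.probe_end
        and w.g + w.N - 1 >= region.probe_start
    ]
    ts = sorted({w.t_index for w in ws})
    ns = sorted({w.N for w in ws})
    grid = np.zeros((len(ts), len(ns)))
    ti = {t: i for i, t in enumerate(ts)}
    ni = {n: i for i, n in enumerate(ns)}
    for w in ws:
        grid[ti[w.t_index], ni[w.N]] = 1.0
    return ts, ns, grid


def plot_region(
    region: Region,
    track: ProbeTrack,
    hits: Sequence = (),
    genes: Sequence = (),
    grid: Optional[Tuple[Sequence[int], Sequence[int], np.ndarray]] = None,
    path: str = "region.png",
    context_probes: int = 10,
) -> str:
    """Render the two-panel region report to ``path`` and return the path."""
    chrom = region.chromosome
    pos = track.positions[chrom]
    lo = max(0, region.probe_start - context_probes)
    hi = min(pos.size - 1, region.probe_end + context_probes)
    xs = pos[lo : hi + 1]
    ys = track.intensities[chrom][lo : hi + 1]

    fig, (ax_a, ax_b) = plt.subplots(
        2, 1, figsize=(9, 7), gridspec_kw={"height_ratios": [2, 1]}
    )

    ax_a.stem(xs, ys, linefmt="C0-", markerfmt="C0o", basefmt="k-")
    ax_a.axvspan(region.start_bp, region.end_bp, color="gold", alpha=0.2, lw=0)
    ax_a.set_xlabel(f"{chrom} position (bp)")
    ax_a.set_ylabel("probe intensity")

    ax_q = ax_a.twinx()
    ax_q.plot(region.positions, region.q_profile, "r-", lw=2)
    ax_q.set_ylabel("probe-significance Q(g)", color="r")
    ax_q.set_ylim(-1.15, 1.05)

    # strand-oriented sequence bars on a lane below the Q curve
    for h in hits:
        base = -0.9
        tip = base + (0.15 if h.strand == "+" else -0.15)
        ax_q.plot([h.position, h.position], [base, tip], "g-", lw=3)

    span = max(1, region.end_bp - region.start_bp)
    for f in genes:
        x = region.start_bp - span // 4 if f.direction == "upstream" else region.end_bp + span // 4
        ax_a.annotate(
            f"{f.gene.gene_name} ({f.gene.strand}) {f.distance_bp} bp",
            xy=(x, float(np.max(ys)) if ys.size else 1.0),
            xytext=(x, float(np.max(ys)) * 1.1 if ys.size else 1.1),
            ha="center",
            fontsize=8,
            arrowprops={"arrowstyle": "->", "color": "0.3"},
        )

    if grid is None:
        grid = significance_grid(region)
    ts, ns, mat = grid
    if mat.size:
        ax_b.imshow(mat, aspect="auto", cmap="Blues", origin="lower", vmin=0, vmax=1)
        ax_b.set_xticks(range(len(ns)), [str(n) for n in ns], fontsize=7)
        ax_b.set_yticks(range(len(ts)), [str(t) for t in ts], fontsize=7)
    ax_b.set_xlabel("window width (probes)")
    ax_b.set_ylabel("threshold level")
    fig.suptitle(
        f"{chrom}:{region.start_bp}-{region.end_bp}  "
        f"({region.n_probes} probes, min adj. p = {region.min_p_adj:.3g})"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)
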