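"""The detection core: multi-threshold, multi-width hypergeometric window tests.

The method discretizes normalized intensities at a grid of thresholds ``t``.
At each threshold, the ``k(t)`` probes exceeding ``t`` are the positive
probes; a window of ``N`` consecutive probes containing ``x`` positives is
scored by the hypergeometric tail probability of drawing at least ``x``
positives in ``N`` draws from a chip of ``K`` probes carrying ``k(t)``
positives.  Because only windows containing at least one positive probe are
evaluated, that tail is conditioned on ``X >= 1``:

    p(g, t, N) = P(X >= x) / P(X >= 1),    X ~ Hypergeometric(K, k(t), N)

The family-wise error is controlled per threshold level with a Bonferroni
factor equal to the number of windows actually evaluated at that level.
Window width is measured in probes, so detection is independent of the local
probe spacing; the genomic span of a window is bounded only by the expected
fragment size of the assay.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Sequence, Tuple

import numpy as np
from scipy.stats import hypergeom

from .io import ProbeTrack

log = logging.getLogger("hat")


@dataclass(frozen=True)
class ThresholdLevel:
    """One discretization cut ``t`` with its chip-wide positive count ``k``."""

    t: float
    k: int
    index: int


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable detection parameters.

    alpha
        Significance level on Bonferroni-adjusted window p-values; the single
        statistical knob of the method.
    max_fragment_bp
        Maximum genomic span (first to last probe) of an evaluated window, in
        bp.  Set from the expected fragment size of the assay, e.g. 600 for
        sonicated ChIP material, 1000 for MeDIP fragments.
    n_thresholds
        Size of the threshold grid over positive intensities.
    threshold_grid
        ``rank-linear`` or ``rank-geometric`` placement of the grid over the
        ranks of the positive probes.
    min_k
        Smallest positive-probe count considered.  A level with k=1 can never
        yield x >= 2, and every x=1 window has conditional p = 1, so the
        default of 2 skips provably fruitless levels.
    """

    alpha: float = 0.05
    max_fragment_bp: int = 600
    n_thresholds: int = 20
    threshold_grid: str = "rank-linear"
    min_k: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.max_fragment_bp <= 0:
            raise ValueError("max_fragment_bp must be positive")
        if self.n_thresholds < 1:
            raise ValueError("n_thresholds must be >= 1")
        if self.threshold_grid not in ("rank-linear", "rank-geometric"):
            raise ValueError(f"unknown threshold grid: {self.threshold_grid!r}")
        if self.min_k < 1:
            raise ValueError("min_k must be >= 1")


@dataclass(frozen=True)
class WindowTest:
    """One evaluated window: position g, width N (probes), threshold, counts."""

    chromosome: str
    g: int              # start probe index (0-based within the chromosome)
    N: int              # window width in probes
    t_index: int
    x: int              # positive probes inside the window
    span_bp: int        # genomic distance first->last probe
    p_raw: float
    p_adj: float
    significant: bool


# ---------------------------------------------------------------------------
# Threshold enumeration
# ---------------------------------------------------------------------------

def enumerate_thresholds(track: ProbeTrack, config: DetectionConfig) -> List[ThresholdLevel]:
    """Place the threshold grid over the ranks of the positive intensities.

    Probes with intensity <= 0 are ignored (the normalized background).  The
    grid targets ``n_thresholds`` distinct values of k(t) spaced linearly or
    geometrically in rank; cuts are placed midway between adjacent order
    statistics so k(t) is well defined under ties, duplicate k values are
    collapsed, and levels with k < min_k are dropped.  Returned levels are
    ordered by increasing t (strictly decreasing k).
    """
    allv = track.all_intensities()
    pos = np.sort(allv[allv > 0.0])
    n_pos = int(pos.size)
    if n_pos == 0:
        log.warning("%s: no probes with positive intensity; no thresholds", track.sample_id)
        return []
    if config.min_k > n_pos:
        log.warning(
            "%s: only %d positive probes (< min_k=%d); no thresholds",
            track.sample_id, n_pos, config.min_k,
        )
        return []
    if config.threshold_grid == "rank-linear":
        targets = np.linspace(config.min_k, n_pos, config.n_thresholds)
    else:
        targets = np.geomspace(config.min_k, n_pos, config.n_thresholds)
    ks = np.unique(np.clip(np.rint(targets).astype(np.int64), config.min_k, n_pos))

    levels: List[Tuple[float, int]] = []
    seen_k: set[int] = set()
    for k_target in ks.tolist():
        v_k = pos[n_pos - k_target]  # k-th largest positive intensity
        lower = pos[n_pos - k_target - 1] if k_target < n_pos else 0.0
        t = 0.5 * (float(lower) + float(v_k))
        k_actual = int(np.count_nonzero(allv > t))
        if k_actual < config.min_k or k_actual in seen_k:
            continue
        seen_k.add(k_actual)
        levels.append((t, k_actual))
    levels.sort(key=lambda tk: tk[0])
    return [ThresholdLevel(t=t, k=k, index=i) for i, (t, k) in enumerate(levels)]


def positive_mask(track: ProbeTrack, level: ThresholdLevel) -> Dict[str, np.ndarray]:
    """Per-chromosome boolean calls: intensity strictly above the cut."""
    return {c: track.intensities[c] > level.t for c in track.positions}


# ---------------------------------------------------------------------------
# Window enumeration
# ---------------------------------------------------------------------------

def _window_arrays(
    positions: np.ndarray, mask: np.ndarray, max_fragment_bp: int
) -> Iterator[Tuple[int, np.ndarray, np.ndarray, np.ndarray]]:
    """Vectorized window sweep on one chromosome.

    Yields ``(N, g, x, span)`` arrays for every window width N with at least
    one eligible window (span within the fragment limit, >= 1 positive
    probe).  Spans grow with N for fixed g, so the sweep stops at the first
    width with no admissible window anywhere.
    """
    P = positions.size
    csum = np.concatenate(([0], np.cumsum(mask, dtype=np.int64)))
    for N in range(1, P + 1):
        span = positions[N - 1 :] - positions[: P - N + 1]
        ok = span <= max_fragment_bp
        if not ok.any():
            break
        x = csum[N:] - csum[: P - N + 1]
        elig = ok & (x >= 1)
        if elig.any():
            g = np.nonzero(elig)[0]
            yield N, g, x[elig], span[elig]


def enumerate_windows(
    track: ProbeTrack, mask: Dict[str, np.ndarray], config: DetectionConfig
) -> Iterator[Tuple[str, int, int, int, int]]:
    """Stream every evaluated window as ``(chromosome, g, N, x, span_bp)``.

    Windows contain N consecutive probes on one chromosome, hold at least one
    positive probe, and span at most ``max_fragment_bp``; for fixed g, N stops
    growing at the first width violating the span limit.
    """
    for chrom in track.chromosomes():
        positions = track.positions[chrom]
        m = mask[chrom]
        csum = np.concatenate(([0], np.cumsum(m, dtype=np.int64)))
        P = positions.size
        for g in range(P):
            for N in range(1, P - g + 1):
                span = int(positions[g + N - 1] - positions[g])
                if span > config.max_fragment_bp:
                    break
                x = int(csum[g + N] - csum[g])
                if x >= 1:
                    yield (chrom, g, N, x, span)


# ---------------------------------------------------------------------------
# Hypergeometric probabilities
# ---------------------------------------------------------------------------

def _validate_hg(x: int, N: int, k: int, K: int) -> None:
    if K < 0 or not (0 <= N <= K) or not (0 <= k <= K) or x < 0:
        raise ValueError(f"hypergeometric parameters out of range: x={x} N={N} k={k} K={K}")


def hypergeom_tail(x: int, N: int, k: int, K: int) -> float:
    """Upper tail P(X >= x) for X ~ Hypergeometric(population K, successes k, draws N).

    Computed in log space; exact 0/1 at the support boundaries.
    """
    _validate_hg(x, N, k, K)
    if x <= max(0, N + k - K):
        return 1.0
    if x > min(N, k):
        return 0.0
    return float(np.exp(hypergeom.logsf(x - 1, K, k, N)))


def conditional_pvalue(x: int, N: int, k: int, K: int) -> float:
    """The window p-value P(X >= x | X >= 1).

    Windows are only evaluated when they contain a positive probe, so the
    hypergeometric tail is renormalized by P(X >= 1) = 1 - C(K-k, N)/C(K, N).
    x = 1 yields exactly 1; x = 0 is rejected (such windows are never tested).
    """
    if x < 1:
        raise ValueError("conditional p-value requires x >= 1")
    if N < 1 or k < 1:
        raise ValueError("conditional p-value requires N >= 1 and k >= 1")
    _validate_hg(x, N, k, K)
    if x == 1:
        return 1.0
    if x > min(N, k):
        return 0.0
    log_num = hypergeom.logsf(x - 1, K, k, N)
    log_den = hypergeom.logsf(0, K, k, N)
    if not np.isfinite(log_den):  # P(X >= 1) = 0: vacuous by convention
        return 1.0
    return float(min(1.0, np.exp(log_num - log_den)))


def _conditional_pvalues_vec(xs: np.ndarray, N: int, k: int, K: int) -> np.ndarray:
    """Vectorized conditional p-values for an array of x at fixed (N, k, K)."""
    xs = np.asarray(xs, dtype=np.int64)
    out = np.zeros(xs.shape, dtype=np.float64)
    upper = min(N, k)
    log_den = hypergeom.logsf(0, K, k, N)
    if not np.isfinite(log_den):
        return np.ones_like(out)
    inside = (xs >= 2) & (xs <= upper)
    if inside.any():
        log_num = hypergeom.logsf(xs[inside] - 1, K, k, N)
        out[inside] = np.minimum(1.0, np.exp(log_num - log_den))
    out[xs <= max(1, N + k - K)] = 1.0
    out[xs == 1] = 1.0
    return out


def bonferroni_adjust(p_raw: float, m: int) -> float:
    """Family-wise adjustment: min(1, m * p) with m tests at one threshold."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p_raw)


# ---------------------------------------------------------------------------
# Significant-window detection
# ---------------------------------------------------------------------------

def detect_significant_windows(
    track: ProbeTrack, config: DetectionConfig
) -> List[WindowTest]:
    """Run the full threshold x width scan and keep windows with p_adj <= alpha.

    For every threshold level: windows are enumerated, conditional p-values
    computed, the Bonferroni factor m set to the number of windows evaluated
    at that level, and windows with adjusted p <= alpha retained.  Fully
    deterministic given identical input and configuration.
    """
    levels = enumerate_thresholds(track, config)
    K = track.K
    results: List[WindowTest] = []
    for level in levels:
        masks = positive_mask(track, level)
        batches = []  # (chrom, N, g, x, span)
        m = 0
        for chrom in track.chromosomes():
            for N, g, x, span in _window_arrays(
                track.positions[chrom], masks[chrom], config.max_fragment_bp
            ):
                batches.append((chrom, N, g, x, span))
                m += int(g.size)
        n_sig = 0
        if m > 0:
            for chrom, N, g, x, span in batches:
                ux = np.unique(x)
                praw_u = _conditional_pvalues_vec(ux, N, level.k, K)
                padj_u = np.minimum(1.0, m * praw_u)
                sig_u = padj_u <= config.alpha
                if not sig_u.any():
                    continue
                ix = np.searchsorted(ux, x)
                take = sig_u[ix]
                for gi, xi, si, ii in zip(
                    g[take].tolist(), x[take].tolist(), span[take].tolist(), ix[take].tolist()
                ):
                    results.append(
                        WindowTest(
                            chromosome=chrom,
                            g=gi,
                            N=N,
                            t_index=level.index,
                            x=xi,
                            span_bp=si,
                            p_raw=float(praw_u[ii]),
                            p_adj=float(padj_u[ii]),
                            significant=True,
                        )
                    )
                    n_sig += 1
        log.info(
            "%s: threshold %d (t=%.4g, k=%d): m=%d windows, %d significant",
            track.sample_id, level.index, level.t, level.k, m, n_sig,
        )
    results.sort(key=lambda w: (w.t_index, w.chromosome, w.g, w.N))
    return results
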