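# Methods

## Model and procedure

Detection treats a tiling array as a finite population of `K` probes. After
normalization the intensities are approximately normal with a negative
median, so background probes lie at or below zero and only probes with
positive intensity can support a region call.

For a discretization threshold `t`, the `k(t)` probes with intensity
strictly above `t` are *positive*. Under the null hypothesis that positive
probes are an exchangeable random subset of the chip — which holds exactly
when background intensities are i.i.d., since only their ranks matter — the
number `X` of positive probes in any fixed window of `N` consecutive probes
is hypergeometric with population `K`, successes `k(t)`, draws `N`. Because
only windows already containing a positive probe are tested, the window
p-value is the tail conditioned on that selection event:

    p(g, t, N) = P(X >= x(g,t,N)) / P(X >= 1),
    P(X >= 1) = 1 - C(K-k, N) / C(K, N).

`x = 1` gives p = 1 exactly, so single-positive windows can never drive a
call; `x = 0` windows are never evaluated.

The scan varies both `t` (so no single intensity cut-off is imposed) and `N`
(so regions of any probe count can be found). Window width is counted in
probes, never in bp, which makes the statistic independent of local probe
spacing; the only genomic constraint is that a window's span (first to last
probe) must not exceed the expected fragment size of the assay. Windows never
cross chromosome boundaries, while `K` and `k(t)` remain chip-wide.

Per threshold level, every evaluated window's p-value is Bonferroni-adjusted
by `m`, the number of windows actually evaluated at that level (those with
`x >= 1` and span within the limit): `p_adj = min(1, m * p)`. Windows with
`p_adj <= alpha` are kept. Keeping `m` per level, rather than pooling levels,
controls the family-wise error at each threshold; the thresholds are heavily
dependent (they are nested discretizations of the same data), and the
adjusted p-values are strongly conservative in practice — the measured null
family-wise rate at `alpha = 0.05` is about 0.01 (see
`scripts/acceptance.py`).

Significant windows merge in two stages, both using the same rule — two
units join when they share at least one probe index: first windows within a
threshold level, then fragments across levels. Adjacent-but-disjoint windows
do not join; merging is idempotent and independent of input order (property
tested). Final regions therefore tend to be wider than any single-setting
call. Each region records a probe-significance profile `Q(g)`: the number of
significant (threshold, width, position) windows covering each probe. By
default `Q` is normalized by its within-region maximum so the best-supported
probe reads 1.0; a `global` mode divides by the region's total contributing
window count instead (the exact normalization constant is a free choice; both
are exposed, `max` is the default because it makes profiles comparable across
regions of very different support).

Common regions across samples use single-linkage clustering: two regions
link when the gap between them is at most `radius` bp, where the gap of
1-based inclusive intervals is `later.start - earlier.end - 1` (0 when
touching, negative when overlapping). The default radius 0 therefore demands
overlap or direct adjacency. A cluster is *common* when it contains regions
from at least two distinct samples. Control subtraction removes any case
region linking to any control region under the same gap rule. Single linkage
is the weakest relation consistent with a "maximum distance" radius; it
coarsens monotonically as the radius grows.

Annotation is exact-match sequence scanning (region plus optional flank,
clipped at chromosome ends): the motif on the forward sequence reports a `+`
hit, its reverse complement a `-` hit, overlapping matches included,
positions always in forward coordinates. Palindromic motifs (GATC) yield
paired hits at identical positions. Motifs are restricted to unambiguous
A/C/G/T strings; IUPAC degeneracy and PWM scanning are out of scope.
Nearest-TSS mapping returns up to four genes — nearest upstream and
downstream in chromosome coordinates, separately for + and − strand genes —
with distance measured from the nearer region boundary (0 when the TSS lies
inside the region; an interior TSS is assigned to the side of its nearer
boundary), a per-direction cap of 300 kb by default, and lexicographic
gene-name tie-breaking.

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| `alpha` | 0.05 | — | the single required statistical parameter; 1e-5 suits deep ChIP comparisons, 0.05 broader surveys |
| `max_fragment_bp` | 600 | bp | expected fragment size: ~600 for sonicated ChIP material, ~1000 for MeDIP fragments |
| `n_thresholds` | 20 | — | grid size over positive intensities; more levels cost linearly and add little once k(t) values collapse |
| `threshold_grid` | rank-linear | — | thresholds placed at rank quantiles of the positive intensities (scale-free); rank-geometric concentrates levels at the high tail |
| `min_k` | 2 | probes | levels with k=1 cannot produce x ≥ 2 and every x=1 window has p = 1, so skipping them is a provable no-op |
| `normalize.shift` | 0.5 | robust σ | output median is exactly −shift; 0.5 puts ~69% of near-normal probes below zero |
| `radius` | 0 | bp | cross-sample linkage distance |
| `max_tss_distance_bp` | 300000 | bp | per-direction cap for nearest-TSS reporting |
| `flank_bp` | 0 | bp | extra sequence scanned around each region |

Threshold placement details: candidate `k` targets are spaced (linearly or
geometrically) over the ranks of the positive intensities; each cut is placed
midway between adjacent order statistics so `k(t)` is well defined under tied
intensities, positivity is strict (`intensity > t`), realized duplicate `k`
values are collapsed, and levels below `min_k` are dropped.

## Normalization

Array-platform normalization models that use probe sequence composition are
deliberately not implemented; the detection statistic needs only the shape of
its input — finite intensities whose majority sits below zero. The built-in
`robust-z-shift` mode produces that regime from raw intensities:
`(x - median) / (1.4826 * MAD) - shift`, pooled across chromosomes per
sample. It is invariant to positive affine rescaling of the input, exact on
the output median, and refuses constant input (zero MAD) with a pointer to
`passthrough`. Users with upstream-normalized tracks should use
`passthrough`, which is bit-identical.

## Synthetic data

The fixture generator emulates the study conditions the detector is designed
for: ~35 bp mean probe spacing (fixed, jittered ±40%, or mixed-resolution
with 25/50 bp modes), i.i.d. N(−0.5, 1) background on the normalized scale
(~31% positive probes), and non-overlapping enriched fragments of configurable
width with an additive effect, placed with a 2 kb minimum separation so truth
intervals stay unambiguous. Optional genome generation plants exact motif
copies (in-spike at fragment centres, or in background clear of all
fragments) and one gene TSS at a fixed offset (default 500 bp) downstream of
each fragment. Everything derives from `(spec, seed)` and is bit-reproducible.

Not emulated: probe-sequence hybridization bias, spatial artifacts,
correlated replicate noise, copy-number structure, and fragment-edge smear
(available as an option, off by default so truth stays crisp). Passing tests
on these fixtures therefore demonstrate the statistical machinery —
error control under exchangeable background, recovery of additive
enrichments, coordinate bookkeeping — not robustness to platform-specific
artifacts, which upstream normalization must remove.

## Numerical choices

- Hypergeometric tails are computed in log space (`scipy` `logsf`) and
  exponentiated after the conditional subtraction; support boundaries return
  exact 0/1. Agreement with an exact rational enumeration oracle is 1e-12
  over the full lattice K ≤ 30.
- Conditional p-values are set to exactly 1.0 at x = 1 rather than relying on
  floating-point cancellation.
- `p_adj = min(1, m·p)`; degenerate inputs (no positive probes, k < min_k)
  yield an empty threshold set and a clean zero-region result.
- The vectorized window sweep and the streaming reference enumerator are
  cross-checked for set equality in the tests.
- Detection contains no randomness; repeated runs are bit-identical, and
  scaling all positions and the fragment limit by the same factor reproduces
  the identical window set in probe-index space.

## Problem sizes used in tests

The statistical tests run on 10,000-probe single-chromosome tracks (the
pipeline itself is linear in probes × widths × thresholds and handles
chromosome-partitioned chips of any size): 200 null replicates for the
family-wise error measurement, 50 spiked replicates (ten 600 bp fragments at
+4σ each) for recovery, and 1,000 randomized window sets for the merge
algebra. The acceptance script uses 100 null and 20 spiked replicates.

## Known limitations

- Bonferroni is applied per threshold level; the union over levels is not
  separately corrected. Empirically the null family-wise rate stays well
  under α because the levels are nested views of the same ranks, but the
  per-level guarantee is the formal one.
- The exchangeability null ignores spatial autocorrelation of background
  noise; strongly autocorrelated background would inflate detections and
  should be handled in normalization.
- Sequence scanning is exact-match only; no motif-enrichment statistics over
  region sets are computed.
- Binary array formats (CEL/BPMAP) are not parsed — tracks are exchanged as
  bedGraph, fixedStep WIG, or plain TSV text.
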