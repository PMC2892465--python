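import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hypergeom_oracle import conditional_exact, tail_exact

from hat.detect import (
    DetectionConfig,
    bonferroni_adjust,
    conditional_pvalue,
    detect_significant_windows,
    enumerate_thresholds,
    enumerate_windows,
    hypergeom_tail,
    positive_mask,
)
from hat.io import ProbeTrack
from hat.simulate import SimulationSpec, generate_null_track


class TestEnumerateThresholds:
    def test_two_levels_on_three_positive_probes(self, tiny_track):
        # positives {3, 2, 1}; rank-linear with n=2, min_k=2 -> k in {2, 3}
        cfg = DetectionConfig(n_thresholds=2, min_k=2)
        levels = enumerate_thresholds(tiny_track, cfg)
        assert [l.k for l in levels] == [3, 2]
        assert levels[0].t < levels[1].t

    def test_all_negative_intensities_yield_no_thresholds(self):
        t = ProbeTrack(
            "neg", {"chr1": np.array([1, 36])}, {"chr1": np.array([-1.0, -2.0])}
        )
        assert enumerate_thresholds(t, DetectionConfig()) == []

    def test_more_thresholds_than_positives_collapse(self, tiny_track):
        cfg = DetectionConfig(n_thresholds=10, min_k=1)
        levels = enumerate_thresholds(tiny_track, cfg)
        assert sorted(l.k for l in levels) == [1, 2, 3]

    def test_k_strictly_decreasing_in_t(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(-0.5, 1.0, size=2000)
        t = ProbeTrack("r", {"chr1": np.arange(1, 2001) * 35}, {"chr1": vals})
        levels = enumerate_thresholds(t, DetectionConfig(n_thresholds=15))
        ts = [l.t for l in levels]
        ks = [l.k for l in levels]
        assert ts == sorted(ts)
        assert all(a > b for a, b in zip(ks, ks[1:]))
        # k is the count of probes strictly above t
        for l in levels:
            assert l.k == int(np.count_nonzero(vals > l.t))

    def test_geometric_grid_accepted(self, tiny_track):
        levels = enumerate_thresholds(
            tiny_track, DetectionConfig(n_thresholds=3, threshold_grid="rank-geometric")
        )
        assert levels and all(l.k >= 2 for l in levels)


class TestPositiveMask:
    def test_mask_between_order_statistics(self, tiny_track):
        cfg = DetectionConfig(n_thresholds=2, min_k=2)
        level_k2 = enumerate_thresholds(tiny_track, cfg)[1]
        mask = positive_mask(tiny_track, level_k2)
        assert mask["chr1"].tolist() == [True, True, False, False, False]

    def test_mask_sum_equals_k(self, tiny_track):
        for level in enumerate_thresholds(tiny_track, DetectionConfig(min_k=1)):
            mask = positive_mask(tiny_track, level)
            assert sum(int(m.sum()) for m in mask.values()) == level.k


class TestEnumerateWindows:
    def test_span_limit_excludes_wide_windows(self, three_probe_track):
        # probes 0/50/100 bp apart, limit 60 bp: widths 1-2 only, no N=3
        cfg = DetectionConfig(max_fragment_bp=60, min_k=1)
        mask = {"chr1": np.array([True, True, True])}
        ws = list(enumerate_windows(three_probe_track, mask, cfg))
        assert ws == [
            ("chr1", 0, 1, 1, 0),
            ("chr1", 0, 2, 2, 50),
            ("chr1", 1, 1, 1, 0),
            ("chr1", 1, 2, 2, 50),
            ("chr1", 2, 1, 1, 0),
        ]

    def test_all_zero_mask_yields_nothing(self, three_probe_track):
        mask = {"chr1": np.zeros(3, dtype=bool)}
        assert list(enumerate_windows(three_probe_track, mask, DetectionConfig())) == []

    def test_single_positive_probe(self, three_probe_track):
        mask = {"chr1": np.array([False, True, False])}
        cfg = DetectionConfig(max_fragment_bp=60)
        ws = list(enumerate_windows(three_probe_track, mask, cfg))
        # every window containing the middle probe, all with x=1
        assert all(x == 1 for (_, _, _, x, _) in ws)
        assert ("chr1", 1, 1, 1, 0) in ws
        assert ("chr1", 0, 2, 1, 50) in ws and ("chr1", 1, 2, 1, 50) in ws

    def test_windows_never_span_chromosomes(self):
        t = ProbeTrack(
            "two",
            {"chr1": np.array([1, 31]), "chr2": np.array([1, 31])},
            {"chr1": np.array([1.0, 1.0]), "chr2": np.array([1.0, 1.0])},
        )
        mask = {c: np.array([True, True]) for c in ("chr1", "chr2")}
        ws = list(enumerate_windows(t, mask, DetectionConfig(max_fragment_bp=1000)))
        assert max(N for (_, _, N, _, _) in ws) == 2  # never 3 or 4


class TestHypergeomTail:
    def test_whole_support_is_one(self):
        assert hypergeom_tail(0, 3, 4, 8) == 1.0

    def test_worked_value_half(self):
        # exact enumeration over all C(8,3)=56 draws gives 28/56
        assert hypergeom_tail(2, 3, 4, 8) == pytest.approx(0.5, abs=1e-12)

    def test_outside_support_is_zero(self):
        assert hypergeom_tail(4, 3, 4, 8) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_tail(1, 9, 4, 8)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.data())
    def test_matches_exact_enumeration(self, data):
        K = data.draw(st.integers(1, 30))
        N = data.draw(st.integers(0, K))
        k = data.draw(st.integers(0, K))
        x = data.draw(st.integers(0, min(N, k) + 1))
        assert hypergeom_tail(x, N, k, K) == pytest.approx(
            float(tail_exact(x, N, k, K)), abs=1e-12
        )


class TestConditionalPvalue:
    def test_x_equals_one_is_exactly_one(self):
        assert conditional_pvalue(1, 5, 3, 20) == 1.0

    def test_worked_value_seven_thirteenths(self):
        # 0.5 / (13/14), both factors by exact enumeration
        assert conditional_pvalue(2, 3, 4, 8) == pytest.approx(7 / 13, abs=1e-12)

    def test_drawing_whole_chip_guarantees_all_positives(self):
        assert conditional_pvalue(4, 8, 4, 8) == pytest.approx(1.0, abs=1e-12)

    def test_x_zero_rejected(self):
        with pytest.raises(ValueError):
            conditional_pvalue(0, 3, 4, 8)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.data())
    def test_monotone_nonincreasing_in_x(self, data):
        K = data.draw(st.integers(2, 60))
        N = data.draw(st.integers(1, K))
        k = data.draw(st.integers(1, K))
        ps = [conditional_pvalue(x, N, k, K) for x in range(1, min(N, k) + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,m,expected",
        [(1e-7, 1000, 1e-4), (0.5, 10, 1.0), (0.123, 1, 0.123)],
    )
    def test_adjustment(self, p, m, expected):
        assert bonferroni_adjust(p, m) == pytest.approx(expected)

    def test_m_must_be_positive(self):
        with pytest.raises(ValueError):
            bonferroni_adjust(0.1, 0)


class TestDetectSignificantWindows:
    def test_alpha_one_returns_every_evaluated_window(self, tiny_track):
        cfg = DetectionConfig(alpha=1.0, max_fragment_bp=600, min_k=2, n_thresholds=2)
        ws = detect_significant_windows(tiny_track, cfg)
        total = 0
        for level in enumerate_thresholds(tiny_track, cfg):
            mask = positive_mask(tiny_track, level)
            total += sum(1 for _ in enumerate_windows(tiny_track, mask, cfg))
        assert len(ws) == total

    def test_agrees_with_streaming_enumeration(self):
        """The vectorized scan must evaluate exactly the streamed window set."""
        rng = np.random.default_rng(11)
        vals = rng.normal(-0.5, 1.0, size=400)
        pos = np.cumsum(rng.integers(25, 51, size=400)) + 1
        t = ProbeTrack("s", {"chr1": pos}, {"chr1": vals})
        cfg = DetectionConfig(alpha=1.0, max_fragment_bp=300, n_thresholds=5)
        fast = {
            (w.t_index, w.chromosome, w.g, w.N, w.x, w.span_bp)
            for w in detect_significant_windows(t, cfg)
        }
        slow = set()
        for level in enumerate_thresholds(t, cfg):
            mask = positive_mask(t, level)
            for chrom, g, N, x, span in enumerate_windows(t, mask, cfg):
                slow.add((level.index, chrom, g, N, x, span))
        assert fast == slow

    def test_spike_yields_significant_windows_over_it(self, spiked_fixture):
        _, track, truth = spiked_fixture
        ws = detect_significant_windows(track, DetectionConfig(alpha=0.05, max_fragment_bp=600))
        assert ws
        pos = track.positions["chr1"]
        for iv in truth:
            covered = any(
                pos[w.g] <= iv.end_bp and pos[w.g + w.N - 1] >= iv.start_bp
                for w in ws
            )
            assert covered, f"no significant window over {iv}"

    def test_detection_is_deterministic(self):
        spec = SimulationSpec(n_probes=1500, seed=3)
        t = generate_null_track(spec)
        cfg = DetectionConfig(alpha=1.0, max_fragment_bp=300, n_thresholds=5)
        assert detect_significant_windows(t, cfg) == detect_significant_windows(t, cfg)

    def test_resolution_independence_under_position_scaling(self):
        rng = np.random.default_rng(23)
        vals = rng.normal(-0.5, 1.0, size=800)
        pos = np.cumsum(rng.integers(25, 51, size=800)) + 1
        t1 = ProbeTrack("s", {"chr1": pos}, {"chr1": vals})
        t3 = ProbeTrack("s", {"chr1": pos * 3}, {"chr1": vals})
        w1 = detect_significant_windows(t1, DetectionConfig(alpha=0.5, max_fragment_bp=600))
        w3 = detect_significant_windows(t3, DetectionConfig(alpha=0.5, max_fragment_bp=1800))
        key = lambda ws: [(w.t_index, w.chromosome, w.g, w.N, w.x, w.p_adj) for w in ws]
        assert key(w1) == key(w3)
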