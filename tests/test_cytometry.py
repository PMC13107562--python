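"""Gating, copy-number classification, CNV-loss phase statistics, and
ploidy-normalized depth tracks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cnvrevert.cytometry import (
    DepthTrack,
    PhaseTimes,
    build_gates,
    classify_cells,
    compare_phase_times,
    phase_times,
    pncn_track,
    read_bedgraph,
    write_bedgraph,
)
from cnvrevert.synth import FlowGeneratorSpec, default_controls, gen_flow_sample


class TestGates:
    def test_nonoverlapping_uniform_controls(self):
        rng = np.random.default_rng(0)
        controls = {
            0: rng.uniform(0, 1, 5000),
            1: rng.uniform(2, 3, 5000),
            2: rng.uniform(4, 5, 5000),
        }
        gates = build_gates(controls, containment=0.95)
        b01, b12 = gates.boundaries
        # central 95% quantile intervals of U(0,1)/U(2,3)/U(4,5) leave gaps
        # with midpoints at 1.5 and 3.5
        assert b01 == pytest.approx(1.5, abs=0.05)
        assert b12 == pytest.approx(3.5, abs=0.05)
        assert all(v == 1.0 for v in gates.achieved_containment.values())

    def test_overlapping_gaussian_controls_hit_target(self):
        # ~5% overlap at the 2.5% tails: achieved containment stays >= 0.95
        rng = np.random.default_rng(1)
        controls = {
            0: np.exp(rng.normal(np.log(0.05), 0.18, 10_000)),
            1: np.exp(rng.normal(0.0, 0.18, 10_000)),
            2: np.exp(rng.normal(np.log(2.0), 0.18, 10_000)),
        }
        gates = build_gates(controls, containment=0.95)
        for k in (0, 1, 2):
            assert gates.achieved_containment[k] >= 0.95

    def test_unordered_medians_rejected(self):
        rng = np.random.default_rng(2)
        same = rng.lognormal(0, 0.1, 1000)
        with pytest.raises(ValueError, match="ordered"):
            build_gates({0: same, 1: same * 0.1, 2: same * 2}, containment=0.95)

    def test_degenerate_identical_controls_rejected(self):
        rng = np.random.default_rng(3)
        one = rng.lognormal(0, 0.1, 1000)
        with pytest.raises(ValueError):
            build_gates({0: one * 0.01, 1: one, 2: one}, containment=0.95)


@pytest.fixture(scope="module")
def gates():
    rng = np.random.default_rng(4)
    return build_gates(default_controls(rng), containment=0.95)


class TestClassify:
    def test_all_cells_in_top_gate(self, gates):
        f = classify_cells(np.full(100, gates.boundaries[1] * 10), gates)
        assert np.allclose(f, [0, 0, 1])

    def test_fractions_partition(self, gates):
        rng = np.random.default_rng(5)
        f = classify_cells(rng.lognormal(0, 1, 10_000), gates)
        assert f.sum() == pytest.approx(1.0, abs=1e-12)

    def test_mixture_recovered_within_misclassification(self, gates):
        # 50:50 one-/two-copy mixture: 2+ fraction within +-5% of 0.5
        rng = np.random.default_rng(6)
        spec = FlowGeneratorSpec(weights=(0.0, 0.5, 0.5))
        values, _ = gen_flow_sample(spec, rng)
        f = classify_cells(values, gates)
        assert 0.45 <= f[2] <= 0.55

    def test_empty_sample(self, gates):
        with pytest.raises(ValueError, match="empty"):
            classify_cells([], gates)


class TestPhaseTimes:
    def test_linear_interpolation(self):
        pt = phase_times([0, 12], [100.0, 70.0])
        assert pt.early == pytest.approx(10.0, abs=1e-12)

    def test_never_lost_is_censored(self):
        pt = phase_times([0, 100, 220], [100, 99, 98])
        assert np.isnan(pt.early) and np.isnan(pt.middle) and np.isnan(pt.late)
        assert pt.horizon == 220
        assert np.allclose(pt.values_at_horizon(), 220)

    def test_exact_boundary_hit(self):
        pt = phase_times([0, 36, 60], [100.0, 75.0, 10.0])
        assert pt.early == pytest.approx(36.0)

    @given(
        drops=st.lists(st.floats(0.0, 12.0), min_size=4, max_size=18),
    )
    @settings(max_examples=100, deadline=None)
    def test_phase_ordering(self, drops):
        """early <= middle <= late whenever all three are observed."""
        pct = np.maximum(100 - np.cumsum([0.0] + drops), 0.0)
        gens = np.arange(len(pct)) * 12
        pt = phase_times(gens, pct)
        vals = [pt.early, pt.middle, pt.late]
        seen = [v for v in vals if not np.isnan(v)]
        assert seen == sorted(seen)


class TestComparePhases:
    def mk(self, e, m, l, horizon=220.0):
        return PhaseTimes(e, m, l, horizon)

    def test_identical_groups(self):
        grp = [self.mk(10, 20, 30), self.mk(15, 25, 40), self.mk(12, 22, 33)]
        out = compare_phase_times(grp, list(grp))
        assert np.allclose(out["t_statistic"], 0.0)
        assert np.allclose(out["p_value"], 1.0)

    def test_constant_difference_degenerate(self):
        a = [self.mk(10, 20, 30), self.mk(20, 30, 40)]
        b = [self.mk(15, 25, 35), self.mk(25, 35, 45)]
        out = compare_phase_times(a, b)
        assert np.all(out["p_value"] < 1e-12)

    def test_censored_enter_at_horizon(self):
        a = [self.mk(10, 20, np.nan), self.mk(12, 25, np.nan)]
        b = [self.mk(50, 90, 150), self.mk(60, 100, 160)]
        out = compare_phase_times(a, b).set_index("phase")
        assert out.loc["late", "median_a"] == 220.0
        assert out.loc["late", "n_censored_a"] == 2

    def test_unpaired_groups_rejected(self):
        with pytest.raises(ValueError, match="unpaired"):
            compare_phase_times([self.mk(1, 2, 3)], [])

    def test_power_against_known_difference(self):
        # mean shift 30 generations, SD 10, 13 pairs: rejection at 5% in
        # >= 99% of simulations (noncentrality ~ 10.8)
        rng = np.random.default_rng(7)
        reject = 0
        n_sim = 1000
        for _ in range(n_sim):
            base = rng.uniform(20, 120, size=13)
            a = base + rng.normal(0, 10 / np.sqrt(2), 13)
            b = base + 30 + rng.normal(0, 10 / np.sqrt(2), 13)
            p = stats.ttest_rel(a, b).pvalue
            ga = [self.mk(x, x + 1, x + 2) for x in a]
            gb = [self.mk(x, x + 1, x + 2) for x in b]
            out = compare_phase_times(ga, gb).set_index("phase")
            assert out.loc["early", "p_value"] == pytest.approx(p, rel=1e-9)
            reject += out.loc["early", "p_value"] < 0.05
        assert reject / n_sim >= 0.99


class TestPNCN:
    def test_uniform_depth_is_one(self):
        track = DepthTrack({"chrI": np.full(5000, 37.0)})
        out = pncn_track(track, window=1000)
        assert np.allclose(out["pncn"], 1.0, atol=1e-12)

    def test_amplified_segment_recovered(self):
        # 3x segment over Poisson depth 50: window PNCN within +-0.1 of 3
        rng = np.random.default_rng(8)
        n = 300_000
        lam = np.full(n, 50.0)
        lam[100_000:235_000] *= 3  # 135 kb amplification
        depth = rng.poisson(lam).astype(float)
        out = pncn_track(DepthTrack({"chrXI": depth}), window=5000)
        inside = out[(out["start"] >= 100_000) & (out["end"] <= 235_000)]
        expected = 3 * 50 / depth.mean()
        assert np.allclose(inside["pncn"], expected, atol=0.1)

    def test_zero_depth_segment(self):
        depth = np.full(2000, 20.0)
        depth[500:1000] = 0.0
        out = pncn_track(DepthTrack({"c": depth}), window=500)
        assert out.iloc[1]["pncn"] == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        depth = rng.poisson(30, 4000).astype(float)
        a = pncn_track(DepthTrack({"c": depth}), window=1000)
        b = pncn_track(DepthTrack({"c": depth * 7.3}), window=1000)
        assert np.allclose(a["pncn"], b["pncn"], atol=1e-12)

    def test_oversized_window_warns(self):
        with pytest.warns(UserWarning, match="whole-chromosome"):
            out = pncn_track(DepthTrack({"c": np.full(100, 5.0)}), window=1000)
        assert len(out) == 1

    def test_bedgraph_roundtrip(self, tmp_path):
        track = DepthTrack({"chrXI": np.full(3000, 10.0)})
        out = pncn_track(track, window=1000)
        path = tmp_path / "pncn.bedgraph"
        write_bedgraph(path, out)
        back = read_bedgraph(path)
        assert np.allclose(back["value"], out["pncn"])
        assert list(back["start"]) == [0, 1000, 2000]
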