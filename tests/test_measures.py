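import numpy as np
import pandas as pd
import pytest

from spinepath import CentroidSpine, Timepoint, ValidationError
from spinepath.measures import (
    balance_offsets,
    compare_clusters,
    measure_spine,
    tangent_angle_measure,
)

from conftest import straight_spine_coords


def _arc_spine(total_angle_deg=60.0, radius=400.0, plane="frontal"):
    """17 points on a circular arc whose tangent direction (from vertical)
    sweeps symmetrically from +angle/2 to -angle/2: analytic tangent-angle
    spread equals total_angle_deg."""
    half = np.radians(total_angle_deg) / 2
    phi = np.linspace(half, -half, 17)  # tangent angle at each point
    z = radius * np.sin(phi)
    offset = radius * (1 - np.cos(phi))
    coords = np.zeros((17, 3))
    coords[:, 2] = z - z[-1]
    coords[:, 0 if plane == "frontal" else 1] = offset
    return CentroidSpine("arc", Timepoint.PO, coords)


class TestTangentAngle:
    def test_straight_spine_is_zero(self):
        spine = CentroidSpine("p", Timepoint.PO, straight_spine_coords())
        assert tangent_angle_measure(spine, "frontal", ("T1", "L5")) == 0.0
        assert tangent_angle_measure(spine, "sagittal", ("T1", "L5")) == 0.0

    @pytest.mark.parametrize("angle", [30.0, 60.0])
    @pytest.mark.parametrize("plane", ["frontal", "sagittal"])
    def test_circular_arc_recovers_subtended_angle(self, angle, plane):
        # tangents are estimated by finite differences, so allow a small
        # discretization error relative to the analytic 60 degrees
        spine = _arc_spine(angle, plane=plane)
        measured = tangent_angle_measure(spine, plane, ("T1", "L5"))
        assert measured == pytest.approx(angle, abs=0.3)

    def test_scale_invariance(self, rng):
        coords = straight_spine_coords()
        coords[:, 0] = rng.normal(0, 20, 17)
        spine = CentroidSpine("p", Timepoint.PO, coords)
        big = CentroidSpine("p", Timepoint.PO, coords * 7.5)
        a = tangent_angle_measure(spine, "frontal", ("T5", "T12"))
        b = tangent_angle_measure(big, "frontal", ("T5", "T12"))
        assert a == pytest.approx(b, abs=1e-10)

    def test_translation_invariance(self, rng):
        coords = straight_spine_coords()
        coords[:, 1] = rng.normal(0, 20, 17)
        spine = CentroidSpine("p", Timepoint.PO, coords)
        moved = CentroidSpine("p", Timepoint.PO, coords + np.array([30.0, -12.0, 0.0]))
        a = tangent_angle_measure(spine, "sagittal", ("T1", "T12"))
        b = tangent_angle_measure(moved, "sagittal", ("T1", "T12"))
        assert a == pytest.approx(b, abs=1e-10)

    def test_short_span_rejected(self):
        spine = CentroidSpine("p", Timepoint.PO, straight_spine_coords())
        with pytest.raises(ValidationError):
            tangent_angle_measure(spine, "frontal", ("T1", "T2"))


class TestBalance:
    def test_straight_spine_balanced(self):
        spine = CentroidSpine("p", Timepoint.PO, straight_spine_coords())
        assert balance_offsets(spine) == (0.0, 0.0)

    def test_frontal_offset(self):
        coords = straight_spine_coords()
        coords[0, 0] = 20.0
        spine = CentroidSpine("p", Timepoint.PO, coords)
        fb, sb = balance_offsets(spine)
        assert fb == 20.0 and sb == 0.0

    def test_rigid_translation_invariant(self, rng):
        coords = straight_spine_coords()
        coords[:, 0] = rng.normal(0, 10, 17)
        a = balance_offsets(CentroidSpine("p", Timepoint.PO, coords))
        b = balance_offsets(
            CentroidSpine("p", Timepoint.PO, coords + np.array([55.0, 0.0, 0.0]))
        )
        assert a == b


class TestMeasureSpine:
    def test_standard_measure_set(self):
        spine = CentroidSpine("p", Timepoint.PO, straight_spine_coords())
        m = measure_spine(spine)
        assert set(m) == {"PTC", "MTC", "LC", "TK_T1_T12", "TK_T4_T12",
                          "LL_L1_L5", "FB", "SB"}
        assert all(v == 0.0 for v in m.values())

    def test_passthrough_carried(self):
        spine = CentroidSpine("p", Timepoint.PO, straight_spine_coords())
        m = measure_spine(spine, passthrough={"MTR": -8.4, "PI": 54.7})
        assert m["MTR"] == -8.4 and m["PI"] == 54.7

    def test_passthrough_shadowing_rejected(self):
        spine = CentroidSpine("p", Timepoint.PO, straight_spine_coords())
        with pytest.raises(ValidationError):
            measure_spine(spine, passthrough={"FB": 1.0})


class TestCompareClusters:
    def test_hand_computed_anova_f(self, rng):
        # {1,2,3} vs {7,8,9}: F = MSB/MSW = 54/1 = 54
        df = pd.DataFrame({"v": [1, 2, 3, 7, 8, 9]}, index=list("abcdef"))
        labels = [1, 1, 1, 2, 2, 2]
        comp = compare_clusters(df, labels)
        v = comp["v"]
        assert v.test == "anova"
        assert v.statistic == pytest.approx(54.0, rel=1e-12)

    def test_identical_clusters_not_significant(self):
        df = pd.DataFrame({"v": [1, 2, 3] * 3}, index=[f"p{i}" for i in range(9)])
        labels = [1, 1, 1, 2, 2, 2, 3, 3, 3]
        comp = compare_clusters(df, labels)
        assert comp["v"].statistic == pytest.approx(0.0, abs=1e-12)
        assert not comp["v"].significant

    def test_large_shift_detected_with_direction(self, rng):
        a = rng.normal(0.0, 1.0, 20)
        b = rng.normal(5.0, 1.0, 20)  # 5 SD shift: power ~ 1
        df = pd.DataFrame({"v": np.concatenate([a, b])},
                          index=[f"p{i}" for i in range(40)])
        comp = compare_clusters(df, [1] * 20 + [2] * 20)
        v = comp["v"]
        assert v.significant
        assert v.group_means[2] > v.group_means[1]

    def test_non_normal_variable_uses_kruskal_dunn(self, rng):
        skewed = np.concatenate([rng.exponential(1.0, 25) ** 3,
                                 rng.exponential(1.0, 25) ** 3 + 50])
        df = pd.DataFrame({"v": skewed}, index=[f"p{i}" for i in range(50)])
        comp = compare_clusters(df, [1] * 25 + [2] * 25)
        assert comp["v"].test == "kruskal"
        assert comp["v"].significant
        assert len(comp["v"].pairwise) == 1

    def test_selection_pure_function_of_shapiro(self, rng):
        from scipy import stats

        values = rng.normal(0, 1, 30)
        df = pd.DataFrame({"v": values}, index=[f"p{i}" for i in range(30)])
        labels = [1] * 15 + [2] * 15
        comp = compare_clusters(df, labels)
        all_normal = all(
            stats.shapiro(values[np.array(labels) == c]).pvalue > 0.05
            for c in (1, 2)
        )
        assert comp["v"].test == ("anova" if all_normal else "kruskal")

    def test_small_cluster_rejected(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0, 4.0]}, index=list("abcd"))
        with pytest.raises(ValidationError):
            compare_clusters(df, [1, 1, 1, 2])

    def test_type_one_error_near_alpha_under_null(self):
        """Omnibus false-positive rate ~ 5% when all clusters share one
        distribution (Monte Carlo over 1000 datasets)."""
        rng = np.random.default_rng(2024)
        n_sim, hits = 1000, 0
        for _ in range(n_sim):
            df = pd.DataFrame({"v": rng.normal(0, 1, 30)},
                              index=[f"p{i}" for i in range(30)])
            comp = compare_clusters(df, [1] * 10 + [2] * 10 + [3] * 10)
            hits += comp["v"].significant
        rate = hits / n_sim
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) < 3 * se + 0.01

    def test_bonferroni_never_smaller(self, rng):
        skewed = np.concatenate([rng.exponential(1.0, 20) ** 3,
                                 rng.exponential(1.0, 20) ** 3 + 10,
                                 rng.exponential(1.0, 20) ** 3 + 30])
        df = pd.DataFrame({"v": skewed}, index=[f"p{i}" for i in range(60)])
        labels = [1] * 20 + [2] * 20 + [3] * 20
        plain = compare_clusters(df, labels)
        bonf = compare_clusters(df, labels, posthoc_correction="bonferroni")
        if plain["v"].test == "kruskal":
            assert (bonf["v"].pairwise.p_value >= plain["v"].pairwise.p_value - 1e-15).all()

    def test_summary_frame_layout(self, rng):
        df = pd.DataFrame(
            {"MTC": rng.normal(55, 8, 30), "TK": rng.normal(25, 10, 30)},
            index=[f"p{i}" for i in range(30)],
        )
        comp = compare_clusters(df, [1] * 10 + [2] * 10 + [3] * 10)
        frame = comp.to_frame()
        assert list(frame.variable) == ["MTC", "TK"]
        assert {"cluster1", "cluster2", "cluster3"} <= set(frame.columns)
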