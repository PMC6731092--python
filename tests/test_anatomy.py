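"""Region assignment, ROI counting, distributions, density maps, SNr fractions."""

import numpy as np
import pytest

from loopmapper import (
    CellPoint,
    RegionPartition,
    RoiSpec,
    PointCloudSpec,
    assign_region,
    count_in_roi,
    density_map,
    generate_point_cloud,
    luminance_profile,
    normalized_distribution,
    snr_fraction,
)


def pt(ap, ml, dv, sec=0, cid="c"):
    return CellPoint(cell_id=cid, AP=ap, ML=ml, DV=dv, section_id=sec)


def brute_force_assign(p, partition):
    for name in partition.region_order:
        for (a0, a1), (m0, m1), (d0, d1) in partition.regions[name]:
            if a0 <= p.AP <= a1 and m0 <= p.ML <= m1 and d0 <= p.DV <= d1:
                return name
    return "outside"


class TestAssignRegion:
    def test_posterior_cells_are_tail_of_striatum(self, mouse_partition):
        """Everything at or posterior to AP -0.8 mm is TS, regardless of ML/DV."""
        assert assign_region(pt(-1.5, 2.0, 3.0), mouse_partition) == "TS"
        assert assign_region(pt(-0.8, 3.9, 5.0), mouse_partition) == "TS"

    def test_ml_midline_tie_breaks_medial(self, mouse_partition):
        # dorsal tier midline at ML 2.1; exactly on it -> medial
        assert assign_region(pt(0.5, 2.1, 2.0), mouse_partition) == "DMS"
        assert assign_region(pt(0.5, 2.11, 2.0), mouse_partition) == "DLS"
        # ventral tier midline at ML 1.4
        assert assign_region(pt(1.0, 1.4, 4.0), mouse_partition) == "VMS"
        assert assign_region(pt(1.0, 1.41, 4.0), mouse_partition) == "VLS"

    def test_far_point_is_outside(self, mouse_partition):
        assert assign_region(pt(5.0, 0.1, 0.1), mouse_partition) == "outside"

    def test_every_point_maps_to_exactly_one_label(self, mouse_partition):
        rng = np.random.default_rng(12)
        for _ in range(300):
            p = pt(rng.uniform(-3, 2.5), rng.uniform(0, 5), rng.uniform(0, 7))
            name = assign_region(p, mouse_partition)
            assert name in set(mouse_partition.region_order) | {"outside"}

    def test_equivalence_with_brute_force_on_random_points(self, mouse_partition):
        rng = np.random.default_rng(42)
        pts = [pt(rng.uniform(-3, 2.5), rng.uniform(0, 5), rng.uniform(0, 7))
               for _ in range(1000)]
        for p in pts:
            assert assign_region(p, mouse_partition) == brute_force_assign(p, mouse_partition)


class TestCountInRoi:
    ROI = RoiSpec(region="DLS", center=(0.16, 3.7, 3.7))

    def test_empty_point_list(self):
        assert count_in_roi([], self.ROI) == 0

    def test_radius_boundary_counts_inside(self):
        # ROI circle radius 0.3 mm; 7 points at 0.29 mm, 3 at 0.31 mm
        sec = round(0.16 / 0.16)
        pts = []
        for k in range(7):
            ang = 2 * np.pi * k / 7
            pts.append(pt(0.16, 3.7 + 0.29 * np.cos(ang), 3.7 + 0.29 * np.sin(ang), sec))
        for k in range(3):
            ang = 2 * np.pi * k / 3
            pts.append(pt(0.16, 3.7 + 0.31 * np.cos(ang), 3.7 + 0.31 * np.sin(ang), sec))
        assert count_in_roi(pts, self.ROI) == 7
        exact = pt(0.16, 3.7 + 0.3, 3.7, sec)
        assert count_in_roi([exact], self.ROI) == 1  # rim inclusive

    def test_point_in_distant_section_excluded(self):
        inside = pt(0.16, 3.7, 3.7, sec=1)
        far = pt(0.16, 3.7, 3.7, sec=3)  # 2 sections beyond the 3-section span
        assert count_in_roi([inside, far], self.ROI) == 1

    def test_matches_brute_force_double_loop(self, mouse_partition):
        spec = PointCloudSpec(per_region_counts={"DLS": 400, "DMS": 300, "TS": 300},
                              region_partition=mouse_partition)
        pts = generate_point_cloud(spec, seed=3)
        roi = RoiSpec(region="DLS", center=(0.48, 3.0, 2.0))
        sections = {2, 3, 4}
        brute = sum(
            1 for p in pts
            if p.section_id in sections
            and np.hypot(p.ML - 3.0, p.DV - 2.0) <= 0.3
        )
        assert count_in_roi(pts, roi) == brute


class TestNormalizedDistribution:
    def test_equal_counts_give_equal_percentages(self, mouse_partition):
        counts = dict.fromkeys(["VMS", "VLS", "DMS", "DLS", "TS"], 10)
        pts = generate_point_cloud(
            PointCloudSpec(per_region_counts=counts, region_partition=mouse_partition),
            seed=1)
        d = normalized_distribution(pts, partition=mouse_partition)
        np.testing.assert_allclose(d.percent, 20.0)

    def test_known_count_arithmetic(self, mouse_partition):
        counts = {"VMS": 2, "VLS": 3, "DMS": 5, "DLS": 0, "TS": 0}
        pts = generate_point_cloud(
            PointCloudSpec(per_region_counts=counts, region_partition=mouse_partition),
            seed=2)
        d = normalized_distribution(pts, partition=mouse_partition).set_index("region")
        assert d.loc["VMS", "percent"] == pytest.approx(20.0)
        assert d.loc["VLS", "percent"] == pytest.approx(30.0)
        assert d.loc["DMS", "percent"] == pytest.approx(50.0)
        assert d.percent.sum() == pytest.approx(100.0)

    def test_two_region_cloud_distribution(self, mouse_partition):
        pts = generate_point_cloud(
            PointCloudSpec(per_region_counts={"VMS": 10, "TS": 5},
                           region_partition=mouse_partition), seed=5)
        d = normalized_distribution(pts, partition=mouse_partition).set_index("region")
        assert d.loc["VMS", "percent"] == pytest.approx(100 * 10 / 15)
        assert d.loc["TS", "percent"] == pytest.approx(100 * 5 / 15)

    def test_cohort_recovery_of_generating_proportions(self, mouse_partition):
        """Mean percentages across animals recover the generating intensities."""
        rng = np.random.default_rng(17)
        target = np.array([30, 10, 25, 30, 5], dtype=float)
        regions = ["VMS", "VLS", "DMS", "DLS", "TS"]
        per_animal = []
        for a in range(6):
            draw = rng.multinomial(300, target / 100.0)
            counts = {r: int(c) for r, c in zip(regions, draw)}
            pts = generate_point_cloud(
                PointCloudSpec(per_region_counts=counts, region_partition=mouse_partition),
                seed=100 + a)
            d = normalized_distribution(pts, partition=mouse_partition)
            per_animal.append(d.set_index("region").percent.reindex(regions).to_numpy())
        per_animal = np.array(per_animal)
        mean = per_animal.mean(axis=0)
        sem = per_animal.std(axis=0, ddof=1) / np.sqrt(len(per_animal))
        assert np.all(np.abs(mean - target) <= 3 * sem + 1e-9)

    def test_zero_total_rejected(self, mouse_partition):
        with pytest.raises(ValueError):
            normalized_distribution([pt(5.0, 0.1, 0.1)], partition=mouse_partition)


class TestDensityMap:
    def test_single_cell_normalizes_to_one(self):
        grids = density_map([pt(0.0, 2.0, 3.0)], n_parts=1)
        g = grids[0]
        assert g.normalized.max() == pytest.approx(1.0)
        assert np.sum(g.normalized > 0) == 1
        assert g.total == 1

    def test_counts_conserved_per_slab(self, mouse_partition):
        counts = {"VMS": 200, "DLS": 300, "TS": 500}
        pts = generate_point_cloud(
            PointCloudSpec(per_region_counts=counts, region_partition=mouse_partition),
            seed=7)
        grids = density_map(pts, n_parts=8)
        assert sum(g.total for g in grids) == 1000
        for g in grids:
            assert 0.0 <= g.normalized.min() and g.normalized.max() <= 1.0
            if g.total:
                assert g.normalized.max() == pytest.approx(1.0)

    def test_grid_counts_match_brute_force(self, mouse_partition):
        pts = generate_point_cloud(
            PointCloudSpec(per_region_counts={"DLS": 1000},
                           region_partition=mouse_partition), seed=8)
        g = density_map(pts, n_parts=1)[0]
        ml = np.array([p.ML for p in pts])
        dv = np.array([p.DV for p in pts])
        for i in range(len(g.ml_edges) - 1):
            for j in range(len(g.dv_edges) - 1):
                lo_m, hi_m = g.ml_edges[i], g.ml_edges[i + 1]
                lo_d, hi_d = g.dv_edges[j], g.dv_edges[j + 1]
                sel = (ml >= lo_m) & (ml < hi_m if i < len(g.ml_edges) - 2 else ml <= hi_m)
                sel &= (dv >= lo_d) & (dv < hi_d if j < len(g.dv_edges) - 2 else dv <= hi_d)
                assert g.counts[i, j] == int(np.sum(sel))

    def test_no_points_gives_empty(self):
        assert density_map([]) == []


class TestSnrFraction:
    EDGES = {0: (0.5, 2.0), 1: (0.6, 2.1), 2: (0.5, 1.9)}

    def test_all_medial(self):
        pts = [pt(-3.0, 0.7, 4.0, sec=s) for s in self.EDGES for _ in range(3)]
        frac = snr_fraction(pts, self.EDGES, n_divisions=2)
        assert frac[0] == pytest.approx(1.0)

    def test_midpoint_tie_goes_lateral(self):
        med, lat = self.EDGES[0]
        p = pt(-3.0, (med + lat) / 2, 4.0, sec=0)
        frac = snr_fraction([p], {0: self.EDGES[0]}, n_divisions=2)
        assert frac[1] == pytest.approx(1.0)

    def test_uniform_quartiles(self):
        rng = np.random.default_rng(23)
        pts = [pt(-3.0, rng.uniform(0.5, 2.0), 4.0, sec=0) for _ in range(1000)]
        frac = snr_fraction(pts, {0: (0.5, 2.0)}, n_divisions=4)
        # binomial error ~ sqrt(0.25*0.75/1000) ~ 1.4% -> 3 sigma band
        assert np.all(np.abs(frac - 0.25) < 0.045)

    def test_outside_edges_clipped_with_warning(self):
        p = pt(-3.0, 3.0, 4.0, sec=0)
        with pytest.warns(UserWarning):
            frac = snr_fraction([p], {0: (0.5, 2.0)}, n_divisions=2)
        assert frac[1] == pytest.approx(1.0)


class TestLuminanceProfile:
    def test_single_dominant_region(self):
        out = luminance_profile({"VMS": 110, "VLS": 10, "DMS": 10, "DLS": 10, "TS": 10},
                                background=10.0).set_index("region")
        assert out.loc["VMS", "percent"] == pytest.approx(100.0)
        assert out.percent.sum() == pytest.approx(100.0)

    def test_equal_above_background(self):
        out = luminance_profile(dict.fromkeys(["VMS", "VLS", "DMS", "DLS", "TS"], 30.0),
                                background=10.0)
        np.testing.assert_allclose(out.percent, 20.0)

    def test_random_vector_sums_to_100(self):
        rng = np.random.default_rng(3)
        raw = {r: float(v) for r, v in zip(["VMS", "VLS", "DMS", "DLS", "TS"],
                                           rng.uniform(20, 200, 5))}
        out = luminance_profile(raw, background=15.0)
        assert out.percent.sum() == pytest.approx(100.0)

    def test_all_below_background_rejected(self):
        with pytest.raises(ValueError):
            luminance_profile(dict.fromkeys(["VMS", "VLS", "DMS", "DLS", "TS"], 5.0),
                              background=10.0)
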