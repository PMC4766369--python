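"""Shell enrichment statistic, its ANOVA, and periphery distances."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from edgewall import enrichment, synthetic
from edgewall.enrichment import (
    cell_distance_to_pm,
    compare_periphery_distributions,
    cut_sections,
    enrichment_anova,
    enrichment_table,
    puncta_periphery_distance,
    relative_enrichment,
    shell_compartments,
)
from edgewall.synthetic import PunctaModel, generate_cells


@pytest.fixture(scope="module")
def cube_grid():
    """Single 10 μm cube at isotropic 0.1 μm voxels."""
    return generate_cells(n_cells=(1, 1, 1), cell_size=10.0,
                          voxel_size=(0.1, 0.1, 0.1), margin=0.5)


@pytest.fixture(scope="module")
def deep_grid():
    """Single 6 μm-deep cell for exact 3 x 2 μm section tiling."""
    return generate_cells(n_cells=(1, 1, 1), cell_size=(8.0, 8.0, 6.0),
                          voxel_size=(0.1, 0.1, 0.2), margin=0.6)


class TestSections:
    def test_three_sections_tile_six_micron_cell(self, deep_grid):
        secs = cut_sections(deep_grid.labels, deep_grid.voxel_size, 1)
        cell = deep_grid.labels == 1
        union = np.zeros_like(cell)
        for i, s in enumerate(secs):
            for t in secs[i + 1:]:
                assert not np.any(s & t)  # pairwise disjoint
            union |= s
        assert np.array_equal(union, cell)  # exact tiling of a 6 μm cell

    def test_section_boundaries_at_expected_depths(self, deep_grid):
        dz = deep_grid.voxel_size[2]
        secs = cut_sections(deep_grid.labels, deep_grid.voxel_size, 1)
        zmax = np.flatnonzero((deep_grid.labels == 1).any(axis=(1, 2))).max()
        z_top = (zmax + 1) * dz
        for s_idx, target in ((0, 2.0), (1, 4.0)):
            deepest = np.flatnonzero(secs[s_idx].any(axis=(1, 2))).min()
            depth_of_boundary = z_top - deepest * dz
            assert abs(depth_of_boundary - target) <= dz / 2 + 1e-9

    def test_shallow_cell_rejected(self):
        g = generate_cells(n_cells=(1, 1, 1), cell_size=(8.0, 8.0, 4.0),
                           voxel_size=(0.1, 0.1, 0.2), margin=0.6)
        with pytest.raises(ValueError, match="required"):
            cut_sections(g.labels, g.voxel_size, 1, n_sections=3, thickness=2.0)

    def test_missing_cell_rejected(self, deep_grid):
        with pytest.raises(ValueError, match="not present"):
            cut_sections(deep_grid.labels, deep_grid.voxel_size, 99)


class TestShellCompartments:
    def test_cube_band_volumes_match_analytic_shells(self, cube_grid):
        g = cube_grid
        dist, slices = cell_distance_to_pm(g.labels, g.voxel_size, 1)
        whole = g.labels == 1
        comps = shell_compartments(whole, dist, slices)
        voxvol = np.prod(g.voxel_size)
        # nested-cube shells: 10^3-8^3, 8^3-6^3, 6^3
        expected = {"outer_border": 488.0, "inner_border": 296.0,
                    "interior": 216.0}
        for name, vol in expected.items():
            measured = comps[name].sum() * voxvol
            assert measured == pytest.approx(vol, rel=0.05)

    def test_bands_partition_cell(self, cube_grid):
        g = cube_grid
        dist, slices = cell_distance_to_pm(g.labels, g.voxel_size, 1)
        whole = g.labels == 1
        comps = shell_compartments(whole, dist, slices)
        total = sum(int(m.sum()) for m in comps.values())
        assert total == int(whole.sum())

    def test_face_adjacent_voxel_distance_small(self, cube_grid):
        g = cube_grid
        dist, slices = cell_distance_to_pm(g.labels, g.voxel_size, 1)
        pos = dist[dist > 0]
        assert pos.min() <= np.linalg.norm(g.voxel_size)

    def test_thin_cell_has_empty_interior(self):
        g = generate_cells(n_cells=(1, 1, 1), cell_size=(6.0, 6.0, 3.0),
                           voxel_size=(0.1, 0.1, 0.2), margin=0.6)
        dist, slices = cell_distance_to_pm(g.labels, g.voxel_size, 1)
        comps = shell_compartments(g.labels == 1, dist, slices)
        assert comps["interior"].sum() == 0  # 3 μm deep: bands exhaust cell


class TestRelativeEnrichment:
    def test_uniform_image_gives_unity_everywhere(self, deep_grid):
        img = np.full(deep_grid.labels.shape, 7.3)
        t = enrichment_table(img, deep_grid.labels, deep_grid.voxel_size)
        vals = t.relative_enrichment.dropna()
        assert np.allclose(vals, 1.0)

    def test_weighted_mean_enrichment_is_one_for_any_image(self, deep_grid):
        rng = np.random.default_rng(0)
        img = rng.random(deep_grid.labels.shape) * 100
        t = enrichment_table(img, deep_grid.labels, deep_grid.voxel_size)
        for (_, _), grp in t.groupby(["cell_id", "section"]):
            ok = grp.dropna(subset=["relative_enrichment"])
            wmean = np.average(ok.relative_enrichment, weights=ok.n_voxels)
            assert wmean == pytest.approx(1.0, abs=1e-12)

    def test_intensity_scale_invariance(self, deep_grid):
        rng = np.random.default_rng(1)
        img = rng.random(deep_grid.labels.shape)
        t1 = enrichment_table(img, deep_grid.labels, deep_grid.voxel_size)
        t2 = enrichment_table(37.0 * img, deep_grid.labels, deep_grid.voxel_size)
        assert np.allclose(t1.relative_enrichment.dropna(),
                           t2.relative_enrichment.dropna())

    def test_signal_confined_to_outer_band_gives_reciprocal_volume_fraction(
        self, deep_grid
    ):
        g = deep_grid
        dist, slices = cell_distance_to_pm(g.labels, g.voxel_size, 1)
        secs = cut_sections(g.labels, g.voxel_size, 1)
        sec = secs[1]
        comps = shell_compartments(sec, dist, slices)
        img = np.zeros(g.labels.shape)
        img[comps["outer_border"]] = 5.0
        rows = relative_enrichment(img, sec, comps)
        outer = next(r for r in rows if r["compartment"] == "outer_border")
        phi = outer["n_voxels"] / int(sec.sum())
        assert outer["relative_enrichment"] == pytest.approx(1 / phi, rel=1e-12)

    def test_empty_compartment_reported_as_missing(self):
        g = generate_cells(n_cells=(1, 1, 1), cell_size=(8.0, 8.0, 3.8),
                           voxel_size=(0.1, 0.1, 0.2), margin=0.6)
        img = np.ones(g.labels.shape)
        t = enrichment_table(img, g.labels, g.voxel_size, n_sections=1,
                             thickness=2.0)
        interior = t[t.compartment == "interior"]
        # deep interior never exists in a 3.8 μm-deep cell's first section
        assert interior.n_voxels.iloc[0] == 0
        assert np.isnan(interior.relative_enrichment.iloc[0])

    def test_noise_free_edge_stack_orders_compartments(self):
        model = PunctaModel(n_puncta=150, edge_fraction=0.9, noise=False)
        s = synthetic.simulate_stack(n_cells=(2, 2, 1), cell_size=7.0,
                                     model=model, seed=21)
        t = enrichment_table(s.intensity, s.labels, s.voxel_size)
        means = t.groupby("compartment")["relative_enrichment"].mean()
        assert means["outer_border"] > means["inner_border"] > means["interior"]


class TestAnova:
    @staticmethod
    def balanced_table(delta=0.0, seed=0):
        """Cell-level enrichment table: 2 treatments x 3 compartments x 12
        cells, optional compartment-by-treatment shift ``delta``."""
        rng = np.random.default_rng(seed)
        rows = []
        for trt in ("a", "b"):
            for cell in range(12):
                for ci, comp in enumerate(("outer", "inner", "interior")):
                    val = rng.normal(1.0, 0.05)
                    if trt == "b" and comp == "outer":
                        val += delta
                    rows.append({"treatment": trt, "cell_id": cell,
                                 "section": 1, "compartment": comp,
                                 "relative_enrichment": val})
        return pd.DataFrame(rows)

    def test_identical_groups_give_unit_pvalues(self):
        t = self.balanced_table()
        t2 = t.copy()
        t2["treatment"] = t["treatment"].map({"a": "b", "b": "a"})
        dup = pd.concat([t[t.treatment == "a"], t2[t2.treatment == "b"]])
        res = enrichment_anova(dup)
        a = res["anova"]
        assert a.loc["C(treatment)", "F"] == pytest.approx(0.0, abs=1e-20)
        assert a.loc["C(treatment)", "PR(>F)"] == pytest.approx(1.0)
        assert a.loc["C(compartment):C(treatment)", "PR(>F)"] == pytest.approx(1.0)

    def test_f_statistics_match_hand_sum_of_squares(self):
        t = self.balanced_table(delta=0.3, seed=3)
        res = enrichment_anova(t)
        a = res["anova"]
        # direct balanced two-way decomposition oracle
        cells = res["cell_means"]
        y = cells.pivot_table(index="cell_id", columns=["treatment", "compartment"],
                              values="relative_enrichment").to_numpy()
        data = cells.copy()
        grand = data.relative_enrichment.mean()
        n_t, n_c, r = 2, 3, 12
        ss_t = sum(
            (data[data.treatment == t_].relative_enrichment.mean() - grand) ** 2
            for t_ in ("a", "b")
        ) * n_c * r
        ss_c = sum(
            (data[data.compartment == c_].relative_enrichment.mean() - grand) ** 2
            for c_ in ("outer", "inner", "interior")
        ) * n_t * r
        ss_cell = 0.0
        for t_ in ("a", "b"):
            for c_ in ("outer", "inner", "interior"):
                sub = data[(data.treatment == t_) & (data.compartment == c_)]
                ss_cell += r * (sub.relative_enrichment.mean() - grand) ** 2
        ss_int = ss_cell - ss_t - ss_c
        ss_err = 0.0
        for t_ in ("a", "b"):
            for c_ in ("outer", "inner", "interior"):
                sub = data[(data.treatment == t_) & (data.compartment == c_)]
                ss_err += ((sub.relative_enrichment
                            - sub.relative_enrichment.mean()) ** 2).sum()
        ms_err = ss_err / (n_t * n_c * (r - 1))
        assert a.loc["C(treatment)", "F"] == pytest.approx(
            (ss_t / (n_t - 1)) / ms_err, rel=1e-10)
        assert a.loc["C(compartment)", "F"] == pytest.approx(
            (ss_c / (n_c - 1)) / ms_err, rel=1e-10)
        assert a.loc["C(compartment):C(treatment)", "F"] == pytest.approx(
            (ss_int / ((n_t - 1) * (n_c - 1))) / ms_err, rel=1e-10)

    def test_missing_factor_combination_rejected(self):
        t = self.balanced_table()
        t = t[~((t.treatment == "b") & (t.compartment == "outer"))]
        with pytest.raises(ValueError, match="empty factor"):
            enrichment_anova(t)

    def test_single_treatment_rejected(self):
        t = self.balanced_table()
        with pytest.raises(ValueError):
            enrichment_anova(t[t.treatment == "a"])


class TestPeripheryDistance:
    def test_punctum_on_membrane_and_cube_center(self, cube_grid):
        g = cube_grid
        lo, hi = g.box(1)
        c = (lo + hi) / 2
        on_pm = lo + np.array([0.0, 5.0, 5.0])
        pts = np.vstack([on_pm, c])
        d = puncta_periphery_distance(g.labels, g.voxel_size, pts,
                                      np.array([1, 1]))
        diag = np.linalg.norm(g.voxel_size)
        assert d[0] <= diag  # on the PM: ~0 within voxel quantization
        assert d[1] == pytest.approx(5.0, abs=diag)

    def test_population_medians_match_generator_truth(self):
        g = generate_cells(n_cells=(2, 1, 1), cell_size=8.0)
        rng = np.random.default_rng(9)
        edge = synthetic.place_puncta(
            g, PunctaModel(n_puncta=400, edge_fraction=1.0), rng)
        unif = synthetic.place_puncta(
            g, PunctaModel(n_puncta=400, edge_fraction=0.0), rng)
        d_edge = puncta_periphery_distance(
            g.labels, g.voxel_size, edge[["x", "y", "z"]].to_numpy(),
            edge.cell_id.to_numpy())
        d_unif = puncta_periphery_distance(
            g.labels, g.voxel_size, unif[["x", "y", "z"]].to_numpy(),
            unif.cell_id.to_numpy())
        diag = np.linalg.norm(g.voxel_size)
        assert abs(np.median(d_edge) - 0.093) <= diag
        # closed-form median for uniform points in an 8 μm cube
        t_med = brentq(lambda t: ((8 - 2 * t) / 8) ** 3 - 0.5, 0, 4)
        assert abs(np.median(d_unif) - t_med) <= diag
        cmp = compare_periphery_distributions(d_edge, d_unif)
        assert cmp["p_value"] < 1e-10
        assert cmp["median1"] < cmp["median2"]

    def test_empty_distribution_flagged(self):
        cmp = compare_periphery_distributions([], [1.0, 2.0])
        assert cmp["n1"] == 0 and np.isnan(cmp["p_value"])

    def test_detection_recovers_bright_puncta(self):
        model = PunctaModel(n_puncta=15, edge_fraction=0.0,
                            photons_per_punctum=30000.0)
        s = synthetic.simulate_stack(n_cells=(1, 1, 1), cell_size=6.0,
                                     model=model, seed=13)
        centers = enrichment.detect_puncta(
            s.intensity, s.labels == 0, s.voxel_size, k=2.0)
        truth = s.puncta[["x", "y", "z"]].to_numpy()
        from scipy.spatial import cKDTree

        d, _ = cKDTree(centers).query(truth)
        # most true puncta matched by a detection within ~2 voxel diagonals
        assert np.median(d) <= 2 * np.linalg.norm(s.voxel_size)
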