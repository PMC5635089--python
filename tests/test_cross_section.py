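"""Perpendicular reslicing, FWHM diameter recovery and exclusion rules."""

import numpy as np
import pytest
from skimage import measure as skmeasure

from aaquant.cross_section import (
    BoundaryError, CrossSection, GeometryError, MeasureConfig,
    MeasurementExclusion, QC_NO_ARTERY, QC_NO_LUMEN, QC_NOISE, QC_OK,
    _smoothed_tangent, extract_cross_section, measure_airway, measure_artery,
    measure_branch, measure_tree, measurements_to_frame,
)
from aaquant.phantom import HU_PARENCHYMA, rasterize
from aaquant.tree_model import AirwayTree, Branch, label_tree
from tests.conftest import straight_tube_tree


def noise_patch(sd=200.0, mean=-500.0, n=129, spacing=0.25, seed=0):
    rng = np.random.default_rng(seed)
    return CrossSection(patch=rng.normal(mean, sd, (n, n)),
                        spacing_mm=spacing, centre_mm=np.zeros(3),
                        axis_u=np.array([1.0, 0, 0]),
                        axis_v=np.array([0, 1.0, 0]),
                        normal=np.array([0, 0, 1.0]))


def lumen_axis_ratio(patch, level=-525.0):
    """Major/minor axis ratio of the thresholded dark lumen region
    (1.0 for a circle, ~1.41 for a 45-degree parallax ellipse)."""
    lab = skmeasure.label(patch < level)
    n = patch.shape[0]
    centre_label = lab[n // 2, n // 2]
    assert centre_label != 0
    region = [r for r in skmeasure.regionprops(lab) if r.label == centre_label][0]
    return region.axis_major_length / region.axis_minor_length


class TestExtraction:
    def test_axis_aligned_normal_and_symmetry(self, tube_volume_fine):
        vol, branch = tube_volume_fine
        cs = extract_cross_section(vol, branch, 0.5)
        np.testing.assert_allclose(np.abs(cs.normal), [0, 0, 1], atol=1e-9)
        assert lumen_axis_ratio(cs.patch) < 1.12

    def test_oblique_tube_no_parallax(self):
        """The perpendicular reslice of a 45-degree tube stays circular,
        while a deliberately axial reslice is elongated by ~1/cos(45)."""
        tree = straight_tube_tree(inner_r=2.0, outer_r=3.0, artery_r=2.5,
                                  direction=(0, 1, 1), length=40.0)
        branch = next(iter(tree))
        vol = rasterize(tree, spacing_mm=0.5, noise_sd_HU=0.0)
        cs = extract_cross_section(vol, branch, 0.5)
        assert lumen_axis_ratio(cs.patch) < 1.12

        centre = branch.point_at(0.5)
        k = int(round(vol.world_to_voxel(centre)[2]))
        axial = vol.data[:, :, k]
        ci, cj = np.round(vol.world_to_voxel(centre)[:2]).astype(int)
        lab = skmeasure.label(axial < -525.0)
        region = [r for r in skmeasure.regionprops(lab)
                  if r.label == lab[ci, cj]][0]
        ratio = region.axis_major_length / region.axis_minor_length
        assert ratio > 1.25  # ~1.41 expected at 45 degrees

    def test_plane_exiting_volume_is_boundary_error(self):
        tree = straight_tube_tree(length=10.0, direction=(1, 0, 0))
        branch = next(iter(tree))
        vol = rasterize(tree, spacing_mm=0.5, noise_sd_HU=0.0, margin_mm=1.0)
        with pytest.raises(BoundaryError):
            extract_cross_section(vol, branch, 0.0,
                                  MeasureConfig(patch_factor=20.0))

    def test_degenerate_tangent_raises(self):
        with pytest.raises(GeometryError):
            _smoothed_tangent(np.zeros((4, 3)), 0.5, window=1)

    def test_position_validated(self, tube_volume_fine):
        vol, branch = tube_volume_fine
        with pytest.raises(ValueError):
            extract_cross_section(vol, branch, 1.5)


class TestAirwayMeasurement:
    def test_recovery_within_quarter_millimetre(self, tube_volume_fine):
        vol, branch = tube_volume_fine
        cs = extract_cross_section(vol, branch, 0.5)
        inner, outer, diag = measure_airway(cs)
        assert inner == pytest.approx(2.0, abs=0.25)
        assert outer == pytest.approx(4.0, abs=0.25)
        assert diag["valid_ray_frac"] >= 0.9

    def test_plugged_lumen_excluded(self):
        tree = straight_tube_tree()
        branch = next(iter(tree))
        vol = rasterize(tree, spacing_mm=0.25, noise_sd_HU=0.0,
                        plugged_branch_ids=["b0"])
        cs = extract_cross_section(vol, branch, 0.5)
        with pytest.raises(MeasurementExclusion) as exc:
            measure_airway(cs)
        assert exc.value.status == QC_NO_LUMEN

    def test_pure_noise_excluded(self):
        with pytest.raises(MeasurementExclusion) as exc:
            measure_airway(noise_patch())
        assert exc.value.status == QC_NOISE


class TestArteryMeasurement:
    def test_artery_recovery(self, tube_volume_fine):
        vol, branch = tube_volume_fine
        cs = extract_cross_section(vol, branch, 0.5)
        d, diag = measure_artery(cs, expected_outer_radius_mm=2.0,
                                 expected_artery_radius_mm=1.5,
                                 airway_outer_radius_mm=2.0)
        assert d == pytest.approx(3.0, abs=0.25)

    def test_suppressed_artery_excluded(self):
        tree = straight_tube_tree()
        branch = next(iter(tree))
        vol = rasterize(tree, spacing_mm=0.25, noise_sd_HU=0.0,
                        suppress_artery_ids=["b0"])
        cs = extract_cross_section(vol, branch, 0.5)
        with pytest.raises(MeasurementExclusion) as exc:
            measure_artery(cs, expected_outer_radius_mm=2.0,
                           expected_artery_radius_mm=1.5,
                           airway_outer_radius_mm=2.0)
        assert exc.value.status == QC_NO_ARTERY

    def test_two_candidates_nearest_wins_and_logged(self, caplog):
        """Two plausible vessels: the nearer one is measured, tie logged."""
        n = 161
        spacing = 0.25
        patch = np.full((n, n), HU_PARENCHYMA)
        yy, xx = np.mgrid[0:n, 0:n]
        c = (n - 1) / 2
        for dist_px, r_px in ((12, 6), (-16, 6)):  # 3 mm and 4 mm away
            patch[np.hypot(yy - c, xx - (c + dist_px)) < r_px] = 50.0
        cs = CrossSection(patch=patch, spacing_mm=spacing,
                          centre_mm=np.zeros(3), axis_u=np.array([1.0, 0, 0]),
                          axis_v=np.array([0, 1.0, 0]),
                          normal=np.array([0, 0, 1.0]), branch_id="bx")
        import logging
        with caplog.at_level(logging.INFO, logger="aaquant.cross_section"):
            d, diag = measure_artery(cs, expected_outer_radius_mm=1.5,
                                     expected_artery_radius_mm=1.5,
                                     airway_outer_radius_mm=1.0)
        assert diag["artery_candidates"] == 2
        assert diag["artery_distance_mm"] == pytest.approx(3.0, abs=0.3)
        assert any("tie broken" in r.message for r in caplog.records)


class TestBatch:
    @pytest.fixture(scope="class")
    def three_branch_setup(self):
        root = Branch("r", None, np.array([[0., 0, 0], [0, 0, 16]]),
                      inner_radius_mm=1.5, outer_radius_mm=2.5,
                      artery_radius_mm=2.0)
        kids = [
            Branch("c0", "r", np.array([[0., 0, 16], [12, 0, 28]]), lobe="RUL",
                   is_segmental_bronchus=True, inner_radius_mm=1.0,
                   outer_radius_mm=1.8, artery_radius_mm=1.5),
            Branch("c1", "r", np.array([[0., 0, 16], [-12, 0, 28]]), lobe="LUL",
                   is_segmental_bronchus=True, inner_radius_mm=1.0,
                   outer_radius_mm=1.8, artery_radius_mm=1.5),
        ]
        tree = AirwayTree([root] + kids)
        vol = rasterize(tree, spacing_mm=0.4, noise_sd_HU=0.0)
        return vol, tree

    def test_one_row_per_branch_all_ok(self, three_branch_setup):
        vol, tree = three_branch_setup
        rows = measure_tree(vol, tree, subject_id="S1")
        assert len(rows) == 3
        assert {m.branch_id for m in rows} == {"r", "c0", "c1"}
        assert all(m.qc_status == QC_OK for m in rows)
        for m in rows:
            assert m.wall_thickness_mm == pytest.approx(
                m.outer_diameter_mm - m.inner_diameter_mm)

    def test_deterministic(self, three_branch_setup):
        vol, tree = three_branch_setup
        a = measurements_to_frame(measure_tree(vol, tree, subject_id="S1"))
        b = measurements_to_frame(measure_tree(vol, tree, subject_id="S1"))
        import pandas as pd
        pd.testing.assert_frame_equal(a, b)

    def test_labels_propagated(self, three_branch_setup):
        vol, tree = three_branch_setup
        rows = measure_tree(vol, tree, subject_id="S1")
        by_id = {m.branch_id: m for m in rows}
        assert by_id["r"].generation == 0
        assert by_id["c0"].segmental_generation == 1

    def test_monotone_visibility_in_diameter(self):
        """Shrinking the true calibre at fixed spacing never turns an
        excluded airway measurable again."""
        statuses = []
        for scale in (1.0, 0.6, 0.45, 0.35, 0.25):
            tree = straight_tube_tree(inner_r=1.0 * scale, outer_r=1.8 * scale,
                                      artery_r=1.4 * scale, length=12.0)
            branch = next(iter(tree))
            vol = rasterize(tree, spacing_mm=0.5, noise_sd_HU=0.0)
            m = measure_branch(vol, branch, label_tree(tree), "S", "inspiration")
            statuses.append(m.qc_status == QC_OK)
        first_excluded = statuses.index(False) if False in statuses else len(statuses)
        assert statuses[0]  # full size measurable
        assert all(not s for s in statuses[first_excluded:])
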