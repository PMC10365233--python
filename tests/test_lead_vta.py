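"""Lead geometry and simplified VTA kernel."""

import math

import numpy as np
import pytest

from tractstim.lead_vta import (
    ALL_CONFIGS,
    LeadModel,
    StimSetting,
    VTA,
    VTAParams,
    contact_frames,
    point_in_vta,
    voxelize_vta,
    vta_for_setting,
    vta_radius_point_source,
)


class TestContactFrames:
    def test_ring_centroids_on_axis(self, canonical_lead):
        frames = {f.contact_id: f for f in contact_frames(canonical_lead)}
        np.testing.assert_allclose(frames[1].centroid, [0, 0, 0.75])
        np.testing.assert_allclose(frames[8].centroid, [0, 0, 6.75])

    def test_level_pitch_is_two_mm(self, canonical_lead):
        offsets = [canonical_lead.level_offset(k) for k in range(1, 5)]
        np.testing.assert_allclose(offsets, [0.75, 2.75, 4.75, 6.75])

    def test_segment_outward_vectors_120_apart(self, canonical_lead):
        frames = {f.contact_id: f for f in contact_frames(canonical_lead)}
        np.testing.assert_allclose(frames[2].outward, [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(frames[3].outward,
                                   [-0.5, math.sqrt(3) / 2, 0], atol=1e-12)
        np.testing.assert_allclose(frames[4].outward,
                                   [-0.5, -math.sqrt(3) / 2, 0], atol=1e-12)

    def test_rotation_equivariance(self):
        lead = LeadModel(tip=np.zeros(3), axis=[0, 0, 1], rotation=math.pi)
        frames = {f.contact_id: f for f in contact_frames(lead)}
        np.testing.assert_allclose(frames[2].outward, [-1, 0, 0], atol=1e-12)

    def test_segment_centroid_offset_by_lead_radius(self, canonical_lead):
        frames = {f.contact_id: f for f in contact_frames(canonical_lead)}
        np.testing.assert_allclose(
            frames[2].centroid, [canonical_lead.lead_radius, 0, 2.75])

    def test_centroids_ordered_along_axis(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            axis = rng.normal(size=3)
            lead = LeadModel(tip=rng.normal(0, 10, 3), axis=axis,
                             rotation=rng.uniform(0, 2 * math.pi))
            frames = contact_frames(lead)
            for f in frames:
                proj = float(np.dot(f.centroid - lead.tip, lead.axis))
                assert proj == pytest.approx(lead.level_offset(f.level),
                                             abs=1e-9)

    def test_zero_axis_rejected(self):
        with pytest.raises(ValueError):
            LeadModel(tip=np.zeros(3), axis=[0, 0, 0])


class TestVtaRadius:
    def test_one_milliamp_reference_value(self, default_vta_params):
        # closed form sqrt(I / (4 pi sigma E_t)) at sigma=0.33, E_t=0.2 V/mm
        assert vta_radius_point_source(1.0, default_vta_params) == \
            pytest.approx(1.098, abs=5e-4)

    def test_square_root_scaling(self, default_vta_params):
        r1 = vta_radius_point_source(1.0, default_vta_params)
        r4 = vta_radius_point_source(4.0, default_vta_params)
        assert r4 / r1 == pytest.approx(2.0, rel=1e-12)

    def test_zero_amplitude(self, default_vta_params):
        assert vta_radius_point_source(0.0, default_vta_params) == 0.0

    def test_negative_amplitude_rejected(self, default_vta_params):
        with pytest.raises(ValueError):
            vta_radius_point_source(-1.0, default_vta_params)

    def test_monotone_in_amplitude(self, default_vta_params):
        radii = [vta_radius_point_source(a, default_vta_params)
                 for a in np.arange(0.5, 8.5, 0.5)]
        assert np.all(np.diff(radii) > 0)

    def test_matches_numeric_field_thresholding(self, default_vta_params):
        """Analytic radius vs brute-force thresholding of the sampled field."""
        p = default_vta_params
        r_grid = np.arange(0.01, 6.0, 0.01)  # mm
        for amp in np.arange(0.5, 8.5, 0.5):
            e = (amp * 1e-3) / (4 * math.pi * p.sigma * (r_grid * 1e-3) ** 2)
            e_mm = e / 1e3  # V/m -> V/mm
            i = int(np.flatnonzero(e_mm >= p.e_threshold).max())
            # locate the threshold crossing between the bracketing samples
            numeric = r_grid[i] + (e_mm[i] - p.e_threshold) / \
                (e_mm[i] - e_mm[i + 1]) * (r_grid[i + 1] - r_grid[i])
            analytic = vta_radius_point_source(float(amp), p)
            assert abs(analytic - numeric) / analytic < 0.005


class TestVtaForSetting:
    def test_level1_equals_contact1(self, canonical_lead):
        a = vta_for_setting(canonical_lead, StimSetting("L1", 2.0))
        b = vta_for_setting(canonical_lead, StimSetting("C1", 2.0))
        np.testing.assert_allclose(a.center, b.center)
        assert a.radius == b.radius and a.sector_axis is None

    def test_pseudoring_is_on_axis(self, canonical_lead):
        vta = vta_for_setting(canonical_lead, StimSetting("L2", 2.0))
        np.testing.assert_allclose(vta.center, [0, 0, 2.75])
        assert vta.sector_axis is None

    def test_segment_sector_containment(self, canonical_lead):
        vta = vta_for_setting(canonical_lead, StimSetting("C2", 2.0))
        out = vta.sector_axis
        assert point_in_vta(vta.center + 0.5 * out, vta)
        assert not point_in_vta(vta.center - 2.0 * out, vta)

    def test_nesting_in_amplitude(self, canonical_lead):
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 3, (1000, 3))
        for cfg in ALL_CONFIGS:
            lo = vta_for_setting(canonical_lead, StimSetting(cfg, 1.0))
            hi = vta_for_setting(canonical_lead, StimSetting(cfg, 1.5))
            inside_lo = np.array([point_in_vta(p, lo) for p in pts])
            inside_hi = np.array([point_in_vta(p, hi) for p in pts])
            assert np.all(~inside_lo | inside_hi)

    def test_full_width_sector_degenerates_to_sphere(self, canonical_lead):
        params = VTAParams(sector_width_deg=360.0)
        vta = vta_for_setting(canonical_lead, StimSetting("C2", 2.0), params)
        assert vta.sector_axis is None

    def test_full_width_sector_accepts_every_direction(self):
        """A 360-degree sector is degenerate: membership reduces to the
        plain sphere test whatever the direction from the centre."""
        rng = np.random.default_rng(2)
        ax = np.array([1.0, 0.0, 0.0])
        sector = VTA(center=np.zeros(3), radius=2.0, sector_axis=ax,
                     sector_width_deg=360.0)
        sphere = VTA(center=np.zeros(3), radius=2.0)
        pts = rng.normal(0, 1.5, (2000, 3))
        for p in pts:
            assert point_in_vta(p, sector) == point_in_vta(p, sphere)

    def test_unknown_config_rejected(self, canonical_lead):
        with pytest.raises(ValueError):
            StimSetting("C9", 2.0)

    def test_off_grid_amplitude_rejected(self):
        with pytest.raises(ValueError):
            StimSetting("C1", 2.3)


class TestPointInVta:
    def test_center_and_boundary(self):
        vta = VTA(center=np.zeros(3), radius=1.0)
        assert point_in_vta([0, 0, 0], vta)
        assert not point_in_vta([0, 0, 1.0 + 1e-9], vta)

    def test_voxelized_agrees_with_analytic(self, canonical_lead):
        vta = vta_for_setting(canonical_lead, StimSetting("C2", 3.0))
        mask = voxelize_vta(vta, voxel_size_mm=0.2, margin_mm=6.0)
        rng = np.random.default_rng(3)
        pts = vta.center + rng.uniform(-2.5, 2.5, (10000, 3)) * vta.radius
        agree = sum(point_in_vta(p, vta) == point_in_vta(p, mask)
                    for p in pts)
        assert agree / len(pts) >= 0.99
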