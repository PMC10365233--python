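"""Geometry, reproducibility and review semantics of the synthetic cohort."""

import numpy as np
import pytest

from tractstim.lead_vta import ALL_CONFIGS
from tractstim.synthetic_cohort import (
    SyntheticParams,
    generate_cohort,
    make_cst_bundle,
    make_hdp_bundle,
    place_lead,
    simulate_review,
    stn_for_hemisphere,
)
from tractstim.tract_io import AMPLITUDE_GRID

PARAMS = SyntheticParams(seed=21, n_streamlines_hdp=120,
                         n_streamlines_cst=300)


class TestHdpBundle:
    def test_terminals_inside_dorsolateral_sector(self):
        stn = stn_for_hemisphere(PARAMS, "right")
        rng = np.random.default_rng(1)
        bundle = make_hdp_bundle(PARAMS, "S01", "right", rng)
        assert len(bundle) == PARAMS.n_streamlines_hdp
        ends = np.array([s.points[-1] for s in bundle.streamlines])
        assert stn.contains(ends).all()
        rel = ends - stn.center
        cosang = (rel @ stn.dorsolateral) / np.linalg.norm(rel, axis=1)
        assert (cosang >= np.cos(np.radians(
            PARAMS.dorsolateral_half_angle_deg)) - 1e-9).all()

    def test_length_bound(self):
        rng = np.random.default_rng(2)
        bundle = make_hdp_bundle(PARAMS, "S01", "left", rng)
        assert max(s.length() for s in bundle.streamlines) <= \
            PARAMS.hdp_max_length

    def test_step_bound_and_weights(self):
        rng = np.random.default_rng(3)
        bundle = make_hdp_bundle(PARAMS, "S01", "right", rng)
        for s in bundle.streamlines[:20]:
            steps = np.linalg.norm(np.diff(s.points, axis=0), axis=1)
            assert steps.max() <= PARAMS.step_mm + 1e-9
            assert s.weight > 0

    def test_same_seed_reproducible(self):
        b1 = make_hdp_bundle(PARAMS, "S01", "right", np.random.default_rng(4))
        b2 = make_hdp_bundle(PARAMS, "S01", "right", np.random.default_rng(4))
        for s1, s2 in zip(b1.streamlines, b2.streamlines):
            np.testing.assert_array_equal(s1.points, s2.points)
            assert s1.weight == s2.weight


class TestCstBundle:
    def test_stays_out_of_stn(self):
        stn = stn_for_hemisphere(PARAMS, "right")
        rng = np.random.default_rng(5)
        bundle = make_cst_bundle(PARAMS, "S01", "right", rng)
        assert len(bundle) == PARAMS.n_streamlines_cst
        pts = np.concatenate([s.points for s in bundle.streamlines])
        assert stn.contains(pts).sum() == 0

    def test_length_band(self):
        rng = np.random.default_rng(6)
        for hemi in ("left", "right"):
            bundle = make_cst_bundle(PARAMS, "S01", hemi, rng)
            lengths = [s.length() for s in bundle.streamlines]
            assert min(lengths) >= PARAMS.cst_min_length
            assert max(lengths) <= PARAMS.cst_max_length

    def test_core_clear_of_stn_center(self):
        """The tube core line stays farther from the STN centre than the
        largest semi-axis."""
        from tractstim.synthetic_cohort import _cst_core
        for hemi in ("left", "right"):
            stn = stn_for_hemisphere(PARAMS, hemi)
            anchor, down = _cst_core(PARAMS, stn)
            rel = stn.center - anchor
            perp = rel - (rel @ down) * down
            assert np.linalg.norm(perp) > stn.semi_axes.max()

    def test_same_seed_reproducible(self):
        b1 = make_cst_bundle(PARAMS, "S01", "right", np.random.default_rng(8))
        b2 = make_cst_bundle(PARAMS, "S01", "right", np.random.default_rng(8))
        np.testing.assert_array_equal(b1.streamlines[0].points,
                                      b2.streamlines[0].points)


class TestPlaceLead:
    def test_tip_near_target_and_tilt_bound(self):
        stn = stn_for_hemisphere(PARAMS, "right")
        canonical = np.array([0.2, 0.35, 1.0])
        canonical /= np.linalg.norm(canonical)
        rng = np.random.default_rng(9)
        for _ in range(20):
            lead = place_lead(PARAMS, stn, rng)
            target = stn.dorsolateral_pole + \
                PARAMS.lead_standoff_mm * stn.dorsolateral
            tip_nominal = target - lead.level_offset(2) * lead.axis
            # isotropic jitter plus axial implant-depth jitter
            spread = np.hypot(PARAMS.lead_jitter_mm,
                              PARAMS.lead_depth_jitter_mm)
            assert np.linalg.norm(lead.tip - tip_nominal) <= 5 * spread
            tilt = np.degrees(np.arccos(np.clip(
                lead.axis @ canonical, -1, 1)))
            assert tilt <= PARAMS.lead_tilt_max_deg + 1e-6

    def test_same_seed_reproducible(self):
        stn = stn_for_hemisphere(PARAMS, "left")
        l1 = place_lead(PARAMS, stn, np.random.default_rng(10))
        l2 = place_lead(PARAMS, stn, np.random.default_rng(10))
        np.testing.assert_array_equal(l1.tip, l2.tip)
        np.testing.assert_array_equal(l1.axis, l2.axis)
        assert l1.rotation == l2.rotation


class TestSimulateReview:
    @pytest.fixture(scope="class")
    @staticmethod
    def lead_and_bundles():
        stn = stn_for_hemisphere(PARAMS, "right")
        rng = np.random.default_rng(11)
        bundles = {
            "HDP": make_hdp_bundle(PARAMS, "S01", "right", rng),
            "CST": make_cst_bundle(PARAMS, "S01", "right", rng),
        }
        return place_lead(PARAMS, stn, rng), bundles

    def test_noiseless_observed_equals_truth(self, lead_and_bundles):
        lead, bundles = lead_and_bundles
        params = SyntheticParams(**{**PARAMS.__dict__, "p_noise": 0.0,
                                    "tested_fraction": 1.0})
        recs, truths = simulate_review(lead, bundles, params.true_models(),
                                       params, np.random.default_rng(12))
        assert len(recs) == len(ALL_CONFIGS)
        for rec in recs:
            assert rec.tested
            assert rec.effect_threshold == truths[rec.config_id]["effect"]
            assert rec.side_effect_threshold == \
                truths[rec.config_id]["side_effect"]

    def test_far_bundles_all_censored(self, lead_and_bundles):
        lead, bundles = lead_and_bundles
        far_lead = type(lead)(tip=lead.tip + 500.0, axis=lead.axis,
                              rotation=lead.rotation)
        recs, _ = simulate_review(far_lead, bundles, PARAMS.true_models(),
                                  PARAMS, np.random.default_rng(13))
        for rec in recs:
            if rec.tested:
                assert rec.effect_threshold is None
                assert rec.side_effect_threshold is None

    def test_thresholds_on_grid(self, lead_and_bundles):
        lead, bundles = lead_and_bundles
        recs, _ = simulate_review(lead, bundles, PARAMS.true_models(),
                                  PARAMS, np.random.default_rng(14))
        for rec in recs:
            for v in (rec.effect_threshold, rec.side_effect_threshold):
                if v is not None:
                    assert v in AMPLITUDE_GRID and v >= 1.0

    def test_tested_fraction_one_tests_everything(self, lead_and_bundles):
        lead, bundles = lead_and_bundles
        params = SyntheticParams(**{**PARAMS.__dict__, "tested_fraction": 1.0})
        recs, _ = simulate_review(lead, bundles, params.true_models(),
                                  params, np.random.default_rng(15))
        assert all(r.tested for r in recs)

    def test_abort_rule_side_effect_first(self, lead_and_bundles):
        lead, bundles = lead_and_bundles
        recs, _ = simulate_review(lead, bundles, PARAMS.true_models(),
                                  PARAMS, np.random.default_rng(16))
        for rec in recs:
            if rec.effect_threshold is not None and \
                    rec.side_effect_threshold is not None:
                assert rec.side_effect_threshold >= rec.effect_threshold


class TestGenerateCohort:
    def test_structure_and_determinism(self, small_cohort):
        p = small_cohort.params
        assert len(small_cohort.leads) == p.n_subjects * p.leads_per_subject
        assert len(small_cohort.subject_ids) == p.n_subjects
        assert len(small_cohort.reviews) == \
            len(small_cohort.leads) * len(ALL_CONFIGS)
        again = generate_cohort(p)
        lid = sorted(small_cohort.leads)[0]
        np.testing.assert_array_equal(small_cohort.leads[lid].tip,
                                      again.leads[lid].tip)
        assert small_cohort.reviews == again.reviews

    def test_activation_profiles_monotone(self, small_cohort):
        for lid, table in small_cohort.activation_tables.items():
            for pathway, cfgs in table.items():
                for cfg, prof in cfgs.items():
                    vals = [prof[a] for a in sorted(prof)]
                    assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_review_grid_membership(self, small_cohort):
        for rec in small_cohort.reviews:
            for v in (rec.effect_threshold, rec.side_effect_threshold):
                assert v is None or v in AMPLITUDE_GRID
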