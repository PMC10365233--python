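"""Fully synthetic STN-DBS cohort with a known ground-truth response.

The generator emulates the statistical structure the analysis assumes: per
hemisphere, a hyperdirect-pathway (HDP) bundle converging from a frontal
cortical disc onto the dorsolateral sector of an ellipsoidal STN, and a
corticospinal-tract (CST) tube descending just posterolateral to the STN;
an 8-contact directional lead targeted at the dorsolateral STN border with
millimetre placement jitter; and a monopolar review simulated from known
logistic ground-truth models on the clinical 0.5 mA amplitude grid, with
optional one-step threshold jitter, censoring at 8 mA, and partial testing
of directional contacts.

Coordinates are world millimetres in a single shared space (an MNI-like
frame: +x right, +y anterior, +z superior).  No image grid is involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .activation import activation_profile
from .lead_vta import ALL_CONFIGS, CONTACT_CONFIGS, LeadModel, VTAParams
from .stim_models import StimulationModel
from .tract_io import AMPLITUDE_GRID, ReviewRecord, Streamline, TractBundle

__all__ = [
    "SyntheticParams",
    "StnEllipsoid",
    "SyntheticCohort",
    "stn_for_hemisphere",
    "make_hdp_bundle",
    "make_cst_bundle",
    "place_lead",
    "simulate_review",
    "lead_activation_table",
    "generate_cohort",
]


@dataclass
class SyntheticParams:
    """Knobs of the synthetic cohort (distances in mm, thresholds in mA)."""

    n_subjects: int = 20
    leads_per_subject: int = 2          # one per hemisphere
    n_streamlines_hdp: int = 500
    n_streamlines_cst: int = 2000
    weight_mu: float = 0.0              # log-normal streamline weights
    weight_sigma: float = 0.8
    # STN ellipsoid (right hemisphere; the left is mirrored in x).
    # Long axis anteroposterior; dorsolateral pole toward +x+z.
    stn_center_right: tuple[float, float, float] = (12.0, -13.0, -7.0)
    stn_semi_axes: tuple[float, float, float] = (3.0, 5.0, 3.0)
    dorsolateral_half_angle_deg: float = 45.0
    # Lead placement: tip near the dorsolateral border, jittered.
    lead_jitter_mm: float = 1.0
    lead_depth_jitter_mm: float = 2.0   # extra variability along the axis
    lead_tilt_max_deg: float = 10.0
    lead_standoff_mm: float = 2.0       # target above the dorsolateral pole
    # HDP: cortical source disc, descent-corridor scatter, length bound.
    hdp_disc_center: tuple[float, float, float] = (28.0, 15.0, 55.0)
    hdp_disc_radius: float = 8.0
    hdp_corridor_sigma: float = 4.0     # lateral fan-out of the funnel, mm
    hdp_max_length: float = 90.0
    # CST: descending tube posterolateral to the STN.
    cst_tube_radius: float = 1.5
    cst_gap_mm: float = 4.0             # dorsolateral pole to tube core, mm
    cst_min_length: float = 80.0
    cst_max_length: float = 135.0
    cst_clearance_mm: float = 1.7       # min contact-to-tube-edge distance
    # Ground-truth stimulation models (intercept, slope per activation unit).
    hdp_true_beta: tuple[float, float] = (-1.15, 11.5)    # a50 = 0.10
    cst_true_beta: tuple[float, float] = (-1.533, 153.3)  # a50 = 0.01
    # Review simulation.
    p_noise: float = 0.2                # one-grid-step threshold jitter
    tested_fraction: float = 0.608      # of directional contacts
    step_mm: float = 1.0                # polyline sampling step
    vta_params: VTAParams = field(default_factory=VTAParams)
    seed: int = 0

    def true_models(self) -> dict[str, StimulationModel]:
        return {
            "HDP": StimulationModel("HDP", *self.hdp_true_beta),
            "CST": StimulationModel("CST", *self.cst_true_beta),
        }


@dataclass
class StnEllipsoid:
    """Axis-aligned ellipsoidal STN with a marked dorsolateral direction."""

    center: np.ndarray
    semi_axes: np.ndarray
    dorsolateral: np.ndarray   # unit vector toward the dorsolateral pole

    def radius_along(self, direction: np.ndarray) -> float:
        """Distance from centre to surface along a unit direction."""
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        return 1.0 / math.sqrt(float(np.sum((d / self.semi_axes) ** 2)))

    @property
    def dorsolateral_pole(self) -> np.ndarray:
        return self.center + self.radius_along(self.dorsolateral) * self.dorsolateral

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        u = (pts - self.center) / self.semi_axes
        return np.einsum("ij,ij->i", u, u) <= 1.0


def stn_for_hemisphere(params: SyntheticParams, hemisphere: str) -> StnEllipsoid:
    sign = 1.0 if hemisphere == "right" else -1.0
    center = np.array(params.stn_center_right, dtype=float)
    center[0] *= sign
    dl = np.array([sign, 0.0, 1.0]) / math.sqrt(2.0)
    return StnEllipsoid(center=center,
                        semi_axes=np.array(params.stn_semi_axes, dtype=float),
                        dorsolateral=dl)


def _sample_in_cone(axis: np.ndarray, half_angle_deg: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Uniform direction within a cone about ``axis``."""
    cos_max = math.cos(math.radians(half_angle_deg))
    c = rng.uniform(cos_max, 1.0)
    phi = rng.uniform(0.0, 2.0 * math.pi)
    s = math.sqrt(max(0.0, 1.0 - c * c))
    local = np.array([s * math.cos(phi), s * math.sin(phi), c])
    # rotate local +z onto axis
    z = np.array([0.0, 0.0, 1.0])
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    v = np.cross(z, a)
    if np.linalg.norm(v) < 1e-12:
        return local if a[2] > 0 else -local
    cth = float(np.dot(z, a))
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    rot = np.eye(3) + vx + vx @ vx / (1.0 + cth)
    return rot @ local


def _bezier(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
            step_mm: float) -> np.ndarray:
    """Quadratic Bezier sampled so no step exceeds ``step_mm``.

    The parametric speed is bounded by 2 max(|p1-p0|, |p2-p1|), which gives
    a safe uniform sample count.
    """
    speed = 2.0 * max(np.linalg.norm(p1 - p0), np.linalg.norm(p2 - p1))
    n = max(8, int(math.ceil(speed / step_mm)))
    t = np.linspace(0.0, 1.0, n + 1)[:, None]
    return ((1 - t) ** 2) * p0 + 2 * (1 - t) * t * p1 + (t ** 2) * p2


def make_hdp_bundle(params: SyntheticParams, subject: str, hemisphere: str,
                    rng: np.random.Generator) -> TractBundle:
    """Streamlines from a frontal cortical disc into the dorsolateral STN.

    Every streamline terminates inside the dorsolateral sector of the STN
    ellipsoid; lengths stay below ``hdp_max_length``; weights are
    log-normal.
    """
    stn = stn_for_hemisphere(params, hemisphere)
    sign = 1.0 if hemisphere == "right" else -1.0
    disc = np.array(params.hdp_disc_center, dtype=float)
    disc[0] *= sign
    streamlines: list[Streamline] = []
    for _ in range(params.n_streamlines_hdp):
        w_dir = _sample_in_cone(stn.dorsolateral,
                                params.dorsolateral_half_angle_deg, rng)
        f = rng.uniform(0.2, 1.0)
        end = stn.center + f * stn.radius_along(w_dir) * w_dir
        rho = params.hdp_disc_radius * math.sqrt(rng.uniform())
        phi = rng.uniform(0.0, 2.0 * math.pi)
        start = disc + np.array([rho * math.cos(phi), rho * math.sin(phi), 0.0])
        # each fibre descends its own corridor: the bend point scatters
        # laterally so the funnel is loose near the lead, tight at the STN
        scatter = rng.normal(0.0, params.hdp_corridor_sigma, size=2)
        control = np.array([end[0] + scatter[0],
                            0.5 * (start[1] + end[1]) + scatter[1],
                            0.55 * start[2] + 0.45 * end[2]])
        pts = _bezier(start, control, end, params.step_mm)
        weight = float(rng.lognormal(params.weight_mu, params.weight_sigma))
        streamlines.append(Streamline(pts, weight))
    return TractBundle("HDP", hemisphere, streamlines)


def _cst_core(params: SyntheticParams,
              stn: StnEllipsoid) -> tuple[np.ndarray, np.ndarray]:
    """Core line of the CST tube: anchor point and descending direction."""
    sign = 1.0 if stn.dorsolateral[0] > 0 else -1.0
    out2d = np.array([sign, -1.0, 0.0]) / math.sqrt(2.0)   # posterolateral
    anchor = stn.dorsolateral_pole + params.cst_gap_mm * out2d
    lean = 0.2   # outward lean keeps the descending tube off the STN belly
    down = np.array([sign * lean, -lean, -1.0])
    return anchor, down / np.linalg.norm(down)


def make_cst_bundle(params: SyntheticParams, subject: str, hemisphere: str,
                    rng: np.random.Generator) -> TractBundle:
    """A near-parallel descending tube passing posterolateral to the STN.

    The tube core runs alongside the dorsolateral STN border with a slight
    outward lean so no fibre enters the ellipsoid; lengths fall in the
    [cst_min_length, cst_max_length] band.
    """
    stn = stn_for_hemisphere(params, hemisphere)
    sign = 1.0 if hemisphere == "right" else -1.0
    anchor, down = _cst_core(params, stn)
    z_top, z_bottom = 45.0, -60.0
    streamlines: list[Streamline] = []
    for _ in range(params.n_streamlines_cst):
        rho = params.cst_tube_radius * math.sqrt(rng.uniform())
        phi = rng.uniform(0.0, 2.0 * math.pi)
        # disc offsets in the plane normal to the descent direction
        e1 = np.cross(down, np.array([0.0, 0.0, 1.0]))
        if np.linalg.norm(e1) < 1e-9:
            e1 = np.array([1.0, 0.0, 0.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(down, e1)
        off = rho * (math.cos(phi) * e1 + math.sin(phi) * e2)
        core = anchor + off
        t_top = (z_top - core[2]) / down[2]
        t_bot = (z_bottom - core[2]) / down[2]
        n = max(8, int(math.ceil(abs(t_bot - t_top) / params.step_mm)))
        t = np.linspace(t_top, t_bot, n + 1)[:, None]
        pts = core + t * down
        weight = float(rng.lognormal(params.weight_mu, params.weight_sigma))
        streamlines.append(Streamline(pts, weight))
    return TractBundle("CST", hemisphere, streamlines)


def place_lead(params: SyntheticParams, stn: StnEllipsoid,
               rng: np.random.Generator) -> LeadModel:
    """A directional lead targeted at the dorsolateral STN border.

    The canonical trajectory puts the second contact level a stand-off
    above the dorsolateral pole; the tip is jittered isotropically
    (``lead_jitter_mm``) and the axis tilted by up to ``lead_tilt_max_deg``.
    Placements whose contact span would come closer than
    ``cst_clearance_mm`` to the edge of the capsule tube are resampled, as
    surgical planning avoids trajectories through the internal capsule.
    """
    sign = 1.0 if stn.dorsolateral[0] > 0 else -1.0
    core_anchor, core_down = _cst_core(params, stn)
    for _ in range(64):
        axis = np.array([sign * 0.2, 0.35, 1.0])
        axis /= np.linalg.norm(axis)
        tilt = math.radians(params.lead_tilt_max_deg) * rng.uniform()
        azimuth = rng.uniform(0.0, 2.0 * math.pi)
        perp = np.cross(axis, np.array([0.0, 0.0, 1.0]))
        perp /= np.linalg.norm(perp)
        perp2 = np.cross(axis, perp)
        tilt_dir = math.cos(azimuth) * perp + math.sin(azimuth) * perp2
        axis = math.cos(tilt) * axis + math.sin(tilt) * tilt_dir
        axis /= np.linalg.norm(axis)
        lead = LeadModel(tip=np.zeros(3), axis=axis,
                         rotation=rng.uniform(0.0, 2.0 * math.pi))
        target = (stn.dorsolateral_pole
                  + params.lead_standoff_mm * stn.dorsolateral)
        tip = (target - lead.level_offset(2) * axis
               + rng.normal(0.0, params.lead_jitter_mm, size=3)
               + rng.normal(0.0, params.lead_depth_jitter_mm) * axis)
        span = tip + np.linspace(0.0, lead.level_offset(4), 32)[:, None] * axis
        rel = span - core_anchor
        dist = np.linalg.norm(rel - (rel @ core_down)[:, None] * core_down,
                              axis=1)
        if dist.min() >= (params.cst_tube_radius + params.cst_clearance_mm):
            return replace(lead, tip=tip)
    raise RuntimeError("could not place a lead clear of the capsule tube")


def _jitter_threshold(value: float | None, p_noise: float,
                      rng: np.random.Generator) -> float | None:
    """One-grid-step threshold jitter; clipped to the sweep, censored past 8."""
    if value is None:
        return None
    if rng.uniform() < p_noise:
        value = value + (0.5 if rng.uniform() < 0.5 else -0.5)
    value = round(value, 1)
    if value < 1.0:
        return 1.0
    if value > 8.0:
        return None
    return value


def _first_crossing(profile: Mapping[float, float], model: StimulationModel,
                    grid: tuple[float, ...]) -> float | None:
    for amp in grid:
        if model.probability(profile[amp]) >= model.class_cutoff:
            return float(amp)
    return None


def lead_activation_table(bundles: Mapping[str, TractBundle], lead: LeadModel,
                          params: VTAParams | None = None,
                          grid: tuple[float, ...] = AMPLITUDE_GRID,
                          ) -> dict[str, dict[str, dict[float, float]]]:
    """Activation profiles for every configuration and pathway of one lead.

    Returns ``{pathway: {config_id: {amplitude: fraction}}}``.
    """
    return {
        pathway: {
            cfg: activation_profile(bundle, lead, cfg, grid, params)
            for cfg in ALL_CONFIGS
        }
        for pathway, bundle in bundles.items()
    }


def simulate_review(lead: LeadModel, bundles: Mapping[str, TractBundle],
                    true_models: Mapping[str, StimulationModel],
                    params: SyntheticParams, rng: np.random.Generator,
                    subject_id: str = "S", lead_id: str = "S_L",
                    activation_table=None,
                    ) -> tuple[list[ReviewRecord], dict[str, dict[str, float | None]]]:
    """Simulate the monopolar review of one lead from the ground truth.

    The review sweeps 1-8 mA in 0.5 mA steps per configuration.  The true
    threshold is the first amplitude whose ground-truth model probability
    reaches the class cutoff; observed thresholds add one-grid-step jitter
    with probability ``p_noise`` and censor past 8 mA.  The sweep aborts
    (censoring the effect threshold) when the side effect comes strictly
    first, as clinical reviews do.  Directional contacts are untested with
    probability ``1 - tested_fraction``.

    Returns the review records plus the post-abort true thresholds per
    config (``{"effect": ..., "side_effect": ...}``).
    """
    table = activation_table or lead_activation_table(
        bundles, lead, params.vta_params)
    sweep = tuple(a for a in AMPLITUDE_GRID if a >= 1.0)
    records: list[ReviewRecord] = []
    truths: dict[str, dict[str, float | None]] = {}
    for cfg in ALL_CONFIGS:
        true_eff = _first_crossing(table["HDP"][cfg], true_models["HDP"], sweep)
        true_se = _first_crossing(table["CST"][cfg], true_models["CST"], sweep)
        if true_se is not None and (true_eff is None or true_se < true_eff):
            true_eff_recorded = None      # review aborted at the side effect
        else:
            true_eff_recorded = true_eff
        obs_eff = _jitter_threshold(true_eff, params.p_noise, rng)
        obs_se = _jitter_threshold(true_se, params.p_noise, rng)
        if obs_se is not None and (obs_eff is None or obs_se < obs_eff):
            obs_eff = None
        tested = True
        if cfg in CONTACT_CONFIGS and int(cfg[1]) in (2, 3, 4, 5, 6, 7):
            tested = bool(rng.uniform() < params.tested_fraction)
        truths[cfg] = {"effect": true_eff_recorded, "side_effect": true_se}
        if tested:
            records.append(ReviewRecord(
                subject_id=subject_id, lead_id=lead_id, config_id=cfg,
                effect_threshold=obs_eff,
                side_effect_threshold=obs_se,
                effect_censored=obs_eff is None,
                side_effect_censored=obs_se is None,
                tested=True,
            ))
        else:
            records.append(ReviewRecord(
                subject_id=subject_id, lead_id=lead_id, config_id=cfg,
                tested=False,
            ))
    return records, truths


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth, keyed by lead id."""

    params: SyntheticParams
    bundles: dict[tuple[str, str], dict[str, TractBundle]]  # (subject, hemi)
    leads: dict[str, LeadModel]
    lead_meta: dict[str, tuple[str, str]]                   # lead -> (subject, hemi)
    reviews: list[ReviewRecord]
    true_models: dict[str, StimulationModel]
    true_thresholds: dict[str, dict[str, dict[str, float | None]]]
    activation_tables: dict[str, dict[str, dict[str, dict[float, float]]]]

    @property
    def subject_ids(self) -> list[str]:
        return sorted({s for s, _ in self.bundles})

    def bundles_for_lead(self, lead_id: str) -> dict[str, TractBundle]:
        subject, hemi = self.lead_meta[lead_id]
        return self.bundles[(subject, hemi)]


def generate_cohort(params: SyntheticParams | None = None) -> SyntheticCohort:
    """Generate the full synthetic cohort, deterministically under the seed."""
    params = params or SyntheticParams()
    hemis = ("left", "right")[: params.leads_per_subject]
    if params.leads_per_subject > 2:
        raise ValueError("at most one lead per hemisphere is modelled")
    bundles: dict[tuple[str, str], dict[str, TractBundle]] = {}
    leads: dict[str, LeadModel] = {}
    lead_meta: dict[str, tuple[str, str]] = {}
    reviews: list[ReviewRecord] = []
    truths: dict[str, dict[str, dict[str, float | None]]] = {}
    tables: dict[str, dict[str, dict[str, dict[float, float]]]] = {}
    true_models = params.true_models()
    for si in range(params.n_subjects):
        subject = f"S{si + 1:02d}"
        for hi, hemi in enumerate(hemis):
            rng = np.random.default_rng([params.seed, si, hi])
            stn = stn_for_hemisphere(params, hemi)
            pair = {
                "HDP": make_hdp_bundle(params, subject, hemi, rng),
                "CST": make_cst_bundle(params, subject, hemi, rng),
            }
            lead = place_lead(params, stn, rng)
            lead_id = f"{subject}_{hemi[0].upper()}"
            table = lead_activation_table(pair, lead, params.vta_params)
            recs, truth = simulate_review(
                lead, pair, true_models, params, rng,
                subject_id=subject, lead_id=lead_id, activation_table=table)
            bundles[(subject, hemi)] = pair
            leads[lead_id] = lead
            lead_meta[lead_id] = (subject, hemi)
            reviews.extend(recs)
            truths[lead_id] = truth
            tables[lead_id] = table
    return SyntheticCohort(
        params=params, bundles=bundles, leads=leads, lead_meta=lead_meta,
        reviews=reviews, true_models=true_models, true_thresholds=truths,
        activation_tables=tables)
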