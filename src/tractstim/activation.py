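"""Weighted pathway activation inside a VTA.

The activation fraction of a bundle is the sum of the weights of the
streamlines intersecting the VTA divided by the bundle's total weight —
the independent variable of the stimulation models.

"Inside" means segment intersection of the polyline with the volume, not
vertex membership: for sphere VTAs the exact point-to-segment distance is
used; for sector-clipped spheres the minimum distance from the centre to
the part of the polyline satisfying the angular constraint is solved in
closed form per segment.  Mask VTAs fall back to a densified vertex test
(the Lead-DBS-style voxel criterion).

For a fixed lead configuration the VTA centre and sector are independent
of amplitude, so each streamline has a *critical radius*: the smallest
sphere radius at which it is activated.  Activation profiles over the
amplitude grid reduce to comparing critical radii against the kernel
radius, which also makes monotonicity in amplitude structural.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .lead_vta import LeadModel, StimSetting, VTA, VTAParams, vta_for_setting, \
    vta_radius_point_source, point_in_vta
from .tract_io import Streamline, TractBundle

__all__ = [
    "streamline_hits_vta",
    "activation_fraction",
    "activation_profile",
    "bundle_critical_radii",
]

_FEAS_TOL = 1e-9


def _segment_arrays(points_list: Sequence[np.ndarray]):
    """Concatenate polylines into segment start/end arrays plus reduce offsets.

    Joint segments between consecutive polylines are kept but masked out.
    Returns (A, B, valid, offsets) where offsets index the first segment of
    each polyline in the flat segment array.
    """
    pts = np.concatenate([np.asarray(p, dtype=float) for p in points_list], axis=0)
    lengths = np.array([len(p) for p in points_list])
    A = pts[:-1]
    B = pts[1:]
    valid = np.ones(len(A), dtype=bool)
    # Segment i joins pts[i] -> pts[i+1]; it bridges two polylines when
    # i+1 is the first point of the next polyline.  Keep those slots (so
    # reduceat blocks stay contiguous) but mask them out.
    joints = np.cumsum(lengths)[:-1]
    valid[joints - 1] = False
    offsets = np.concatenate([[0], joints])
    return A, B, valid, offsets


def _critical_radii_sq(points_list: Sequence[np.ndarray], center: np.ndarray,
                       sector_axis: np.ndarray | None,
                       sector_width_deg: float | None) -> np.ndarray:
    """Squared critical radius per polyline for a (sector-)sphere centre.

    The critical radius is min ||p - c|| over all points p of the polyline
    that satisfy the sector constraint (all points, for a plain sphere);
    +inf if no point of the polyline ever lies in the sector.
    """
    A, B, valid, offsets = _segment_arrays(points_list)
    d = B - A
    u0 = A - center
    q2 = np.einsum("ij,ij->i", d, d)
    q1 = 2.0 * np.einsum("ij,ij->i", u0, d)
    q0 = np.einsum("ij,ij->i", u0, u0)

    def q_at(t):
        return q2 * t * t + q1 * t + q0

    with np.errstate(divide="ignore", invalid="ignore"):
        tq = np.where(q2 > 0, -q1 / (2.0 * q2), 0.0)
    tq = np.clip(tq, 0.0, 1.0)

    use_sector = (
        sector_axis is not None
        and sector_width_deg is not None
        and sector_width_deg < 360.0
    )
    if not use_sector:
        crit_sq = q_at(tq)
    else:
        n = np.asarray(sector_axis, dtype=float)
        k = math.cos(math.radians(sector_width_deg / 2.0))
        g0 = u0 @ n
        g1 = d @ n
        # Candidate parameters where the constrained minimum of q can sit:
        # the interval endpoints, the unconstrained minimiser, the root of
        # the linear form g(t) = dot(u, n), and the roots of
        # G(t) = g(t)^2 - k^2 q(t) (the cone boundary).
        with np.errstate(divide="ignore", invalid="ignore"):
            t_g = np.where(g1 != 0, -g0 / g1, np.nan)
        a = g1 * g1 - k * k * q2
        b = 2 * g0 * g1 - k * k * q1
        c = g0 * g0 - k * k * q0
        disc = b * b - 4 * a * c
        sq = np.sqrt(np.maximum(disc, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            tG1 = np.where((np.abs(a) > 1e-300) & (disc >= 0),
                           (-b - sq) / (2 * a), np.nan)
            tG2 = np.where((np.abs(a) > 1e-300) & (disc >= 0),
                           (-b + sq) / (2 * a), np.nan)
            t_lin = np.where((np.abs(a) <= 1e-300) & (b != 0), -c / b, np.nan)
        cands = np.stack([
            np.zeros_like(q0), np.ones_like(q0), tq, t_g, tG1, tG2, t_lin,
        ], axis=1)
        in_range = (cands >= 0.0) & (cands <= 1.0)
        cands = np.where(in_range, cands, np.nan)
        # feasibility: angle(u(t), n) <= width/2, i.e. dot >= k * ||u||
        u = u0[:, None, :] + cands[:, :, None] * d[:, None, :]
        norm = np.linalg.norm(u, axis=2)
        dots = u @ n
        feas = in_range & (dots >= k * norm - _FEAS_TOL * (norm + 1.0))
        qv = (q2[:, None] * cands * cands + q1[:, None] * cands + q0[:, None])
        qv = np.where(feas, qv, np.inf)
        crit_sq = np.min(qv, axis=1)
        crit_sq = np.where(np.isnan(crit_sq), np.inf, crit_sq)

    crit_sq = np.where(valid, crit_sq, np.inf)
    per_stream = np.minimum.reduceat(crit_sq, offsets)
    return per_stream


def bundle_critical_radii(bundle: TractBundle, center: np.ndarray,
                          sector_axis: np.ndarray | None = None,
                          sector_width_deg: float | None = None) -> np.ndarray:
    """Smallest sphere radius activating each streamline of ``bundle``.

    ``inf`` for streamlines that never enter the sector.
    """
    pts = [s.points for s in bundle.streamlines]
    return np.sqrt(np.maximum(
        _critical_radii_sq(pts, np.asarray(center, dtype=float),
                           sector_axis, sector_width_deg), 0.0))


def streamline_hits_vta(streamline: Streamline, vta: VTA,
                        mask_step_fraction: float = 0.5) -> bool:
    """True iff any segment of the polyline intersects the VTA.

    Analytic VTAs are tested exactly; mask VTAs by densifying every
    segment to at most ``mask_step_fraction`` of the voxel size and
    vertex-testing the resampled points.
    """
    if vta.is_analytic:
        crit_sq = _critical_radii_sq(
            [streamline.points], vta.center, vta.sector_axis,
            vta.sector_width_deg)
        return bool(crit_sq[0] <= vta.radius ** 2)
    voxel = float(np.min(np.abs(np.diag(vta.affine)[:3])))
    step = mask_step_fraction * voxel
    pts = _densify(streamline.points, step)
    inv = np.linalg.inv(vta.affine)
    ijk = (inv[:3, :3] @ pts.T).T + inv[:3, 3]
    idx = np.rint(ijk).astype(int)
    ok = np.all((idx >= 0) & (idx < np.array(vta.grid.shape)), axis=1)
    if not ok.any():
        return False
    return bool(vta.grid[idx[ok, 0], idx[ok, 1], idx[ok, 2]].any())


def _densify(points: np.ndarray, max_step: float) -> np.ndarray:
    seg = np.diff(points, axis=0)
    lens = np.linalg.norm(seg, axis=1)
    out = [points[:1]]
    for i, L in enumerate(lens):
        n = max(1, int(math.ceil(L / max_step)))
        t = np.linspace(0, 1, n + 1)[1:, None]
        out.append(points[i] + t * seg[i])
    return np.concatenate(out, axis=0)


def activation_fraction(bundle: TractBundle, vta: VTA) -> float:
    """Weighted fraction of ``bundle`` inside ``vta`` (in [0, 1])."""
    weights = bundle.weights
    if vta.is_analytic:
        crit = bundle_critical_radii(
            bundle, vta.center, vta.sector_axis, vta.sector_width_deg)
        hit = crit <= vta.radius
    else:
        hit = np.array([streamline_hits_vta(s, vta)
                        for s in bundle.streamlines])
    return float(weights[hit].sum() / weights.sum())


def activation_profile(bundle: TractBundle, lead: LeadModel, config_id: str,
                       grid: Sequence[float],
                       params: VTAParams | None = None) -> dict[float, float]:
    """Activation fraction of ``bundle`` over an amplitude grid for one config.

    Computed via per-streamline critical radii, so the profile is
    non-decreasing in amplitude by construction (VTA nesting).
    """
    params = params or VTAParams()
    ref = vta_for_setting(lead, StimSetting(config_id, grid[0] if grid else 1.0),
                          params)
    crit = bundle_critical_radii(
        bundle, ref.center, ref.sector_axis, ref.sector_width_deg)
    weights = bundle.weights
    total = weights.sum()
    out: dict[float, float] = {}
    for amp in grid:
        r = vta_radius_point_source(amp, params)
        out[float(amp)] = float(weights[crit <= r].sum() / total)
    return out
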