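"""Directional-lead geometry and simplified volumes of tissue activated.

The lead is an 8-contact directional electrode (Boston Scientific Vercise
Cartesia layout): a distal ring, two levels of three 120-degree segments,
and a proximal ring, with 1.5 mm contacts on a 2.0 mm pitch.

VTAs follow the thresholded e-field idea: the full finite-element field is
replaced by the homogeneous point-source closed form

    E(r) = I / (4 pi sigma r^2),

thresholded at ``e_threshold`` so a sphere of radius

    r(I) = sqrt(I / (4 pi sigma E_t))

is activated.  Segmented contacts additionally clip the sphere to an
angular sector about the contact's outward normal.  The kernel is
deliberately simple; its parameters (conductivity, threshold) are the
knobs a practitioner would recognise from VTA modelling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .tract_io import AMPLITUDE_GRID

__all__ = [
    "LeadModel",
    "ContactFrame",
    "StimSetting",
    "VTAParams",
    "VTA",
    "LEVEL_CONFIGS",
    "CONTACT_CONFIGS",
    "ALL_CONFIGS",
    "contact_frames",
    "vta_radius_point_source",
    "vta_for_setting",
    "point_in_vta",
    "voxelize_vta",
]

LEVEL_CONFIGS = ("L1", "L2", "L3", "L4")
CONTACT_CONFIGS = tuple(f"C{i}" for i in range(1, 9))
ALL_CONFIGS = LEVEL_CONFIGS + CONTACT_CONFIGS

#: contact id -> (level, kind, angle index for segments)
_CONTACT_LAYOUT = {
    1: (1, "ring", None),
    2: (2, "segment", 0),
    3: (2, "segment", 1),
    4: (2, "segment", 2),
    5: (3, "segment", 0),
    6: (3, "segment", 1),
    7: (3, "segment", 2),
    8: (4, "ring", None),
}


@dataclass
class LeadModel:
    """Pose plus geometry constants of one 1-3-3-1 directional lead."""

    tip: np.ndarray                 # distal contact base, world mm
    axis: np.ndarray                # unit vector, distal -> proximal
    rotation: float = 0.0           # rad; direction of segment "a" (contacts 2/5)
    contact_length: float = 1.5     # mm
    inter_contact_gap: float = 0.5  # mm
    lead_radius: float = 0.635      # mm

    def __post_init__(self) -> None:
        self.tip = np.asarray(self.tip, dtype=float)
        axis = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm == 0 or not np.isfinite(norm):
            raise ValueError("lead axis must be a non-zero finite vector")
        self.axis = axis / norm

    @property
    def pitch(self) -> float:
        """Centre-to-centre level spacing: contact length + gap."""
        return self.contact_length + self.inter_contact_gap

    def level_offset(self, level: int) -> float:
        """Axial offset (mm) of a level centroid from the tip."""
        return self.contact_length / 2 + (level - 1) * self.pitch

    def level_centroid(self, level: int) -> np.ndarray:
        return self.tip + self.level_offset(level) * self.axis

    def radial_basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic perpendicular frame (e1, e2) with e2 = axis x e1.

        e1 at ``rotation=0`` is the projection of world +x onto the plane
        normal to the axis (falls back to +y for an axis parallel to x).
        """
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, self.axis)) > 0.99:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = ref - np.dot(ref, self.axis) * self.axis
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(self.axis, e1)
        return e1, e2


@dataclass
class ContactFrame:
    contact_id: int
    level: int
    kind: str                       # "ring" | "segment"
    centroid: np.ndarray            # world mm
    outward: np.ndarray | None      # unit vector, segments only


@dataclass
class StimSetting:
    """One monopolar stimulation setting (frequency/pulse width are metadata)."""

    config_id: str
    amplitude: float                # mA
    pulse_width_us: float = 60.0
    frequency_hz: float = 130.0

    def __post_init__(self) -> None:
        if self.config_id not in ALL_CONFIGS:
            raise ValueError(f"unknown config_id {self.config_id!r}")
        if round(self.amplitude, 1) not in AMPLITUDE_GRID:
            raise ValueError(
                f"amplitude {self.amplitude} mA is off the 0.5 mA sweep grid"
            )


@dataclass
class VTAParams:
    """Parameters of the simplified VTA kernel.

    sigma is the grey-matter conductivity in S/m; ``sigma_white`` is
    accepted for completeness but unused by the homogeneous point-source
    kernel.  ``e_threshold`` is in V/mm (0.2 V/mm gives millimetre-scale
    radii at clinical amplitudes).
    """

    sigma: float = 0.33             # S/m (grey matter)
    sigma_white: float = 0.14       # S/m (unused by the default kernel)
    e_threshold: float = 0.2        # V/mm
    kernel: str = "point_source"
    sector_width_deg: float = 180.0  # angular width of a segment VTA
    radial_offset_fraction: float = 1.0  # segment centroid offset, x lead_radius

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.e_threshold <= 0:
            raise ValueError("e_threshold must be positive")
        if not 0 < self.sector_width_deg <= 360:
            raise ValueError("sector_width_deg must lie in (0, 360]")
        if self.kernel != "point_source":
            raise ValueError(f"unknown VTA kernel {self.kernel!r}")


@dataclass
class VTA:
    """Analytic (sphere, optionally sector-clipped) or voxel-mask VTA."""

    center: np.ndarray | None = None
    radius: float | None = None
    sector_axis: np.ndarray | None = None   # outward unit vector
    sector_width_deg: float | None = None   # full width, degrees
    grid: np.ndarray | None = None          # boolean voxel grid
    affine: np.ndarray | None = None        # voxel -> world mm

    @property
    def is_analytic(self) -> bool:
        return self.center is not None

    def __post_init__(self) -> None:
        if self.is_analytic:
            self.center = np.asarray(self.center, dtype=float)
            if self.radius is None or self.radius < 0:
                raise ValueError("analytic VTA needs a radius >= 0")
            if self.sector_axis is not None:
                ax = np.asarray(self.sector_axis, dtype=float)
                self.sector_axis = ax / np.linalg.norm(ax)
                if not 0 < (self.sector_width_deg or 0) <= 360:
                    raise ValueError("sector width must lie in (0, 360] degrees")
        elif self.grid is None or self.affine is None:
            raise ValueError("a VTA is either analytic or a voxel mask")


def contact_frames(lead: LeadModel,
                   radial_offset_fraction: float = 1.0) -> list[ContactFrame]:
    """Centroids and outward normals of the 8 contacts of ``lead``.

    Ring centroids sit on the lead axis; segment centroids are displaced
    ``radial_offset_fraction * lead_radius`` along their outward normal.
    Segment angles are ``rotation + {0, 120, 240}`` degrees about the axis.
    """
    e1, e2 = lead.radial_basis()
    frames: list[ContactFrame] = []
    for cid, (level, kind, angle_idx) in _CONTACT_LAYOUT.items():
        centroid = lead.level_centroid(level)
        outward = None
        if kind == "segment":
            theta = lead.rotation + angle_idx * (2 * math.pi / 3)
            outward = math.cos(theta) * e1 + math.sin(theta) * e2
            centroid = centroid + radial_offset_fraction * lead.lead_radius * outward
        frames.append(ContactFrame(cid, level, kind, centroid, outward))
    return frames


def vta_radius_point_source(amplitude_ma: float, params: VTAParams) -> float:
    """Activated radius (mm) of the thresholded point-source field.

    E(r) = I / (4 pi sigma r^2) >= E_t  <=>  r <= sqrt(I / (4 pi sigma E_t)).
    Amplitude is in mA, sigma in S/m, E_t in V/mm; the radius comes out in mm.
    """
    if amplitude_ma < 0:
        raise ValueError("amplitude must be non-negative")
    current_a = amplitude_ma * 1e-3
    e_t_v_per_m = params.e_threshold * 1e3
    r_m = math.sqrt(current_a / (4 * math.pi * params.sigma * e_t_v_per_m))
    return r_m * 1e3


def vta_for_setting(lead: LeadModel, setting: StimSetting,
                    params: VTAParams | None = None) -> VTA:
    """Analytic VTA for one stimulation setting on ``lead``.

    Rings and pseudorings (level configs) give a sphere at the level
    centroid; a directional contact gives a sphere at its offset centroid
    clipped to the angular sector about its outward normal.  For a fixed
    configuration, VTAs are nested in amplitude.
    """
    params = params or VTAParams()
    radius = vta_radius_point_source(setting.amplitude, params)
    cfg = setting.config_id
    if cfg in LEVEL_CONFIGS:
        level = int(cfg[1])
        return VTA(center=lead.level_centroid(level), radius=radius)
    frames = {f.contact_id: f for f in
              contact_frames(lead, params.radial_offset_fraction)}
    frame = frames[int(cfg[1])]
    if frame.kind == "ring":
        return VTA(center=frame.centroid, radius=radius)
    if params.sector_width_deg >= 360.0:
        return VTA(center=frame.centroid, radius=radius)
    return VTA(center=frame.centroid, radius=radius,
               sector_axis=frame.outward,
               sector_width_deg=params.sector_width_deg)


def point_in_vta(point: np.ndarray, vta: VTA) -> bool:
    """Membership test for a single point (distance + sector, or voxel lookup)."""
    point = np.asarray(point, dtype=float)
    if vta.is_analytic:
        u = point - vta.center
        dist = float(np.linalg.norm(u))
        if dist > vta.radius:
            return False
        if vta.sector_axis is None or dist == 0.0:
            return True
        cos_half = math.cos(math.radians(vta.sector_width_deg / 2))
        return float(np.dot(u, vta.sector_axis)) >= cos_half * dist
    ijk = np.linalg.inv(vta.affine) @ np.append(point, 1.0)
    idx = np.rint(ijk[:3]).astype(int)
    if np.any(idx < 0) or np.any(idx >= vta.grid.shape):
        return False
    return bool(vta.grid[tuple(idx)])


def voxelize_vta(vta: VTA, voxel_size_mm: float = 0.2,
                 margin_mm: float = 1.0) -> VTA:
    """Rasterise an analytic VTA onto an isotropic voxel grid.

    Voxel centres inside the analytic volume are marked; the affine maps
    voxel indices to world mm.
    """
    if not vta.is_analytic:
        return vta
    lo = vta.center - vta.radius - margin_mm
    n = int(math.ceil((2 * (vta.radius + margin_mm)) / voxel_size_mm)) + 1
    affine = np.eye(4)
    affine[:3, :3] *= voxel_size_mm
    affine[:3, 3] = lo
    idx = np.indices((n, n, n)).reshape(3, -1).T
    pts = idx * voxel_size_mm + lo
    u = pts - vta.center
    dist = np.linalg.norm(u, axis=1)
    inside = dist <= vta.radius
    if vta.sector_axis is not None:
        cos_half = math.cos(math.radians(vta.sector_width_deg / 2))
        dots = u @ vta.sector_axis
        with np.errstate(invalid="ignore"):
            ok = dots >= cos_half * dist
        ok |= dist == 0
        inside &= ok
    grid = np.zeros((n, n, n), dtype=bool)
    grid[idx[:, 0], idx[:, 1], idx[:, 2]] = inside
    return VTA(grid=grid, affine=affine)
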