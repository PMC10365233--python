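"""Readers and writers for the formats the pipeline touches.

Streamline bundles travel as MRtrix TCK files with a companion plain-text
weights file (one positive float per streamline, the SIFT2 convention).
Monopolar-review tables and lead poses are CSV; binary VTA masks are
NIfTI-1.  All coordinates are world millimetres in one shared physical
space; nothing here resamples or warps.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "Streamline",
    "TractBundle",
    "ReviewRecord",
    "TckFormatError",
    "AMPLITUDE_GRID",
    "read_tck",
    "write_tck",
    "read_weights",
    "write_weights",
    "read_mask_nifti",
    "write_mask_nifti",
    "read_reviews",
    "write_reviews",
    "read_lead_poses",
    "write_lead_poses",
    "write_report",
]

#: The monopolar-review amplitude sweep: 0.5 .. 8.0 mA in 0.5 mA steps.
AMPLITUDE_GRID = tuple(round(0.5 * k, 1) for k in range(1, 17))

#: Token used to serialize a censored threshold (sweep ended at 8 mA
#: without reaching the effect / side effect).
CENSOR_TOKEN = ">8"

REVIEW_COLUMNS = (
    "subject_id",
    "lead_id",
    "config_id",
    "effect_threshold_mA",
    "side_effect_threshold_mA",
    "tested",
)

VALID_CONFIG_IDS = tuple(f"L{i}" for i in range(1, 5)) + tuple(
    f"C{i}" for i in range(1, 9)
)


class TckFormatError(ValueError):
    """Raised when a track file violates the MRtrix TCK format."""


@dataclass
class Streamline:
    """An ordered 3-D polyline with a positive SIFT2-style weight.

    Coordinates are world millimetres.
    """

    points: np.ndarray  # (n, 3) float
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("streamline points must be an (n, 3) array")
        if self.points.shape[0] < 2:
            raise ValueError("a streamline needs at least 2 points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("streamline coordinates must be finite")
        if not (self.weight > 0 and math.isfinite(self.weight)):
            raise ValueError("streamline weight must be a positive finite real")

    def length(self) -> float:
        """Arc length in mm."""
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class TractBundle:
    """A named, single-hemisphere collection of weighted streamlines."""

    name: str
    hemisphere: str
    streamlines: list[Streamline]

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right"):
            raise ValueError("hemisphere must be 'left' or 'right'")
        if not self.streamlines:
            raise ValueError("a tract bundle cannot be empty")

    @property
    def total_weight(self) -> float:
        return float(sum(s.weight for s in self.streamlines))

    @property
    def weights(self) -> np.ndarray:
        return np.array([s.weight for s in self.streamlines], dtype=float)

    def __len__(self) -> int:
        return len(self.streamlines)


@dataclass
class ReviewRecord:
    """One monopolar-review row: thresholds for a single lead configuration.

    ``effect_threshold`` / ``side_effect_threshold`` are mA values on the
    0.5 mA grid, or ``None``.  A ``None`` threshold means *censored* (the
    sweep reached 8 mA without the effect) when the matching ``*_censored``
    flag is set, and *missing / not recorded* otherwise.  ``tested=False``
    marks configurations skipped in the review.
    """

    subject_id: str
    lead_id: str
    config_id: str
    effect_threshold: float | None = None
    side_effect_threshold: float | None = None
    effect_censored: bool = False
    side_effect_censored: bool = False
    tested: bool = True

    def __post_init__(self) -> None:
        if self.config_id not in VALID_CONFIG_IDS:
            raise ValueError(
                f"unknown config_id {self.config_id!r}; expected one of "
                f"{', '.join(VALID_CONFIG_IDS)}"
            )
        for label, value in (
            ("effect_threshold", self.effect_threshold),
            ("side_effect_threshold", self.side_effect_threshold),
        ):
            if value is not None and round(value, 1) not in AMPLITUDE_GRID:
                raise ValueError(
                    f"{label}={value} is not on the 0.5 mA grid "
                    f"{AMPLITUDE_GRID[0]}..{AMPLITUDE_GRID[-1]}"
                )
        if self.effect_censored and self.effect_threshold is not None:
            raise ValueError("a censored effect threshold cannot carry a value")
        if self.side_effect_censored and self.side_effect_threshold is not None:
            raise ValueError("a censored side-effect threshold cannot carry a value")


# ---------------------------------------------------------------------------
# TCK + weights
# ---------------------------------------------------------------------------


def read_tck(path: str | Path) -> list[Streamline]:
    """Read an MRtrix track (TCK) file into unit-weight streamlines.

    Delegates parsing to nibabel and validates the header on top of it:
    a missing/invalid datatype or magic raises :class:`TckFormatError`,
    and a ``count`` field that disagrees with the number of streamlines
    actually present triggers a warning (the streamlines found win).
    """
    path = Path(path)
    _validate_tck_header(path)
    try:
        tck = nib.streamlines.load(str(path), lazy_load=False)
    except Exception as exc:  # pragma: no cover - nibabel message passthrough
        raise TckFormatError(f"cannot parse {path.name}: {exc}") from exc
    streamlines = [Streamline(np.asarray(s, dtype=float)) for s in tck.streamlines]
    declared = tck.header.get("count")
    if declared is not None:
        try:
            declared_n = int(declared)
        except (TypeError, ValueError):
            declared_n = None
        if declared_n is not None and declared_n != len(streamlines):
            warnings.warn(
                f"{path.name}: header count={declared_n} but "
                f"{len(streamlines)} streamlines present; using the data",
                stacklevel=2,
            )
    return streamlines


def _validate_tck_header(path: Path) -> None:
    """Check the plain-text TCK header fields nibabel is lenient about."""
    with open(path, "rb") as fh:
        first = fh.readline()
        if not first.startswith(b"mrtrix tracks"):
            raise TckFormatError(
                f"{path.name}: missing 'mrtrix tracks' magic line"
            )
        datatype = None
        for _ in range(200):
            line = fh.readline()
            if not line or line.strip() == b"END":
                break
            if line.startswith(b"datatype:"):
                datatype = line.split(b":", 1)[1].strip().decode()
        if datatype is None:
            raise TckFormatError(f"{path.name}: header has no datatype field")
        if not datatype.startswith("Float32"):
            raise TckFormatError(
                f"{path.name}: unsupported datatype {datatype!r} "
                "(expected Float32LE/BE)"
            )


def write_tck(streamlines: Sequence[Streamline] | Sequence[np.ndarray],
              path: str | Path) -> None:
    """Write streamlines to a TCK file (weights are written separately)."""
    arrays = [
        np.asarray(s.points if isinstance(s, Streamline) else s, dtype=np.float32)
        for s in streamlines
    ]
    tractogram = nib.streamlines.Tractogram(arrays, affine_to_rasmm=np.eye(4))
    nib.streamlines.save(tractogram, str(Path(path)))


def read_weights(path: str | Path, n_expected: int) -> list[float]:
    """Read SIFT2-style streamline weights (whitespace-separated floats).

    Raises if the number of weights disagrees with ``n_expected`` or any
    weight is non-positive (offending line numbers are reported).
    """
    path = Path(path)
    values: list[float] = []
    bad_lines: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            for tok in line.split():
                try:
                    v = float(tok)
                except ValueError:
                    raise ValueError(
                        f"{path.name}: line {lineno}: {tok!r} is not a number"
                    ) from None
                if not (v > 0 and math.isfinite(v)):
                    bad_lines.append(lineno)
                values.append(v)
    if bad_lines:
        raise ValueError(
            f"{path.name}: non-positive weight(s) on line(s) "
            + ", ".join(map(str, sorted(set(bad_lines))))
        )
    if len(values) != n_expected:
        raise ValueError(
            f"{path.name}: {len(values)} weights but {n_expected} streamlines"
        )
    return values


def write_weights(weights: Iterable[float], path: str | Path) -> None:
    with open(path, "w") as fh:
        for w in weights:
            fh.write(f"{float(w):.9g}\n")


def load_bundle(tck_path: str | Path, weights_path: str | Path | None,
                name: str, hemisphere: str) -> TractBundle:
    """Convenience: TCK + optional weights file -> :class:`TractBundle`."""
    streamlines = read_tck(tck_path)
    if weights_path is not None:
        for s, w in zip(streamlines, read_weights(weights_path, len(streamlines))):
            s.weight = float(w)
    return TractBundle(name=name, hemisphere=hemisphere, streamlines=streamlines)


# ---------------------------------------------------------------------------
# NIfTI masks
# ---------------------------------------------------------------------------


def read_mask_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a binary mask volume; returns ``(grid, affine)``.

    ``grid`` is boolean (> 0.5 is "inside"); ``affine`` maps voxel indices
    (centres) to world mm.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    return data > 0.5, np.asarray(img.affine, dtype=float)


def write_mask_nifti(grid: np.ndarray, affine: np.ndarray,
                     path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(grid, dtype=np.uint8), np.asarray(affine))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Review tables and lead poses (CSV dialects)
# ---------------------------------------------------------------------------


def _format_threshold(value: float | None, censored: bool) -> str:
    if censored:
        return CENSOR_TOKEN
    if value is None:
        return ""
    return f"{value:.1f}"


def _parse_threshold(token: str, column: str, lineno: int) -> tuple[float | None, bool]:
    token = token.strip()
    if token == "":
        return None, False
    if token == CENSOR_TOKEN:
        return None, True
    try:
        value = float(token)
    except ValueError:
        raise ValueError(
            f"review row {lineno}: {column}={token!r} is not a number, "
            f"empty, or {CENSOR_TOKEN!r}"
        ) from None
    if round(value, 1) not in AMPLITUDE_GRID:
        raise ValueError(
            f"review row {lineno}: {column}={value} off the 0.5 mA grid"
        )
    return round(value, 1), False


def read_reviews(path: str | Path) -> list[ReviewRecord]:
    """Read a monopolar-review CSV (see :data:`REVIEW_COLUMNS`)."""
    path = Path(path)
    records: list[ReviewRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if tuple(reader.fieldnames or ()) != REVIEW_COLUMNS:
            raise ValueError(
                f"{path.name}: expected columns {','.join(REVIEW_COLUMNS)}, "
                f"got {','.join(reader.fieldnames or ())}"
            )
        for lineno, row in enumerate(reader, start=2):
            eff, eff_cens = _parse_threshold(
                row["effect_threshold_mA"], "effect_threshold_mA", lineno)
            se, se_cens = _parse_threshold(
                row["side_effect_threshold_mA"], "side_effect_threshold_mA", lineno)
            tested = row["tested"].strip().lower() in ("1", "true", "yes")
            records.append(ReviewRecord(
                subject_id=row["subject_id"].strip(),
                lead_id=row["lead_id"].strip(),
                config_id=row["config_id"].strip(),
                effect_threshold=eff,
                side_effect_threshold=se,
                effect_censored=eff_cens,
                side_effect_censored=se_cens,
                tested=tested,
            ))
    return records


def write_reviews(records: Sequence[ReviewRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(REVIEW_COLUMNS)
        for r in records:
            writer.writerow([
                r.subject_id,
                r.lead_id,
                r.config_id,
                _format_threshold(r.effect_threshold, r.effect_censored),
                _format_threshold(r.side_effect_threshold, r.side_effect_censored),
                "1" if r.tested else "0",
            ])


LEAD_POSE_COLUMNS = (
    "subject_id", "lead_id",
    "tip_x", "tip_y", "tip_z",
    "axis_x", "axis_y", "axis_z",
    "rotation_rad",
)


def read_lead_poses(path: str | Path) -> list[dict]:
    """Read lead poses; each row gives tip (mm), axis direction, rotation."""
    path = Path(path)
    poses: list[dict] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if tuple(reader.fieldnames or ()) != LEAD_POSE_COLUMNS:
            raise ValueError(
                f"{path.name}: expected columns {','.join(LEAD_POSE_COLUMNS)}"
            )
        for row in reader:
            poses.append({
                "subject_id": row["subject_id"].strip(),
                "lead_id": row["lead_id"].strip(),
                "tip": np.array([float(row[f"tip_{c}"]) for c in "xyz"]),
                "axis": np.array([float(row[f"axis_{c}"]) for c in "xyz"]),
                "rotation": float(row["rotation_rad"]),
            })
    return poses


def write_lead_poses(poses: Sequence[dict], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(LEAD_POSE_COLUMNS)
        for p in poses:
            writer.writerow(
                [p["subject_id"], p["lead_id"]]
                + [f"{v:.6f}" for v in p["tip"]]
                + [f"{v:.9f}" for v in p["axis"]]
                + [f"{p['rotation']:.9f}"]
            )


def write_report(results: dict, path: str | Path) -> None:
    """Write an analysis report as JSON (numpy scalars coerced)."""

    def _coerce(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(results, fh, indent=2, default=_coerce)
        fh.write("\n")
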