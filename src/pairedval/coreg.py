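"""Two-manipulator co-registration: tilt transform and affine software correction.

A paired-recording rig drives a juxtacellular pipette with a reference
manipulator (the "PS" frame, aligned to the stereotaxic axes) and an
extracellular polytrode with a second, tilted manipulator (the "IVM" frame).
The IVM is rotated about the Y (anterior-posterior) axis by its approach
angle theta, so converting its native readings into the stereotaxic frame is
a planar rotation in XZ::

    x_ref =  cos(theta) * z + sin(theta) * x
    y_ref =  y
    z_ref = -sin(theta) * z + cos(theta) * x

Residual mechanical misalignment (imperfect squaring, axis non-orthogonality,
scale errors) is then absorbed by an affine map ``reference = A @ p + b``
fitted by ordinary least squares to pairs of coordinates observed at the same
physical point (the microscope crosshair) in both frames.

Units are micrometres throughout. X is medio-lateral, Y anterior-posterior,
Z dorso-ventral.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Position3D",
    "ManipulatorReading",
    "CalibrationPair",
    "AffineCorrection",
    "DistanceErrorSummary",
    "tilt_to_reference",
    "reference_to_tilt",
    "fit_affine_correction",
    "apply_correction",
    "distance_errors",
    "calibration_grid",
    "read_calibration_pairs",
    "write_calibration_pairs",
]

#: Approach angle of the tilted manipulator used on the original rig, degrees.
DEFAULT_THETA_DEG = 48.2

# Sign convention: the rig tilts the manipulator by -48.2 degrees from the
# horizontal; we store theta as +48.2 and use the rotation exactly as written
# above. Negating theta transposes the rotation matrix.


class InvalidCoordinateError(ValueError):
    """A coordinate or angle is non-finite or out of its allowed range."""


class DegenerateFitError(ValueError):
    """The calibration design is rank-deficient (too few / coplanar points)."""


@dataclass(frozen=True)
class Position3D:
    """A point in the stereotaxic reference (PS) frame, micrometres."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.as_array())):
            raise InvalidCoordinateError(f"non-finite coordinates: {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class ManipulatorReading:
    """Native-axis coordinates of the tilted manipulator, micrometres.

    ``theta_deg`` is the approach angle about the Y axis; it must lie in the
    open interval (-90, 90).
    """

    x: float
    y: float
    z: float
    theta_deg: float = DEFAULT_THETA_DEG

    def __post_init__(self) -> None:
        vals = np.array([self.x, self.y, self.z, self.theta_deg], dtype=float)
        if not np.all(np.isfinite(vals)):
            raise InvalidCoordinateError(f"non-finite reading: {self}")
        if not -90.0 < self.theta_deg < 90.0:
            raise InvalidCoordinateError(
                f"theta_deg must be in (-90, 90), got {self.theta_deg}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class CalibrationPair:
    """The same physical point observed in both manipulator frames."""

    reference: Position3D
    moving: ManipulatorReading


@dataclass
class AffineCorrection:
    """Fitted map ``reference = linear @ p + offset`` (p already tilt-transformed).

    ``linear`` is unitless; ``offset`` and the residual statistics are in
    micrometres. ``linear`` must be invertible.
    """

    linear: np.ndarray
    offset: np.ndarray
    fit_residual_mean: float = 0.0
    fit_residual_sd: float = 0.0

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=float).reshape(3, 3)
        self.offset = np.asarray(self.offset, dtype=float).reshape(3)
        if abs(np.linalg.det(self.linear)) < 1e-12:
            raise DegenerateFitError("linear part of correction is singular")
        if self.fit_residual_mean < 0 or self.fit_residual_sd < 0:
            raise ValueError("residual statistics must be non-negative")

    @classmethod
    def identity(cls) -> "AffineCorrection":
        return cls(np.eye(3), np.zeros(3))

    def transform(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.linear.T + self.offset

    # 12-number flat serialization: row-major 3x3 then offset
    def to_flat(self) -> np.ndarray:
        return np.concatenate([self.linear.ravel(), self.offset])

    @classmethod
    def from_flat(cls, values: Sequence[float], **stats: float) -> "AffineCorrection":
        vals = np.asarray(values, dtype=float).reshape(12)
        return cls(vals[:9].reshape(3, 3), vals[9:], **stats)

    def to_json_dict(self) -> dict:
        return {
            "linear": self.linear.tolist(),
            "offset_um": self.offset.tolist(),
            "fit_residual_mean_um": self.fit_residual_mean,
            "fit_residual_sd_um": self.fit_residual_sd,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "AffineCorrection":
        return cls(
            np.array(d["linear"]),
            np.array(d["offset_um"]),
            fit_residual_mean=d.get("fit_residual_mean_um", 0.0),
            fit_residual_sd=d.get("fit_residual_sd_um", 0.0),
        )


def _tilt_matrix(theta_deg: float) -> np.ndarray:
    th = np.deg2rad(theta_deg)
    c, s = np.cos(th), np.sin(th)
    # rows map (x, y, z)_native -> (x, y, z)_reference
    return np.array([[s, 0.0, c], [0.0, 1.0, 0.0], [c, 0.0, -s]])


def tilt_to_reference(reading: ManipulatorReading) -> Position3D:
    """Rotate a tilted-manipulator reading into the stereotaxic frame.

    The transform is orthogonal, so vector norms are preserved and the
    inverse is the transpose (see :func:`reference_to_tilt`).
    """
    out = _tilt_matrix(reading.theta_deg) @ reading.as_array()
    return Position3D(*out)


def reference_to_tilt(
    position: Position3D, theta_deg: float = DEFAULT_THETA_DEG
) -> ManipulatorReading:
    """Inverse of :func:`tilt_to_reference` (the matrix is its own inverse's
    transpose; here it is symmetric-orthogonal so transpose == matrix)."""
    native = _tilt_matrix(theta_deg).T @ position.as_array()
    return ManipulatorReading(*native, theta_deg=theta_deg)


def _tilted_points(pairs: Sequence[CalibrationPair]) -> np.ndarray:
    return np.array(
        [tilt_to_reference(p.moving).as_array() for p in pairs], dtype=float
    )


def _reference_points(pairs: Sequence[CalibrationPair]) -> np.ndarray:
    return np.array([p.reference.as_array() for p in pairs], dtype=float)


def fit_affine_correction(pairs: Sequence[CalibrationPair]) -> AffineCorrection:
    """Least-squares fit of the affine map from tilt-transformed readings to
    reference coordinates.

    Minimizes ``sum_i || reference_i - (A @ p_i + b) ||^2`` over the 3x3
    matrix A and offset b via the homogeneous design ``[p | 1]``. Requires at
    least 4 pairs whose moving points are not coplanar (affine design rank 4).
    """
    if len(pairs) < 4:
        raise DegenerateFitError(
            f"need at least 4 calibration pairs, got {len(pairs)}"
        )
    moving = _tilted_points(pairs)
    ref = _reference_points(pairs)
    design = np.column_stack([moving, np.ones(len(pairs))])
    rank = np.linalg.matrix_rank(design, tol=1e-8 * max(1.0, np.abs(design).max()))
    if rank < 4:
        raise DegenerateFitError(
            f"moving points are coplanar or collinear (affine design rank "
            f"{rank} < 4); spread the calibration points over a 3D volume"
        )
    coef, *_ = np.linalg.lstsq(design, ref, rcond=None)
    linear = coef[:3].T
    offset = coef[3]
    predicted = design @ coef
    per_point = np.linalg.norm(ref - predicted, axis=1)
    return AffineCorrection(
        linear,
        offset,
        fit_residual_mean=float(per_point.mean()),
        fit_residual_sd=float(per_point.std(ddof=0)),
    )


def apply_correction(
    correction: AffineCorrection, reading: ManipulatorReading
) -> Position3D:
    """Tilt-transform a reading, then apply the fitted affine correction."""
    p = tilt_to_reference(reading).as_array()
    return Position3D(*(correction.linear @ p + correction.offset))


@dataclass
class DistanceErrorSummary:
    """Per-point Euclidean position errors and their summary statistics (um)."""

    per_point_um: np.ndarray
    mean_um: float = field(init=False)
    sd_um: float = field(init=False)

    def __post_init__(self) -> None:
        self.per_point_um = np.asarray(self.per_point_um, dtype=float)
        self.mean_um = float(self.per_point_um.mean())
        self.sd_um = float(self.per_point_um.std(ddof=0))


def distance_errors(
    pairs: Sequence[CalibrationPair],
    correction: AffineCorrection | None = None,
) -> DistanceErrorSummary:
    """Euclidean distance between each reference point and the predicted
    position of the moving manipulator.

    With ``correction=None`` the prediction is the raw tilt transform,
    measuring physical misalignment; with a fitted correction it measures the
    residual after software alignment.
    """
    if len(pairs) == 0:
        raise ValueError("distance_errors requires at least one pair")
    predicted = _tilted_points(pairs)
    if correction is not None:
        predicted = correction.transform(predicted)
    errs = np.linalg.norm(_reference_points(pairs) - predicted, axis=1)
    return DistanceErrorSummary(errs)


def calibration_grid(
    extent_um: Sequence[float] = (5000.0, 5000.0, 5000.0),
    step_um: float = 1000.0,
    n_points: int | None = None,
    seed: int | None = None,
) -> list[Position3D]:
    """Seeded subsample of a cubic calibration lattice.

    The lattice spans ``[0, extent]`` on each axis in ``step_um`` steps
    (defaults: a 5 x 5 x 5 mm volume in 1 mm steps, 216 nodes). When
    ``n_points`` is given, a deterministic random subset is drawn; for
    ``n_points >= 4`` the subset is redrawn until its affine design has full
    rank, so it is always usable for fitting.
    """
    extent = np.asarray(extent_um, dtype=float)
    if step_um <= 0:
        raise ValueError("step_um must be positive")
    counts = extent / step_um
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("step_um must divide every component of extent_um")
    axes = [np.arange(0.0, e + step_um / 2, step_um) for e in extent]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    if n_points is None or n_points == len(grid):
        return [Position3D(*p) for p in grid]
    if n_points > len(grid):
        raise ValueError(
            f"n_points={n_points} exceeds lattice size {len(grid)}"
        )
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        idx = rng.choice(len(grid), size=n_points, replace=False)
        pts = grid[idx]
        if n_points < 4:
            break
        design = np.column_stack([pts, np.ones(n_points)])
        if np.linalg.matrix_rank(design) == 4:
            break
    else:  # pragma: no cover - lattice subsets are almost surely full rank
        raise RuntimeError("could not draw a full-rank calibration subset")
    return [Position3D(*p) for p in pts]


# ---------------------------------------------------------------------------
# CSV I/O for calibration pairs
# ---------------------------------------------------------------------------

_PAIR_COLUMNS = [
    "pair_index",
    "ref_x_um",
    "ref_y_um",
    "ref_z_um",
    "mov_x_um",
    "mov_y_um",
    "mov_z_um",
    "theta_deg",
]


def write_calibration_pairs(pairs: Sequence[CalibrationPair], path) -> None:
    import pandas as pd

    rows = [
        {
            "pair_index": i,
            "ref_x_um": p.reference.x,
            "ref_y_um": p.reference.y,
            "ref_z_um": p.reference.z,
            "mov_x_um": p.moving.x,
            "mov_y_um": p.moving.y,
            "mov_z_um": p.moving.z,
            "theta_deg": p.moving.theta_deg,
        }
        for i, p in enumerate(pairs)
    ]
    pd.DataFrame(rows, columns=_PAIR_COLUMNS).to_csv(path, index=False)


def read_calibration_pairs(path) -> list[CalibrationPair]:
    import pandas as pd

    df = pd.read_csv(path)
    missing = set(_PAIR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"calibration pair table missing columns: {sorted(missing)}")
    return [
        CalibrationPair(
            reference=Position3D(r.ref_x_um, r.ref_y_um, r.ref_z_um),
            moving=ManipulatorReading(
                r.mov_x_um, r.mov_y_um, r.mov_z_um, theta_deg=r.theta_deg
            ),
        )
        for r in df.sort_values("pair_index").itertuples()
    ]
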