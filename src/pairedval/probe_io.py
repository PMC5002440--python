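"""Probe geometry factories and raw/tabular I/O for paired recordings.

Raw extracellular data are flat binary files of 16-bit signed integers,
sample-major (channel-interleaved: all channels of sample 0, then all
channels of sample 1, ...), sampled at 30 kHz. Conversion to microvolts uses
a configurable amplifier step, default 0.195 uV/bit.

Probe coordinates live on the shank plane: ``x`` is the lateral offset and
``z`` the axial (depth) coordinate, increasing with depth, with 0 at the
top-most site. All distances in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProbeGeometry",
    "RawRecording",
    "PairMetadata",
    "make_probe_32ch_poly3",
    "make_probe_128ch",
    "read_raw",
    "write_raw",
    "read_geometry",
    "write_geometry",
    "read_pair_table",
    "write_pair_table",
    "DEFAULT_SCALE_UV_PER_BIT",
]

DEFAULT_SCALE_UV_PER_BIT = 0.195
DEFAULT_RATE_HZ = 30000.0


class TruncatedFileError(IOError):
    """Raw binary file size is not a whole number of frames."""


class SchemaError(ValueError):
    """A tabular input is missing a required column or violates an invariant."""


@dataclass
class ProbeGeometry:
    """Site layout of a silicon polytrode shank.

    ``site_xz_um[i]`` is the (lateral, axial) position of ``site_ids[i]``.
    ``adjacency_radius_um`` bounds the center-to-center distance at which two
    sites count as neighbours for flood-fill detection.
    """

    site_ids: np.ndarray
    site_xz_um: np.ndarray
    site_area_um2: np.ndarray
    adjacency_radius_um: float = 30.0
    name: str = ""

    def __post_init__(self) -> None:
        self.site_ids = np.asarray(self.site_ids)
        self.site_xz_um = np.asarray(self.site_xz_um, dtype=float).reshape(-1, 2)
        self.site_area_um2 = np.broadcast_to(
            np.asarray(self.site_area_um2, dtype=float), (len(self.site_ids),)
        ).copy()
        if len({tuple(p) for p in self.site_xz_um}) != len(self.site_xz_um):
            raise ValueError("site positions must be unique")
        if self.n_sites > 1 and self.adjacency_radius_um <= self.min_pitch_um():
            raise ValueError(
                "adjacency_radius_um must exceed the minimum inter-site pitch"
            )

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def axial_span_um(self) -> float:
        z = self.site_xz_um[:, 1]
        return float(z.max() - z.min())

    def pairwise_distances(self) -> np.ndarray:
        d = self.site_xz_um[:, None, :] - self.site_xz_um[None, :, :]
        return np.linalg.norm(d, axis=-1)

    def min_pitch_um(self) -> float:
        d = self.pairwise_distances()
        np.fill_diagonal(d, np.inf)
        return float(d.min())

    def nearest_neighbor_distances(self) -> np.ndarray:
        d = self.pairwise_distances()
        np.fill_diagonal(d, np.inf)
        return d.min(axis=1)

    def adjacency(self) -> np.ndarray:
        """Boolean neighbour matrix (self-adjacency excluded)."""
        d = self.pairwise_distances()
        adj = d <= self.adjacency_radius_um
        np.fill_diagonal(adj, False)
        return adj

    def site_index(self, site_id) -> int:
        idx = np.nonzero(self.site_ids == site_id)[0]
        if len(idx) == 0:
            raise KeyError(f"unknown site id {site_id!r}")
        return int(idx[0])


def make_probe_32ch_poly3() -> ProbeGeometry:
    """32-site, 3-column staggered ("poly3") layout.

    Twelve sites in the central column at 25 um axial spacing (axial span
    275 um) flanked by two 10-site columns offset half a period axially and
    18.5 um laterally, giving staggered nearest-neighbour distances of
    ~22.3 um — inside the probe's 22-25 um pitch range. Site area 177 um^2.
    The exact stagger and the site numbering (center column first, then
    left, then right, each top to bottom) are package conventions.
    """
    xs, zs = [], []
    for k in range(12):  # center column, z = 0 .. 275
        xs.append(0.0)
        zs.append(25.0 * k)
    for k in range(10):  # left column
        xs.append(-18.5)
        zs.append(25.0 + 25.0 * k - 12.5)
    for k in range(10):  # right column
        xs.append(18.5)
        zs.append(25.0 + 25.0 * k - 12.5)
    xz = np.column_stack([xs, zs])
    return ProbeGeometry(
        site_ids=np.arange(32),
        site_xz_um=xz,
        site_area_um2=177.0,
        adjacency_radius_um=30.0,
        name="poly3-32ch",
    )


def make_probe_128ch(columns: int = 4) -> ProbeGeometry:
    """128-site regular grid, 22.5 um pitch in both directions, 20x20 um sites."""
    if columns <= 0 or 128 % columns != 0:
        raise ValueError(f"columns must divide 128, got {columns}")
    rows = 128 // columns
    pitch = 22.5
    xz = np.array(
        [(c * pitch, r * pitch) for r in range(rows) for c in range(columns)]
    )
    return ProbeGeometry(
        site_ids=np.arange(128),
        site_xz_um=xz,
        site_area_um2=400.0,
        adjacency_radius_um=30.0,
        name=f"grid-128ch-{columns}col",
    )


def write_geometry(geometry: ProbeGeometry, path) -> None:
    df = pd.DataFrame(
        {
            "site_id": geometry.site_ids,
            "x_um": geometry.site_xz_um[:, 0],
            "z_um": geometry.site_xz_um[:, 1],
            "area_um2": geometry.site_area_um2,
        }
    )
    df.to_csv(path, index=False)


def read_geometry(path, adjacency_radius_um: float = 30.0) -> ProbeGeometry:
    df = pd.read_csv(path)
    required = {"site_id", "x_um", "z_um", "area_um2"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"geometry file missing columns: {sorted(missing)}")
    return ProbeGeometry(
        site_ids=df["site_id"].to_numpy(),
        site_xz_um=df[["x_um", "z_um"]].to_numpy(),
        site_area_um2=df["area_um2"].to_numpy(),
        adjacency_radius_um=adjacency_radius_um,
        name=str(Path(path).stem),
    )


@dataclass
class RawRecording:
    """Multichannel int16 recording plus the metadata to interpret it."""

    samples: np.ndarray  # channels x time, int16
    scale_uv_per_bit: float = DEFAULT_SCALE_UV_PER_BIT
    rate_hz: float = DEFAULT_RATE_HZ
    channel_order: np.ndarray | None = None  # file order -> geometry site ids

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples))
        if self.samples.dtype != np.int16:
            info = np.iinfo(np.int16)
            if self.samples.size and (
                self.samples.min() < info.min or self.samples.max() > info.max
            ):
                raise ValueError("sample values exceed the 16-bit range")
            self.samples = self.samples.astype(np.int16)
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def to_uv(self) -> np.ndarray:
        """Samples converted to microvolts (float64, channels x time)."""
        return self.samples.astype(np.float64) * self.scale_uv_per_bit


def write_raw(recording: RawRecording, path) -> None:
    """Write sample-major (channel-interleaved) int16 binary."""
    recording.samples.T.astype("<i2").tofile(path)


def read_raw(
    path,
    n_channels: int,
    scale_uv_per_bit: float = DEFAULT_SCALE_UV_PER_BIT,
    rate_hz: float = DEFAULT_RATE_HZ,
) -> RawRecording:
    """Read sample-major int16 binary into a channels x time matrix."""
    path = Path(path)
    nbytes = path.stat().st_size
    frame_bytes = 2 * n_channels
    if nbytes % frame_bytes != 0:
        raise TruncatedFileError(
            f"{path}: {nbytes} bytes is not a whole number of "
            f"{frame_bytes}-byte frames ({n_channels} channels x int16); "
            f"{nbytes % frame_bytes} trailing bytes"
        )
    flat = np.fromfile(path, dtype="<i2")
    samples = flat.reshape(-1, n_channels).T if flat.size else np.zeros(
        (n_channels, 0), dtype=np.int16
    )
    return RawRecording(
        samples=np.ascontiguousarray(samples),
        scale_uv_per_bit=scale_uv_per_bit,
        rate_hz=rate_hz,
    )


# ---------------------------------------------------------------------------
# Pair metadata tables
# ---------------------------------------------------------------------------

#: Pairs whose pipette recording showed a negative-before-positive spike
#: (incomplete membrane contact); all other pairs are positive-first.
NEGATIVE_FIRST_PAIR_IDS = frozenset(
    {"2015_09_04_Pair 5.0", "2015_09_03_Pair 9.0"}
)

_REQUIRED_PAIR_COLUMNS = ["pair_id", "distance_um", "depth_um", "juxta_threshold"]


@dataclass
class PairMetadata:
    """One row of the paired-recording summary table."""

    pair_id: str
    distance_um: float
    depth_um: float = float("nan")
    juxta_threshold: float = float("nan")
    distance_err_um: float = 10.5
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.distance_um < 0:
            raise SchemaError(
                f"{self.pair_id}: distance_um must be >= 0, got {self.distance_um}"
            )

    @property
    def polarity(self) -> str:
        """Juxtacellular spike polarity: which extremum leads the waveform."""
        if self.pair_id in NEGATIVE_FIRST_PAIR_IDS:
            return "negative-first"
        return self.notes.get("polarity", "positive-first")


def write_pair_table(rows: Sequence[PairMetadata], path) -> None:
    extra_keys = sorted({k for r in rows for k in r.notes})
    records = []
    for r in rows:
        rec = {
            "pair_id": r.pair_id,
            "distance_um": r.distance_um,
            "depth_um": r.depth_um,
            "juxta_threshold": r.juxta_threshold,
            "distance_err_um": r.distance_err_um,
        }
        rec.update({k: r.notes.get(k, "") for k in extra_keys})
        records.append(rec)
    pd.DataFrame(records).to_csv(path, index=False)


def read_pair_table(path) -> list[PairMetadata]:
    df = pd.read_csv(path)
    missing = set(_REQUIRED_PAIR_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"pair table missing required columns: {sorted(missing)}")
    if df["pair_id"].duplicated().any():
        dupes = df.loc[df["pair_id"].duplicated(), "pair_id"].tolist()
        raise SchemaError(f"duplicate pair ids: {dupes}")
    known = set(_REQUIRED_PAIR_COLUMNS) | {"distance_err_um"}
    rows = []
    for rec in df.to_dict("records"):
        notes = {k: v for k, v in rec.items() if k not in known}
        rows.append(
            PairMetadata(
                pair_id=str(rec["pair_id"]),
                distance_um=float(rec["distance_um"]),
                depth_um=float(rec["depth_um"]),
                juxta_threshold=float(rec["juxta_threshold"]),
                distance_err_um=float(rec.get("distance_err_um", 10.5)),
                notes=notes,
            )
        )
    return rows
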