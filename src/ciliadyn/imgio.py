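"""File I/O, configuration and shared containers for the quantification pipeline.

Conventions used throughout the package:

* images are stored ``(channel, z, y, x)`` with 0-based, pixel-center
  coordinates, x rightward and y downward;
* all lengths are micrometres, all angles degrees, all times seconds;
* angle computations flip to a y-up mathematical frame exactly once, at
  vector construction (see :mod:`ciliadyn.polarity`).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml


class PipelineIOError(Exception):
    """Raised for missing files, corrupt pages or absent metadata."""


class ParseError(PipelineIOError):
    """Raised for malformed table rows; names the offending column/line."""


class ParameterError(ValueError):
    """Raised when an operation receives invalid parameters."""


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class ImageStack:
    """A two-or-more channel 3D fluorescence stack with physical pixel size.

    Parameters
    ----------
    voxels
        4-D non-negative intensity array indexed ``(channel, z, y, x)``.
    pixel_size_um
        Isotropic in-plane pixel size in micrometres. Never defaulted: the
        acquisition pixel size must come from metadata or the caller.
    channel_names
        One name per channel (e.g. ``["pericentrin", "ac-tubulin"]``).
    """

    voxels: np.ndarray
    pixel_size_um: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 4:
            raise ParameterError("voxels must be (channel, z, y, x)")
        if min(self.voxels.shape) < 1:
            raise ParameterError("every stack dimension must be >= 1")
        if not (self.pixel_size_um > 0):
            raise ParameterError("pixel_size_um must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.voxels.shape[0])]
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ParameterError("channel_names length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def n_z(self) -> int:
        return self.voxels.shape[1]


@dataclass
class RoiPolygon:
    """A manually traced cell outline, 0-based pixel-center vertices."""

    cell_id: str
    vertices: np.ndarray  # (n, 2) as (x, y)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ParameterError("vertices must be (n, 2)")
        if len(self.vertices) < 3:
            raise ParameterError("a polygon needs at least 3 vertices")


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class Config:
    """Every tunable threshold of the pipeline, with defaults.

    The source scripts behind the published analysis do not print their
    parameter values; these defaults were fixed once against the synthetic
    data model (see docs/methods.md) and are exposed so real data can be
    calibrated per microscope.
    """

    # centrosome spot detection (difference-of-Gaussians + local maxima)
    spot_sigma_px: float = 2.0
    min_peak_snr: float = 5.0
    min_separation_px: float = 5.0
    # peri-centrosomal crop
    crop_side_um: float = 11.0
    # proximal-cluster seed segmentation
    seed_quantile: float = 0.99
    min_seed_px: int = 4
    # axoneme region growing
    contrast_stop_ratio: float = 1.5
    max_grow_iterations: int = 200
    # ciliation call
    min_cilium_length_um: float = 1.0
    # basal-body adaptive threshold
    adaptive_window_px: int = 51
    adaptive_offset: float = 0.0
    # bead tracks
    min_net_disp_um: float = 0.1
    frame_interval_s: float = 1.0 / 37.0
    # interaction screen
    lumier_threshold: float = 3.0
    # rose-plot binning
    n_hist_bins: int = 24

    def __post_init__(self) -> None:
        if not (0 < self.seed_quantile < 1):
            raise ParameterError("seed_quantile must lie in (0, 1)")
        if self.contrast_stop_ratio <= 1:
            raise ParameterError("contrast_stop_ratio must exceed 1")
        for name in ("spot_sigma_px", "min_peak_snr", "min_separation_px",
                     "crop_side_um", "frame_interval_s"):
            if not (getattr(self, name) > 0):
                raise ParameterError(f"{name} must be positive")
        for name in ("min_seed_px", "max_grow_iterations", "adaptive_window_px",
                     "n_hist_bins"):
            if int(getattr(self, name)) != getattr(self, name) or getattr(self, name) < 0:
                raise ParameterError(f"{name} must be a non-negative integer")


def load_config(path: str | Path) -> Config:
    """Load a YAML key/value file into a :class:`Config`.

    Unknown keys are rejected and every value is type-checked against the
    dataclass field, so a typo never silently falls back to a default.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: config must be a mapping")
    known = {f.name: f for f in dataclasses.fields(Config)}
    unknown = sorted(set(raw) - set(known))
    if unknown:
        raise ParseError(f"{path}: unknown config keys {unknown}")
    for key, value in raw.items():
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ParseError(f"{path}: key '{key}' must be numeric, got {value!r}")
    return Config(**raw)


# --------------------------------------------------------------------------
# TIFF stacks
# --------------------------------------------------------------------------

_RES_UNIT_CM = 3  # TIFF ResolutionUnit: centimetre


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as plain multi-page grayscale TIFF, channel-major pages.

    Pixel size goes into the X/Y resolution tags (pixels per centimetre) and,
    with the channel layout, into a JSON ImageDescription so a round trip
    needs no side channel.
    """
    c, z, y, x = stack.voxels.shape
    pages = stack.voxels.reshape(c * z, y, x).astype(np.float32)
    ppcm = 1e4 / stack.pixel_size_um
    meta = {"n_channels": c, "n_z": z,
            "pixel_size_um": stack.pixel_size_um,
            "channel_names": stack.channel_names}
    tifffile.imwrite(path, pages, photometric="minisblack",
                     resolution=(ppcm, ppcm), resolutionunit=_RES_UNIT_CM,
                     description=json.dumps(meta))


def read_stack(path: str | Path, n_channels: int | None = None,
               pixel_size_um: float | None = None) -> ImageStack:
    """Read a channel-major multi-page TIFF into an :class:`ImageStack`.

    ``pixel_size_um`` overrides are used only when the file carries no
    resolution metadata; a file with neither raises :class:`PipelineIOError`.
    """
    path = Path(path)
    if not path.exists():
        raise PipelineIOError(f"no such file: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            pages = tif.asarray()
            first = tif.pages[0]
            desc = first.description
            tags = first.tags
            meta = None
            if desc:
                try:
                    meta = json.loads(desc)
                except (ValueError, TypeError):
                    meta = None
            px = None
            if isinstance(meta, dict) and "pixel_size_um" in meta:
                px = float(meta["pixel_size_um"])
            else:
                xres = tags.get("XResolution")
                unit = tags.get("ResolutionUnit")
                if xres is not None and unit is not None and unit.value == _RES_UNIT_CM:
                    num, den = xres.value
                    if num:
                        px = 1e4 * den / num
    except tifffile.TiffFileError as exc:
        raise PipelineIOError(f"corrupt TIFF {path}: {exc}") from exc

    if px is None:
        px = pixel_size_um
    if px is None:
        raise PipelineIOError(
            f"{path}: pixel size unknown (no resolution metadata and no override)")

    if pages.ndim == 2:
        pages = pages[None]
    n_pages = pages.shape[0]
    names: list[str] = []
    if n_channels is None:
        if isinstance(meta, dict) and "n_channels" in meta:
            n_channels = int(meta["n_channels"])
            names = list(meta.get("channel_names", []))
        else:
            n_channels = 1
    if n_pages % n_channels:
        raise PipelineIOError(
            f"{path}: {n_pages} pages not divisible by {n_channels} channels")
    z = n_pages // n_channels
    voxels = pages.reshape(n_channels, z, *pages.shape[1:])
    return ImageStack(voxels, px, names or None or [])


# --------------------------------------------------------------------------
# CSV tables
# --------------------------------------------------------------------------

VECTOR_COLUMNS = ("cell_id", "base_x", "base_y", "tip_x", "tip_y")
ROI_COLUMNS = ("cell_id", "vertex", "x", "y")
TRACK_COLUMNS = ("track_id", "frame", "x", "y")
LUMIER_COLUMNS = ("prey", "lir_rep1", "lir_rep2")


def _read_table(path: str | Path, required: Sequence[str],
                numeric: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise PipelineIOError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            # +2: 1-based line numbering plus the header line
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ParseError(
                f"{path}: non-numeric value {df[col].iloc[line - 2]!r} "
                f"in column '{col}' at line {line}")
        df[col] = vals
    return df


def read_vectors(path: str | Path):
    """Read traced base→tip vectors into an OrientationVectorSet.

    Columns: cell_id, base_x, base_y, tip_x, tip_y; an optional ``condition``
    column is preserved. Coordinates are image storage coordinates (y down).
    """
    from .polarity import OrientationVectorSet

    df = _read_table(path, VECTOR_COLUMNS, VECTOR_COLUMNS[1:])
    groups: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    conditions: dict[str, str] = {}
    for _, row in df.iterrows():
        gid = str(row["cell_id"])
        base = np.array([row["base_x"], row["base_y"]], dtype=float)
        tip = np.array([row["tip_x"], row["tip_y"]], dtype=float)
        groups.setdefault(gid, []).append((base, tip))
        if "condition" in df.columns:
            conditions[gid] = str(row["condition"])
    return OrientationVectorSet(groups=groups, kind="cell",
                                conditions=conditions or None)


def write_vectors(vecset, path: str | Path) -> None:
    rows = []
    for gid in sorted(vecset.groups):
        for base, tip in vecset.groups[gid]:
            row = {"cell_id": gid, "base_x": base[0], "base_y": base[1],
                   "tip_x": tip[0], "tip_y": tip[1]}
            if vecset.conditions:
                row["condition"] = vecset.conditions.get(gid, "")
            rows.append(row)
    cols = list(VECTOR_COLUMNS) + (["condition"] if vecset.conditions else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_rois(path: str | Path) -> list[RoiPolygon]:
    """Read cell-outline vertices (columns cell_id, vertex, x, y)."""
    df = _read_table(path, ROI_COLUMNS, ("vertex", "x", "y"))
    out = []
    for gid, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("vertex")
        out.append(RoiPolygon(str(gid), grp[["x", "y"]].to_numpy(float)))
    return out


def write_rois(rois: Sequence[RoiPolygon], path: str | Path) -> None:
    rows = [{"cell_id": r.cell_id, "vertex": i, "x": v[0], "y": v[1]}
            for r in rois for i, v in enumerate(r.vertices)]
    pd.DataFrame(rows, columns=list(ROI_COLUMNS)).to_csv(path, index=False)


def read_tracks(path: str | Path, frame_interval_s: float):
    """Read bead detections/trajectories (columns track_id, frame, x, y; µm)."""
    from .flow import TrackSet

    df = _read_table(path, TRACK_COLUMNS, TRACK_COLUMNS[1:])
    tracks: dict[str, np.ndarray] = {}
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy(float)
        if np.any(np.diff(frames) <= 0):
            raise ParseError(f"{path}: track {tid!r} has non-increasing frames")
        tracks[str(tid)] = grp[["frame", "x", "y"]].to_numpy(float)
    return TrackSet(tracks=tracks, frame_interval_s=frame_interval_s)


def write_tracks(trackset, path: str | Path) -> None:
    rows = [{"track_id": tid, "frame": int(f), "x": x, "y": y}
            for tid in sorted(trackset.tracks)
            for f, x, y in trackset.tracks[tid]]
    pd.DataFrame(rows, columns=list(TRACK_COLUMNS)).to_csv(path, index=False)


def read_lumier(path: str | Path):
    """Read an interaction-screen table (columns prey, lir_rep1, lir_rep2)."""
    from .stats import LumierTable

    df = _read_table(path, LUMIER_COLUMNS, ("lir_rep1", "lir_rep2"))
    return LumierTable(df[list(LUMIER_COLUMNS)].copy())


def write_lumier(table, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def write_results(records: Sequence[Mapping] | pd.DataFrame,
                  path: str | Path) -> None:
    """Write result records as CSV with a stable column order and row order.

    Rows sort by their non-float (group key) columns; floats are written at 6
    significant digits, so identical inputs yield byte-identical files.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        records = list(records)
        if records:
            cols = list(records[0].keys())
            df = pd.DataFrame(records, columns=cols)
        else:
            df = pd.DataFrame()
    if len(df):
        keys = [c for c in df.columns
                if not pd.api.types.is_float_dtype(df[c])]
        if keys:
            df = df.sort_values(keys, kind="mergesort")
    try:
        df.to_csv(path, index=False, float_format="%.6g")
    except OSError as exc:
        raise PipelineIOError(f"cannot write {path}: {exc}") from exc


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
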