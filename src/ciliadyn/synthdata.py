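"""Synthetic fluorescence data with known ground truth.

The raw microscopy behind the quantifications this package implements is not
publicly deposited, so every pipeline stage is validated by parameter
recovery on simulated inputs that reproduce the statistical structure the
analysis assumes:

* two-channel 3D fields — sparse bright diffraction-limited centrosome spots
  (channel 0) and curved filamentous axonemes of known arc length attached to
  a subset of centrosomes (channel 1), with Poisson shot noise on
  signal + background and additive Gaussian read noise;
* per-cell orientation vectors with von Mises-distributed angles of known
  mean direction and concentration κ;
* bead trajectories that are directed drift plus isotropic Gaussian jitter;
* interaction-screen tables with a known set of true hits.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import line
from scipy.ndimage import binary_dilation
from skimage.morphology import disk

from .imgio import ImageStack, ParameterError

__all__ = [
    "FieldParams", "CentrosomeTruth", "GroundTruth",
    "generate_cilia_field", "generate_polarity_cells",
    "generate_bead_tracks", "generate_lumier_table",
]


# --------------------------------------------------------------------------
# cilia fields
# --------------------------------------------------------------------------

@dataclass
class FieldParams:
    """Parameters of one simulated two-channel field.

    Defaults emulate a 10-z-plane confocal acquisition of a ciliated
    epithelial field at moderate signal-to-noise: centrosome spots are
    bright and diffraction limited, axonemes are thin curved filaments of
    2–6 µm, and the camera model is Poisson shot noise on signal plus
    background with Gaussian read noise.
    """

    field_size_px: tuple[int, int] = (768, 768)  # (height, width)
    pixel_size_um: float = 0.25
    n_centrosomes: int = 100
    ciliation_fraction: float = 0.7
    cilium_length_um_range: tuple[float, float] = (2.0, 6.0)
    cilium_curvature: float = 0.3  # max radians of heading change per µm
    spot_intensity: float = 300.0
    axoneme_intensity: float = 80.0
    background_level: float = 20.0
    noise_sd: float = 2.0
    n_z: int = 10
    crowded: bool = False  # disable the minimum-separation placement rule

    def __post_init__(self) -> None:
        h, w = self.field_size_px
        if int(h) != h or int(w) != w or h < 1 or w < 1:
            raise ParameterError("field_size_px must be positive integers")
        if not (0 <= self.ciliation_fraction <= 1):
            raise ParameterError("ciliation_fraction must lie in [0, 1]")
        lo, hi = self.cilium_length_um_range
        if not (0 < lo <= hi):
            raise ParameterError("cilium_length_um_range must be 0 < min <= max")
        if self.noise_sd < 0 or self.cilium_curvature < 0:
            raise ParameterError("noise_sd and cilium_curvature must be >= 0")
        if self.n_centrosomes < 0 or self.n_z < 1:
            raise ParameterError("n_centrosomes >= 0 and n_z >= 1 required")
        if not (self.pixel_size_um > 0):
            raise ParameterError("pixel_size_um must be positive")
        for name in ("spot_intensity", "axoneme_intensity", "background_level"):
            if not (getattr(self, name) > 0):
                raise ParameterError(f"{name} must be positive")


@dataclass
class CentrosomeTruth:
    position: np.ndarray            # (x, y) px
    ciliated: bool
    true_length_um: float
    axoneme_polyline: np.ndarray    # (n, 2) px, empty if not ciliated


@dataclass
class GroundTruth:
    centrosomes: list[CentrosomeTruth] = field(default_factory=list)

    @property
    def n_ciliated(self) -> int:
        return sum(c.ciliated for c in self.centrosomes)

    @property
    def ciliated_fraction(self) -> float:
        n = len(self.centrosomes)
        return self.n_ciliated / n if n else float("nan")

    def to_records(self) -> pd.DataFrame:
        rows = [{"index": i, "x": c.position[0], "y": c.position[1],
                 "ciliated": c.ciliated, "true_length_um": c.true_length_um}
                for i, c in enumerate(self.centrosomes)]
        return pd.DataFrame(rows, columns=["index", "x", "y", "ciliated",
                                           "true_length_um"])


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _place_centrosomes(params: FieldParams, rng: np.random.Generator,
                       margin_px: float) -> np.ndarray:
    """Random (x, y) positions with a minimum pairwise separation.

    Default separation is the crop side (2x the crop half-width, 11 µm) so
    peri-centrosomal crops never collide; ``crowded=True`` drops the rule.
    """
    h, w = params.field_size_px
    min_sep = 0.0 if params.crowded else 11.0 / params.pixel_size_um
    pos: list[np.ndarray] = []
    attempts = 0
    max_attempts = 20000 + 200 * params.n_centrosomes
    while len(pos) < params.n_centrosomes:
        attempts += 1
        if attempts > max_attempts:
            raise ParameterError(
                "could not place centrosomes with the required separation; "
                "enlarge the field or set crowded=True")
        p = rng.uniform([margin_px, margin_px], [w - margin_px, h - margin_px])
        if min_sep and any(np.hypot(*(p - q)) < min_sep for q in pos):
            continue
        pos.append(p)
    return np.array(pos).reshape(params.n_centrosomes, 2)


def _axoneme_polyline(base_px: np.ndarray, length_um: float, params: FieldParams,
                      rng: np.random.Generator) -> np.ndarray:
    """A curved polyline of exact arc length, in pixel coordinates."""
    step_um = 0.1
    n_full, rem = divmod(length_um, step_um)
    steps = [step_um] * int(n_full) + ([rem] if rem > 1e-9 else [])
    heading = rng.uniform(0.0, 2.0 * np.pi)
    pts = [base_px.astype(float)]
    for s in steps:
        heading += rng.uniform(-1.0, 1.0) * params.cilium_curvature * s
        d = np.array([np.cos(heading), np.sin(heading)]) * (s / params.pixel_size_um)
        pts.append(pts[-1] + d)
    return np.array(pts)


def _render_polyline_mask(polyline: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polyline and dilate to a ~3 px wide filament mask."""
    mask = np.zeros(shape, dtype=bool)
    pts = np.round(polyline).astype(int)
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        rr, cc = line(y0, x0, y1, x1)
        keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        mask[rr[keep], cc[keep]] = True
    return binary_dilation(mask, disk(1))


def render_axoneme_image(polylines: Sequence[np.ndarray],
                         shape: tuple[int, int], intensity: float) -> np.ndarray:
    """Noise-free axoneme channel: dilated polylines, lightly blurred.

    Integrated intensity grows with total filament length, mimicking uniform
    axoneme staining.
    """
    canvas = np.zeros(shape, dtype=float)
    for poly in polylines:
        canvas[_render_polyline_mask(poly, shape)] = 1.0
    return gaussian_filter(canvas, 0.7) * intensity


def render_spot_image(positions: np.ndarray, shape: tuple[int, int],
                      intensity: float, sigma_px: float = 2.0) -> np.ndarray:
    """Noise-free centrosome channel: isotropic Gaussian spots."""
    canvas = np.zeros(shape, dtype=float)
    half = int(np.ceil(4 * sigma_px))
    for x, y in np.atleast_2d(positions) if len(positions) else []:
        cx, cy = int(round(x)), int(round(y))
        y0, y1 = max(cy - half, 0), min(cy + half + 1, shape[0])
        x0, x1 = max(cx - half, 0), min(cx + half + 1, shape[1])
        yy, xx = np.mgrid[y0:y1, x0:x1]
        canvas[y0:y1, x0:x1] += intensity * np.exp(
            -((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma_px ** 2))
    return canvas


def generate_cilia_field(params: FieldParams, seed: int
                         ) -> tuple[ImageStack, GroundTruth]:
    """Simulate one two-channel z-stack plus its ground truth.

    Channel 0 carries centrosome-marker spots for every centrosome; channel 1
    carries an axoneme filament for the ciliated subset, drawn along each
    ciliated centrosome's polyline. Signal is spread over z with a Gaussian
    axial profile, Poisson noise is applied to signal + background, and
    Gaussian read noise is added per plane. The same ``(params, seed)`` pair
    always returns bit-identical output.
    """
    rng = np.random.default_rng(seed)
    h, w = params.field_size_px
    margin = 4.0 / params.pixel_size_um  # keep bases away from the border
    margin = min(margin, min(h, w) / 4)
    positions = _place_centrosomes(params, rng, margin)

    n_cil = _round_half_up(params.ciliation_fraction * params.n_centrosomes)
    ciliated = np.zeros(params.n_centrosomes, dtype=bool)
    if n_cil:
        ciliated[rng.choice(params.n_centrosomes, size=n_cil, replace=False)] = True

    lo, hi = params.cilium_length_um_range
    truth = GroundTruth()
    polylines = []
    for i in range(params.n_centrosomes):
        if ciliated[i]:
            length = float(rng.uniform(lo, hi))
            poly = _axoneme_polyline(positions[i], length, params, rng)
            polylines.append(poly)
        else:
            length, poly = 0.0, np.empty((0, 2))
        truth.centrosomes.append(CentrosomeTruth(
            position=positions[i].copy(), ciliated=bool(ciliated[i]),
            true_length_um=length, axoneme_polyline=poly))

    spots = render_spot_image(positions, (h, w), params.spot_intensity)
    axonemes = render_axoneme_image(polylines, (h, w), params.axoneme_intensity)

    # Gaussian axial intensity profile, peaking at the focal (centre) plane.
    z = np.arange(params.n_z)
    z_profile = np.exp(-0.5 * ((z - (params.n_z - 1) / 2) / max(params.n_z / 4, 1)) ** 2)
    voxels = np.empty((2, params.n_z, h, w), dtype=float)
    for ci, signal in enumerate((spots, axonemes)):
        expected = signal[None] * z_profile[:, None, None] + params.background_level
        noisy = rng.poisson(expected).astype(float)
        if params.noise_sd > 0:
            noisy += rng.normal(0.0, params.noise_sd, size=noisy.shape)
        voxels[ci] = np.clip(noisy, 0.0, None)

    stack = ImageStack(voxels, params.pixel_size_um,
                       ["centrosome", "axoneme"])
    return stack, truth


# --------------------------------------------------------------------------
# polarity vectors
# --------------------------------------------------------------------------

def generate_polarity_cells(n_cells: int, vectors_per_cell: int, kappa: float,
                            cell_mean_spread_deg: float, seed: int):
    """Simulate traced base→tip orientation vectors for polarity analysis.

    Each cell draws a mean direction (a global direction plus a normal spread
    of ``cell_mean_spread_deg``), then ``vectors_per_cell`` angles from a von
    Mises distribution with concentration ``kappa`` about that mean
    (``kappa=0`` gives uniform angles). Bases sit on a jittered grid; tips are
    base + the unit vector of the drawn angle, stored in image (y-down)
    coordinates so that reading the table back recovers the drawn angles.
    """
    from .polarity import OrientationVectorSet

    if n_cells < 1 or vectors_per_cell < 1:
        raise ParameterError("n_cells and vectors_per_cell must be >= 1")
    if kappa < 0:
        raise ParameterError("kappa must be non-negative")
    rng = np.random.default_rng(seed)
    grid = int(np.ceil(np.sqrt(n_cells)))
    global_mean = rng.uniform(0.0, 360.0)
    groups: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    angles: dict[str, np.ndarray] = {}
    for i in range(n_cells):
        mean_deg = (global_mean + rng.normal(0.0, cell_mean_spread_deg)) % 360.0
        if kappa == 0:
            a = rng.uniform(0.0, 360.0, size=vectors_per_cell)
        else:
            a = np.degrees(rng.vonmises(np.radians(mean_deg), kappa,
                                        size=vectors_per_cell)) % 360.0
        base0 = np.array([(i % grid) * 20.0, (i // grid) * 20.0])
        vecs = []
        for j, ang in enumerate(a):
            base = base0 + rng.uniform(0.0, 10.0, size=2)
            rad = np.radians(ang)
            tip = base + np.array([np.cos(rad), -np.sin(rad)])  # y-down storage
            vecs.append((base, tip))
        cid = f"cell{i:03d}"
        groups[cid] = vecs
        angles[cid] = a
    return OrientationVectorSet(groups=groups, kind="cell",
                                true_angles_deg=angles)


# --------------------------------------------------------------------------
# bead tracks
# --------------------------------------------------------------------------

def generate_bead_tracks(n_tracks: int, speed_um_s: float, diffusion_sd_um: float,
                         n_frames: int, frame_interval_s: float, seed: int):
    """Simulate bead trajectories: directed drift plus Gaussian jitter.

    Each track moves ``speed_um_s * frame_interval_s`` per frame along a fixed
    random heading, with isotropic Gaussian positional jitter of sd
    ``diffusion_sd_um`` added independently per frame
    (``diffusion_sd_um=0`` gives perfectly straight tracks).
    """
    from .flow import TrackSet

    if n_frames < 2:
        raise ParameterError("n_frames must be >= 2")
    if speed_um_s < 0 or diffusion_sd_um < 0:
        raise ParameterError("speed and diffusion sd must be non-negative")
    if not (frame_interval_s > 0):
        raise ParameterError("frame_interval_s must be positive")
    rng = np.random.default_rng(seed)
    tracks: dict[str, np.ndarray] = {}
    for i in range(n_tracks):
        origin = rng.uniform(0.0, 100.0, size=2)
        heading = rng.uniform(0.0, 2 * np.pi)
        step = speed_um_s * frame_interval_s
        t = np.arange(n_frames)
        drift = np.outer(t, step * np.array([np.cos(heading), np.sin(heading)]))
        jitter = (rng.normal(0.0, diffusion_sd_um, size=(n_frames, 2))
                  if diffusion_sd_um > 0 else np.zeros((n_frames, 2)))
        pos = origin + drift + jitter
        tracks[f"track{i:04d}"] = np.column_stack([t, pos])
    return TrackSet(tracks=tracks, frame_interval_s=frame_interval_s)


# --------------------------------------------------------------------------
# interaction screen
# --------------------------------------------------------------------------

def generate_lumier_table(n_preys: int, n_true_hits: int,
                          hit_lir_range: tuple[float, float],
                          null_lir_range: tuple[float, float], seed: int,
                          threshold: float = 3.0):
    """Simulate a duplicate interaction screen with a known hit set.

    Exactly ``n_true_hits`` preys get both replicate luminescence intensity
    ratios drawn from ``hit_lir_range`` (entirely at or above the hit
    threshold); the rest draw from ``null_lir_range`` (entirely below it).
    """
    from .stats import LumierTable

    if n_true_hits > n_preys or n_true_hits < 0:
        raise ParameterError("need 0 <= n_true_hits <= n_preys")
    if hit_lir_range[0] < threshold or hit_lir_range[0] > hit_lir_range[1]:
        raise ParameterError("hit_lir_range must lie entirely >= threshold")
    if null_lir_range[1] >= threshold or null_lir_range[0] > null_lir_range[1]:
        raise ParameterError("null_lir_range must lie entirely below threshold")
    rng = np.random.default_rng(seed)
    hit_idx = set(rng.choice(n_preys, size=n_true_hits, replace=False).tolist()
                  if n_true_hits else [])
    rows = []
    for i in range(n_preys):
        lo, hi = hit_lir_range if i in hit_idx else null_lir_range
        rows.append({"prey": f"prey{i:03d}",
                     "lir_rep1": float(rng.uniform(lo, hi)),
                     "lir_rep2": float(rng.uniform(lo, hi))})
    return LumierTable(pd.DataFrame(rows)), sorted(f"prey{i:03d}" for i in hit_idx)
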