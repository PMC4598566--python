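"""Automated cilia detection, axoneme length measurement and time-course
aggregation for two-channel 3D stacks (centrosome marker + axoneme marker).

The detection routine is a six-step procedure applied per field:

1. maximum-intensity projection of the centrosome channel along z;
2. centrosome spot detection (difference-of-Gaussians band-pass, robust
   SNR threshold, non-maximum suppression);
3. an 11 × 11 µm peri-centrosomal crop of the z-projected axoneme channel
   around each spot;
4. segmentation of the bright proximal cluster of the axoneme near the
   centrosome (quantile threshold, component nearest the crop centre);
5. completion of the axoneme mask by region growing while candidate border
   pixels keep sufficient contrast over the local background;
6. skeletonization of the mask and measurement of axoneme length as the
   longest geodesic path through the skeleton.

A centrosome is called ciliated when the measured length reaches
``min_cilium_length_um``. Per-field ciliation percentages are then pooled
into time courses (mean ± s.e.m. over replicate fields, Welch's t-test of
each condition against a named control at each timepoint).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.sparse.csgraph import dijkstra
from skimage.measure import label
from scipy.ndimage import binary_dilation
from skimage.morphology import skeletonize

from .imgio import Config, ImageStack, ParameterError
from .stats import sem, welch_t_test

__all__ = [
    "CentrosomeSpot", "CiliumRecord", "FieldSummary", "TimecoursePoint",
    "project_max", "detect_centrosomes", "crop_pericentrosomal",
    "segment_proximal_cluster", "grow_axoneme", "measure_axoneme_length",
    "quantify_field", "summarize_timecourse",
]

_SQRT2 = float(np.sqrt(2.0))


@dataclass
class CentrosomeSpot:
    position: tuple[float, float]   # (x, y) px on the projected image
    peak_intensity: float


@dataclass
class CiliumRecord:
    centrosome: CentrosomeSpot
    ciliated: bool
    axoneme_mask: np.ndarray        # bool, crop coordinates
    crop_origin: tuple[int, int]    # (x0, y0) of the crop in the full image
    length_um: float
    padded: bool = False            # crop clipped at the image border


@dataclass
class FieldSummary:
    condition: str
    timepoint_h: float
    n_cells: int
    percent_ciliated: float
    mean_length_um: float           # over ciliated cells only; nan if none
    sd_length_um: float
    field_id: str = ""
    valid: bool = True


@dataclass
class TimecoursePoint:
    condition: str
    timepoint_h: float
    mean_percent_ciliated: float
    sem_percent_ciliated: float     # nan for a single replicate
    n_replicates: int


# --------------------------------------------------------------------------
# steps 1-6
# --------------------------------------------------------------------------

def project_max(stack: ImageStack, channel: int) -> np.ndarray:
    """Maximum-intensity projection of one channel along z."""
    if not (0 <= channel < stack.n_channels):
        raise ParameterError(f"channel {channel} out of range")
    return stack.voxels[channel].max(axis=0)


def detect_centrosomes(projected: np.ndarray, spot_sigma_px: float = 2.0,
                       min_peak_snr: float = 5.0,
                       min_separation_px: float = 5.0) -> list[CentrosomeSpot]:
    """Detect diffraction-limited spots on a projected centrosome image.

    The image is band-passed with a difference of Gaussians (sigma, 1.6 sigma),
    local maxima are thresholded at ``median + min_peak_snr * 1.4826 * MAD``
    of the band-passed image (a robust background estimate), and maxima closer
    than ``min_separation_px`` are suppressed keeping the brighter spot (ties
    broken toward the smaller (y, x) position).
    """
    if min(spot_sigma_px, min_peak_snr, min_separation_px) <= 0:
        raise ParameterError("detection parameters must be positive")
    img = np.asarray(projected, dtype=float)
    if img.size == 0:
        return []
    dog = gaussian_filter(img, spot_sigma_px) - gaussian_filter(img, 1.6 * spot_sigma_px)
    med = float(np.median(dog))
    mad_sd = 1.4826 * float(np.median(np.abs(dog - med)))
    thresh = med + min_peak_snr * mad_sd

    # strict local maxima on the band-passed image (8-neighbourhood)
    pad = np.pad(dog, 1, mode="constant", constant_values=-np.inf)
    is_max = np.ones_like(dog, dtype=bool)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            shifted = pad[1 + dy:1 + dy + dog.shape[0], 1 + dx:1 + dx + dog.shape[1]]
            is_max &= dog >= shifted
    ys, xs = np.nonzero(is_max & (dog > thresh))
    if len(ys) == 0:
        return []
    order = sorted(range(len(ys)),
                   key=lambda i: (-dog[ys[i], xs[i]], ys[i], xs[i]))
    accepted: list[CentrosomeSpot] = []
    acc_yx: list[tuple[int, int]] = []
    for i in order:
        y, x = int(ys[i]), int(xs[i])
        if all(np.hypot(y - ay, x - ax) >= min_separation_px for ay, ax in acc_yx):
            acc_yx.append((y, x))
            accepted.append(CentrosomeSpot(position=(float(x), float(y)),
                                           peak_intensity=float(img[y, x])))
    accepted.sort(key=lambda s: (s.position[1], s.position[0]))
    return accepted


def crop_pericentrosomal(tubulin_projected: np.ndarray, spot: CentrosomeSpot,
                         pixel_size_um: float, crop_side_um: float = 11.0
                         ) -> tuple[np.ndarray, tuple[int, int], bool]:
    """Square crop of the axoneme channel centred on a centrosome spot.

    The side is ``round(crop_side_um / pixel_size_um)`` px forced odd so the
    spot is the exact centre pixel. Area falling outside the image is padded
    with the image background median and flagged.

    Returns ``(crop, (x0, y0) origin, padded)``.
    """
    side = int(round(crop_side_um / pixel_size_um))
    if side % 2 == 0:
        side += 1
    if side < 3:
        raise ParameterError("crop side below 3 px; check pixel size")
    half = side // 2
    cx, cy = int(round(spot.position[0])), int(round(spot.position[1]))
    h, w = tubulin_projected.shape
    y0, y1 = cy - half, cy + half + 1
    x0, x1 = cx - half, cx + half + 1
    bg = float(np.median(tubulin_projected))
    crop = np.full((side, side), bg, dtype=float)
    sy0, sy1 = max(y0, 0), min(y1, h)
    sx0, sx1 = max(x0, 0), min(x1, w)
    padded = (sy0 != y0) or (sy1 != y1) or (sx0 != x0) or (sx1 != x1)
    crop[sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = tubulin_projected[sy0:sy1, sx0:sx1]
    return crop, (x0, y0), padded


def segment_proximal_cluster(crop: np.ndarray, seed_quantile: float = 0.99,
                             min_seed_px: int = 4) -> np.ndarray:
    """Segment the bright cluster marking the proximal axoneme.

    Thresholds the crop at its ``seed_quantile`` intensity quantile and keeps
    the 8-connected component nearest the crop centre whose area reaches
    ``min_seed_px``; returns an all-false mask when none qualifies (e.g. a
    constant crop).
    """
    if not (0 < seed_quantile < 1):
        raise ParameterError("seed_quantile must lie in (0, 1)")
    crop = np.asarray(crop, dtype=float)
    thresh = float(np.quantile(crop, seed_quantile))
    binary = crop > thresh
    if not binary.any():
        return np.zeros_like(binary)
    labels = label(binary, connectivity=2)
    cy, cx = (np.asarray(crop.shape) - 1) / 2.0
    best, best_dist = 0, np.inf
    for lab in range(1, labels.max() + 1):
        ys, xs = np.nonzero(labels == lab)
        if len(ys) < min_seed_px:
            continue
        d = float(np.min(np.hypot(ys - cy, xs - cx)))
        if d < best_dist:
            best, best_dist = lab, d
    return labels == best if best else np.zeros_like(binary)


def grow_axoneme(crop: np.ndarray, seed_mask: np.ndarray,
                 contrast_stop_ratio: float = 1.5,
                 max_iterations: int = 200) -> np.ndarray:
    """Complete the axoneme mask by contrast-guarded region growing.

    At each iteration the 8-connected border pixels of the current mask are
    admitted when their intensity keeps contrast over the local background —
    at least ``contrast_stop_ratio`` times the median of crop pixels outside
    the mask dilated by 2 px. Growth stops when no border pixel qualifies or
    after ``max_iterations``. The result always contains the seed; an empty
    seed is returned unchanged.
    """
    if contrast_stop_ratio <= 1:
        raise ParameterError("contrast_stop_ratio must exceed 1")
    crop = np.asarray(crop, dtype=float)
    mask = np.asarray(seed_mask, dtype=bool).copy()
    if not mask.any():
        return mask
    sel = np.ones((3, 3), dtype=bool)
    for _ in range(max_iterations):
        dil2 = binary_dilation(binary_dilation(mask, sel), sel)
        outside = ~dil2
        if not outside.any():
            break
        background = float(np.median(crop[outside]))
        border = binary_dilation(mask, sel) & ~mask
        admit = border & (crop >= background * contrast_stop_ratio)
        if not admit.any():
            break
        mask |= admit
    return mask


def measure_axoneme_length(mask: np.ndarray, pixel_size_um: float) -> float:
    """Axoneme length: longest geodesic path through the mask skeleton.

    The mask is thinned to a 1-px skeleton; path steps cost 1 axially and
    sqrt(2) diagonally, and the returned length is the largest finite
    pairwise geodesic distance times the pixel size (0 for an empty mask).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0.0
    skel = skeletonize(mask)
    ys, xs = np.nonzero(skel)
    n = len(ys)
    if n <= 1:
        return 0.0
    index = {(y, x): i for i, (y, x) in enumerate(zip(ys, xs))}
    rows, cols, data = [], [], []
    for i, (y, x) in enumerate(zip(ys, xs)):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dy == 0 and dx == 0:
                    continue
                j = index.get((y + dy, x + dx))
                if j is not None and j > i:
                    w = _SQRT2 if dy and dx else 1.0
                    rows.append(i)
                    cols.append(j)
                    data.append(w)
    from scipy.sparse import csr_matrix

    graph = csr_matrix((data, (rows, cols)), shape=(n, n))
    dist = dijkstra(graph, directed=False)
    finite = dist[np.isfinite(dist)]
    return float(finite.max()) * pixel_size_um


# --------------------------------------------------------------------------
# field- and timecourse-level quantification
# --------------------------------------------------------------------------

def quantify_field(stack: ImageStack, config: Config | None = None,
                   condition: str = "", timepoint_h: float = 0.0,
                   field_id: str = "",
                   centrosome_channel: int = 0, axoneme_channel: int = 1
                   ) -> tuple[list[CiliumRecord], FieldSummary]:
    """Run the full six-step procedure on one two-channel field.

    Returns one :class:`CiliumRecord` per detected centrosome and a
    :class:`FieldSummary` with the ciliation percentage and length statistics
    (over ciliated cells only). Zero detected centrosomes yields a summary
    flagged invalid.
    """
    cfg = config or Config()
    if stack.n_channels < 2:
        raise ParameterError("quantify_field needs a two-channel stack")
    centro = project_max(stack, centrosome_channel)
    tub = project_max(stack, axoneme_channel)
    spots = detect_centrosomes(centro, cfg.spot_sigma_px, cfg.min_peak_snr,
                               cfg.min_separation_px)
    records: list[CiliumRecord] = []
    for spot in spots:
        crop, origin, padded = crop_pericentrosomal(
            tub, spot, stack.pixel_size_um, cfg.crop_side_um)
        seed = segment_proximal_cluster(crop, cfg.seed_quantile, cfg.min_seed_px)
        mask = grow_axoneme(crop, seed, cfg.contrast_stop_ratio,
                            cfg.max_grow_iterations)
        length = measure_axoneme_length(mask, stack.pixel_size_um)
        ciliated = length >= cfg.min_cilium_length_um
        if not ciliated:
            mask = np.zeros_like(mask)
            length = 0.0
        records.append(CiliumRecord(centrosome=spot, ciliated=ciliated,
                                    axoneme_mask=mask, crop_origin=origin,
                                    length_um=length, padded=padded))
    n = len(records)
    n_cil = sum(r.ciliated for r in records)
    lengths = np.array([r.length_um for r in records if r.ciliated])
    summary = FieldSummary(
        condition=condition, timepoint_h=timepoint_h, field_id=field_id,
        n_cells=n,
        percent_ciliated=100.0 * n_cil / n if n else 0.0,
        mean_length_um=float(lengths.mean()) if len(lengths) else float("nan"),
        sd_length_um=float(lengths.std(ddof=1)) if len(lengths) > 1 else float("nan"),
        valid=n > 0)
    return records, summary


def records_to_frame(records: Sequence[CiliumRecord], field_id: str = ""
                     ) -> pd.DataFrame:
    rows = [{"field_id": field_id,
             "centrosome_x": r.centrosome.position[0],
             "centrosome_y": r.centrosome.position[1],
             "ciliated": r.ciliated, "length_um": r.length_um}
            for r in records]
    return pd.DataFrame(rows, columns=["field_id", "centrosome_x",
                                       "centrosome_y", "ciliated", "length_um"])


def summarize_timecourse(summaries: Sequence[FieldSummary], control: str
                         ) -> tuple[list[TimecoursePoint], pd.DataFrame]:
    """Pool replicate field summaries into a disassembly time course.

    Groups by condition × timepoint; reports mean and s.e.m. of the ciliation
    percentage over replicates (s.e.m. missing for a single replicate) and a
    two-sided Welch t-test of every non-control condition against ``control``
    at each shared timepoint (skipped with a warning when either side has a
    single replicate).
    """
    from .imgio import warn

    conditions = {s.condition for s in summaries}
    if control not in conditions:
        raise ParameterError(f"unknown control condition {control!r}")
    groups: dict[tuple[str, float], list[float]] = {}
    for s in summaries:
        if not s.valid:
            warn(f"field {s.field_id!r} invalid (no centrosomes); excluded")
            continue
        groups.setdefault((s.condition, s.timepoint_h), []).append(s.percent_ciliated)

    points = [TimecoursePoint(
        condition=cond, timepoint_h=tp,
        mean_percent_ciliated=float(np.mean(vals)),
        sem_percent_ciliated=sem(vals),
        n_replicates=len(vals))
        for (cond, tp), vals in sorted(groups.items())]

    tests = []
    for (cond, tp), vals in sorted(groups.items()):
        if cond == control:
            continue
        ctl = groups.get((control, tp))
        if ctl is None:
            continue
        if len(vals) < 2 or len(ctl) < 2:
            warn(f"t-test skipped for {cond!r} at t={tp} h: "
                 "needs >= 2 replicates per group")
            t = p = float("nan")
        else:
            t, p = welch_t_test(vals, ctl)
        tests.append({"condition": cond, "control": control, "timepoint_h": tp,
                      "t": t, "p": p})
    test_frame = pd.DataFrame(tests, columns=["condition", "control",
                                              "timepoint_h", "t", "p"])
    return points, test_frame
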