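"""Rotational and translational basal-body polarity via circular statistics.

Motile cilia beat in a direction set by the orientation of the basal rootlet
appended to each basal body (BB). Two levels of planar polarization are
quantified here:

* **rotational polarity** — alignment of basal-rootlet orientation vectors
  (BROVs) among the cilia of one multiciliated cell. Dispersion is the
  circular standard deviation (CSD) of the per-cell BROV angles; a condition
  is summarized by mean ± s.d. of CSD across cells.
* **translational polarity** — displacement of each cell's BB patch from the
  cell centre, measured as a BB orientation vector (BBOV) from the cell
  outline's area centroid to the BB-patch centroid. Dispersion is the CSD of
  BBOV angles within each field of view; a condition is summarized by
  mean ± s.d. of CSD across fields.

For display, angles within a group are re-centred so the group's circular
mean sits at 90 degrees (angle − group mean + 90°, mod 360), then pooled into
rose-plot histograms. Conditions are compared with a two-sided Mann-Whitney
U test on the per-group CSDs.

Angle convention: counterclockwise from +x in a y-up mathematical frame.
Image-storage coordinates are y-down; the flip happens exactly once, when a
stored base→tip pair is converted to an angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.ndimage import uniform_filter
from skimage.draw import polygon2mask
from skimage.measure import label

from .imgio import ParameterError, RoiPolygon, warn

__all__ = [
    "OrientationVectorSet", "PolaritySummary", "MannWhitneyResult",
    "vector_angle", "vector_angle_image", "circular_mean", "circular_sd",
    "normalize_angles", "angle_histogram", "mann_whitney",
    "rotational_polarity_summary", "segment_basal_bodies", "bbov",
    "translational_polarity_summary", "rose_plot",
]


@dataclass
class OrientationVectorSet:
    """Grouped base→tip coordinate pairs in image-storage (y-down) pixels.

    ``kind`` is "cell" for rotational (per-cell) groups or "field" for
    translational (per-field-of-view) groups. ``true_angles_deg`` is filled
    by the synthetic generator for recovery tests; ``conditions`` optionally
    maps each group to an experimental condition label.
    """

    groups: dict[str, list[tuple[np.ndarray, np.ndarray]]]
    kind: str = "cell"
    conditions: dict[str, str] | None = None
    true_angles_deg: dict[str, np.ndarray] | None = None

    def angles_deg(self, group_id: str) -> np.ndarray:
        """Angles of a group's vectors, y-flip applied here (and only here)."""
        return np.array([vector_angle_image(base, tip)
                         for base, tip in self.groups[group_id]])


@dataclass
class MannWhitneyResult:
    condition_a: str
    condition_b: str
    u: float
    p: float
    method: str


@dataclass
class PolaritySummary:
    condition: str
    group_csd_deg: dict[str, float]
    normalized_angles_deg: np.ndarray
    mean_csd_deg: float
    sd_csd_deg: float                    # nan for a single group
    histogram_edges: np.ndarray
    histogram_counts: np.ndarray
    n_groups: int
    excluded_groups: list[str] = field(default_factory=list)


# --------------------------------------------------------------------------
# elementary circular statistics
# --------------------------------------------------------------------------

def _wrap_deg(deg: float) -> float:
    """Map to [0, 360); guards against float `x % 360 == 360.0`."""
    deg = deg % 360.0
    return 0.0 if deg >= 360.0 else deg


def vector_angle(base, tip) -> float:
    """Angle of tip−base in degrees [0, 360), CCW from +x, y-up frame."""
    base = np.asarray(base, dtype=float)
    tip = np.asarray(tip, dtype=float)
    d = tip - base
    if np.hypot(*d) == 0:
        raise ParameterError("degenerate vector: base equals tip")
    return _wrap_deg(float(np.degrees(np.arctan2(d[1], d[0]))))


def vector_angle_image(base, tip) -> float:
    """Angle of a vector stored in image (y-down) coordinates."""
    base = np.asarray(base, dtype=float)
    tip = np.asarray(tip, dtype=float)
    return vector_angle((base[0], -base[1]), (tip[0], -tip[1]))


def circular_mean(angles_deg) -> tuple[float, float]:
    """Circular mean direction and mean resultant length R.

    Returns ``(mean_deg in [0, 360), R)``; the mean is NaN (undefined) when
    R < 1e-12, e.g. for antipodal pairs.
    """
    angles = np.asarray(angles_deg, dtype=float)
    if angles.size == 0:
        raise ParameterError("circular_mean of an empty list")
    rad = np.radians(angles)
    s, c = np.mean(np.sin(rad)), np.mean(np.cos(rad))
    r = float(np.hypot(s, c))
    if r < 1e-12:
        return float("nan"), r
    return _wrap_deg(float(np.degrees(np.arctan2(s, c)))), r


def circular_sd(angles_deg) -> float:
    """Circular standard deviation sqrt(-2 ln R), in degrees.

    R is the mean resultant length of the unit vectors; R → 0 gives +inf
    (infinite dispersion).
    """
    _, r = circular_mean(angles_deg)
    if r == 0:
        return float("inf")
    return float(np.degrees(np.sqrt(-2.0 * np.log(r))))


def normalize_angles(angles_deg) -> np.ndarray:
    """Re-centre a group of angles so its circular mean is 90 degrees.

    Each output is ``(angle − group circular mean + 90) mod 360``; raises for
    a group whose circular mean is undefined.
    """
    angles = np.asarray(angles_deg, dtype=float)
    mean, _ = circular_mean(angles)
    if np.isnan(mean):
        raise ParameterError("cannot normalize: group circular mean undefined")
    out = (angles - mean + 90.0) % 360.0
    return np.where(out >= 360.0, 0.0, out)


def angle_histogram(angles_deg, n_bins: int = 24
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width counts over [0, 360), left-closed right-open bins."""
    if n_bins < 1:
        raise ParameterError("n_bins must be >= 1")
    angles = np.mod(np.asarray(angles_deg, dtype=float), 360.0)
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    idx = np.floor(angles / (360.0 / n_bins)).astype(int)
    counts = np.bincount(idx, minlength=n_bins)[:n_bins]
    return edges, counts


def mann_whitney(a, b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    The exact permutation distribution is used when min(n_a, n_b) <= 8 and
    there are no ties across the pooled sample; otherwise the normal
    approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("mann_whitney needs two non-empty samples")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if min(a.size, b.size) <= 8 and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return MannWhitneyResult(condition_a="a", condition_b="b",
                             u=float(res.statistic), p=float(min(res.pvalue, 1.0)),
                             method=method)


# --------------------------------------------------------------------------
# rotational polarity (per-cell BROVs)
# --------------------------------------------------------------------------

def _summarize_groups(angle_lists: Mapping[str, np.ndarray], condition: str,
                      n_bins: int) -> PolaritySummary:
    csds: dict[str, float] = {}
    normalized: list[np.ndarray] = []
    excluded: list[str] = []
    for gid in sorted(angle_lists):
        angles = angle_lists[gid]
        if len(angles) < 2:
            warn(f"group {gid!r} has fewer than 2 vectors; excluded")
            excluded.append(gid)
            continue
        mean, r = circular_mean(angles)
        if np.isnan(mean):
            warn(f"group {gid!r} has undefined mean direction; excluded")
            excluded.append(gid)
            continue
        csds[gid] = circular_sd(angles)
        normalized.append(normalize_angles(angles))
    pooled = np.concatenate(normalized) if normalized else np.empty(0)
    edges, counts = angle_histogram(pooled, n_bins)
    vals = np.array(list(csds.values()))
    return PolaritySummary(
        condition=condition, group_csd_deg=csds, normalized_angles_deg=pooled,
        mean_csd_deg=float(vals.mean()) if len(vals) else float("nan"),
        sd_csd_deg=float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
        histogram_edges=edges, histogram_counts=counts,
        n_groups=len(csds), excluded_groups=excluded)


def rotational_polarity_summary(conditions: Mapping[str, OrientationVectorSet],
                                compare: tuple[str, str] | None = None,
                                n_bins: int = 24
                                ) -> tuple[dict[str, PolaritySummary],
                                           MannWhitneyResult | None]:
    """Per-cell CSD of rootlet orientation vectors, summarized per condition.

    Cells with a single vector are excluded with a warning. When ``compare``
    names two conditions (default: the only two present), their per-cell CSD
    lists are compared with a two-sided Mann-Whitney U test.
    """
    summaries = {
        cond: _summarize_groups(
            {gid: vecset.angles_deg(gid) for gid in vecset.groups},
            cond, n_bins)
        for cond, vecset in conditions.items()}
    test = None
    if compare is None and len(summaries) == 2:
        compare = tuple(summaries)  # type: ignore[assignment]
    if compare is not None:
        ca, cb = compare
        if ca not in summaries or cb not in summaries:
            raise ParameterError(f"unknown condition in compare={compare}")
        test = mann_whitney(list(summaries[ca].group_csd_deg.values()),
                            list(summaries[cb].group_csd_deg.values()))
        test.condition_a, test.condition_b = ca, cb
    return summaries, test


# --------------------------------------------------------------------------
# translational polarity (per-field BBOVs)
# --------------------------------------------------------------------------

def _roi_mask(roi: RoiPolygon, shape: tuple[int, int]) -> np.ndarray:
    # polygon2mask takes (row, col) = (y, x) vertex order
    return polygon2mask(shape, roi.vertices[:, ::-1])


def segment_basal_bodies(gamma_tubulin: np.ndarray, roi: RoiPolygon,
                         window_px: int = 51, offset: float = 0.0
                         ) -> np.ndarray:
    """Segment the BB patch inside one cell by adaptive mean thresholding.

    A pixel is kept when its intensity exceeds the local mean over a square
    ``window_px`` window plus ``offset``, restricted to the ROI interior; the
    largest 8-connected component is returned (all-false when nothing passes).
    """
    img = np.asarray(gamma_tubulin, dtype=float)
    roi_mask = _roi_mask(roi, img.shape)
    if not roi_mask.any():
        raise ParameterError(f"ROI {roi.cell_id!r} lies outside the image")
    local_mean = uniform_filter(img, size=window_px, mode="reflect")
    binary = (img > local_mean + offset) & roi_mask
    if not binary.any():
        return np.zeros_like(binary)
    labels = label(binary, connectivity=2)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return labels == int(sizes.argmax())


def roi_centroid(roi: RoiPolygon) -> np.ndarray:
    """Uniform-area centroid of a simple polygon (shoelace formula), (x, y)."""
    v = roi.vertices
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = cross.sum() / 2.0
    if area == 0:
        raise ParameterError(f"ROI {roi.cell_id!r} has zero area")
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    return np.array([cx, cy])


def bbov(roi: RoiPolygon, bb_mask: np.ndarray) -> float:
    """BB orientation vector angle: cell centroid → BB-patch pixel centroid.

    The cell centroid is the polygon's uniform-area centre; the patch
    centroid is the unweighted mean of its pixel centres. Degenerate
    (coincident) centroids raise a :class:`ParameterError`.
    """
    mask = np.asarray(bb_mask, dtype=bool)
    if not mask.any():
        raise ParameterError("empty BB patch")
    ys, xs = np.nonzero(mask)
    patch = np.array([xs.mean(), ys.mean()])
    cell = roi_centroid(roi)
    if np.hypot(*(patch - cell)) < 1e-9:
        raise ParameterError("degenerate BBOV: patch centroid at cell centroid")
    return vector_angle_image(cell, patch)


def translational_polarity_summary(
        conditions: Mapping[str, Sequence[Sequence[tuple[RoiPolygon, np.ndarray]]]],
        compare: tuple[str, str] | None = None, n_bins: int = 24
        ) -> tuple[dict[str, PolaritySummary], MannWhitneyResult | None]:
    """Per-field CSD of BB orientation vectors, summarized per condition.

    Input per condition is a list of fields, each a list of
    ``(roi, bb_mask)`` cells. Cells with an empty patch or a degenerate BBOV,
    and fields with fewer than two valid BBOVs, are excluded with a warning.
    Normalization to a 90-degree circular mean is applied per field before
    pooling. ``compare`` behaves as in :func:`rotational_polarity_summary`,
    operating on per-field CSDs.
    """
    summaries: dict[str, PolaritySummary] = {}
    for cond, fields in conditions.items():
        angle_lists: dict[str, np.ndarray] = {}
        for fi, cells in enumerate(fields):
            angles = []
            for roi, mask in cells:
                try:
                    angles.append(bbov(roi, mask))
                except ParameterError as exc:
                    warn(f"cell {roi.cell_id!r} excluded: {exc}")
            angle_lists[f"field{fi:03d}"] = np.array(angles)
        summaries[cond] = _summarize_groups(angle_lists, cond, n_bins)
    test = None
    if compare is None and len(summaries) == 2:
        compare = tuple(summaries)  # type: ignore[assignment]
    if compare is not None:
        ca, cb = compare
        if ca not in summaries or cb not in summaries:
            raise ParameterError(f"unknown condition in compare={compare}")
        test = mann_whitney(list(summaries[ca].group_csd_deg.values()),
                            list(summaries[cb].group_csd_deg.values()))
        test.condition_a, test.condition_b = ca, cb
    return summaries, test


# --------------------------------------------------------------------------
# plotting
# --------------------------------------------------------------------------

def rose_plot(angles_deg, n_bins: int = 24, ax=None):
    """Rose (polar histogram) plot of a list of angles in degrees."""
    import matplotlib.pyplot as plt

    edges, counts = angle_histogram(angles_deg, n_bins)
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    width = np.radians(360.0 / n_bins)
    ax.bar(np.radians(edges[:-1]) + width / 2, counts, width=width,
           edgecolor="black", linewidth=0.5)
    return ax


def summaries_to_frame(summaries: Mapping[str, PolaritySummary],
                       test: MannWhitneyResult | None) -> pd.DataFrame:
    """Flatten polarity summaries to the documented CSV schema."""
    rows = []
    for cond in sorted(summaries):
        s = summaries[cond]
        for gid in sorted(s.group_csd_deg):
            rows.append({"row_type": "group", "condition": cond,
                         "group_id": gid, "csd_deg": s.group_csd_deg[gid],
                         "n_groups": np.nan, "mean_csd_deg": np.nan,
                         "sd_csd_deg": np.nan, "u": np.nan, "p": np.nan})
        rows.append({"row_type": "condition", "condition": cond, "group_id": "",
                     "csd_deg": np.nan, "n_groups": s.n_groups,
                     "mean_csd_deg": s.mean_csd_deg, "sd_csd_deg": s.sd_csd_deg,
                     "u": np.nan, "p": np.nan})
    if test is not None:
        rows.append({"row_type": "test",
                     "condition": f"{test.condition_a} vs {test.condition_b}",
                     "group_id": "", "csd_deg": np.nan, "n_groups": np.nan,
                     "mean_csd_deg": np.nan, "sd_csd_deg": np.nan,
                     "u": test.u, "p": test.p})
    return pd.DataFrame(rows)
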