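"""Membrane-channel segmentation of sporangia and forespore/mother pairing.

The FM 4-64 membrane channel shows every cell outline, with a brighter
double-membrane outline around the forespore. Thresholding high therefore
isolates forespores; thresholding low gives whole-cell outlines; filling
holes turns outlines into regions; subtracting (dilated) forespores from
whole cells leaves mother cells. Forespores are then paired to mother cells
by centroid distance, then by the angle between the mother cell's major axis
and the centroid-to-centroid vector — strict filters chosen to avoid false
matches over maximizing recall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology

from .io import ImageStack

DEFAULT_HIGH_QUANTILE = 0.995
DEFAULT_LOW_QUANTILE = 0.95
DEFAULT_MIN_AREA = 20  # px^2
DEFAULT_MAX_DISTANCE = 3.0  # um, about one sporangium length
DEFAULT_MAX_ANGLE = 30.0  # degrees


@dataclass
class CellObject:
    """One segmented cell: mask, geometry and per-channel mean intensities."""

    label: int
    mask: np.ndarray  # boolean, full image shape
    centroid: tuple[float, float]  # (row, col), px
    area: int  # px^2
    orientation: float  # major-axis angle in degrees, (-90, 90]
    mean_intensity: dict[str, float]

    def centroid_um(self, pixel_size: float) -> np.ndarray:
        return np.asarray(self.centroid) * pixel_size


@dataclass
class SegmentedSporangium:
    """A matched forespore/mother-cell pair with pairing diagnostics."""

    forespore: CellObject
    mother_cell: CellObject
    pair_distance: float  # um, centroid to centroid
    pair_angle: float  # degrees between MC axis and the centroid vector


def resolve_threshold(image: np.ndarray, spec) -> float:
    """Resolve a threshold spec to an absolute intensity.

    ``("quantile", q)`` takes the q-quantile of the image; ``("abs", v)`` or
    a bare number is used as-is.
    """
    if isinstance(spec, (int, float, np.floating)):
        return float(spec)
    kind, value = spec
    if kind == "quantile":
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"quantile must be in [0, 1], got {value}")
        return float(np.quantile(image, value))
    if kind == "abs":
        return float(value)
    raise ValueError(f"unknown threshold spec {spec!r}")


def _principal_axis_deg(mask: np.ndarray) -> float:
    """Major-axis angle in degrees from the +column axis, in (-90, 90].

    Computed as the leading principal component of the mask's pixel
    coordinates (rows treated as y), so the convention matches the
    centroid-to-centroid vectors used in pairing.
    """
    coords = np.argwhere(mask).astype(float)
    centered = coords - coords.mean(axis=0)
    if len(coords) < 2:
        return 0.0
    cov = centered.T @ centered / len(coords)
    vals, vecs = np.linalg.eigh(cov)
    vr, vc = vecs[:, np.argmax(vals)]  # (row, col) components
    angle = np.rad2deg(np.arctan2(vr, vc))
    if angle <= -90.0:
        angle += 180.0
    elif angle > 90.0:
        angle -= 180.0
    return float(angle)


def _objects_from_mask(
    mask: np.ndarray, stack: ImageStack, min_area: int, start_label: int = 1
) -> list[CellObject]:
    filled = ndi.binary_fill_holes(mask)
    labels = measure.label(filled, connectivity=2)
    objects = []
    next_label = start_label
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        obj_mask = labels == region.label
        means = {
            name: float(ch[obj_mask].mean()) for name, ch in stack.channels.items()
        }
        orient = _principal_axis_deg(obj_mask)
        objects.append(
            CellObject(
                label=next_label,
                mask=obj_mask,
                centroid=tuple(region.centroid),
                area=int(region.area),
                orientation=float(orient),
                mean_intensity=means,
            )
        )
        next_label += 1
    # stable ordering by position so labels are reproducible across runs
    objects.sort(key=lambda o: o.centroid)
    for i, obj in enumerate(objects):
        obj.label = start_label + i
    return objects


def segment_membrane(
    stack: ImageStack,
    high_level=("quantile", DEFAULT_HIGH_QUANTILE),
    low_level=("quantile", DEFAULT_LOW_QUANTILE),
    min_area: int = DEFAULT_MIN_AREA,
) -> tuple[list[CellObject], list[CellObject]]:
    """Dual-threshold segmentation of the membrane channel.

    Thresholding high keeps only the bright double membrane around
    forespores; thresholding low keeps all cell outlines. Both masks are
    hole-filled, labelled with 8-connectivity and filtered by ``min_area``.

    Returns ``(forespores, whole_cells)``.
    """
    if "membrane" not in stack.channels:
        raise ValueError("stack has no 'membrane' channel")
    membrane = stack.channel("membrane")
    high = resolve_threshold(membrane, high_level)
    low = resolve_threshold(membrane, low_level)
    if high <= low:
        raise ValueError(
            f"high threshold ({high:g}) must exceed low threshold ({low:g})"
        )
    forespores = _objects_from_mask(membrane > high, stack, min_area)
    whole_cells = _objects_from_mask(membrane > low, stack, min_area)
    return forespores, whole_cells


def derive_mother_cells(
    whole_cells: list[CellObject],
    forespores: list[CellObject],
    stack: ImageStack,
    dilate_px: int = 1,
) -> list[CellObject]:
    """Subtract (dilated) forespore masks from whole-cell masks.

    Forespores are dilated by ``dilate_px`` before subtraction so shared
    membrane-outline pixels are not attributed to the mother cell. Whole
    cells left with an empty remainder yield no mother cell.
    """
    if forespores:
        fs_union = np.any([f.mask for f in forespores], axis=0)
        if dilate_px > 0:
            fs_union = ndi.binary_dilation(
                fs_union, structure=morphology.disk(dilate_px)
            )
    else:
        fs_union = None
    mothers: list[CellObject] = []
    next_label = 1
    for wc in whole_cells:
        remainder = wc.mask if fs_union is None else (wc.mask & ~fs_union)
        if not remainder.any():
            continue
        objs = _objects_from_mask(remainder, stack, min_area=1, start_label=next_label)
        if not objs:
            continue
        # keep the largest remainder piece as the mother cell
        mc = max(objs, key=lambda o: o.area)
        mc.label = next_label
        mothers.append(mc)
        next_label += 1
    return mothers


def _axis_angle(mother: CellObject, forespore: CellObject) -> float:
    """Angle (deg, 0-90) between the MC major axis and the MC->FS vector."""
    vec = np.asarray(forespore.centroid) - np.asarray(mother.centroid)
    if np.allclose(vec, 0):
        return 0.0
    vec_angle = np.rad2deg(np.arctan2(vec[0], vec[1]))  # from +col axis
    diff = abs(vec_angle - mother.orientation) % 180.0
    return min(diff, 180.0 - diff)


def pair_sporangia(
    forespores: list[CellObject],
    mother_cells: list[CellObject],
    pixel_size: float,
    max_distance: float = DEFAULT_MAX_DISTANCE,
    max_angle: float = DEFAULT_MAX_ANGLE,
) -> tuple[list[SegmentedSporangium], list[CellObject], list[CellObject]]:
    """One-to-one forespore/mother-cell matching with strict filters.

    Candidate pairs must be within ``max_distance`` (um, centroids) and the
    mother cell's major axis must point at the forespore to within
    ``max_angle`` degrees. Surviving candidates are matched greedily by
    (distance, angle, forespore label, mother label) so ties break toward
    the smaller angle and then the smaller label.

    Returns ``(pairs, unmatched_forespores, unmatched_mother_cells)``.
    """
    candidates = []
    for fs in forespores:
        for mc in mother_cells:
            dist = float(
                np.linalg.norm(np.asarray(fs.centroid) - np.asarray(mc.centroid))
                * pixel_size
            )
            if dist > max_distance:
                continue
            angle = _axis_angle(mc, fs)
            if angle > max_angle:
                continue
            candidates.append((dist, angle, fs.label, mc.label, fs, mc))
    candidates.sort(key=lambda c: c[:4])
    used_fs: set[int] = set()
    used_mc: set[int] = set()
    pairs: list[SegmentedSporangium] = []
    for dist, angle, fs_label, mc_label, fs, mc in candidates:
        if fs_label in used_fs or mc_label in used_mc:
            continue
        if np.any(fs.mask & mc.mask):  # disjointness is a hard invariant
            continue
        used_fs.add(fs_label)
        used_mc.add(mc_label)
        pairs.append(
            SegmentedSporangium(
                forespore=fs, mother_cell=mc, pair_distance=dist, pair_angle=angle
            )
        )
    unmatched_fs = [f for f in forespores if f.label not in used_fs]
    unmatched_mc = [m for m in mother_cells if m.label not in used_mc]
    return pairs, unmatched_fs, unmatched_mc


def segment_and_pair(
    stack: ImageStack,
    high_level=("quantile", DEFAULT_HIGH_QUANTILE),
    low_level=("quantile", DEFAULT_LOW_QUANTILE),
    min_area: int = DEFAULT_MIN_AREA,
    max_distance: float = DEFAULT_MAX_DISTANCE,
    max_angle: float = DEFAULT_MAX_ANGLE,
) -> list[SegmentedSporangium]:
    """Full segmentation pipeline: threshold, subtract, pair."""
    forespores, whole_cells = segment_membrane(stack, high_level, low_level, min_area)
    mothers = derive_mother_cells(whole_cells, forespores, stack)
    pairs, _, _ = pair_sporangia(
        forespores, mothers, stack.pixel_size, max_distance, max_angle
    )
    return pairs


def auto_thresholds(stack: ImageStack) -> tuple[float, float]:
    """Data-driven absolute thresholds for the generator's imaging regime.

    Splits the membrane intensity histogram at the midpoints between the
    background mode and the two outline levels (single vs double membrane)
    using the background median/MAD and the channel maximum.
    """
    membrane = stack.channel("membrane")
    bg = float(np.median(membrane))
    peak = float(membrane.max())
    low = bg + 0.25 * (peak - bg)
    high = bg + 0.60 * (peak - bg)
    return high, low
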