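"""Per-cell fluorescence quantification over segmented sporangia.

Covers the study's four single-cell readouts: forespore/mother-cell reporter
concentration ratios, reporter depletion time courses, BONCAT protein-
synthesis quantification from summed optical sections, and the engulfment /
phase-bright spore assays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology

from .io import ImageStack
from .segmentation import CellObject, SegmentedSporangium, resolve_threshold

PHASE_BRIGHT_THRESHOLD = 0.1  # AU, strict exceedance constitutes "phase bright"
DEFAULT_MAX_TRACK_STEP = 1.0  # um/frame for time-lapse nearest-centroid linking


@dataclass
class BackgroundEstimate:
    """Mean and SD of an acellular background region."""

    mean: float
    sd: float
    n_pixels: int


@dataclass
class VolumeEstimate:
    """Cell volumes from mask geometry, in um^3 (= fL).

    The mother cell is modelled as a spherocylinder
    (V = pi r^2 (L - 2r) + 4/3 pi r^3 from mask length L and width 2r),
    the forespore as a prolate spheroid (V = 4/3 pi a b^2 from its mask
    semi-axes).
    """

    fs_volume: float
    mc_volume: float


@dataclass
class RatioMeasurement:
    """Volume-aware forespore:mother-cell reporter concentration ratio."""

    fs_mean: float
    mc_mean: float
    fs_conc: float
    mc_conc: float
    ratio: float | None  # None when the mother-cell concentration is zero

    @property
    def defined(self) -> bool:
        return self.ratio is not None


@dataclass
class DepletionSeries:
    """Per-cell normalized intensity time course (initial value = 1)."""

    frame_times: np.ndarray
    fs_norm: np.ndarray
    mc_norm: np.ndarray
    truncated: bool = False


@dataclass
class BoncatMeasurement:
    """Background- and reference-normalized new-protein-synthesis signal."""

    fs_value: float
    mc_value: float


@dataclass
class PhaseScore:
    engulfed: bool
    avg_phase: float  # background-subtracted, AU
    bright: bool


def estimate_background(
    stack: ImageStack,
    channel: str = "reporter",
    low_level=None,
    dilate_px: int = 3,
) -> BackgroundEstimate:
    """Background statistics from the complement of the cell mask.

    The complement of the (dilated) low-threshold membrane mask serves as
    the acellular region, following the membrane-complement backgrounding of
    the phase-bright assay.
    """
    from .segmentation import DEFAULT_LOW_QUANTILE

    membrane = stack.channel("membrane")
    if low_level is None:
        low_level = ("quantile", DEFAULT_LOW_QUANTILE)
    low = resolve_threshold(membrane, low_level)
    cells = ndi.binary_fill_holes(membrane > low)
    if dilate_px > 0:
        cells = ndi.binary_dilation(cells, structure=morphology.disk(dilate_px))
    bg_mask = ~cells
    if not bg_mask.any():
        raise ValueError("no background pixels left after masking cells")
    vals = stack.channel(channel)[bg_mask]
    return BackgroundEstimate(
        mean=float(vals.mean()), sd=float(vals.std(ddof=1)), n_pixels=int(vals.size)
    )


def estimate_volumes(
    pair: SegmentedSporangium, pixel_size: float
) -> VolumeEstimate:
    """Spherocylinder / prolate-spheroid volumes from the pair's masks."""
    fs_props = measure.regionprops(pair.forespore.mask.astype(int))[0]
    mc_props = measure.regionprops(pair.mother_cell.mask.astype(int))[0]
    a = fs_props.axis_major_length / 2 * pixel_size
    b = fs_props.axis_minor_length / 2 * pixel_size
    fs_volume = 4.0 / 3.0 * np.pi * a * b**2
    L = mc_props.axis_major_length * pixel_size
    # rod radius from the distance transform: robust against the bite the
    # forespore subtraction takes out of the pole (which inflates the
    # moments-based minor axis)
    r = float(ndi.distance_transform_edt(pair.mother_cell.mask).max()) * pixel_size
    L = max(L, 2 * r)  # degenerate masks: treat as a sphere
    mc_volume = np.pi * r**2 * (L - 2 * r) + 4.0 / 3.0 * np.pi * r**3
    return VolumeEstimate(fs_volume=float(fs_volume), mc_volume=float(mc_volume))


def _masked_mean(channel: np.ndarray, mask: np.ndarray) -> float:
    if not mask.any():
        raise ValueError("empty mask")
    return float(channel[mask].mean())


def concentration_ratio(
    pair: SegmentedSporangium,
    stack: ImageStack,
    background: BackgroundEstimate | float,
    channel: str = "reporter",
    volume_mode: bool = False,
) -> RatioMeasurement:
    """Forespore-to-mother-cell reporter concentration ratio.

    Mean intensities over the paired masks are background-subtracted and
    clipped at zero. By default the per-pixel mean itself is the
    concentration proxy (intensity per unit projected area); with
    ``volume_mode`` the mask-integrated intensity is divided by the model
    volume from :func:`estimate_volumes`, correcting for the axial depth
    difference between the two cells.
    """
    bg = background.mean if isinstance(background, BackgroundEstimate) else background
    ch = stack.channel(channel)
    fs_mean = max(_masked_mean(ch, pair.forespore.mask) - bg, 0.0)
    mc_mean = max(_masked_mean(ch, pair.mother_cell.mask) - bg, 0.0)
    if volume_mode:
        vols = estimate_volumes(pair, stack.pixel_size)
        px_area = stack.pixel_size**2
        fs_conc = fs_mean * pair.forespore.area * px_area / vols.fs_volume
        mc_conc = mc_mean * pair.mother_cell.area * px_area / vols.mc_volume
    else:
        fs_conc, mc_conc = fs_mean, mc_mean
    ratio = None if mc_conc == 0 else fs_conc / mc_conc
    return RatioMeasurement(
        fs_mean=fs_mean, mc_mean=mc_mean, fs_conc=fs_conc, mc_conc=mc_conc, ratio=ratio
    )


def _nearest_object(
    objects: list[CellObject], centroid, pixel_size: float, max_step_um: float
) -> CellObject | None:
    best, best_d = None, np.inf
    for obj in objects:
        d = np.linalg.norm(
            (np.asarray(obj.centroid) - np.asarray(centroid)) * pixel_size
        )
        if d < best_d:
            best, best_d = obj, d
    return best if best is not None and best_d <= max_step_um else None


def depletion_timecourse(
    frames: list[ImageStack],
    initial_pair: SegmentedSporangium,
    backgrounds: list[BackgroundEstimate | float],
    segment_frame,
    channel: str = "reporter",
    max_step_um: float = DEFAULT_MAX_TRACK_STEP,
) -> DepletionSeries:
    """Track one sporangium through a time-lapse and normalize to frame 0.

    ``segment_frame`` maps an :class:`ImageStack` to a list of
    :class:`SegmentedSporangium`; the initial pair is linked across frames
    by nearest forespore centroid (maximum step ``max_step_um``). Each
    cell's background-subtracted mean series is divided by its own first
    value, so both series start at exactly 1. Losing the track truncates
    the series with a warning.
    """
    if len(frames) < 2:
        raise ValueError("a depletion time course needs at least 2 frames")
    fs_vals, mc_vals, times = [], [], []
    centroid = initial_pair.forespore.centroid
    truncated = False
    for f, (stack, bg) in enumerate(zip(frames, backgrounds)):
        bg_mean = bg.mean if isinstance(bg, BackgroundEstimate) else bg
        pairs = segment_frame(stack) if f > 0 else [initial_pair]
        fs_objs = [p.forespore for p in pairs]
        fs = _nearest_object(fs_objs, centroid, stack.pixel_size, max_step_um)
        if fs is None:
            warnings.warn(
                f"track lost at frame {f}; series truncated", stacklevel=2
            )
            truncated = True
            break
        pair = pairs[[p.forespore for p in pairs].index(fs)]
        centroid = pair.forespore.centroid
        ch = stack.channel(channel)
        fs_vals.append(max(_masked_mean(ch, pair.forespore.mask) - bg_mean, 0.0))
        mc_vals.append(max(_masked_mean(ch, pair.mother_cell.mask) - bg_mean, 0.0))
        t = stack.frame_times[0] if stack.frame_times is not None else float(f)
        times.append(float(t))
    fs_vals = np.asarray(fs_vals)
    mc_vals = np.asarray(mc_vals)
    if fs_vals[0] <= 0 or mc_vals[0] <= 0:
        raise ValueError("initial intensities must be positive to normalize")
    return DepletionSeries(
        frame_times=np.asarray(times),
        fs_norm=fs_vals / fs_vals[0],
        mc_norm=mc_vals / mc_vals[0],
        truncated=truncated,
    )


def boncat_quantify(
    z_sections: list[np.ndarray] | np.ndarray,
    pair: SegmentedSporangium,
    background_mask: np.ndarray,
    reference_medians: dict[str, float],
) -> BoncatMeasurement:
    """BONCAT per-cell synthesis signal from summed optical sections.

    The z-sections (typically eight spanning ~1 um) are sum-projected; each
    cell's mean is corrected by subtracting the background mean plus two
    background SDs, clipped at zero, and divided by the reference median of
    its cell type (an isogenic control strain).
    """
    for cell_type in ("forespore", "mother_cell"):
        if reference_medians.get(cell_type, 0.0) <= 0:
            raise ValueError(f"reference median for {cell_type!r} must be positive")
    sections = np.asarray(z_sections, dtype=float)
    projection = sections.sum(axis=0) if sections.ndim == 3 else sections
    if np.any(background_mask & (pair.forespore.mask | pair.mother_cell.mask)):
        raise ValueError("background region overlaps a cell mask")
    bg_vals = projection[background_mask]
    cutoff = float(bg_vals.mean()) + 2.0 * float(bg_vals.std(ddof=1))
    fs = max(_masked_mean(projection, pair.forespore.mask) - cutoff, 0.0)
    mc = max(_masked_mean(projection, pair.mother_cell.mask) - cutoff, 0.0)
    return BoncatMeasurement(
        fs_value=fs / reference_medians["forespore"],
        mc_value=mc / reference_medians["mother_cell"],
    )


def classify_engulfed(
    stack: ImageStack,
    forespores: list[CellObject],
    diff_threshold: float | None = None,
    dapi_level=("quantile", 0.99),
) -> list[bool]:
    """Engulfment calls from the two-membrane-dye difference image.

    The membrane-impermeant dye cannot reach a fully engulfed forespore's
    membranes, so the (permeant - impermeant) difference image shows only
    engulfed forespore outlines. A forespore is engulfed iff its outline
    signal in the difference image exceeds ``diff_threshold`` (default: half
    the brightest outline signal present) AND no DAPI-positive object
    overlaps its mask (DAPI cannot enter engulfed spores, so any overlap
    marks an unengulfed or lysed cell).
    """
    for needed in ("membrane", "mito", "dapi"):
        if needed not in stack.channels:
            raise ValueError(f"engulfment classification requires channel {needed!r}")
    diff = stack.channel("mito") - stack.channel("membrane")
    dapi = stack.channel("dapi")
    dapi_mask = dapi > resolve_threshold(dapi, dapi_level)
    dapi_labels = measure.label(dapi_mask, connectivity=2)
    flags = []
    outline_signals = []
    for fs in forespores:
        outline = fs.mask & ~ndi.binary_erosion(fs.mask)
        outline_signals.append(float(diff[outline].mean()))
    if diff_threshold is None:
        top = max(outline_signals, default=0.0)
        diff_threshold = top / 2.0
    for fs, signal in zip(forespores, outline_signals):
        has_dapi = bool(np.any(dapi_labels[fs.mask] > 0))
        flags.append(bool(signal > diff_threshold and not has_dapi))
    return flags


def phase_bright_score(
    stack: ImageStack,
    forespores: list[CellObject],
    engulfed_flags: list[bool],
    background_mask: np.ndarray,
    threshold: float = PHASE_BRIGHT_THRESHOLD,
) -> list[PhaseScore]:
    """Phase-bright spore scoring at the 0.1 AU decision boundary.

    Only engulfed forespores are scored; a spore is phase bright iff its
    background-subtracted average phase intensity strictly exceeds the
    threshold (0.1 AU by default — the lowest value above which the
    engulfment-completed wild-type population lies).
    """
    phase = stack.channel("phase")
    if not background_mask.any():
        raise ValueError("empty background mask")
    bg = float(phase[background_mask].mean())
    scores = []
    for fs, engulfed in zip(forespores, engulfed_flags):
        avg = _masked_mean(phase, fs.mask) - bg
        scores.append(
            PhaseScore(
                engulfed=bool(engulfed),
                avg_phase=float(avg),
                bright=bool(engulfed and avg > threshold),
            )
        )
    return scores
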