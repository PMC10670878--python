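"""Seeded, ground-truthed generators emulating the study's raw data.

Three generators stand in for the experimental inputs:

- :func:`generate_sporangium_image` renders fields of sporulating cells in
  five channels (FM 4-64 membrane, GFP reporter, MitoTracker, DAPI,
  phase-contrast). A mother cell is a 2D spherocylinder; its forespore is an
  axis-aligned ellipse at one pole whose membrane outline is brighter than
  the mother cell's (the double membrane formed during engulfment). Fully
  engulfed forespores are invisible to the membrane-impermeant dye but stain
  with the permeant one.
- :func:`generate_photobleach_trace` simulates calcein FRAP/FLIP traces from
  a two-compartment exchange model: amounts flow between forespore and
  mother cell at rate J = k (c_mc - c_fs), with an instantaneous bleach
  after the single prebleach frame and a multiplicative per-acquisition
  photobleaching loss.
- :func:`generate_peptide_table` emits surrogate tryptic peptide records with
  regulon structure (sigma-factor regulons assigning each protein to the
  forespore, the mother cell, or vegetative expression) and per-compartment
  heavy-arginine labeling probabilities.

Every generator returns a :class:`GroundTruth` carrying the exact masks,
concentrations, rates and probabilities used, so estimators can be tested
against known answers. Identical parameters and seed give bit-identical
output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .io import ImageStack, TraceTable, write_label_image

# -- shared rendering constants (AU) -----------------------------------------
DAPI_INTENSITY = 50.0  # nucleoid signal
PHASE_BACKGROUND = 0.02  # phase channel baseline on the normalized AU scale
PHASE_NOISE_SD = 0.005  # phase channel read noise when noise is on


class GenerationError(RuntimeError):
    """Raised when a field cannot be rendered (e.g. colliding sporangia)."""


@dataclass
class SporangiumImageParams:
    """Geometry, intensity and noise parameters for one rendered field.

    Lengths are in micrometres, intensities in arbitrary units (AU).
    ``fs_semiaxes`` is (axial, radial): the axial semi-axis must fit in the
    mother-cell half-length and the radial one inside the cell radius.
    Scalar per-cell parameters broadcast over ``n_sporangia``.
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.065
    n_sporangia: int = 4
    mc_length: float = 2.8
    mc_radius: float = 0.5
    fs_semiaxes: tuple[float, float] = (0.9, 0.4)
    fs_offset: float = 0.45
    membrane_intensity_mc: float = 60.0
    fs_outline_multiplier: float = 2.0
    reporter_conc_fs: float | list = 80.0
    reporter_conc_mc: float | list = 80.0
    phase_intensity_fs: float | list = 0.15
    engulfed: bool | list = False
    background_mean: float = 10.0
    background_sd: float = 0.0
    poisson_noise: bool = False
    seed: int = 0

    def validate(self) -> None:
        a, b = self.fs_semiaxes
        if not (0 < b < self.mc_radius and 0 < a < self.mc_length / 2):
            raise ValueError(
                "forespore semiaxes must fit inside the mother cell: "
                f"need radial<{self.mc_radius} and axial<{self.mc_length / 2}, "
                f"got (axial, radial)={self.fs_semiaxes}"
            )
        if self.fs_outline_multiplier < 1:
            raise ValueError("fs_outline_multiplier must be >= 1")
        if self.mc_length <= 2 * self.mc_radius:
            raise ValueError("mc_length must exceed the cell diameter")
        for name in (
            "membrane_intensity_mc",
            "background_mean",
            "background_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("reporter_conc_fs", "reporter_conc_mc", "phase_intensity_fs"):
            if np.any(np.asarray(getattr(self, name), dtype=float) < 0):
                raise ValueError(f"{name} must be >= 0")
        if self.n_sporangia < 0:
            raise ValueError("n_sporangia must be >= 0")

    def per_cell(self, name: str) -> np.ndarray:
        """Broadcast a scalar-or-sequence field to one value per sporangium."""
        val = np.asarray(getattr(self, name))
        if val.ndim == 0:
            return np.repeat(val[None], self.n_sporangia, axis=0)
        if len(val) != self.n_sporangia:
            raise ValueError(
                f"{name} has {len(val)} entries for {self.n_sporangia} sporangia"
            )
        return val


@dataclass
class PhotobleachParams:
    """Two-compartment calcein exchange and acquisition parameters.

    ``k`` (fL/s) is the exchange coefficient of the intercellular channel:
    the amount flux between compartments is J = k (c_mc - c_fs) where c are
    concentrations (AU/fL). ``acq_loss`` is the fluorescence retained per
    image acquisition (photobleaching by imaging itself). The bleach pulse is
    instantaneous, applied right after the single prebleach frame.
    """

    v_fs: float = 0.6
    v_mc: float = 1.9
    c0: float = 100.0
    k: float = 0.03
    bleach_target: str = "forespore"  # forespore | mother_cell | none
    bleach_efficiency: float = 0.9
    acq_loss: float = 1.0
    frame_interval: float = 3.0
    n_postbleach_frames: int = 30
    n_distal_cells: int = 3
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.v_fs <= 0 or self.v_mc <= 0:
            raise ValueError("compartment volumes must be positive")
        if self.v_fs >= self.v_mc:
            raise ValueError("v_fs must be smaller than v_mc (forespore is smaller)")
        if self.k < 0:
            raise ValueError("exchange coefficient k must be >= 0")
        if self.bleach_target not in {"forespore", "mother_cell", "none"}:
            raise ValueError(f"unknown bleach_target {self.bleach_target!r}")
        if not 0 <= self.bleach_efficiency <= 1:
            raise ValueError("bleach_efficiency must be in [0, 1]")
        if not 0 < self.acq_loss <= 1:
            raise ValueError("acq_loss must be in (0, 1]")
        if self.n_postbleach_frames < 1:
            raise ValueError("need at least one postbleach frame")
        if self.n_distal_cells < 3:
            raise ValueError("need >= 3 distal cells for the standard curve")

    @property
    def rate(self) -> float:
        """Concentration-difference decay rate k (1/v_fs + 1/v_mc), 1/s."""
        return self.k * (1.0 / self.v_fs + 1.0 / self.v_mc)


#: per-compartment heavy-arginine labeling probabilities for the three
#: transporter-expression scenarios: a control strain lacking arginine
#: transporters (background incorporation only), mother-cell transporter
#: expression (strong uptake, trafficked onward to the forespore), and
#: forespore transporter expression (a modest pre-engulfment window).
SCENARIO_P_HEAVY = {
    "control": {"mother_cell": 0.12, "forespore": 0.12, "background": 0.12},
    "mc_transporter": {"mother_cell": 0.30, "forespore": 0.30, "background": 0.12},
    "fs_transporter": {"mother_cell": 0.15, "forespore": 0.162, "background": 0.12},
}

#: regulon names by expression class
VEGETATIVE_REGULONS = ("SigA", "SigH", "Spo0A")
FS_REGULONS = ("SigF", "SigG")
MC_REGULONS = ("SigE", "SigK")


@dataclass
class PeptideTableParams:
    """Composition of a surrogate cell-specific SILAC peptide table.

    ``n_proteins`` gives protein counts per regulon class; defaults are sized
    so a run yields a few thousand arginine-containing sporulation-specific
    peptides, the scale of a real experiment. Distribution specs are
    ``("poisson", mean, minimum)`` or a fixed integer.
    """

    n_proteins: dict = field(
        default_factory=lambda: {
            "sigF": 50,
            "sigG": 100,
            "sigE": 250,
            "sigK": 100,
            "vegetative": 300,
        }
    )
    peptides_per_protein: tuple | int = ("poisson", 12, 1)
    arg_per_peptide: tuple | int = ("poisson", 0.9, 0)
    scenario: str = "control"
    p_heavy: dict | None = None  # overrides the scenario preset when given
    dual_vegetative_fraction: float = 0.05
    dual_celltype_fraction: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.scenario not in SCENARIO_P_HEAVY:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        for key, p in self.effective_p_heavy().items():
            if not 0 <= p <= 1:
                raise ValueError(f"p_heavy[{key!r}]={p} outside [0, 1]")
        for frac in (self.dual_vegetative_fraction, self.dual_celltype_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("dual-membership fractions must be in [0, 1]")
        for cls, n in self.n_proteins.items():
            if n < 0:
                raise ValueError(f"negative protein count for {cls}")

    def effective_p_heavy(self) -> dict:
        probs = dict(SCENARIO_P_HEAVY[self.scenario])
        if self.p_heavy:
            probs.update(self.p_heavy)
        return probs


@dataclass
class GroundTruth:
    """Generator-side truth emitted alongside every synthetic dataset."""

    # imaging truth
    fs_labels: np.ndarray | None = None
    mc_labels: np.ndarray | None = None
    whole_labels: np.ndarray | None = None
    centers_px: list | None = None
    orientations_deg: list | None = None
    true_concentrations: dict | None = None  # {"fs": [...], "mc": [...]}
    true_ratio: list | None = None
    true_engulfed: list | None = None
    # time-lapse truth
    true_ratio_series: np.ndarray | None = None
    true_fs_series: np.ndarray | None = None
    true_mc_series: np.ndarray | None = None
    # photobleach truth
    true_k: float | None = None
    true_rate: float | None = None
    volumes: dict | None = None
    acq_loss: float | None = None
    true_conc_fs: np.ndarray | None = None
    true_conc_mc: np.ndarray | None = None
    # peptide truth
    true_label_probs: dict | None = None
    protein_compartments: dict | None = None
    regulon_map: pd.DataFrame | None = None

    def save(self, directory: str | Path) -> None:
        """Serialize to JSON (+ label TIFFs / regulon TSV where present)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        scalars: dict = {}
        for name, value in asdict(self).items():
            if value is None:
                continue
            if name in {"fs_labels", "mc_labels", "whole_labels"}:
                write_label_image(directory / f"{name}.tif", getattr(self, name))
                scalars[name] = f"{name}.tif"
            elif name == "regulon_map":
                self.regulon_map.to_csv(
                    directory / "regulon_map.tsv", sep="\t", index=False
                )
                scalars[name] = "regulon_map.tsv"
            elif isinstance(value, np.ndarray):
                scalars[name] = value.tolist()
            else:
                scalars[name] = value
        (directory / "ground_truth.json").write_text(
            json.dumps(scalars, indent=2, default=_jsonable)
        )


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# sporangium image rendering
# ---------------------------------------------------------------------------


def _sporangium_masks(shape, pixel_size, center_px, theta_deg, params):
    """Boolean whole-cell and forespore masks for one sporangium.

    The mother cell is the set of pixels within ``mc_radius`` of the axis
    segment (a 2D spherocylinder); the forespore an ellipse centred
    ``fs_offset`` um from midcell along the axis.
    """
    rows, cols = shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    y = (rr - center_px[0]) * pixel_size
    x = (cc - center_px[1]) * pixel_size
    th = np.deg2rad(theta_deg)
    u = x * np.cos(th) + y * np.sin(th)  # along the cell axis, um
    v = -x * np.sin(th) + y * np.cos(th)
    half = params.mc_length / 2 - params.mc_radius  # axis segment half-length
    du = np.clip(u, -half, half)
    whole = np.hypot(u - du, v) <= params.mc_radius
    a, b = params.fs_semiaxes
    fs = ((u - params.fs_offset) / a) ** 2 + (v / b) ** 2 <= 1.0
    fs &= whole
    return whole, fs


def _outline(mask: np.ndarray) -> np.ndarray:
    """One-pixel inner outline of a boolean mask."""
    return mask & ~ndi.binary_erosion(mask)


def _place_sporangia(params: SporangiumImageParams, rng) -> tuple[list, list]:
    """Choose non-overlapping centres/orientations; error on packing failure."""
    shape = params.image_shape
    margin = (params.mc_length / 2 + params.mc_radius) / params.pixel_size + 2
    if 2 * margin >= min(shape):
        raise GenerationError(
            f"image {shape} too small for sporangia of length {params.mc_length} um"
        )
    occupancy = np.zeros(shape, dtype=int)  # 0 = free, else sporangium index+1
    centers, angles = [], []
    for i in range(params.n_sporangia):
        placed = False
        colliders: set[int] = set()
        for _ in range(200):
            r0 = rng.uniform(margin, shape[0] - margin)
            c0 = rng.uniform(margin, shape[1] - margin)
            theta = rng.uniform(0.0, 180.0)
            whole, _ = _sporangium_masks(
                shape, params.pixel_size, (r0, c0), theta, params
            )
            footprint = ndi.binary_dilation(whole, iterations=2)
            hits = occupancy[footprint]
            if np.any(hits):
                colliders.update(int(h) - 1 for h in np.unique(hits) if h)
                continue
            occupancy[footprint] = i + 1
            centers.append((r0, c0))
            angles.append(theta)
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"could not place sporangium {i} without overlap; "
                f"colliding with indices {sorted(colliders)}"
            )
    return centers, angles


def _apply_noise(expectation: np.ndarray, params, rng, phase: bool = False):
    """Poisson shot noise on expected counts plus Gaussian read noise."""
    img = expectation
    if phase:
        if params.background_sd > 0 or params.poisson_noise:
            img = img + rng.normal(0.0, PHASE_NOISE_SD, size=img.shape)
        return np.clip(img, 0.0, None)
    if params.poisson_noise:
        img = rng.poisson(img).astype(float)
    if params.background_sd > 0:
        img = img + rng.normal(0.0, params.background_sd, size=img.shape)
    return np.clip(img, 0.0, None)


def _render_field(params, centers, angles, rng):
    """Render the five channels and truth labels for fixed placements."""
    shape = params.image_shape
    conc_fs = params.per_cell("reporter_conc_fs").astype(float)
    conc_mc = params.per_cell("reporter_conc_mc").astype(float)
    phase_fs = params.per_cell("phase_intensity_fs").astype(float)
    engulfed = params.per_cell("engulfed").astype(bool)

    membrane = np.full(shape, params.background_mean, dtype=float)
    reporter = np.full(shape, params.background_mean, dtype=float)
    mito = np.full(shape, params.background_mean, dtype=float)
    dapi = np.full(shape, params.background_mean, dtype=float)
    phase = np.full(shape, PHASE_BACKGROUND, dtype=float)
    fs_labels = np.zeros(shape, dtype=int)
    mc_labels = np.zeros(shape, dtype=int)
    whole_labels = np.zeros(shape, dtype=int)

    for i, (center, theta) in enumerate(zip(centers, angles)):
        whole, fs = _sporangium_masks(shape, params.pixel_size, center, theta, params)
        mc_interior = whole & ~ndi.binary_dilation(fs)
        wall = _outline(whole)
        fs_wall = _outline(fs)
        membrane[wall] += params.membrane_intensity_mc
        mito[wall] += params.membrane_intensity_mc
        boost = params.membrane_intensity_mc * params.fs_outline_multiplier
        mito[fs_wall] += boost
        if not engulfed[i]:
            # double membrane around the forespore stains with the
            # impermeant dye only while it is still accessible from outside
            membrane[fs_wall] += boost
            dapi[fs] += DAPI_INTENSITY
        reporter[fs] += conc_fs[i]
        reporter[mc_interior] += conc_mc[i]
        dapi[mc_interior] += DAPI_INTENSITY
        phase[fs] += phase_fs[i]
        fs_labels[fs] = i + 1
        mc_labels[mc_interior] = i + 1
        whole_labels[whole] = i + 1

    channels = {
        "membrane": _apply_noise(membrane, params, rng),
        "reporter": _apply_noise(reporter, params, rng),
        "mito": _apply_noise(mito, params, rng),
        "dapi": _apply_noise(dapi, params, rng),
        "phase": _apply_noise(phase, params, rng, phase=True),
    }
    stack = ImageStack(channels=channels, pixel_size=params.pixel_size)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(conc_mc > 0, conc_fs / conc_mc, np.nan)
    truth = GroundTruth(
        fs_labels=fs_labels,
        mc_labels=mc_labels,
        whole_labels=whole_labels,
        centers_px=[list(c) for c in centers],
        orientations_deg=list(angles),
        true_concentrations={"fs": conc_fs.tolist(), "mc": conc_mc.tolist()},
        true_ratio=ratio.tolist(),
        true_engulfed=engulfed.tolist(),
    )
    return stack, truth


def generate_sporangium_image(
    params: SporangiumImageParams,
) -> tuple[ImageStack, GroundTruth]:
    """Render one field of sporangia with exact ground-truth masks.

    Returns the five-channel :class:`~sporoquant.io.ImageStack` and a
    :class:`GroundTruth` whose label images match the rendered geometry
    pixel-for-pixel.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    centers, angles = _place_sporangia(params, rng)
    return _render_field(params, centers, angles, rng)


def generate_timelapse(
    params: SporangiumImageParams,
    depletion_rate: float,
    n_frames: int,
    frame_interval_min: float = 5.0,
) -> tuple[list[ImageStack], GroundTruth]:
    """Render a time-lapse where the forespore reporter depletes geometrically.

    Frame f has forespore reporter expectation
    ``reporter_conc_fs * (1 - depletion_rate) ** f`` while the mother-cell
    expectation stays constant — the pattern of a metabolic enzyme that is
    degraded specifically in the forespore.
    """
    params.validate()
    if not 0.0 <= depletion_rate <= 1.0:
        raise ValueError("depletion_rate must be in [0, 1]")
    if n_frames < 2:
        raise ValueError("a time-lapse needs at least 2 frames")
    rng = np.random.default_rng(params.seed)
    centers, angles = _place_sporangia(params, rng)
    conc_fs0 = params.per_cell("reporter_conc_fs").astype(float)
    conc_mc = params.per_cell("reporter_conc_mc").astype(float)
    frames: list[ImageStack] = []
    fs_series = np.empty((n_frames, params.n_sporangia))
    truth0 = None
    for f in range(n_frames):
        conc_f = conc_fs0 * (1.0 - depletion_rate) ** f
        fs_series[f] = conc_f
        frame_params = SporangiumImageParams(**{**asdict(params)})
        frame_params.reporter_conc_fs = conc_f.tolist()
        stack, truth = _render_field(frame_params, centers, angles, rng)
        stack.frame_times = np.array([f * frame_interval_min * 60.0])
        frames.append(stack)
        if truth0 is None:
            truth0 = truth
    mc_series = np.tile(conc_mc, (n_frames, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_series = np.where(mc_series > 0, fs_series / mc_series, np.nan)
    truth0.true_fs_series = fs_series
    truth0.true_mc_series = mc_series
    truth0.true_ratio_series = ratio_series
    return frames, truth0


# ---------------------------------------------------------------------------
# two-compartment photobleaching traces
# ---------------------------------------------------------------------------


def exchange_difference_closed_form(delta0, k, v_fs, v_mc, t):
    """Closed form of the concentration difference under linear exchange.

    With amounts A obeying dA_fs/dt = k (c_mc - c_fs) = -dA_mc/dt, the
    difference Delta = c_fs - c_mc decays as
    Delta(t) = Delta0 exp(-k (1/v_fs + 1/v_mc) t) while total amount is
    conserved.
    """
    rate = k * (1.0 / v_fs + 1.0 / v_mc)
    return delta0 * np.exp(-rate * np.asarray(t, dtype=float))


def _exchange_step(c_fs, c_mc, k, v_fs, v_mc, dt):
    """Exact update of the linear two-compartment system over dt."""
    total = v_fs * c_fs + v_mc * c_mc
    vtot = v_fs + v_mc
    delta = (c_fs - c_mc) * np.exp(-k * (1.0 / v_fs + 1.0 / v_mc) * dt)
    c_fs_new = (total + v_mc * delta) / vtot
    c_mc_new = (total - v_fs * delta) / vtot
    return c_fs_new, c_mc_new


def euler_exchange_oracle(c_fs0, c_mc0, k, v_fs, v_mc, t_end, n_steps=200_000):
    """Fine-step explicit-Euler integration of the exchange ODE (testing aid).

    Deliberately independent of :func:`_exchange_step`; used to validate the
    exact per-frame update.
    """
    dt = t_end / n_steps
    c_fs, c_mc = float(c_fs0), float(c_mc0)
    for _ in range(n_steps):
        flux = k * (c_mc - c_fs)
        c_fs += flux / v_fs * dt
        c_mc -= flux / v_mc * dt
    return c_fs, c_mc


def generate_photobleach_trace(
    params: PhotobleachParams,
) -> tuple[TraceTable, GroundTruth]:
    """Simulate a FRAP/FLIP experiment on one sporangium.

    The trace table carries roles ``bleached_fs``, ``bleached_mc``, a
    ``reference_cell`` (an unbleached sporangium, whole-cell intensity) and
    ``distal_<i>`` cells affected only by acquisition loss. Frame 0 is the
    single prebleach frame; the bleach is applied instantaneously before
    frame 1 (t = 0), after which concentrations relax by intercellular
    exchange between acquisitions. Each acquisition multiplies all remaining
    fluorophore by ``acq_loss`` (photodestruction by imaging).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n_frames = params.n_postbleach_frames + 1
    dt = params.frame_interval
    frame_times = np.concatenate([[-dt], np.arange(params.n_postbleach_frames) * dt])

    c_fs = c_mc = params.c0
    c_ref = params.c0  # unbleached reference sporangium (well-mixed pair)
    c_distal = np.full(params.n_distal_cells, params.c0)

    fs = np.empty(n_frames)
    mc = np.empty(n_frames)
    ref = np.empty(n_frames)
    distal = np.empty((params.n_distal_cells, n_frames))
    for i in range(n_frames):
        fs[i], mc[i], ref[i] = c_fs, c_mc, c_ref
        distal[:, i] = c_distal
        # acquisition photobleaching: every imaged cell loses fluorophore
        c_fs *= params.acq_loss
        c_mc *= params.acq_loss
        c_ref *= params.acq_loss
        c_distal = c_distal * params.acq_loss
        if i == 0:
            if params.bleach_target == "forespore":
                c_fs *= 1.0 - params.bleach_efficiency
            elif params.bleach_target == "mother_cell":
                c_mc *= 1.0 - params.bleach_efficiency
        else:
            c_fs, c_mc = _exchange_step(
                c_fs, c_mc, params.k, params.v_fs, params.v_mc, dt
            )

    roles = {"bleached_fs": fs, "bleached_mc": mc, "reference_cell": ref}
    for j in range(params.n_distal_cells):
        roles[f"distal_{j}"] = distal[j]
    if params.noise_sd > 0:
        for role in roles:
            roles[role] = roles[role] + rng.normal(
                0.0, params.noise_sd, size=n_frames
            )
    trace = TraceTable(frame_times=frame_times, roles=roles, bleach_frame_index=1)
    truth = GroundTruth(
        true_k=params.k,
        true_rate=params.rate,
        volumes={"v_fs": params.v_fs, "v_mc": params.v_mc},
        acq_loss=params.acq_loss,
        true_conc_fs=fs,
        true_conc_mc=mc,
    )
    return trace, truth


# ---------------------------------------------------------------------------
# surrogate SILAC peptide tables
# ---------------------------------------------------------------------------

_REGULON_CLASS = {
    "sigF": "SigF",
    "sigG": "SigG",
    "sigE": "SigE",
    "sigK": "SigK",
}
_NON_KR = list("ACDEFGHILMNPQSTVWY")


def _draw_counts(spec, n, rng) -> np.ndarray:
    if isinstance(spec, (int, np.integer)):
        return np.full(n, int(spec), dtype=int)
    kind, mean, minimum = spec
    if kind != "poisson":
        raise ValueError(f"unknown distribution spec {spec!r}")
    return np.maximum(rng.poisson(mean, size=n), int(minimum)).astype(int)


def _surrogate_sequences(arg_counts: np.ndarray, rng) -> list[str]:
    """Plausible tryptic peptide strings with exact arginine counts.

    Random non-K/R body, then the declared arginines and a tryptic C-terminal
    R (or K for arginine-free peptides).
    """
    n = len(arg_counts)
    body_len = np.maximum(rng.integers(7, 20, size=n) - arg_counts, 3)
    offsets = np.concatenate([[0], np.cumsum(body_len)])
    flat = rng.choice(_NON_KR, size=int(offsets[-1]))
    return [
        "".join(flat[offsets[i] : offsets[i + 1]])
        + ("R" * int(c) if c > 0 else "K")
        for i, c in enumerate(arg_counts)
    ]


def _compartment_of(regulons: set[str]) -> str:
    """Same precedence the analysis applies: vegetative > cell-specific."""
    if set(regulons) & set(VEGETATIVE_REGULONS):
        return "vegetative"
    is_fs = bool(set(regulons) & set(FS_REGULONS))
    is_mc = bool(set(regulons) & set(MC_REGULONS))
    if is_fs and is_mc:
        return "ambiguous"
    if is_fs:
        return "forespore"
    if is_mc:
        return "mother_cell"
    return "unknown"


def generate_peptide_table(
    params: PeptideTableParams,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Emit a surrogate peptide-level MS export with regulon structure.

    Each protein belongs to one primary regulon; small fractions carry dual
    membership (an extra vegetative regulon, or a second cell type) to
    exercise the classification rules. A peptide is heavy when it has at
    least one arginine and a Bernoulli draw at its compartment's labeling
    probability succeeds; vegetative, ambiguous and unknown compartments
    label at the background probability.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    probs = params.effective_p_heavy()

    proteins: list[dict] = []
    for cls, n in sorted(params.n_proteins.items()):
        for j in range(n):
            pid = f"{cls.upper()}_{j:04d}"
            if cls == "vegetative":
                regs = {str(rng.choice(VEGETATIVE_REGULONS))}
            else:
                regs = {_REGULON_CLASS[cls]}
                if rng.random() < params.dual_vegetative_fraction:
                    regs.add(str(rng.choice(VEGETATIVE_REGULONS)))
                elif rng.random() < params.dual_celltype_fraction:
                    other = MC_REGULONS if cls in ("sigF", "sigG") else FS_REGULONS
                    regs.add(str(rng.choice(other)))
            proteins.append({"protein_id": pid, "regulons": sorted(regs)})

    compartments = np.array(
        [_compartment_of(set(p["regulons"])) for p in proteins]
    )
    p_by_protein = np.array(
        [probs.get(c, probs["background"]) for c in compartments]
    )
    n_peps = _draw_counts(params.peptides_per_protein, len(proteins), rng)
    protein_idx = np.repeat(np.arange(len(proteins)), n_peps)
    total = len(protein_idx)
    arg = _draw_counts(params.arg_per_peptide, total, rng)
    heavy = (arg >= 1) & (rng.random(total) < p_by_protein[protein_idx])
    table = pd.DataFrame(
        {
            "peptide_id": [f"PEP{i:06d}" for i in range(total)],
            "sequence": _surrogate_sequences(arg, rng),
            "protein_id": [proteins[i]["protein_id"] for i in protein_idx],
            "arg_count": arg,
            "heavy": heavy,
            "intensity": np.round(rng.lognormal(10.0, 1.0, size=total), 1),
        }
    )
    regulon_map = pd.DataFrame(
        {
            "protein_id": [p["protein_id"] for p in proteins],
            "regulons": [",".join(p["regulons"]) for p in proteins],
        }
    )
    truth = GroundTruth(
        true_label_probs=probs,
        protein_compartments={
            p["protein_id"]: _compartment_of(set(p["regulons"])) for p in proteins
        },
        regulon_map=regulon_map,
    )
    return table, truth
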