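# Methods

`sporoquant` quantifies sporulation experiments in *Bacillus subtilis*, where
an asymmetric division produces a sporangium: a small forespore (FS) nurtured
inside a larger mother cell (MC). The package implements the measurement side
of five assays — fluorescence ratiometry, reporter-depletion time courses,
BONCAT protein-synthesis imaging, FRAP/FLIP photobleaching of calcein, and
cell-specific SILAC proteomics — together with seeded synthetic-data
generators that emit exact ground truth, so every estimator is validated
against known answers.

## Synthetic data generators

### Sporangium images

A mother cell is rendered as a 2D spherocylinder (all pixels within radius
*r* of an axis segment of length *L* − 2*r*), the forespore as an
axis-aligned ellipse with semi-axes (*a*, *b*) placed `fs_offset` µm from
midcell toward a pole. Membrane outlines are one-pixel inner boundaries of
these regions; the forespore outline is brighter by `fs_outline_multiplier`
(default 2), standing in for the double membrane laid down during
engulfment. Five channels are rendered: an impermeant membrane dye (which
does not show engulfed forespores), a cytoplasmic reporter, a permeant
membrane dye (which shows all outlines), DAPI (absent from engulfed
forespores), and phase contrast (forespore interior only, on a normalized
0–~0.3 AU scale). Ground-truth label images match the rendered geometry
pixel-for-pixel.

Defaults emulate a typical epifluorescence configuration: 0.065 µm/px,
*L* = 2.8 µm, *r* = 0.5 µm, (*a*, *b*) = (0.9, 0.4) µm, background 10 AU,
membrane 60 AU, reporter ~80 AU. Noise is optional Poisson shot noise on
expected counts followed by additive Gaussian read noise (`background_sd`);
the phase channel instead gets a small fixed Gaussian term, since its scale
is arbitrary-unit, not photon-count. Placement is rejection sampling with a
two-pixel clearance; irreducible collisions raise an error naming the
offending indices.

What the generator does **not** emulate: the point-spread function and
optical sectioning, deconvolution artifacts, uneven illumination, cell
crowding/touching, septation intermediates, and intensity variation within
a cell. Passing tests therefore demonstrate correctness of the measurement
arithmetic and the segmentation logic under the stated image model, not
performance on raw micrographs.

### Two-compartment photobleaching traces

Calcein exchange between the compartments is modelled as a linear
two-compartment system: with amounts *A* and concentrations *c* = *A*/*V*,

    dA_fs/dt = k (c_mc − c_fs) = −dA_mc/dt,

so the concentration difference Δ = c_fs − c_mc decays exponentially at

    rate = k (1/v_fs + 1/v_mc)

while total amount is conserved. The simulator uses this closed form as an
exact per-frame update (the system is linear; no step-size error); an
explicit-Euler integrator is retained in the package purely as an
independent test oracle. The bleach is an instantaneous multiplicative
reduction of the target compartment's amount applied right after the single
prebleach frame — justified because the 0.1 s bleach pulse is short against
the 3 s frame interval. Acquisition photobleaching multiplies every imaged
cell's fluorophore by `acq_loss` at each acquisition, after the frame is
recorded. Traces are emitted for the bleached sporangium's two compartments,
one unbleached reference sporangium, and ≥3 distal cells experiencing only
acquisition loss; Gaussian noise of `noise_sd` is added to recorded values.

Default volumes v_fs = 0.6 fL and v_mc = 1.9 fL are the prolate-spheroid and
spherocylinder volumes of the default image geometry, keeping the imaging
and trace simulators mutually consistent. Default timing is one prebleach
frame plus 30 postbleach frames at 3 s.

### SILAC peptide tables

Surrogate proteins are drawn per regulon class (defaults: 50 SigF, 100 SigG,
250 SigE, 100 SigK, 300 vegetative — sized so a run yields >3000
arginine-containing sporulation-specific peptides, the scale of the real
experiment). Small fractions of sporulation proteins carry dual regulon
memberships (5% an extra vegetative regulon, 2% a second cell type) to
exercise the precedence rules. Peptide counts per protein and arginine
counts per peptide are Poisson (means 12 and 0.9; the latter gives ~59%
arginine-containing, close to tryptic expectations). A peptide is heavy when
it contains ≥1 arginine and a Bernoulli draw at its compartment's labeling
probability succeeds. Scenario presets are the study conditions:

| scenario        | p(MC) | p(FS) | p(vegetative) |
|-----------------|-------|-------|---------------|
| control         | 0.12  | 0.12  | 0.12          |
| mc_transporter  | 0.30  | 0.30  | 0.12          |
| fs_transporter  | 0.15  | 0.162 | 0.12          |

0.12 is the background incorporation of a transporter-less control strain;
the mother-cell transporter scenario raises both compartments 2.5-fold
(imported arginine is trafficked onward into forespore proteins); the
forespore transporter scenario gives only a 1.35-fold rise in the forespore
(a short pre-engulfment import window) and a modest 1.25-fold rise in the
mother cell. Sequences are surrogates — random non-K/R bodies with the
declared arginines and a tryptic C-terminus — not in-silico digests.

## Segmentation

Forespores are connected components (8-connectivity) of the membrane channel
above a high threshold, whole cells above a low threshold, both hole-filled
and filtered at `min_area` (default 20 px²). Mother cells are whole cells
minus forespores dilated by 1 px (shared outline pixels must not count as
mother-cell signal); the largest remainder piece is kept, empty remainders
drop the cell. Thresholds may be given as image quantiles (defaults 0.995
and 0.95), absolute intensities, or derived from the membrane histogram
(`auto_thresholds`: background median plus 25% / 60% of the dynamic range,
splitting background vs single vs double membrane).

Pairing is deliberately strict — precision over recall: a candidate pair
must have centroid distance ≤ 3 µm and the angle between the mother cell's
major axis (leading principal component of its pixel coordinates) and the
centroid-to-centroid vector ≤ 30°. Candidates are matched greedily, one to
one, ordered by (distance, angle, forespore label, mother label), so exact
ties break toward the smaller angle and then the smaller label. Unmatched
objects are reported, never force-paired.

## Cytometry

- **Concentration ratio**: background-subtracted per-pixel means over the
  paired masks, clipped at zero; ratio = FS/MC, flagged undefined (not NaN)
  when the MC concentration is 0. The per-pixel mean is the default
  concentration proxy; `volume_mode` instead divides mask-integrated
  intensity by model volumes (spherocylinder V = πr²(L−2r) + 4/3πr³ with the
  rod radius taken from the mask's distance transform, robust to the bite
  the forespore subtraction leaves; prolate spheroid V = 4/3πab² from mask
  moments). Both modes ship because "volume-normalized" admits either
  reading; per-pixel mean is the default and is what the recovery studies
  validate.
- **Background**: mean ± SD over the complement of the dilated low-threshold
  cell mask.
- **Depletion time courses**: nearest-centroid tracking (max step 1 µm/frame,
  lost tracks truncate with a warning); each cell's background-subtracted
  mean series divided by its own first value, so both series start at
  exactly 1.
- **BONCAT**: optical sections are sum-projected; per-cell mean minus
  (background mean + 2 SD), clipped at zero, divided by the cell-type
  reference median from an isogenic control strain. The reference median is
  a required input, not estimated in-package.
- **Engulfment**: a forespore is engulfed iff its outline signal in the
  (permeant − impermeant) dye difference image exceeds a threshold (default:
  half the brightest outline present) and no DAPI-positive object overlaps
  its mask. Any overlap excludes — the fractional-overlap alternative is not
  used, since partial DAPI intrusion already falsifies engulfment.
- **Phase-bright**: only engulfed forespores are scored; bright iff the
  background-subtracted average phase intensity **strictly exceeds**
  0.1 AU. The boundary is exclusive because the threshold is defined as the
  lowest value *above which* the engulfment-completed population lies.

## Photobleaching analysis

- **cFR**: r(t) = bleached/reference intensity per frame (the reference is
  the nearest unbleached sporangium's whole-cell intensity, which also
  cancels acquisition loss); cFR = (r − r_b)/(r_0 − r_b) with r_0 the
  prebleach and r_b the first-postbleach ratio, making the anchors exact by
  construction. Traces with r_0 = r_b (no detectable bleach) are rejected
  with a diagnostic. Time is measured from the first postbleach frame.
- **Recovery plateau**: under the model above, a bleached forespore recovers
  to cFR(∞) = v_mc/(v_fs + v_mc), *not* 1 — the bleached molecules are gone,
  so both compartments equilibrate below the prebleach concentration, and
  the deficit is independent of bleach efficiency. The package's closed form
  cFR(t) = (v_mc/(v_fs+v_mc))(1 − e^(−rate·t)) is verified against the Euler
  oracle; the classic 1 − e^(−rate·t) is its v_fs ≪ v_mc limit.
- **Exchange-rate fit**: the default fit holds the plateau at its model
  value and treats the cFR normalization honestly as a noise source: both
  anchors come from single frames, so their noise enters every postbleach
  point as a common-mode scale error (via 1/(r_0 − r_b)) and a common-mode
  offset (via −r_b). The model y = s·m(rate) + o + η with ridge priors
  s ~ N(1, 2σ²), o ~ N(0, σ²) in per-frame-noise units (the 2 because the
  scale error combines two anchor frames) is profiled over (s, o) in closed
  form and minimized over rate ∈ [10⁻⁶, 10] s⁻¹ on a log scale. With
  noise-free data the priors are inactive and the exact rate is recovered;
  under SNR ≈ 10 the median bias stays below 10% for k up to 0.1 fL/s,
  where a plain fixed-plateau fit is biased upward by the anchor noise and
  a free-plateau fit loses the slow-exchange regime to rate–plateau
  confounding. A plain free-plateau nonlinear least squares remains
  available (`plateau="free"`). k̂ = ratê / (1/v_fs + 1/v_mc).
- **Acquisition-loss standard curve**: per-frame empirical mean of distal
  traces normalized to their prebleach values (an exponential fit is an
  optional view, not the correction); FLIP series are divided by the
  retention factors, then the forespore is normalized to prebleach = 1 and
  the mother cell rescaled to prebleach = 1, first-postbleach = 0. The
  forespore is never forced to 0 — its loss is the measured transport
  signal.
- **Averaging**: pointwise mean ± SD on a shared time grid; mismatched grids
  are an error (no resampling).

## SILAC analysis

Compartment assignment is deterministic: membership in SigA, SigH or Spo0A
regulons ⇒ vegetative (takes precedence — such proteins predate the
asymmetric division, so their labeling cannot witness compartment-specific
import); otherwise SigF/SigG ⇒ forespore, SigE/SigK ⇒ mother cell; both
cell types ⇒ ambiguous (excluded — misassignment would bias transport
inference); no known regulon ⇒ unknown. Arginine-free peptides are removed
first; the filter report accounts for every input row, and the partition is
property-tested. Incorporation fractions carry Wilson 95% intervals (robust
at small n and extreme fractions); forespore peptides are additionally
stratified by SigF (made during engulfment) vs SigG (after completion), and
mother-cell peptides by SigE vs SigK. Fold-changes over a control are
fraction ratios with a conservative interval from the crossed Wilson bounds;
a zero control fraction leaves the fold undefined and flagged. Peptides are
taken as given — no re-digestion, razor-peptide resolution, or FDR control —
and a peptide is "heavy" iff the search export flags ≥1 labeled arginine.

Ordering note: the arginine filter is applied before the compartment filter;
the reported totals reflect that order (fractions are unaffected).

## Pipeline plumbing

The CLI wraps the library one-to-one; YAML configs are validated before any
stage runs (bad configs exit nonzero with nothing written), and every run
emits a JSON manifest with the tool version, a config hash, input file
hashes, seeds and per-stage record counts, sufficient to reproduce outputs
bit-for-bit. Config validation is a hand-rolled schema check with named
errors rather than a JSON-schema engine dependency.

## Problem sizes and numerical choices

Validation studies run at: 50 replicates per noise condition for rate and
ratio recovery (SNR ≈ 10; Poisson + Gaussian read noise for images,
σ = c₀/10 for traces), 200 runs for interval calibration (~3300
compartment-specific arginine peptides each), 20 random layouts × 3
sporangia for segmentation recovery, and 25 bisection steps for the
phase-bright boundary. Images are 256×256 px. All randomness flows from one
integer seed per generator call via `numpy.random.default_rng`; identical
parameters and seed give bit-identical outputs.

Degenerate inputs are defined errors, not silent NaNs: empty masks,
nonpositive volumes or reference medians, missing channels, all-excluded
distal traces, and undetectable bleaches all raise with messages naming the
offending quantity. Negative background-corrected intensities clip to zero
before ratios (concentrations are nonnegative).

## Known limitations

- The image model is 2D and noise-level-calibrated, not PSF-realistic;
  segmentation accuracy on real micrographs will be lower than the 100%
  recovery the clean synthetic study shows.
- Time-lapse tracking is nearest-centroid linking, adequate for agarose-pad
  fields but not for motile or dense samples.
- Compartments in the exchange model are well-mixed; intra-compartment
  diffusion gradients are not modelled.
- Volume-mode concentrations inherit the spherocylinder/spheroid idealization
  and the 2D projection mismatch; the per-pixel-mean default is the
  validated estimator.
- SILAC fractions treat peptides as independent Bernoulli trials; within-
  protein correlation of labeling is not modelled, and the Wilson intervals
  are calibrated only under that assumption.
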