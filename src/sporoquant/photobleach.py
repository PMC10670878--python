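"""FRAP/FLIP photobleaching analysis and intercellular exchange fitting.

A FRAP experiment bleaches the forespore's calcein and watches it recover by
influx from the mother cell; a FLIP experiment bleaches the mother cell and
watches the forespore's signal drain. Both report transport through the
intercellular (A-Q) channel. The analyses here:

- corrected fluorescence recovery (cFR): the bleached/unbleached intensity
  ratio rescaled so the prebleach frame is exactly 1 and the first
  postbleach frame exactly 0;
- an acquisition-bleaching standard curve from cells distal to the bleach,
  correcting for fluorophore destroyed by imaging itself;
- corrected, normalized FLIP series (prebleach = 1 for both cells,
  mother-cell first-postbleach = 0, forespore left free — its loss is the
  measured signal);
- replicate averaging (pointwise mean +/- SD);
- exchange-rate estimation. Under the well-mixed two-compartment model with
  exchange flux J = k (c_mc - c_fs), the concentration difference decays at
  rate = k (1/v_fs + 1/v_mc) and the cFR of a bleached forespore follows
  cFR(t) = (v_mc / (v_fs + v_mc)) (1 - exp(-rate t)): recovery plateaus
  below 1 because the bleached molecules are permanently lost and both
  compartments equilibrate to a lower shared concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .io import TraceTable

RATE_BOUND = 10.0  # 1/s, upper bound of the exchange-rate fit


@dataclass
class CfrSeries:
    """Corrected fluorescence recovery over the postbleach frames.

    ``frame_times`` start at 0 at the first postbleach frame. The prebleach
    anchor (cFR = 1) is stored separately from the postbleach series, whose
    first element is exactly 0 by construction.
    """

    frame_times: np.ndarray
    cfr: np.ndarray
    r0: float  # prebleach bleached/unbleached ratio
    rb: float  # first-postbleach ratio

    @property
    def prebleach_cfr(self) -> float:
        return 1.0


@dataclass
class AcquisitionLossCurve:
    """Per-frame fluorescence retention fitted from distal cells."""

    factors: np.ndarray  # one per frame; factors[0] (prebleach) == 1
    n_cells: int

    def exponential_fit(self) -> float:
        """Per-frame retention of the best-fit exponential (optional view)."""
        n = np.arange(len(self.factors))
        pos = self.factors > 0
        slope = np.polyfit(n[pos], np.log(self.factors[pos]), 1)[0]
        return float(np.exp(slope))


@dataclass
class FlipSeries:
    """Acquisition-corrected, anchor-normalized fluorescence-loss series."""

    frame_times: np.ndarray  # all frames, prebleach first
    fs_norm: np.ndarray
    mc_norm: np.ndarray
    bleach_frame_index: int


@dataclass
class AveragedCurve:
    frame_times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: int


@dataclass
class ExchangeFit:
    """Exchange-rate estimate from a cFR series."""

    k_hat: float  # fL/s
    rate_hat: float  # 1/s, = k_hat (1/v_fs + 1/v_mc)
    plateau: float
    residual: float  # rms of the fit residuals
    converged: bool


def compute_cfr(
    trace: TraceTable,
    bleached_role: str = "bleached_fs",
    reference_role: str = "reference_cell",
) -> CfrSeries:
    """Corrected fluorescence recovery from a background-subtracted trace.

    The bleached cell's intensity is divided by the unbleached reference
    cell's at each frame (cancelling acquisition bleaching), and the ratio
    is rescaled so the prebleach frame maps to 1 and the first postbleach
    frame to 0.
    """
    for role in (bleached_role, reference_role):
        if role not in trace.roles:
            raise ValueError(f"trace has no role {role!r}")
    b = trace.bleach_frame_index
    if b < 1:
        raise ValueError("trace must contain one prebleach frame before the bleach")
    bleached = np.asarray(trace.roles[bleached_role], dtype=float)
    reference = np.asarray(trace.roles[reference_role], dtype=float)
    if np.any(reference <= 0):
        raise ValueError("reference-cell trace must stay positive")
    r = bleached / reference
    r0 = float(r[b - 1])
    rb = float(r[b])
    if np.isclose(r0, rb):
        raise ValueError(
            "no detectable bleach: prebleach and first-postbleach ratios are "
            f"equal ({r0:g}); trace rejected"
        )
    cfr = (r[b:] - rb) / (r0 - rb)
    times = np.asarray(trace.frame_times[b:], dtype=float)
    return CfrSeries(frame_times=times - times[0], cfr=cfr, r0=r0, rb=rb)


def fit_acquisition_loss(distal_traces: list[np.ndarray]) -> AcquisitionLossCurve:
    """Standard curve of fluorescence retention per frame.

    Each distal-cell trace is divided by its own prebleach (first-frame)
    value; the per-frame average across cells is the retention factor.
    Traces with nonpositive prebleach intensity are excluded with a warning.
    """
    kept = []
    for i, tr in enumerate(distal_traces):
        tr = np.asarray(tr, dtype=float)
        if tr[0] <= 0:
            warnings.warn(
                f"distal trace {i} has nonpositive prebleach intensity; excluded",
                stacklevel=2,
            )
            continue
        kept.append(tr / tr[0])
    if not kept:
        raise ValueError("no usable distal traces for the standard curve")
    factors = np.mean(kept, axis=0)
    return AcquisitionLossCurve(factors=factors, n_cells=len(kept))


def compute_flip(
    trace: TraceTable,
    loss_curve: AcquisitionLossCurve,
    fs_role: str = "bleached_fs",
    mc_role: str = "bleached_mc",
) -> FlipSeries:
    """Acquisition-corrected, normalized FLIP series for one sporangium.

    Both cells' traces are divided by the retention factors, then the
    forespore series is normalized to its prebleach value (prebleach = 1)
    and the mother-cell series is rescaled so prebleach = 1 and the first
    postbleach frame = 0. The forespore is deliberately not forced to 0:
    its postbleach decline is the transport signal.
    """
    b = trace.bleach_frame_index
    factors = np.asarray(loss_curve.factors, dtype=float)
    if len(factors) < len(trace.frame_times):
        raise ValueError("loss curve does not cover all frames")
    if np.any(factors <= 0):
        raise ValueError("retention factors must be positive")
    fs = np.asarray(trace.roles[fs_role], dtype=float) / factors[: len(trace.frame_times)]
    mc = np.asarray(trace.roles[mc_role], dtype=float) / factors[: len(trace.frame_times)]
    if fs[b - 1] <= 0 or np.isclose(mc[b - 1], mc[b]):
        raise ValueError("cannot normalize: bad prebleach anchor or no bleach")
    fs_norm = fs / fs[b - 1]
    mc_norm = (mc - mc[b]) / (mc[b - 1] - mc[b])
    return FlipSeries(
        frame_times=np.asarray(trace.frame_times, dtype=float),
        fs_norm=fs_norm,
        mc_norm=mc_norm,
        bleach_frame_index=b,
    )


def _as_time_value(series):
    if isinstance(series, CfrSeries):
        return series.frame_times, series.cfr
    if isinstance(series, tuple) and len(series) == 2:
        return np.asarray(series[0], float), np.asarray(series[1], float)
    values = np.asarray(series, dtype=float)
    return np.arange(len(values), dtype=float), values


def average_curves(series_list) -> AveragedCurve:
    """Pointwise mean +/- SD over replicate curves sharing one time grid.

    Accepts :class:`CfrSeries`, ``(times, values)`` tuples, or bare arrays
    (implicit frame-index grid). Mismatched time grids are an error — no
    resampling is attempted.
    """
    if not series_list:
        raise ValueError("no curves to average")
    times0, _ = _as_time_value(series_list[0])
    values = []
    for s in series_list:
        t, v = _as_time_value(s)
        if len(t) != len(times0) or not np.allclose(t, times0):
            raise ValueError("curves are on different time grids")
        values.append(v)
    values = np.asarray(values)
    sd = values.std(axis=0, ddof=1) if len(values) > 1 else np.zeros_like(times0)
    return AveragedCurve(
        frame_times=times0, mean=values.mean(axis=0), sd=sd, n=len(values)
    )


def recovery_plateau(v_fs: float, v_mc: float) -> float:
    """Asymptotic cFR of a bleached forespore: v_mc / (v_fs + v_mc).

    The bleach removes fluorophore permanently, so the shared equilibrium
    concentration is below the prebleach one by exactly the bleached
    fraction of the total pool.
    """
    return v_mc / (v_fs + v_mc)


def _anchored_rate_fit(t, y, plateau):
    """Rate fit that models the cFR normalization noise explicitly.

    The cFR anchors come from single frames (one prebleach, one first-
    postbleach), so their noise enters every postbleach point as a
    common-mode scale error (through the 1/(r0 - rb) rescale) and a
    common-mode offset (through the -rb shift), on top of iid per-frame
    noise. The fit is therefore y = s * m(rate) + o + eta with ridge priors
    s ~ N(1, 2 sigma^2) and o ~ N(0, sigma^2) in units of the per-frame
    noise variance sigma^2 (the factor 2 because the scale error combines
    two anchor frames); (s, o) are profiled out in closed form and the rate
    is found by bounded 1-D minimization on a log scale. With noise-free
    data the priors are inactive and the exact rate is recovered.
    """

    def profiled(rate):
        m = plateau * (1.0 - np.exp(-rate * t))
        A = np.array(
            [[m @ m + 0.5, m.sum()], [m.sum(), len(t) + 1.0]]
        )
        b = np.array([y @ m + 0.5, y.sum()])
        s, o = np.linalg.solve(A, b)
        r = y - s * m - o
        return r @ r + (s - 1.0) ** 2 / 2.0 + o**2, r

    res = optimize.minimize_scalar(
        lambda lr: profiled(np.exp(lr))[0],
        bounds=(np.log(1e-6), np.log(RATE_BOUND)),
        method="bounded",
    )
    rate_hat = float(np.exp(res.x))
    _, resid = profiled(rate_hat)
    return rate_hat, float(np.sqrt(np.mean(resid**2))), bool(res.success)


def estimate_exchange_rate(
    cfr: CfrSeries,
    v_fs: float,
    v_mc: float,
    plateau: float | str = "volumes",
) -> ExchangeFit:
    """Least-squares exchange-rate fit to cFR(t) = plateau (1 - exp(-rate t)).

    ``plateau`` is ``"volumes"`` (default: fixed to
    :func:`recovery_plateau`, the two-compartment model's value, with the
    anchor-noise-aware fit of :func:`_anchored_rate_fit`), ``"free"``
    (plateau fitted jointly with the rate by plain nonlinear least squares),
    or a number (fixed plateau, anchor-noise-aware fit). The rate is bounded
    to [0, 10] 1/s; ``k_hat = rate_hat / (1/v_fs + 1/v_mc)``.
    """
    if v_fs <= 0 or v_mc <= 0:
        raise ValueError("volumes must be positive")
    t = cfr.frame_times
    y = cfr.cfr
    if len(t) < 5:
        raise ValueError("need at least 5 postbleach frames to fit a rate")
    inv_sum = 1.0 / v_fs + 1.0 / v_mc

    if plateau == "free":
        p0 = max(float(y[-1]), 0.1)
        frac = 1.0 - np.clip(y / p0, None, 1.0 - 1e-9)
        pos = (frac > 1e-9) & (t > 0)
        if pos.sum() >= 2:
            rate0 = float(-np.polyfit(t[pos], np.log(frac[pos]), 1)[0])
            rate0 = min(max(rate0, 1e-6), RATE_BOUND)
        else:
            rate0 = 1e-3

        def resid(p):
            return p[1] * (1.0 - np.exp(-p[0] * t)) - y

        sol = optimize.least_squares(
            resid, x0=[rate0, p0], bounds=([0.0, 0.0], [RATE_BOUND, 1.5])
        )
        rate_hat, plateau_hat = float(sol.x[0]), float(sol.x[1])
        rms = float(np.sqrt(np.mean(sol.fun**2)))
        converged = bool(sol.success)
    else:
        plateau_hat = (
            recovery_plateau(v_fs, v_mc) if plateau == "volumes" else float(plateau)
        )
        rate_hat, rms, converged = _anchored_rate_fit(t, y, plateau_hat)

    if not converged:
        warnings.warn(
            f"exchange-rate fit did not converge; rate reported at bound "
            f"({rate_hat:g} 1/s)",
            stacklevel=2,
        )
    return ExchangeFit(
        k_hat=rate_hat / inv_sum,
        rate_hat=rate_hat,
        plateau=plateau_hat,
        residual=rms,
        converged=converged,
    )


def unpaired_ttest(values_a, values_b) -> tuple[float, float]:
    """Two-sided unpaired t-test (plumbing for cohort comparisons)."""
    res = stats.ttest_ind(np.asarray(values_a), np.asarray(values_b))
    return float(res.statistic), float(res.pvalue)
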