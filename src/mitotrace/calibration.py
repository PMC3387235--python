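"""Indicator calibrations: free Mg²⁺, membrane-potential percentage, matrix pH,
and normalized light scatter.

All single-wavelength indicator calibrations here are endpoint calibrations:
the assay itself records a floor (EDTA for Magnesium Green; the pre-addition
plateau for scatter; the pre-ADP plateau for safranine O) and a ceiling
(25 mM MgCl₂; alamethicin; the uncoupler SF 6847).  The ratiometric BCECF pH
indicator instead uses a fitted model pH = a·exp[b/(x + c)] over buffers of
known pH.

Settling convention: the first ``settle`` seconds after an addition are
excluded (mixing artifacts) and a plateau is the median of the following
``duration`` seconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import (
    BelowFloorError,
    CalibrationError,
    DomainError,
    EventError,
    FitError,
    InsufficientDataError,
    SaturationError,
)
from .trace_io import CalibrationResult, EventLog, Trace

log = logging.getLogger("mitotrace")

#: seconds excluded after each addition (mixing artifact)
SETTLE_S = 10.0
#: seconds of plateau used for endpoint medians
PLATEAU_S = 20.0
#: clamping band near calibration endpoints, as a fraction of (F_max - F_min)
ENDPOINT_BAND = 0.02


# ---------------------------------------------------------------------------
# endpoint (F_min / F_max) calibration


def endpoint_calibration(
    trace: Trace,
    events: EventLog,
    settle: float = SETTLE_S,
    duration: float = PLATEAU_S,
    indicator: str = "MgG",
) -> CalibrationResult:
    """Two-point calibration from the EDTA (floor) / MgCl₂ (ceiling) additions.

    F_min is the plateau median after the 5 mM EDTA addition, F_max after the
    subsequent 25 mM MgCl₂ addition.  Plateau windows never cross the next
    event.
    """
    edta = events.first("EDTA")
    if edta is None:
        raise CalibrationError("calibration incomplete: no EDTA addition in event log")
    mgcl2 = next((e for e in events.of("MgCl2") if e.time > edta.time), None)
    if mgcl2 is None:
        raise CalibrationError("calibration incomplete: no MgCl2 addition after EDTA")

    f_min = _plateau_after(trace, events, edta.time, settle, duration)
    f_max = _plateau_after(trace, events, mgcl2.time, settle, duration)
    if f_min >= f_max:
        raise CalibrationError(
            f"inverted calibration: post-EDTA plateau {f_min:g} >= post-MgCl2 plateau {f_max:g}"
        )
    return CalibrationResult(indicator=indicator, params={"F_min": f_min, "F_max": f_max})


def _plateau_after(
    trace: Trace, events: EventLog, t_event: float, settle: float, duration: float
) -> float:
    t0 = t_event + settle
    nxt = events.next_after(t_event)
    t1 = min(t0 + duration, nxt.time if nxt is not None else trace.span[1] + 1.0)
    if t1 <= t0:
        raise InsufficientDataError(
            f"no room for a settled plateau after t={t_event:g} s (next event at {nxt.time:g} s)"
        )
    return trace.plateau_median(t0, t1, min_samples=3)


def free_mg_from_fluorescence(
    F: float | np.ndarray,
    cal: CalibrationResult,
    Kd_MgG: float = 1.0,
    band: float = ENDPOINT_BAND,
) -> float | np.ndarray:
    """Invert the single-site binding isotherm of Magnesium Green.

    Forward model: F = F_min + (F_max − F_min)·Mg_f/(Kd + Mg_f); hence
    Mg_f = Kd·(F − F_min)/(F_max − F).  Values within ``band``·(F_max−F_min)
    of either endpoint are clamped to the band edge with a warning; values
    beyond raise :class:`SaturationError` / :class:`BelowFloorError`.
    """
    f_min, f_max = cal.params["F_min"], cal.params["F_max"]
    eps = band * (f_max - f_min)
    scalar = np.isscalar(F)
    F = np.atleast_1d(np.asarray(F, dtype=float))
    if np.any(F >= f_max - eps):
        raise SaturationError(
            f"fluorescence >= F_max - {eps:g} ({f_max - eps:g}); indicator saturated"
        )
    if np.any(F < f_min - eps):
        raise BelowFloorError(f"fluorescence below calibrated floor F_min - {eps:g}")
    n_clamped = int(np.count_nonzero(F < f_min))
    if n_clamped:
        log.warning("clamped %d samples inside the floor tolerance band to F_min", n_clamped)
        F = np.maximum(F, f_min)
    mg = Kd_MgG * (F - f_min) / (f_max - F)
    return float(mg[0]) if scalar else mg


def flag_free_mg(
    F: np.ndarray,
    cal: CalibrationResult,
    Kd_MgG: float = 1.0,
    band: float = ENDPOINT_BAND,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Array variant used on whole traces: out-of-domain samples become NaN
    (flagged) instead of raising, so the rest of a run stays analysable.

    Returns ``(Mg_f, bad_mask, n_clamped)``.
    """
    f_min, f_max = cal.params["F_min"], cal.params["F_max"]
    eps = band * (f_max - f_min)
    F = np.asarray(F, dtype=float)
    bad = (F >= f_max - eps) | (F < f_min - eps)
    clamped = (F < f_min) & ~bad
    Fc = np.where(clamped, f_min, F)
    with np.errstate(invalid="ignore", divide="ignore"):
        mg = Kd_MgG * (Fc - f_min) / (f_max - Fc)
    mg = np.where(bad, np.nan, mg)
    return mg, bad, int(clamped.sum())


# ---------------------------------------------------------------------------
# BCECF pH calibration


@dataclass
class PHCalibration:
    """Fitted constants of pH = a·exp[b/(x + c)] with x the BCECF excitation
    ratio (490 nm over the quasi-isosbestic 450 nm by default)."""

    a: float
    b: float
    c: float
    r_squared: float
    se_a: float
    se_b: float
    se_c: float
    x_range: tuple[float, float] = (0.0, np.inf)

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise FitError(f"r_squared {self.r_squared!r} outside [0, 1]")
        self.r_squared = min(self.r_squared, 1.0)


def _ph_model(x: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    return a * np.exp(b / (x + c))


def fit_ph_calibration(
    points: list[tuple[float, float]],
    n_starts: int = 5,
    perturb: float = 0.5,
) -> PHCalibration:
    """Nonlinear least-squares fit of pH = a·exp[b/(x + c)].

    The exponential model has a narrow convergence basin, so the fit uses a
    coarse grid search over c (with (ln a, b) solved linearly in log space)
    to seed ``n_starts`` multi-start Levenberg–Marquardt refinements whose
    initial points are perturbed by ±``perturb`` relative.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
        raise InsufficientDataError(f"need >= 4 (ratio, pH) points, got {pts.shape}")
    x, ph = pts[:, 0], pts[:, 1]
    if ph.max() - ph.min() < 0.5:
        raise InsufficientDataError(
            f"calibration points span {ph.max() - ph.min():.3g} pH units, need >= 0.5"
        )

    a0, b0, c0 = _grid_seed(x, ph)
    rng = np.random.default_rng(0)  # internal multi-start jitter; fit is deterministic
    starts = [(a0, b0, c0)]
    starts += [
        tuple(p * (1.0 + perturb * rng.uniform(-1.0, 1.0)) for p in (a0, b0, c0))
        for _ in range(n_starts - 1)
    ]

    best = None
    best_sse = np.inf
    for p0 in starts:
        try:
            popt, pcov = curve_fit(_ph_model, x, ph, p0=p0, maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        resid = ph - _ph_model(x, *popt)
        sse = float(resid @ resid)
        if np.all(np.isfinite(popt)) and sse < best_sse:
            best, best_sse = (popt, pcov), sse
    if best is None:
        raise FitError("pH calibration fit did not converge from any start", best_residual=None)

    (a, b, c), pcov = best
    ss_tot = float(np.sum((ph - ph.mean()) ** 2))
    r2 = 1.0 - best_sse / ss_tot if ss_tot > 0 else 1.0
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf)) if np.all(np.isfinite(pcov)) else np.full(3, np.nan)
    if np.min(x) + c <= 0:
        raise FitError(
            f"fitted c={c:g} puts a pole inside the calibrated ratio range", best_residual=best_sse
        )
    return PHCalibration(
        a=float(a), b=float(b), c=float(c),
        r_squared=max(0.0, min(1.0, r2)),
        se_a=float(se[0]), se_b=float(se[1]), se_c=float(se[2]),
        x_range=(float(np.min(x)), float(np.max(x))),
    )


def _grid_seed(x: np.ndarray, ph: np.ndarray) -> tuple[float, float, float]:
    """Seed (a, b, c) by grid search on c with linear solve of ln pH = ln a + b/(x+c)."""
    xr = float(np.ptp(x))
    c_grid = np.linspace(-float(np.min(x)) + 0.05 * xr, 5.0 * xr + 1.0, 60)
    lp = np.log(ph)
    best = (float(np.max(ph)), -0.1, 1.0)
    best_sse = np.inf
    for c in c_grid:
        u = 1.0 / (x + c)
        A = np.column_stack([np.ones_like(u), u])
        coef, *_ = np.linalg.lstsq(A, lp, rcond=None)
        sse = float(np.sum((ph - np.exp(A @ coef)) ** 2))
        if sse < best_sse:
            best_sse = sse
            best = (float(np.exp(coef[0])), float(coef[1]), float(c))
    return best


def ph_from_ratio(x: float, cal: PHCalibration, extrapolation_margin: float = 0.1) -> float:
    """Evaluate the fitted pH model at ratio ``x``.

    ``extrapolation_margin`` is a fraction of the calibrated ratio range;
    beyond it a range warning is logged (the value is still returned).
    """
    if x + cal.c <= 0:
        raise DomainError(f"ratio {x:g} with fitted c={cal.c:g} gives x + c <= 0")
    lo, hi = cal.x_range
    margin = extrapolation_margin * (hi - lo)
    if not (lo - margin <= x <= hi + margin):
        log.warning("ratio %g outside calibrated range [%g, %g] +/- %g", x, lo, hi, margin)
    return float(cal.a * np.exp(cal.b / (x + cal.c)))


def ratio_from_ph(ph: float, cal: PHCalibration) -> float:
    """Analytic inverse x = b/ln(pH/a) − c of the pH model."""
    if ph <= 0 or ph == cal.a:
        raise DomainError(f"pH {ph!r} outside the invertible range of the model")
    return float(cal.b / np.log(ph / cal.a) - cal.c)


# ---------------------------------------------------------------------------
# safranine O membrane-potential percentage


@dataclass
class PolarizationScale:
    """Endpoints of the safranine O percentage scale.

    100% polarization is the pre-ADP (substrates-only) plateau; 0% is the
    plateau after 1 µM SF 6847.  In quench mode (495/585 nm, 5 µM dye)
    safranine fluorescence rises on depolarization, so typically
    F_uncoupled > F_baseline; the percentage formula needs only that the two
    endpoints differ.
    """

    F_baseline: float
    F_uncoupled: float

    def __post_init__(self) -> None:
        if self.F_uncoupled == self.F_baseline:
            raise CalibrationError("degenerate polarization scale: endpoints are equal")


def polarization_scale_from_trace(
    trace: Trace,
    events: EventLog,
    settle: float = SETTLE_S,
    duration: float = PLATEAU_S,
) -> PolarizationScale:
    """Measure the percentage-scale endpoints from a run's own trace:
    baseline = plateau just before the ADP addition, uncoupled = plateau
    after the SF 6847 addition."""
    adp = events.first("ADP")
    if adp is None:
        raise EventError("no ADP addition: cannot locate the 100%-polarization baseline")
    unc = events.first("SF6847")
    if unc is None:
        raise EventError("no SF6847 addition: cannot locate the 0%-polarization endpoint")
    f_base = trace.plateau_median(max(trace.span[0], adp.time - duration - 1.0), adp.time - 1.0, 3)
    f_unc = _plateau_after(trace, events, unc.time, settle, duration)
    return PolarizationScale(F_baseline=f_base, F_uncoupled=f_unc)


def polarization_percent(trace: Trace, scale: PolarizationScale) -> Trace:
    """Express a safranine O trace on the percentage polarization scale:
    P(t) = 100·(F_uncoupled − F(t))/(F_uncoupled − F_baseline)."""
    denom = scale.F_uncoupled - scale.F_baseline
    p = 100.0 * (scale.F_uncoupled - trace.signal) / denom
    return Trace(trace.time.copy(), p, units="percent", channel=trace.channel)


def adp_depolarization_percent(
    trace: Trace,
    events: EventLog,
    scale: PolarizationScale,
    settle: float = SETTLE_S,
    smooth_s: float = 2.0,
) -> float:
    """Depth of the ADP-induced depolarization, in percent of full scale.

    Returns 100 − min(polarization) over the post-ADP steady window (from
    ADP + ``settle`` to the next addition or trace end), with the
    polarization trace passed through a ``smooth_s`` rolling median so the
    minimum is not a single-sample noise excursion.  0% = no depolarization,
    100% = collapse to the uncoupled level.
    """
    adp = events.first("ADP")
    if adp is None:
        raise EventError("no ADP addition in event log")
    nxt = events.next_after(adp.time)
    t1 = nxt.time if nxt is not None else trace.span[1] + 1.0
    t0 = adp.time + settle
    if t1 - t0 < settle:
        raise InsufficientDataError(
            f"trace holds only {max(0.0, t1 - t0):g} s past the ADP settling window"
        )
    pol = polarization_percent(trace, scale).crop(t0, t1)
    smoothed = _rolling_median(pol.signal, pol.time, smooth_s)
    return float(100.0 - np.min(smoothed))


def _rolling_median(y: np.ndarray, t: np.ndarray, width_s: float) -> np.ndarray:
    dt = float(np.median(np.diff(t)))
    w = max(1, int(round(width_s / dt)))
    w += 1 - w % 2  # odd
    if w <= 1 or w > y.size:
        return y
    return pd.Series(y).rolling(w, center=True, min_periods=1).median().to_numpy()


@dataclass
class DoseResponseTable:
    """ADP-depolarization depths on a (pH_o × inhibitor dose) grid, with a
    per-row flag marking whether depth is non-increasing with dose."""

    table: pd.DataFrame  # index pH_o, columns dose, values depolarization %
    monotone_nonincreasing: dict[float, bool]
    errors: dict[tuple[float, float], str]


def dose_response_table(
    runs: list[tuple[Trace, EventLog, PolarizationScale, float, float]],
    monotone_slack: float = 2.0,
) -> DoseResponseTable:
    """Aggregate ``(trace, events, scale, pH_o, dose)`` runs into a dose-response
    grid of ADP-depolarization depths.

    ``monotone_slack`` (percentage points) absorbs measurement noise when
    flagging rows as non-increasing with dose; replicate cells are averaged.
    """
    cells: dict[tuple[float, float], list[float]] = {}
    errors: dict[tuple[float, float], str] = {}
    for trace, events, scale, ph_o, dose in runs:
        try:
            depth = adp_depolarization_percent(trace, events, scale)
        except Exception as exc:  # collected per cell, not fatal
            errors[(ph_o, dose)] = f"{type(exc).__name__}: {exc}"
            continue
        cells.setdefault((ph_o, dose), []).append(depth)
    if not cells:
        return DoseResponseTable(pd.DataFrame(), {}, errors)
    ph_vals = sorted({k[0] for k in cells})
    doses = sorted({k[1] for k in cells})
    table = pd.DataFrame(index=ph_vals, columns=doses, dtype=float)
    table.index.name = "pH_o"
    table.columns.name = "dose_uM"
    for (ph_o, dose), vals in cells.items():
        table.loc[ph_o, dose] = float(np.mean(vals))
    flags = {}
    for ph_o in ph_vals:
        row = table.loc[ph_o].dropna().to_numpy()
        flags[ph_o] = bool(np.all(np.diff(row) <= monotone_slack))
    return DoseResponseTable(table, flags, errors)


# ---------------------------------------------------------------------------
# light-scatter normalization


def normalize_scatter(
    trace: Trace,
    events: EventLog,
    settle: float = SETTLE_S,
    duration: float = PLATEAU_S,
) -> Trace:
    """Normalize a 660 nm scatter trace to percent of the pre-addition level,
    with the post-alamethicin (maximal swelling) plateau as 0%:
    S(t) = 100·(A(t) − A_alm)/(A_0 − A_alm)."""
    alm = events.first("alamethicin")
    if alm is None:
        raise CalibrationError("no alamethicin addition: scatter cannot be normalized")
    first = events.entries[0]
    a0 = trace.plateau_median(trace.span[0], min(first.time, alm.time), min_samples=3)
    a_alm = _plateau_after(trace, events, alm.time, settle, duration)
    if a0 <= a_alm:
        raise CalibrationError(
            f"inverted scatter: pre-addition plateau {a0:g} <= post-alamethicin plateau {a_alm:g}"
        )
    s = 100.0 * (trace.signal - a_alm) / (a0 - a_alm)
    return Trace(trace.time.copy(), s, units="percent", channel=trace.channel)
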