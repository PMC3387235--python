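"""Reconstruction of extramitochondrial [ATP] from free Mg²⁺ and estimation of
the ANT-mediated ADP-ATP exchange rate.

Principle: ATP chelates Mg²⁺ more tightly than ADP (Kd_ATP < Kd_ADP), so as
energized mitochondria convert medium ADP to ATP, free [Mg²⁺] falls.  With
conserved totals (Mg_T, adenine A_T = ATP_T + ADP_T, indicator dye D_T) the
mass-action conservation law

    Mg_T = Mg_f · [1 + ATP_T/(Kd_ATP + Mg_f) + ADP_T/(Kd_ADP + Mg_f)
                     + D_T/(Kd_MgG + Mg_f)]

links free Mg²⁺ to ATP_T.  The forward direction (``free_mg_given_atp``) is a
bisection root-find kept deliberately primitive — it is the oracle against
which the closed-form inversion (``atp_from_free_mg``) is validated:

    ATP_T = [Mg_T − Mg_f − D_T·β_MgG − A_T·β_ADP] / (β_ATP − β_ADP),
    β_X = Mg_f/(Kd_X + Mg_f).

An optional extra ligand (L_total, Kd_L) supports sensitivity checks for
weakly chelating buffer components; by default none is included.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .calibration import endpoint_calibration, flag_free_mg
from .errors import (
    ConfigurationError,
    DomainError,
    EventError,
    InconsistentInputError,
    InsufficientDataError,
    UndefinedRatioError,
)
from .trace_io import AssayConfig, CalibrationResult, EventLog, Trace

log = logging.getLogger("mitotrace")

#: numeric clamping tolerance for ATP_T at the [0, A_total] endpoints (mM)
ATP_CLAMP_TOL = 1e-6


@dataclass(frozen=True)
class SpeciationSystem:
    """Conserved totals and dissociation constants of the Mg²⁺ speciation system (all mM)."""

    Mg_total: float
    adenine_total: float
    dye_total: float = 0.0
    Kd_ATP: float = 0.04
    Kd_ADP: float = 0.35
    Kd_MgG: float = 1.0
    L_total: float = 0.0
    Kd_L: float = 100.0

    def __post_init__(self) -> None:
        if not self.Mg_total > 0:
            raise ConfigurationError("Mg_total must be > 0")
        for name in ("adenine_total", "dye_total", "L_total"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("Kd_ATP", "Kd_ADP", "Kd_MgG", "Kd_L"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.Kd_ATP >= self.Kd_ADP:
            raise ConfigurationError(
                "Kd_ATP must be < Kd_ADP; equal affinities make ATP_T unidentifiable"
            )

    @classmethod
    def from_config(cls, cfg: AssayConfig, adenine_total: float | None = None) -> "SpeciationSystem":
        return cls(
            Mg_total=cfg.Mg_total,
            adenine_total=cfg.adenine_total if adenine_total is None else adenine_total,
            dye_total=cfg.dye_total,
            Kd_ATP=cfg.Kd_ATP,
            Kd_ADP=cfg.Kd_ADP,
            Kd_MgG=cfg.Kd_MgG,
        )


def _total_mg(sys: SpeciationSystem, mg_f: float, atp_t: float) -> float:
    """Total Mg implied by free Mg and the ATP/ADP split (conservation law)."""
    adp_t = sys.adenine_total - atp_t
    return mg_f * (
        1.0
        + atp_t / (sys.Kd_ATP + mg_f)
        + adp_t / (sys.Kd_ADP + mg_f)
        + sys.dye_total / (sys.Kd_MgG + mg_f)
        + sys.L_total / (sys.Kd_L + mg_f)
    )


def free_mg_given_atp(sys: SpeciationSystem, ATP_T: float, xtol: float = 1e-13) -> float:
    """Free [Mg²⁺] for a given ATP_T — the brute-force bisection oracle.

    The conservation residual g(m) = m·[1 + Σ X/(Kd_X + m)] − Mg_T is strictly
    increasing in m, so the root in (0, Mg_total] is unique; plain bisection
    converges to better than 1e-12 mM.
    """
    if not (-1e-12 <= ATP_T <= sys.adenine_total + 1e-12):
        raise DomainError(f"ATP_T={ATP_T!r} outside [0, adenine_total={sys.adenine_total!r}]")
    ATP_T = float(np.clip(ATP_T, 0.0, sys.adenine_total))
    if sys.adenine_total == 0.0 and sys.dye_total == 0.0 and sys.L_total == 0.0:
        return sys.Mg_total
    lo, hi = 0.0, sys.Mg_total
    # g(lo) = -Mg_T < 0; g(hi) >= 0 since every binding term is non-negative
    while hi - lo > xtol:
        mid = 0.5 * (lo + hi)
        if _total_mg(sys, mid, ATP_T) < sys.Mg_total:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def atp_from_free_mg(sys: SpeciationSystem, Mg_f: float, tol: float = ATP_CLAMP_TOL) -> float:
    """Closed-form inversion of the conservation law: ATP_T from free [Mg²⁺].

    Results within ``tol`` outside [0, A_total] are clamped with a warning;
    larger excursions raise :class:`InconsistentInputError` (wrong totals or
    calibration).
    """
    if not (0.0 < Mg_f <= sys.Mg_total):
        raise DomainError(f"Mg_f={Mg_f!r} outside (0, Mg_total={sys.Mg_total!r}]")
    b_atp = Mg_f / (sys.Kd_ATP + Mg_f)
    b_adp = Mg_f / (sys.Kd_ADP + Mg_f)
    b_dye = Mg_f / (sys.Kd_MgG + Mg_f)
    b_lig = Mg_f / (sys.Kd_L + Mg_f)
    atp = (
        sys.Mg_total - Mg_f - sys.dye_total * b_dye - sys.L_total * b_lig
        - sys.adenine_total * b_adp
    ) / (b_atp - b_adp)
    if atp < -tol or atp > sys.adenine_total + tol:
        raise InconsistentInputError(
            f"inverted ATP_T={atp:g} mM outside [0, {sys.adenine_total:g}] by more than "
            f"{tol:g} mM: totals or calibration are inconsistent with the signal"
        )
    if atp < 0.0 or atp > sys.adenine_total:
        log.warning("ATP_T clamped to the [0, adenine_total] endpoint (within %g mM)", tol)
        atp = float(np.clip(atp, 0.0, sys.adenine_total))
    return float(atp)


def _atp_from_free_mg_array(sys: SpeciationSystem, mg: np.ndarray) -> np.ndarray:
    """Vectorized closed form; NaN passes through (flagged samples)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        b_atp = mg / (sys.Kd_ATP + mg)
        b_adp = mg / (sys.Kd_ADP + mg)
        b_dye = mg / (sys.Kd_MgG + mg)
        b_lig = mg / (sys.Kd_L + mg)
        atp = (
            sys.Mg_total - mg - sys.dye_total * b_dye - sys.L_total * b_lig
            - sys.adenine_total * b_adp
        ) / (b_atp - b_adp)
    return atp


@dataclass
class ExchangeResult:
    """ADP-ATP exchange estimate: the reconstructed [ATP] time course, the
    OLS rate over the regression window, and its standard error."""

    rate: float  # mM / min
    rate_se: float  # mM / min
    window: tuple[float, float]  # s
    atp_timecourse: Trace | None = None
    inhibition_percent_vs_control: float | None = None
    warnings: list[str] = field(default_factory=list)

    def rate_nmol_per_min_per_mg(self, cfg: AssayConfig) -> float:
        """Mass-specific rate: mM/min × chamber ml = µmol/min; ×1000/protein mg."""
        return self.rate * cfg.chamber_volume * 1000.0 / cfg.protein_mass


def reconstruct_atp_timecourse(
    trace: Trace,
    events: EventLog,
    cal: CalibrationResult,
    sys: SpeciationSystem,
) -> Trace:
    """Pointwise composition indicator-inversion → speciation-inversion on a
    Magnesium Green trace.

    Applied from the ADP addition to the first of (EDTA event, trace end);
    pre-ADP samples are set to 0 mM ATP.  Saturated/out-of-band samples are
    flagged NaN; more than 5% flagged-or-clamped samples logs a quality
    warning.
    """
    adp = events.first("ADP")
    if adp is None:
        raise EventError("no ADP addition: cannot anchor the exchange phase")
    edta = next((e for e in events.of("EDTA") if e.time > adp.time), None)
    t_end = edta.time if edta is not None else trace.span[1] + 1.0
    m = trace.mask(trace.span[0], t_end)
    t = trace.time[m]
    atp = np.zeros_like(t)
    phase = t >= adp.time
    mg, bad, n_clamped = flag_free_mg(trace.signal[m][phase], cal, sys.Kd_MgG)
    atp_phase = _atp_from_free_mg_array(sys, mg)
    atp_phase = np.clip(atp_phase, 0.0, sys.adenine_total)
    atp_phase[bad] = np.nan
    atp[phase] = atp_phase
    n_bad = int(bad.sum()) + n_clamped
    if n_bad > 0.05 * max(1, int(phase.sum())):
        log.warning(
            "quality: %d of %d exchange-phase samples flagged or clamped (>5%%)",
            n_bad, int(phase.sum()),
        )
    return Trace(t, atp, units="mM", channel="ATP", allow_nan=True)


def exchange_rate(
    atp: Trace,
    window: tuple[float, float] | str = "auto",
    t_adp: float | None = None,
    A_total: float | None = None,
) -> ExchangeResult:
    """OLS slope of [ATP] vs time over the regression window, in mM/min.

    ``window="auto"`` spans from 5 s after the ADP addition (``t_adp``,
    default: trace start) to whichever comes first of 60 s later or the
    moment 25% of ``A_total`` has been consumed.  NaN (flagged) samples are
    excluded; fewer than 10 usable samples is an error.
    """
    if window == "auto":
        t0 = (atp.time[0] if t_adp is None else t_adp) + 5.0
        t1 = t0 + 60.0
        if A_total is not None:
            crossed = atp.time[np.nan_to_num(atp.signal, nan=0.0) >= 0.25 * A_total]
            if crossed.size:
                t1 = min(t1, float(crossed[0]))
    else:
        t0, t1 = window
    m = atp.mask(t0, t1) & np.isfinite(atp.signal)
    if int(m.sum()) < 10:
        raise InsufficientDataError(
            f"only {int(m.sum())} usable samples in window [{t0:g}, {t1:g}) s, need >= 10"
        )
    res = stats.linregress(atp.time[m], atp.signal[m])
    return ExchangeResult(
        rate=float(res.slope) * 60.0,
        rate_se=float(res.stderr) * 60.0,
        window=(float(atp.time[m][0]), float(atp.time[m][-1])),
        atp_timecourse=atp,
    )


def inhibition_summary(control: ExchangeResult, treated: ExchangeResult) -> float:
    """Percent inhibition of the treated exchange rate relative to control:
    100·(1 − treated/control); negative values (treated faster than control)
    are reported as 0 with a warning."""
    if control.rate <= 0:
        raise UndefinedRatioError("control exchange rate is <= 0; inhibition undefined")
    if treated.rate < 0:
        log.warning("treated rate %g < 0; treating as 0 for inhibition", treated.rate)
    pct = 100.0 * (1.0 - max(treated.rate, 0.0) / control.rate)
    if pct < 0:
        log.warning("treated rate exceeds control; reporting 0%% inhibition")
        return 0.0
    return float(pct)


def exchange_pipeline(
    trace: Trace,
    events: EventLog,
    cfg: AssayConfig,
    window: tuple[float, float] | str = "auto",
) -> ExchangeResult:
    """Full exchange analysis of one Magnesium Green run: endpoint calibration
    → [Mg²⁺]_f → [ATP] reconstruction → OLS rate.  The adenine total is taken
    from the ADP addition amount unless the config already fixes it."""
    adp = events.first("ADP")
    if adp is None:
        raise EventError("no ADP addition in event log")
    a_total = cfg.adenine_total if cfg.adenine_total > 0 else adp.amount
    sys = SpeciationSystem.from_config(cfg, adenine_total=a_total)
    cal = endpoint_calibration(trace, events)
    atp = reconstruct_atp_timecourse(trace, events, cal, sys)
    return exchange_rate(atp, window=window, t_adp=adp.time, A_total=a_total)
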