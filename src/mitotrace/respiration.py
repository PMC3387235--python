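"""Oxygraph analysis: mass-specific oxygen flux, per-state fluxes, and the
respiratory control ratio.

Flux is the negative time derivative of the chamber O₂ concentration divided
by the mitochondrial mass density:

    J(t) = −dC/dt [µM/s] / (protein_mass/chamber_volume [mg/ml]) × 1000
         →  pmol O₂ · s⁻¹ · mg⁻¹

The derivative is a centered moving OLS slope over a configurable window
(default 10 s), because raw 5 Hz finite differences are noise-dominated.
Dithionite segments (non-biological oxygen removal) are always excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .errors import ConfigurationError, InsufficientDataError, UndefinedRatioError
from .trace_io import AssayConfig, EventLog, Trace

log = logging.getLogger("mitotrace")

#: seconds excluded after each addition before a state segment is averaged
SETTLE_S = 10.0
#: seconds excluded at the tail of each segment (smoothing leakage from the next state)
EDGE_S = 6.0
#: minimum usable segment length after exclusions (s)
MIN_SEGMENT_S = 15.0

#: addition → state label for the segment that follows it
_STATE_LABELS = {
    "substrates": "basal",
    "ADP": "state3",
    "cATR": "post_cATR",
    "SF6847": "uncoupled",
    "KCN": "post_KCN",
    "oligomycin": "post_oligomycin",
}


@dataclass
class StateSegment:
    mean_flux: float  # pmol O2 / s / mg
    sd_flux: float
    window: tuple[float, float]  # s


@dataclass
class StateTable:
    """Mean flux per inter-event segment, labelled by the preceding addition."""

    segments: dict[str, StateSegment]
    warnings: list[str] = field(default_factory=list)

    @property
    def cyanide_sensitive(self) -> bool | None:
        """True when the post-KCN flux is < 2% of state 3 (respiration fully
        attributable to the respiratory chain)."""
        if "post_KCN" not in self.segments or "state3" not in self.segments:
            return None
        s3 = self.segments["state3"].mean_flux
        return bool(abs(self.segments["post_KCN"].mean_flux) < 0.02 * s3) if s3 > 0 else None

    @property
    def uncoupled_exceeds_state3(self) -> bool | None:
        if "uncoupled" not in self.segments or "state3" not in self.segments:
            return None
        return bool(self.segments["uncoupled"].mean_flux > self.segments["state3"].mean_flux)


@dataclass
class RCRResult:
    """Respiratory control ratio with the denominator choice recorded.

    The controlled-state denominator is the post-cATR segment when present
    (ANT blocked, state-4-like), else basal; ``all_ratios`` reports every
    available denominator.
    """

    rcr: float
    denominator: str
    all_ratios: dict[str, float]


def oxygen_flux(trace: Trace, cfg: AssayConfig, window_s: float = 10.0) -> Trace:
    """Convert an O₂ concentration trace (µM) to mass-specific flux.

    Uses a centered moving-OLS derivative of width ``window_s`` (requires
    near-uniform sampling); the half-window at each end is trimmed, so the
    output is shorter than the input by one derivative window.
    """
    density = cfg.protein_mass / cfg.chamber_volume  # mg/ml
    if density <= 0:
        raise ConfigurationError("protein mass density must be > 0")
    dt = np.diff(trace.time)
    if np.ptp(dt) > 0.1 * np.median(dt):
        raise InsufficientDataError("flux derivative requires near-uniform sampling")
    step = float(np.median(dt))
    w = max(3, int(round(window_s / step)))
    w += 1 - w % 2  # odd
    if w > len(trace):
        raise InsufficientDataError(
            f"trace shorter ({len(trace)} samples) than the derivative window ({w})"
        )
    # polyorder-1 Savitzky-Golay first derivative == centered moving OLS slope
    slope = savgol_filter(trace.signal, w, polyorder=1, deriv=1, delta=step)
    half = w // 2
    flux = -slope[half:-half] * 1000.0 / density
    return Trace(trace.time[half:-half], flux, units="pmol_O2_s_mg", channel="flux")


def state_fluxes(
    flux: Trace,
    events: EventLog,
    settle: float = SETTLE_S,
    edge: float = EDGE_S,
    min_segment: float = MIN_SEGMENT_S,
) -> StateTable:
    """Mean flux per inter-event segment, labelled by the preceding addition.

    The initial segment (before any addition) is "basal".  Segments shorter
    than ``min_segment`` after settling/edge exclusions are skipped with a
    warning; the dithionite segment is always excluded.
    """
    t_start, t_end = flux.span
    boundaries: list[tuple[float, str]] = [(t_start, "basal")]
    for ev in events:
        if ev.time <= t_start or ev.time >= t_end:
            continue
        if ev.compound == "dithionite":
            boundaries.append((ev.time, "_dithionite"))
        elif ev.compound in _STATE_LABELS:
            boundaries.append((ev.time, _STATE_LABELS[ev.compound]))
        # other compounds (e.g. vehicle) do not open a new state segment
    boundaries.sort(key=lambda b: b[0])

    segments: dict[str, StateSegment] = {}
    warnings: list[str] = []
    for i, (t_ev, label) in enumerate(boundaries):
        if label == "_dithionite":
            continue
        t_next = boundaries[i + 1][0] if i + 1 < len(boundaries) else t_end
        t0 = t_ev + (settle if i > 0 else 0.0)
        t1 = t_next - edge
        if t1 - t0 < min_segment:
            warnings.append(f"segment {label!r} too short ({max(0.0, t1 - t0):g} s); skipped")
            log.warning("%s", warnings[-1])
            continue
        m = flux.mask(t0, t1)
        seg = StateSegment(
            mean_flux=float(np.mean(flux.signal[m])),
            sd_flux=float(np.std(flux.signal[m], ddof=1)),
            window=(t0, t1),
        )
        if label in segments:
            warnings.append(f"repeated state {label!r}; keeping the first occurrence")
            log.warning("%s", warnings[-1])
        else:
            segments[label] = seg
    return StateTable(segments=segments, warnings=warnings)


def respiratory_control_ratio(states: StateTable) -> RCRResult:
    """RCR = state-3 flux / controlled-state flux.

    Prefers post-cATR as the controlled state, falling back to basal; both
    ratios are reported in ``all_ratios`` where available.
    """
    if "state3" not in states.segments:
        raise UndefinedRatioError("no state-3 segment; RCR undefined")
    s3 = states.segments["state3"].mean_flux
    ratios = {}
    for denom in ("post_cATR", "basal", "post_oligomycin"):
        if denom in states.segments:
            d = states.segments[denom].mean_flux
            if d > 0:
                ratios[denom] = s3 / d
    preferred = next((d for d in ("post_cATR", "basal") if d in ratios), None)
    if preferred is None:
        raise UndefinedRatioError("no controlled-state segment with positive flux; RCR undefined")
    return RCRResult(rcr=float(ratios[preferred]), denominator=preferred, all_ratios=ratios)


def respiration_pipeline(
    trace: Trace, events: EventLog, cfg: AssayConfig, window_s: float = 10.0
) -> tuple[Trace, StateTable, RCRResult]:
    """O₂ trace → flux trace → state table → RCR."""
    flux = oxygen_flux(trace, cfg, window_s=window_s)
    states = state_fluxes(flux, events)
    return flux, states, respiratory_control_ratio(states)
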