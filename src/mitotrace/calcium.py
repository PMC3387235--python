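"""Ca²⁺ bolus detection, uptake rates, maximum uptake capacity, treatment
comparison, and swelling classification.

The Calcium Green 5N indicator is used qualitatively: each CaCl₂ bolus steps
the fluorescence up, and sequestration by mitochondria decays it back toward
baseline.  Capacity counting follows the "no further decrease" rule: boluses
are counted as sequestered while the fluorescence step is substantially
removed before the next addition; the count stops at the first failure.
Bolus amounts always come from the event log — step heights are never
converted to concentration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigurationError,
    EventError,
    HeterogeneityError,
    InsufficientDataError,
)
from .trace_io import AssayConfig, EventLog, Trace

log = logging.getLogger("mitotrace")

#: residual fraction below which a bolus counts as sequestered
SEQUESTERED_THRESHOLD = 0.5
#: decision timeout after a bolus when no further event follows (s)
DECISION_TIMEOUT_S = 120.0
#: window for locating the post-addition peak (s)
PEAK_SEARCH_S = 15.0
#: half-width of the median window around the peak (s)
PEAK_MEDIAN_HALF_S = 1.0
#: maximum initial-decay regression window (s)
UPTAKE_WINDOW_S = 20.0


@dataclass
class BolusRecord:
    """One CaCl₂ addition: its fluorescence step, decay, and sequestration verdict."""

    time: float  # s
    amount: float  # mM in-chamber increment
    sequestered: bool
    uptake_rate: float | None  # signal units per s; None if too few samples
    residual_fraction: float  # fraction of the step remaining at decision time
    step_amplitude: float  # afu
    decision_time: float  # s
    warnings: list[str] = field(default_factory=list)


@dataclass
class CapacityResult:
    """Maximum Ca²⁺ uptake capacity from consecutive sequestered boluses."""

    n_sequestered: int
    capacity_umol_per_mg: float
    per_bolus: list[BolusRecord]


def detect_boluses(
    trace: Trace,
    events: EventLog,
    threshold: float = SEQUESTERED_THRESHOLD,
    timeout: float = DECISION_TIMEOUT_S,
) -> list[BolusRecord]:
    """Characterize every CaCl₂ addition on a Calcium Green 5N trace.

    For each bolus: step amplitude = (median of 2 s around the maximum within
    15 s post-addition) − (median of the 5 s pre-addition baseline); the decay
    is tracked to the decision time (next event, ``timeout`` seconds, or trace
    end, whichever first) where the residual fraction of the step is read out.
    Steps at or below the noise floor (3 × the normal-scaled MAD of the
    baseline) are kept with ``sequestered=False`` and a warning.
    """
    boluses = events.of("CaCl2")
    if not boluses:
        return []
    records: list[BolusRecord] = []
    for ev in boluses:
        warns: list[str] = []
        t0 = max(trace.span[0], ev.time - 5.0)
        base_mask = trace.mask(t0, ev.time)
        if base_mask.sum() < 3:
            raise InsufficientDataError(f"no baseline samples before bolus at {ev.time:g} s")
        base_sig = trace.signal[base_mask]
        baseline = float(np.median(base_sig))
        noise_floor = 3.0 * stats.median_abs_deviation(base_sig, scale="normal")

        peak_mask = trace.mask(ev.time, min(ev.time + PEAK_SEARCH_S, trace.span[1]))
        if peak_mask.sum() < 3:
            raise InsufficientDataError(f"no post-addition samples for bolus at {ev.time:g} s")
        t_peak = float(trace.time[peak_mask][np.argmax(trace.signal[peak_mask])])
        # 2 s median around the maximum, never reaching back before the addition
        peak = trace.plateau_median(
            max(t_peak - PEAK_MEDIAN_HALF_S, ev.time), t_peak + PEAK_MEDIAN_HALF_S
        )
        amplitude = peak - baseline

        nxt = events.next_after(ev.time)
        decision = min(
            nxt.time if nxt is not None else np.inf, ev.time + timeout, trace.span[1]
        )
        level = trace.plateau_median(decision - 2.0, decision)
        detected = amplitude > noise_floor
        if not detected:
            warns.append(
                f"step {amplitude:g} afu at t={ev.time:g} s below noise floor {noise_floor:g}"
            )
            log.warning("%s", warns[-1])
        residual = float(np.clip((level - baseline) / amplitude, 0.0, 1.0)) if detected else 1.0

        rate = None
        try:
            rate = uptake_rate(trace, (t_peak, min(t_peak + UPTAKE_WINDOW_S, decision)))
            if rate is not None and rate < 0:
                warns.append(f"rising post-bolus signal at t={ev.time:g} s (Ca release?)")
                log.warning("%s", warns[-1])
        except InsufficientDataError as exc:
            warns.append(str(exc))

        records.append(
            BolusRecord(
                time=ev.time,
                amount=ev.amount,
                sequestered=bool(detected and residual < threshold),
                uptake_rate=rate,
                residual_fraction=residual,
                step_amplitude=float(amplitude),
                decision_time=float(decision),
                warnings=warns,
            )
        )
    return records


def uptake_rate(trace: Trace, window: tuple[float, float]) -> float:
    """Initial Ca²⁺ uptake rate over ``window`` as the negative OLS slope of
    the fluorescence decay (signal units per second; positive = uptake)."""
    t0, t1 = window
    m = trace.mask(t0, t1)
    if int(m.sum()) < 10:
        raise InsufficientDataError(
            f"only {int(m.sum())} samples in uptake window [{t0:g}, {t1:g}), need >= 10"
        )
    res = stats.linregress(trace.time[m], trace.signal[m])
    return float(-res.slope)


def capacity(records: list[BolusRecord], cfg: AssayConfig) -> CapacityResult:
    """Maximum Ca²⁺ uptake capacity per mg protein.

    Counts consecutive sequestered boluses from the start (the first failure
    terminates counting, matching the "until no further decrease" rule; the
    failing addition itself is excluded) and converts via

        capacity = n × bolus_mM × chamber_ml / protein_mg   (mM·ml = µmol).

    ``cfg.capacity_correction`` (default 1, i.e. uncorrected for
    non-mitochondrial protein contamination) multiplies the result.
    """
    n_seq = 0
    for rec in records:
        if not rec.sequestered:
            break
        n_seq += 1
    if records:
        amounts = np.array([r.amount for r in records])
        if np.ptp(amounts) > 1e-9:
            raise HeterogeneityError(
                f"bolus amounts differ ({sorted(set(amounts.tolist()))} mM); "
                "capacity counting requires uniform additions"
            )
        bolus = float(amounts[0])
    else:
        bolus = 0.0
    cap = n_seq * bolus * cfg.chamber_volume / cfg.protein_mass * cfg.capacity_correction
    return CapacityResult(n_sequestered=n_seq, capacity_umol_per_mg=cap, per_bolus=records)


def relative_capacity(
    groups: dict[str, list[CapacityResult]], control: str = "control"
) -> pd.DataFrame:
    """Mean capacity of each treatment group as percent of the control mean.

    Returns a DataFrame indexed by group with columns
    ``mean_umol_per_mg, percent_of_control, n, sem``.  Empty groups are
    omitted with a warning; a missing or zero-capacity control is an error.
    """
    if control not in groups or not groups[control]:
        raise ConfigurationError(f"no group labelled {control!r} with at least one result")
    ctrl_vals = np.array([r.capacity_umol_per_mg for r in groups[control]])
    ctrl_mean = float(ctrl_vals.mean())
    if ctrl_mean <= 0:
        raise ConfigurationError("control mean capacity is 0; relative capacity undefined")
    rows = {}
    for name, results in groups.items():
        if not results:
            log.warning("group %r is empty; omitted from the relative-capacity table", name)
            continue
        vals = np.array([r.capacity_umol_per_mg for r in results])
        sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        rows[name] = {
            "mean_umol_per_mg": float(vals.mean()),
            "percent_of_control": 100.0 * float(vals.mean()) / ctrl_mean,
            "n": int(vals.size),
            "sem": sem,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def classify_swelling(
    scatter_percent: Trace,
    events: EventLog,
    drop_threshold: float = 15.0,
    sustain_s: float = 30.0,
) -> str:
    """Classify a normalized scatter trace as ``"swelling"`` or ``"no_swelling"``.

    Swelling = a sustained (≥ ``sustain_s`` seconds) excursion of the
    pre-alamethicin signal below (100 − ``drop_threshold``) percent.  The
    calibration drop after alamethicin is excluded by construction.
    """
    alm = events.first("alamethicin")
    if alm is None:
        raise EventError("no alamethicin addition: cannot delimit the pre-calibration span")
    t0 = scatter_percent.span[0]
    if alm.time - t0 < 60.0:
        raise InsufficientDataError(
            f"pre-alamethicin span is {alm.time - t0:g} s, need >= 60 s"
        )
    m = scatter_percent.mask(t0, alm.time)
    t = scatter_percent.time[m]
    below = scatter_percent.signal[m] < (100.0 - drop_threshold)
    # longest contiguous run of below-threshold samples, in seconds
    longest = 0.0
    run_start = None
    for i, flag in enumerate(below):
        if flag and run_start is None:
            run_start = t[i]
        elif not flag and run_start is not None:
            longest = max(longest, t[i] - run_start)
            run_start = None
    if run_start is not None:
        longest = max(longest, t[-1] - run_start)
    return "swelling" if longest >= sustain_s else "no_swelling"


def capacity_pipeline(
    trace: Trace,
    events: EventLog,
    cfg: AssayConfig,
    threshold: float = SEQUESTERED_THRESHOLD,
) -> CapacityResult:
    """Detect boluses on a Calcium Green 5N trace and compute capacity."""
    return capacity(detect_boluses(trace, events, threshold=threshold), cfg)
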