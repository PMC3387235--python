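"""Domain containers, file I/O and run configuration shared by all assay stages.

Canonical unit system: time in seconds, concentrations in mM, volume in ml,
protein in mg, temperature in °C.  The single exception is alamethicin, which
is dosed by mass (µg) in the swelling assay.

File formats
------------
* Trace CSV: header ``time_s,<channel>``, UTF-8, ``.`` decimal separator.
* Event CSV: header ``time_s,compound,amount,unit``.
* Config: YAML (JSON is a YAML subset) whose keys are AssayConfig fields.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigurationError,
    InsufficientDataError,
    OrderingError,
    TraceFormatError,
    VocabularyError,
)

log = logging.getLogger("mitotrace")

#: Controlled vocabulary for addition events.
COMPOUNDS = frozenset(
    {
        "CaCl2",
        "ADP",
        "BKA",
        "cATR",
        "NH4OH",
        "cysA",
        "alamethicin",
        "EDTA",
        "MgCl2",
        "SF6847",
        "KCN",
        "dithionite",
        "substrates",
        "oligomycin",
    }
)

#: Compounds dosed by mass; their amounts are stored in µg, not mM.
MASS_DOSED = frozenset({"alamethicin"})

VALID_TRACE_UNITS = frozenset(
    {"afu", "ratio", "uM_O2", "afu_scatter", "percent", "mM", "pmol_O2_s_mg"}
)

# ---------------------------------------------------------------------------
# unit conversion


def to_mM(value: float, unit: str) -> float:
    """Convert a concentration to mM.  Conversions are closed (µM→mM→µM is identity)."""
    factors = {"mM": 1.0, "uM": 1e-3, "M": 1e3, "nM": 1e-6}
    if unit not in factors:
        raise VocabularyError(f"unknown concentration unit {unit!r}; allowed: {sorted(factors)}")
    return value * factors[unit]


def to_ug(value: float, unit: str) -> float:
    """Convert a mass to µg."""
    factors = {"ug": 1.0, "mg": 1e3, "ng": 1e-3}
    if unit not in factors:
        raise VocabularyError(f"unknown mass unit {unit!r}; allowed: {sorted(factors)}")
    return value * factors[unit]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class Trace:
    """A single-channel time series.

    ``time`` must be strictly increasing after deduplication: exactly equal
    consecutive stamps (a fluorimeter export artifact) are collapsed by
    averaging their signal values; decreasing stamps are an error, never
    silently reordered.
    """

    time: np.ndarray
    signal: np.ndarray
    units: str
    channel: str = ""
    #: derived traces (e.g. reconstructions) may carry NaN as a flagged-sample
    #: marker; raw input traces must be finite
    allow_nan: bool = False

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape or self.time.ndim != 1:
            raise TraceFormatError("time and signal must be 1-D arrays of equal length")
        if self.units not in VALID_TRACE_UNITS:
            raise TraceFormatError(f"unknown units {self.units!r}; allowed: {sorted(VALID_TRACE_UNITS)}")
        if not np.all(np.isfinite(self.time)):
            raise TraceFormatError("non-finite time stamps")
        dt = np.diff(self.time)
        if np.any(dt < 0):
            i = int(np.argmax(dt < 0))
            raise OrderingError(
                f"time decreases at index {i + 1} ({self.time[i]:g} -> {self.time[i + 1]:g})"
            )
        if np.any(dt == 0):
            # collapse duplicate stamps by averaging
            uniq, inverse, counts = np.unique(self.time, return_inverse=True, return_counts=True)
            sums = np.zeros_like(uniq)
            np.add.at(sums, inverse, self.signal)
            n_dup = int(self.time.size - uniq.size)
            self.time, self.signal = uniq, sums / counts
            log.warning("collapsed %d duplicate time stamps by averaging", n_dup)
        if self.time.size < 2:
            raise InsufficientDataError(f"trace needs >= 2 samples, got {self.time.size}")
        if not self.allow_nan and not np.all(np.isfinite(self.signal)):
            raise TraceFormatError("non-finite signal values")

    def __len__(self) -> int:
        return int(self.time.size)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.time[0]), float(self.time[-1])

    def mask(self, t0: float, t1: float) -> np.ndarray:
        """Boolean mask of samples with t0 <= time < t1."""
        return (self.time >= t0) & (self.time < t1)

    def crop(self, t0: float, t1: float) -> "Trace":
        m = self.mask(t0, t1)
        if m.sum() < 2:
            raise InsufficientDataError(f"fewer than 2 samples in window [{t0:g}, {t1:g})")
        return Trace(self.time[m], self.signal[m], self.units, self.channel)

    def plateau_median(self, t0: float, t1: float, min_samples: int = 1) -> float:
        """Median signal over [t0, t1)."""
        m = self.mask(t0, t1)
        if m.sum() < min_samples:
            raise InsufficientDataError(
                f"window [{t0:g}, {t1:g}) holds {int(m.sum())} samples, need >= {min_samples}"
            )
        return float(np.median(self.signal[m]))


@dataclass(frozen=True)
class Event:
    time: float
    compound: str
    amount: float  # mM, except µg for mass-dosed compounds
    unit: str  # canonical: "mM" or "ug"
    note: str = ""


@dataclass
class EventLog:
    """Timestamped additions annotating a trace."""

    entries: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.compound not in COMPOUNDS:
                raise VocabularyError(
                    f"unknown compound {e.compound!r}; allowed: {sorted(COMPOUNDS)}"
                )
        self.entries = sorted(self.entries, key=lambda e: e.time)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def of(self, compound: str) -> list[Event]:
        return [e for e in self.entries if e.compound == compound]

    def first(self, compound: str) -> Event | None:
        for e in self.entries:
            if e.compound == compound:
                return e
        return None

    def next_after(self, t: float) -> Event | None:
        """First event strictly after time t."""
        for e in self.entries:
            if e.time > t:
                return e
        return None


@dataclass
class AssayConfig:
    """Buffer/run constants for one assay.

    Defaults mirror the Mg²⁺-indicator exchange buffer: 2 ml chamber, 1 mM
    total Mg²⁺, 2 µM Magnesium Green, and dissociation constants
    Kd_ATP = 0.04 mM < Kd_ADP = 0.35 mM (required for identifiability of the
    speciation inversion) and Kd_MgG = 1.0 mM.
    """

    chamber_volume: float = 2.0  # ml
    protein_mass: float = 1.0  # mg
    temperature: float = 27.0  # °C
    Mg_total: float = 1.0  # mM
    dye_total: float = 0.002  # mM
    adenine_total: float = 0.0  # mM, set from the ADP addition when 0
    Kd_ATP: float = 0.04  # mM
    Kd_ADP: float = 0.35  # mM
    Kd_MgG: float = 1.0  # mM
    pH_o: float = 7.25
    capacity_correction: float = 1.0  # purity correction for capacity; 1 = uncorrected

    def __post_init__(self) -> None:
        for name in ("chamber_volume", "protein_mass", "Mg_total", "dye_total",
                     "Kd_ATP", "Kd_ADP", "Kd_MgG", "capacity_correction"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ConfigurationError(f"{name} must be a positive finite number, got {v!r}")
        if self.adenine_total < 0:
            raise ConfigurationError("adenine_total must be >= 0")
        if self.Kd_ATP >= self.Kd_ADP:
            raise ConfigurationError(
                f"Kd_ATP ({self.Kd_ATP}) must be < Kd_ADP ({self.Kd_ADP}): "
                "equal or inverted affinities make the speciation inversion unidentifiable"
            )

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass
class CalibrationResult:
    """Fitted calibration parameters for an indicator.

    Endpoint calibrations carry only ``F_min``/``F_max`` and no fit-quality
    block; model fits add r² and per-parameter standard errors.
    """

    indicator: str
    params: dict[str, float]
    fit_quality: dict[str, float] | None = None

    def __post_init__(self) -> None:
        p = self.params
        if "F_min" in p and "F_max" in p and not p["F_min"] < p["F_max"]:
            raise CalibrationError(
                f"inverted calibration: F_min ({p['F_min']:g}) >= F_max ({p['F_max']:g})"
            )
        if self.fit_quality is not None:
            r2 = self.fit_quality.get("r_squared")
            if r2 is not None and not (0.0 <= r2 <= 1.0):
                raise CalibrationError(f"r_squared {r2!r} outside [0, 1]")


@dataclass
class AssayReport:
    """Per-assay derived quantities with provenance of the windows used.

    ``derived`` maps a name (units embedded, e.g. ``exchange_rate_mM_per_min``)
    to ``{"value": ..., "window_s": [t0, t1]}``; every scalar names the window
    it came from (``window_s`` may be null for window-free quantities such as
    counts).
    """

    assay_kind: str
    derived: dict[str, dict[str, Any]] = field(default_factory=dict)
    windows: dict[str, list[float]] = field(default_factory=dict)
    config_snapshot: dict[str, float] | None = None
    warnings: list[str] = field(default_factory=list)

    def add(self, name: str, value: Any, window: tuple[float, float] | None = None) -> None:
        entry: dict[str, Any] = {"value": value}
        entry["window_s"] = list(window) if window is not None else None
        self.derived[name] = entry
        if window is not None:
            self.windows[name] = list(window)

    def to_json(self, **kwargs: Any) -> str:
        return json.dumps(dataclasses.asdict(self), default=_json_default, **kwargs)


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# readers / writers


def read_trace(path: str | Path, units: str) -> Trace:
    """Read a trace CSV with header ``time_s,<channel>``.

    Rows with non-finite values are dropped with a logged count; duplicate
    time stamps are averaged; decreasing time stamps raise
    :class:`~mitotrace.errors.OrderingError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise TraceFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    if df.shape[1] != 2 or df.columns[0] != "time_s":
        raise TraceFormatError(
            f"{path}: expected header 'time_s,<channel>', got {list(df.columns)!r}"
        )
    channel = str(df.columns[1])
    vals = df.to_numpy(dtype=float)
    finite = np.isfinite(vals).all(axis=1)
    n_dropped = int((~finite).sum())
    if n_dropped:
        log.warning("%s: dropped %d rows with non-finite values", path.name, n_dropped)
    vals = vals[finite]
    if vals.shape[0] < 2:
        raise InsufficientDataError(f"{path}: fewer than 2 valid rows")
    return Trace(vals[:, 0], vals[:, 1], units=units, channel=channel)


def write_trace(trace: Trace, path: str | Path) -> None:
    """Write a trace CSV; numeric content round-trips at full precision."""
    path = Path(path)
    header = f"time_s,{trace.channel or 'signal'}"
    lines = [header]
    lines += [f"{float(t)!r},{float(s)!r}" for t, s in zip(trace.time, trace.signal)]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_events(path: str | Path) -> EventLog:
    """Read an event CSV with header ``time_s,compound,amount,unit``.

    Amounts are converted to the canonical units (mM; µg for mass-dosed
    compounds such as alamethicin).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"compound": str, "unit": str})
    required = ["time_s", "compound", "amount", "unit"]
    if list(df.columns[:4]) != required:
        raise TraceFormatError(f"{path}: expected header {','.join(required)}")
    entries = []
    for row in df.itertuples(index=False):
        compound = row.compound.strip()
        if compound not in COMPOUNDS:
            raise VocabularyError(
                f"{path}: unknown compound {compound!r}; allowed: {sorted(COMPOUNDS)}"
            )
        note = str(getattr(row, "note", "") or "") if hasattr(row, "note") else ""
        if compound in MASS_DOSED:
            amount, unit = to_ug(float(row.amount), row.unit.strip()), "ug"
        else:
            amount, unit = to_mM(float(row.amount), row.unit.strip()), "mM"
        entries.append(Event(float(row.time_s), compound, amount, unit, note))
    return EventLog(entries)


def write_events(events: EventLog, path: str | Path) -> None:
    path = Path(path)
    lines = ["time_s,compound,amount,unit"]
    lines += [f"{float(e.time)!r},{e.compound},{float(e.amount)!r},{e.unit}" for e in events]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_config(path: str | Path) -> AssayConfig:
    """Load an AssayConfig from a YAML/JSON key-value file.

    Omitted keys take the documented defaults (in particular the three
    dissociation constants); all invariants are checked on construction.
    """
    path = Path(path)
    data = yaml.safe_load(path.read_text(encoding="utf-8"))
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: config must be a mapping, got {type(data).__name__}")
    known = {f.name for f in dataclasses.fields(AssayConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
    return AssayConfig(**{k: float(v) for k, v in data.items()})


def write_config(cfg: AssayConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False), encoding="utf-8")


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def events_within_span(events: EventLog, trace: Trace, slack: float = 1.0) -> bool:
    """True when every event time lies within the trace span ± slack seconds."""
    t0, t1 = trace.span
    return all(t0 - slack <= e.time <= t1 + slack for e in events)
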