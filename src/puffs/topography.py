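"""Puffing-topography signals: flow traces, puff detection, session summaries.

A topography record is a time series of the volumetric flow rate drawn through
an e-cigarette mouthpiece, sampled by a wearable monitor or an emissions
machine.  This module turns that raw signal into discrete puffs — each with a
duration ``d`` [s], mean flow rate ``q`` [mL/s] and volume ``v = q·d`` [mL] —
and groups puffs into use sessions.  Those per-puff ``(q, d, v)`` triples are
the user-behaviour inputs of the emissions models in :mod:`puffs.emissions`.

Units are fixed throughout the package: time in seconds, flow in mL/s,
volume in mL.  Convert at the I/O boundary if your instrument logs anything
else; the emissions-model coefficients are bound to these units.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import yaml

from .errors import ParseError, StructuralError

__all__ = [
    "FlowTrace",
    "Puff",
    "Session",
    "SessionSummary",
    "read_flow_trace",
    "write_flow_trace",
    "load_session_trace",
    "detect_puffs",
    "session_summary",
    "write_puffs",
    "DEFAULT_THRESHOLD",
    "DEFAULT_MIN_DURATION",
    "DEFAULT_MIN_GAP",
]

#: Default puff-detection parameters.  The source data carry no detection rule,
#: so these are package defaults: a 1 mL/s threshold sits well below any
#: deliberate draw but above sensor noise; 0.1 s discards glitches; below-
#: threshold dips shorter than 0.3 s within a draw are bridged.
DEFAULT_THRESHOLD = 1.0
DEFAULT_MIN_DURATION = 0.1
DEFAULT_MIN_GAP = 0.3

TRACE_HEADER = ("time_s", "flow_ml_s")


@dataclass(frozen=True)
class FlowTrace:
    """A time-stamped volumetric flow-rate stream.

    Attributes
    ----------
    time : ndarray, seconds, strictly increasing
    flow : ndarray, mL/s, non-negative and finite
    n_clipped : number of negative raw samples clipped to zero on ingest
    meta : free-form metadata (e.g. from ``#`` header lines or a YAML sidecar)
    """

    time: np.ndarray
    flow: np.ndarray
    n_clipped: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.flow, dtype=float)
        if t.ndim != 1 or f.ndim != 1 or t.shape != f.shape:
            raise StructuralError("time and flow must be 1-D arrays of equal length")
        if t.size and not np.all(np.isfinite(t)):
            raise StructuralError("non-finite timestamps in trace")
        if t.size and not np.all(np.isfinite(f)):
            raise StructuralError("non-finite flow values in trace")
        if t.size and np.any(np.diff(t) <= 0):
            i = int(np.argmax(np.diff(t) <= 0))
            raise StructuralError(
                f"time must be strictly increasing; violation after sample {i} "
                f"(t={t[i]:g} followed by t={t[i + 1]:g})"
            )
        if t.size and np.any(f < 0):
            raise StructuralError("negative flow in trace; clip on ingest")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "flow", f)

    def __len__(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        """Span of the trace in seconds (0 for traces with < 2 samples)."""
        return float(self.time[-1] - self.time[0]) if len(self) > 1 else 0.0

    def total_volume(self) -> float:
        """Trapezoidal integral of flow over the whole trace [mL]."""
        if len(self) < 2:
            return 0.0
        return float(np.trapezoid(self.flow, self.time))


@dataclass(frozen=True)
class Puff:
    """One discrete puff: start time, duration ``d``, volume ``v``, mean flow ``q``.

    ``q`` is the volume-weighted mean flow ``v / d`` rather than the arithmetic
    mean of samples, so that ``q · d = v`` holds as an identity — the form the
    per-puff yield summation relies on.
    """

    start: float
    duration: float
    volume: float

    def __post_init__(self) -> None:
        if not (self.duration > 0):
            raise StructuralError(f"puff duration must be positive, got {self.duration!r}")
        if not (self.volume > 0):
            raise StructuralError(f"puff volume must be positive, got {self.volume!r}")

    @property
    def mean_flow(self) -> float:
        """Mean flow rate q = v / d [mL/s]."""
        return self.volume / self.duration

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class Session:
    """An ordered collection of non-overlapping puffs from one use session."""

    puffs: tuple[Puff, ...]
    session_id: str = ""
    participant_id: str = ""

    def __post_init__(self) -> None:
        puffs = tuple(self.puffs)
        if not puffs:
            raise StructuralError("a session must contain at least one puff")
        for a, b in zip(puffs, puffs[1:]):
            if b.start < a.end:
                raise StructuralError(
                    f"puffs overlap or are out of order: one ends at {a.end:g} s, "
                    f"next starts at {b.start:g} s"
                )
        object.__setattr__(self, "puffs", puffs)

    def __len__(self) -> int:
        return len(self.puffs)

    def intervals(self) -> np.ndarray:
        """Inter-puff intervals i_n = start_{n+1} − end_n [s]."""
        return np.array([b.start - a.end for a, b in zip(self.puffs, self.puffs[1:])])


class SessionSummary(NamedTuple):
    """Per-session topography summary in the conventional reporting order."""

    mean_duration: float
    mean_flow: float
    total_volume: float
    n_puffs: int


def session_summary(session: Session) -> SessionSummary:
    """Arithmetic mean of per-puff d and q, total volume, and puff count."""
    d = np.array([p.duration for p in session.puffs])
    q = np.array([p.mean_flow for p in session.puffs])
    v = np.array([p.volume for p in session.puffs])
    return SessionSummary(float(d.mean()), float(q.mean()), float(v.sum()), len(session))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_flow_trace(path: str | os.PathLike, *, clip_negative: bool = True) -> FlowTrace:
    """Read a two-column topography CSV into a :class:`FlowTrace`.

    The format is ``time_s,flow_ml_s`` with optional ``#``-prefixed metadata
    lines; a header row is optional (files may start directly with numbers).
    Negative flows are clipped to zero and counted in ``FlowTrace.n_clipped``;
    duplicate or decreasing timestamps are rejected.
    """
    meta: dict = {}
    times: list[float] = []
    flows: list[float] = []
    header_seen = False
    with open(path, "r", newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            first = row[0].lstrip()
            if first.startswith("#"):
                text = ",".join([first[1:]] + row[1:]).strip()
                if ":" in text:
                    key, _, val = text.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            if len(row) < 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 columns, got {len(row)}")
            try:
                t, f = float(row[0]), float(row[1])
            except ValueError:
                # at most one non-numeric row is tolerated: the column header
                if not header_seen and not times and _looks_like_header(row):
                    header_seen = True
                    continue
                raise ParseError(
                    f"{path}: line {lineno}: could not parse row {row!r} as numbers"
                ) from None
            if not (np.isfinite(t) and np.isfinite(f)):
                raise ParseError(f"{path}: line {lineno}: non-finite value in row {row!r}")
            times.append(t)
            flows.append(f)
    t_arr = np.asarray(times)
    f_arr = np.asarray(flows)
    n_clipped = 0
    if clip_negative and f_arr.size:
        n_clipped = int(np.sum(f_arr < 0))
        f_arr = np.clip(f_arr, 0.0, None)
    try:
        return FlowTrace(t_arr, f_arr, n_clipped=n_clipped, meta=meta)
    except StructuralError as exc:
        raise StructuralError(f"{path}: {exc}") from None


def _looks_like_header(row: Sequence[str]) -> bool:
    try:
        float(row[0])
        return False
    except ValueError:
        return True


def write_flow_trace(trace: FlowTrace, path: str | os.PathLike) -> None:
    """Write a trace in the canonical CSV dialect (full float precision)."""
    with open(path, "w", newline="") as fh:
        for key, val in trace.meta.items():
            fh.write(f"# {key}: {val}\n")
        fh.write(",".join(TRACE_HEADER) + "\n")
        for t, f in zip(trace.time, trace.flow):
            fh.write(f"{float(t)!r},{float(f)!r}\n")


def load_session_trace(path: str | os.PathLike) -> FlowTrace:
    """Read a session trace CSV together with its YAML sidecar, if present.

    The sidecar shares the CSV's stem with a ``.yaml`` suffix and carries
    ``session_id`` / ``participant_id``; its keys are merged into the trace
    metadata (sidecar wins over in-file ``#`` lines).
    """
    trace = read_flow_trace(path)
    base, _ = os.path.splitext(os.fspath(path))
    for suffix in (".yaml", ".yml"):
        sidecar = base + suffix
        if os.path.exists(sidecar):
            with open(sidecar) as fh:
                data = yaml.safe_load(fh) or {}
            if not isinstance(data, dict):
                raise ParseError(f"{sidecar}: sidecar must be a YAML mapping")
            trace.meta.update(data)
            break
    return trace


def write_puffs(puffs: Iterable[Puff], path_or_buf) -> None:
    """Write detected puffs as CSV (start_s, duration_s, mean_flow_ml_s, volume_ml)."""
    own = isinstance(path_or_buf, (str, os.PathLike))
    fh = open(path_or_buf, "w", newline="") if own else path_or_buf
    try:
        fh.write("start_s,duration_s,mean_flow_ml_s,volume_ml\n")
        for p in puffs:
            fh.write(
                f"{float(p.start)!r},{float(p.duration)!r},"
                f"{float(p.mean_flow)!r},{float(p.volume)!r}\n"
            )
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------
# Puff detection
# ---------------------------------------------------------------------------

def detect_puffs(
    trace: FlowTrace,
    threshold: float = DEFAULT_THRESHOLD,
    min_duration: float = DEFAULT_MIN_DURATION,
    min_gap: float = DEFAULT_MIN_GAP,
) -> list[Puff]:
    """Segment a flow trace into discrete puffs by threshold crossing.

    A puff is a maximal run of samples with ``flow >= threshold``.  Runs
    separated by a below-threshold gap shorter than ``min_gap`` are merged
    (the gap samples are included in the merged window, so volume is the
    trapezoidal integral over the whole window).  Runs whose duration is
    below ``min_duration`` are discarded.  An empty or all-quiet trace
    yields an empty list.

    Parameters
    ----------
    threshold : mL/s, must be positive.
    min_duration : s, runs shorter than this are dropped.
    min_gap : s, below-threshold dips shorter than this are bridged.
    """
    if not threshold > 0:
        raise ValueError(f"threshold must be positive, got {threshold!r}")
    if min_duration < 0:
        raise ValueError(f"min_duration must be >= 0, got {min_duration!r}")
    if min_gap < 0:
        raise ValueError(f"min_gap must be >= 0, got {min_gap!r}")
    if len(trace) == 0:
        return []

    above = trace.flow >= threshold
    if not above.any():
        return []

    runs = _runs(above)

    # merge runs separated by short gaps
    merged: list[tuple[int, int]] = []
    for i0, i1 in runs:
        if merged and trace.time[i0] - trace.time[merged[-1][1]] < min_gap:
            merged[-1] = (merged[-1][0], i1)
        else:
            merged.append((i0, i1))

    puffs: list[Puff] = []
    for i0, i1 in merged:
        d = float(trace.time[i1] - trace.time[i0])
        if d < min_duration or d <= 0:
            continue
        v = float(np.trapezoid(trace.flow[i0 : i1 + 1], trace.time[i0 : i1 + 1]))
        if v <= 0:
            continue
        puffs.append(Puff(start=float(trace.time[i0]), duration=d, volume=v))
    return puffs


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, stop) index pairs of consecutive True runs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[breaks + 1]]
    stops = np.r_[idx[breaks], idx[-1]]
    return list(zip(starts.tolist(), stops.tolist()))
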