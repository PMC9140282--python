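"""Trial-level behavioural records for the light-off jump assay.

The assay exposes single flies, seated in one of 16 chambers on one of two
recording systems, to a train of brief light-off pulses.  Wing-vibration
noise is recorded for 500 ms after each pulse; a supra-threshold amplitude
anywhere in that window counts as a jump.  This module holds the protocol
presets, converts raw amplitude traces into per-trial jump booleans, reads
long-format trial tables, and assembles per-fly sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConflictError,
    IncompleteSessionError,
    InvalidInputError,
    ParseError,
    SchemaError,
)

__all__ = [
    "Protocol",
    "HABITUATION",
    "FATIGUE",
    "get_protocol",
    "AmplitudeTrace",
    "FlySession",
    "detect_jump",
    "parse_events_table",
    "parse_trace_table",
    "score_traces",
    "assemble_sessions",
    "sessions_to_frame",
]


@dataclass(frozen=True)
class Protocol:
    """Stimulation protocol constants.

    The habituation protocol delivers 100 light-off pulses (15 ms each) at
    1 s intervals; the fatigue control delivers 50 pulses at 5 s intervals,
    an inter-trial spacing long enough to prevent habituation so that
    persistent jumping distinguishes learning from motor exhaustion.
    """

    name: str
    n_trials: int
    inter_trial_interval_s: float
    pulse_duration_ms: float = 15.0
    record_window_ms: float = 500.0

    def __post_init__(self) -> None:
        if self.n_trials <= 0:
            raise InvalidInputError("n_trials must be positive")
        if self.inter_trial_interval_s <= 0:
            raise InvalidInputError("inter_trial_interval_s must be positive")


HABITUATION = Protocol("habituation", n_trials=100, inter_trial_interval_s=1.0)
FATIGUE = Protocol("fatigue", n_trials=50, inter_trial_interval_s=5.0)

_PRESETS: Mapping[str, Protocol] = {"habituation": HABITUATION, "fatigue": FATIGUE}


def get_protocol(name: str) -> Protocol:
    """Return a named protocol preset (``habituation`` or ``fatigue``)."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise InvalidInputError(
            f"unknown protocol {name!r}; expected one of {sorted(_PRESETS)}"
        ) from None


@dataclass
class AmplitudeTrace:
    """Raw wing-vibration amplitudes for one trial of one fly.

    Samples cover the 500 ms post-stimulus recording window; amplitudes are
    non-negative in arbitrary hardware units.
    """

    fly_id: str
    trial_index: int  # 1-based
    samples: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise InvalidInputError("trace has no samples")
        if np.any(self.samples < 0):
            raise InvalidInputError("trace amplitudes must be non-negative")
        if self.sample_rate_hz <= 0:
            raise InvalidInputError("sample_rate_hz must be positive")
        if self.trial_index < 1:
            raise InvalidInputError("trial_index is 1-based and must be >= 1")


@dataclass
class FlySession:
    """One fly's ordered jump outcomes under a protocol, with batch labels.

    ``day`` and ``system`` are the batch covariates the downstream linear
    model corrects for; ``chamber`` is 1-16 within a system.
    """

    fly_id: str
    genotype: str
    day: str
    system: str
    chamber: int
    protocol: Protocol
    jumps: tuple[bool, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.jumps = tuple(bool(j) for j in self.jumps)
        if len(self.jumps) != self.protocol.n_trials:
            raise InvalidInputError(
                f"fly {self.fly_id!r}: {len(self.jumps)} jump outcomes but "
                f"protocol {self.protocol.name!r} has {self.protocol.n_trials} trials"
            )


def detect_jump(trace: AmplitudeTrace, threshold: float) -> bool:
    """True iff any sample in the recording window reaches ``threshold``.

    The threshold is in the raw amplitude units of the trace; it plays the
    role of the noise-rejection threshold the recording rig applies and is a
    per-run configuration value rather than something auto-calibrated here.
    """
    if threshold <= 0:
        raise InvalidInputError("threshold must be positive")
    return bool(np.max(trace.samples) >= threshold)


_DEFAULT_TRUE = frozenset({"true", "1", "yes", "t", "y"})
_DEFAULT_FALSE = frozenset({"false", "0", "no", "f", "n"})

_REQUIRED_COLUMNS = ("fly_id", "genotype", "day", "system", "chamber", "trial", "jumped")


def parse_events_table(
    path,
    sep: str = ",",
    true_values: Iterable[str] = _DEFAULT_TRUE,
    false_values: Iterable[str] = _DEFAULT_FALSE,
) -> pd.DataFrame:
    """Read a long-format trial table into a validated DataFrame.

    Expected columns: fly_id, genotype, day, system, chamber, trial, jumped.
    The boolean vocabulary for ``jumped`` is configurable (e.g. yes/no).
    Malformed rows are reported with their 1-based file line numbers.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    truths = {str(v).strip().lower() for v in true_values}
    falses = {str(v).strip().lower() for v in false_values}

    bad_lines: list[int] = []
    jumped = np.empty(len(df), dtype=bool)
    trial = np.empty(len(df), dtype=int)
    chamber = np.empty(len(df), dtype=int)
    for i, (raw_j, raw_t, raw_c) in enumerate(
        zip(df["jumped"], df["trial"], df["chamber"])
    ):
        line_no = i + 2  # 1-based, after the header line
        tok = str(raw_j).strip().lower()
        if tok in truths:
            jumped[i] = True
        elif tok in falses:
            jumped[i] = False
        else:
            bad_lines.append(line_no)
            continue
        try:
            trial[i] = int(raw_t)
            chamber[i] = int(raw_c)
        except ValueError:
            bad_lines.append(line_no)
    if bad_lines:
        raise ParseError(
            f"{len(bad_lines)} malformed row(s) at line(s) "
            f"{', '.join(map(str, bad_lines[:20]))}",
            lines=bad_lines,
        )

    out = df[["fly_id", "genotype", "day", "system"]].copy()
    out["chamber"] = chamber
    out["trial"] = trial
    out["jumped"] = jumped
    return out


def parse_trace_table(path, sample_rate_hz: float, sep: str = ",") -> list[AmplitudeTrace]:
    """Read a raw-trace table (fly_id, trial, sample_index, amplitude)."""
    df = pd.read_csv(path, sep=sep)
    required = ("fly_id", "trial", "sample_index", "amplitude")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    traces = []
    for (fly, trial), grp in df.groupby(["fly_id", "trial"], sort=True):
        grp = grp.sort_values("sample_index")
        traces.append(
            AmplitudeTrace(
                fly_id=str(fly),
                trial_index=int(trial),
                samples=grp["amplitude"].to_numpy(float),
                sample_rate_hz=sample_rate_hz,
            )
        )
    return traces


def score_traces(
    traces: Sequence[AmplitudeTrace],
    threshold: float,
    metadata: Mapping[str, Mapping[str, object]],
) -> pd.DataFrame:
    """Apply jump detection to raw traces and emit a trial-record frame.

    ``metadata`` maps fly_id to a dict with genotype/day/system/chamber.
    """
    rows = []
    for tr in traces:
        meta = metadata.get(tr.fly_id, {})
        rows.append(
            {
                "fly_id": tr.fly_id,
                "genotype": meta.get("genotype", "unknown"),
                "day": meta.get("day", "1"),
                "system": meta.get("system", "1"),
                "chamber": int(meta.get("chamber", 1)),
                "trial": tr.trial_index,
                "jumped": detect_jump(tr, threshold),
            }
        )
    return pd.DataFrame(rows)


def assemble_sessions(records: pd.DataFrame, protocol: Protocol) -> list[FlySession]:
    """Group trial records by fly into complete, ordered sessions.

    Each fly must contribute exactly one record per trial index 1..n_trials.
    The result is independent of the input row order.
    """
    sessions: list[FlySession] = []
    n = protocol.n_trials
    for fly_id, grp in records.groupby("fly_id", sort=True):
        trials = grp["trial"].to_numpy(int)
        if len(np.unique(trials)) != len(trials):
            dup = int(trials[pd.Series(trials).duplicated()].min())
            raise ConflictError(f"fly {fly_id!r}: duplicate record for trial {dup}")
        expected = np.arange(1, n + 1)
        present = np.sort(trials)
        if len(present) != n or not np.array_equal(present, expected):
            missing = sorted(set(expected) - set(present))
            extra = sorted(set(present) - set(expected))
            detail = []
            if missing:
                detail.append(f"missing trials {missing[:5]}")
            if extra:
                detail.append(f"unexpected trials {extra[:5]}")
            raise IncompleteSessionError(
                f"fly {fly_id!r}: expected trials 1..{n}; " + "; ".join(detail)
            )
        grp = grp.sort_values("trial")
        meta = grp.iloc[0]
        sessions.append(
            FlySession(
                fly_id=str(fly_id),
                genotype=str(meta["genotype"]),
                day=str(meta["day"]),
                system=str(meta["system"]),
                chamber=int(meta["chamber"]),
                protocol=protocol,
                jumps=tuple(bool(j) for j in grp["jumped"]),
            )
        )
    return sessions


def sessions_to_frame(sessions: Sequence[FlySession]) -> pd.DataFrame:
    """Flatten sessions back to a long-format trial table."""
    rows = []
    for s in sessions:
        for t, j in enumerate(s.jumps, start=1):
            rows.append(
                {
                    "fly_id": s.fly_id,
                    "genotype": s.genotype,
                    "day": s.day,
                    "system": s.system,
                    "chamber": s.chamber,
                    "trial": t,
                    "jumped": j,
                }
            )
    return pd.DataFrame(rows)
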