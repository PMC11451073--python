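"""Readers and writers for the formats the pipeline touches.

Audio travels as PCM WAV, annotations as Praat TextGrid interval tiers
(long and short text dialects, UTF-8 or UTF-16), behavioural records as
flat CSV session logs, and session plans as CSV/JSON playlists.  All
readers validate; correctness flags in session logs are recomputed from
stimulus/response agreement rather than trusted.
"""

from __future__ import annotations

import csv
import io
import json
import re
import wave
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Waveform",
    "AnnotatedInterval",
    "TrialResult",
    "SessionRecord",
    "ExperimentLog",
    "read_wave",
    "write_wave",
    "read_annotations",
    "write_annotations",
    "read_session_log",
    "write_session_log",
    "write_playlist",
    "read_playlist",
]

SESSION_LOG_COLUMNS = [
    "session_id",
    "trial_index",
    "stimulus_type",
    "response_type",
    "correct",
    "repeat_flag",
    "terminated",
]


@dataclass
class Waveform:
    """Mono audio signal: float samples in [-1, 1] plus a sampling rate in Hz."""

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("waveform must be one-dimensional (mono)")
        if self.samples.size == 0:
            raise ValueError("waveform must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    def slice(self, start: float, end: float) -> "Waveform":
        """Extract the half-open time interval [start, end) as a new Waveform."""
        i0 = int(round(start * self.rate))
        i1 = int(round(end * self.rate))
        if start < 0 or i1 > self.samples.size or i0 >= i1:
            raise ValueError(
                f"interval [{start}, {end}) out of bounds for "
                f"{self.duration:.6f} s recording"
            )
        return Waveform(self.samples[i0:i1].copy(), self.rate)


@dataclass(frozen=True)
class AnnotatedInterval:
    """A labelled time interval [start, end) on a recording, in seconds."""

    start: float
    end: float
    label: str
    quality_ok: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if not self.label:
            raise ValueError("interval label must be non-empty")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class TrialResult:
    trial_index: int
    stimulus_type: int
    response_type: int
    correct: bool
    repeat_flag: bool = False


@dataclass
class SessionRecord:
    session_id: int
    trials: list[TrialResult]
    terminated: bool = False
    experiment: str = "1"

    def __post_init__(self) -> None:
        if not self.trials:
            raise ValueError(f"session {self.session_id} has no trials")


@dataclass
class ExperimentLog:
    """Ordered sessions of trial results; terminated sessions stay flagged."""

    sessions: list[SessionRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.session_id for s in self.sessions]
        if any(b <= a for a, b in zip(ids, ids[1:])):
            raise ValueError("session ids must be strictly increasing")

    def valid_sessions(self) -> list[SessionRecord]:
        """Sessions retained for analysis (terminated ones are excluded)."""
        return [s for s in self.sessions if not s.terminated]


# --------------------------------------------------------------------------
# WAV
# --------------------------------------------------------------------------

_PCM_SCALE = {2: 2**15, 3: 2**23, 4: 2**31}


def read_wave(path: str | Path) -> Waveform:
    """Read a PCM WAV file (16/24/32-bit) into a [-1, 1]-scaled Waveform.

    Multi-channel files are averaged to mono.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with wave.open(str(path), "rb") as wf:
        nchan = wf.getnchannels()
        width = wf.getsampwidth()
        rate = wf.getframerate()
        nframes = wf.getnframes()
        raw = wf.readframes(nframes)
    if width not in _PCM_SCALE:
        raise ValueError(f"unsupported PCM sample width: {width * 8} bit")
    if nframes == 0:
        raise ValueError(f"empty audio file: {path}")
    if width == 3:  # 24-bit: sign-extend into int32
        b = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 3)
        ints = (
            b[:, 0].astype(np.int32)
            | (b[:, 1].astype(np.int32) << 8)
            | (b[:, 2].astype(np.int8).astype(np.int32) << 16)
        )
    else:
        ints = np.frombuffer(raw, dtype=f"<i{width}").astype(np.int64)
    samples = ints.astype(np.float64) / _PCM_SCALE[width]
    if nchan > 1:
        samples = samples.reshape(-1, nchan).mean(axis=1)
    return Waveform(samples, rate)


def write_wave(path: str | Path, w: Waveform, bit_depth: int = 16) -> None:
    """Write a Waveform as PCM WAV at 16 or 24 bit; samples are clipped to full scale."""
    if bit_depth not in (16, 24):
        raise ValueError("bit_depth must be 16 or 24")
    width = bit_depth // 8
    scale = _PCM_SCALE[width]
    ints = np.round(w.samples * scale).astype(np.int64)
    ints = np.clip(ints, -scale, scale - 1)
    if width == 3:
        u = ints.astype(np.int32)
        raw = np.empty((u.size, 3), dtype=np.uint8)
        raw[:, 0] = u & 0xFF
        raw[:, 1] = (u >> 8) & 0xFF
        raw[:, 2] = (u >> 16) & 0xFF
        data = raw.tobytes()
    else:
        data = ints.astype("<i2").tobytes()
    with wave.open(str(path), "wb") as wf:
        wf.setnchannels(1)
        wf.setsampwidth(width)
        wf.setframerate(w.rate)
        wf.writeframes(data)


# --------------------------------------------------------------------------
# Praat TextGrid
# --------------------------------------------------------------------------

_TG_NUMBER = re.compile(r"^[+-]?\d+(\.\d*)?([eE][+-]?\d+)?$")


def _decode_textgrid(data: bytes) -> str:
    if data.startswith(b"\xfe\xff") or data.startswith(b"\xff\xfe"):
        return data.decode("utf-16")
    return data.decode("utf-8-sig")


def _tokenize_textgrid(text: str) -> list[str]:
    """Reduce a long- or short-format TextGrid to its bare value stream.

    Long format carries ``key = value`` lines plus structural lines such as
    ``item [1]:``; short format carries bare values.  Both reduce to the same
    positional token sequence once keys and structural lines are stripped.
    """
    tokens: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if "=" in line:
            line = line.split("=", 1)[1].strip()
            if not line:
                tokens.append('""')
                continue
        if line.startswith('"') or _TG_NUMBER.match(line):
            tokens.append(line)
        # anything else ("item []:", "intervals [3]:", "<exists>") is structure
    return tokens


class _TokenStream:
    def __init__(self, tokens: Sequence[str]):
        self._tokens = list(tokens)
        self._pos = 0

    def next_number(self) -> float:
        tok = self._next()
        try:
            return float(tok)
        except ValueError:
            raise ValueError(f"malformed TextGrid: expected number, got {tok!r}")

    def next_string(self) -> str:
        tok = self._next()
        if not (tok.startswith('"') and tok.endswith('"') and len(tok) >= 2):
            raise ValueError(f"malformed TextGrid: expected string, got {tok!r}")
        return tok[1:-1].replace('""', '"')

    def _next(self) -> str:
        if self._pos >= len(self._tokens):
            raise ValueError("malformed TextGrid: unexpected end of file")
        tok = self._tokens[self._pos]
        self._pos += 1
        return tok


def _parse_textgrid(text: str) -> dict[str, list[tuple[float, float, str]]]:
    if "ooTextFile" not in text or "TextGrid" not in text:
        raise ValueError("not a Praat TextGrid file")
    body = text.split('"TextGrid"', 1)[1]
    stream = _TokenStream(_tokenize_textgrid(body))
    stream.next_number()  # global xmin
    stream.next_number()  # global xmax
    n_tiers = int(stream.next_number())
    tiers: dict[str, list[tuple[float, float, str]]] = {}
    for _ in range(n_tiers):
        klass = stream.next_string()
        name = stream.next_string()
        stream.next_number()  # tier xmin
        stream.next_number()  # tier xmax
        n_items = int(stream.next_number())
        if klass == "IntervalTier":
            items = []
            for _ in range(n_items):
                xmin = stream.next_number()
                xmax = stream.next_number()
                label = stream.next_string()
                items.append((xmin, xmax, label))
            tiers[name] = items
        elif klass == "TextTier":
            for _ in range(n_items):  # point tiers: skip number + mark
                stream.next_number()
                stream.next_string()
            tiers[name] = []
        else:
            raise ValueError(f"malformed TextGrid: unknown tier class {klass!r}")
    return tiers


def read_annotations(path: str | Path, tier: str) -> list[AnnotatedInterval]:
    """Read labelled intervals from one interval tier of a Praat TextGrid.

    Empty-labelled (silence) intervals are dropped; the result is sorted by
    start time.  Overlapping labelled intervals raise, since a single tier
    partitions the time axis.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    tiers = _parse_textgrid(_decode_textgrid(path.read_bytes()))
    if tier not in tiers:
        raise KeyError(f"tier {tier!r} not found; available: {sorted(tiers)}")
    intervals = [
        AnnotatedInterval(xmin, xmax, label.strip())
        for xmin, xmax, label in tiers[tier]
        if label.strip()
    ]
    intervals.sort(key=lambda iv: iv.start)
    for a, b in zip(intervals, intervals[1:]):
        if b.start < a.end:
            raise ValueError(
                f"overlapping labelled intervals in tier {tier!r}: "
                f"[{a.start}, {a.end}) {a.label!r} and [{b.start}, {b.end}) {b.label!r}"
            )
    return intervals


def write_annotations(
    path: str | Path,
    intervals: Iterable[AnnotatedInterval],
    tier: str = "vocalizations",
    xmax: float | None = None,
) -> None:
    """Write intervals as a long-format TextGrid with a single interval tier.

    Gaps between labelled intervals are filled with empty-label intervals so
    the tier partitions [0, xmax], as Praat requires.
    """
    ivs = sorted(intervals, key=lambda iv: iv.start)
    if xmax is None:
        xmax = ivs[-1].end if ivs else 1.0
    rows: list[tuple[float, float, str]] = []
    cursor = 0.0
    for iv in ivs:
        if iv.start > cursor:
            rows.append((cursor, iv.start, ""))
        rows.append((iv.start, iv.end, iv.label))
        cursor = iv.end
    if cursor < xmax:
        rows.append((cursor, xmax, ""))
    out = io.StringIO()
    out.write('File type = "ooTextFile"\nObject class = "TextGrid"\n\n')
    out.write(f"xmin = 0\nxmax = {xmax!r}\ntiers? <exists>\nsize = 1\nitem []:\n")
    out.write('    item [1]:\n        class = "IntervalTier"\n')
    out.write(f'        name = "{tier}"\n        xmin = 0\n        xmax = {xmax!r}\n')
    out.write(f"        intervals: size = {len(rows)}\n")
    for i, (xmin_i, xmax_i, label) in enumerate(rows, 1):
        esc = label.replace('"', '""')
        out.write(f"        intervals [{i}]:\n")
        out.write(f"            xmin = {xmin_i!r}\n            xmax = {xmax_i!r}\n")
        out.write(f'            text = "{esc}"\n')
    Path(path).write_text(out.getvalue(), encoding="utf-8")


# --------------------------------------------------------------------------
# Session logs
# --------------------------------------------------------------------------


def read_session_log(path: str | Path) -> tuple[ExperimentLog, list[str]]:
    """Load a trial-level CSV session log.

    The ``correct`` column is recomputed as ``stimulus_type == response_type``;
    rows whose stored flag disagrees are reported in the returned warning list
    and the recomputed value is used.  Terminated sessions are loaded but
    flagged, so analysis defaults can exclude them.

    Returns (log, warnings).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty session log: {path}")
    missing = [c for c in SESSION_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"session log missing columns: {missing}")
    if df.empty:
        raise ValueError(f"session log has no trials: {path}")
    warnings: list[str] = []
    sessions: list[SessionRecord] = []
    experiment_col = df["experiment"] if "experiment" in df.columns else None
    for sid, grp in df.groupby("session_id", sort=True):
        grp = grp.sort_values("trial_index")
        trials = []
        for row in grp.itertuples():
            recomputed = int(row.stimulus_type) == int(row.response_type)
            if bool(row.correct) != recomputed:
                warnings.append(
                    f"session {sid} trial {row.trial_index}: stored correct="
                    f"{bool(row.correct)} disagrees with stimulus/response; recomputed"
                )
            trials.append(
                TrialResult(
                    trial_index=int(row.trial_index),
                    stimulus_type=int(row.stimulus_type),
                    response_type=int(row.response_type),
                    correct=recomputed,
                    repeat_flag=bool(row.repeat_flag),
                )
            )
        sessions.append(
            SessionRecord(
                session_id=int(sid),
                trials=trials,
                terminated=bool(grp["terminated"].any()),
                experiment=str(experiment_col.loc[grp.index[0]]) if experiment_col is not None else "1",
            )
        )
    return ExperimentLog(sessions), warnings


def write_session_log(path: str | Path, log: ExperimentLog) -> None:
    rows = []
    for s in log.sessions:
        for t in s.trials:
            rows.append(
                {
                    "session_id": s.session_id,
                    "trial_index": t.trial_index,
                    "stimulus_type": t.stimulus_type,
                    "response_type": t.response_type,
                    "correct": int(t.correct),
                    "repeat_flag": int(t.repeat_flag),
                    "terminated": int(s.terminated),
                    "experiment": s.experiment,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# --------------------------------------------------------------------------
# Playlists
# --------------------------------------------------------------------------


def write_playlist(path: str | Path, plan, fmt: str = "csv") -> None:
    """Write a session plan as a playlist (CSV or JSON).

    `plan` is a session_design.SessionPlan; stored columns are trial index,
    stimulus id and vocal type, plus the experiment id and seed as metadata.
    """
    path = Path(path)
    records = [
        {"trial_index": i + 1, "stimulus_id": sid, "stimulus_type": stype}
        for i, (sid, stype) in enumerate(plan.trials)
    ]
    if fmt == "json":
        payload = {"experiment": plan.experiment, "seed": plan.seed, "trials": records}
        path.write_text(json.dumps(payload, indent=1))
    elif fmt == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["trial_index", "stimulus_id", "stimulus_type", "experiment", "seed"]
            )
            writer.writeheader()
            for rec in records:
                writer.writerow({**rec, "experiment": plan.experiment, "seed": plan.seed})
    else:
        raise ValueError(f"unknown playlist format: {fmt}")


def read_playlist(path: str | Path):
    """Read a playlist written by write_playlist back into a SessionPlan."""
    from .session_design import SessionPlan

    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        trials = [(r["stimulus_id"], int(r["stimulus_type"])) for r in payload["trials"]]
        return SessionPlan(experiment=int(payload["experiment"]), trials=trials, seed=int(payload["seed"]))
    df = pd.read_csv(path)
    trials = [(str(r.stimulus_id), int(r.stimulus_type)) for r in df.itertuples()]
    return SessionPlan(experiment=int(df["experiment"].iloc[0]), trials=trials, seed=int(df["seed"].iloc[0]))
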