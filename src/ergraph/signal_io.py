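"""Waveform I/O, min-max normalization and amplitude quantization.

A recording is a short single-channel transient (a few hundred samples at
2 kHz for a photopic electroretinogram) plus acquisition metadata: subject,
diagnostic group, sex, eye, flash strength in Troland-seconds, and a
recording index (subjects contribute 1-4 repeats per eye x flash).

Two CSV dialects are supported.  The canonical *long* dialect has one row
per sample::

    subject_id, group, sex, eye, flash_td, recording_index, sample_index, amplitude_uv

with ``sample_index`` 0-based and contiguous within a recording.  The *wide*
dialect has one row per recording: the metadata columns followed by
``s0 ... s{N-1}`` amplitude columns.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Group",
    "Sex",
    "Eye",
    "Waveform",
    "QuantizedSignal",
    "read_waveforms",
    "write_waveforms",
    "normalize",
    "quantize",
    "LONG_COLUMNS",
]


class Group(str, enum.Enum):
    """Diagnostic group label."""

    ASD = "ASD"
    ADHD = "ADHD"
    ASD_ADHD = "ASD_ADHD"
    CONTROL = "CONTROL"
    UNKNOWN = "UNKNOWN"


class Sex(str, enum.Enum):
    M = "M"
    F = "F"
    UNKNOWN = "UNKNOWN"


class Eye(str, enum.Enum):
    RIGHT = "RIGHT"
    LEFT = "LEFT"
    UNKNOWN = "UNKNOWN"


def _parse_enum(cls, value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return cls.UNKNOWN
    s = str(value).strip()
    if not s:
        return cls.UNKNOWN
    return cls(s.upper())


@dataclass
class Waveform:
    """One recording: an amplitude sequence plus acquisition metadata.

    ``samples`` are microvolts for raw input and dimensionless in [0, 1]
    after :func:`normalize`.  The sample index is the canonical time axis;
    milliseconds are derived (``times_ms``).
    """

    samples: np.ndarray
    sampling_rate: float = 2000.0
    subject_id: str = ""
    group: Group = Group.UNKNOWN
    sex: Sex = Sex.UNKNOWN
    eye: Eye = Eye.UNKNOWN
    flash_td: float | None = None
    recording_index: int = 1
    normalized: bool = False
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("waveform needs a 1-D sample array with >= 2 samples")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if self.recording_index < 1:
            raise ValueError("recording_index must be >= 1")
        self.group = _parse_enum(Group, self.group) if not isinstance(self.group, Group) else self.group
        self.sex = _parse_enum(Sex, self.sex) if not isinstance(self.sex, Sex) else self.sex
        self.eye = _parse_enum(Eye, self.eye) if not isinstance(self.eye, Eye) else self.eye

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * 1000.0 / self.sampling_rate

    def key(self) -> tuple:
        """Identity of the recording: (subject, eye, flash, recording index)."""
        return (self.subject_id, self.eye.value, self.flash_td, self.recording_index)


@dataclass
class QuantizedSignal:
    """Quantized level sequence q(t) with values in {0, 1/(Q-1), ..., 1}.

    ``epsilon`` = 1/(Q-1) is the inter-level spacing; it doubles as the
    self-loop regularizer in the inverse-distance edge weight downstream.
    """

    levels: np.ndarray
    Q: int
    source: Waveform | None = None

    def __post_init__(self) -> None:
        if self.Q < 2:
            raise ValueError("Q must be >= 2")
        self.levels = np.asarray(self.levels, dtype=float)
        if self.levels.ndim != 1 or self.levels.size < 1:
            raise ValueError("levels must be a non-empty 1-D array")

    @property
    def epsilon(self) -> float:
        return 1.0 / (self.Q - 1)

    @property
    def indices(self) -> np.ndarray:
        """Integer level index k such that level = k/(Q-1)."""
        return np.rint(self.levels * (self.Q - 1)).astype(int)

    @property
    def n_distinct(self) -> int:
        return int(np.unique(self.indices).size)


def normalize(w: Waveform) -> Waveform:
    """Min-max normalize to [0, 1]: x(t) = (x~(t) - min) / (max - min).

    Normalization is strictly per-waveform so that graph topology reflects
    relative amplitude dynamics, independent of electrode gain.  A flat
    signal (max == min) is mapped to the all-0.5 constant and flagged
    ``degenerate`` instead of raising, keeping batch pipelines total.
    """
    lo = float(np.min(w.samples))
    hi = float(np.max(w.samples))
    if hi == lo:
        return replace(w, samples=np.full(w.n_samples, 0.5), normalized=True, degenerate=True)
    return replace(w, samples=(w.samples - lo) / (hi - lo), normalized=True, degenerate=False)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # Fixed tie rule: 0.5 rounds up (half away from zero on nonnegative input),
    # so outputs do not depend on the platform's banker's rounding.
    return np.floor(x + 0.5)


def quantize(w: Waveform, Q: int) -> QuantizedSignal:
    """Quantize a normalized waveform onto Q levels: q(t) = round(x(t)(Q-1))/(Q-1)."""
    if Q < 2:
        raise ValueError("Q must be >= 2")
    x = np.asarray(w.samples, dtype=float)
    if x.min() < 0.0 or x.max() > 1.0:
        raise ValueError("quantize expects a normalized waveform with samples in [0, 1]")
    idx = _round_half_away(x * (Q - 1)).astype(int)
    idx = np.clip(idx, 0, Q - 1)
    return QuantizedSignal(levels=idx / (Q - 1), Q=Q, source=w)


# ---------------------------------------------------------------------------
# CSV I/O

LONG_COLUMNS = [
    "subject_id",
    "group",
    "sex",
    "eye",
    "flash_td",
    "recording_index",
    "sample_index",
    "amplitude_uv",
]

_META_COLUMNS = LONG_COLUMNS[:6]


def _meta_value(e) -> str:
    return "" if e.value == "UNKNOWN" else e.value


def _waveform_meta_row(w: Waveform) -> dict:
    return {
        "subject_id": w.subject_id,
        "group": _meta_value(w.group),
        "sex": _meta_value(w.sex),
        "eye": _meta_value(w.eye),
        "flash_td": "" if w.flash_td is None else w.flash_td,
        "recording_index": w.recording_index,
    }


def write_waveforms(waveforms: Sequence[Waveform], path, dialect: str = "long",
                    sampling_rate: float | None = None) -> None:
    """Write a collection of waveforms to CSV (long or wide dialect)."""
    waveforms = list(waveforms)
    if not waveforms:
        raise ValueError("cannot write an empty waveform collection")
    path = Path(path)
    if dialect == "long":
        frames = []
        for w in waveforms:
            df = pd.DataFrame({"sample_index": np.arange(w.n_samples), "amplitude_uv": w.samples})
            for k, v in _waveform_meta_row(w).items():
                df[k] = v
            frames.append(df[LONG_COLUMNS])
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    elif dialect == "wide":
        n = waveforms[0].n_samples
        if any(w.n_samples != n for w in waveforms):
            raise ValueError("wide dialect requires equal-length waveforms")
        rows = []
        for w in waveforms:
            row = _waveform_meta_row(w)
            row.update({f"s{i}": v for i, v in enumerate(w.samples)})
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _check_columns(df: pd.DataFrame, required: Iterable[str]) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"malformed header: missing column(s) {', '.join(missing)}")


def _build_waveform(samples, meta, sampling_rate) -> Waveform:
    flash = meta.get("flash_td")
    if flash is not None:
        flash = float(flash)
        if np.isnan(flash):
            flash = None
    return Waveform(
        samples=np.asarray(samples, dtype=float),
        sampling_rate=sampling_rate,
        subject_id=str(meta.get("subject_id", "")),
        group=_parse_enum(Group, meta.get("group")),
        sex=_parse_enum(Sex, meta.get("sex")),
        eye=_parse_enum(Eye, meta.get("eye")),
        flash_td=flash,
        recording_index=int(meta.get("recording_index", 1)),
    )


def read_waveforms(path, dialect: str = "long", sampling_rate: float = 2000.0) -> list[Waveform]:
    """Read waveforms from CSV.

    Recordings containing missing amplitude values are rejected (dropped
    with a logged warning).  Duplicated or non-monotone sample indices
    within a recording raise a data error.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    out: list[Waveform] = []
    if dialect == "long":
        _check_columns(df, LONG_COLUMNS)
        group_keys = ["subject_id", "eye", "flash_td", "recording_index"]
        for key, sub in df.groupby(group_keys, dropna=False, sort=False):
            idx = sub["sample_index"].to_numpy()
            if np.unique(idx).size != idx.size:
                raise ValueError(f"duplicated sample_index in recording {key}")
            if not np.all(np.diff(idx) > 0):
                raise ValueError(f"non-monotone sample_index in recording {key}")
            if not (idx[0] == 0 and np.all(np.diff(idx) == 1)):
                raise ValueError(f"sample_index not contiguous from 0 in recording {key}")
            amp = sub["amplitude_uv"].to_numpy(dtype=float)
            if np.isnan(amp).any():
                logger.warning("rejecting recording %s: missing amplitude values", key)
                continue
            out.append(_build_waveform(amp, sub.iloc[0].to_dict(), sampling_rate))
    elif dialect == "wide":
        _check_columns(df, _META_COLUMNS)
        sample_cols = sorted(
            (c for c in df.columns if c.startswith("s") and c[1:].isdigit()),
            key=lambda c: int(c[1:]),
        )
        if not sample_cols:
            raise ValueError("malformed header: missing sample columns s0...")
        expected = [f"s{i}" for i in range(len(sample_cols))]
        if sample_cols != expected:
            raise ValueError("sample columns are not contiguous s0..s{N-1}")
        for _, row in df.iterrows():
            amp = row[sample_cols].to_numpy(dtype=float)
            if np.isnan(amp).any():
                logger.warning("rejecting recording %s: missing amplitude values",
                               row.get("subject_id"))
                continue
            out.append(_build_waveform(amp, row.to_dict(), sampling_rate))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    keys = [w.key() for w in out]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicated (subject, eye, flash, recording) identity in file")
    return out
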