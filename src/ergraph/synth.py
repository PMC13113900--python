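"""Synthetic photopic ERG cohort generator.

The study's clinical recordings are private, so every downstream stage is
exercised on simulated waveforms that emulate light-adapted ERG morphology:
a negative a-wave trough near 15 ms, a dominant positive b-wave peak near
32 ms, high-frequency oscillatory potentials (OPs) riding the b-wave rising
limb, a late photopic negative response (PhNR), and band-limited recording
noise, sampled at 2 kHz over 250 ms (N = 500).

A waveform is a sum of unit-height Gaussian bumps plus a Gaussian-windowed
sinusoid and low-pass-filtered Gaussian noise:

    x(t) = -a_amp g(t; a_time, a_width) + b_amp g(t; b_time, b_width)
           + op_amp sin(2 pi f_op t) g(t; op_time, op_width)
           - phnr_amp g(t; phnr_time, phnr_width) + noise(t)

Group styles encode the topological contrast the downstream graphs must
recover: a "compact" style (narrow amplitude excursion relative to the
noise floor, as described for ASD) and an "expansive" style (large b-wave
and OPs, as described for ADHD).  The preset constants are emulation
targets chosen to reproduce that qualitative contrast; they are not fitted
to any clinical data.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import scipy.signal

from .signal_io import Eye, Group, Sex, Waveform

__all__ = [
    "GroupStyle",
    "MorphologyParams",
    "GroupSpec",
    "CohortSpec",
    "preset",
    "blend",
    "generate_waveform",
    "generate_cohort",
    "default_study_cohort",
]


class GroupStyle(str, enum.Enum):
    CONTROL_LIKE = "CONTROL_LIKE"
    COMPACT = "COMPACT"        # ASD-like: constrained amplitude dynamics
    EXPANSIVE = "EXPANSIVE"    # ADHD-like: broad amplitude dynamics


@dataclass
class MorphologyParams:
    """Morphology and acquisition parameters (amplitudes in microvolts,
    times/widths in ms, frequencies in Hz)."""

    a_amp: float = 12.0         # a-wave trough depth
    a_time: float = 15.0        # trough latency
    a_width: float = 3.0
    b_amp: float = 25.0         # b-wave peak (dominant component)
    b_time: float = 32.0
    b_width: float = 8.0
    op_amp: float = 3.0         # oscillatory-potential ripple
    op_freq: float = 120.0      # within the 0.1-300 Hz acquisition band
    op_time: float = 24.0       # OP window centre (b-wave rising limb)
    op_width: float = 6.0
    phnr_amp: float = 2.5       # photopic negative response
    phnr_time: float = 55.0
    phnr_width: float = 12.0
    noise_sd: float = 1.2       # band-limited recording noise
    noise_cutoff_hz: float = 300.0
    duration_ms: float = 250.0
    sampling_rate: float = 2000.0

    def validate(self) -> None:
        if not (0 < self.a_time < self.b_time < self.duration_ms):
            raise ValueError("need 0 < a_time < b_time < duration_ms")
        if self.a_amp <= 0 or self.b_amp <= 0:
            raise ValueError("a_amp and b_amp must be positive")
        if self.op_amp < 0 or self.phnr_amp < 0 or self.noise_sd < 0:
            raise ValueError("op_amp, phnr_amp and noise_sd must be >= 0")
        if not self.op_freq < self.sampling_rate / 2:
            raise ValueError("op_freq must be below the Nyquist frequency")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_ms * self.sampling_rate / 1000.0))


# Frozen preset constants.  The compact style has reduced component
# amplitudes and slightly sharper transients against an unchanged absolute
# noise floor, so after per-waveform normalization its level trajectory
# flickers over a wider relative band (dense, clustered, small-diameter
# graphs); the expansive style has elevated b-wave/OPs, giving a smooth,
# chain-like sweep through many levels (sparse, large-diameter graphs).
_PRESETS: dict[GroupStyle, MorphologyParams] = {
    GroupStyle.CONTROL_LIKE: MorphologyParams(),
    GroupStyle.COMPACT: MorphologyParams(
        a_amp=6.0, a_width=1.2, b_amp=12.0, b_width=2.0,
        op_amp=0.8, phnr_amp=1.5, phnr_width=9.0, noise_sd=1.1,
    ),
    GroupStyle.EXPANSIVE: MorphologyParams(
        a_amp=16.0, a_width=4.0, b_amp=42.0, b_width=8.0,
        op_amp=6.5, phnr_amp=3.0, noise_sd=1.5,
    ),
}


def preset(style: GroupStyle | str) -> MorphologyParams:
    """Morphology preset for a group style (returns a copy)."""
    return replace(_PRESETS[GroupStyle(style)])


def blend(p1: MorphologyParams, p2: MorphologyParams, w: float = 0.5) -> MorphologyParams:
    """Convex combination of two parameter sets (used for the co-occurring
    group in four-group cohorts)."""
    kwargs = {}
    for name in MorphologyParams.__dataclass_fields__:
        v1, v2 = getattr(p1, name), getattr(p2, name)
        kwargs[name] = (1 - w) * v1 + w * v2
    return MorphologyParams(**kwargs)


def _gauss(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def _band_limited_noise(n: int, sd: float, fs: float, cutoff: float,
                        rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    if cutoff >= fs / 2:
        noise = white
    else:
        sos = scipy.signal.butter(4, cutoff, btype="low", fs=fs, output="sos")
        noise = scipy.signal.sosfiltfilt(sos, white)
        s = noise.std()
        if s > 0:
            noise = noise / s
    return sd * noise


def generate_waveform(p: MorphologyParams, rng: np.random.Generator,
                      **meta) -> Waveform:
    """Draw one waveform from the morphology model (raw microvolt units)."""
    p.validate()
    n = p.n_samples
    t = np.arange(n) * 1000.0 / p.sampling_rate  # ms
    x = (
        -p.a_amp * _gauss(t, p.a_time, p.a_width)
        + p.b_amp * _gauss(t, p.b_time, p.b_width)
        + p.op_amp * np.sin(2 * np.pi * p.op_freq * t / 1000.0)
        * _gauss(t, p.op_time, p.op_width)
        - p.phnr_amp * _gauss(t, p.phnr_time, p.phnr_width)
    )
    if p.noise_sd > 0:
        x = x + _band_limited_noise(n, p.noise_sd, p.sampling_rate,
                                    p.noise_cutoff_hz, rng)
    return Waveform(samples=x, sampling_rate=p.sampling_rate, **meta)


@dataclass
class GroupSpec:
    """One diagnostic group in a cohort: base morphology plus cohort sizes."""

    params: MorphologyParams
    n_subjects: int = 10
    sex_ratio: float = 0.5          # probability of male
    between_sd: float = 0.15        # log-normal sigma across subjects
    within_sd: float = 0.05         # log-normal sigma across repeats

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("each group needs at least 2 subjects")


_AMPLITUDE_FIELDS = ("a_amp", "b_amp", "op_amp", "phnr_amp")

#: Amplitude scale per flash strength (Td.s).  The stronger flash elicits a
#: larger retinal response; the scaling emulates that the 446 Td.s condition
#: separates groups more cleanly, with no claim of physiological accuracy.
FLASH_SCALE: dict[float, float] = {113.0: 1.0, 446.0: 1.5}


@dataclass
class CohortSpec:
    """Full cohort description: groups, repeats, eyes, flash strengths, seed."""

    groups: Mapping[str, GroupSpec]
    recordings_per_subject: int | tuple[int, int] = 2   # or (lo, hi) drawn per combo
    eyes: Sequence[Eye] = (Eye.RIGHT, Eye.LEFT)
    flashes: Sequence[float] = (113.0, 446.0)
    seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("cohort needs at least one group")
        for gs in self.groups.values():
            gs.validate()
        r = self.recordings_per_subject
        lo, hi = (r, r) if isinstance(r, int) else r
        if not (1 <= lo <= hi <= 4):
            raise ValueError("recordings_per_subject must lie in [1, 4]")


def _scaled(p: MorphologyParams, mult: Mapping[str, float],
            flash: float | None) -> MorphologyParams:
    kwargs = {f: getattr(p, f) * mult[f] for f in _AMPLITUDE_FIELDS}
    if flash is not None:
        scale = FLASH_SCALE.get(float(flash), 1.0)
        kwargs = {k: v * scale for k, v in kwargs.items()}
    return replace(p, **kwargs)


def generate_cohort(spec: CohortSpec) -> list[Waveform]:
    """Generate a full cohort; identical specs produce byte-identical output.

    Per-subject morphology is drawn around the group base with log-normal
    multipliers on the component amplitudes (between_sd); repeat recordings
    jitter the subject's parameters with a smaller within-subject sigma, so
    repeats of a subject resemble each other more than other subjects —
    the structure subject-wise cross-validation must respect.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    out: list[Waveform] = []
    subject_counter = 0
    r = spec.recordings_per_subject
    lo, hi = (r, r) if isinstance(r, int) else r
    for group_name in spec.groups:
        gs = spec.groups[group_name]
        group = Group(group_name)
        for _ in range(gs.n_subjects):
            subject_counter += 1
            sid = f"S{subject_counter:04d}"
            sex = Sex.M if rng.random() < gs.sex_ratio else Sex.F
            subj_mult = {f: float(np.exp(rng.normal(0.0, gs.between_sd)))
                         for f in _AMPLITUDE_FIELDS}
            for eye in spec.eyes:
                for flash in spec.flashes:
                    n_rec = int(rng.integers(lo, hi + 1)) if hi > lo else lo
                    for rec in range(1, n_rec + 1):
                        mult = {f: subj_mult[f] * float(np.exp(rng.normal(0.0, gs.within_sd)))
                                for f in _AMPLITUDE_FIELDS}
                        p = _scaled(gs.params, mult, flash)
                        out.append(generate_waveform(
                            p, rng, subject_id=sid, group=group, sex=sex,
                            eye=eye, flash_td=float(flash) if flash is not None else None,
                            recording_index=rec,
                        ))
    return out


def default_study_cohort(seed: int = 0, scale: float = 1.0) -> CohortSpec:
    """Cohort shaped like the study population: four groups with subject
    counts 77 (compact), 43 (expansive), 21 (co-occurring blend) and 137
    (control), 1-4 repeats per eye x flash, both eyes, both flash strengths.

    ``scale`` shrinks the subject counts proportionally (minimum 2/group)
    for quick experiments.
    """
    def n(x: int) -> int:
        return max(2, int(round(x * scale)))

    compact = preset(GroupStyle.COMPACT)
    expansive = preset(GroupStyle.EXPANSIVE)
    return CohortSpec(
        groups={
            Group.ASD.value: GroupSpec(compact, n_subjects=n(77), sex_ratio=56 / 77),
            Group.ADHD.value: GroupSpec(expansive, n_subjects=n(43), sex_ratio=25 / 43),
            Group.ASD_ADHD.value: GroupSpec(blend(compact, expansive),
                                            n_subjects=n(21), sex_ratio=16 / 21),
            Group.CONTROL.value: GroupSpec(preset(GroupStyle.CONTROL_LIKE),
                                           n_subjects=n(137), sex_ratio=57 / 137),
        },
        recordings_per_subject=(1, 4),
        seed=seed,
    )
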