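"""Synthetic multi-lead ECG streams with known beat-level ground truth.

A heartbeat is modelled as a sum of five Gaussian deflections (P, Q, R, S, T)
on a unit-time axis, plus an optional ST-segment plateau between the end of
the S wave and the start of the T wave.  The model is deliberately analytic:
every morphological change used downstream (absent P wave, widened QRS,
ST shift, inverted T, premature beats) is a deterministic transformation of
the wave parameters, so detector behaviour can be verified against exact
ground truth rather than against another signal-processing stage.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "WaveSpec",
    "BeatTemplateSpec",
    "MorphLabel",
    "SyntheticStream",
    "BeatVariability",
    "make_beat",
    "st_plateau_indices",
    "apply_morph",
    "sample_patient_spec",
    "synthesize_stream",
    "DEFAULT_BEAT",
]

WAVE_ORDER = ("P", "Q", "R", "S", "T")


class InvalidSpecError(ValueError):
    """Raised when a beat template violates its structural constraints."""


@dataclass(frozen=True)
class WaveSpec:
    """One Gaussian deflection: amplitude (mV), center and width as beat fractions."""

    amplitude: float
    center: float
    width: float


@dataclass(frozen=True)
class BeatTemplateSpec:
    """Parameters of one beat template.

    ``waves`` maps each of P/Q/R/S/T to a :class:`WaveSpec`.  ``st_shift`` is an
    additive plateau (mV) applied between the end of the S wave and the start of
    the T wave, with half-cosine ramps so the waveform stays smooth.
    """

    waves: dict[str, WaveSpec]
    baseline: float = 0.0
    st_shift: float = 0.0
    beat_period: float = 0.8
    period_jitter_sd: float = 0.004
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        missing = [w for w in WAVE_ORDER if w not in self.waves]
        if missing:
            raise InvalidSpecError(f"missing wave definitions: {missing}")
        widths = [self.waves[w].width for w in WAVE_ORDER]
        if any(w <= 0 for w in widths):
            raise InvalidSpecError("wave widths must be strictly positive")
        centers = [self.waves[w].center for w in WAVE_ORDER]
        if not all(a < b for a, b in zip(centers, centers[1:])):
            raise InvalidSpecError("wave centers must be strictly increasing P<Q<R<S<T")
        if self.beat_period <= 0:
            raise InvalidSpecError("beat_period must be positive")
        if self.noise_sd < 0 or self.period_jitter_sd < 0:
            raise InvalidSpecError("noise_sd and period_jitter_sd must be >= 0")


#: A plausible resting sinus beat: ~1 mV R wave, 0.8 s period (75 bpm).
DEFAULT_BEAT = BeatTemplateSpec(
    waves={
        "P": WaveSpec(0.15, 0.18, 0.035),
        "Q": WaveSpec(-0.10, 0.39, 0.012),
        "R": WaveSpec(1.00, 0.44, 0.016),
        "S": WaveSpec(-0.20, 0.49, 0.012),
        "T": WaveSpec(0.30, 0.72, 0.060),
    },
)


class MorphLabel(enum.Enum):
    """Disease-like morphological variants of a base beat template.

    The labels emulate the kinds of abnormality an anomaly detector is asked to
    flag on real recordings: atrial-fibrillation-like beats (no P wave,
    irregular spacing), bundle-branch-block-like beats (wide, low QRS),
    ST depression/elevation, T-wave inversion and premature beats.
    """

    NORMAL = "NORMAL"
    AF_LIKE = "AF_LIKE"
    BBB_LIKE = "BBB_LIKE"
    STD_LIKE = "STD_LIKE"
    STE_LIKE = "STE_LIKE"
    TINV_LIKE = "TINV_LIKE"
    PREMATURE = "PREMATURE"


# Morph magnitudes: QRS widening/attenuation for BBB-like beats, |ST shift| in
# mV, and the elevated R-R jitter of AF-like rhythm.
BBB_WIDTH_FACTOR = 1.8
BBB_R_AMPLITUDE_FACTOR = 0.55
ST_SHIFT_MV = 0.2
AF_JITTER_SD = 0.05
PREMATURE_INTERVAL_FACTOR = 0.6


def apply_morph(spec: BeatTemplateSpec, label: MorphLabel) -> BeatTemplateSpec:
    """Deterministically transform a base template into the labelled morphology."""
    if label is MorphLabel.NORMAL:
        return spec
    waves = dict(spec.waves)
    if label is MorphLabel.AF_LIKE:
        waves["P"] = replace(waves["P"], amplitude=0.0)
        return replace(spec, waves=waves, period_jitter_sd=AF_JITTER_SD)
    if label in (MorphLabel.BBB_LIKE, MorphLabel.PREMATURE):
        for w in ("Q", "R", "S"):
            waves[w] = replace(waves[w], width=waves[w].width * BBB_WIDTH_FACTOR)
        waves["R"] = replace(waves["R"], amplitude=waves["R"].amplitude * BBB_R_AMPLITUDE_FACTOR)
        return replace(spec, waves=waves)
    if label is MorphLabel.STD_LIKE:
        return replace(spec, st_shift=spec.st_shift - ST_SHIFT_MV)
    if label is MorphLabel.STE_LIKE:
        return replace(spec, st_shift=spec.st_shift + ST_SHIFT_MV)
    if label is MorphLabel.TINV_LIKE:
        waves["T"] = replace(waves["T"], amplitude=-waves["T"].amplitude)
        return replace(spec, waves=waves)
    raise ValueError(f"unknown morph label {label!r}")


@dataclass(frozen=True)
class BeatVariability:
    """Cycle-to-cycle morphological variability within one subject.

    Real consecutive sinus beats are not identical copies: autonomic tone and
    respiration modulate the individual wave amplitudes and widths and let the
    ST level drift slightly.  Each beat's template is re-drawn around the
    subject's template with these standard deviations (relative for amplitude
    and width factors, absolute mV for the ST level).  ``synthesize_stream``
    applies no such variability unless an instance is passed explicitly, so
    the exact-repetition semantics of the plain generator are unchanged.
    """

    amplitude_rel_sd: float = 0.03
    width_rel_sd: float = 0.02
    st_level_sd: float = 0.015


def sample_patient_spec(
    base: BeatTemplateSpec,
    rng: np.random.Generator,
    amplitude_rel_sd: float = 0.10,
    width_rel_sd: float = 0.08,
    center_sd: float = 0.008,
    st_level_sd: float = 0.03,
    period_sd: float = 0.08,
) -> BeatTemplateSpec:
    """Draw one subject's beat template from a population around ``base``.

    Emulates inter-patient morphology differences: wave amplitudes and widths
    scaled by independent lognormal-ish factors, centers nudged (order
    preserved by construction of the small default sd), a resting ST level in
    the tens of microvolts, and a subject heart rate around 75 bpm.
    """
    waves = {}
    for name in WAVE_ORDER:
        w = base.waves[name]
        waves[name] = WaveSpec(
            amplitude=w.amplitude * (1.0 + amplitude_rel_sd * rng.standard_normal()),
            center=w.center + center_sd * rng.standard_normal(),
            width=w.width * float(np.exp(width_rel_sd * rng.standard_normal())),
        )
    centers = [waves[n].center for n in WAVE_ORDER]
    if not all(a < b for a, b in zip(centers, centers[1:])):  # extreme draw: keep base timing
        waves = {n: replace(waves[n], center=base.waves[n].center) for n in WAVE_ORDER}
    return replace(
        base,
        waves=waves,
        st_shift=base.st_shift + st_level_sd * rng.standard_normal(),
        beat_period=max(base.beat_period + period_sd * rng.standard_normal(), 0.45),
    )


def _jitter_beat_spec(
    spec: BeatTemplateSpec, rng: np.random.Generator, var: BeatVariability
) -> BeatTemplateSpec:
    waves = {
        n: replace(
            spec.waves[n],
            amplitude=spec.waves[n].amplitude
            * (1.0 + var.amplitude_rel_sd * rng.standard_normal()),
            width=spec.waves[n].width * float(np.exp(var.width_rel_sd * rng.standard_normal())),
        )
        for n in WAVE_ORDER
    }
    return replace(spec, waves=waves, st_shift=spec.st_shift + var.st_level_sd * rng.standard_normal())


def _st_interval(spec: BeatTemplateSpec) -> tuple[float, float]:
    """(start, end) of the ST segment as beat fractions: S end to T start."""
    s, t = spec.waves["S"], spec.waves["T"]
    start = s.center + 2.0 * s.width
    end = t.center - 2.0 * t.width
    if end <= start:
        raise InvalidSpecError("ST interval collapsed; S and T waves overlap")
    return start, end


def _st_profile(spec: BeatTemplateSpec, t: np.ndarray) -> np.ndarray:
    """ST plateau with half-cosine ramps occupying 20% of the interval each."""
    start, end = _st_interval(spec)
    ramp = 0.2 * (end - start)
    prof = np.zeros_like(t)
    up = (t >= start) & (t < start + ramp)
    prof[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - start) / ramp))
    flat = (t >= start + ramp) & (t <= end - ramp)
    prof[flat] = 1.0
    down = (t > end - ramp) & (t <= end)
    prof[down] = 0.5 * (1 - np.cos(np.pi * (end - t[down]) / ramp))
    return spec.st_shift * prof


def st_plateau_indices(spec: BeatTemplateSpec, n_samples: int) -> np.ndarray:
    """Sample indices of the flat part of the ST segment (shift applied in full)."""
    start, end = _st_interval(spec)
    ramp = 0.2 * (end - start)
    t = np.arange(n_samples) / n_samples
    return np.nonzero((t >= start + ramp) & (t <= end - ramp))[0]


def make_beat(spec: BeatTemplateSpec, n_samples: int) -> np.ndarray:
    """Render one noiseless beat on ``n_samples`` uniform points of [0, 1).

    The time axis is ``t_k = k / n_samples`` so consecutive beats concatenate
    without a duplicated endpoint.
    """
    if n_samples < 8:
        raise InvalidSpecError("n_samples must be >= 8")
    t = np.arange(n_samples) / n_samples
    y = np.full(n_samples, float(spec.baseline))
    for name in WAVE_ORDER:
        w = spec.waves[name]
        if w.amplitude != 0.0:
            y += w.amplitude * np.exp(-((t - w.center) ** 2) / (2.0 * w.width**2))
    if spec.st_shift != 0.0:
        y += _st_profile(spec, t)
    return y


@dataclass
class SyntheticStream:
    """A generated multi-lead recording plus its beat-level ground truth."""

    sample_rate: float
    lead_gains: list[float]
    samples: np.ndarray  # shape (n_leads, n_samples), mV
    beat_onsets: np.ndarray  # sample index of each beat start
    beat_labels: list[MorphLabel]
    r_centers: np.ndarray = field(default=None)  # sample index of each R peak
    seed: int = 0

    def __post_init__(self) -> None:
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.lead_gains):
            raise InvalidSpecError("samples must be (n_leads, n_samples)")
        if len(self.beat_onsets) != len(self.beat_labels):
            raise InvalidSpecError("one label per beat onset required")
        if np.any(np.diff(self.beat_onsets) <= 0):
            raise InvalidSpecError("beat_onsets must be strictly increasing")

    @property
    def n_leads(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.sample_rate


def synthesize_stream(
    spec: BeatTemplateSpec,
    labels: Sequence[MorphLabel],
    sample_rate: float = 500.0,
    lead_gains: Sequence[float] = (1.0, 0.8, 1.2),
    seed: int = 0,
    beat_variability: BeatVariability | None = None,
) -> SyntheticStream:
    """Concatenate morph-labelled beats into a seeded multi-lead stream.

    Each beat's period is ``beat_period + N(0, period_jitter_sd^2)`` (jitter of
    the morphed template, so AF-like beats are irregular); a premature beat
    shortens the interval occupied by its *preceding* beat by the factor
    ``PREMATURE_INTERVAL_FACTOR``.  Per lead the waveform is scaled by the lead
    gain and independent ``N(0, noise_sd^2)`` noise is added.

    Parameters
    ----------
    labels
        Morph label per beat; length defines the number of beats.
    sample_rate
        Hz; the default 500 matches routine multi-lead clinical recordings.
    seed
        Single integer seeding every random draw (periods, noise and, when
        enabled, per-beat template variability).
    beat_variability
        Optional within-subject cycle-to-cycle morphological variability;
        ``None`` (default) renders every beat of a given label identically.
    """
    labels = list(labels)
    if not labels:
        raise InvalidSpecError("labels must be non-empty")
    if sample_rate <= 0:
        raise InvalidSpecError("sample_rate must be positive")
    lead_gains = list(lead_gains)
    if not lead_gains:
        raise InvalidSpecError("lead_gains must be non-empty")

    rng = np.random.default_rng(seed)
    morphed = [apply_morph(spec, lab) for lab in labels]
    if beat_variability is not None:
        morphed = [_jitter_beat_spec(m, rng, beat_variability) for m in morphed]

    periods = np.array(
        [m.beat_period + rng.normal(0.0, m.period_jitter_sd) if m.period_jitter_sd > 0 else m.beat_period for m in morphed]
    )
    periods = np.maximum(periods, 0.2)  # keep beats physically renderable
    for i, lab in enumerate(labels):
        if lab is MorphLabel.PREMATURE and i > 0:
            periods[i - 1] *= PREMATURE_INTERVAL_FACTOR

    n_per_beat = np.maximum(np.round(periods * sample_rate).astype(int), 8)
    onsets = np.concatenate([[0], np.cumsum(n_per_beat)[:-1]])
    waveform = np.concatenate([make_beat(m, n) for m, n in zip(morphed, n_per_beat)])
    r_centers = onsets + np.round(
        [m.waves["R"].center * n for m, n in zip(morphed, n_per_beat)]
    ).astype(int)

    n_total = waveform.size
    samples = np.empty((len(lead_gains), n_total))
    for li, gain in enumerate(lead_gains):
        samples[li] = gain * waveform
        if spec.noise_sd > 0:
            samples[li] += rng.normal(0.0, spec.noise_sd, size=n_total)

    return SyntheticStream(
        sample_rate=float(sample_rate),
        lead_gains=[float(g) for g in lead_gains],
        samples=samples,
        beat_onsets=onsets,
        beat_labels=labels,
        r_centers=r_centers,
        seed=int(seed),
    )
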