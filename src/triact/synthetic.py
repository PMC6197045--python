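"""Seeded generator of labeled tri-axial signals with the statistical
structure of the ten activities.

Signal families
---------------
periodic (WS, WF, RS, RF, JR)
    A sum of decaying harmonics at a subject-specific fundamental drawn
    from the class frequency range, per-axis amplitudes, Gaussian noise
    and a constant gravity offset.  Jumping rope carries a strongly
    elevated vertical amplitude.
pulse (SU, SD)
    Periodic asymmetric vertical peaks — sharp rise / slow fall for
    ascending, the mirror image for descending — so the two stair classes
    share summary statistics but differ in waveform shape.
transient (ST, SI)
    Stillness plus a repeated posture-change signature: a smooth lateral
    reorientation bump and a derivative-of-Gaussian vertical burst, with
    opposite sign for standing up versus sitting down.
still (NA)
    Gravity plus low-amplitude noise.

All class parameter defaults are configuration choices exposed here, not
measured values; they respect the ±4 g sensor envelope and keep the
ordinal structure walking < running in step frequency.  Everything is
deterministic given the generator seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from triact.codes import ActivityCode, CANONICAL_CODES
from triact.signal_io import (
    DEFAULT_SAMPLE_RATE_HZ,
    TriaxialRecording,
    WINDOW_LEN,
)

MIN_DURATION_S = WINDOW_LEN / DEFAULT_SAMPLE_RATE_HZ  # one window, ~2.82 s


@dataclass
class ClassSignalModel:
    """Generative parameters of one activity class."""

    kind: str = "periodic"  # periodic | pulse | transient | still
    freq_range_hz: tuple[float, float] = (1.5, 1.8)
    axis_amps_g: tuple[float, float, float] = (0.1, 0.15, 0.3)
    harmonic_count: int = 3
    harmonic_decay: float = 0.5
    pulse_rise: float = 0.08   # pulse kind: rise width (fraction of cycle)
    pulse_fall: float = 0.25   # pulse kind: fall width
    transient_sign: float = 1.0  # transient kind: +1 stand up, -1 sit down
    event_period_range_s: tuple[float, float] = (1.8, 2.4)
    noise_sd_g: float = 0.02
    gravity_g: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        lo, hi = self.freq_range_hz
        if not 0.5 < lo <= hi < DEFAULT_SAMPLE_RATE_HZ / 2:
            raise ValueError(
                f"freq_range_hz {self.freq_range_hz} must lie within "
                f"(0.5, Nyquist)"
            )
        hsum = (
            (1 - self.harmonic_decay**self.harmonic_count)
            / (1 - self.harmonic_decay)
            if self.harmonic_decay < 1 else self.harmonic_count
        )
        peak = np.linalg.norm(self.gravity_g) + hsum * np.linalg.norm(
            self.axis_amps_g
        )
        if peak > 4.0:
            raise ValueError(
                f"amplitude configuration can exceed the ±4 g envelope "
                f"(worst case {peak:.2f} g)"
            )


@dataclass
class CohortConfig:
    """Cohort-level generation settings.

    ``freq_variability`` / ``amp_variability`` scale the inter-subject
    random effects; at 0 every subject shares the class-center
    parameters.
    """

    n_subjects: int = 10
    duration_s: float = 14.0
    freq_variability: float = 0.7
    amp_variability: float = 1.0
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.duration_s <= 0:
            raise ValueError("n_subjects and duration_s must be positive")
        if self.freq_variability < 0 or self.amp_variability < 0:
            raise ValueError("variability scales must be non-negative")


DEFAULT_MODELS: dict[ActivityCode, ClassSignalModel] = {
    ActivityCode.WS: ClassSignalModel(
        kind="periodic", freq_range_hz=(1.5, 1.8),
        axis_amps_g=(0.10, 0.15, 0.30),
    ),
    ActivityCode.WF: ClassSignalModel(
        kind="periodic", freq_range_hz=(1.9, 2.3),
        axis_amps_g=(0.12, 0.22, 0.45),
    ),
    ActivityCode.RS: ClassSignalModel(
        kind="periodic", freq_range_hz=(2.45, 2.75),
        axis_amps_g=(0.18, 0.35, 0.70),
    ),
    ActivityCode.RF: ClassSignalModel(
        kind="periodic", freq_range_hz=(2.85, 3.3),
        axis_amps_g=(0.22, 0.45, 0.95),
    ),
    ActivityCode.SU: ClassSignalModel(
        kind="pulse", freq_range_hz=(1.4, 1.7),
        axis_amps_g=(0.22, 0.20, 0.50), pulse_rise=0.08, pulse_fall=0.25,
    ),
    ActivityCode.SD: ClassSignalModel(
        kind="pulse", freq_range_hz=(1.6, 1.9),
        axis_amps_g=(0.10, 0.20, 0.75), pulse_rise=0.25, pulse_fall=0.08,
    ),
    # jumping rope: narrow symmetric landing spikes, strongly vertical
    ActivityCode.JR: ClassSignalModel(
        kind="pulse", freq_range_hz=(2.0, 2.8),
        axis_amps_g=(0.15, 0.25, 1.60), pulse_rise=0.06, pulse_fall=0.06,
    ),
    ActivityCode.ST: ClassSignalModel(kind="transient", transient_sign=1.0),
    ActivityCode.SI: ClassSignalModel(kind="transient", transient_sign=-1.0),
    ActivityCode.NA: ClassSignalModel(kind="still", noise_sd_g=0.01),
}


#: Fixed harmonic phase offsets: the waveform template is consistent
#: within a class (recordings differ only by a global time shift per
#: axis), which is what makes the shape learnable across subjects.
_HARMONIC_PHASES = (0.0, 1.3, 2.1, 0.7)


def _periodic_axes(
    t: np.ndarray, fundamental: float, model: ClassSignalModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Decaying-harmonic oscillation per axis with a random time shift."""
    out = np.zeros((t.size, 3))
    theta = 2.0 * np.pi * fundamental * t
    for axis, amp in enumerate(model.axis_amps_g):
        shift = rng.uniform(0.0, 2.0 * np.pi)
        sig = np.zeros_like(t)
        for h in range(model.harmonic_count):
            psi = _HARMONIC_PHASES[h % len(_HARMONIC_PHASES)]
            sig += model.harmonic_decay**h * np.sin(
                (h + 1) * (theta + shift) + psi
            )
        out[:, axis] = amp * sig
    return out


def _pulse_wave(frac: np.ndarray, rise: float, fall: float) -> np.ndarray:
    """Asymmetric periodic peak on cycle fraction in [0, 1): Gaussian
    flanks of different widths around the peak at 0.4, mean-removed."""
    centered = frac - 0.4
    width = np.where(centered < 0, rise, fall)
    wave = np.exp(-0.5 * (centered / width) ** 2)
    return wave - wave.mean()


def _pulse_axes(
    t: np.ndarray, fundamental: float, model: ClassSignalModel,
    rng: np.random.Generator,
) -> np.ndarray:
    out = np.zeros((t.size, 3))
    phase0 = rng.uniform(0.0, 1.0)
    frac = np.mod(fundamental * t + phase0, 1.0)
    vertical = _pulse_wave(frac, model.pulse_rise, model.pulse_fall)
    scale = max(vertical.std(), 1e-12)
    out[:, 2] = model.axis_amps_g[2] * vertical / scale * 0.5
    for axis in (0, 1):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        out[:, axis] = model.axis_amps_g[axis] * np.sin(
            2.0 * np.pi * fundamental * t + phase
        )
    return out


def _transient_axes(
    t: np.ndarray, model: ClassSignalModel, rng: np.random.Generator,
    amp_scale: float,
) -> np.ndarray:
    """Repeated posture-change signatures over stillness."""
    out = np.zeros((t.size, 3))
    sigma = 0.15  # burst width (s)
    event_time = rng.uniform(0.4, 0.8)
    lo, hi = model.event_period_range_s
    while event_time < t[-1]:
        dt = t - event_time
        # vertical derivative-of-Gaussian burst
        out[:, 2] += (
            model.transient_sign * amp_scale * 0.7
            * (dt / sigma) * np.exp(-0.5 * (dt / sigma) ** 2)
        )
        # lateral reorientation bump
        out[:, 0] += (
            model.transient_sign * amp_scale * 0.4
            * np.exp(-0.5 * (dt / (2 * sigma)) ** 2)
        )
        event_time += rng.uniform(lo, hi)
    return out


def simulate_recording(
    subject_id: str,
    activity: ActivityCode,
    duration_s: float,
    model: ClassSignalModel,
    rng: np.random.Generator,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    fundamental_hz: float | None = None,
    amp_scale: float = 1.0,
) -> TriaxialRecording:
    """Generate one subject-activity recording.

    ``fundamental_hz`` overrides the draw from the class frequency range
    (used by :func:`simulate_cohort` for subject-level effects);
    ``amp_scale`` multiplies all movement amplitudes.  Deterministic for
    a given generator state.
    """
    if duration_s < MIN_DURATION_S:
        raise ValueError(
            f"duration {duration_s:.2f} s is shorter than one window "
            f"({MIN_DURATION_S:.2f} s)"
        )
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    if fundamental_hz is None:
        fundamental_hz = rng.uniform(*model.freq_range_hz)
    if model.kind == "periodic":
        motion = amp_scale * _periodic_axes(t, fundamental_hz, model, rng)
    elif model.kind == "pulse":
        motion = amp_scale * _pulse_axes(t, fundamental_hz, model, rng)
    elif model.kind == "transient":
        motion = _transient_axes(t, model, rng, amp_scale)
    elif model.kind == "still":
        motion = np.zeros((n, 3))
    else:
        raise ValueError(f"unknown signal kind {model.kind!r}")
    noise = rng.normal(0.0, model.noise_sd_g, size=(n, 3))
    samples = motion + noise + np.asarray(model.gravity_g)
    return TriaxialRecording(
        subject_id=subject_id,
        activity=activity,
        samples=samples,
        sample_rate_hz=sample_rate_hz,
    )


def simulate_cohort(
    config: CohortConfig,
    models: dict[ActivityCode, ClassSignalModel] | None = None,
) -> tuple[list[TriaxialRecording], dict]:
    """Generate every subject x activity recording with subject-level
    random effects on fundamental frequency and amplitude.

    Returns the recordings (grouped by subject, activities in canonical
    order) and a manifest recording the seed and resolved parameters.
    """
    models = models or DEFAULT_MODELS
    rng = np.random.default_rng(config.rng_seed)
    recordings: list[TriaxialRecording] = []
    manifest: dict = {
        "rng_seed": config.rng_seed,
        "n_subjects": config.n_subjects,
        "duration_s": config.duration_s,
        "sample_rate_hz": config.sample_rate_hz,
        "subjects": {},
    }
    for s in range(config.n_subjects):
        subject_id = f"S{s:03d}"
        subject_entry: dict = {}
        for code in CANONICAL_CODES:
            model = models[code]
            lo, hi = model.freq_range_hz
            center = 0.5 * (lo + hi)
            draw = rng.uniform(lo, hi)
            fundamental = center + config.freq_variability * (draw - center)
            amp_scale = 1.0 + config.amp_variability * rng.uniform(-0.15, 0.15)
            rec = simulate_recording(
                subject_id, code, config.duration_s, model, rng,
                sample_rate_hz=config.sample_rate_hz,
                fundamental_hz=fundamental, amp_scale=amp_scale,
            )
            recordings.append(rec)
            subject_entry[code.value] = {
                "fundamental_hz": fundamental,
                "amp_scale": amp_scale,
            }
        manifest["subjects"][subject_id] = subject_entry
    return recordings, manifest


def narrowed_models(
    separation: float,
    models: dict[ActivityCode, ClassSignalModel] | None = None,
) -> dict[ActivityCode, ClassSignalModel]:
    """Shrink every class's frequency range toward the global center by
    ``1 - separation`` (separation 1 = defaults, 0 = all classes share
    one fundamental).  Used for dose-response sanity checks."""
    if not 0 <= separation <= 1:
        raise ValueError("separation must be in [0, 1]")
    models = models or DEFAULT_MODELS
    centers = [
        0.5 * (m.freq_range_hz[0] + m.freq_range_hz[1])
        for m in models.values() if m.kind in ("periodic", "pulse")
    ]
    global_center = float(np.mean(centers))
    out = {}
    for code, m in models.items():
        if m.kind not in ("periodic", "pulse"):
            out[code] = m
            continue
        lo, hi = m.freq_range_hz
        new_lo = global_center + separation * (lo - global_center)
        new_hi = global_center + separation * (hi - global_center)
        out[code] = replace(m, freq_range_hz=(new_lo, new_hi))
    return out
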