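"""Filtering, window segmentation, rotational augmentation and block-wise
fold assembly.

The high-pass filter is a zero-phase frequency-domain filter: transform,
zero every bin strictly below the cutoff (including DC), inverse
transform.  It is exactly idempotent and leaves pass-band tones untouched.

Rotational augmentation applies one rigid rotation per copy, composed as
roll (about x), then pitch (about y), then yaw (about z), with each angle
drawn uniformly within its ± bound.  Rotations are orthogonal, so the
per-sample vector norm is preserved.

Fold assembly is block-wise: each class's subject-ordered, unshuffled
window list is split into k contiguous blocks whose sizes differ by at
most one; fold i of the dataset is the union of block i over classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from triact.codes import ActivityCode, CANONICAL_CODES
from triact.signal_io import DatasetBundle, TriaxialRecording, Window

logger = logging.getLogger(__name__)


@dataclass
class AugmentationConfig:
    """Bounds for random sensor-misalignment rotations.

    Defaults: ±10° yaw, ±15° pitch, ±20° roll, one rotated copy per base
    window.
    """

    max_yaw_deg: float = 10.0
    max_pitch_deg: float = 15.0
    max_roll_deg: float = 20.0
    copies_per_window: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.max_yaw_deg, self.max_pitch_deg, self.max_roll_deg) < 0:
            raise ValueError("angle bounds must be non-negative")
        if self.copies_per_window < 0:
            raise ValueError("copies_per_window must be >= 0")


@dataclass
class FoldAssignment:
    """Per-class fold index arrays for block-wise k-fold cross-validation.

    ``assignments[code][i]`` is the fold (0..k-1) of the i-th window of
    that class in bundle order.
    """

    k: int
    assignments: dict[ActivityCode, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        for code, arr in self.assignments.items():
            arr = np.asarray(arr, dtype=int)
            self.assignments[code] = arr
            if arr.size and (arr.min() < 0 or arr.max() >= self.k):
                raise ValueError(f"fold index out of range for {code.value}")

    def split(
        self, bundle: DatasetBundle, held_out_fold: int
    ) -> tuple[list[Window], list[Window]]:
        """Return (training windows, validation windows) for one fold."""
        if not 0 <= held_out_fold < self.k:
            raise IndexError(
                f"held_out_fold {held_out_fold} out of range [0, {self.k})"
            )
        train: list[Window] = []
        val: list[Window] = []
        for code in CANONICAL_CODES:
            wins = bundle.windows[code]
            folds = self.assignments.get(code)
            if folds is None:
                if wins:
                    raise ValueError(f"no fold assignment for class {code.value}")
                continue
            for w, f in zip(wins, folds):
                (val if f == held_out_fold else train).append(w)
        return train, val


def highpass_filter(
    recording: TriaxialRecording, cutoff_hz: float = 0.5
) -> TriaxialRecording:
    """Remove frequency content strictly below ``cutoff_hz`` on every axis.

    Zero-phase frequency-domain implementation; output length equals input
    length.  Raises ``ValueError`` if the cutoff is at or above Nyquist or
    the recording is shorter than two samples.
    """
    n = len(recording)
    if n < 2:
        raise ValueError("recording must have at least 2 samples to filter")
    nyquist = recording.sample_rate_hz / 2.0
    if cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below Nyquist {nyquist} Hz"
        )
    spectrum = np.fft.rfft(recording.samples, axis=0)
    freqs = np.fft.rfftfreq(n, d=1.0 / recording.sample_rate_hz)
    spectrum[freqs < cutoff_hz, :] = 0.0
    filtered = np.fft.irfft(spectrum, n=n, axis=0)
    return TriaxialRecording(
        subject_id=recording.subject_id,
        activity=recording.activity,
        samples=filtered,
        sample_rate_hz=recording.sample_rate_hz,
    )


def segment_windows(
    recording: TriaxialRecording,
    window_len: int = 128,
    overlap_fraction: float = 0.5,
) -> list[Window]:
    """Cut a recording into fixed-length windows with fractional overlap.

    Stride is ``int(window_len * (1 - overlap_fraction))``; the window
    count is ``floor((N - window_len) / stride) + 1`` and any trailing
    remainder shorter than a stride is dropped.  A recording shorter than
    one window yields an empty list with a logged warning.
    """
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must be in [0, 1)")
    n = len(recording)
    if n < window_len:
        logger.warning(
            "recording %s/%s has %d samples, shorter than one window (%d)",
            recording.subject_id, recording.activity.value, n, window_len,
        )
        return []
    stride = int(window_len * (1.0 - overlap_fraction))
    stride = max(stride, 1)
    count = (n - window_len) // stride + 1
    windows = []
    for i in range(count):
        start = i * stride
        windows.append(
            Window(
                values=recording.samples[start : start + window_len].copy(),
                label=recording.activity,
                subject_id=recording.subject_id,
                origin={"start": start, "rotation_deg": None},
            )
        )
    return windows


def rotation_matrix(
    roll_deg: float, pitch_deg: float, yaw_deg: float
) -> np.ndarray:
    """Rigid rotation composed as roll (x), then pitch (y), then yaw (z)."""
    r, p, y = np.deg2rad([roll_deg, pitch_deg, yaw_deg])
    cr, sr = np.cos(r), np.sin(r)
    cp, sp = np.cos(p), np.sin(p)
    cy, sy = np.cos(y), np.sin(y)
    rx = np.array([[1, 0, 0], [0, cr, -sr], [0, sr, cr]])
    ry = np.array([[cp, 0, sp], [0, 1, 0], [-sp, 0, cp]])
    rz = np.array([[cy, -sy, 0], [sy, cy, 0], [0, 0, 1]])
    return rz @ ry @ rx


def random_rotation(
    window: Window, config: AugmentationConfig, rng: np.random.Generator
) -> Window:
    """Apply one random rigid rotation to all 128 sample vectors.

    The three angles are drawn uniformly within their ± bounds and recorded
    in the window's provenance.  Label and subject are preserved.
    """
    roll = rng.uniform(-config.max_roll_deg, config.max_roll_deg)
    pitch = rng.uniform(-config.max_pitch_deg, config.max_pitch_deg)
    yaw = rng.uniform(-config.max_yaw_deg, config.max_yaw_deg)
    if roll == 0.0 and pitch == 0.0 and yaw == 0.0:
        rotated = window.values.copy()
    else:
        rotated = window.values @ rotation_matrix(roll, pitch, yaw).T
    origin = dict(window.origin)
    origin["rotation_deg"] = (roll, pitch, yaw)
    return Window(
        values=rotated,
        label=window.label,
        subject_id=window.subject_id,
        origin=origin,
    )


def build_dataset(
    recordings: list[TriaxialRecording], aug: AugmentationConfig
) -> DatasetBundle:
    """Segment and augment recordings into a per-class window bundle.

    Per class, windows appear subject-by-subject in input order; each base
    window is immediately followed by its ``copies_per_window`` rotated
    copies, so the per-class count is ``base * (1 + copies_per_window)``.
    The data is never shuffled.
    """
    if not recordings:
        raise ValueError("build_dataset requires at least one recording")
    rng = np.random.default_rng(aug.rng_seed)
    bundle = DatasetBundle()
    for rec in recordings:
        for base in segment_windows(rec):
            bundle.windows[rec.activity].append(base)
            for _ in range(aug.copies_per_window):
                bundle.windows[rec.activity].append(
                    random_rotation(base, aug, rng)
                )
    return bundle


def _block_sizes(n: int, k: int) -> list[int]:
    """Balanced integer partition: sizes differ by at most one; the larger
    blocks come first."""
    base, rem = divmod(n, k)
    return [base + 1] * rem + [base] * (k - rem)


def make_folds(bundle: DatasetBundle, k: int = 10) -> FoldAssignment:
    """Split each class's ordered window list into k contiguous blocks.

    Raises ``ValueError`` if any non-empty class has fewer than k windows.
    Deterministic: no randomness is involved.
    """
    assignments: dict[ActivityCode, np.ndarray] = {}
    for code in CANONICAL_CODES:
        n = bundle.class_count(code)
        if n == 0:
            continue
        if n < k:
            raise ValueError(
                f"class {code.value} has {n} windows, fewer than k={k}"
            )
        arr = np.repeat(np.arange(k), _block_sizes(n, k))
        assignments[code] = arr
    if not assignments:
        raise ValueError("bundle is empty")
    return FoldAssignment(k=k, assignments=assignments)


def fold_index_splits(
    bundle: DatasetBundle, folds: FoldAssignment
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-fold (train_idx, val_idx) into the flattened bundle order.

    The flattened order is classes in canonical order, windows in bundle
    order within each class — the same order as
    ``[w for c in CANONICAL_CODES for w in bundle.windows[c]]``.
    """
    flat_folds = []
    for code in CANONICAL_CODES:
        wins = bundle.windows[code]
        if not wins:
            continue
        flat_folds.append(folds.assignments[code])
    flat = np.concatenate(flat_folds) if flat_folds else np.empty(0, dtype=int)
    splits = []
    for f in range(folds.k):
        val = np.flatnonzero(flat == f)
        train = np.flatnonzero(flat != f)
        splits.append((train, val))
    return splits
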