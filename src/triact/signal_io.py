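"""Data model and file I/O for labeled tri-axial acceleration recordings.

Native storage is plain delimited text (comma or tab), three numeric
columns ``x, y, z`` in g units, one optional header line, UTF-8.  Window
bundles are a directory of per-window CSV files plus a JSON manifest
mapping class code to an ordered list of window files.

Acceleration is in g units throughout; the nominal sensor range is ±4 g.
Out-of-range samples are retained but logged as a warning, since they
normally indicate a misconfigured synthetic generator rather than
recoverable data.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from triact.codes import ActivityCode, CANONICAL_CODES

logger = logging.getLogger(__name__)

SENSOR_RANGE_G = 4.0
DEFAULT_SAMPLE_RATE_HZ = 45.4
WINDOW_LEN = 128

_DELIM = re.compile(r"[,\t]")


class SignalIOError(Exception):
    """Base class for recording / bundle I/O failures."""


class EmptyFileError(SignalIOError):
    """The file contains no data rows."""


class ColumnCountError(SignalIOError):
    """A data row does not have exactly three columns."""


class NonNumericRowError(SignalIOError):
    """A data row contains a non-numeric entry."""


class WindowShapeError(SignalIOError):
    """A window file does not hold a 128 x 3 array."""


@dataclass
class TriaxialRecording:
    """One subject-activity acceleration signal.

    Parameters
    ----------
    subject_id : str
        Opaque subject identifier.
    activity : ActivityCode
        Ground-truth activity label for the whole recording.
    samples : (N, 3) ndarray
        Acceleration triples (x, y, z) in g units, N >= 1, all finite.
    sample_rate_hz : float
        Sampling frequency, > 0 (default 45.4 Hz).
    """

    subject_id: str
    activity: ActivityCode
    samples: np.ndarray
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError(
                f"samples must be (N, 3), got {self.samples.shape}"
            )
        if self.samples.shape[0] < 1:
            raise ValueError("recording must contain at least one sample")
        if not np.isfinite(self.samples).all():
            raise ValueError("recording contains non-finite samples")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        n_out = int((np.abs(self.samples) > SENSOR_RANGE_G).sum())
        if n_out:
            logger.warning(
                "recording %s/%s: %d sample values exceed the ±%g g sensor "
                "range (retained unmodified)",
                self.subject_id, self.activity.value, n_out, SENSOR_RANGE_G,
            )

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return len(self) / self.sample_rate_hz


@dataclass
class Window:
    """A 128 x 3 labeled segment: the network's input tensor.

    ``origin`` is a free-form provenance record (source recording, start
    index, augmentation angles applied).
    """

    values: np.ndarray
    label: ActivityCode
    subject_id: str
    origin: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (WINDOW_LEN, 3):
            raise WindowShapeError(
                f"window must be ({WINDOW_LEN}, 3), got {self.values.shape}"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("window contains non-finite values")


@dataclass
class DatasetBundle:
    """Per-class ordered lists of windows, concatenated subject-by-subject.

    Within each class, all windows of one subject are contiguous; subjects
    appear in the order their recordings were supplied.
    """

    windows: dict[ActivityCode, list[Window]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code in CANONICAL_CODES:
            self.windows.setdefault(code, [])

    def class_count(self, code: ActivityCode) -> int:
        return len(self.windows[code])

    @property
    def total(self) -> int:
        return sum(len(v) for v in self.windows.values())

    def manifest(self) -> dict:
        """Counts per class and per (class, subject)."""
        per_class = {}
        for code, wins in self.windows.items():
            per_subject: dict[str, int] = {}
            for w in wins:
                per_subject[w.subject_id] = per_subject.get(w.subject_id, 0) + 1
            per_class[code.value] = {
                "count": len(wins),
                "per_subject": per_subject,
            }
        return {"classes": per_class, "total": self.total}

    def validate_contiguity(self) -> None:
        """Raise if any class interleaves windows of different subjects."""
        for code, wins in self.windows.items():
            seen: list[str] = []
            for w in wins:
                if seen and w.subject_id != seen[-1]:
                    if w.subject_id in seen:
                        raise ValueError(
                            f"class {code.value}: subject "
                            f"{w.subject_id!r} windows are not contiguous"
                        )
                    seen.append(w.subject_id)
                elif not seen:
                    seen.append(w.subject_id)


def _parse_rows(path: Path) -> np.ndarray:
    try:
        text = path.read_text(encoding="utf-8")
    except FileNotFoundError:
        raise
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise EmptyFileError(f"{path}: no data rows")
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines, start=1):
        fields = [f.strip() for f in _DELIM.split(line)]
        try:
            values = [float(f) for f in fields]
        except ValueError:
            if lineno == 1:
                continue  # single optional header line
            raise NonNumericRowError(
                f"{path}: non-numeric entry on line {lineno}"
            ) from None
        if len(values) != 3:
            raise ColumnCountError(
                f"{path}: line {lineno} has {len(values)} columns, expected 3"
            )
        rows.append(values)
    if not rows:
        raise EmptyFileError(f"{path}: header only, no data rows")
    return np.array(rows, dtype=float)


def read_recording(
    path: str | Path,
    label: ActivityCode,
    subject_id: str,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
) -> TriaxialRecording:
    """Read a delimited-text recording (three numeric columns, optional
    single header line) into a :class:`TriaxialRecording`.

    Raises
    ------
    FileNotFoundError, EmptyFileError, ColumnCountError, NonNumericRowError
    """
    samples = _parse_rows(Path(path))
    return TriaxialRecording(
        subject_id=subject_id,
        activity=label,
        samples=samples,
        sample_rate_hz=sample_rate_hz,
    )


def write_recording(recording: TriaxialRecording, path: str | Path) -> None:
    """Write a recording as CSV with a header naming axes and units.

    Values are formatted with ``repr`` (shortest exact float form) so a
    read/write round trip is bitwise stable.
    """
    path = Path(path)
    lines = ["x_g,y_g,z_g"]
    for x, y, z in recording.samples:
        lines.append(f"{float(x)!r},{float(y)!r},{float(z)!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_window_bundle(bundle: DatasetBundle, directory: str | Path) -> Path:
    """Write every window as a CSV file plus a JSON manifest.

    Returns the manifest path.  Layout::

        directory/
          manifest.json
          WS/000000.csv, WS/000001.csv, ...
          WF/...
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"classes": {}}
    for code, wins in bundle.windows.items():
        cls_dir = directory / code.value
        entries = []
        if wins:
            cls_dir.mkdir(exist_ok=True)
        for i, w in enumerate(wins):
            rel = f"{code.value}/{i:06d}.csv"
            rows = ["x_g,y_g,z_g"]
            rows += [
                f"{float(x)!r},{float(y)!r},{float(z)!r}"
                for x, y, z in w.values
            ]
            (directory / rel).write_text("\n".join(rows) + "\n", encoding="utf-8")
            entries.append({"file": rel, "subject_id": w.subject_id})
        manifest["classes"][code.value] = entries
    manifest["counts"] = {c.value: len(ws) for c, ws in bundle.windows.items()}
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return manifest_path


def read_window_bundle(
    directory: str | Path, manifest: str | Path | None = None
) -> DatasetBundle:
    """Read a window bundle written by :func:`write_window_bundle`.

    ``manifest`` defaults to ``directory/manifest.json``.  Raises
    :class:`WindowShapeError` for malformed window files and ``KeyError``
    for unknown class codes.
    """
    directory = Path(directory)
    manifest_path = Path(manifest) if manifest else directory / "manifest.json"
    spec = json.loads(manifest_path.read_text(encoding="utf-8"))
    bundle = DatasetBundle()
    for code_str, entries in spec["classes"].items():
        try:
            code = ActivityCode(code_str)
        except ValueError:
            raise KeyError(f"unknown activity code in manifest: {code_str!r}")
        for entry in entries:
            values = _parse_rows(directory / entry["file"])
            if values.shape != (WINDOW_LEN, 3):
                raise WindowShapeError(
                    f"{entry['file']}: expected ({WINDOW_LEN}, 3), "
                    f"got {values.shape}"
                )
            bundle.windows[code].append(
                Window(
                    values=values,
                    label=code,
                    subject_id=entry.get("subject_id", ""),
                    origin={"file": entry["file"]},
                )
            )
    counts = spec.get("counts")
    if counts:
        for code_str, n in counts.items():
            actual = len(bundle.windows[ActivityCode(code_str)])
            if actual != n:
                raise SignalIOError(
                    f"manifest count mismatch for {code_str}: "
                    f"listed {n}, found {actual}"
                )
    return bundle


def stack_windows(
    windows: Iterable[Window],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack windows into ``(X, y)`` arrays: X is (N, 128, 3), y holds
    canonical class indices."""
    wins = list(windows)
    X = np.stack([w.values for w in wins]) if wins else np.empty((0, WINDOW_LEN, 3))
    y = np.array([w.label.index for w in wins], dtype=int)
    return X, y
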