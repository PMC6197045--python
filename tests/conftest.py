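import numpy as np
import pytest

from triact.cnn_model import NetworkSpec
from triact.codes import ActivityCode, CANONICAL_CODES
from triact.signal_io import DatasetBundle, TriaxialRecording, Window


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_window(
    values: np.ndarray | None = None,
    label: ActivityCode = ActivityCode.WS,
    subject_id: str = "s1",
    rng: np.random.Generator | None = None,
) -> Window:
    if values is None:
        rng = rng or np.random.default_rng(0)
        values = rng.normal(0.0, 0.5, size=(128, 3))
    return Window(values=values, label=label, subject_id=subject_id)


def make_recording(
    n: int = 256,
    activity: ActivityCode = ActivityCode.WS,
    subject_id: str = "s1",
    samples: np.ndarray | None = None,
    sample_rate_hz: float = 45.4,
) -> TriaxialRecording:
    if samples is None:
        samples = np.random.default_rng(1).normal(0.0, 0.3, size=(n, 3))
    return TriaxialRecording(
        subject_id=subject_id,
        activity=activity,
        samples=samples,
        sample_rate_hz=sample_rate_hz,
    )


@pytest.fixture
def tiny_bundle() -> DatasetBundle:
    """8 windows per class, two subjects (4 each, contiguous)."""
    rng = np.random.default_rng(7)
    bundle = DatasetBundle()
    for code in CANONICAL_CODES:
        for subject in ("a", "b"):
            for _ in range(4):
                bundle.windows[code].append(
                    make_window(
                        values=rng.normal(0, 0.5, size=(128, 3)),
                        label=code,
                        subject_id=subject,
                    )
                )
    return bundle


@pytest.fixture
def tiny_spec() -> NetworkSpec:
    """Small but structurally complete network for fast training tests."""
    return NetworkSpec(
        input_len=128,
        input_channels=3,
        conv_blocks=((5, 8), (3, 8)),
        pool_size=2,
        fc_width=16,
        dropout_rate=0.5,
        n_classes=10,
    )
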