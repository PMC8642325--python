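import numpy as np
import pytest

from imprintkit import ArenaGeometry, ExperimentConfig, KeypointTable


@pytest.fixture
def geometry() -> ArenaGeometry:
    """Default 90 x 60 cm arena with 30 cm stimulus zones."""
    return ArenaGeometry()


@pytest.fixture
def basic_config() -> ExperimentConfig:
    return ExperimentConfig(
        days=2,
        sessions_per_day=3,
        imprint_session_s=1200.0,
        test_session_s=600.0,
        inter_session_pause_s=600.0,
        imprint_set=("imp_a", "imp_b"),
        test_set_a=("fam_1", "fam_2"),
        test_set_b=("nov_1", "nov_2"),
        phase_order=("imprinting", "test"),
        seed=42,
    )


def make_table(parts: dict[str, np.ndarray], fps: float = 30.0,
               units: str = "px") -> KeypointTable:
    return KeypointTable.from_arrays(parts, fps=fps, units=units)


@pytest.fixture
def head_track_cm():
    """Hand-built 12-frame cm-space track with all head keypoints.

    The body runs left zone -> middle -> right zone; keypoints are a rigid
    triangle heading +x (toward the right screen).
    """
    xs = np.array([5, 10, 20, 28, 40, 45, 50, 62, 70, 80, 85, 88], float)
    ys = np.full_like(xs, 30.0)
    like = np.ones_like(xs)
    body = np.column_stack([xs, ys, like])
    beak = np.column_stack([xs + 2.0, ys, like])
    left_eye = np.column_stack([xs, ys - 0.75, like])
    right_eye = np.column_stack([xs, ys + 0.75, like])
    return make_table(
        {"beak": beak, "left_eye": left_eye, "right_eye": right_eye,
         "head_center": body},
        fps=30.0,
        units="cm",
    )
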