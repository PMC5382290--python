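import numpy as np
import pytest

from ccmigrate.io import read_annotation
from ccmigrate.model import PipelineConfig
from ccmigrate.pipeline import segment_and_track
from ccmigrate.synthetic import (
    MotionSegment,
    SceneConfig,
    annotation_dataframe,
    generate_movie,
)


@pytest.fixture(scope="session")
def running_movie():
    """A short default-noise running movie with ground truth (5 frames)."""
    cfg = SceneConfig(
        motion_schedule=[MotionSegment("running", 4, 1.5, (0.0, 0.0, 1.0))],
        seed=11)
    return generate_movie(cfg)


@pytest.fixture(scope="session")
def segmented_running(running_movie, tmp_path_factory):
    """Full pipeline output on the short running movie."""
    movie, truth = running_movie
    ann_path = tmp_path_factory.mktemp("ann") / "annotation.csv"
    annotation_dataframe(truth, movie).to_csv(ann_path, index=False)
    annotation = read_annotation(ann_path, movie.frame_shape)
    seg = segment_and_track(movie, annotation, PipelineConfig())
    return seg, truth


@pytest.fixture(scope="session")
def rotating_truth():
    """Ground truth of a clean equatorial rotation (8 frames)."""
    cfg = SceneConfig(
        motion_schedule=[MotionSegment("rotating", 7, 5.0, (1.0, 0.0, 0.0))],
        seed=5, bleach_rate=0.0, noise_gaussian=0.0, poisson_noise=False)
    _, truth = generate_movie(cfg)
    return truth


def gaussian_blob(shape, center, sigma, amplitude=100.0):
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return amplitude * np.exp(-0.5 * d2 / sigma**2)
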