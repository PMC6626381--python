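import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import headingdate as hd

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def window32() -> hd.WindowConfig:
    """Grid-matched window geometry for the synthetic study, 32 px input."""
    return hd.WindowConfig(80, 80, 80, classifier_input_size=32)


@pytest.fixture(scope="session")
def train_series() -> hd.ImageSeries:
    """Large synthetic series supplying 500 annotated flowering boxes."""
    params = hd.PhenologyParams(
        emergence_schedule={80 + d: 50 for d in range(10)},
        images_per_day=1, image_w=960, image_h=720, rng_seed=123)
    return hd.generate_field_series(params, name="train")


@pytest.fixture(scope="session")
def training_patches32(train_series, window32):
    pos = hd.extract_positive_patches(train_series, 500, size=32, seed=1)
    neg = hd.sample_negative_patches(train_series, 500, window32, seed=2)
    return pos + neg


@pytest.fixture(scope="session")
def trained_model32(training_patches32) -> hd.SmallCNN:
    """Patch classifier trained under the standard protocol at 32 px."""
    return hd.train_classifier(training_patches32, hd.TrainConfig(rng_seed=0))


@pytest.fixture(scope="session")
def holdout_series() -> hd.ImageSeries:
    params = hd.PhenologyParams(
        emergence_schedule={80 + d: 10 for d in range(5)},
        images_per_day=1, rng_seed=77)
    return hd.generate_field_series(params, name="holdout")


@pytest.fixture(scope="session")
def holdout_patches32(holdout_series, window32):
    pos = hd.extract_positive_patches(holdout_series, 50, size=32, seed=3)
    neg = hd.sample_negative_patches(holdout_series, 50, window32, seed=4)
    return pos + neg


@pytest.fixture(scope="session")
def small_series() -> hd.ImageSeries:
    """Tiny 2-day series (2 then 3 panicles), one image per day."""
    params = hd.PhenologyParams(
        emergence_schedule={80: 2, 81: 3}, images_per_day=1, rng_seed=7)
    return hd.generate_field_series(params, name="tiny")
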