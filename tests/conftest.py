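import datetime

import numpy as np
import pytest

from mrmsi import MRMImage, MRMTransition, PixelGrid


def make_transition(label="t1", q1=313.2, q3=183.1, ce=20.0):
    return MRMTransition(
        label=label, precursor_mz=q1, product_mz=q3, collision_energy=ce
    )


def random_image(seed, n_rows=4, n_cols=5, n_transitions=3, sample_id=None):
    """A random labeled acquisition for round-trip and property tests."""
    rng = np.random.default_rng(seed)
    transitions = [
        make_transition(f"t{j}", q1=300.0 + 10 * j, q3=150.0 + 5 * j, ce=15.0 + j)
        for j in range(n_transitions)
    ]
    grid = PixelGrid(n_rows, n_cols)
    responses = rng.gamma(2.0, 10.0, size=(grid.n_pixels, n_transitions))
    labels = rng.choice(
        ["", "background", "tissue"], size=grid.n_pixels, p=[0.3, 0.3, 0.4]
    ).astype(object)
    return MRMImage(
        grid=grid,
        transitions=transitions,
        responses=responses,
        sample_id=sample_id or f"acq{seed}",
        acquisition_date=datetime.date(2024, 1, 1) + datetime.timedelta(int(seed) % 60),
        pixel_labels=labels,
    )


@pytest.fixture
def tiny_image():
    """2x2 grid, one transition, responses 1..4, with a background pixel."""
    grid = PixelGrid(2, 2)
    return MRMImage(
        grid=grid,
        transitions=[make_transition()],
        responses=np.array([[1.0], [2.0], [3.0], [4.0]]),
        sample_id="tiny",
        pixel_labels=np.array(["background", "", "tissue", "tissue"], dtype=object),
    )
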