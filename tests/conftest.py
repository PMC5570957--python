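"""Shared fixtures: canonical configs and small simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest

import fretscreen as fs
from fretscreen.simulate import QCRates


def zncc_bruteforce(image: np.ndarray, template: np.ndarray):
    """Exhaustive double-loop ZNCC oracle: returns (score, x_topleft, y_topleft)."""
    h, w = template.shape
    t0 = template - template.mean()
    tnorm = np.sqrt((t0 * t0).sum())
    best = (-2.0, -1, -1)
    for y in range(image.shape[0] - h + 1):
        for x in range(image.shape[1] - w + 1):
            win = image[y : y + h, x : x + w]
            w0 = win - win.mean()
            den2 = (w0 * w0).sum()
            score = 0.0 if den2 <= 1e-12 else float((w0 * t0).sum() / (np.sqrt(den2) * tnorm))
            if score > best[0]:
                best = (score, x, y)
    return best


@pytest.fixture(scope="session")
def timing() -> fs.ProtocolTiming:
    return fs.ProtocolTiming()


@pytest.fixture(scope="session")
def template() -> fs.NeuronTemplate:
    return fs.NeuronTemplate(fs.make_template(2.0))


@pytest.fixture(scope="session")
def det_config() -> fs.DetectionConfig:
    return fs.DetectionConfig()


@pytest.fixture(scope="session")
def geom() -> fs.SceneParams:
    """Default trap geometry (regions are derived from it)."""
    return fs.SceneParams()


@pytest.fixture(scope="session")
def make_scene():
    """Factory for randomized but bounded worm scenes."""

    def _make(rng: np.random.Generator, **overrides) -> fs.SceneParams:
        params = dict(
            neuron_x=float(rng.uniform(24, 32)),
            neuron_y=float(rng.uniform(46, 54)),
            z_true_um=float(rng.uniform(30, 70)),
        )
        params.update(overrides)
        return fs.SceneParams(**params)

    return _make


@pytest.fixture(scope="session")
def small_plate_dir(tmp_path_factory):
    """A tiny on-disk plate dataset: 2 compound wells + 1 control, 3 worms each."""
    from fretscreen.screening import PlateLayout

    root = tmp_path_factory.mktemp("small_plate") / "plate"
    layout = PlateLayout(
        {"B2": "compound", "B3": "compound", "B11": "vehicle_control"},
        {"B2": "drugA", "B3": "drugB"},
    )
    fs.simulate_plate_to_dir(
        layout, root, effects={"B2": 0.8}, worms_per_well=3, cv=0.1,
        qc_rates=QCRates(0.0, 0.0, 0.0, 0.0), seed=11,
    )
    return root


@pytest.fixture(scope="session")
def integration_plate_dir(tmp_path_factory):
    """The 12-well integration plate: known hit structure, QC classes, default noise."""
    root = tmp_path_factory.mktemp("integration") / "plate"
    layout, effects = fs.demo_plate()
    fs.simulate_plate_to_dir(
        layout, root, effects=effects, worms_per_well=10, cv=0.15, seed=2026,
    )
    return root, effects
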