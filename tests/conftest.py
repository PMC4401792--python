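"""Shared fixtures: the standard simulated tissue and derived artifacts."""

from __future__ import annotations

import numpy as np
import pytest

from ajtrack.preprocess import clahe_3d
from ajtrack.synthetic import (
    RenderParams,
    TissueSimulationParams,
    generate_tissue_sequence,
    render_volume,
)


@pytest.fixture(scope="session")
def standard_sequence():
    """The default study scenario: 50 cells, 10 frames, 3 mitoses, 2 apoptoses."""
    return generate_tissue_sequence(TissueSimulationParams(seed=0))


@pytest.fixture(scope="session")
def standard_cells(standard_sequence):
    """Per-frame (cells, cell graph, positions) and boundary rings."""
    per_frame = [f.cell_objects() for f in standard_sequence.frames]
    boundaries = [f.boundary_ring() for f in standard_sequence.frames]
    return per_frame, boundaries


@pytest.fixture(scope="session")
def rendered_frame0(standard_sequence):
    """Frame 0 rendered at the default (moderate) noise level, plus truth."""
    rp = RenderParams(seed=0)
    vol = render_volume(standard_sequence.frames[0], rp)
    return vol, rp


@pytest.fixture(scope="session")
def equalized_frame0(rendered_frame0):
    vol, rp = rendered_frame0
    return clahe_3d(vol, tile_shape=(12, 33, 33), clip_limit=0.02), rp


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
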