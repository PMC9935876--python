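"""Shared fixtures: every structural test runs on generator output with
planted ground truth, so expected values are known exactly."""

from __future__ import annotations

import numpy as np
import pytest

from pcpcad.synthetic import (
    SyntheticComplexSpec,
    SyntheticImageSpec,
    make_cell_image,
    make_msa,
    make_toy_complex,
)

PLANTED = [
    ("EC1", "EC2", "salt_bridge", 3.0),
    ("EC2", "EC3", "hbond", 3.0),
    ("EC3", "EC4", "vdw", 5.0),
]


@pytest.fixture(scope="session")
def toy_bundle():
    """Annotated two-chain complex with one planted contact of each kind."""
    spec = SyntheticComplexSpec(planted_contacts=list(PLANTED), seed=11)
    return make_toy_complex(spec)


@pytest.fixture(scope="session")
def bent_pair():
    """(bent, unbent) twin complexes differing by a 30° EC1 hinge bend."""
    bent, ann, _ = make_toy_complex(SyntheticComplexSpec(hinge_bend=("EC1", 30.0), seed=5))
    straight, _, _ = make_toy_complex(SyntheticComplexSpec(seed=5))
    return bent, straight, ann


@pytest.fixture(scope="session")
def cell_image():
    spec = SyntheticImageSpec(seed=4)
    return make_cell_image(spec), spec


@pytest.fixture(scope="session")
def conserved_msa():
    return make_msa(18, 60, conserved_columns=set(range(30)), motif_plant=35, seed=9)


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
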