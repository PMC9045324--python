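"""Shared fixtures: small synthetic replicons and annotation files.

All fixture data is generated programmatically (seeded) at test time.
"""

from __future__ import annotations

import numpy as np
import pytest

from linrep.io import Replicon
from linrep.simulate import generate_replicon, plant_cassettes


@pytest.fixture(scope="session")
def small_replicon() -> Replicon:
    """A 30-kb seeded high-GC linear replicon."""
    return generate_replicon(30_000, gc_target=0.72, seed=11, replicon_id="fix30k")


@pytest.fixture(scope="session")
def annotated_plasmid():
    """A 300-kb plasmid with planted transposase/regulator/hypothetical CDS."""
    rep = generate_replicon(300_000, gc_target=0.696, seed=17, replicon_id="plasmid")
    feats = plant_cassettes(
        rep,
        [
            (10, 1000, "transposase"),
            (8, 800, "transcriptional_regulator"),
            (40, 700, "hypothetical"),
        ],
        seed=18,
    )
    return rep, feats


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
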