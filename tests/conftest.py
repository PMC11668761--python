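from __future__ import annotations

import numpy as np
import pytest

from locmorph.fieldio import BrainMask, VectorField, assemble_cohort
from locmorph.synthdata import SimConfig, simulate_fields, simulate_genotypes


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_mask() -> BrainMask:
    """Irregular 6x5x4 mask with 2 mm spacing."""
    gen = np.random.default_rng(7)
    vox = gen.random((6, 5, 4)) < 0.6
    vox[3, 2, 1] = True  # guarantee non-empty
    return BrainMask(voxels=vox, spacing=(2.0, 2.0, 2.0))


@pytest.fixture
def small_cohort(small_mask, rng):
    """12 random subjects on the small mask."""
    fields = [
        VectorField(data=rng.standard_normal(small_mask.dims + (3,)),
                    spacing=small_mask.spacing)
        for _ in range(12)
    ]
    return assemble_cohort(fields, small_mask, [f"s{i}" for i in range(12)])


@pytest.fixture(scope="session")
def oracle_cohort():
    """The small synthetic cohort used by the dense-oracle checks.

    20 subjects on a 6^3 grid, seed 0 -- small enough that dense p x p
    eigendecompositions are instant.
    """
    cfg = SimConfig(n=20, m=10, grid=(6, 6, 6), spacing=(2.0, 2.0, 2.0),
                    missing_rate=0.0, seed=0)
    g = simulate_genotypes(cfg)
    fields, mask, covars, truth = simulate_fields(cfg, g)
    cohort = assemble_cohort(fields, mask, [str(i) for i in g.samples["iid"]])
    return cohort, mask
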