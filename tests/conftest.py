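import numpy as np
import pytest

from cuemed import synthetic


@pytest.fixture(scope="session")
def small_design():
    """Two subjects per group, full 5x12 schedule."""
    spec = synthetic.DesignSpec(n_subjects_per_group=2, seed=11)
    return synthetic.generate_design(spec)


@pytest.fixture(scope="session")
def rated_table(small_design):
    params = synthetic.RatingParams.paper_defaults()
    return synthetic.generate_ratings(small_design, params, seed=12)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def planted_brain():
    """Small dataset with one strong planted mediator region."""
    spec = synthetic.DesignSpec(n_subjects_per_group=4, seed=21)
    table = synthetic.generate_design(spec)
    table = synthetic.generate_ratings(
        table, synthetic.RatingParams.paper_defaults(), seed=22)
    region = synthetic.MediatorRegion(
        name="planted",
        coords=[[x, y, z] for x in (3, 4) for y in (3, 4) for z in (3, 4)],
        a_mean=0.9, a_sd=0.2, b_mean=0.9, b_sd=0.2)
    brain_spec = synthetic.BrainSimSpec(shape=(8, 8, 8), regions=(region,),
                                        region_noise_sd=1.0,
                                        voxel_noise_sd=1.0, seed=23)
    return synthetic.generate_brain(table, brain_spec, seed=23), brain_spec
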