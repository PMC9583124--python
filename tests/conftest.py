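"""Shared fixtures: desk-scale datasets and trained decoders.

Everything is generated at the reduced 128 px profile so the whole suite runs
on one CPU in minutes; session scope keeps the expensive artifacts (simulated
datasets, trained CNNs) shared across test modules.
"""

import numpy as np
import pytest

import morphocode as mc


SMALL_SPEC = dict(conv_filters=(8, 16), fc_width=32, max_epochs=50)


@pytest.fixture(scope="session")
def codebook3():
    return mc.build_codebook(["A", "B", "C"], 2)


@pytest.fixture(scope="session")
def reduced_cfg():
    """(params, layout, geometry, seeding_noise) at snr 3.5."""
    return mc.profiles.reduced(n_bits=2, snr=3.5)


@pytest.fixture(scope="session")
def train3(codebook3, reduced_cfg):
    params, layout, geom, noise = reduced_cfg
    return mc.generate_dataset(
        codebook3, layout, params, geom, reps_per_class=16, base_seed=11,
        seeding_noise=noise,
    )


@pytest.fixture(scope="session")
def test3(codebook3, reduced_cfg):
    params, layout, geom, noise = reduced_cfg
    return mc.make_test_set(
        codebook3, layout, params, geom, reps_per_class=8, base_seed=11,
        seeding_noise=noise,
    )


@pytest.fixture(scope="session")
def model3(train3):
    spec = mc.DecoderSpec(n_classes=3, **SMALL_SPEC)
    return mc.train_decoder(train3, spec, rng_seed=0)


@pytest.fixture(scope="session")
def branching_pattern(reduced_cfg):
    """One default-parameter pattern plus its seeding field."""
    params, layout, geom, noise = reduced_cfg
    rng = np.random.default_rng(5)
    field = mc.bits_to_seeding("10", layout, noise, rng)
    return mc.simulate(field, params, geom, rng), field
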