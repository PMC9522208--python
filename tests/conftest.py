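import numpy as np
import pytest

from spiroscale.morphometry import SPIRACLE_LABELS, Specimen, SpiracleMeasurement
from spiroscale.synth import GeneratorConfig, generate_study


@pytest.fixture(scope="session")
def default_study():
    """One seeded synthetic study at the default design (17 specimens,
    10 species, masses in 0.097-18 g)."""
    cfg = GeneratorConfig(seed=20)
    specimens, tree = generate_study(cfg)
    return cfg, specimens, tree


@pytest.fixture(scope="session")
def noiseless_study():
    """Noise-free, phylogeny-free study: every log-log relation exact."""
    cfg = GeneratorConfig(
        seed=21,
        area_noise_sd=(0.0,) * 8,
        depth_noise_sd=(0.0,) * 8,
        within_species_mass_jitter=0.0,
        lambda_signal=0.0,
    )
    specimens, tree = generate_study(cfg)
    return cfg, specimens, tree


def make_specimen(specimen_id="b1", species="spX", mass=1.0, d_t=2.0, d_s=1.0,
                  depth=0.5, labels=SPIRACLE_LABELS):
    """A specimen with identical spiracles, handy for hand oracles."""
    return Specimen(
        specimen_id=specimen_id,
        species=species,
        sex="F",
        mass=mass,
        spiracles=tuple(
            SpiracleMeasurement(
                spiracle_label=l, d_transverse=d_t, d_sagittal=d_s, depth=depth
            )
            for l in labels
        ),
    )


@pytest.fixture
def uniform_specimen():
    return make_specimen()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
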