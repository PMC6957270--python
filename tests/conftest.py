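import numpy as np
import pytest

from signalscan.images import ImageRecord, Manifest
from signalscan.synthetic import default_spec, generate_dataset, recovery_experiment


def make_record(image_id, individual, species, pixels, side="whole"):
    return ImageRecord(
        image_id=image_id,
        individual_id=individual,
        species_id=species,
        pixels=np.asarray(pixels, dtype=np.float64),
        side=side,
    )


def constant_image(shape, value):
    """H x W x 3 image with a constant per-channel value (scalar or 3-vector)."""
    h, w = shape
    value = np.broadcast_to(np.asarray(value, dtype=np.float64), (3,))
    return np.broadcast_to(value, (h, w, 3)).copy()


def separable_manifest(shape=(8, 8), n_species=3, n_individuals=4, n_images=2):
    """Species of mutually distinct constant images; trivially separable."""
    records = []
    for s in range(n_species):
        value = (s + 1) / (n_species + 1)
        for i in range(n_individuals):
            for k in range(n_images):
                records.append(
                    make_record(
                        f"sp{s}_i{i}_img{k}", f"sp{s}_i{i}", f"sp{s}",
                        constant_image(shape, value),
                    )
                )
    return Manifest(tuple(records))


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def default_dataset():
    """The desk-scale synthetic dataset at seed 1 (manifest, ground truth)."""
    return generate_dataset(default_spec(seed=1))


@pytest.fixture(scope="session")
def default_recovery():
    """Full-pipeline recovery report on the default synthetic spec, seed 1."""
    return recovery_experiment(default_spec(seed=1))
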