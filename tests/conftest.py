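import numpy as np
import pytest
from hypothesis import settings

from secretominer import registry_io, simulate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def registry():
    return registry_io.load_species_registry()


@pytest.fixture(scope="session")
def fixture_clusters(registry):
    return registry_io.load_cluster_fixture(registry)


@pytest.fixture(scope="session")
def dataset():
    """One default synthetic dataset shared by read-only tests."""
    return simulate.generate_proteome(simulate.SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def small_dataset():
    """A small eight-species dataset (two species per lifestyle group)."""
    assignment = {}
    for i, lifestyle in enumerate(
        ["Ectomycorrhizal", "White rot", "Brown rot", "Litter decayers"] * 2
    ):
        assignment[f"Simulatus minor{i + 1:02d}"] = lifestyle
    cfg = simulate.SimulationConfig(
        seed=11, n_species=8, lifestyle_assignment=assignment, proteome_size=150
    )
    return simulate.generate_proteome(cfg)


def random_protein(rng: np.random.Generator, length: int, protein_id="p", species=""):
    from secretominer.models import AMINO_ACIDS, ProteinRecord

    seq = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))
    return ProteinRecord(protein_id, seq, species)
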