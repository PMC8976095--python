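import numpy as np
import pytest
from hypothesis import settings

from toeholdkit import rnafold, synthgen
from toeholdkit.seqcore import BarcodeGene, SequenceRecord

settings.register_profile("suite", max_examples=50, derandomize=True, deadline=None)
settings.load_profile("suite")

BASES = np.array(list("ACGU"))


def random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


@pytest.fixture(scope="session")
def unit_model() -> rnafold.EnergyModel:
    return rnafold.EnergyModel.unit()


@pytest.fixture(scope="session")
def stack_model() -> rnafold.EnergyModel:
    return rnafold.DEFAULT_MODEL


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_family() -> synthgen.GeneFamily:
    """A compact three-marker panel used across design/specificity tests."""
    return synthgen.synth_gene_family(
        synthgen.GeneFamilySpec(
            n_species=4, gene_length=150, per_site_substitution_rate=0.1, seed=7
        )
    )


def make_gene(seq: str, species: str = "spX", marker: str = "MatK") -> BarcodeGene:
    return BarcodeGene(species, marker, SequenceRecord(f"{species}_{marker}", seq))
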