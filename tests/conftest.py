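import hypothesis
import pytest

import rlenet as r
from rlenet.core import EnzymeIndex, EnzymeRecord, PathwayCategory

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")

CARB = PathwayCategory.CARBOHYDRATE
LIPID = PathwayCategory.LIPID
NUC = PathwayCategory.NUCLEOTIDE


def mkenzyme(ec, organisms=("hsa",), is_rle=False, categories=(CARB,)):
    return EnzymeRecord(
        ec=ec,
        organisms=frozenset(organisms),
        is_rle=is_rle,
        categories=frozenset(categories),
    )


@pytest.fixture
def toy_enzymes():
    """Five enzymes in one organism; E1 and E3 rate-limiting."""
    return EnzymeIndex(
        [
            mkenzyme("1.1.1.1", is_rle=True, categories=(CARB,)),
            mkenzyme("2.2.2.2", categories=(LIPID,)),
            mkenzyme("3.3.3.3", is_rle=True, categories=(NUC,)),
            mkenzyme("4.4.4.4", categories=(CARB, LIPID)),
            mkenzyme("5.5.5.5", categories=(NUC,)),
        ]
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted synthetic dataset shared across read-only tests."""
    config = r.GeneratorConfig(seed=42, n_enzymes=120, n_compounds=100)
    dataset, truth = r.generate(config)
    return dataset, truth
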