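import numpy as np
import pytest

from varstruct.annotate import AnnotationConfig, annotate_structure
from varstruct.pdbio import Residue
from varstruct.synthetic import (
    ChainRecipe,
    Segment,
    build_ideal_structure,
    bundle_recipe,
    mixed_chain_recipe,
)
from varstruct.variants import VariantRecord, VariantSet


@pytest.fixture(scope="session")
def helix_chain():
    chains = build_ideal_structure(
        [ChainRecipe("A", [Segment("helix", "A" * 12)])], seed=11)
    return chains["A"]


@pytest.fixture(scope="session")
def mixed_structure():
    return build_ideal_structure(mixed_chain_recipe(), seed=1)


@pytest.fixture(scope="session")
def mixed_annotation(mixed_structure):
    return annotate_structure(mixed_structure, AnnotationConfig())


@pytest.fixture(scope="session")
def bundle_structure():
    return build_ideal_structure(bundle_recipe(), seed=2)


@pytest.fixture(scope="session")
def bundle_annotation(bundle_structure):
    return annotate_structure(bundle_structure, AnnotationConfig())


def make_residue(chain, number, aa, name3, atoms):
    return Residue(chain, str(number), aa, name3,
                   {k: np.asarray(v, dtype=float) for k, v in atoms.items()})


@pytest.fixture
def toy_variants():
    recs = [
        VariantRecord("P1", 1, "A", "V", "SVD", "toy", 100000),
        VariantRecord("P1", 5, "D", "R", "SVD", "toy", 100001),
        VariantRecord("P1", 9, "W", "S", "SVD", "toy", 100002),
    ]
    return VariantSet("SVD", recs)
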