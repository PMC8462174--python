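import numpy as np
import pytest

from mfnet import FuzzyTraitTable, SampleMatrix


@pytest.fixture
def one_category_traits():
    """Three species, three modalities in a single trait category."""
    return FuzzyTraitTable(
        species_ids=["spA", "spB", "spC"],
        modality_ids=["m1", "m2", "m3"],
        category_of_modality={"m1": "cat", "m2": "cat", "m3": "cat"},
        scores=np.array([[1.0, 1.0, 0.0], [0.0, 1.0, 1.0], [1.0, 0.0, 1.0]]),
    )


@pytest.fixture
def block_traits():
    """Six species in two planted blocks of three; block members share all
    five of their modalities, blocks disjoint, N = 10."""
    scores = np.zeros((6, 10))
    scores[:3, :5] = 1.0
    scores[3:, 5:] = 1.0
    return FuzzyTraitTable(
        species_ids=[f"sp{i}" for i in range(6)],
        modality_ids=[f"m{j}" for j in range(10)],
        category_of_modality={f"m{j}": "cat" for j in range(10)},
        scores=scores,
    )


@pytest.fixture
def abundance_small():
    return SampleMatrix(
        sample_ids=["s1", "s2"],
        variable_ids=["sp1", "sp2", "sp3"],
        values=np.array([[3.0, 4.0, 2.0], [0.0, 1.0, 5.0]]),
        kind="abundance",
    )
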