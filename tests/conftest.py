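import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mutclust3d import MutationTable, SyntheticSpec, make_structure

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def collinear_structure():
    return make_structure(SyntheticSpec(N=30, geometry="collinear", seed=11))


@pytest.fixture
def hairpin_structure():
    return make_structure(SyntheticSpec(N=20, geometry="hairpin", seed=11))


@pytest.fixture
def figure_counts():
    """Worked toy example: 7 mutations over residues 2, 3, 5 and 6."""
    return {2: 1, 3: 3, 5: 1, 6: 2}


@pytest.fixture
def figure_table(figure_counts):
    return MutationTable(protein_id="TOY", counts=dict(figure_counts), m=3)


@pytest.fixture
def hairpin_table():
    """Two mutation groups at opposite sequence ends of the hairpin.

    Residues 2/3 and 18/19 are sequence-distant but face each other
    across the hairpin strands (~5 Å apart).
    """
    return MutationTable(
        protein_id="SYNTH", counts={2: 2, 3: 2, 18: 2, 19: 2}, m=4
    )
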