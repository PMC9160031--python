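import numpy as np
import pytest

from targetscreen.chemio import parse_molecule
from targetscreen.synthetic import DECORATIONS, SCAFFOLD_TEMPLATES, SyntheticSpec


@pytest.fixture(scope="session")
def random_molecules():
    """60 structurally varied molecules minted from the synthetic vocabulary."""
    rng = np.random.default_rng(20240917)
    mols = []
    for i in range(60):
        template = SCAFFOLD_TEMPLATES[rng.integers(len(SCAFFOLD_TEMPLATES))]
        a, b = rng.choice(DECORATIONS, size=2)
        mols.append(parse_molecule(template.format(a, b), f"rand{i}"))
    return mols


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(seed=11, n_targets=4, ligands_per_target=8,
                         n_molecules=60, n_scaffolds=6)
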