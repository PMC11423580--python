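import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from helpers import random_rows  # noqa: E402


@pytest.fixture
def seeded_rows():
    return random_rows


@pytest.fixture
def toy_clusters():
    from predrigid.synthetic import gen_toy_clusters

    return gen_toy_clusters(n_structures=6, atoms_range=(2, 5), box=3.5, seed=11)
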