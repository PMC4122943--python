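import numpy as np
import pytest

from mitorearr import ancestral_order
from mitorearr.models import GeneLabel, SignedGeneOrder

# toy circles use real PCG names so GeneLabel validation passes
TOY9 = ["cox1", "cox2", "cox3", "cob", "nad1", "nad2", "nad3", "atp6", "atp8"]


def toy_order(tokens, taxon="toy"):
    return SignedGeneOrder.from_tokens(tokens, taxon=taxon)


def random_toy_order(rng: np.random.Generator, n: int, taxon="rand"):
    names = TOY9[:n]
    perm = rng.permutation(n)
    return SignedGeneOrder(
        [(GeneLabel(names[i]), int(rng.choice([1, -1]))) for i in perm],
        taxon=taxon,
    )


@pytest.fixture(scope="session")
def anc():
    return ancestral_order()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
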