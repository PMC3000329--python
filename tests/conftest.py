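import numpy as np
import pytest

from paleonumt.mito_core import load_default_gene_map
from paleonumt.synthetic_data import random_mito_reference

_CONV = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CONV[_b] = _i


def encode_rows(seqs: dict[str, str], order: list[str]) -> np.ndarray:
    """Stack sequences into the int8 code matrix used by the likelihood
    and distance machinery (0..3 = ACGT, 4 = gap/N)."""
    return np.vstack(
        [_CONV[np.frombuffer(seqs[l].encode(), dtype=np.uint8)] for l in order]
    )


def roles_for(labels) -> dict[str, str]:
    roles = {}
    for name in labels:
        if name.startswith("human"):
            roles[name] = "human"
        elif name == "neanderthal":
            roles[name] = "neanderthal"
        elif name == "numt":
            roles[name] = "numt"
        elif name == "chimp":
            roles[name] = "chimp"
        elif name == "bonobo":
            roles[name] = "bonobo"
        else:
            roles[name] = "outgroup"
    return roles


@pytest.fixture(scope="session")
def gene_map():
    return load_default_gene_map()


@pytest.fixture(scope="session")
def reference(gene_map):
    return random_mito_reference(0, gene_map)
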