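import numpy as np
import pytest

from famkit import AlignParams, ReferenceLoops, SeqRecord
from famkit.synthetic import default_family_config, generate_family


@pytest.fixture(scope="session")
def params():
    return AlignParams()


@pytest.fixture(scope="session")
def calmodulin_ref():
    return ReferenceLoops.default()


@pytest.fixture(scope="session")
def default_family():
    """One deterministic draw of the standard synthetic family."""
    cfg = default_family_config(seed=11)
    records, truth = generate_family(cfg)
    return cfg, records, truth


def make_protein(rng: np.random.Generator, length: int,
                 rec_id: str = "p") -> SeqRecord:
    residues = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
    return SeqRecord(id=rec_id, residues=residues)
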