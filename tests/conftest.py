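import pytest

from rnaccess.accessibility import accessibility_all
from rnaccess.energy_model import EnergyParameters
from rnaccess.inside import fill_inside
from rnaccess.oracle import enumerate_structures, random_sequences
from rnaccess.outside import fill_outside, record_accessibility_helpers
from rnaccess.sequence import RnaSequence


@pytest.fixture(scope="session")
def params():
    return EnergyParameters.default()


@pytest.fixture(scope="session")
def zero_params():
    return EnergyParameters.zeroed()


@pytest.fixture(scope="session")
def small_seqs():
    """A quick seeded batch of short sequences for oracle comparisons."""
    return random_sequences(10, (8, 14), 0.5, seed=20210) + [
        RnaSequence("GGGAAACCC", name="hairpin"),
        RnaSequence("GCGAAAGC", name="hairpin-only"),
    ]


@pytest.fixture(scope="session")
def folded(params, small_seqs):
    """(seq, ensemble, inside, outside-with-helpers) for each fixture seq."""
    out = []
    for seq in small_seqs:
        ens = enumerate_structures(seq, params)
        ins = fill_inside(seq, params)
        ot = fill_outside(seq, params, ins)
        record_accessibility_helpers(seq, params, ins, ot)
        out.append((seq, ens, ins, ot))
    return out


@pytest.fixture(scope="session")
def accessibilities(params, folded):
    return [
        (seq, ens, accessibility_all(seq, params, ins, ot))
        for seq, ens, ins, ot in folded
    ]
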