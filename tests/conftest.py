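import numpy as np
import pytest

import mtmixgraph as mg


def make_reference(length, seed=0, fixed=None, name="synthref"):
    """Random A/C/G/T reference with specific bases forced at 1-based
    positions (used to rebuild printed worked examples on synthetic
    backbones)."""
    rng = np.random.default_rng(seed)
    bases = list(rng.choice(list("ACGT"), size=length))
    for pos, b in (fixed or {}).items():
        bases[pos - 1] = b
    return mg.ReferenceSequence(name, "".join(bases))


@pytest.fixture
def fig2_ref():
    # two adjacent ambiguous sites on AACCT spell AATTT/AATCT/AACTT/AACCT
    return mg.ReferenceSequence("fig2", "AACCT")


@pytest.fixture
def fig2_graph(fig2_ref):
    return mg.build_mixture_graph(mg.parse_variant_string("3Y 4Y", fig2_ref))


@pytest.fixture
def fig3_ref():
    return mg.ReferenceSequence("fig3", "AACT")


@pytest.fixture
def fig3_graph(fig3_ref):
    # AACT mixed with AACCT: an optional C insertion after position 3
    return mg.build_mixture_graph(mg.parse_variant_string("3.1C", fig3_ref))


@pytest.fixture
def homopolymer_ref():
    return mg.ReferenceSequence("hp", "AACAAGT")


@pytest.fixture
def worked_ref():
    # reference with A at 73/154/178 for the 73G 154W 178M example
    return make_reference(200, seed=11, fixed={73: "A", 154: "A", 178: "A"})


def decode(ref, variant_string):
    profile = mg.parse_variant_string(variant_string, ref, single_source=True)
    return mg.decode_haplotype(ref, profile.calls)
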