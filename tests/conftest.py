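import pytest

from mitoremodel import synth


@pytest.fixture(scope="session")
def two_family():
    """One two-family + outgroup study dataset, shared across tests."""
    return synth.generate_two_family_dataset(seed=11)


@pytest.fixture(scope="session")
def template_orders():
    """Ancestral template order and its PCG-only projection, anchored."""
    from mitoremodel import PCGS
    from mitoremodel.gene_order import SignedGeneOrder, anchor_order

    full, lengths = synth.ancestral_template()
    pcg = anchor_order(SignedGeneOrder(
        "template_pcg", tuple(x for x in full.genes if x[0] in PCGS),
        "circular"))
    return full, pcg, lengths
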