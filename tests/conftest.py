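import pytest

from pepfunnel.peptide import (PeptideRecord, semaglutide_template,
                               semaglutide_template_spec)
from pepfunnel.synth import build_ideal_helix, combine_models


@pytest.fixture(scope="session")
def template():
    return semaglutide_template()


@pytest.fixture(scope="session")
def template_spec():
    return semaglutide_template_spec()


@pytest.fixture(scope="session")
def helix_model(template):
    """Ideal 31-residue agonist helix, chain A."""
    return build_ideal_helix(template)


@pytest.fixture(scope="session")
def complex_model(template):
    """Two-chain synthetic complex: agonist helix A + receptor stand-in B."""
    a = build_ideal_helix(template, chain_id="A")
    b = build_ideal_helix(template, chain_id="B", origin=(0.0, 9.0, 0.0),
                          start_serial=1000)
    return combine_models(a, b)


def make_record(seq: str, rid: str = "x", start: int = 7) -> PeptideRecord:
    return PeptideRecord(rid, tuple(seq), start)
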