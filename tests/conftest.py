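import pytest

from npvs.chem_io import Library, record_from_smiles
from npvs.fixtures import FixtureSpec, generate_library, reference_screening_model


def rec(smiles, rec_id="m", **kw):
    r = record_from_smiles(smiles, rec_id, **kw)
    assert r is not None, f"unparseable test SMILES {smiles!r}"
    return r


@pytest.fixture(scope="session")
def fixture_library():
    """Small block-assembled library with brute-forced ground truths."""
    return generate_library(FixtureSpec(n_molecules=10, seed=11))


@pytest.fixture(scope="session")
def ref_model():
    """Rigid 4-aminophenol reference model (2 HBD, 2 HBA, AR)."""
    return reference_screening_model()


@pytest.fixture()
def smi_file(tmp_path):
    def _write(lines, name="lib.smi"):
        p = tmp_path / name
        p.write_text("\n".join(lines) + "\n")
        return p

    return _write
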