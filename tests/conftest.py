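import pytest
from rdkit import Chem, RDLogger

from fragcompare.chem_io import MoleculeRecord
from fragcompare.synthetic_data import GeneratorParams, generate_benchmark_suite, generate_library

RDLogger.DisableLog("rdApp.*")


def mol(smiles: str) -> Chem.Mol:
    out = Chem.MolFromSmiles(smiles)
    assert out is not None, f"bad test SMILES {smiles!r}"
    return out


def canonical(smiles: str) -> str:
    return Chem.MolToSmiles(mol(smiles))


@pytest.fixture(scope="session")
def benchmark_suite():
    return generate_benchmark_suite(seed=7, n=120)


@pytest.fixture(scope="session")
def np_like_records():
    return generate_library(GeneratorParams(n=150, profile="np_like", seed=3))


@pytest.fixture(scope="session")
def synthetic_like_records():
    return generate_library(GeneratorParams(n=150, profile="synthetic_like", seed=4))


@pytest.fixture()
def pending(request):
    def make(smiles: str, source_id: str = "x") -> MoleculeRecord:
        return MoleculeRecord(source_id=source_id, raw_smiles=smiles)

    return make
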