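import numpy as np
import pytest

from xlmstruct.core import CrossLink, ResidueRef, c3_annotation, default_bs3_linker
from xlmstruct.quant import Detection, QuantRecord


@pytest.fixture(scope="session")
def bs3():
    return default_bs3_linker()


@pytest.fixture(scope="session")
def c3():
    return c3_annotation()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_record(
    sample="I-1",
    experiment="I",
    heavy="condition1",
    pep="p1",
    res=(10, 20),
    area_light=1e6,
    area_heavy=1e6,
    detection=Detection.DOUBLET,
):
    return QuantRecord(
        sample_id=sample,
        experiment_id=experiment,
        label_orientation=heavy,
        peptide_pair_id=pep,
        crosslink=CrossLink(ResidueRef(res[0]), ResidueRef(res[1])),
        area_light=area_light,
        area_heavy=area_heavy,
        detection=detection,
    )


@pytest.fixture
def record_factory():
    return make_record


TOY_PDB = """\
CRYST1  100.000  100.000  100.000  90.00  90.00  90.00 P 1           1
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA  LYS A   2       4.000   4.000   0.000  1.00  0.00           C
ATOM      4  CA  SER A   3       8.000   0.000   3.000  1.00  0.00           C
END
"""


@pytest.fixture
def toy_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path
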