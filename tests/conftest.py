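import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def write_fasta_file(tmp_path):
    def _write(text, name="seqs.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


TOY_GFF3 = """\
##gff-version 3
scf1\tsrc\tgene\t1\t12\t.\t+\t.\tID=gene1
scf1\tsrc\tmRNA\t1\t12\t.\t+\t.\tID=tx1;Parent=gene1
scf1\tsrc\tCDS\t10\t12\t.\t+\t0\tID=tx1.c2;Parent=tx1
scf1\tsrc\tCDS\t1\t6\t.\t+\t0\tID=tx1.c1;Parent=tx1
"""


@pytest.fixture
def toy_gff3(tmp_path):
    path = tmp_path / "toy.gff3"
    path.write_text(TOY_GFF3)
    return path
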