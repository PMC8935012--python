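import numpy as np
import pytest

from pcfm.effects import PcfmTemplate
from pcfm.phylo import tree_from_newick
from pcfm.simulate import sample_tree


@pytest.fixture(scope="session")
def balanced4():
    return tree_from_newick("((a:1,b:1):1,(c:1,d:1):1);")


@pytest.fixture(scope="session")
def tree20():
    """A fixed 20-leaf tree shared by the simulation-heavy tests."""
    return sample_tree(20, 0.05, np.random.default_rng(2024))


@pytest.fixture(scope="session")
def del21_template():
    """2-nt deletion + 1-nt deletion separated by 26 nt (a published
    high-confidence pair shape)."""
    return PcfmTemplate("deletion", 2, "deletion", 1, 26)


@pytest.fixture()
def tmp_fasta(tmp_path):
    def write(records, name="aln.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")
        return path

    return write
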