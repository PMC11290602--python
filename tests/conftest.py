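import dendropy
import pytest


def tree_from(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             rooting="default-rooted")


@pytest.fixture
def cherry():
    return tree_from("(A:10,B:10);")


@pytest.fixture
def three_tip():
    # ((A:4,B:4):6,C:10); root age 10, A/B stem at 4
    return tree_from("((A:4,B:4):6,C:10);")


@pytest.fixture
def write_trees(tmp_path):
    def _write(newicks, name="trees.nwk"):
        path = tmp_path / name
        path.write_text("\n".join(newicks) + "\n")
        return path
    return _write
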