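import dendropy
import matplotlib
import pytest

from polyqevo.seqio import CodonAlignment

matplotlib.use("Agg")


@pytest.fixture
def four_leaf_tree():
    return dendropy.Tree.get(data="((a,b),(c,d));", schema="newick",
                             preserve_underscores=True)


@pytest.fixture
def four_leaf_alignment():
    # one variable site: CAG/CAG vs CAA/CAA
    return CodonAlignment(
        ["a", "b", "c", "d"],
        {"a": ["ATG", "CAG"], "b": ["ATG", "CAG"],
         "c": ["ATG", "CAA"], "d": ["ATG", "CAA"]},
    )


@pytest.fixture
def toy_nexus(tmp_path):
    """3-taxon Nexus (9 nt each) with an embedded tree holding an extra leaf."""
    text = """#NEXUS
BEGIN DATA;
    DIMENSIONS NTAX=3 NCHAR=9;
    FORMAT DATATYPE=DNA MISSING=? GAP=-;
    MATRIX
        a ATGCAGCAA
        b ATGCAGCAG
        c ATGCAACAA
    ;
END;
BEGIN TREES;
    TREE t1 = ((a,b),(c,d));
END;
"""
    path = tmp_path / "toy.nex"
    path.write_text(text)
    return path
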