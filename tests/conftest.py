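import numpy as np
import pytest

import caap


@pytest.fixture(scope="session")
def lg():
    return caap.build_model("LG")


@pytest.fixture(scope="session")
def all_schemes():
    return [caap.load_scheme(s) for s in ["US", "GS0", "GS1", "GS2", "GS3", "GS4"]]


@pytest.fixture(scope="session")
def quartet_tree():
    return caap.PhyloTree.from_newick(
        "((A:0.12,B:0.07)ab:0.05,(C:0.3,D:0.02)cd:0.11);"
    )


@pytest.fixture(scope="session")
def quartet_alignment():
    rows = {"A": "ARNDC", "B": "ARDDC", "C": "AKNDW", "D": "ARNEW"}
    return caap.ProteinAlignment(
        "quartet", list(rows), np.array([list(s) for s in rows.values()])
    )


@pytest.fixture(scope="session")
def sim_tree():
    """The shared 36-taxon calibration topology (seeded)."""
    ss = np.random.SeedSequence(1)
    topo_seed, pair_seed, _ = ss.spawn(3)
    tree = caap.random_topology(36, topo_seed, 0.1)
    pair = caap.choose_calibration_pair(tree, pair_seed)
    return tree, pair


def write_fasta(path, aln: caap.ProteinAlignment) -> None:
    with open(path, "w") as fh:
        for taxon, row in zip(aln.taxa, aln.residues):
            fh.write(f">{taxon}\n{''.join(row)}\n")
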