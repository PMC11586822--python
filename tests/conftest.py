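"""Shared fixtures: small synthetic systems, a planted-patch complex and
one fully trained ensemble (session-scoped, since training dominates the
suite's runtime)."""

import numpy as np
import pytest

import graphbnc as g

MASTER_SEED = 3


@pytest.fixture(scope="session")
def protein():
    """120-residue self-avoiding chain with one planted +1 patch."""
    return g.make_protein(n_residues=120, n_patches=1, patch_size=6,
                          seed=MASTER_SEED)


@pytest.fixture(scope="session")
def cluster():
    """Au25-scale synthetic cluster: 18 ligands, heads at 8 A."""
    return g.make_cluster(n_ligands=18, radius=8.0, seed=MASTER_SEED)


@pytest.fixture(scope="session")
def featurized(protein, cluster):
    """Protein graph with WL features plus featurized cluster."""
    pg = g.featurize_protein(protein.coarse, atoms=protein.atoms)
    g.featurize_cluster(cluster.model)
    return pg


@pytest.fixture(scope="session")
def planted_phi(protein, cluster):
    """Hand-built interaction-strength table: 1 on patch residues, else 0."""
    phi = np.zeros((cluster.model.n_ligands, len(protein.coarse)))
    phi[:, protein.patches[0]] = 1.0
    return phi


@pytest.fixture(scope="session")
def oracle_dataset(protein, cluster, featurized):
    """250 oracle-labelled configurations and their pair batches."""
    dataset = g.sample_configurations(protein, cluster, n_configs=250, seed=4)
    batches = g.training_batches(featurized, cluster, dataset)
    return dataset, batches


@pytest.fixture(scope="session")
def trained_model(oracle_dataset):
    """Five-fold ensemble trained on the first 200 configurations."""
    _, batches = oracle_dataset
    return g.train(batches[:200], seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# Tiny hand-written PDB fixtures (constructed programmatically)

THREE_RESIDUE_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.450   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.300   2.400   0.000  1.00  0.00           O
ATOM      5  N   ALA A   2       3.300   1.500   0.000  1.00  0.00           N
ATOM      6  CA  ALA A   2       3.900   2.800   0.200  1.00  0.00           C
ATOM      7  CB  ALA A   2       4.200   3.300   1.600  1.00  0.00           C
ATOM      8  C   ALA A   2       5.200   2.800  -0.600  1.00  0.00           C
ATOM      9  O   ALA A   2       5.700   1.700  -0.900  1.00  0.00           O
ATOM     10  N   ARG A   3       5.800   3.900  -0.900  1.00  0.00           N
ATOM     11  CA  ARG A   3       7.100   3.900  -1.600  1.00  0.00           C
ATOM     12  C   ARG A   3       8.200   4.400  -0.700  1.00  0.00           C
ATOM     13  O   ARG A   3       8.000   5.400   0.000  1.00  0.00           O
END
"""


@pytest.fixture()
def three_residue_pdb(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(THREE_RESIDUE_PDB)
    return path
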