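import numpy as np
import pytest

from invdock import docking, fixtures, sitedb


@pytest.fixture(scope="session")
def curcumin():
    return fixtures.make_curcumin()


@pytest.fixture(scope="session")
def toy_complex_pdb():
    return fixtures.make_toy_complex(fixtures.FixtureSpec(seed=0))


@pytest.fixture(scope="session")
def toy_entry(toy_complex_pdb):
    return sitedb.load_structure(toy_complex_pdb, entry_id="toy00")


@pytest.fixture(scope="session")
def site_params():
    return sitedb.SiteDbParams()


@pytest.fixture(scope="session")
def redock_suite():
    """Seeded toy complexes with a knowledge-based potential pooled over an
    eight-complex training corpus; re-docking targets are complexes 1-5.
    Yields ([(site, ligand molecule, protein, ligand types, crystal
    coords), ...], potential)."""
    corpus = []
    for seed in range(8):
        spec = fixtures.FixtureSpec(seed=seed)
        entry = sitedb.load_structure(fixtures.make_toy_complex(spec), entry_id=f"toy{seed:02d}")
        site = sitedb.build_site_database([entry], sitedb.SiteDbParams())[0]
        mol = fixtures.make_toy_ligand_molecule(spec)
        prot = docking.Protein(sitedb.assembly_chains(entry))
        types, coords = docking.ligand_view(mol)
        corpus.append((site, mol, prot, types, coords))
    pot = docking.derive_pair_potential([(d[2], (d[3], d[4])) for d in corpus])
    return corpus[1:6], pot


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
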