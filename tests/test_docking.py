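"""Docking engine: potential derivation, scoring, grid, clique linking,
minimization and full re-docking recovery."""

import itertools

import numpy as np
import pytest

from invdock import docking, fixtures, sitedb
from invdock.chem import Atom, Bond, Molecule, fragment_ligand, perceive_rotatable_bonds


def _protein_at(coords, elements=None):
    coords = np.asarray(coords, float)
    elements = elements or ["C"] * len(coords)
    residues = [
        sitedb.Residue("ALA", i + 1, "", [sitedb.StructAtom("CA", e, c)])
        for i, (e, c) in enumerate(zip(elements, coords))
    ]
    return docking.Protein([sitedb.ProteinChain("A", residues)])


def _site_with_spheres(spheres):
    residues = [sitedb.SiteResidue("A", "ALA", 1, "", np.zeros(3))]
    s = sitedb.BindingSite("s", "e", "A", residues)
    s.centroids = [(np.asarray(c, float), r) for c, r in spheres]
    return s


class TestPairPotential:
    def test_uniform_shell_training_gives_near_zero_values(self, rng):
        # pair distances drawn with density proportional to r^2 (uniform in a ball)
        n = 40000
        radii = 6.0 * rng.uniform(size=n) ** (1 / 3)
        directions = rng.normal(size=(n, 3))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        prot = _protein_at(radii[:, None] * directions)
        pot = docking.derive_pair_potential([(prot, (["C"], np.zeros((1, 3))))])
        assert np.all(np.abs(pot.values[("C", "C")]) < 0.15)

    def test_handcounted_toy_enrichment(self):
        # 10 C-C pairs: 6 in the 3.0-3.5 bin, 4 spread at 5.0-5.5
        coords = [[3.2, 0, 0]] * 6 + [[5.2, 0, 0]] * 4
        prot = _protein_at(coords)
        pot = docking.derive_pair_potential([(prot, (["C"], np.zeros((1, 3))))])
        vals = pot.values[("C", "C")]
        shell = (np.arange(13)[1:] ** 3 - np.arange(13)[:-1] ** 3) / 12.0 ** 3
        expected_bin6 = -np.log((6 + 1) / (10 * shell[6] + 1))
        assert vals[6] == pytest.approx(expected_bin6, abs=1e-9)
        assert vals[6] < 0  # enriched contact is favorable

    def test_table_symmetric_under_type_swap(self):
        prot = _protein_at([[3.2, 0, 0]], elements=["N"])
        pot = docking.derive_pair_potential([(prot, (["C"], np.zeros((1, 3))))])
        assert pot.value("C", "N", 3.2) == pot.value("N", "C", 3.2)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            docking.derive_pair_potential([])


class TestScorePose:
    def test_zero_potential_scores_zero(self):
        prot = _protein_at([[3, 0, 0]])
        pot = docking.PairPotential()
        assert docking.score_pose(pot, ["C"], np.zeros((1, 3)), prot) == 0.0

    def test_single_pair_reads_its_bin(self):
        prot = _protein_at([[3.2, 0, 0]])
        pot = docking.PairPotential()
        vals = np.zeros(12)
        vals[6] = -1.0  # 3.0-3.5 A bin
        pot.values[("C", "C")] = vals
        assert docking.score_pose(pot, ["C"], np.zeros((1, 3)), prot) == -1.0

    def test_equals_bruteforce_double_loop(self, rng):
        prot_xyz = rng.uniform(-8, 8, size=(50, 3))
        prot_el = list(rng.choice(["C", "N", "O", "S"], size=50))
        lig_xyz = rng.uniform(-4, 4, size=(30, 3))
        lig_types = list(rng.choice(["C", "N", "O"], size=30))
        prot = _protein_at(prot_xyz, prot_el)
        pot = docking.PairPotential()
        for pair in itertools.combinations_with_replacement(["C", "N", "O", "S"], 2):
            pot.values[tuple(sorted(pair))] = rng.normal(size=12)
        got = docking.score_pose(pot, lig_types, lig_xyz, prot)
        expected = 0.0
        for lt, lp in zip(lig_types, lig_xyz):
            for pt, pp in zip(prot_el, prot_xyz):
                r = float(np.linalg.norm(lp - pp))
                if r < pot.cutoff:
                    expected += pot.value(lt, pt, r)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_linear_in_potential_scale(self, rng):
        prot = _protein_at(rng.uniform(-5, 5, (20, 3)))
        pot = docking.PairPotential()
        pot.values[("C", "C")] = rng.normal(size=12)
        lig = rng.uniform(-2, 2, (5, 3))
        s1 = docking.score_pose(pot, ["C"] * 5, lig, prot)
        s2 = docking.score_pose(pot.scaled(2.5), ["C"] * 5, lig, prot)
        assert s2 == pytest.approx(2.5 * s1, rel=1e-9)


class TestGrid:
    def test_point_count_matches_bruteforce_lattice_scan(self):
        site = _site_with_spheres([([0.3, -0.2, 0.1], 2.0)])
        grid = docking.generate_grid(site, 1.0)
        count = 0
        for i in range(-5, 6):
            for j in range(-5, 6):
                for k in range(-5, 6):
                    p = np.array([i, j, k], float)
                    if np.linalg.norm(p - [0.3, -0.2, 0.1]) <= 2.0:
                        count += 1
        assert len(grid.points) == count

    def test_all_points_inside_union(self):
        site = _site_with_spheres([([0, 0, 0], 2.0), ([3, 0, 0], 1.5)])
        grid = docking.generate_grid(site, 0.7)
        centers = np.array([[0, 0, 0], [3, 0, 0]], float)
        radii = np.array([2.0, 1.5])
        d = np.linalg.norm(grid.points[:, None] - centers[None], axis=2)
        assert np.all((d <= radii + 1e-9).any(axis=1))

    def test_doubling_spacing_never_gains_points(self):
        site = _site_with_spheres([([0, 0, 0], 3.0)])
        assert len(docking.generate_grid(site, 2.0).points) <= len(
            docking.generate_grid(site, 1.0).points
        )

    def test_nonpositive_spacing_rejected(self):
        site = _site_with_spheres([([0, 0, 0], 2.0)])
        with pytest.raises(ValueError):
            docking.generate_grid(site, 0.0)


def _single_atom_fragment_graph():
    mol = Molecule([Atom("C", [0, 0, 0])], [])
    return fragment_ligand(perceive_rotatable_bonds(mol))


class TestDockFragments:
    def test_single_atom_single_point_lands_there(self):
        fg = _single_atom_fragment_graph()
        grid = docking.Grid(1.0, np.array([[1.0, 2.0, 3.0]]))
        prot = _protein_at([[30, 0, 0]])
        pot = docking.PairPotential()
        lists = docking.dock_fragments(fg, grid, prot, pot, docking.DockingParams(), seed=0)
        assert len(lists) == 1
        np.testing.assert_allclose(lists[0][0].coords, [[1.0, 2.0, 3.0]])

    def test_pose_lists_sorted_and_bounded(self, redock_suite):
        data, pot = redock_suite
        site, mol, prot, _, _ = data[0]
        fg = fragment_ligand(mol)
        params = docking.DockingParams()
        grid = docking.generate_grid(site, params.grid_spacing)
        lists = docking.dock_fragments(fg, grid, prot, pot, params, seed=0)
        for lst in lists:
            assert len(lst) <= params.k_keep
            scores = [p.score for p in lst]
            assert scores == sorted(scores)

    def test_same_seed_reproduces_poses(self, redock_suite):
        data, pot = redock_suite
        site, mol, prot, _, _ = data[0]
        fg = fragment_ligand(mol)
        params = docking.DockingParams()
        grid = docking.generate_grid(site, params.grid_spacing)
        a = docking.dock_fragments(fg, grid, prot, pot, params, seed=7)
        b = docking.dock_fragments(fg, grid, prot, pot, params, seed=7)
        for la, lb in zip(a, b):
            for pa, pb in zip(la, lb):
                np.testing.assert_array_equal(pa.coords, pb.coords)

    def test_clash_filter_respects_cutoff(self, redock_suite):
        data, pot = redock_suite
        site, mol, prot, _, _ = data[0]
        fg = fragment_ligand(mol)
        params = docking.DockingParams()
        grid = docking.generate_grid(site, params.grid_spacing)
        for lst in docking.dock_fragments(fg, grid, prot, pot, params, seed=0):
            for pose in lst:
                d, _ = prot.tree.query(pose.coords, k=1)
                assert float(np.min(d)) >= params.clash_cutoff


def _two_fragment_molecule(bond_length=1.5):
    """Two 2-atom rigid pieces joined by one rotatable bond... built directly:
    atoms 0-1 | 2-3 with the 1-2 bond cut."""
    atoms = [
        Atom("C", [0.0, 0.0, 0.0]), Atom("C", [1.5, 0.0, 0.0]),
        Atom("C", [1.5 + bond_length, 0.0, 0.0]), Atom("C", [3.0 + bond_length, 0.0, 0.0]),
    ]
    bonds = [Bond(0, 1), Bond(1, 2), Bond(2, 3)]
    mol = perceive_rotatable_bonds(Molecule(atoms, bonds))
    return fragment_ligand(mol)


class TestLinkFragments:
    def test_correct_bond_distance_reconstructs(self):
        fg = _two_fragment_molecule()
        assert len(fg.fragments) == 2
        prot = _protein_at([[40, 0, 0]])
        pot = docking.PairPotential()
        coords = fg.molecule.coords
        pose_lists = [
            [docking.FragmentPose(0, coords[[0, 1]], 0.0, 0, 0)],
            [docking.FragmentPose(1, coords[[2, 3]], 0.0, 1, 0)],
        ]
        out = docking.link_fragments(fg, pose_lists, prot, pot)
        assert len(out) == 1
        bond = np.linalg.norm(out[0].coords[1] - out[0].coords[2])
        assert bond == pytest.approx(fg.links[0].ref_length, abs=1e-6)

    def test_stretched_bond_rejected(self):
        fg = _two_fragment_molecule()
        prot = _protein_at([[40, 0, 0]])
        pot = docking.PairPotential()
        coords = fg.molecule.coords
        far = coords[[2, 3]] + [5.0, 0, 0]  # bond would be 6.5 A off reference
        pose_lists = [
            [docking.FragmentPose(0, coords[[0, 1]], 0.0, 0, 0)],
            [docking.FragmentPose(1, far, 0.0, 1, 0)],
        ]
        assert docking.link_fragments(fg, pose_lists, prot, pot) == []

    def test_unique_threeclique_found(self):
        """Crafted 3-fragment case with one compatible pose combination."""
        atoms = [Atom("C", [1.5 * k, 0.0, 0.0]) for k in range(5)]
        bonds = [Bond(k, k + 1) for k in range(4)]
        mol = perceive_rotatable_bonds(Molecule(atoms, bonds))
        fg = fragment_ligand(mol)
        assert len(fg.fragments) == 3
        prot = _protein_at([[40, 0, 0]])
        pot = docking.PairPotential()
        coords = mol.coords
        frag_idx = [sorted(f) for f in fg.fragments]
        pose_lists = []
        for fi, idx in enumerate(frag_idx):
            good = docking.FragmentPose(fi, coords[idx], 0.0, 0, 0)
            bad = docking.FragmentPose(fi, coords[idx] + [0, 30 + 10 * fi, 0], 1.0, 1, 0)
            pose_lists.append([good, bad])
        out = docking.link_fragments(fg, pose_lists, prot, pot)
        assert len(out) == 1
        np.testing.assert_allclose(out[0].coords, coords, atol=1e-6)

    @pytest.mark.parametrize("trial", range(5))
    def test_clique_search_matches_exhaustive_subsets(self, trial):
        """Random compatibility graphs with <= 15 nodes: the engine's
        full-cover cliques equal brute-force subset enumeration."""
        rng = np.random.default_rng(400 + trial)
        n_frag = 3
        per_frag = rng.integers(2, 5)
        nodes = [(f, p) for f in range(n_frag) for p in range(per_frag)]
        edges = set()
        for a, b in itertools.combinations(nodes, 2):
            if a[0] != b[0] and rng.uniform() < 0.5:
                edges.add(frozenset((a, b)))

        # brute force: all one-pose-per-fragment combinations, all pairs connected
        expected = set()
        for combo in itertools.product(range(per_frag), repeat=n_frag):
            chosen = [(f, combo[f]) for f in range(n_frag)]
            if all(frozenset((x, y)) in edges for x, y in itertools.combinations(chosen, 2)):
                expected.add(tuple(chosen))

        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(tuple(e) for e in edges)
        got = {
            tuple(sorted(clique)) for clique in nx.find_cliques(g) if len(clique) == n_frag
        }
        assert got == expected


class TestMinimization:
    def _quadratic_well_setup(self):
        """One protein atom, potential favoring r = 3.25 A: the minimizer
        must place a single-atom ligand on the 3.25 A sphere."""
        prot = _protein_at([[0, 0, 0]])
        pot = docking.PairPotential()
        vals = np.array([5.0, 5.0, 4.0, 3.0, 2.0, 1.0, -2.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        pot.values[("C", "C")] = vals
        return prot, pot

    def test_reaches_analytic_optimum(self):
        prot, pot = self._quadratic_well_setup()
        fg = _single_atom_fragment_graph()
        start = np.array([[4.4, 0.0, 0.0]])
        pose = docking.DockedPose(start, docking.score_pose(pot, ["C"], start, prot))
        out = docking.minimize_pose(pose, fg, prot, pot)
        r = float(np.linalg.norm(out.coords[0]))
        assert abs(r - 3.25) <= 0.1
        assert out.score == -2.0

    def test_score_never_increases(self, redock_suite):
        data, pot = redock_suite
        site, mol, prot, _, _ = data[1]
        fg = fragment_ligand(mol)
        params = docking.DockingParams()
        grid = docking.generate_grid(site, params.grid_spacing)
        lists = docking.dock_fragments(fg, grid, prot, pot, params, seed=0)
        for cand in docking.link_fragments(fg, lists, prot, pot, params)[:5]:
            refined = docking.minimize_pose(cand, fg, prot, pot, params)
            assert refined.score <= cand.score + 1e-9

    def test_local_minimum_left_unchanged(self):
        prot, pot = self._quadratic_well_setup()
        fg = _single_atom_fragment_graph()
        start = np.array([[3.25, 0.0, 0.0]])
        pose = docking.DockedPose(start, docking.score_pose(pot, ["C"], start, prot))
        out = docking.minimize_pose(pose, fg, prot, pot)
        assert out.score == pose.score
        assert abs(float(np.linalg.norm(out.coords[0])) - 3.25) <= 0.25


class TestDockLigand:
    def test_redocking_recovers_crystal_pose(self, redock_suite):
        """Each toy ligand carved from its own complex re-docks within
        2 A heavy-atom RMSD of the crystal placement."""
        data, pot = redock_suite
        params = docking.DockingParams(n_rotations=60, k_keep=30, max_minimize=20)
        for site, mol, prot, types, crystal in data:
            poses = docking.dock_ligand(mol, site, prot, pot, params, seed=0)
            assert poses, "no pose produced"
            assert docking.rmsd(poses[0].coords, crystal) <= 2.0

    def test_output_sorted_ascending(self, redock_suite):
        data, pot = redock_suite
        site, mol, prot, _, _ = data[0]
        poses = docking.dock_ligand(mol, site, prot, pot, seed=0)
        scores = [p.score for p in poses]
        assert scores == sorted(scores)

    def test_potential_scaling_preserves_ranking(self, redock_suite):
        data, pot = redock_suite
        site, mol, prot, _, _ = data[2]
        params = docking.DockingParams(max_minimize=0)  # ranking pre-refinement
        a = docking.dock_ligand(mol, site, prot, pot, params, seed=0)
        b = docking.dock_ligand(mol, site, prot, pot.scaled(3.0), params, seed=0)
        assert len(a) == len(b)
        for pa, pb in zip(a, b):
            assert pb.score == pytest.approx(3.0 * pa.score, rel=1e-9, abs=1e-9)

    def test_same_seed_same_best_score(self, redock_suite):
        data, pot = redock_suite
        site, mol, prot, _, _ = data[1]
        s1 = docking.dock_ligand(mol, site, prot, pot, seed=3)[0].score
        s2 = docking.dock_ligand(mol, site, prot, pot, seed=3)[0].score
        assert s1 == s2
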