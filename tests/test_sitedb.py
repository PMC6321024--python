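"""Binding-site extraction, clustering and database construction."""

import numpy as np
import pytest

from invdock import fixtures, sitedb


def _het(coords, code="LIG", elements=None):
    coords = np.asarray(coords, float)
    elements = elements or ["C"] * len(coords)
    atoms = [sitedb.StructAtom(f"{e}{i}", e, c) for i, (e, c) in enumerate(zip(elements, coords))]
    return sitedb.HetGroup(code, 900, "A", atoms)


def _chain_at(points, names=None):
    names = names or ["ALA"] * len(points)
    residues = [
        sitedb.Residue(names[i], i + 1, "", [sitedb.StructAtom("CA", "C", np.asarray(p, float))])
        for i, p in enumerate(points)
    ]
    return sitedb.ProteinChain("A", residues)


def _site(names, coords, site_id="s", n_ligands=0):
    residues = [
        sitedb.SiteResidue("A", nm, i + 1, "", np.asarray(c, float))
        for i, (nm, c) in enumerate(zip(names, coords))
    ]
    ligs = [_het([[0, 0, 0]]) for _ in range(n_ligands)]
    return sitedb.BindingSite(site_id, "e", "A", residues, source_ligands=ligs)


class TestLoadStructure:
    def test_toy_complex_parses_chain_het_no_waters(self, toy_entry):
        assert len(toy_entry.chains) == 1
        assert [h.het_code for h in toy_entry.het_groups] == ["LIG"]
        assert toy_entry.source_organism == "Homo Sapiens"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sitedb.load_structure("")

    def test_het_only_file_rejected(self):
        pdb = "HETATM    1  C1  LIG A 900       0.000   0.000   0.000  1.00  0.00           C\nEND\n"
        with pytest.raises(ValueError, match="no protein ATOM"):
            sitedb.load_structure(pdb)

    def test_remark350_twofold_doubles_assembly_chains(self):
        pdb = (
            "REMARK 350 BIOMOLECULE: 1\n"
            "REMARK 350 APPLY THE FOLLOWING TO CHAINS: A\n"
            "REMARK 350   BIOMT1   1  1.000000  0.000000  0.000000        0.00000\n"
            "REMARK 350   BIOMT2   1  0.000000  1.000000  0.000000        0.00000\n"
            "REMARK 350   BIOMT3   1  0.000000  0.000000  1.000000        0.00000\n"
            "REMARK 350   BIOMT1   2 -1.000000  0.000000  0.000000       20.00000\n"
            "REMARK 350   BIOMT2   2  0.000000 -1.000000  0.000000        0.00000\n"
            "REMARK 350   BIOMT3   2  0.000000  0.000000  1.000000        0.00000\n"
            "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C\n"
            "END\n"
        )
        entry = sitedb.load_structure(pdb, entry_id="dimer")
        assert len(entry.assembly_transforms) == 2
        chains = sitedb.assembly_chains(entry)
        assert [c.chain_id for c in chains] == ["A", "A-2"]
        np.testing.assert_allclose(chains[1].residues[0].atoms[0].coords, [19.0, -2.0, 3.0])

    def test_altloc_keeps_highest_occupancy(self):
        pdb = (
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.30  0.00           C\n"
            "ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.70  0.00           C\n"
            "END\n"
        )
        entry = sitedb.load_structure(pdb, entry_id="alt")
        res = entry.chains[0].residues[0]
        assert len(res.atoms) == 1
        np.testing.assert_allclose(res.atoms[0].coords, [9.0, 0.0, 0.0])


class TestCandidateLigands:
    @pytest.mark.parametrize(
        "n_atoms,distance,kept",
        [(8, 2.5, True), (7, 2.5, False), (9, 3.2, False)],
        ids=["passes-both", "heavy-atom-boundary", "distance-cutoff"],
    )
    def test_filters(self, n_atoms, distance, kept, site_params):
        chain = _chain_at([[0, 0, 0]])
        coords = [[distance + 1.6 * k, 0, 0] for k in range(n_atoms)]
        entry = sitedb.StructureEntry("e", [chain], [_het(coords)])
        got = sitedb.extract_candidate_ligands(entry, chain, site_params)
        assert bool(got) is kept

    def test_cofactor_codes_excluded(self, site_params):
        chain = _chain_at([[0, 0, 0]])
        coords = [[2.5 + 1.6 * k, 0, 0] for k in range(9)]
        entry = sitedb.StructureEntry("e", [chain], [_het(coords, code="HEM")])
        assert sitedb.extract_candidate_ligands(entry, chain, site_params) == []

    def test_relaxing_cutoffs_is_monotone(self, toy_entry):
        strict = sitedb.SiteDbParams()
        loose = sitedb.SiteDbParams(min_heavy_atoms=4, ligand_contact_cutoff=6.0)
        chain = sitedb.assembly_chains(toy_entry)[0]
        kept_strict = {l.ref for l in sitedb.extract_candidate_ligands(toy_entry, chain, strict)}
        kept_loose = {l.ref for l in sitedb.extract_candidate_ligands(toy_entry, chain, loose)}
        assert kept_strict <= kept_loose


class TestBindingResidues:
    @pytest.mark.parametrize("d,included", [(4.9, True), (5.1, False)])
    def test_strict_cutoff(self, d, included, site_params):
        chain = _chain_at([[d, 0, 0]])
        keys = sitedb.binding_residues(chain, _het([[0, 0, 0]]), site_params)
        assert (len(keys) == 1) is included

    def test_equals_bruteforce_all_pairs_scan(self, rng, site_params):
        chain_pts = rng.uniform(-10, 10, size=(60, 3))
        lig_pts = rng.uniform(-4, 4, size=(8, 3))
        chain = _chain_at(chain_pts)
        lig = _het(lig_pts)
        got = sitedb.binding_residues(chain, lig, site_params)
        expected = set()
        for res in chain.residues:  # O(n*m) double loop oracle
            for a in res.atoms:
                for lp in lig_pts:
                    if np.linalg.norm(a.coords - lp) < site_params.binding_residue_cutoff:
                        expected.add(res.key)
        assert got == expected


class TestSequenceClustering:
    def test_identical_sequences_share_cluster(self, site_params):
        a = _chain_at([[0, 0, 0], [3, 0, 0]], ["ALA", "GLY"])
        b = _chain_at([[9, 9, 9], [12, 9, 9]], ["ALA", "GLY"])
        assert sitedb.cluster_sequences([a, b], site_params) == [[0, 1]]

    def test_one_mismatch_splits_at_full_identity(self, site_params):
        a = _chain_at([[0, 0, 0], [3, 0, 0]], ["ALA", "GLY"])
        b = _chain_at([[0, 0, 0], [3, 0, 0]], ["ALA", "SER"])
        assert sitedb.cluster_sequences([a, b], site_params) == [[0], [1]]

    def test_distinct_sequences_all_singletons(self, site_params):
        chains = [_chain_at([[0, 0, 0]], [nm]) for nm in ("ALA", "GLY", "SER", "THR")]
        assert sitedb.cluster_sequences(chains, site_params) == [[0], [1], [2], [3]]


class TestSiteSimilarity:
    def _varied_site(self, rng, n=10, site_id="s"):
        names = [fixtures._RESIDUE_ROSTER[i % len(fixtures._RESIDUE_ROSTER)] for i in range(n)]
        coords = rng.uniform(-8, 8, size=(n, 3))
        return _site(names, coords, site_id)

    def test_self_similarity_exceeds_cluster_threshold(self, rng):
        s = self._varied_site(rng)
        assert sitedb.site_similarity_z(s, s) >= 2.0

    def test_unrelated_sites_average_near_zero(self, rng):
        zs = []
        for k in range(8):
            a = self._varied_site(np.random.default_rng(100 + k))
            b = self._varied_site(np.random.default_rng(200 + k))
            zs.append(sitedb.site_similarity_z(a, b, seed=k))
        assert abs(np.mean(zs)) < 1.0

    def test_symmetry_within_null_tolerance(self, rng):
        a = self._varied_site(rng, site_id="a")
        b = self._varied_site(rng, site_id="b")
        z_ab = sitedb.site_similarity_z(a, b)
        z_ba = sitedb.site_similarity_z(b, a)
        assert z_ab == pytest.approx(z_ba, abs=1.0)

    def test_small_site_rejected(self, rng):
        small = self._varied_site(rng, n=2)
        with pytest.raises(ValueError):
            sitedb.site_similarity_z(small, small)


class TestSiteClustering:
    def test_duplicate_sites_merge_with_deterministic_representative(self, rng, site_params):
        rng_local = np.random.default_rng(7)
        names = [fixtures._RESIDUE_ROSTER[i % 10] for i in range(10)]
        coords = rng_local.uniform(-8, 8, size=(10, 3))
        a = _site(names, coords, "siteA", n_ligands=2)
        b = _site(names, coords, "siteB", n_ligands=1)
        clusters = sitedb.cluster_sites([a, b], site_params)
        assert len(clusters) == 1
        assert clusters[0]["representative"].site_id == "siteA"  # most ligands

    def test_dissimilar_sites_stay_singletons(self, site_params):
        rng1, rng2 = np.random.default_rng(31), np.random.default_rng(77)
        names = [fixtures._RESIDUE_ROSTER[i % 10] for i in range(10)]
        a = _site(names, rng1.uniform(-8, 8, (10, 3)), "a")
        b = _site(list(reversed(names)), rng2.uniform(-8, 8, (10, 3)), "b")
        clusters = sitedb.cluster_sites([a, b], site_params)
        if len(clusters) == 2:  # expected for unrelated geometry
            assert {c["representative"].site_id for c in clusters} == {"a", "b"}

    def test_matches_bruteforce_component_oracle(self, site_params):
        rng = np.random.default_rng(5)
        names = [fixtures._RESIDUE_ROSTER[i % 10] for i in range(10)]
        shared = rng.uniform(-8, 8, (10, 3))
        sites = [
            _site(names, shared, "a"),
            _site(names, shared + rng.normal(scale=0.05, size=shared.shape), "b"),
            _site(names, rng.uniform(-8, 8, (10, 3)), "c"),
        ]
        clusters = sitedb.cluster_sites(sites, site_params)
        # brute-force union-find over the thresholded z matrix
        n = len(sites)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                z = sitedb.site_similarity_z(
                    sites[i], sites[j], tol=site_params.similarity_tol,
                    n_permutations=site_params.n_null_permutations,
                    seed=site_params.similarity_seed,
                )
                if z >= site_params.site_z_cutoff:
                    parent[find(i)] = find(j)
        expected = {frozenset(s.site_id for k, s in enumerate(sites) if find(k) == root)
                    for root in {find(k) for k in range(n)}}
        got = {frozenset(s.site_id for s in c["members"]) for c in clusters}
        assert got == expected


class TestCentroids:
    def test_single_atom_ligand_one_sphere(self):
        s = _site(["ALA", "GLY", "SER"], [[0, 0, 0], [3, 0, 0], [0, 3, 0]])
        s.source_ligands = [_het([[1, 1, 1]])]
        spheres = sitedb.make_centroids(s)
        assert len(spheres) == 1
        center, radius = spheres[0]
        assert np.linalg.norm(center - [1, 1, 1]) <= radius <= 4.0

    def test_union_covers_and_count_bounded(self, rng):
        pts = rng.uniform(-6, 6, size=(12, 3))
        s = _site(["ALA", "GLY", "SER"], [[0, 0, 0], [3, 0, 0], [0, 3, 0]])
        s.source_ligands = [_het(pts)]
        spheres = sitedb.make_centroids(s)
        assert s.covering_ok()
        assert len(spheres) <= len(pts)
        assert all(r <= 4.0 for _, r in spheres)


class TestBuildDatabase:
    def test_taxon_filter_excludes_non_human(self):
        human = sitedb.load_structure(
            fixtures.make_toy_complex(fixtures.FixtureSpec(seed=0)), entry_id="hum")
        mouse = sitedb.load_structure(
            fixtures.make_toy_complex(fixtures.FixtureSpec(seed=1, organism="Mus musculus")),
            entry_id="mus")
        sites = sitedb.build_site_database([human, mouse], sitedb.SiteDbParams())
        assert {s.entry_id for s in sites} == {"hum"}

    def test_identical_chains_collapse_to_one_representative(self, toy_complex_pdb):
        a = sitedb.load_structure(toy_complex_pdb, entry_id="aaa")
        b = sitedb.load_structure(toy_complex_pdb, entry_id="bbb")
        sites = sitedb.build_site_database([a, b], sitedb.SiteDbParams())
        assert len(sites) == 1

    def test_database_write_is_byte_stable(self, tmp_path, toy_entry):
        p = sitedb.SiteDbParams()
        out1, out2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        sitedb.write_site_database(sitedb.build_site_database([toy_entry], p), out1)
        sitedb.write_site_database(sitedb.build_site_database([toy_entry], p), out2)
        assert out1.read_bytes() == out2.read_bytes()

    def test_all_emitted_sites_satisfy_covering_invariant(self, toy_entry):
        for s in sitedb.build_site_database([toy_entry], sitedb.SiteDbParams()):
            assert s.covering_ok()
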