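"""Hierarchical fragment docking with knowledge-based pairwise scoring.

The engine reconstructs a ligand inside a binding site "atoms to
fragments, fragments to ligands": rigid fragments are sampled over an
atomic grid spanning the site's centroid spheres, scored with a
statistical pair potential, linked into whole-ligand candidates by
maximum-clique search over a pose-compatibility graph, snapped to exact
cut-bond geometry, and refined by rigid-body plus torsion minimization.
The lowest pose score is the ligand's docking score for that protein
(arbitrary units, lower is better).

The potential is a radial-mean-referenced log-odds score: observed
protein-ligand atom-pair counts per element-pair and distance bin are
compared with the counts expected if pairs were spread uniformly over
spherical shells, within a 6 A cutoff by default.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from invdock.chem import FragmentGraph, Molecule, fragment_ligand, perceive_rotatable_bonds
from invdock.sitedb import BindingSite, ProteinChain

logger = logging.getLogger(__name__)

HALOGENS = frozenset({"F", "Cl", "Br", "I"})
ATOM_TYPES = ("C", "N", "O", "S", "P", "X")  # X = any halogen


def atom_type(element: str) -> str | None:
    """Element-based scoring type; hydrogens are not scored."""
    if element in HALOGENS:
        return "X"
    if element in ATOM_TYPES:
        return element
    return None


@dataclass(frozen=True)
class DockingParams:
    """Engine defaults; distances in angstroms."""

    grid_spacing: float = 1.0
    n_rotations: int = 24
    k_keep: int = 20
    clash_cutoff: float = 2.0
    overlap_cutoff: float = 1.5
    link_tol: float = 1.0
    max_candidates: int = 50
    max_minimize: int = 10
    minimize_max_iter: int = 200
    minimize_f_tol: float = 1e-4


_TYPE_IDX = {t: i for i, t in enumerate(ATOM_TYPES)}


class Protein:
    """Receptor view for scoring: typed heavy atoms behind a KD-tree."""

    def __init__(self, chains: list[ProteinChain]):
        coords = []
        types = []
        for chain in chains:
            for res in chain.residues:
                for a in res.atoms:
                    t = atom_type(a.element)
                    if t is not None:
                        coords.append(a.coords)
                        types.append(t)
        self.coords = np.array(coords, dtype=float) if coords else np.empty((0, 3))
        self.types = types
        self.type_idx = np.array([_TYPE_IDX[t] for t in types], dtype=int)
        self.tree = cKDTree(self.coords) if len(coords) else None


@dataclass
class PairPotential:
    """Distance-binned knowledge-based score per atom-type pair.

    ``values[(t1, t2)]`` (keys sorted) is an array over distance bins of
    width ``bin_width`` out to ``cutoff``; scores are zero beyond the
    cutoff.  Units are arbitrary; lower is more favorable.
    """

    bin_width: float = 0.5
    cutoff: float = 6.0
    values: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return int(round(self.cutoff / self.bin_width))

    def key(self, t1: str, t2: str) -> tuple[str, str]:
        return (t1, t2) if t1 <= t2 else (t2, t1)

    def value(self, t1: str, t2: str, r: float) -> float:
        if r >= self.cutoff:
            return 0.0
        arr = self.values.get(self.key(t1, t2))
        if arr is None:
            return 0.0
        return float(arr[min(int(r / self.bin_width), self.n_bins - 1)])

    def value_smooth(self, t1: str, t2: str, r: float) -> float:
        """Linear interpolation between bin centers; used only inside the
        minimizer to give the binned landscape a usable local slope."""
        if r >= self.cutoff:
            return 0.0
        arr = self.values.get(self.key(t1, t2))
        if arr is None:
            return 0.0
        centers = (np.arange(self.n_bins) + 0.5) * self.bin_width
        return float(np.interp(r, centers, arr))

    def scaled(self, lam: float) -> "PairPotential":
        return PairPotential(self.bin_width, self.cutoff,
                             {k: lam * v for k, v in self.values.items()})

    def dense_table(self) -> np.ndarray:
        """(n_types, n_types, n_bins) lookup array for vectorized scoring;
        cached, so mutate ``values`` only before first scoring use."""
        cached = getattr(self, "_table", None)
        if cached is not None:
            return cached
        nt = len(ATOM_TYPES)
        table = np.zeros((nt, nt, self.n_bins))
        for (t1, t2), arr in self.values.items():
            i, j = _TYPE_IDX[t1], _TYPE_IDX[t2]
            table[i, j] = arr
            table[j, i] = arr
        object.__setattr__(self, "_table", table)
        return table

    def validate(self) -> None:
        for (t1, t2), arr in self.values.items():
            if (t1, t2) != self.key(t1, t2):
                raise AssertionError("non-canonical type-pair key")
            if len(arr) != self.n_bins or not np.all(np.isfinite(arr)):
                raise AssertionError("bad value table")


def derive_pair_potential(
    complexes: list[tuple[Protein, tuple[list[str], np.ndarray]]],
    bin_width: float = 0.5,
    cutoff: float = 6.0,
) -> PairPotential:
    """Train the potential from observed protein-ligand complexes.

    Each complex is (protein, (ligand atom types, ligand coords)).  For
    every type pair, value(bin) = -log[(observed + 1) / (reference + 1)]
    where the reference distributes that pair's total count over bins in
    proportion to shell volume (r_hi^3 - r_lo^3): the radial mean.
    """
    if not complexes:
        raise ValueError("empty training set")
    n_bins = int(round(cutoff / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    shell = edges[1:] ** 3 - edges[:-1] ** 3
    shell = shell / shell.sum()
    counts: dict[tuple[str, str], np.ndarray] = {}
    for protein, (lig_types, lig_coords) in complexes:
        if protein.tree is None or len(lig_coords) == 0:
            continue
        pairs = protein.tree.query_ball_point(lig_coords, cutoff)
        for li, plist in enumerate(pairs):
            lt = lig_types[li]
            if lt is None:
                continue
            for pi in plist:
                r = float(np.linalg.norm(lig_coords[li] - protein.coords[pi]))
                if r >= cutoff:
                    continue
                key = (lt, protein.types[pi]) if lt <= protein.types[pi] else (protein.types[pi], lt)
                arr = counts.setdefault(key, np.zeros(n_bins))
                arr[min(int(r / bin_width), n_bins - 1)] += 1
    pot = PairPotential(bin_width, cutoff)
    for key, obs in counts.items():
        ref = obs.sum() * shell
        pot.values[key] = -np.log((obs + 1.0) / (ref + 1.0))
    pot.validate()
    return pot


def ligand_view(m: Molecule) -> tuple[list[str], np.ndarray]:
    """(scoring types, heavy-atom coords) for a molecule."""
    return [atom_type(a.element) for a in m.atoms], m.coords


def _pair_arrays(pot: PairPotential, lig_types, lig_coords, protein: Protein):
    pairs = protein.tree.query_ball_point(lig_coords, pot.cutoff)
    li_idx: list[int] = []
    pi_idx: list[int] = []
    for li, plist in enumerate(pairs):
        if lig_types[li] is None:
            continue
        li_idx.extend([li] * len(plist))
        pi_idx.extend(plist)
    if not li_idx:
        return None
    li_arr = np.array(li_idx)
    pi_arr = np.array(pi_idx)
    r = np.linalg.norm(lig_coords[li_arr] - protein.coords[pi_arr], axis=1)
    keep = r < pot.cutoff
    lt = np.array([_TYPE_IDX[lig_types[i]] for i in li_arr[keep]])
    return lt, protein.type_idx[pi_arr[keep]], r[keep]


def score_pose(
    pot: PairPotential,
    lig_types: list[str],
    lig_coords: np.ndarray,
    protein: Protein,
    smooth: bool = False,
) -> float:
    """Sum of potential values over all protein-ligand heavy-atom pairs
    within the cutoff.  Lower is better.  ``smooth`` switches to the
    interpolated potential (minimizer internals only)."""
    if protein.tree is None or len(lig_coords) == 0:
        return 0.0
    arrs = _pair_arrays(pot, lig_types, lig_coords, protein)
    if arrs is None:
        return 0.0
    lt, pt, r = arrs
    table = pot.dense_table()
    if not smooth:
        bins = np.minimum((r / pot.bin_width).astype(int), pot.n_bins - 1)
        return float(table[lt, pt, bins].sum())
    # linear interpolation between bin centers, clamped at the edges
    pos = np.clip(r / pot.bin_width - 0.5, 0.0, pot.n_bins - 1 - 1e-9)
    b0 = pos.astype(int)
    w = pos - b0
    b1 = np.minimum(b0 + 1, pot.n_bins - 1)
    return float(((1 - w) * table[lt, pt, b0] + w * table[lt, pt, b1]).sum())


@dataclass
class Grid:
    spacing: float
    points: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")


def generate_grid(site: BindingSite, spacing: float = 1.0) -> Grid:
    """Lattice points (given spacing, origin-anchored) inside the union of
    the site's centroid spheres, in deterministic lexicographic order."""
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    if not site.centroids:
        raise ValueError("site has no centroids")
    centers = np.array([c for c, _ in site.centroids])
    radii = np.array([r for _, r in site.centroids])
    lo = np.floor((centers - radii[:, None]).min(axis=0) / spacing).astype(int)
    hi = np.ceil((centers + radii[:, None]).max(axis=0) / spacing).astype(int)
    axes = [np.arange(lo[k], hi[k] + 1) * spacing for k in range(3)]
    pts = np.array(np.meshgrid(*axes, indexing="ij")).reshape(3, -1).T
    d = np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=2)
    inside = (d <= radii[None, :]).any(axis=1)
    return Grid(spacing, pts[inside])


@dataclass
class FragmentPose:
    frag_idx: int
    coords: np.ndarray
    score: float
    grid_idx: int = -1
    rot_idx: int = -1


@dataclass
class DockedPose:
    """A whole-ligand pose; ``coords`` in molecule atom order."""

    coords: np.ndarray
    score: float
    provenance: list[FragmentPose] = field(default_factory=list)


def _rotations(n_rot: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    mats = [np.eye(3)]
    if n_rot > 1:
        mats.extend(Rotation.random(n_rot - 1, random_state=rng).as_matrix())
    return mats


def dock_fragments(
    fg: FragmentGraph,
    grid: Grid,
    protein: Protein,
    pot: PairPotential,
    params: DockingParams = DockingParams(),
    seed: int = 0,
) -> list[list[FragmentPose]]:
    """Sample each rigid fragment over the grid.

    Each fragment centroid visits every grid point under ``n_rotations``
    seeded orientations (identity included); clashing placements (any
    protein heavy atom closer than the clash cutoff) are dropped and the
    ``k_keep`` best-scoring poses are kept, sorted ascending by score.
    """
    if len(grid.points) == 0:
        raise ValueError("empty grid")
    mol = fg.molecule
    all_types, all_coords = ligand_view(mol)
    rots = _rotations(params.n_rotations, seed)
    out: list[list[FragmentPose]] = []
    for fi, frag in enumerate(fg.fragments):
        idx = sorted(frag)
        base = all_coords[idx]
        base = base - base.mean(axis=0)
        types = [all_types[k] for k in idx]
        candidates: list[FragmentPose] = []
        for ri, rot in enumerate(rots):
            rotated = base @ rot.T
            for gi, gp in enumerate(grid.points):
                coords = rotated + gp
                if protein.tree is not None:
                    d, _ = protein.tree.query(coords, k=1)
                    if float(np.min(d)) < params.clash_cutoff:
                        continue
                s = score_pose(pot, types, coords, protein)
                candidates.append(FragmentPose(fi, coords, s, grid_idx=gi, rot_idx=ri))
        candidates.sort(key=lambda p: (p.score, p.grid_idx, p.rot_idx))
        if not candidates:
            logger.warning("fragment %d: no clash-free placement in search volume", fi)
        out.append(candidates[: params.k_keep])
    return out


def _frag_local_index(fg: FragmentGraph) -> dict[int, tuple[int, int]]:
    """molecule atom index -> (fragment index, position within sorted fragment)."""
    mapping = {}
    for fi, frag in enumerate(fg.fragments):
        for pos, a in enumerate(sorted(frag)):
            mapping[a] = (fi, pos)
    return mapping


def _links_between(fg: FragmentGraph):
    by_pair: dict[tuple[int, int], list] = {}
    for link in fg.links:
        by_pair.setdefault((link.frag_a, link.frag_b), []).append(link)
    return by_pair


def _poses_compatible(
    fg: FragmentGraph,
    loc: dict[int, tuple[int, int]],
    links_by_pair,
    fa: int,
    pa: FragmentPose,
    fb: int,
    pb: FragmentPose,
    params: DockingParams,
) -> bool:
    d = np.linalg.norm(pa.coords[:, None, :] - pb.coords[None, :, :], axis=2)
    pair = (fa, fb) if fa < fb else (fb, fa)
    links = links_by_pair.get(pair, [])
    link_pairs = set()
    for link in links:
        ia = loc[link.atom_i][1] if loc[link.atom_i][0] == fa else loc[link.atom_j][1]
        ib = loc[link.atom_j][1] if loc[link.atom_j][0] == fb else loc[link.atom_i][1]
        bond_len = d[ia, ib]
        if abs(bond_len - link.ref_length) > params.link_tol:
            return False
        link_pairs.add((ia, ib))
    mask = np.ones_like(d, dtype=bool)
    for ia, ib in link_pairs:
        mask[ia, ib] = False  # bonded atoms are allowed to be close
    if np.any(d[mask] < params.overlap_cutoff):
        return False
    return True


def _snap_assembly(fg: FragmentGraph, poses: dict[int, FragmentPose]) -> np.ndarray:
    """Combine fragment poses into whole-ligand coordinates with exact
    cut-bond lengths: fragments are attached breadth-first from the
    largest fragment, each translated along the bond direction so the cut
    bond matches its reference length."""
    loc = _frag_local_index(fg)
    n_atoms = len(fg.molecule.atoms)
    coords = np.zeros((n_atoms, 3))
    ftree = nx.Graph()
    ftree.add_nodes_from(range(len(fg.fragments)))
    for link in fg.links:
        ftree.add_edge(link.frag_a, link.frag_b, link=link)
    root = max(range(len(fg.fragments)), key=lambda fi: (len(fg.fragments[fi]), -fi))
    placed_shift: dict[int, np.ndarray] = {root: np.zeros(3)}
    for a in sorted(fg.fragments[root]):
        coords[a] = poses[root].coords[loc[a][1]]
    for parent, child in nx.bfs_edges(ftree, root):
        link = ftree.edges[parent, child]["link"]
        if link.frag_a == parent:
            ap, ac = link.atom_i, link.atom_j
        else:
            ap, ac = link.atom_j, link.atom_i
        p_pos = poses[parent].coords[loc[ap][1]] + placed_shift[parent]
        c_pos = poses[child].coords[loc[ac][1]]
        v = c_pos - p_pos
        norm = np.linalg.norm(v)
        if norm < 1e-9:
            v = np.array([1.0, 0.0, 0.0])
            norm = 1.0
        shift = p_pos + v / norm * link.ref_length - c_pos
        placed_shift[child] = shift
        for a in sorted(fg.fragments[child]):
            coords[a] = poses[child].coords[loc[a][1]] + shift
    return coords


def _grow_from_anchors(
    fg: FragmentGraph,
    pose_lists: list[list[FragmentPose]],
    protein: Protein,
    pot: PairPotential,
    params: DockingParams,
    seed: int,
) -> list[dict[int, FragmentPose]]:
    """Hierarchical fallback when no pose clique covers every fragment:
    anchor on each kept pose of the largest fragment and grow the
    remaining fragments breadth-first along the cut-bond tree, placing
    each child at exact reference bond length under sampled orientations
    and keeping the best clash-free, non-overlapping placement."""
    mol = fg.molecule
    all_types, all_coords = ligand_view(mol)
    loc = _frag_local_index(fg)
    ftree = nx.Graph()
    ftree.add_nodes_from(range(len(fg.fragments)))
    for link in fg.links:
        ftree.add_edge(link.frag_a, link.frag_b, link=link)
    root = max(range(len(fg.fragments)), key=lambda fi: (len(fg.fragments[fi]), -fi))
    rots = _rotations(max(params.n_rotations, 24), seed + 1)
    out: list[dict[int, FragmentPose]] = []
    for anchor in pose_lists[root]:
        placed: dict[int, FragmentPose] = {root: anchor}
        occupied = [anchor.coords]
        ok = True
        for parent, child in nx.bfs_edges(ftree, root):
            link = ftree.edges[parent, child]["link"]
            if link.frag_a == parent:
                ap, ac = link.atom_i, link.atom_j
            else:
                ap, ac = link.atom_j, link.atom_i
            p_pos = placed[parent].coords[loc[ap][1]]
            idx = sorted(fg.fragments[child])
            base = all_coords[idx] - all_coords[ac]  # child link atom at origin
            ctypes = [all_types[k] for k in idx]
            bond_pairs = {(loc[ap][1], loc[ac][1])}
            best_pose = None
            best_score = np.inf
            for rot in rots:
                coords = base @ rot.T
                coords = coords + p_pos + link.ref_length * rot[:, 0]
                if protein.tree is not None and len(coords):
                    d, _ = protein.tree.query(coords, k=1)
                    if float(np.min(d)) < params.clash_cutoff:
                        continue
                clash = False
                for prev_fi, prev in placed.items():
                    d = np.linalg.norm(coords[:, None, :] - prev.coords[None, :, :], axis=2)
                    mask = np.ones_like(d, dtype=bool)
                    if prev_fi == parent:
                        mask[loc[ac][1], loc[ap][1]] = False
                    if np.any(d[mask] < params.overlap_cutoff):
                        clash = True
                        break
                if clash:
                    continue
                s = score_pose(pot, ctypes, coords, protein)
                if s < best_score:
                    best_score = s
                    best_pose = coords
            if best_pose is None:
                ok = False
                break
            placed[child] = FragmentPose(child, best_pose, best_score)
            occupied.append(best_pose)
        if ok:
            out.append(placed)
        if len(out) >= params.max_candidates:
            break
    return out


def link_fragments(
    fg: FragmentGraph,
    pose_lists: list[list[FragmentPose]],
    protein: Protein,
    pot: PairPotential,
    params: DockingParams = DockingParams(),
) -> list[DockedPose]:
    """Assemble whole-ligand candidates by maximum-clique search.

    Compatibility graph: one node per (fragment, pose); an edge joins
    poses of distinct fragments that do not overlap (no heavy-atom pair
    closer than the overlap cutoff) and whose every shared cut bond is
    within ``link_tol`` of its reference length.  Cliques covering all
    fragments become candidates; enumeration is exact (Bron-Kerbosch via
    networkx) for graphs up to 64 nodes and greedy above.  Candidates are
    snapped to exact cut-bond geometry and rescored.  No full-cover clique
    yields an empty result with a diagnostic (the docking pipeline then
    falls back to hierarchical anchor-and-grow reconstruction).
    """
    n_frag = len(fg.fragments)
    if any(not lst for lst in pose_lists):
        logger.warning("a fragment has no poses; no full assembly possible")
        return []
    if n_frag == 1:
        out = [DockedPose(_snap_assembly(fg, {0: p}), p.score, [p]) for p in pose_lists[0]]
        for dp in out:
            types, _ = ligand_view(fg.molecule)
            dp.score = score_pose(pot, types, dp.coords, protein)
        out.sort(key=lambda p: p.score)
        return out[: params.max_candidates]

    loc = _frag_local_index(fg)
    links_by_pair = _links_between(fg)
    nodes = [(fi, pi) for fi, lst in enumerate(pose_lists) for pi in range(len(lst))]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for (fa, pa), (fb, pb) in itertools.combinations(nodes, 2):
        if fa == fb:
            continue
        if _poses_compatible(fg, loc, links_by_pair, fa, pose_lists[fa][pa], fb, pose_lists[fb][pb], params):
            g.add_edge((fa, pa), (fb, pb))

    assemblies: list[dict[int, FragmentPose]] = []
    if g.number_of_nodes() <= 64:
        for clique in nx.find_cliques(g):
            if len(clique) == n_frag:
                assemblies.append({fi: pose_lists[fi][pi] for fi, pi in clique})
    else:
        # greedy heuristic: seed on each node, extend with the best-scoring
        # compatible pose of every remaining fragment
        for seed_node in sorted(nodes, key=lambda n: pose_lists[n[0]][n[1]].score):
            chosen = {seed_node[0]: seed_node}
            ok = True
            for fi in range(n_frag):
                if fi in chosen:
                    continue
                found = None
                for pi in range(len(pose_lists[fi])):
                    cand = (fi, pi)
                    if all(g.has_edge(cand, c) for c in chosen.values()):
                        found = cand
                        break
                if found is None:
                    ok = False
                    break
                chosen[fi] = found
            if ok:
                assemblies.append({fi: pose_lists[fi][pi] for fi, (f2, pi) in chosen.items()})
            if len(assemblies) >= params.max_candidates:
                break
    if not assemblies:
        logger.warning("no full-cover clique found among %d nodes", g.number_of_nodes())
        return []
    types, _ = ligand_view(fg.molecule)
    out = []
    seen = set()
    for asm in assemblies:
        sig = tuple(sorted((fi, p.grid_idx, p.rot_idx) for fi, p in asm.items()))
        if sig in seen:
            continue
        seen.add(sig)
        coords = _snap_assembly(fg, asm)
        s = score_pose(pot, types, coords, protein)
        out.append(DockedPose(coords, s, provenance=sorted(asm.values(), key=lambda p: p.frag_idx)))
    out.sort(key=lambda p: p.score)
    return out[: params.max_candidates]


# ---------------------------------------------------------------------------
# Minimization


def _torsion_subtrees(fg: FragmentGraph) -> list[tuple[int, int, np.ndarray]]:
    """For each link: (axis atom a, axis atom b, mask of atoms rotated when
    the torsion about a-b turns).  The rotated side is the fragment-tree
    side containing frag_b."""
    ftree = nx.Graph()
    ftree.add_nodes_from(range(len(fg.fragments)))
    for link in fg.links:
        ftree.add_edge(link.frag_a, link.frag_b, link=link)
    n_atoms = len(fg.molecule.atoms)
    out = []
    for link in fg.links:
        ftree.remove_edge(link.frag_a, link.frag_b)
        side = nx.node_connected_component(ftree, link.frag_b)
        ftree.add_edge(link.frag_a, link.frag_b, link=link)
        mask = np.zeros(n_atoms, dtype=bool)
        for fi in side:
            for a in fg.fragments[fi]:
                mask[a] = True
        out.append((link.atom_i, link.atom_j, mask))
    return out


def _rotmat(axis: np.ndarray, angle: float) -> np.ndarray:
    return Rotation.from_rotvec(axis / np.linalg.norm(axis) * angle).as_matrix()


def minimize_pose(
    pose: DockedPose,
    fg: FragmentGraph,
    protein: Protein,
    pot: PairPotential,
    params: DockingParams = DockingParams(),
) -> DockedPose:
    """Directional line-search descent (Powell) over rigid-body
    translation/rotation (6 dof) and cut-bond torsions.  All moves preserve
    intra-fragment geometry and cut-bond lengths exactly.  Descent runs on
    the linearly interpolated potential (the binned landscape is piecewise
    constant and has no usable slope); the returned pose carries the binned
    score and is kept only if it improves on the input, so the output score
    never exceeds the input score."""
    from scipy.optimize import minimize as _scipy_minimize

    types, _ = ligand_view(fg.molecule)
    base = pose.coords.copy()
    torsions = _torsion_subtrees(fg)
    center = base.mean(axis=0)

    def build(x: np.ndarray) -> np.ndarray:
        coords = base.copy()
        for t, (ai, aj, mask) in enumerate(torsions):
            angle = x[6 + t]
            axis = coords[aj] - coords[ai]
            if abs(angle) < 1e-12 or np.linalg.norm(axis) < 1e-9:
                continue
            rm = _rotmat(axis, angle)
            coords[mask] = (coords[mask] - coords[ai]) @ rm.T + coords[ai]
        rotvec = x[3:6]
        if np.linalg.norm(rotvec) > 1e-12:
            rm = Rotation.from_rotvec(rotvec).as_matrix()
            coords = (coords - center) @ rm.T + center
        return coords + x[0:3]

    def objective(x: np.ndarray) -> float:
        return score_pose(pot, types, build(x), protein, smooth=True)

    x0 = np.zeros(6 + len(torsions))
    res = _scipy_minimize(
        objective, x0, method="Powell",
        options={"maxiter": params.minimize_max_iter, "xtol": 1e-3,
                 "ftol": params.minimize_f_tol, "disp": False},
    )
    coords = build(res.x)
    binned_in = score_pose(pot, types, pose.coords, protein)
    binned_out = score_pose(pot, types, coords, protein)
    if binned_out <= binned_in:
        final = DockedPose(coords, binned_out, provenance=list(pose.provenance))
    else:
        final = DockedPose(pose.coords.copy(), binned_in, provenance=list(pose.provenance))
    assert final.score <= binned_in + 1e-9
    return final


# ---------------------------------------------------------------------------
# Full pipeline


def dock_ligand(
    m: Molecule,
    site: BindingSite,
    protein: Protein,
    pot: PairPotential,
    params: DockingParams = DockingParams(),
    seed: int = 0,
) -> list[DockedPose]:
    """Fragment, sample, link, minimize; return poses sorted ascending by
    score.  The first pose's score is the protein's docking score.  An
    empty list is the documented no-pose outcome."""
    if not any(b.is_rotatable for b in m.bonds):
        m = perceive_rotatable_bonds(m)
    fg = fragment_ligand(m)
    grid = generate_grid(site, params.grid_spacing)
    pose_lists = dock_fragments(fg, grid, protein, pot, params, seed=seed)
    candidates = link_fragments(fg, pose_lists, protein, pot, params)
    if not candidates and any(pose_lists) and all(pose_lists):
        # hierarchical fallback: grow the ligand from anchored fragment poses
        types, _ = ligand_view(fg.molecule)
        grown = _grow_from_anchors(fg, pose_lists, protein, pot, params, seed)
        candidates = []
        for asm in grown:
            coords = _snap_assembly(fg, asm)
            s = score_pose(pot, types, coords, protein)
            candidates.append(DockedPose(coords, s, provenance=sorted(asm.values(), key=lambda p: p.frag_idx)))
        candidates.sort(key=lambda p: p.score)
        candidates = candidates[: params.max_candidates]
    if not candidates:
        return []
    refined = [minimize_pose(p, fg, protein, pot, params) for p in candidates[: params.max_minimize]]
    refined.extend(candidates[params.max_minimize:])
    refined.sort(key=lambda p: p.score)
    return refined


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """In-place heavy-atom RMSD (no superposition)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
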