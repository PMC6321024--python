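"""Seeded synthetic inputs: toy protein-ligand complexes in PDB format,
the curcumin reference structure, and labeled score tables.

Toy complexes are concave shells of residues (CA/CB pseudo-side-chain
atoms on a sphere) enclosing a small het-group ligand; they have trivially
auditable geometry and are built to exercise the distance filters, grid
construction, docking and interaction profiling with no downloads.
Residue names cycle through a fixed roster so that site-similarity label
matching is non-degenerate.  All generators are deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from invdock.chem import Atom, Bond, Molecule, parse_small_molecule, perceive_rotatable_bonds
from invdock.metrics import LabeledRanking

#: Curcumin (diferuloylmethane), stored as the enol tautomer that
#: dominates at physiological pH: two methoxylated phenol rings joined by
#: a conjugated keto-enol linker.
CURCUMIN_SMILES = "COc1cc(/C=C/C(=O)/C=C(O)/C=C/c2ccc(O)c(OC)c2)ccc1O"

#: Published inverse-screen reference: the 21 curcumin candidate targets
#: selected at the -53.21 arb. unit threshold, with their docking scores.
#: Used as a printed input for threshold-selection checks.
CURCUMIN_TARGET_TABLE: list[tuple[str, str, float]] = [
    ("4kmyA", "folate receptor beta (FR-beta)", -63.30),
    ("3iadA", "cAMP-specific 3',5'-cyclic phosphodiesterase 4D (PDE4D)", -62.24),
    ("1u7tA", "17-beta-hydroxysteroid dehydrogenase type 10", -61.46),
    ("2qrvA", "DNA (cytosine-5)-methyltransferase 3A", -58.59),
    ("1ck7A", "metalloproteinase-2 (MMP-2)", -57.93),
    ("3qeoA", "deoxycytidine kinase", -57.37),
    ("4x3oA", "NAD-dependent protein deacetylase sirtuin-2", -56.96),
    ("3e7oA", "mitogen-activated protein kinase 9 (MAPK-9)", -56.93),
    ("4h2iA", "ecto-5'-nucleotidase", -55.95),
    ("4nwgA", "tyrosine-protein phosphatase non-receptor type 11", -55.49),
    ("1zr3A", "core histone macro-H2A.1", -55.46),
    ("4zzjA", "NAD-dependent protein deacetylase sirtuin-1", -54.89),
    ("4zseA", "epidermal growth factor receptor", -54.81),
    ("5kviA", "apoptosis-inducing factor 1", -54.76),
    ("3lcoA", "macrophage colony-stimulating factor 1 receptor", -54.59),
    ("2rgcA", "GTPase HRas", -54.43),
    ("2clpA", "aflatoxin B1 aldehyde reductase member 3", -53.86),
    ("1s1pA", "aldo-keto reductase family 1 member C3", -53.69),
    ("3hi7A", "amiloride-sensitive amine oxidase", -53.51),
    ("2a2aA", "death-associated protein kinase 2", -53.41),
    ("1r6tA", "tryptophan-tRNA ligase", -53.31),
]

#: Reference screen shape: 21 confirmed actives among 13,553 ranked sites.
SCREEN_N_ACTIVE = 21
SCREEN_N_TOTAL = 13553
SCORE_THRESHOLD = -53.21

_RESIDUE_ROSTER = ["ALA", "SER", "VAL", "LEU", "THR", "GLY", "PHE", "ASP", "LYS", "ILE"]


@dataclass
class FixtureSpec:
    seed: int = 0
    n_entries: int = 3
    pocket_radius: float = 10.0
    ligand_size: int = 9
    n_shell: int = 30
    organism: str = "Homo sapiens"
    het_code: str = "LIG"
    cradle: bool = True  # element-matched contact atoms around the ligand
    score_model: dict = field(default_factory=lambda: {
        "active_mean": -55.0, "inactive_mean": -27.0, "sd": 13.0,
        "n": SCREEN_N_ACTIVE, "N": SCREEN_N_TOTAL,
    })


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic near-uniform points on the unit sphere."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0))
    y = 1 - 2 * i / max(n - 1, 1)
    r = np.sqrt(np.clip(1 - y * y, 0, 1))
    return np.column_stack([np.cos(phi * i) * r, y, np.sin(phi * i) * r])


def _pdb_line(record: str, serial: int, name: str, resname: str, chain: str,
              resseq: int, xyz: np.ndarray, element: str) -> str:
    return (
        f"{record:<6}{serial:>5} {name:<4}{resname:>4} {chain}{resseq:>4}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2}"
    )


_LIG_ELEMENTS = ["C", "O", "C", "N", "C", "C", "N", "C", "O", "C", "C", "C"]


def toy_ligand_topology(size: int) -> tuple[list[str], list[tuple[int, int]], np.ndarray]:
    """Deterministic toy ligand: a rigid planar 4-ring, and for sizes of 8
    or more a second 4-ring joined by one rotatable bridge, with any
    remaining atoms as a short chain.  Returns (elements, bonds, local
    coordinates before placement)."""
    if size < 4:
        raise ValueError("toy ligand needs at least 4 atoms")
    square = np.array([[0.75, 0.75, 0.0], [-0.75, 0.75, 0.0],
                       [-0.75, -0.75, 0.0], [0.75, -0.75, 0.0]])
    coords = [square[k] for k in range(4)]
    bonds = [(0, 1), (1, 2), (2, 3), (3, 0)]
    if size >= 8:
        # second ring attached to atom 3 by a 1.5 A bridge, tilted out of plane
        tilt = np.array([[1.0, 0.0, 0.0],
                         [0.0, np.cos(0.6), -np.sin(0.6)],
                         [0.0, np.sin(0.6), np.cos(0.6)]])
        u = np.array([1.0, -1.0, 0.3])
        u /= np.linalg.norm(u)
        ring_b = square @ tilt.T
        shift = coords[3] + 1.5 * u - ring_b[0]
        coords.extend(ring_b + shift)
        bonds.extend([(3, 4), (4, 5), (5, 6), (6, 7), (7, 4)])
        tail_from, tail_dir = 6, u
        next_idx = 8
    else:
        tail_from, tail_dir = 3, np.array([1.0, 0.0, 0.0])
        next_idx = 4
    for k in range(next_idx, size):
        coords.append(coords[tail_from] + 1.5 * (k - next_idx + 1) * tail_dir)
        bonds.append((tail_from if k == next_idx else k - 1, k))
    elements = [_LIG_ELEMENTS[k % len(_LIG_ELEMENTS)] for k in range(size)]
    return elements, bonds, np.array(coords)


def _toy_complex_parts(spec: FixtureSpec, seed: int):
    """Shared geometry for the PDB complex and the ligand Molecule:
    (shell coords, ligand elements, ligand in-pocket coords, bonds)."""
    R = spec.pocket_radius
    if spec.ligand_size * 1.5 > 4 * R:
        raise ValueError("ligand too large for the pocket")
    shell = _fibonacci_sphere(spec.n_shell) * R
    rng = np.random.default_rng(seed)
    shell = shell + rng.normal(scale=0.3, size=shell.shape)

    elements, bonds, lig = toy_ligand_topology(spec.ligand_size)
    lig = lig - lig.mean(axis=0)
    # seeded rigid orientation
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.default_rng(seed + 1)).as_matrix()
    lig = lig @ rot.T
    # anchor the ligand off-center near the +x wall, then walk it toward its
    # nearest shell atom until the closest contact sits just under the 3 A
    # chain-contact filter (target 2.85 A), staying clash-free
    wall_idx = int(np.argmax(shell[:, 0]))
    wall = shell[wall_idx]
    direction = wall / np.linalg.norm(wall)
    lig = lig + wall - (2.85 + float(np.max(lig @ direction))) * direction

    def _closest(pts):
        d = np.linalg.norm(pts[:, None, :] - shell[None, :, :], axis=2)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        return float(d[i, j]), i, j

    for _ in range(200):
        dmin, i, j = _closest(lig)
        if dmin <= 2.9:
            break
        u = shell[j] - lig[i]
        u /= np.linalg.norm(u)
        lig = lig + min(0.2, dmin - 2.85) * u
    for _ in range(200):
        dmin, i, j = _closest(lig)
        if dmin >= 2.2:
            break
        u = shell[j] - lig[i]
        u /= np.linalg.norm(u)
        lig = lig - 0.1 * u
    # cradle: one contact atom of the same element 3.4 A outward of each
    # ligand atom, giving the crystal placement a distinctive element-matched
    # contact signature (a knowledge-based potential trained on this complex
    # then has its minimum at the crystal pose)
    cradle: list[tuple[str, np.ndarray]] = []
    if not spec.cradle:
        return shell, elements, lig, bonds, cradle
    lig_center = lig.mean(axis=0)
    for i, pos in enumerate(lig):
        outward = pos - lig_center
        norm = np.linalg.norm(outward)
        outward = outward / norm if norm > 1e-6 else np.array([0.0, 0.0, 1.0])
        side = np.cross(outward, [0.0, 0.0, 1.0])
        if np.linalg.norm(side) < 1e-6:
            side = np.cross(outward, [1.0, 0.0, 0.0])
        side /= np.linalg.norm(side)
        for direction in (outward, side):
            cpos = pos + 3.4 * direction
            if np.min(np.linalg.norm(lig - cpos, axis=1)) < 2.0:
                continue
            if cradle and min(np.linalg.norm(c - cpos) for _, c in cradle) < 2.0:
                continue
            if np.min(np.linalg.norm(shell - cpos, axis=1)) < 2.0:
                continue
            cradle.append((elements[i], cpos))
    return shell, elements, lig, bonds, cradle


def make_toy_complex(spec: FixtureSpec | None = None, seed: int | None = None) -> str:
    """PDB text for one toy complex: a concave residue shell of radius
    ``pocket_radius`` with a het-group ligand inside, at least one ligand
    atom within 3 A of the chain, plus two waters.  Deterministic per seed.
    """
    spec = spec or FixtureSpec()
    seed = spec.seed if seed is None else seed
    shell, elements, lig, _bonds, cradle = _toy_complex_parts(spec, seed)

    lines = [
        "HEADER    TOY COMPLEX",
        f"SOURCE    ORGANISM_SCIENTIFIC: {spec.organism.upper()};",
    ]
    serial = 1
    for i, pos in enumerate(shell):
        resname = _RESIDUE_ROSTER[i % len(_RESIDUE_ROSTER)]
        outward = pos / np.linalg.norm(pos)
        lines.append(_pdb_line("ATOM", serial, "CA", resname, "A", i + 1, pos, "C"))
        serial += 1
        lines.append(_pdb_line("ATOM", serial, "CB", resname, "A", i + 1, pos + 1.5 * outward, "C"))
        serial += 1
    for j, (el, cpos) in enumerate(cradle):
        atom_name = {"C": "CA", "N": "N", "O": "O"}.get(el, "CA")
        lines.append(_pdb_line("ATOM", serial, atom_name, "GLY", "A", 500 + j, cpos, el))
        serial += 1
    for k, pos in enumerate(lig):
        el = elements[k]
        lines.append(_pdb_line("HETATM", serial, f"{el}{k + 1}", spec.het_code, "A", 900, pos, el))
        serial += 1
    for k in range(2):
        wpos = np.array([0.0, 0.0, spec.pocket_radius + 4.0 + 2.0 * k])
        lines.append(_pdb_line("HETATM", serial, "O", "HOH", "A", 950 + k, wpos, "O"))
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_toy_ligand_molecule(spec: FixtureSpec | None = None, seed: int | None = None) -> Molecule:
    """The toy complex's ligand as a bonded :class:`Molecule` placed at its
    in-pocket crystal coordinates (same generator, same seed)."""
    spec = spec or FixtureSpec()
    seed = spec.seed if seed is None else seed
    _shell, elements, lig, bonds, _cradle = _toy_complex_parts(spec, seed)
    atoms = [Atom(elements[k], lig[k]) for k in range(spec.ligand_size)]
    mol = Molecule(atoms, [Bond(i, j, 1.0) for i, j in bonds], name=f"toy-ligand-{seed}")
    return perceive_rotatable_bonds(mol)


def make_curcumin(embed_seed: int | None = None) -> Molecule:
    """Curcumin with a deterministic 3D embedding and rotatable bonds set."""
    kwargs = {} if embed_seed is None else {"embed_seed": embed_seed}
    mol = parse_small_molecule(CURCUMIN_SMILES, name="curcumin", **kwargs)
    return perceive_rotatable_bonds(mol)


def make_labeled_scores(spec: FixtureSpec | None = None, seed: int | None = None) -> LabeledRanking:
    """Labeled ranking with planted actives: ``n`` active scores from
    Normal(active_mean, sd) and ``N - n`` inactive scores from
    Normal(inactive_mean, sd), merged and sorted.  Defaults emulate the
    reference screen shape (21 actives among 13,553)."""
    spec = spec or FixtureSpec()
    seed = spec.seed if seed is None else seed
    m = spec.score_model
    rng = np.random.default_rng(seed)
    n, N, sd = m["n"], m["N"], m["sd"]
    active = rng.normal(m["active_mean"], sd, size=n)
    inactive = rng.normal(m["inactive_mean"], sd, size=N - n)
    ids = [f"act{i:05d}" for i in range(n)] + [f"dec{i:05d}" for i in range(N - n)]
    scores = np.concatenate([active, inactive])
    labels = np.concatenate([np.ones(n, int), np.zeros(N - n, int)])
    return LabeledRanking(ids, scores, labels)


def target_table_ranking() -> "LabeledRanking":
    """The printed 21-target table as a score ranking (all labeled active),
    for threshold-selection checks."""
    ids = [t[0] for t in CURCUMIN_TARGET_TABLE]
    scores = np.array([t[2] for t in CURCUMIN_TARGET_TABLE])
    return LabeledRanking(ids, scores, np.ones(len(ids), int))
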