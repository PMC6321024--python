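"""Geometric protein-ligand interaction profiling.

Detects seven non-covalent interaction types from a docked pose:
hydrogen bonds, hydrophobic contacts, pi-stacking, pi-cation contacts,
salt bridges, water bridges and halogen bonds.  Detection windows follow
widely used profiler defaults and are all configurable:

- hydrogen bond: donor-acceptor <= 3.5 A, D-H...A angle >= 120 deg when
  the donor hydrogen position is known (distance-only otherwise);
- hydrophobic: apolar carbon pairs at 3.3-4.0 A;
- pi-stacking: ring-centroid distance <= 5.0 A with interplanar angle
  <= 30 deg (parallel) or 60-90 deg (T-shaped);
- pi-cation: centroid-cation <= 5.0 A;
- salt bridge: charged-group centroids <= 5.0 A, opposite signs;
- water bridge: a water oxygen within hydrogen-bond range of a polar atom
  on each side;
- halogen bond: C-X...A with X...A <= 3.8 A and angle >= 140 deg.

Ligand geometry comes from a :class:`~invdock.chem.Molecule` (aromatic
rings, formal charges, explicit hydrogens when present); protein groups
come from per-residue templates over standard PDB atom names.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from invdock.chem import Molecule
from invdock.sitedb import ProteinChain, Residue

HBOND_DIST = 3.5
HBOND_ANGLE = 120.0
HYDROPHOBIC_MIN = 3.3
HYDROPHOBIC_MAX = 4.0
PI_STACK_DIST = 5.0
PI_STACK_PARALLEL_MAX = 30.0
PI_STACK_T_MIN = 60.0
PI_STACK_T_MAX = 90.0
PI_CATION_DIST = 5.0
SALT_BRIDGE_DIST = 5.0
HALOGEN_DIST = 3.8
HALOGEN_ANGLE = 140.0

KINDS = (
    "hydrogen_bond",
    "hydrophobic",
    "pi_stacking",
    "pi_cation",
    "salt_bridge",
    "water_bridge",
    "halogen_bond",
)

# Protein residue templates over standard PDB atom names
_DONORS = {
    "backbone": ["N"],
    "ARG": ["NE", "NH1", "NH2"], "ASN": ["ND2"], "GLN": ["NE2"],
    "HIS": ["ND1", "NE2"], "LYS": ["NZ"], "SER": ["OG"], "THR": ["OG1"],
    "TRP": ["NE1"], "TYR": ["OH"], "CYS": ["SG"],
}
_ACCEPTORS = {
    "backbone": ["O"],
    "ASN": ["OD1"], "ASP": ["OD1", "OD2"], "GLN": ["OE1"],
    "GLU": ["OE1", "OE2"], "HIS": ["ND1", "NE2"], "SER": ["OG"],
    "THR": ["OG1"], "TYR": ["OH"], "MET": ["SD"],
}
_RINGS = {
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TRP": [["CG", "CD1", "CD2", "NE1", "CE2"], ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"]],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
}
_NEG_GROUPS = {"ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"]}
_POS_GROUPS = {"LYS": ["NZ"], "ARG": ["CZ", "NH1", "NH2"]}
_APOLAR_RESIDUES = {
    "ALA": ["CB"], "VAL": ["CB", "CG1", "CG2"], "LEU": ["CB", "CG", "CD1", "CD2"],
    "ILE": ["CB", "CG1", "CG2", "CD1"], "MET": ["CB", "CG", "CE"],
    "PRO": ["CB", "CG", "CD"], "PHE": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TRP": ["CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"],
    "TYR": ["CB", "CG", "CD1", "CD2", "CE1", "CE2"],
}


@dataclass(frozen=True)
class InteractionParams:
    hbond_dist: float = HBOND_DIST
    hbond_angle: float = HBOND_ANGLE
    hydrophobic_min: float = HYDROPHOBIC_MIN
    hydrophobic_max: float = HYDROPHOBIC_MAX
    pi_stack_dist: float = PI_STACK_DIST
    pi_parallel_max: float = PI_STACK_PARALLEL_MAX
    pi_t_min: float = PI_STACK_T_MIN
    pi_t_max: float = PI_STACK_T_MAX
    pi_cation_dist: float = PI_CATION_DIST
    salt_bridge_dist: float = SALT_BRIDGE_DIST
    halogen_dist: float = HALOGEN_DIST
    halogen_angle: float = HALOGEN_ANGLE


@dataclass(frozen=True)
class InteractionRecord:
    kind: str
    ligand_atoms: tuple
    residue: tuple  # (chain_id, seqnum, icode, resname)
    geometry: dict = field(default_factory=dict)

    def validates(self, p: InteractionParams = InteractionParams()) -> bool:
        """Re-check this record's geometry against its kind's window."""
        g = self.geometry
        if self.kind == "hydrogen_bond":
            ok = g["distance"] <= p.hbond_dist
            if "angle" in g:
                ok = ok and g["angle"] >= p.hbond_angle
            return ok
        if self.kind == "hydrophobic":
            return p.hydrophobic_min <= g["distance"] <= p.hydrophobic_max
        if self.kind == "pi_stacking":
            ang = g["interplanar_angle"]
            return g["distance"] <= p.pi_stack_dist and (
                ang <= p.pi_parallel_max or p.pi_t_min <= ang <= p.pi_t_max
            )
        if self.kind == "pi_cation":
            return g["distance"] <= p.pi_cation_dist
        if self.kind == "salt_bridge":
            return g["distance"] <= p.salt_bridge_dist
        if self.kind == "water_bridge":
            return g["distance_ligand"] <= p.hbond_dist and g["distance_protein"] <= p.hbond_dist
        if self.kind == "halogen_bond":
            return g["distance"] <= p.halogen_dist and g["angle"] >= p.halogen_angle
        return False


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))


def _ring_normal(pts: np.ndarray) -> np.ndarray:
    centered = pts - pts.mean(axis=0)
    _, _, vh = np.linalg.svd(centered)
    return vh[2]


def _ligand_rings(m: Molecule) -> list[list[int]]:
    """Aromatic rings as atom-index cycles (simple cycles of the aromatic
    subgraph, 5- or 6-membered)."""
    g = nx.Graph()
    for b in m.bonds:
        if m.atoms[b.i].is_aromatic and m.atoms[b.j].is_aromatic:
            g.add_edge(b.i, b.j)
    rings = []
    for cyc in nx.cycle_basis(g):
        if len(cyc) in (5, 6):
            rings.append(sorted(cyc))
    return rings


def _ligand_apolar(m: Molecule) -> list[int]:
    polar_nbr = set()
    for b in m.bonds:
        if m.atoms[b.i].element in ("N", "O", "S", "P"):
            polar_nbr.add(b.j)
        if m.atoms[b.j].element in ("N", "O", "S", "P"):
            polar_nbr.add(b.i)
    return [i for i, a in enumerate(m.atoms) if a.element == "C" and i not in polar_nbr]


def _ligand_h_of(m: Molecule, heavy_idx: int) -> list[np.ndarray]:
    return [h for parent, h in m.explicit_h if parent == heavy_idx]


def _residue_atom(res: Residue, name: str) -> np.ndarray | None:
    for a in res.atoms:
        if a.name == name:
            return a.coords
    return None


def profile_interactions(
    ligand: Molecule,
    pose_coords: np.ndarray,
    protein: ProteinChain | list[ProteinChain],
    waters: list[np.ndarray] | None = None,
    params: InteractionParams = InteractionParams(),
) -> list[InteractionRecord]:
    """Detect all interactions between a ligand pose and the protein.

    ``pose_coords`` are heavy-atom coordinates in ligand atom order
    (explicit ligand hydrogens, when stored, are rigidly carried along
    only if the pose equals the molecule's own geometry; otherwise
    hydrogen-dependent angle checks fall back to distance-only).
    Output is deterministic: sorted by residue key then kind, and
    invariant to atom input order.
    """
    chains = protein if isinstance(protein, list) else [protein]
    pose_coords = np.asarray(pose_coords, float)
    same_geometry = len(ligand.atoms) == len(pose_coords) and np.allclose(
        ligand.coords, pose_coords, atol=1e-6
    )

    lig_donors = [
        i for i, a in enumerate(ligand.atoms)
        if a.element in ("N", "O", "S") and ligand.n_hydrogens[i] > 0
    ]
    lig_acceptors = [
        i for i, a in enumerate(ligand.atoms)
        if a.element in ("N", "O") and a.formal_charge <= 0
    ]
    lig_rings = _ligand_rings(ligand)
    lig_apolar = _ligand_apolar(ligand)
    lig_cations = [i for i, a in enumerate(ligand.atoms) if a.formal_charge > 0]
    lig_anions = [i for i, a in enumerate(ligand.atoms) if a.formal_charge < 0]
    lig_halogens = [i for i, a in enumerate(ligand.atoms) if a.element in ("F", "Cl", "Br", "I")]
    nbrs: dict[int, list[int]] = {}
    for b in ligand.bonds:
        nbrs.setdefault(b.i, []).append(b.j)
        nbrs.setdefault(b.j, []).append(b.i)

    records: list[InteractionRecord] = []

    for chain in chains:
        for res in chain.residues:
            rkey = (chain.chain_id, res.seqnum, res.icode, res.name)
            res_donor_names = _DONORS["backbone"] + _DONORS.get(res.name, [])
            res_acceptor_names = _ACCEPTORS["backbone"] + _ACCEPTORS.get(res.name, [])

            # --- hydrogen bonds -------------------------------------------
            for dname in res_donor_names:
                d_pos = _residue_atom(res, dname)
                if d_pos is None:
                    continue
                h_pos = _residue_atom(res, "H" + dname[1:]) if len(dname) > 1 else _residue_atom(res, "H")
                for ai in lig_acceptors:
                    a_pos = pose_coords[ai]
                    dist = float(np.linalg.norm(d_pos - a_pos))
                    if dist > params.hbond_dist:
                        continue
                    geom = {"distance": dist}
                    if h_pos is not None:
                        ang = _angle(d_pos, h_pos, a_pos)
                        if ang < params.hbond_angle:
                            continue
                        geom["angle"] = ang
                    records.append(InteractionRecord("hydrogen_bond", (ai,), rkey, geom))
            for di in lig_donors:
                d_pos = pose_coords[di]
                h_list = _ligand_h_of(ligand, di) if same_geometry else []
                for aname in res_acceptor_names:
                    a_pos = _residue_atom(res, aname)
                    if a_pos is None:
                        continue
                    dist = float(np.linalg.norm(d_pos - a_pos))
                    if dist > params.hbond_dist:
                        continue
                    geom = {"distance": dist}
                    if h_list:
                        ang = max(_angle(d_pos, h, a_pos) for h in h_list)
                        if ang < params.hbond_angle:
                            continue
                        geom["angle"] = ang
                    records.append(InteractionRecord("hydrogen_bond", (di,), rkey, geom))

            # --- hydrophobic ----------------------------------------------
            apolar_names = _APOLAR_RESIDUES.get(res.name, [])
            best: dict[int, tuple[float, str]] = {}
            for cname in apolar_names:
                c_pos = _residue_atom(res, cname)
                if c_pos is None:
                    continue
                for li in lig_apolar:
                    dist = float(np.linalg.norm(c_pos - pose_coords[li]))
                    if params.hydrophobic_min <= dist <= params.hydrophobic_max:
                        if li not in best or dist < best[li][0]:
                            best[li] = (dist, cname)
            for li, (dist, cname) in sorted(best.items()):
                records.append(
                    InteractionRecord("hydrophobic", (li,), rkey,
                                      {"distance": dist, "protein_atom": cname})
                )

            # --- pi systems ------------------------------------------------
            res_rings = []
            for names in _RINGS.get(res.name, []):
                pts = [_residue_atom(res, nm) for nm in names]
                if all(p is not None for p in pts):
                    res_rings.append(np.array(pts))
            for rpts in res_rings:
                r_cen = rpts.mean(axis=0)
                r_norm = _ring_normal(rpts)
                for ring in lig_rings:
                    lpts = pose_coords[ring]
                    l_cen = lpts.mean(axis=0)
                    dist = float(np.linalg.norm(r_cen - l_cen))
                    if dist > params.pi_stack_dist:
                        continue
                    l_norm = _ring_normal(lpts)
                    cosang = abs(float(np.dot(r_norm, l_norm)))
                    ang = float(np.degrees(np.arccos(np.clip(cosang, 0, 1))))
                    if ang <= params.pi_parallel_max or params.pi_t_min <= ang <= params.pi_t_max:
                        records.append(
                            InteractionRecord("pi_stacking", tuple(ring), rkey,
                                              {"distance": dist, "interplanar_angle": ang})
                        )
                for ci in lig_cations:
                    dist = float(np.linalg.norm(r_cen - pose_coords[ci]))
                    if dist <= params.pi_cation_dist:
                        records.append(
                            InteractionRecord("pi_cation", (ci,), rkey, {"distance": dist})
                        )
            pos_names = _POS_GROUPS.get(res.name)
            if pos_names:
                pts = [_residue_atom(res, nm) for nm in pos_names]
                pts = [p for p in pts if p is not None]
                if pts:
                    cat_cen = np.mean(pts, axis=0)
                    for ring in lig_rings:
                        dist = float(np.linalg.norm(cat_cen - pose_coords[ring].mean(axis=0)))
                        if dist <= params.pi_cation_dist:
                            records.append(
                                InteractionRecord("pi_cation", tuple(ring), rkey, {"distance": dist})
                            )

            # --- salt bridges ---------------------------------------------
            for groups, lig_charged in ((_NEG_GROUPS, lig_cations), (_POS_GROUPS, lig_anions)):
                names = groups.get(res.name)
                if not names or not lig_charged:
                    continue
                pts = [_residue_atom(res, nm) for nm in names]
                pts = [p for p in pts if p is not None]
                if not pts:
                    continue
                g_cen = np.mean(pts, axis=0)
                for li in lig_charged:
                    dist = float(np.linalg.norm(g_cen - pose_coords[li]))
                    if dist <= params.salt_bridge_dist:
                        records.append(
                            InteractionRecord("salt_bridge", (li,), rkey, {"distance": dist})
                        )

            # --- water bridges --------------------------------------------
            if waters:
                polar_res = []
                for nm in set(res_donor_names + res_acceptor_names):
                    pnt = _residue_atom(res, nm)
                    if pnt is not None:
                        polar_res.append((nm, pnt))
                lig_polar = sorted(set(lig_donors) | set(lig_acceptors))
                for wi, w in enumerate(waters):
                    w = np.asarray(w, float)
                    for li in lig_polar:
                        dl = float(np.linalg.norm(w - pose_coords[li]))
                        if dl > params.hbond_dist:
                            continue
                        for nm, pnt in polar_res:
                            dp = float(np.linalg.norm(w - pnt))
                            if dp <= params.hbond_dist:
                                records.append(
                                    InteractionRecord(
                                        "water_bridge", (li,), rkey,
                                        {"distance_ligand": dl, "distance_protein": dp,
                                         "water_index": wi, "protein_atom": nm},
                                    )
                                )

            # --- halogen bonds --------------------------------------------
            for xi in lig_halogens:
                carbons = [j for j in nbrs.get(xi, []) if ligand.atoms[j].element == "C"]
                if not carbons:
                    continue
                c_pos = pose_coords[carbons[0]]
                x_pos = pose_coords[xi]
                for aname in res_acceptor_names:
                    a_pos = _residue_atom(res, aname)
                    if a_pos is None:
                        continue
                    dist = float(np.linalg.norm(x_pos - a_pos))
                    if dist > params.halogen_dist:
                        continue
                    ang = _angle(c_pos, x_pos, a_pos)
                    if ang >= params.halogen_angle:
                        records.append(
                            InteractionRecord("halogen_bond", (xi,), rkey,
                                              {"distance": dist, "angle": ang})
                        )

    records.sort(key=lambda rec: (rec.residue, KINDS.index(rec.kind), rec.ligand_atoms))
    return records
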