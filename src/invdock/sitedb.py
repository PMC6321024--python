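"""Binding-site database construction from protein structures.

The pipeline mirrors how proteome-wide inverse-docking databases are
prepared from the PDB:

1. build the presumed biological assembly from header transforms, then for
   each protein chain keep co-crystallized HETATM groups with more than a
   minimum number of heavy atoms that touch the chain (closest heavy-atom
   distance below a contact cutoff), and record the binding residues
   (any atom closer than a residue cutoff to any ligand atom);
2. cluster chains at 100% sequence identity; waters and configured
   cofactor codes are not treated as site-defining ligands;
3.-4. compare binding sites all-against-all within each sequence cluster
   with a residue-correspondence similarity score standardized against a
   permutation null, and single-linkage cluster pairs with z >= 2.0;
5. pick one representative site per cluster;
6. delimit each representative's search volume as a union of centroid
   spheres covering the source-ligand atoms;
7. filter by source organism (human by default).

PDB parsing is delegated to gemmi; this module owns the filtering,
similarity and clustering logic.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from invdock.chem import SUPPORTED_ELEMENTS

logger = logging.getLogger(__name__)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: Common cofactor het codes excluded from site-defining ligands; waters are
#: always excluded.  Override through ``SiteDbParams.cofactor_codes``.
DEFAULT_COFACTOR_CODES = frozenset({
    "HEM", "NAD", "NAI", "NAP", "NDP", "FAD", "FMN", "ATP", "ADP", "AMP",
    "GTP", "GDP", "GMP", "COA", "SAM", "SAH", "PLP", "TPP", "TDP", "BTN",
})


@dataclass(frozen=True)
class SiteDbParams:
    """Cutoffs controlling database construction.  Distances in angstroms.

    ``min_heavy_atoms=8`` keeps ligands with *more than* 7 heavy atoms;
    strict inequalities apply at the distance cutoffs.
    """

    min_heavy_atoms: int = 8
    ligand_contact_cutoff: float = 3.0
    binding_residue_cutoff: float = 5.0
    seq_identity_cutoff: float = 1.00
    site_z_cutoff: float = 2.0
    taxon_filter: str = "Homo sapiens"
    cofactor_codes: frozenset = DEFAULT_COFACTOR_CODES
    max_centroid_radius: float = 4.0
    min_centroid_radius: float = 1.5
    similarity_tol: float = 1.5
    n_null_permutations: int = 100
    similarity_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_heavy_atoms < 1:
            raise ValueError("min_heavy_atoms must be positive")
        for name in ("ligand_contact_cutoff", "binding_residue_cutoff", "site_z_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.seq_identity_cutoff <= 1):
            raise ValueError("seq_identity_cutoff must lie in (0, 1]")


@dataclass(frozen=True)
class StructAtom:
    """A named protein/het atom (PDB atom name + element + coordinates)."""

    name: str
    element: str
    coords: np.ndarray

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass
class Residue:
    name: str
    seqnum: int
    icode: str
    atoms: list[StructAtom]

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.seqnum, self.icode, self.name)


@dataclass
class ProteinChain:
    chain_id: str
    residues: list[Residue]

    @property
    def sequence(self) -> str:
        return "".join(THREE_TO_ONE.get(r.name, "X") for r in self.residues)

    def heavy_coords(self) -> np.ndarray:
        pts = [a.coords for r in self.residues for a in r.atoms if a.is_heavy]
        return np.array(pts, dtype=float) if pts else np.empty((0, 3))

    def heavy_atoms(self) -> list[tuple[Residue, StructAtom]]:
        return [(r, a) for r in self.residues for a in r.atoms if a.is_heavy]


@dataclass
class HetGroup:
    """A co-crystallized non-water heteroatom group."""

    het_code: str
    seqnum: int
    chain_id: str
    atoms: list[StructAtom]
    parent_entry: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("HetGroup must contain atoms")
        if self.het_code == "HOH":
            raise ValueError("waters are not het groups")

    @property
    def ref(self) -> str:
        return f"{self.het_code}:{self.chain_id}:{self.seqnum}"

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms if a.is_heavy], dtype=float)

    def n_heavy(self) -> int:
        return sum(1 for a in self.atoms if a.is_heavy)


@dataclass
class StructureEntry:
    entry_id: str
    chains: list[ProteinChain]
    het_groups: list[HetGroup]
    assembly_transforms: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    source_organism: str = "unknown"

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate chain identifiers")
        if not self.assembly_transforms:
            self.assembly_transforms = [(np.eye(3), np.zeros(3))]


@dataclass(frozen=True)
class SiteResidue:
    """A binding-site residue: key plus label and representative (CA) position."""

    chain_id: str
    name: str
    seqnum: int
    icode: str
    ca: np.ndarray

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chain_id, self.seqnum, self.icode, self.name)


@dataclass
class BindingSite:
    """Residues plus centroid spheres delimiting a docking search volume."""

    site_id: str
    entry_id: str
    chain_id: str
    residues: list[SiteResidue]
    source_ligands: list[HetGroup] = field(default_factory=list)
    centroids: list[tuple[np.ndarray, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("BindingSite needs at least one residue")

    def covering_ok(self) -> bool:
        """True iff every source-ligand heavy atom lies inside the centroid union."""
        if not self.centroids:
            return not self.source_ligands
        centers = np.array([c for c, _ in self.centroids])
        radii = np.array([r for _, r in self.centroids])
        for lig in self.source_ligands:
            pts = lig.heavy_coords()
            d = np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=2)
            if not np.all((d <= radii[None, :] + 1e-9).any(axis=1)):
                return False
        return True


# ---------------------------------------------------------------------------
# Structure loading

_ORGANISM_RE = re.compile(r"ORGANISM_SCIENTIFIC:\s*([^;]+);?")


def load_structure(pdb_text: str, entry_id: str = "") -> StructureEntry:
    """Parse PDB-format text into a :class:`StructureEntry`.

    First model only; waters dropped; for alternate locations the highest
    occupancy conformer of each atom is kept; biological-assembly
    transforms come from the REMARK 350 header (identity if absent).
    """
    import gemmi

    if not pdb_text.strip():
        raise ValueError("empty PDB input")
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"PDB parse failure: {exc}") from exc
    if len(st) == 0:
        raise ValueError("no models in PDB input")
    if not entry_id:
        entry_id = st.name.strip().lower() or "entry"
    organism = "unknown"
    m = _ORGANISM_RE.search(pdb_text)
    if m:
        organism = m.group(1).strip().title()

    model = st[0]
    chains: list[ProteinChain] = []
    hets: list[HetGroup] = []
    n_protein_atoms = 0
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            if res.name == "HOH":
                continue
            best: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = best.get(at.name)
                if prev is None or at.occ > prev.occ:
                    best[at.name] = at
            atoms = [
                StructAtom(at.name, at.element.name, np.array([at.pos.x, at.pos.y, at.pos.z]))
                for at in best.values()
            ]
            if not all(np.all(np.isfinite(a.coords)) for a in atoms):
                raise ValueError(f"non-finite coordinates in residue {res.name} {res.seqid.num}")
            if res.name in THREE_TO_ONE:
                residues.append(Residue(res.name, res.seqid.num, res.seqid.icode.strip(), atoms))
                n_protein_atoms += len(atoms)
            else:
                hets.append(HetGroup(res.name, res.seqid.num, chain.name, atoms, parent_entry=entry_id))
        if residues:
            chains.append(ProteinChain(chain.name, residues))
    if n_protein_atoms == 0:
        raise ValueError("no protein ATOM records found")

    transforms: list[tuple[np.ndarray, np.ndarray]] = []
    if st.assemblies:
        asm = st.assemblies[0]
        for gen in asm.generators:
            for op in gen.operators:
                rot = np.array(op.transform.mat.tolist())
                vec = np.array(op.transform.vec.tolist())
                transforms.append((rot, vec))
    if not transforms:
        transforms = [(np.eye(3), np.zeros(3))]
    return StructureEntry(entry_id, chains, hets, transforms, organism)


def _transform_atoms(atoms: list[StructAtom], rot: np.ndarray, vec: np.ndarray) -> list[StructAtom]:
    return [StructAtom(a.name, a.element, rot @ a.coords + vec) for a in atoms]


def assembly_chains(entry: StructureEntry) -> list[ProteinChain]:
    """Chains of the biological assembly: one copy per header transform."""
    out: list[ProteinChain] = []
    for k, (rot, vec) in enumerate(entry.assembly_transforms):
        suffix = "" if k == 0 else f"-{k + 1}"
        for chain in entry.chains:
            residues = [
                Residue(r.name, r.seqnum, r.icode, _transform_atoms(r.atoms, rot, vec))
                for r in chain.residues
            ]
            out.append(ProteinChain(chain.chain_id + suffix, residues))
    return out


# ---------------------------------------------------------------------------
# Step 1: ligand and binding-residue extraction


def extract_candidate_ligands(
    entry: StructureEntry, chain: ProteinChain, p: SiteDbParams
) -> list[HetGroup]:
    """Het groups with >= ``min_heavy_atoms`` heavy atoms whose closest heavy
    atom lies strictly within ``ligand_contact_cutoff`` of the chain.
    Waters never appear; cofactor codes are excluded here."""
    chain_pts = chain.heavy_coords()
    if chain_pts.size == 0:
        return []
    tree = cKDTree(chain_pts)
    kept = []
    for lig in entry.het_groups:
        if lig.het_code in p.cofactor_codes:
            continue
        if lig.n_heavy() < p.min_heavy_atoms:
            continue
        d, _ = tree.query(lig.heavy_coords(), k=1)
        if float(np.min(d)) < p.ligand_contact_cutoff:
            kept.append(lig)
    return kept


def binding_residues(
    chain: ProteinChain, lig: HetGroup, p: SiteDbParams
) -> set[tuple[int, str, str]]:
    """Residue keys with any atom strictly closer than
    ``binding_residue_cutoff`` to any ligand heavy atom."""
    lig_pts = lig.heavy_coords()
    tree = cKDTree(lig_pts)
    keys = set()
    for res in chain.residues:
        pts = np.array([a.coords for a in res.atoms if a.is_heavy])
        if pts.size == 0:
            continue
        d, _ = tree.query(pts, k=1)
        if float(np.min(d)) < p.binding_residue_cutoff:
            keys.add(res.key)
    return keys


# ---------------------------------------------------------------------------
# Step 2: sequence clustering


def cluster_sequences(chains: list[ProteinChain], p: SiteDbParams) -> list[list[int]]:
    """Single-linkage clusters of chain indices by sequence identity.

    At the default cutoff of 1.0 this groups chains with byte-identical
    sequences.  For cutoffs below 1.0 identity is computed position-wise
    between equal-length sequences (no alignment)."""
    n = len(chains)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    seqs = [c.sequence for c in chains]
    for i in range(n):
        for j in range(i + 1, n):
            if p.seq_identity_cutoff >= 1.0:
                same = seqs[i] == seqs[j] and seqs[i] != ""
            else:
                if len(seqs[i]) != len(seqs[j]) or not seqs[i]:
                    same = False
                else:
                    ident = sum(a == b for a, b in zip(seqs[i], seqs[j])) / len(seqs[i])
                    same = ident >= p.seq_identity_cutoff
            if same:
                g.add_edge(i, j)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: c[0])
    return comps


# ---------------------------------------------------------------------------
# Steps 3-4: site similarity and clustering


def _correspondence_size(
    labels_a: list[str], xyz_a: np.ndarray, labels_b: list[str], xyz_b: np.ndarray, tol: float
) -> int:
    """Size of the best residue-label-compatible, distance-consistent
    correspondence between two sites.

    Seeded by matching label-compatible residue triplets whose pairwise
    CA distances agree within ``tol`` (a geometric hash over triplets),
    then greedily extended with pairs whose distances to every matched
    pair also agree within ``tol``."""
    na, nb = len(labels_a), len(labels_b)
    da = np.linalg.norm(xyz_a[:, None] - xyz_a[None, :], axis=2)
    db = np.linalg.norm(xyz_b[:, None] - xyz_b[None, :], axis=2)
    compat = np.array([[labels_a[i] == labels_b[j] for j in range(nb)] for i in range(na)])
    best = 0
    # triplet seeds: first residue pairs with compatible labels, grown to triplets
    for i in range(na):
        for j in range(nb):
            if not compat[i, j]:
                continue
            # greedy extension from the seed pair
            matched_a = [i]
            matched_b = [j]
            used_b = {j}
            for ii in range(na):
                if ii in matched_a:
                    continue
                for jj in range(nb):
                    if jj in used_b or not compat[ii, jj]:
                        continue
                    if all(
                        abs(da[ii, ka] - db[jj, kb]) <= tol
                        for ka, kb in zip(matched_a, matched_b)
                    ):
                        matched_a.append(ii)
                        matched_b.append(jj)
                        used_b.add(jj)
                        break
            if len(matched_a) >= 3:  # require at least a consistent triplet
                best = max(best, len(matched_a))
    return best


def site_similarity_z(
    a: BindingSite,
    b: BindingSite,
    tol: float = 1.5,
    n_permutations: int = 100,
    seed: int = 0,
) -> float:
    """Similarity z-score between two binding sites.

    Raw score: best label-compatible, distance-consistent residue
    correspondence (CA positions, tolerance ``tol``).  The null
    distribution comes from ``n_permutations`` random permutations of the
    second site's residue labels (fixed seed); z = (raw - mean)/sd with
    the sd floored at one residue to keep degenerate nulls finite.
    """
    if len(a.residues) < 3 or len(b.residues) < 3:
        raise ValueError("site similarity needs at least 3 residues per site")
    labels_a = [r.name for r in a.residues]
    labels_b = [r.name for r in b.residues]
    xyz_a = np.array([r.ca for r in a.residues])
    xyz_b = np.array([r.ca for r in b.residues])
    raw = _correspondence_size(labels_a, xyz_a, labels_b, xyz_b, tol)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    lb = np.array(labels_b)
    for k in range(n_permutations):
        perm = rng.permutation(len(lb))
        null[k] = _correspondence_size(labels_a, xyz_a, list(lb[perm]), xyz_b, tol)
    sd = max(float(np.std(null)), 1.0)
    return (raw - float(np.mean(null))) / sd


def cluster_sites(sites: list[BindingSite], p: SiteDbParams) -> list[dict]:
    """Single-linkage clusters over site pairs with z >= ``site_z_cutoff``.

    Returns one dict per cluster: ``{"members": [...], "representative": site}``
    where the representative carries the most source ligands (ties broken
    by lexicographic site id)."""
    n = len(sites)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            z = site_similarity_z(
                sites[i], sites[j], tol=p.similarity_tol,
                n_permutations=p.n_null_permutations, seed=p.similarity_seed,
            )
            if z >= p.site_z_cutoff:
                g.add_edge(i, j)
    clusters = []
    for comp in nx.connected_components(g):
        members = sorted(comp, key=lambda i: sites[i].site_id)
        rep = max(members, key=lambda i: (len(sites[i].source_ligands), _neg_id(sites[i].site_id)))
        clusters.append({"members": [sites[i] for i in members], "representative": sites[rep]})
    clusters.sort(key=lambda c: c["representative"].site_id)
    return clusters


class _neg_id(str):
    """Inverts lexicographic comparison so max() breaks ties toward the
    lexicographically smallest site id."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):  # pragma: no cover - trivial
        return str.__lt__(self, other)


# ---------------------------------------------------------------------------
# Step 6: centroid spheres


def make_centroids(
    site: BindingSite, max_radius: float = 4.0, min_radius: float = 1.5
) -> list[tuple[np.ndarray, float]]:
    """Greedy sphere cover of the site's source-ligand heavy atoms.

    Repeatedly seeds a sphere on the first uncovered atom, absorbs
    uncovered atoms within half the maximum radius of the seed, and
    centers the sphere on their mean.  Every sphere radius is at most
    ``max_radius`` and the union covers all ligand atoms (asserted)."""
    if not site.source_ligands:
        raise ValueError("make_centroids requires source ligands")
    pts = np.vstack([lig.heavy_coords() for lig in site.source_ligands])
    uncovered = list(range(len(pts)))
    spheres: list[tuple[np.ndarray, float]] = []
    while uncovered:
        seed = uncovered[0]
        group = [i for i in uncovered if np.linalg.norm(pts[i] - pts[seed]) <= max_radius / 2]
        center = pts[group].mean(axis=0)
        radius = max(float(np.max(np.linalg.norm(pts[group] - center, axis=1))) + 0.5, min_radius)
        radius = min(radius, max_radius)
        spheres.append((center, radius))
        uncovered = [
            i for i in uncovered if np.linalg.norm(pts[i] - center) > radius + 1e-9
        ]
    site.centroids = spheres
    assert site.covering_ok(), "centroid union fails to cover ligand atoms"
    return spheres


# ---------------------------------------------------------------------------
# Step 1-7 composition


def _sites_for_chain(entry: StructureEntry, chain: ProteinChain, p: SiteDbParams) -> list[BindingSite]:
    sites = []
    for lig in extract_candidate_ligands(entry, chain, p):
        keys = binding_residues(chain, lig, p)
        if not keys:
            continue
        residues = []
        for res in chain.residues:
            if res.key in keys:
                ca = next((a.coords for a in res.atoms if a.name == "CA"), res.atoms[0].coords)
                residues.append(SiteResidue(chain.chain_id, res.name, res.seqnum, res.icode, ca))
        site_id = f"{entry.entry_id}{chain.chain_id}:{lig.het_code}:{lig.seqnum}"
        sites.append(
            BindingSite(site_id, entry.entry_id, chain.chain_id, residues, source_ligands=[lig])
        )
    return sites


def build_site_database(entries: list[StructureEntry], p: SiteDbParams | None = None) -> list[BindingSite]:
    """Full pipeline: per-chain site extraction, sequence clustering,
    site-similarity clustering, representative selection, centroid
    spheres, and taxon filtering.  Per-entry failures are logged and
    skipped, never aborting the batch.  Output order is deterministic
    (sorted by site id)."""
    p = p or SiteDbParams()
    taxon = p.taxon_filter.strip().lower()
    all_chains: list[tuple[StructureEntry, ProteinChain]] = []
    for entry in entries:
        if taxon and taxon not in entry.source_organism.strip().lower():
            logger.info("entry %s excluded by taxon filter (%s)", entry.entry_id, entry.source_organism)
            continue
        try:
            for chain in assembly_chains(entry):
                all_chains.append((entry, chain))
        except Exception:
            logger.exception("skipping entry %s", entry.entry_id)
    chains = [c for _, c in all_chains]
    clusters = cluster_sequences(chains, p)
    representatives: list[BindingSite] = []
    for cluster in clusters:
        sites: list[BindingSite] = []
        for idx in cluster:
            entry, chain = all_chains[idx]
            try:
                sites.extend(_sites_for_chain(entry, chain, p))
            except Exception:
                logger.exception("skipping chain %s of %s", chain.chain_id, entry.entry_id)
        if not sites:
            continue
        big = [s for s in sites if len(s.residues) >= 3]
        small = [s for s in sites if len(s.residues) < 3]
        if big:
            for c in cluster_sites(big, p):
                representatives.append(c["representative"])
        representatives.extend(small)
    representatives.sort(key=lambda s: s.site_id)
    for site in representatives:
        make_centroids(site, p.max_centroid_radius, p.min_centroid_radius)
    return representatives


# ---------------------------------------------------------------------------
# Serialization


def write_site_database(sites: list[BindingSite], path) -> None:
    """Write the database as TSV: one row per site with residue keys and
    centroid spheres; byte-stable for identical inputs."""
    lines = ["entry\tchain\tsite_id\tresidues\tcentroids\tsource_ligands"]
    for s in sites:
        res = ",".join(f"{r.name}{r.seqnum}{r.icode}" for r in s.residues)
        cen = ";".join(
            f"{c[0]:.3f},{c[1]:.3f},{c[2]:.3f},{r:.3f}" for c, r in s.centroids
        )
        ligs = ",".join(l.ref for l in s.source_ligands)
        lines.append(f"{s.entry_id}\t{s.chain_id}\t{s.site_id}\t{res}\t{cen}\t{ligs}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
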