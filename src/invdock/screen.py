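"""End-to-end inverse screen: site database -> docking -> prioritization.

`run_inverse_screen` composes the full protocol: build the binding-site
database from a directory of PDB files, derive the knowledge-based
potential from the co-crystallized complexes themselves, dock the query
ligand into every site, keep each protein's best score, fit the score
distribution, threshold at the central-interval edge, and optionally
profile interactions on selected poses and validate against labels.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from invdock.chem import parse_small_molecule, perceive_rotatable_bonds
from invdock.docking import (
    DockingParams,
    Protein,
    derive_pair_potential,
    dock_ligand,
    ligand_view,
)
from invdock.interactions import profile_interactions
from invdock.metrics import LabeledRanking, MetricParams, metrics_report
from invdock.prioritize import ScreenResult, central_interval, fit_normal, select_targets
from invdock.sitedb import (
    SiteDbParams,
    assembly_chains,
    build_site_database,
    load_structure,
    write_site_database,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    structure_dir: str = "structures"
    ligand: str = ""  # SMILES string, or path to a .smi/.sdf file
    output_dir: str = "invdock_out"
    labels_tsv: str = ""  # optional id/score/active table for validation
    site_params: SiteDbParams = field(default_factory=SiteDbParams)
    docking_params: DockingParams = field(default_factory=DockingParams)
    metric_params: MetricParams = field(default_factory=MetricParams)
    threshold_level: float = 0.95
    profile_selected: bool = True
    seed: int = 0

    def hash(self) -> str:
        blob = json.dumps(
            {
                "site": asdict(self.site_params) | {"cofactor_codes": sorted(self.site_params.cofactor_codes)},
                "dock": asdict(self.docking_params),
                "metric": asdict(self.metric_params),
                "level": self.threshold_level,
                "seed": self.seed,
                "ligand": self.ligand,
            },
            sort_keys=True, default=str,
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_ligand(spec: str):
    """Ligand from a SMILES string or a .smi/.sdf file path."""
    p = Path(spec)
    if p.suffix.lower() in (".smi", ".smiles") and p.exists():
        text = p.read_text().strip().splitlines()[0].split()[0]
        mol = parse_small_molecule(text)
    elif p.suffix.lower() == ".sdf" and p.exists():
        mol = parse_small_molecule(p.read_text())
    else:
        mol = parse_small_molecule(spec)
    return perceive_rotatable_bonds(mol)


def run_inverse_screen(config: RunConfig):
    """Run the full inverse screen; returns (ScreenResult, ThresholdReport).

    Per-site docking failures are logged and skipped; sites with no valid
    pose are excluded from the fitted distribution.  All outputs land in
    ``config.output_dir`` tagged with the config hash.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()

    structure_dir = Path(config.structure_dir)
    pdb_files = sorted(structure_dir.glob("*.pdb"))
    if not pdb_files:
        raise FileNotFoundError(f"no PDB files in {structure_dir}")
    if not config.ligand:
        raise FileNotFoundError("no ligand configured")
    ligand = load_ligand(config.ligand)

    entries = []
    for f in pdb_files:
        try:
            entries.append(load_structure(f.read_text(), entry_id=f.stem))
        except ValueError:
            logger.exception("skipping unreadable structure %s", f)
    sites = build_site_database(entries, config.site_params)
    write_site_database(sites, out / f"sites-{cfg_hash}.tsv")
    logger.info("site database: %d representative sites", len(sites))

    entry_map = {e.entry_id: e for e in entries}
    proteins = {}
    for e in entries:
        proteins[e.entry_id] = Protein(assembly_chains(e))

    # knowledge-based potential trained on the input co-crystal complexes
    complexes = []
    for site in sites:
        prot = proteins[site.entry_id]
        for lig in site.source_ligands:
            types = [a.element if a.element not in ("F", "Cl", "Br", "I") else "X"
                     for a in lig.atoms if a.is_heavy]
            types = [t if t in ("C", "N", "O", "S", "P", "X") else None for t in types]
            complexes.append((prot, (types, lig.heavy_coords())))
    if not complexes:
        raise RuntimeError("no co-crystallized complexes to train the potential on")
    pot = derive_pair_potential(complexes)

    rows = []
    poses = {}
    for site in sites:
        prot = proteins[site.entry_id]
        try:
            ranked = dock_ligand(ligand, site, prot, pot, config.docking_params, seed=config.seed)
        except Exception:
            logger.exception("docking failed for site %s", site.site_id)
            continue
        if not ranked:
            logger.info("no pose for site %s", site.site_id)
            continue
        protein_id = f"{site.entry_id}{site.chain_id}"
        rows.append((protein_id, site.site_id, ranked[0].score))
        poses[site.site_id] = ranked[0]
        logger.info("site %s: best score %.3f (%d poses)", site.site_id, ranked[0].score, len(ranked))

    if not rows:
        logger.warning("screen produced no scores")
        empty = ScreenResult.from_records([], ligand_name=ligand.name, params_hash=cfg_hash)
        return empty, None

    # best score per protein
    df = pd.DataFrame(rows, columns=["protein_id", "site_id", "score"])
    best = df.loc[df.groupby("protein_id")["score"].idxmin()].sort_values("protein_id")
    result = ScreenResult(best.reset_index(drop=True), ligand_name=ligand.name, params_hash=cfg_hash)
    df.sort_values(["protein_id", "site_id"]).to_csv(out / f"screen-{cfg_hash}.tsv", sep="\t", index=False)

    report = None
    if len(result.rows) >= 2 and result.rows["score"].std() > 0:
        fit = fit_normal(result.rows["score"])
        low, high = central_interval(fit, config.threshold_level)
        report = select_targets(result, low, level=config.threshold_level, high=high)
        summary = {
            "config_hash": cfg_hash,
            "ligand": ligand.name,
            "n_sites": len(sites),
            "n_scored": int(len(result.rows)),
            "fit": {"mean": fit.mean, "sd": fit.sd, "n": fit.n},
            "interval": [low, high],
            "selected": report.selected.to_dict(orient="records"),
        }
        (out / f"threshold-{cfg_hash}.json").write_text(json.dumps(summary, indent=2))
        report.selected.to_csv(out / f"selected-{cfg_hash}.tsv", sep="\t", index=False)
    else:
        logger.warning("too few scores to fit a distribution; skipping thresholding")

    if config.profile_selected and report is not None:
        prof_rows = []
        for _, row in report.selected.iterrows():
            site_id = row["site_id"]
            pose = poses[site_id]
            entry_id = site_id.split(":")[0]
            entry = next(e for e in entries if site_id.startswith(e.entry_id))
            recs = profile_interactions(ligand, pose.coords, assembly_chains(entry))
            for rec in recs:
                prof_rows.append({
                    "site_id": site_id, "kind": rec.kind,
                    "residue": "".join(str(x) for x in rec.residue),
                    "ligand_atoms": ",".join(map(str, rec.ligand_atoms)),
                    **{k: v for k, v in rec.geometry.items() if isinstance(v, float)},
                })
        pd.DataFrame(prof_rows).to_csv(out / f"interactions-{cfg_hash}.tsv", sep="\t", index=False)

    if config.labels_tsv:
        ranking = LabeledRanking.from_tsv(config.labels_tsv)
        (out / f"validation-{cfg_hash}.json").write_text(
            json.dumps(metrics_report(ranking, config.metric_params), indent=2)
        )

    with open(out / f"config-{cfg_hash}.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "structure_dir": str(config.structure_dir),
                "ligand": config.ligand,
                "threshold_level": config.threshold_level,
                "seed": config.seed,
                "hash": cfg_hash,
            },
            fh,
        )
    return result, report
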