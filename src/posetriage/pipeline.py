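"""End-to-end orchestration: synth -> cluster -> SIFt -> halogen ->
pharmacophore -> report.

A run is a pure function of (inputs, configuration, seed): stage outputs are
written with deterministic serialisation (sorted keys, fixed float precision,
no timestamps), and the manifest records the configuration hash so reruns can
be byte-compared. Every printed-parameter default (clustering height 2.0 A,
>= 6 of 8 ligands per CSC, 5 A fingerprint cutoff, halogen criteria,
0.001 au isovalue) is a named configuration field, never a magic number in
stage code.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .structio import PoseSet, ReceptorStructure, read_poses, read_receptor, write_poses
from .scaffold import (ScaffoldDefinition, complete_linkage, label_csc,
                       pairwise_matrix)
from .sift import build_sift, detect_hbonds, detect_hydrophobic, occupancy_profile, proximal_residues
from .halogen import (Thresholds, classify_contact, find_halogen_contacts,
                      frequency_analysis, ring_position, select_qm_candidates)
from .pharmacophore import (derive_features, detect_ring_interactions,
                            count_by_kind, excluded_volumes, model_to_dict)
from .energetics import compare_sources, rank_correlation, read_energies, rsq

logger = logging.getLogger("posetriage.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are preserved in the run directory."""


@dataclass
class RunConfig:
    """All paths and stage parameters of one pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    # inputs; None for the synthetic route
    receptor: str | None = None
    poses: str | None = None
    energies: str | None = None
    scaffold_smarts: str | None = None
    # synth stage
    synth: bool = True
    n_ligands: int = 8
    poses_per_ligand: int = 100
    jitter_sigma: float = 0.5
    decoy_fraction: float = 0.2
    # cluster stage (printed defaults)
    cluster_height: float = 2.0
    min_ligands: int = 6
    # sift stage
    sift_cutoff: float = 5.0
    hydrophobic_cutoff: float = 4.5
    # halogen stage
    halogen_search_cutoff: float = 4.5
    # esp stage
    isovalue: float = 0.001
    log_level: str = "INFO"

    def config_hash(self) -> str:
        doc = dataclasses.asdict(self)
        doc.pop("out_dir", None)   # where results land is not part of the science
        doc.pop("log_level", None)
        return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory.

    Outputs: clusters.csv, occupancy.csv, contacts.csv, frequency.csv,
    pharmacophore.json, report.json and manifest.json. Any stage error
    aborts with the stage name; outputs written so far remain on disk.
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    stage = "setup"
    try:
        # ------------------------------------------------------------- input
        stage = "synth" if cfg.synth else "input"
        truth = None
        if cfg.synth:
            from .synthdata import SynthConfig, generate, make_energy_table

            scfg = SynthConfig(seed=cfg.seed, n_ligands=cfg.n_ligands,
                               poses_per_ligand=cfg.poses_per_ligand,
                               jitter_sigma=cfg.jitter_sigma,
                               decoy_fraction=cfg.decoy_fraction,
                               cluster_height=cfg.cluster_height)
            receptor, ps, truth = generate(scfg, out_dir=out / "synth")
            from .energetics import write_energies

            energy_records = make_energy_table(ps, truth, seed=cfg.seed)
            write_energies(energy_records, out / "synth" / "energies.csv")
        else:
            if not cfg.receptor or not cfg.poses:
                raise PipelineError("receptor and poses paths required when synth=false")
            receptor = read_receptor(cfg.receptor)
            ps = read_poses(cfg.poses)
            energy_records = read_energies(cfg.energies) if cfg.energies else []
        logger.info("input: %d poses of %d ligands; receptor %d residues",
                    len(ps), len(ps.by_ligand), len(receptor))

        # ----------------------------------------------------------- cluster
        stage = "cluster"
        sd = ScaffoldDefinition(cfg.scaffold_smarts) if cfg.scaffold_smarts \
            else ScaffoldDefinition()
        matrix = pairwise_matrix(ps, sd)
        part = label_csc(complete_linkage(matrix, cfg.cluster_height),
                         min_ligands=cfg.min_ligands, n_ligands=len(ps.by_ligand))
        counts = part.pose_counts()
        if cfg.min_ligands > len(ps.by_ligand):
            logger.warning("min_ligands (%d) exceeds ligand count (%d): no CSC possible",
                           cfg.min_ligands, len(ps.by_ligand))
        cluster_of = part.cluster_of()
        rows = [{"ligand_id": k[0], "pose_id": k[1], "cluster_id": c,
                 "csc_label": part.labels.get(c, "residual")}
                for k, c in sorted(cluster_of.items())]
        pd.DataFrame(rows).to_csv(out / "clusters.csv", index=False)
        write_poses(ps, out / "poses_annotated.sdf",
                    extra_props={k: {"cluster_id": str(c),
                                     "csc_label": part.labels.get(c, "residual")}
                                 for k, c in cluster_of.items()})
        n_csc_clusters = sum(1 for v in part.labels.values() if v == "CSC")
        logger.info("cluster: %d clusters (%d CSC) | CSC poses %d, residual %d",
                    len(part.clusters), n_csc_clusters, counts["CSC"], counts["residual"])
        report["clusters"] = {"n_clusters": len(part.clusters),
                              "n_csc_clusters": n_csc_clusters,
                              "csc_poses": counts["CSC"],
                              "residual_poses": counts["residual"],
                              "total_poses": len(ps)}

        # -------------------------------------------------------------- sift
        stage = "sift"
        universe: set = set()
        per_pose_universe = {}
        for p in ps:
            prox = proximal_residues(p, receptor, cfg.sift_cutoff)
            per_pose_universe[p.key] = prox
            universe.update(prox)
        all_records = []
        for p in ps:
            all_records += detect_hbonds(p, receptor, universe=per_pose_universe[p.key])
            all_records += detect_hydrophobic(p, receptor, cfg.hydrophobic_cutoff,
                                              universe=per_pose_universe[p.key])
        sift = build_sift(all_records, [p.key for p in ps], sorted(universe))
        subsets = {
            "CSC": [k for k, c in cluster_of.items() if part.labels.get(c) == "CSC"],
            "residual": [k for k, c in cluster_of.items()
                         if part.labels.get(c) != "CSC"],
        }
        occ_rows = []
        for name, keys in subsets.items():
            if not keys:
                continue
            prof = occupancy_profile(sift, keys, name)
            for (rk, kind), pct in sorted(prof.percent.items()):
                occ_rows.append({"chain": rk[0], "resseq": rk[1], "icode": rk[2],
                                 "kind": kind, "subset": name, "percent": pct})
        pd.DataFrame(occ_rows).to_csv(out / "occupancy.csv", index=False)
        logger.info("sift: %d contact records over %d residues", len(all_records),
                    len(universe))
        report["sift"] = {"n_records": len(all_records), "n_residues": len(universe)}

        # ----------------------------------------------------------- halogen
        stage = "halogen"
        thresholds = Thresholds(search_cutoff=cfg.halogen_search_cutoff)
        contacts = []
        from .scaffold import match_scaffold

        for p in ps:
            cs = find_halogen_contacts(p, receptor, cfg.halogen_search_cutoff)
            if cs:
                m = match_scaffold(p, sd)
                for c in cs:
                    classify_contact(c, thresholds)
                    c.ring_position = ring_position(p, c.x_atom, m)
            contacts += cs
        n_pass = sum(1 for c in contacts if c.classification in ("xbond", "x_as_acceptor"))
        poses_with_contact = len({c.pose_key for c in contacts})
        poses_passing = len({c.pose_key for c in contacts
                             if c.classification in ("xbond", "x_as_acceptor")})
        logger.info("halogen: %d contacts (%d passing) | %d of %d poses with X contacts pass",
                    len(contacts), n_pass, poses_passing, poses_with_contact)
        crow = [{"ligand_id": c.pose_key[0], "pose_id": c.pose_key[1],
                 "x_element": c.x_element, "ring_position": c.ring_position,
                 "residue": c.residue_label, "partner": c.partner_name,
                 "d": c.d_x_partner, "theta_sigma": c.theta_sigma,
                 "theta_acceptor": c.theta_acceptor, "class": c.classification,
                 "trace": json.dumps(c.trace, sort_keys=True)} for c in contacts]
        pd.DataFrame(crow, columns=["ligand_id", "pose_id", "x_element", "ring_position",
                                    "residue", "partner", "d", "theta_sigma",
                                    "theta_acceptor", "class", "trace"]
                     ).to_csv(out / "contacts.csv", index=False)
        by_pos, by_partner = frequency_analysis(ps, contacts)
        by_pos.to_csv(out / "frequency.csv", index=False)
        by_partner.to_csv(out / "partners.csv", index=False)
        report["halogen"] = {"n_contacts": len(contacts), "n_passing": n_pass,
                             "poses_with_contacts": poses_with_contact,
                             "poses_passing": poses_passing}

        # ------------------------------------------------- QM pose selection
        stage = "select"
        glide = {r.pose_key: r.dg_bind for r in energy_records if r.source == "glide"}
        selected, unselected = {}, []
        if glide:
            csc_poses = [p for p in ps if part.labels.get(cluster_of[p.key]) == "CSC"]
            selected, unselected = select_qm_candidates(csc_poses, contacts, glide)
            logger.info("select: %d ligands selected, %d without passing pose",
                        len(selected), len(unselected))
        report["selection"] = {
            "selected": {lig: list(key) for lig, key in sorted(selected.items())},
            "unselected": sorted(unselected)}

        # ------------------------------------------------------------- pharm
        stage = "pharmacophore"
        pharm_pose = None
        if selected:
            lig, key = sorted(selected.items())[0]
            pharm_pose = next(p for p in ps if p.key == tuple(key))
        elif len(ps):
            pharm_pose = ps.poses[0]
        if pharm_pose is not None:
            hb = detect_hbonds(pharm_pose, receptor)
            hyd = detect_hydrophobic(pharm_pose, receptor, cfg.hydrophobic_cutoff)
            pose_contacts = [c for c in contacts if c.pose_key == pharm_pose.key]
            ri = detect_ring_interactions(pharm_pose, receptor)
            model = derive_features(pharm_pose, hb, hyd, pose_contacts, ri)
            model.excluded_volumes = excluded_volumes(pharm_pose, receptor)
            _json_dump(model_to_dict(model), out / "pharmacophore.json")
            report["pharmacophore"] = {"pose": list(pharm_pose.key),
                                       "counts": count_by_kind(model),
                                       "n_excluded_volumes": len(model.excluded_volumes)}
            logger.info("pharmacophore: %s", report["pharmacophore"]["counts"])

        # ------------------------------------------------------------- stats
        stage = "stats"
        if energy_records:
            cmp_df = compare_sources(energy_records)
            if len(cmp_df) >= 3:
                rs = rank_correlation(cmp_df["dG_glide"], cmp_df["dG_qmmm"])
                r2 = rsq(cmp_df["dG_glide"], cmp_df["dG_qmmm"])
                cmp_df.to_csv(out / "ddg.csv", index=False)
                report["stats"] = {"n_pairs": len(cmp_df),
                                   "spearman_rs": round(rs, 4), "r2": round(r2, 4),
                                   "mean_ddG": round(float(cmp_df["ddG"].mean()), 4)}
                logger.info("stats: r_s=%.2f r^2=%.2f over %d pose pairs",
                            rs, r2, len(cmp_df))

        # ------------------------------------------------------------ report
        stage = "report"
        manifest = {"tool": "posetriage", "version": __version__,
                    "config": dataclasses.asdict(cfg),
                    "config_hash": cfg.config_hash(), "seed": cfg.seed}
        _json_dump(manifest, out / "manifest.json")
        _json_dump(report, out / "report.json")
        return out
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
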