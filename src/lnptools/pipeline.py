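"""Config-driven pipeline: fixture -> insertion -> trajectory -> analysis.

A single YAML config (sections ``fixture`` / ``insertion`` / ``trajectory``
/ ``analysis``) drives an end-to-end run that writes every artifact plus a
manifest (inputs, derived seeds, package version, effective parameters) so
any output can be reproduced.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from . import analysis as an
from .composition import CompositionSpec
from .errors import LnpError
from .fixtures import FixtureSpec, TiltModel, generate_bilayer, generate_trajectory
from .insertion import run_insertion
from .pdbio import read_structure, write_structure, write_trajectory
from .species import Protonation, Species
from .study import derive_seed
from .system import Trajectory, assign_leaflets
from .template import LipidTemplate, default_l5_template

log = logging.getLogger("lnptools")

KNOWN_METRICS = ("density", "rdf", "order", "crossing", "partition", "clusters")


class ConfigError(LnpError):
    """The pipeline config is missing or misusing a key."""


def fixture_spec_from_dict(d: dict, seed: int = 0) -> FixtureSpec:
    comp = d.get("composition", {})
    spec = FixtureSpec(
        lattice_nx=int(d.get("nx", 10)),
        lattice_ny=int(d.get("ny", 10)),
        lattice_a=float(d.get("lattice_a", 8.0)),
        leaflet_offset_z=float(d.get("leaflet_offset_z", 20.0)),
        composition=CompositionSpec(
            total_lipids_per_leaflet=int(
                comp.get("total_lipids_per_leaflet", d.get("nx", 10) * d.get("ny", 10))
            ),
            l5_fraction=float(comp.get("l5_fraction", 0.0)),
            chol_fraction=float(comp.get("chol_fraction", 0.40)),
            protonated_fraction_of_l5=float(comp.get("protonated_fraction", 0.5)),
            seed=seed,
        ),
        box_z=float(d.get("box_z", 90.0)),
        water_mode=str(d.get("water_mode", "none")),
        water_boundary_z=float(d.get("water_boundary_z", 28.0)),
        n_frames=int(d.get("n_frames", 1)),
        jitter_sigma=float(d.get("jitter_sigma", 0.0)),
        seed=seed,
    )
    for sp_name, tm in d.get("tilt", {}).items():
        spec.tilt[Species(sp_name)] = TiltModel(
            mean_deg=float(tm.get("mean_deg", 0.0)), kappa=float(tm.get("kappa", 50.0))
        )
    return spec


def validate_config(config: dict) -> None:
    if "fixture" not in config and "structure" not in config:
        raise ConfigError("config needs a 'fixture' section or a 'structure' path")
    metrics = config.get("analysis", {}).get("metrics", [])
    unknown = [m for m in metrics if m not in KNOWN_METRICS]
    if unknown:
        raise ConfigError(f"unknown metrics {unknown}; choose from {KNOWN_METRICS}")
    ins = config.get("insertion")
    if ins is not None and "l5_fraction" not in ins:
        raise ConfigError("'insertion' section requires 'l5_fraction'")


def _density_table(traj: Trajectory) -> pd.DataFrame:
    cols = {}
    for prot, label in ((Protonation.PROTONATED, "protonated"), (Protonation.NEUTRAL, "neutral")):
        prof = an.scaled_mass_density(
            traj, an.atom_selector(species=Species.L5, protonation=prot, name="N")
        )
        cols.setdefault("z", prof.bin_centers)
        cols[f"scaled_density_{label}"] = prof.scaled_counts
    return pd.DataFrame(cols)


def run_analysis(traj: Trajectory, metrics, out_dir: Path, cfg: dict) -> dict:
    """Compute the requested metrics over the trailing window; one CSV each."""
    window = cfg.get("window", "last-third")
    if window == "last-third":
        traj = an.analysis_window(traj)
    elif window != "full":
        raise ConfigError(f"unknown analysis window {window!r}")
    summary: dict = {"n_frames_analysed": traj.n_frames}
    out_dir.mkdir(parents=True, exist_ok=True)
    for metric in metrics:
        t0 = time.perf_counter()
        if metric == "density":
            _density_table(traj).to_csv(out_dir / "density.csv", index=False)
        elif metric == "rdf":
            rdf = an.lateral_rdf(
                traj,
                an.molecule_selector(species=Species.L5, protonation=Protonation.PROTONATED),
            )
            pd.DataFrame({"r": rdf.r_centers, "g": rdf.g_values}).to_csv(
                out_dir / "rdf.csv", index=False
            )
            summary["rdf_n_reference"] = rdf.n_reference
        elif metric == "order":
            rows = []
            for sp, prot, label in (
                (Species.DSPC, None, "DSPC"),
                (Species.L5, Protonation.PROTONATED, "L5_protonated"),
                (Species.L5, Protonation.NEUTRAL, "L5_neutral"),
            ):
                recs = an.orientation_angles(traj, sp, protonation=prot)
                if recs:
                    res = an.modified_order_parameter(recs, group=label)
                    rows.append({"group": label, "S": res.S, "n_samples": res.n_samples})
            pd.DataFrame(rows).to_csv(out_dir / "order.csv", index=False)
            summary["order_parameters"] = {r["group"]: r["S"] for r in rows}
        elif metric == "crossing":
            rows = {}
            for prot, label in (
                (Protonation.PROTONATED, "protonated"),
                (Protonation.NEUTRAL, "neutral"),
            ):
                h = an.crossing_angle_distribution(traj, group=prot)
                if not h.is_empty:
                    rows.setdefault(
                        "cos_center", 0.5 * (h.bin_edges[:-1] + h.bin_edges[1:])
                    )
                    rows[f"p_{label}"] = h.probabilities
            pd.DataFrame(rows).to_csv(out_dir / "crossing.csv", index=False)
        elif metric == "partition":
            boundaries = cfg.get("water_boundaries")
            part = an.cholesterol_partitioning(
                traj,
                surface_cutoff=float(cfg.get("surface_cutoff", 10.0)),
                water_boundaries=tuple(boundaries) if boundaries else None,
            )
            pd.DataFrame(
                [{"n_surface": part.n_surface, "n_core": part.n_core, "ratio": part.ratio}]
            ).to_csv(out_dir / "partition.csv", index=False)
            summary["partition_ratio"] = part.ratio
        elif metric == "clusters":
            sys0 = traj.frame_system(traj.n_frames - 1)
            sel = an.atom_selector(
                species=Species.L5, protonation=Protonation.NEUTRAL, name="N"
            )(sys0)
            labels = an.cluster_aggregates(
                sys0.positions[sel],
                sys0.box,
                eps=float(cfg.get("eps", 5.0)),
                min_points=int(cfg.get("min_points", 50)),
            )
            pd.DataFrame(
                {"atom_index": sel, "cluster": labels.labels}
            ).to_csv(out_dir / "clusters.csv", index=False)
            summary["n_clusters"] = labels.n_clusters
        log.info(
            "stage=analyze metric=%s elapsed=%.2fs", metric, time.perf_counter() - t0
        )
    return summary


def run_pipeline(config: dict, out_dir, master_seed: int = 0) -> dict:
    """Execute fixture -> insert -> trajectory -> analyze; return the manifest."""
    validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": _version,
        "master_seed": master_seed,
        "config": config,
        "seeds": {},
        "outputs": [],
    }

    t0 = time.perf_counter()
    if "fixture" in config:
        seed = derive_seed(master_seed, "fixture")
        manifest["seeds"]["fixture"] = seed
        spec = fixture_spec_from_dict(config["fixture"], seed=seed)
        system = generate_bilayer(spec)
        write_structure(system, out_dir / "system.pdb")
        manifest["outputs"].append("system.pdb")
        log.info("stage=fixture seed=%d n_atoms=%d elapsed=%.2fs",
                 seed, system.n_atoms, time.perf_counter() - t0)
    else:
        system = read_structure(config["structure"])
        log.info("stage=load structure=%s n_atoms=%d", config["structure"], system.n_atoms)
    system = assign_leaflets(system)

    if config.get("insertion"):
        ins = config["insertion"]
        seed = derive_seed(master_seed, "insertion")
        manifest["seeds"]["insertion"] = seed
        spec = CompositionSpec(
            total_lipids_per_leaflet=sum(
                1 for m in system.molecules
                if m.species not in (Species.WATER, Species.ION)
            ) // 2,
            l5_fraction=float(ins["l5_fraction"]),
            chol_fraction=float(ins.get("chol_fraction", 0.40)),
            protonated_fraction_of_l5=float(ins.get("protonated_fraction", 0.5)),
            seed=seed,
        )
        template = (
            LipidTemplate.load(ins["template"]) if ins.get("template") else default_l5_template()
        )
        t1 = time.perf_counter()
        system, report = run_insertion(
            system, spec, template, k0=float(ins.get("k0", 1.0)), return_report=True
        )
        write_structure(system, out_dir / "inserted.pdb")
        (out_dir / "insertion_report.json").write_text(json.dumps(report.to_dict(), indent=1))
        manifest["outputs"] += ["inserted.pdb", "insertion_report.json"]
        log.info("stage=insert seed=%d n_replaced=%d elapsed=%.2fs",
                 seed, len(report.selected), time.perf_counter() - t1)

    traj = Trajectory.from_system(system)
    if config.get("trajectory"):
        tr = config["trajectory"]
        seed = derive_seed(master_seed, "trajectory")
        manifest["seeds"]["trajectory"] = seed
        traj = generate_trajectory(
            system,
            n_frames=int(tr.get("n_frames", 1)),
            jitter_sigma=float(tr.get("jitter_sigma", 0.0)),
            seed=seed,
        )
        write_trajectory(traj, out_dir / "traj.pdb")
        manifest["outputs"].append("traj.pdb")
        log.info("stage=trajectory seed=%d n_frames=%d", seed, traj.n_frames)

    if config.get("analysis"):
        acfg = dict(config["analysis"])
        metrics = acfg.pop("metrics", list(KNOWN_METRICS))
        summary = run_analysis(traj, metrics, out_dir, acfg)
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
        manifest["outputs"] += [f"{m}.csv" for m in metrics] + ["summary.json"]

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    manifest["outputs"].append("manifest.json")
    return manifest
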