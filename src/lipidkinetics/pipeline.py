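"""Configuration-driven orchestration of the full analysis chain.

A single YAML config describes either an external topology+trajectory pair
or a synthetic-membrane specification, plus per-stage parameters.  Stages
run in dependency order -- equilibration window, contacts, duration
profiles, k_off, site identification, spatial statistics, interplay, PMF --
and every intermediate table is persisted under the run directory.  One
global seed expands deterministically into per-stage seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .composition import (
    MembraneComposition,
    SystemConfig,
    build_default_composition,
    composition_from_yaml,
)
from .contacts import (
    DEFAULT_LOWER_CUTOFF_NM,
    DEFAULT_SHELL_RADIUS_NM,
    DEFAULT_UPPER_CUTOFF_NM,
    NoPlateauError,
    detect_species_contacts,
    estimate_equilibration,
    first_shell_series,
    residue_duration_profile,
)
from .kinetics import site_koff
from .sites import identify_sites, interplay_matrix
from .spatial import SurfaceRDF, surface_rdf, voronoi_apl
from .synthetic import (
    BindingSiteSpec,
    build_seven_helix_receptor,
    design_site,
    simulate_membrane_trajectory,
)
from .trajectory import Trajectory, load_trajectory, write_trajectory

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "classify_species_by_rdf"]

DEFAULT_RDF_CONTACT_THRESHOLD = 1.5


@dataclass
class PipelineConfig:
    """All stage toggles and parameters for one pipeline run."""

    output_dir: str = "run"
    seed: int = 0
    # input: either explicit files or a synthetic spec
    topology: str | None = None
    trajectory: str | None = None
    composition_file: str | None = None
    synthetic: dict[str, Any] = field(default_factory=dict)
    # stage toggles
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "contacts": True,
            "kinetics": True,
            "sites": True,
            "spatial": True,
            "interplay": False,
            "pmf": False,
        }
    )
    # stage parameters
    lower_cutoff_nm: float = DEFAULT_LOWER_CUTOFF_NM
    upper_cutoff_nm: float = DEFAULT_UPPER_CUTOFF_NM
    shell_radius_nm: float = DEFAULT_SHELL_RADIUS_NM
    equilibration_tolerance: float = 2.0
    species: list[str] = field(default_factory=list)
    pmf: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in doc.items() if k in known})

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class RunReport:
    """Per-stage summaries with provenance; serializable without timestamps."""

    config_hash: str
    seed: int
    version: str
    sections: dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "version": self.version,
                "sections": self.sections,
            },
            indent=2,
            sort_keys=True,
            default=_jsonify,
        )


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def classify_species_by_rdf(
    rdfs: Sequence[SurfaceRDF],
    contact_threshold: float = DEFAULT_RDF_CONTACT_THRESHOLD,
    shell_radius_nm: float = DEFAULT_SHELL_RADIUS_NM,
) -> tuple[list[str], list[str]]:
    """Split species into receptor-proximal and bulk groups.

    Species whose first-shell peak g(r) (r within the first shell) exceeds
    the threshold form group 1 (receptor-enriched); the rest are group 2
    (bulk).
    """
    if not rdfs:
        raise ValueError("no RDFs supplied")
    group1, group2 = [], []
    for rdf in rdfs:
        (group1 if rdf.first_shell_value(shell_radius_nm) > contact_threshold else group2).append(
            rdf.species
        )
    return sorted(group1), sorted(group2)


def _load_inputs(
    cfg: PipelineConfig,
    seed_override: int | None = None,
) -> tuple[Trajectory, MembraneComposition, Any, list[BindingSiteSpec]]:
    if cfg.topology:
        comp = (
            composition_from_yaml(Path(cfg.composition_file))
            if cfg.composition_file
            else build_default_composition()
        )
        traj = load_trajectory(cfg.topology, cfg.trajectory)
        return traj, comp, None, []
    # synthetic input
    spec = dict(cfg.synthetic)
    comp = build_default_composition()
    sys_cfg = SystemConfig(
        box_nm=tuple(spec.get("box_nm", (14.0, 14.0, 10.0))),
        frame_stride_ns=float(spec.get("stride_ns", 2.0)),
        total_time_us=float(spec.get("total_time_us", 1.0)),
        seed=cfg.stage_seed("simulate") if seed_override is None else seed_override,
    )
    receptor = build_seven_helix_receptor()
    sites = []
    for s in spec.get(
        "sites",
        [
            {"helix": "TM1", "leaflet": "lower", "species": "PIP2", "k_on": 50.0, "k_off": 5.0},
            {"helix": "TM4", "leaflet": "upper", "species": "GM3", "k_on": 50.0, "k_off": 8.0},
        ],
    ):
        sites.append(
            design_site(
                receptor,
                s["helix"],
                s["leaflet"],
                s["species"],
                site_id=f"{s['species']}@{s['helix']}",
                k_on_per_us=float(s["k_on"]),
                k_off_true_per_us=float(s["k_off"]),
            )
        )
    traj, ledger = simulate_membrane_trajectory(
        comp, receptor, sites, sys_cfg, n_upper=spec.get("n_upper"), n_lower=spec.get("n_lower")
    )
    return traj, comp, receptor, sites


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute the enabled stages in dependency order.

    Analysis is restricted to the post-equilibration window estimated from
    first-shell occupancy (falling back to the full span when no species
    equilibrates under the tolerance).  Identical config and seed give a
    byte-identical report body.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=cfg.config_hash(), seed=cfg.seed, version=__version__)
    (out / "config.yaml").write_text(cfg.to_yaml())

    traj, comp, receptor, designed_sites = _load_inputs(cfg)
    if cfg.topology is None:
        write_trajectory(traj, out / "system.gro", out / "system.xtc")
    species_list = cfg.species or sorted(
        {s.species for s in designed_sites} or set(traj.lipid_species())
    )

    # --- equilibration window -------------------------------------------
    begin_ns = 0.0
    occ_rows = []
    for sp in species_list:
        occ = first_shell_series(traj, sp, cfg.shell_radius_nm)
        try:
            t_eq = estimate_equilibration(occ, tolerance=cfg.equilibration_tolerance)
        except (NoPlateauError, ValueError):
            t_eq = None
        occ_rows.append({"species": sp, "equilibration_ns": t_eq})
        pd.DataFrame({"t_ns": occ.times_ns, "count": occ.counts}).to_csv(
            out / f"occupancy_{sp}.csv", index=False
        )
        if t_eq is not None:
            begin_ns = max(begin_ns, t_eq)
    end_ns = float(traj.frame_times_ns[-1])
    report.sections["equilibration"] = {
        "per_species": occ_rows,
        "analysis_window_ns": [begin_ns, end_ns],
    }

    profile = None
    if cfg.stages.get("contacts", True):
        all_events = []
        for sp in species_list:
            all_events += detect_species_contacts(
                traj,
                sp,
                lower=cfg.lower_cutoff_nm,
                upper=cfg.upper_cutoff_nm,
                begin_ns=begin_ns,
                end_ns=end_ns,
            )
        pd.DataFrame(
            [
                {
                    "lipid_id": e.lipid_id,
                    "residue_id": e.residue_id,
                    "species": e.species,
                    "t_start_ns": e.t_start_ns,
                    "t_end_ns": e.t_end_ns,
                    "censored": e.censored,
                }
                for e in all_events
            ]
        ).to_csv(out / "contact_events.csv", index=False)
        profile = residue_duration_profile(all_events)
        profile.table.to_csv(out / "duration_profile.csv", index=False)
        report.sections["contacts"] = {
            "n_events": len(all_events),
            "n_censored": int(sum(e.censored for e in all_events)),
        }

    sites_found = []
    if cfg.stages.get("sites", True) and profile is not None and receptor is not None:
        sites_found = identify_sites(profile, receptor)
        site_rows = []
        for s in sites_found:
            row = {
                "site_id": s.site_id,
                "residues": list(s.residues),
                "species": s.species,
                "max_duration_ns": s.max_duration_ns,
                "n_events": s.n_events,
            }
            if cfg.stages.get("kinetics", True):
                try:
                    fit = site_koff(
                        profile, s.residues, species=s.species, min_events=20,
                        seed=cfg.stage_seed("kinetics"),
                    )
                    row["k_off_per_us"] = fit.k_off_per_us
                    s.k_off_per_us = fit.k_off_per_us
                except ValueError:
                    row["k_off_per_us"] = None
            site_rows.append(row)
        (out / "sites.yaml").write_text(yaml.safe_dump(site_rows, sort_keys=False))
        report.sections["sites"] = site_rows

        # pose scoring for the top-ranked site: scores as CSV, the
        # highest-scoring snapshot as a GRO file
        if sites_found:
            from .sites import representative_pose, score_poses
            from .trajectory import slice_frames

            top = sites_found[0]
            try:
                scores = score_poses(
                    traj, top, top.species, basic_residues=list(top.residues)
                )
            except ValueError:
                scores = []
            if scores:
                pd.DataFrame(
                    [
                        {"frame": s.frame, "lipid_id": s.lipid_id,
                         "score": s.score, "rank": s.rank}
                        for s in scores
                    ]
                ).to_csv(out / f"pose_scores_{top.site_id}.csv", index=False)
                best = representative_pose(scores)
                write_trajectory(
                    slice_frames(traj, best), out / f"representative_pose_{top.site_id}.gro"
                )
                report.sections["representative_pose"] = {
                    "site_id": top.site_id, "frame": best,
                }

    if cfg.stages.get("spatial", True):
        rdfs = []
        for sp in species_list:
            rdf = surface_rdf(
                traj, sp, comp, seed=cfg.stage_seed("spatial"),
                begin_ns=begin_ns, end_ns=end_ns,
            )
            rdfs.append(rdf)
            pd.DataFrame({"r_nm": rdf.bin_centers_nm, "g": rdf.g}).to_csv(
                out / f"rdf_{sp}.csv", index=False
            )
        g1, g2 = classify_species_by_rdf(rdfs)
        apl = voronoi_apl(traj, comp, frame=traj.n_frames - 1)
        apl.per_species.to_csv(out / "apl.csv", index=False)
        report.sections["spatial"] = {
            "rdf_group1": g1,
            "rdf_group2": g2,
            "apl": apl.per_species.to_dict("records"),
        }

    if cfg.stages.get("interplay", False) and cfg.topology is None:
        # interplay needs per-repeat mean durations: run independent
        # synthetic repeats (fresh lipid configurations, same kinetics)
        n_repeats = int(cfg.synthetic.get("n_repeats", 3))
        repeat_events = []
        for r in range(n_repeats):
            rep_cfg = dataclasses.replace(cfg)
            rep_cfg.synthetic = dict(cfg.synthetic)
            rep_traj, rep_comp, _, _ = _load_inputs(
                rep_cfg, seed_override=cfg.stage_seed(f"simulate-rep{r}")
            )
            ev = []
            for sp in species_list:
                ev += detect_species_contacts(
                    rep_traj, sp,
                    lower=cfg.lower_cutoff_nm, upper=cfg.upper_cutoff_nm,
                    begin_ns=begin_ns, end_ns=float(rep_traj.frame_times_ns[-1]),
                )
            repeat_events.append(ev)
        rep_profile = residue_duration_profile(repeat_events, repeats=True)
        piv = rep_profile.per_repeat.pivot_table(
            index="species", columns="repeat", values="mean_duration_ns",
            aggfunc="mean",
        )
        mat = interplay_matrix(piv)
        mat.to_csv(out / "interplay.csv")
        report.sections["interplay"] = {
            "n_repeats": n_repeats,
            "pcc": mat.to_dict(),
        }

    if cfg.stages.get("pmf", False):
        from .pmf import bayesian_bootstrap_pmf, estimate_kd, sample_biased_synthetic, wham_1d

        p = dict(cfg.pmf)
        centers = np.arange(
            float(p.get("xi_min_nm", 0.3)),
            float(p.get("xi_min_nm", 0.3))
            + float(p.get("spacing_nm", 0.05)) * int(p.get("n_windows", 50)),
            float(p.get("spacing_nm", 0.05)),
        )
        depth = float(p.get("well_depth_kj_mol", 20.0))
        x0 = float(p.get("well_center_nm", 0.5))
        width = float(p.get("well_width_nm", 0.15))
        true_pmf = lambda x: -depth * np.exp(-((x - x0) ** 2) / (2 * width**2))
        windows = sample_biased_synthetic(
            true_pmf,
            centers,
            force_constant=float(p.get("force_constant", 1000.0)),
            n_per_window=int(p.get("n_per_window", 2000)),
            seed=cfg.stage_seed("pmf"),
        )
        prof = wham_1d(windows)
        sd = bayesian_bootstrap_pmf(
            windows, n_boot=int(p.get("n_boot", 20)), seed=cfg.stage_seed("pmf-boot")
        )
        kd = estimate_kd(prof)
        pd.DataFrame(
            {"xi_nm": prof.xi_nm, "W_kJ_mol": prof.w_kj_mol, "sd_kJ_mol": sd}
        ).to_csv(out / "pmf.csv", index=False)
        report.sections["pmf"] = {
            "depth_kj_mol": float(np.nanmax(prof.w_kj_mol[np.isfinite(prof.w_kj_mol)])),
            "kd_mol_per_l": kd.kd_mol_per_l,
            "convention": kd.convention,
        }

    (out / "report.json").write_text(report.to_json())
    return report
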