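"""End-to-end orchestration: ingest -> cluster -> metrics -> contacts ->
energetics -> reports, from a single flat key-value config.

A pipeline run analyses one receptor(-form) complex: its replicas are
concatenated with the equilibration discard, clustered, summarized
(RMSD/RMSF/PCA), scanned for H-bond and salt-bridge occupancies, and
scored with the MM/PBSA breakdown and per-residue decomposition.  Every
random draw is seeded from the config, and a manifest records the config
hash, seeds, per-stage frame counts and output inventory, so re-running an
identical config reproduces identical report files.

Cross-system comparison (ranking by binding energy, per-residue ddG maps
against a wild-type label, component-total correlations) operates on the
energy reports of several runs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, energetics, geometry, interactions, io_formats
from . import synthetic as synth
from .system import backbone_mask, calpha_mask


class PipelineError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Configuration

_DEFAULTS = {
    "discard_ps": "0",
    "cluster_cutoff": "2.0",
    "seed": "0",
    "hbond_dmax": "3.5",
    "hbond_use_angle": "false",
    "saltbridge_dmax": "4.0",
    "saltbridge_cutoff": "10.0",
    "min_occupancy": "10.0",
    "grid_spacing": "0.5",
    "grid_padding": "10.0",
    "solute_dielectric": "2.0",
    "solvent_dielectric": "80.0",
    "ionic_strength": "0.15",
    "temperature": "310.0",
    "gamma": "0.00542",
    "stride": "1",
    "energy_stride": "1",
    "n_cterm_exclude": "0",
    "include_pb": "true",
    "sasa_points": "240",
    "section": "all",
}


@dataclass
class PipelineConfig:
    """Validated flat key-value configuration of one pipeline run."""

    values: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str, **overrides) -> "PipelineConfig":
        values: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise PipelineError(f"config line {lineno} is not key = value")
            k, v = line.split("=", 1)
            values[k.strip()] = v.strip()
        values.update({k: str(v) for k, v in overrides.items()})
        cfg = cls(values)
        cfg.validate()
        return cfg

    @classmethod
    def from_dict(cls, values: dict) -> "PipelineConfig":
        cfg = cls({k: str(v) for k, v in values.items()})
        cfg.validate()
        return cfg

    # typed accessors -------------------------------------------------

    def get(self, key: str) -> str:
        if key in self.values:
            return self.values[key]
        if key in _DEFAULTS:
            return _DEFAULTS[key]
        raise KeyError(key)

    def get_float(self, key: str) -> float:
        return float(self.get(key))

    def get_int(self, key: str) -> int:
        return int(self.get(key))

    def get_bool(self, key: str) -> bool:
        return self.get(key).lower() in ("1", "true", "yes")

    def has(self, key: str) -> bool:
        return key in self.values

    def is_synthetic(self) -> bool:
        return self.get_bool("synthetic") if self.has("synthetic") else False

    def validate(self) -> None:
        real = any(self.has(k) for k in ("structure", "trajectories"))
        if self.is_synthetic() and real:
            raise PipelineError(
                "config must name either real inputs or a synthetic spec, "
                "not both"
            )
        if not self.is_synthetic() and not real:
            raise PipelineError("config names neither inputs nor a synthetic spec")
        for key, lo, hi in (
            ("cluster_cutoff", 0.0, np.inf),
            ("min_occupancy", 0.0, 100.0),
            ("grid_spacing", 0.0, np.inf),
            ("discard_ps", -1e-9, np.inf),
        ):
            v = self.get_float(key)
            if not lo <= v <= hi:
                raise PipelineError(f"config key {key}={v} out of range")

    def canonical(self) -> str:
        merged = dict(_DEFAULTS)
        merged.update(self.values)
        return "\n".join(f"{k} = {merged[k]}" for k in sorted(merged))

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]

    def grid_spec(self) -> energetics.PBGridSpec:
        return energetics.PBGridSpec(
            spacing=self.get_float("grid_spacing"),
            padding=self.get_float("grid_padding"),
            solute_dielectric=self.get_float("solute_dielectric"),
            solvent_dielectric=self.get_float("solvent_dielectric"),
            ionic_strength=self.get_float("ionic_strength"),
            temperature=self.get_float("temperature"),
        )


# ---------------------------------------------------------------------------
# Input assembly

def _default_contact_plan(spec: synth.SyntheticSpec) -> list[synth.ContactPlan]:
    """Planted ligand-receptor contacts: one nearly persistent (98%, the
    hinge-like anchor) and one moderate (47%, a gatekeeper-like contact)."""
    p1, p2 = synth.pocket_residues(spec)
    plan = [synth.ContactPlan(("LIG", "N1"), (p1, "OD1"), 0.98)]
    if p2 != p1:
        plan.append(synth.ContactPlan(("LIG", "C1"), (p2, "O"), 0.47,
                                      bound_distance=3.0))
    return plan


def _build_synthetic(cfg: PipelineConfig):
    plan = None
    if cfg.has("synthetic_charge_plan"):
        plan = [int(x) for x in cfg.get("synthetic_charge_plan").split(",")]
    n_res = cfg.get_int("synthetic_n_residues") \
        if cfg.has("synthetic_n_residues") else 12
    if plan is None:
        plan = synth.variant_charge_plans(n_res)["wildtype"]
    spec = synth.SyntheticSpec(
        n_residues=n_res,
        charge_plan=plan,
        fluctuation_amplitudes=cfg.get_float("synthetic_amplitude")
        if cfg.has("synthetic_amplitude") else 0.5,
        replica_count=cfg.get_int("synthetic_replica_count")
        if cfg.has("synthetic_replica_count") else 2,
        frames_per_replica=cfg.get_int("synthetic_frames_per_replica")
        if cfg.has("synthetic_frames_per_replica") else 5000,
        frame_spacing=cfg.get_float("synthetic_frame_spacing")
        if cfg.has("synthetic_frame_spacing") else 10.0,
        seed=cfg.get_int("seed"),
    )
    spec.contact_plan = _default_contact_plan(spec)
    system = synth.make_toy_complex(spec)
    traj, _truth = synth.simulate_trajectory(system, spec, cfg.get("section"))
    # hand the replicas to the concatenation stage individually so the
    # equilibration discard applies to the head of each replica
    replica_trajs = [
        synth.Trajectory(traj.coords[traj.replica_ids == r],
                         frame_spacing=traj.frame_spacing)
        for r in traj.replicas()
    ]
    contacts = [
        interactions.ContactDefinition(
            kind="hbond",
            donor_atoms=(d,),
            acceptor_atoms=(a,),
            label=f"{system.names[d]}-({system.names[a]})"
            f"{system.res_names[a]}{system.res_ids[a]}",
        )
        for (d, a) in (synth.resolve_contact_atoms(system, c)
                       for c in spec.contact_plan)
    ]
    labels = [cfg.get("section")] * len(replica_trajs)
    return system, replica_trajs, labels, contacts


def _load_real(cfg: PipelineConfig):
    system = io_formats.read_pdb(cfg.get("structure"))
    if cfg.has("parameter_table"):
        table = io_formats.read_parameter_table(cfg.get("parameter_table"))
        system = io_formats.apply_parameters(system, table)
    paths = [p.strip() for p in cfg.get("trajectories").split(",")]
    labels = (
        [s.strip() for s in cfg.get("sections").split(",")]
        if cfg.has("sections") else [cfg.get("section")] * len(paths)
    )
    trajs = [
        io_formats.read_multimodel_trajectory(p, system)
        for p in paths
    ]
    contacts = []  # real-input contact lists come from the CLI layer
    return system, trajs, labels, contacts


# ---------------------------------------------------------------------------
# Manifest

@dataclass
class RunManifest:
    config_hash: str
    seeds: dict
    frame_counts: dict
    outputs: list[str]

    def to_text(self) -> str:
        lines = [f"config_hash: {self.config_hash}"]
        for k in sorted(self.seeds):
            lines.append(f"seed.{k}: {self.seeds[k]}")
        for k in sorted(self.frame_counts):
            lines.append(f"frames.{k}: {self.frame_counts[k]}")
        for p in sorted(self.outputs):
            lines.append(f"output: {p}")
        return "\n".join(lines) + "\n"


def _write_tsv(df: pd.DataFrame, path: Path, outputs: list[str]) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    outputs.append(path.name)


# ---------------------------------------------------------------------------
# The pipeline

def run_pipeline(cfg: PipelineConfig, out_dir: str) -> RunManifest:
    """Execute all analysis stages; write TSV/CSV reports and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    frame_counts: dict[str, int] = {}
    seed = cfg.get_int("seed")

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return _Ctx()

    with stage("ingest"):
        if cfg.is_synthetic():
            system, trajs, labels, contacts = _build_synthetic(cfg)
        else:
            system, trajs, labels, contacts = _load_real(cfg)
        frame_counts["input"] = sum(t.n_frames for t in trajs)

    with stage("concatenate"):
        traj = io_formats.concatenate_replicas(
            trajs, labels, discard_ps=cfg.get_float("discard_ps")
        )
        frame_counts["analysis"] = traj.n_frames

    with stage("cluster"):
        ca_mask = calpha_mask(system)
        assignment = clustering.fast_reference_clustering(
            traj, ca_mask, cutoff=cfg.get_float("cluster_cutoff"), seed=seed
        )
        representation = clustering.section_representation(assignment, traj)
        rows = []
        for ri, ref in enumerate(assignment.reference_frames):
            row = {
                "reference_frame": int(ref),
                "cluster_size": int((assignment.membership == ri).sum()),
            }
            for si, s in enumerate(representation.sections):
                row[f"section_{s}"] = int(representation.counts[ri, si])
            rows.append(row)
        _write_tsv(pd.DataFrame(rows), out / "cluster_report.tsv", outputs)
        for s in representation.sections:
            rep_frame = clustering.select_representative(
                assignment, representation, s
            )
            rep_system = system.with_coords(traj.coords[rep_frame])
            io_formats.write_pdb(rep_system, str(out / f"representative_{s}.pdb"))
            outputs.append(f"representative_{s}.pdb")

    with stage("metrics"):
        bb = backbone_mask(system)
        n_cterm = cfg.get_int("n_cterm_exclude")
        rmsd_mask = geometry.exclude_terminal_residues(bb, system, n_cterm)
        rmsd = geometry.rmsd_series(traj, traj.coords[0], fit_mask=rmsd_mask)
        _write_tsv(
            pd.DataFrame({"frame_index": np.arange(traj.n_frames),
                          "rmsd_A": rmsd}),
            out / "rmsd.tsv", outputs,
        )
        prof = geometry.rmsf_per_residue(traj, system, bb)
        _write_tsv(
            pd.DataFrame({
                "residue_id": [f"{c}:{r}:{n}" for c, r, n in prof.residues],
                "rmsf_A": prof.values,
            }),
            out / "rmsf.tsv", outputs,
        )
        evals, _ = geometry.pca_covariance(traj, bb)
        _write_tsv(
            pd.DataFrame({"mode": np.arange(1, len(evals) + 1),
                          "eigenvalue_A2": evals}),
            out / "pca_eigenvalues.tsv", outputs,
        )

    with stage("hbonds"):
        if contacts:
            crit = interactions.HBondCriteria(
                d_max=cfg.get_float("hbond_dmax"),
                use_angle=cfg.get_bool("hbond_use_angle"),
            )
            table = interactions.hbond_occupancy(traj, contacts, crit)
            _write_tsv(table.to_dataframe(), out / "hbonds.tsv", outputs)

    with stage("saltbridges"):
        pairs = interactions.ligand_proximal_residue_pairs(
            system, traj.coords[0], cutoff=cfg.get_float("saltbridge_cutoff")
        )
        if pairs:
            table = interactions.salt_bridge_occupancy(
                traj, pairs,
                interactions.SaltBridgeCriteria(cfg.get_float("saltbridge_dmax")),
                min_occupancy_pct=cfg.get_float("min_occupancy"),
            )
            _write_tsv(table.to_dataframe(), out / "saltbridges.tsv", outputs)

    with stage("energy"):
        grid = cfg.grid_spec()
        nonpolar = energetics.NonpolarParams(gamma=cfg.get_float("gamma"))
        stride = cfg.get_int("energy_stride")
        include_pb = cfg.get_bool("include_pb")
        sasa_points = cfg.get_int("sasa_points")
        report = energetics.binding_energy_trajectory(
            traj, system, grid, nonpolar, stride=stride,
            include_pb=include_pb, sasa_points=sasa_points,
        )
        frame_counts["energy"] = len(report.per_frame)
        rows = [report.to_series().rename("merged")]
        for rep, b in energetics.replica_breakdowns(report).items():
            rows.append(b.to_series().rename(f"replica{rep}"))
        energy_df = pd.DataFrame(rows)
        energy_df.insert(0, "scope", energy_df.index)
        _write_tsv(energy_df, out / "energy.tsv", outputs)

        decomp = energetics.per_residue_decomposition(
            traj, system, grid, nonpolar, stride=stride,
            include_pb=include_pb, sasa_points=sasa_points,
        )
        decomp.to_dataframe().to_csv(
            out / "residue_decomposition.csv", index=False,
            float_format="%.6g",
        )
        outputs.append("residue_decomposition.csv")

    manifest = RunManifest(
        config_hash=cfg.config_hash(),
        seeds={"pipeline": seed, "cluster": seed},
        frame_counts=frame_counts,
        outputs=outputs,
    )
    (out / "manifest.txt").write_text(manifest.to_text())
    return manifest


# ---------------------------------------------------------------------------
# Cross-system comparison

@dataclass
class EnergyReport:
    """One system's binding-energy outcome used for comparison."""

    label: str
    breakdown: energetics.EnergyBreakdown
    decomposition: energetics.ResidueDecomposition | None = None


@dataclass
class SystemComparison:
    ranking: pd.DataFrame
    ddg_maps: dict
    correlations: dict


def compare_systems(
    reports: dict[str, EnergyReport], wt_label: str
) -> SystemComparison:
    """Rank systems by binding energy and map per-residue differences.

    The ranking is by G_bind ascending (most negative = strongest
    predicted binder first).  ddG maps are mutant-minus-wild-type per
    residue; correlations are component-vs-total Pearson r across the
    systems (NaN when fewer than 3 systems).
    """
    if wt_label not in reports:
        raise KeyError(f"wild-type label {wt_label!r} missing from reports")
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to compare")
    rows = []
    for label, rep in reports.items():
        s = rep.breakdown.to_series()
        s["label"] = label
        rows.append(s)
    ranking = pd.DataFrame(rows).set_index("label")
    ranking = ranking.sort_values("dG_bind")
    ranking["rank"] = np.arange(1, len(ranking) + 1)

    wt = reports[wt_label]
    ddg_maps = {}
    for label, rep in reports.items():
        if label == wt_label or rep.decomposition is None \
                or wt.decomposition is None:
            continue
        ddg_maps[label] = energetics.delta_delta_map(
            rep.decomposition, wt.decomposition
        )

    correlations = {}
    breakdowns = [r.breakdown for r in reports.values()]
    for comp in ("e_vdw", "e_elect", "g_polar", "g_nonpolar", "g_sol"):
        try:
            correlations[comp] = energetics.component_total_correlation(
                breakdowns, comp
            )
        except ValueError:
            correlations[comp] = float("nan")
    return SystemComparison(ranking, ddg_maps, correlations)
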