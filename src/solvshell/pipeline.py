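"""End-to-end orchestration: config validation, staged analysis, manifest.

The pipeline reproduces the full analysis sequence on a trajectory
(synthetic or read from disk): interaction energies, two-domain Gamma,
RDF -> long-range fit -> Kirkwood-Buff contact coefficient, mode
classification and spatial density, residence dynamics, and the toy
thermodynamic-integration run. Outputs are TSV (plus Gaussian cube for
densities) under one output directory, tied together by a JSON
manifest with per-file checksums, so a run is a pure function of
(inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import time as _time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dynamics, energetics, modes, solvation, synth, ti
from .errors import ConfigError, FeatureNotFoundError, FitFailureError, SolvshellError
from .io import read_trajectory, write_topology, write_trajectory

ALL_STAGES = ("synth", "energy", "gamma", "rdf", "kb", "modes", "density", "dwell", "ti")


@dataclass
class AnalysisConfig:
    # inputs: either paths or a synthetic box spec
    trajectory: str | None = None
    topology: str | None = None
    stages: tuple = ALL_STAGES
    output_dir: str = "solvshell_out"
    seed: int = 0
    # synthetic box
    box: float = 32.0
    n_urea: int = 40
    n_water: int = 300
    enrichment: float = 1.0
    shell_radius: float = 10.0
    n_frames: int = 20
    # analysis parameters
    local_cutoff: float = 4.5
    stacking_theta1: float = 40.0
    stacking_theta2_lo: float = 70.0
    stacking_theta2_hi: float = 110.0
    nh_pi_theta4: float = 150.0
    nh_pi_theta4_lo: float = 30.0
    nh_pi_theta3: float = 150.0
    hbond_distance: float = 3.5
    hbond_angle: float = 150.0
    t_star_distribution: float = 500.0   # ps
    t_star_lifetime: float = 100.0       # ps
    discard_fraction: float = 0.2
    rdf_bin_width: float = 0.1
    ti_n_per_leg: int = 100
    modes_list: tuple = ("stacking", "nh_pi", "hbond")


def validate_config(raw: dict | AnalysisConfig) -> AnalysisConfig:
    """Normalize a raw mapping into an AnalysisConfig or raise ConfigError.

    Unknown keys, unknown analysis names, non-positive thresholds and
    missing input files are all collected into one error list.
    """
    if isinstance(raw, AnalysisConfig):
        raw = asdict(raw)
    problems = []
    known = set(AnalysisConfig.__dataclass_fields__)
    for key in raw:
        if key not in known:
            problems.append(f"unknown config key {key!r}")
    cfg = AnalysisConfig(**{k: v for k, v in raw.items() if k in known})
    cfg.stages = tuple(cfg.stages)
    cfg.modes_list = tuple(cfg.modes_list)
    for stage in cfg.stages:
        if stage not in ALL_STAGES:
            problems.append(
                f"unknown analysis {stage!r}; valid names: {', '.join(ALL_STAGES)}"
            )
    for name in (
        "local_cutoff", "stacking_theta1", "hbond_distance", "hbond_angle",
        "rdf_bin_width", "box", "shell_radius",
    ):
        if getattr(cfg, name) <= 0:
            problems.append(f"{name} must be positive, got {getattr(cfg, name)}")
    if not 0 <= cfg.discard_fraction < 1:
        problems.append(f"discard_fraction must be in [0, 1), got {cfg.discard_fraction}")
    if cfg.trajectory is not None and cfg.topology is None:
        problems.append("trajectory given without topology")
    for attr in ("trajectory", "topology"):
        p = getattr(cfg, attr)
        if p is not None and not Path(p).exists():
            problems.append(f"{attr} file not found: {p}")
    if cfg.ti_n_per_leg < 1:
        problems.append("ti_n_per_leg must be >= 1")
    if problems:
        raise ConfigError(problems)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


class _Run:
    def __init__(self, cfg: AnalysisConfig):
        self.cfg = cfg
        self.outdir = Path(cfg.output_dir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest = {
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(cfg).items()},
            "stages": {},
            "outputs": {},
            "warnings": [],
        }
        self.trajectory = None
        self.bookkeeping = None
        self.profiles = {}

    def register(self, path: Path):
        self.manifest["outputs"][path.name] = _sha256(path)

    # -- stages --------------------------------------------------------
    def stage_synth(self):
        spec = synth.MixtureSpec(
            box=self.cfg.box, n_urea=self.cfg.n_urea, n_water=self.cfg.n_water,
            enrichment=self.cfg.enrichment, shell_radius=self.cfg.shell_radius,
            seed=self.cfg.seed,
        )
        self.trajectory, self.bookkeeping = synth.build_solvent_box(
            spec, n_frames=self.cfg.n_frames
        )
        tpath = self.outdir / "trajectory.xyz"
        write_trajectory(self.trajectory, tpath)
        ppath = self.outdir / "topology.tsv"
        write_topology(self.trajectory.topology, ppath)
        self.register(tpath)
        self.register(ppath)
        return {"n_frames": len(self.trajectory), "n_atoms": self.trajectory.topology.n_atoms}

    def _require_trajectory(self):
        if self.trajectory is None:
            self.trajectory = read_trajectory(self.cfg.trajectory, self.cfg.topology)
        return self.trajectory

    def stage_energy(self):
        traj = self._require_trajectory()
        br = energetics.solute_solvent_energy(traj, self.cfg.discard_fraction)
        path = self.outdir / "energy.tsv"
        _write_tsv(
            pd.DataFrame(
                {"frame": np.arange(br.total.size), "total": br.total,
                 "electrostatic": br.electrostatic, "lennard_jones": br.lennard_jones}
            ),
            path,
            f"mean_total={br.mean_total:.6f} stderr={br.stderr_total:.6f}\n"
            f"mean_elec={br.mean_electrostatic:.6f} mean_lj={br.mean_lennard_jones:.6f}",
        )
        self.register(path)
        return {"mean_total": br.mean_total, "stderr": br.stderr_total}

    def stage_gamma(self):
        traj = self._require_trajectory()
        counts = solvation.two_domain_counts(traj, self.cfg.local_cutoff)
        res = solvation.preferential_interaction_coefficient(counts)
        path = self.outdir / "gamma.tsv"
        _write_tsv(
            pd.DataFrame(
                {"frame": np.arange(counts.n_frames),
                 "n_urea_local": counts.n_urea_local,
                 "n_water_local": counts.n_water_local,
                 "n_urea_bulk": counts.n_urea_bulk,
                 "n_water_bulk": counts.n_water_bulk,
                 "gamma": res.per_frame}
            ),
            path,
            f"cutoff={self.cfg.local_cutoff} gamma={res.gamma:.6f} stderr={res.stderr:.6f}",
        )
        self.register(path)
        return {"gamma": res.gamma, "stderr": res.stderr}

    def _rdf_with_fit(self, role: str):
        traj = self._require_trajectory()
        prof = solvation.compute_rdf(traj, role, self.cfg.rdf_bin_width)
        sm = solvation.smooth_rdf(prof)
        stitched = None
        fit_info = {}
        try:
            fit = solvation.fit_long_range(sm)
            stitched = fit.stitched()
            fit_info = {k: getattr(fit, k) for k in "abcde"}
        except (FeatureNotFoundError, FitFailureError) as exc:
            self.manifest["warnings"].append(f"rdf {role}: {exc}")
        self.profiles[role] = (prof, sm, stitched)
        return prof, sm, stitched, fit_info

    def stage_rdf(self):
        info = {}
        for role in ("urea_C", "water_O"):
            prof, sm, stitched, fit_info = self._rdf_with_fit(role)
            path = self.outdir / f"rdf_{role}.tsv"
            _write_tsv(
                pd.DataFrame(
                    {"r": prof.r, "g_direct": prof.g, "g_smoothed": sm.g,
                     "g_stitched": stitched.g if stitched is not None else sm.g}
                ),
                path,
                f"target={role} bin_width={prof.bin_width} rho={prof.rho:.8f}",
            )
            self.register(path)
            info[role] = fit_info
        return info

    def stage_kb(self):
        traj = self._require_trajectory()
        out = {}
        rows = []
        R = float(traj[0].box.min() / 2) - self.cfg.rdf_bin_width
        for role in ("urea_C", "water_O"):
            if role not in self.profiles:
                self._rdf_with_fit(role)
            prof, sm, stitched = self.profiles[role]
            use = stitched if stitched is not None else sm
            res = solvation.kb_integral(use, R)
            out[role] = res.G
            rows.append({"target": role, "G": res.G, "R": res.R})
        rho_u = self.profiles["urea_C"][0].rho
        gamma_kb = solvation.contact_coefficient(out["urea_C"], out["water_O"], rho_u)
        path = self.outdir / "kb.tsv"
        _write_tsv(
            pd.DataFrame(rows), path,
            f"contact_coefficient={gamma_kb:.6f} rho_urea={rho_u:.8f}",
        )
        self.register(path)
        return {"G_urea": out["urea_C"], "G_water": out["water_O"],
                "contact_coefficient": gamma_kb}

    def stage_modes(self):
        traj = self._require_trajectory()
        rows = []
        for j, frame in enumerate(traj):
            for mid in traj.topology.molecule_ids_of_kind("urea"):
                g = modes.measure_geometry(frame, traj.topology, mid, j)
                rows.append(
                    {
                        "frame": j, "molecule": mid,
                        "d_com": g.d_com, "d_comN": g.d_comN,
                        "theta1": g.theta1, "theta2": g.theta2,
                        "theta3": g.theta3, "theta4": g.theta4,
                        "stacking": modes.classify_stacking(g),
                        "nh_pi": modes.classify_nh_pi(g),
                        "hbond": modes.classify_hbond(frame, traj.topology, mid),
                    }
                )
        df = pd.DataFrame(rows)
        path = self.outdir / "mode_events.tsv"
        _write_tsv(df, path, "per-frame geometric classification of urea molecules")
        self.register(path)
        # 2D (distance, angle) probability histograms per angular mode
        geoms = [
            modes.InteractionGeometry(
                r.d_com, r.d_comN, r.theta1, r.theta2, r.theta3, r.theta4
            )
            for r in df.itertuples(index=False)
        ]
        for mode in ("stacking", "nh_pi"):
            hist, d_edges, a_edges = modes.mode_distribution(geoms, mode)
            hpath = self.outdir / f"mode_hist_{mode}.tsv"
            hdf = pd.DataFrame(
                hist,
                index=np.round(0.5 * (d_edges[:-1] + d_edges[1:]), 3),
                columns=np.round(0.5 * (a_edges[:-1] + a_edges[1:]), 1),
            )
            with open(hpath, "w") as fh:
                fh.write(f"# {mode}: rows = distance bin centers (A), "
                         f"columns = angle bin centers (deg)\n")
                hdf.to_csv(fh, sep="\t")
            self.register(hpath)
        return {
            m: int(df[m].sum()) for m in ("stacking", "nh_pi", "hbond")
        }

    def stage_density(self):
        traj = self._require_trajectory()
        info = {}
        for kind in ("C", "N", "O"):
            grid = modes.spatial_density(traj, kind)
            path = self.outdir / f"density_{kind}.cube"
            modes.write_cube(grid, path, traj[0], traj.topology)
            self.register(path)
            info[kind] = int(grid.counts.sum())
        return info

    def stage_dwell(self):
        traj = self._require_trajectory()
        info = {}
        for mode in self.cfg.modes_list:
            series = dynamics.contact_series(traj, mode)
            dwells = dynamics.dwell_events(series, self.cfg.t_star_lifetime)
            if dwells.n_dwell == 0:
                info[mode] = None
                continue
            surv = dynamics.survival_probability(dwells)
            life = dynamics.mean_lifetime(surv)
            path = self.outdir / f"dwell_{mode}.tsv"
            _write_tsv(
                pd.DataFrame({"time": surv.time, "survival": surv.S}),
                path,
                f"mode={mode} t_star={self.cfg.t_star_lifetime} "
                f"mean_lifetime={life:.4f} n_dwell={dwells.n_dwell}",
            )
            self.register(path)
            info[mode] = {"mean_lifetime": life, "n_dwell": dwells.n_dwell}
        return info

    def stage_ti(self):
        system = ti.HarmonicLambdaSystem(1.0, 4.0)
        fwd = ti.ti_harmonic(system, kT=1.0, n_lambda=self.cfg.ti_n_per_leg,
                             seed=self.cfg.seed)
        bwd = ti.ti_harmonic(system, kT=1.0, n_lambda=self.cfg.ti_n_per_leg,
                             seed=self.cfg.seed + 1, direction="backward")
        h, converged = ti.hysteresis(fwd, bwd)
        path = self.outdir / "ti.tsv"
        _write_tsv(
            pd.DataFrame(
                {"direction": ["forward", "backward"],
                 "delta_g": [fwd.delta_g, bwd.delta_g],
                 "stderr": [fwd.stderr, bwd.stderr]}
            ),
            path,
            f"toy harmonic lambda-scaling; analytic={system.analytic_delta_g(1.0):.6f} "
            f"hysteresis={h:.6f} converged={converged}",
        )
        self.register(path)
        return {"delta_g_forward": fwd.delta_g, "delta_g_backward": bwd.delta_g,
                "hysteresis": h, "converged": bool(converged)}


def run_pipeline(config: dict | AnalysisConfig) -> dict:
    """Execute the requested stages in dependency order; return the manifest.

    Any stage error aborts the run with the stage name; outputs written
    so far stay on disk and are listed in the partial manifest.
    """
    cfg = validate_config(config)
    run = _Run(cfg)
    order = [s for s in ALL_STAGES if s in cfg.stages]
    if cfg.trajectory is not None and "synth" in order:
        order.remove("synth")  # inputs come from disk
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for stage in order:
            t0 = _time.perf_counter()
            try:
                result = getattr(run, f"stage_{stage}")()
            except SolvshellError as exc:
                run.manifest["stages"][stage] = {"error": str(exc)}
                _dump_manifest(run)
                raise SolvshellError(f"stage {stage!r} failed: {exc}") from exc
            run.manifest["stages"][stage] = {
                "result": result,
                "seconds": round(_time.perf_counter() - t0, 3),
            }
        run.manifest["warnings"].extend(str(w.message) for w in caught)
    _dump_manifest(run)
    return run.manifest


def _dump_manifest(run: _Run) -> None:
    path = run.outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(run.manifest, fh, indent=2, default=str)
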