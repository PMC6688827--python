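"""Config-driven orchestration over replicate ensembles.

A :class:`RunConfig` (typically loaded from YAML) names either a synthetic
ensemble specification or a manifest of structure + trajectory files, the
selections/cutoffs/bins to use, and which analysis stages to run.
:func:`run_pipeline` executes the enabled stages in dependency order and
returns a :class:`ReportBundle` whose ``write`` method emits deterministic
CSV/JSON (and optionally PNG) outputs with a provenance block.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binding import (
    CG_CONTACT_CUTOFF,
    DistanceSeries,
    com_distance_series,
    ensemble_mean,
    fit_binding_curve,
    residue_contact_profile,
)
from .core import (
    DEFAULT_RESIDUE_MAP,
    ResidueMap,
    Trajectory,
    load_structure,
    load_trajectory,
)
from .dimer import hinge_angle_series, rmsf, subunit_distance_series
from .landscape import (
    DLKGS_RESIDUES,
    distance_orientation_map,
    find_modes,
    orientation_series,
    pick_reference,
)
from .synthetic import (
    BilayerSpec,
    BindingMode,
    EncounterParams,
    build_bilayer,
    build_protein_model,
    simulate_encounter,
)

logger = logging.getLogger("membind")

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "PRESETS"]

ALL_STAGES = ("bind", "contacts", "landscape", "dimer", "rmsf")

#: Named synthetic presets.  ``monomer-cg`` reproduces the coarse-grained
#: monomer encounter conditions: a 7.5 x 7.5 nm bilayer patch of 75/20/5
#: PC/PS/PI4P, kinase COM starting 8 nm from the bilayer COM, 2 us of
#: frames every 0.5 ns.
PRESETS: dict[str, dict[str, Any]] = {
    "monomer-cg": {
        "bilayer": {"grid_nx": 10, "grid_ny": 10, "spacing": 0.75},
        "encounter": {},
        "replicates": 5,
    },
    "demo": {
        "bilayer": {},
        "encounter": {"n_frames": 400, "dt": 0.5, "tau": 20.0},
        "replicates": 3,
    },
}


class ConfigError(ValueError):
    """The run configuration is invalid."""


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    synthetic: dict | None = None          # {"preset": ..} or {"bilayer": .., "encounter": .., "replicates": n}
    manifest: list[dict] = field(default_factory=list)  # [{"structure": .., "trajectory": ..}]
    stages: tuple[str, ...] = ALL_STAGES
    protein_sel: str = "species protein"
    membrane_sel: str = "not species protein"
    lipid_target_sel: str = "species PI4P and headgroup"
    contact_cutoff: float = CG_CONTACT_CUTOFF
    contact_mode: str = "min_particle"
    distance_metric: str = "z_component"
    catalytic_residues: tuple[int, ...] = DLKGS_RESIDUES
    n_bins: int = 50
    seed: int = 0
    output_dir: str = "membind_out"
    plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: tuple(v) if isinstance(v, list) and k in
                     ("stages", "catalytic_residues") else v
                     for k, v in raw.items()})
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for s in self.stages:
            if s not in ALL_STAGES:
                raise ConfigError(f"unknown stage {s!r}; valid: {ALL_STAGES}")
        if self.synthetic is None and not self.manifest:
            raise ConfigError("config needs either a synthetic spec or a "
                              "file manifest")
        for entry in self.manifest:
            for key in ("structure", "trajectory"):
                p = entry.get(key)
                if p is None or not Path(p).exists():
                    raise ConfigError(f"manifest path missing: {key}={p!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """Results of a pipeline run, writable as deterministic text files."""

    config: RunConfig
    provenance: dict
    distance_series: list[DistanceSeries] = field(default_factory=list)
    mean_series: DistanceSeries | None = None
    binding_fit: dict | None = None
    contact_profile: pd.DataFrame | None = None
    density_map: pd.DataFrame | None = None
    modes: list[dict] = field(default_factory=list)
    hinge: pd.DataFrame | None = None
    subunit_distances: pd.DataFrame | None = None
    rmsf_profile: pd.DataFrame | None = None
    partial: bool = False
    errors: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path | None = None) -> Path:
        out = Path(out_dir or self.config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = "%.8g"
        (out / "provenance.json").write_text(
            json.dumps(self.provenance, indent=1, sort_keys=True, default=str))
        if self.distance_series:
            df = pd.DataFrame({"time_ns": self.distance_series[0].times})
            for i, s in enumerate(self.distance_series):
                df[f"replicate_{i}"] = s.values
            if self.mean_series is not None:
                df["mean"] = self.mean_series.values
            df.to_csv(out / "distance_series.csv", index=False,
                      float_format=fmt)
        if self.binding_fit is not None:
            (out / "binding_fit.json").write_text(
                json.dumps(self.binding_fit, indent=1, sort_keys=True))
        if self.contact_profile is not None:
            self.contact_profile.to_csv(out / "contact_profile.csv",
                                        index=False, float_format=fmt)
        if self.density_map is not None:
            self.density_map.to_csv(out / "density_map.csv", index=False,
                                    float_format=fmt)
            if self.config.plots:
                self._plot_map(out / "density_map.png")
        if self.modes:
            (out / "modes.json").write_text(
                json.dumps(self.modes, indent=1, sort_keys=True))
        if self.hinge is not None:
            self.hinge.to_csv(out / "hinge_angle.csv", index=False,
                              float_format=fmt)
        if self.subunit_distances is not None:
            self.subunit_distances.to_csv(out / "subunit_distances.csv",
                                          index=False, float_format=fmt)
        if self.rmsf_profile is not None:
            self.rmsf_profile.to_csv(out / "rmsf.csv", index=False,
                                     float_format=fmt)
        if self.errors:
            (out / "errors.json").write_text(
                json.dumps(self.errors, indent=1, sort_keys=True))
        return out

    def _plot_map(self, path: Path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        piv = self.density_map.pivot(index="d_bin", columns="rzz_bin",
                                     values="probability")
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.imshow(piv.values, origin="lower", aspect="auto", cmap="viridis")
        ax.set_xlabel("Rzz bin")
        ax.set_ylabel("distance bin")
        fig.savefig(path, dpi=100)
        plt.close(fig)


def _synthetic_ensemble(cfg: RunConfig) -> tuple[list[Trajectory], list]:
    spec = dict(cfg.synthetic or {})
    preset = spec.pop("preset", None)
    if preset is not None:
        if preset not in PRESETS:
            raise ConfigError(f"unknown preset {preset!r}; "
                              f"available: {sorted(PRESETS)}")
        base = {k: (dict(v) if isinstance(v, dict) else v)
                for k, v in PRESETS[preset].items()}
        for k, v in spec.items():
            if isinstance(v, dict) and isinstance(base.get(k), dict):
                base[k].update(v)
            else:
                base[k] = v
        spec = base
    bilayer_kwargs = spec.get("bilayer", {})
    enc_kwargs = dict(spec.get("encounter", {}))
    n_rep = int(spec.get("replicates", 1))
    protein_kwargs = spec.get("protein", {})
    if "modes" in enc_kwargs:
        enc_kwargs["modes"] = tuple(
            BindingMode(**m) for m in enc_kwargs["modes"])
    bilayer = build_bilayer(BilayerSpec(**bilayer_kwargs), seed=cfg.seed)
    protein = build_protein_model(seed=cfg.seed, **protein_kwargs)
    trajs, truths = [], []
    for rep in range(n_rep):
        params = EncounterParams(**{**enc_kwargs,
                                    "seed": cfg.seed * 10007 + rep})
        traj, truth = simulate_encounter(protein, bilayer, params)
        trajs.append(traj)
        truths.append(truth)
    return trajs, truths


def _load_ensemble(cfg: RunConfig) -> list[Trajectory]:
    trajs = []
    for entry in cfg.manifest:
        topology, _ = load_structure(entry["structure"])
        trajs.append(load_trajectory(entry["trajectory"], topology,
                                     dt=entry.get("dt")))
    return trajs


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the enabled analysis stages over the configured ensemble.

    Stage failures mark the bundle partial and skip dependent stages rather
    than aborting the run.
    """
    config.validate()
    t_start = time.time()
    provenance = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "membind_version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
    }
    bundle = ReportBundle(config=config, provenance=provenance)

    truths = None
    if config.synthetic is not None:
        trajs, truths = _synthetic_ensemble(config)
    else:
        trajs = _load_ensemble(config)
    logger.info("loaded %d trajectories (%.1f s)", len(trajs),
                time.time() - t_start)

    def stage(name):
        def deco(fn):
            if name in config.stages:
                t0 = time.time()
                try:
                    fn()
                    logger.info("stage %-10s done in %.1f s", name,
                                time.time() - t0)
                except Exception as exc:
                    logger.error("stage %s failed: %s", name, exc)
                    bundle.errors[name] = str(exc)
                    bundle.partial = True
            return fn
        return deco

    series: list[DistanceSeries] = []

    @stage("bind")
    def _bind():
        for traj in trajs:
            series.append(com_distance_series(
                traj, config.protein_sel, config.membrane_sel,
                metric=config.distance_metric))
        bundle.distance_series = series
        bundle.mean_series = ensemble_mean(series)
        fit = fit_binding_curve(bundle.mean_series)
        bundle.binding_fit = {
            "d0_nm": fit.d0, "d_inf_nm": fit.d_inf, "tau_ns": fit.tau,
            "residual_rms_nm": fit.residual_rms, "converged": fit.converged,
        }

    @stage("contacts")
    def _contacts():
        profiles = [residue_contact_profile(
            traj, lipid_target_sel=config.lipid_target_sel,
            cutoff=config.contact_cutoff, mode=config.contact_mode)
            for traj in trajs]
        raw = np.sum([p.raw for p in profiles], axis=0)
        peak = raw.max(initial=0)
        rmap = DEFAULT_RESIDUE_MAP
        pdb = []
        for r in profiles[0].residues:
            try:
                pdb.append(rmap.to_pdb(int(r)))
            except IndexError:
                pdb.append(-1)
        bundle.contact_profile = pd.DataFrame({
            "residue": profiles[0].residues,
            "pdb_residue": pdb,
            "raw": raw,
            "normalized": raw / peak if peak else np.zeros_like(raw, float),
        })

    @stage("landscape")
    def _landscape():
        ref, ref_prov = pick_reference(
            trajs, catalytic_residues=config.catalytic_residues,
            lipid_target_sel=config.lipid_target_sel,
            cutoff=config.contact_cutoff, protein_sel=config.protein_sel)
        pairs = []
        for i, traj in enumerate(trajs):
            # landscape distance axis is always the |z| COM separation
            if config.distance_metric == "z_component" and i < len(series):
                d = series[i]
            else:
                d = com_distance_series(
                    traj, config.protein_sel, config.membrane_sel,
                    metric="z_component")
            o = orientation_series(traj, config.protein_sel, ref)
            pairs.append((d, o))
        dmap = distance_orientation_map(pairs, n_bins_d=config.n_bins,
                                        n_bins_r=config.n_bins)
        d_c, r_c = dmap.d_centers, dmap.rzz_centers
        rows = [(d_c[i], r_c[j], dmap.probabilities[i, j])
                for i in range(len(d_c)) for j in range(len(r_c))]
        bundle.density_map = pd.DataFrame(
            rows, columns=["d_bin", "rzz_bin", "probability"])
        bundle.provenance["reference"] = ref_prov
        bundle.modes = [
            {"label": m.label, "peak_distance_nm": m.peak_distance,
             "peak_rzz": m.peak_rzz, "mass": m.mass}
            for m in find_modes(dmap, k=2)]

    @stage("dimer")
    def _dimer():
        traj = trajs[0]
        subs = sorted(set(traj.topology.subunits[
            traj.topology.species == "protein"]))
        if len(subs) < 2:
            raise ConfigError("dimer stage needs two protein subunits")
        angles = hinge_angle_series(traj)
        rows = {"time_ns": angles.times, "theta_deg": angles.theta}
        bundle.hinge = pd.DataFrame(rows)
        dist_rows = {"time_ns": traj.times}
        for su in subs[:2]:
            s = subunit_distance_series(
                traj, f"subunit {su} and species protein",
                config.membrane_sel, metric=config.distance_metric)
            dist_rows[f"subunit_{su}_nm"] = s.values
        bundle.subunit_distances = pd.DataFrame(dist_rows)

    @stage("rmsf")
    def _rmsf():
        residues, fluct = rmsf(trajs[0])
        bundle.rmsf_profile = pd.DataFrame(
            {"residue": residues, "rmsf_nm": fluct})

    if truths is not None:
        bundle.provenance["synthetic_truth"] = [
            {"seed": t.params.seed, "tau_ns": t.params.tau,
             "binding_frame": t.binding_frame,
             "bound_mode": int(t.mode_per_frame.max())}
            for t in truths]
    logger.info("pipeline finished in %.2f s", time.time() - t_start)
    return bundle
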