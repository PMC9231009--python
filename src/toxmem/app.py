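"""Configuration, pipeline wiring and command-line interface.

One YAML config file drives the whole analysis: generate synthetic
trajectories and series, score insertion, profile the dipole, estimate
diffusion, run the metadynamics toy, sweep the RD binding-fraction model,
and decompose synthetic pair energies. Every stochastic stage carries an
explicit seed, so a rerun with the same config reproduces every output
byte for byte; the run manifest records the config hash, seeds and library
versions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from importlib import resources
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import diffusion as dif
from . import dipole as dip
from . import energetics as ene
from . import insertion as ins
from . import metadynamics as mtd
from . import rdmodel as rd
from . import synthetic as syn

log = logging.getLogger("toxmem")

STOCHASTIC_STAGES = ("simulate", "diffusion", "metad", "energetics")


class ConfigError(ValueError):
    pass


def load_config(path=None) -> dict:
    """Load a YAML run config; with no path, the packaged demo config."""
    if path is None:
        text = (resources.files("toxmem.data") / "demo_config.yaml").read_text()
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)


def validate_config(config: dict) -> None:
    seeds = config.get("seeds", {})
    for stage in STOCHASTIC_STAGES:
        if stage not in seeds:
            raise ConfigError(f"missing seed for stochastic stage '{stage}'")
    if "output_dir" not in config:
        raise ConfigError("config must name an output_dir")


def config_hash(config: dict) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


# ------------------------------------------------------------------ stages

def _simulate(config: dict):
    c = config.get("bilayer", {})
    b = config.get("binding", {})
    seed = config["seeds"]["simulate"]
    fixture = syn.load_snx482_fixture()
    bilayer = syn.make_bilayer(
        syn.BilayerSpec(
            n_lipids=c.get("n_lipids", 308),
            popg_fraction=c.get("popg_fraction", 0.25),
            head_roughness_sigma=c.get("head_roughness_sigma", 0.05),
            n_frames=c.get("n_frames", 300),
            frame_dt=c.get("frame_dt", 2.0),
            seed=seed,
        )
    )
    depths = np.full(fixture.n_residues, b.get("other_depth", 0.6))
    for r in fixture.hydrophobic_patch:
        depths[r - 1] = b.get("patch_depth", -0.3)
    scenario = syn.BindingScenario(
        target_depths=depths,
        start_distance=b.get("start_distance", 2.5),
        onset_frame=b.get("onset_frame"),
        approach_speed=b.get("approach_speed", 0.05),
        depth_noise_sigma=b.get("depth_noise_sigma", 0.1),
        seed=seed,
    )
    return syn.make_binding_trajectory(bilayer, scenario, fixture)


def stage_simulate(config: dict, outdir: Path) -> dict:
    traj = _simulate(config)
    traj.to_csv(outdir / "trajectory.csv")
    return {"frames": traj.n_frames, "residues": traj.n_residues}


def stage_insertion(config: dict, outdir: Path) -> dict:
    c = config.get("insertion", {})
    traj = _simulate(config)
    matrix = ins.classify_insertions(
        traj, criterion=c.get("criterion", "residue_com"), gate_nm=c.get("gate_nm", 0.5)
    )
    profile = ins.insertion_probability(matrix)
    score = ins.insertion_score(profile)
    pd.DataFrame(
        {"residue": np.arange(1, traj.n_residues + 1), "Ip": profile.ip}
    ).to_csv(outdir / "insertion_ip.csv", index=False)
    dist, plateau = ins.com_distance_and_plateau(traj)
    pd.DataFrame({"time_ns": traj.times, "com_distance_nm": dist}).to_csv(
        outdir / "com_distance.csv", index=False
    )
    summary = {
        "IS": score,
        "onset_frame": matrix.onset_frame,
        "plateau_frame": plateau,
        "criterion": matrix.criterion,
    }
    pd.DataFrame([summary]).to_csv(outdir / "insertion_summary.csv", index=False)
    return summary


def stage_dipole(config: dict, outdir: Path) -> dict:
    c = config.get("dipole", {})
    traj = _simulate(config)
    records = dip.dipole_profile(traj)
    records.to_csv(outdir / "dipole_records.csv", index=False)
    dip.bin_by_distance(records, bin_nm=c.get("distance_bin_nm", 0.25)).to_csv(
        outdir / "dipole_by_distance.csv", index=False
    )
    centers, prob = dip.angle_histogram(records, bin_deg=c.get("bin_deg", 5.0))
    pd.DataFrame({"angle_deg": centers, "probability": prob}).to_csv(
        outdir / "dipole_angle_hist.csv", index=False
    )
    bound = records[records["membrane_distance_nm"] < 0.5]
    return {
        "mean_bound_magnitude_debye": float(bound["magnitude_debye"].mean()),
        "mean_bound_angle_deg": float(bound["angle_z_deg"].mean()),
    }


def stage_diffusion(config: dict, outdir: Path) -> dict:
    c = config.get("diffusion", {})
    seed = config["seeds"]["diffusion"]
    out = {}
    rows = []
    for label, d_true, ndim in (
        ("bulk_3d", c.get("D3", 1.0e-6), 3),
        ("lateral_2d", c.get("D2", 4.1e-8), 2),
    ):
        times, pos = syn.make_brownian(
            syn.BrownianSpec(
                D=d_true,
                n_dims=ndim,
                dt=c.get("dt_ps", 10.0),
                n_steps=c.get("n_steps", 200_000),
                seed=seed,
            )
        )
        curve = dif.msd(pos, times, max_lag_fraction=c.get("max_lag_fraction", 0.002))
        est = dif.einstein_fit(curve, (c.get("fit_lo", 0.1), c.get("fit_hi", 0.5)))
        row = {
            "series": label,
            "n_dims": ndim,
            "D_true_cm2_s": d_true,
            "D_est_cm2_s": est.D_cm2_s,
            "stderr_cm2_s": est.stderr_cm2_s,
        }
        if ndim == 2:
            psd = dif.PSDInputs(**c.get("psd", {}))
            d_inf, delta = dif.psd_extrapolate(est.D_cm2_s, psd)
            row["D_infinity_cm2_s"] = d_inf
            row["psd_correction_cm2_s"] = delta
        rows.append(row)
        out[label] = row["D_est_cm2_s"]
    pd.DataFrame(rows).to_csv(outdir / "diffusion_estimates.csv", index=False)
    return out


def stage_metad(config: dict, outdir: Path) -> dict:
    c = config.get("metad", {})
    params = mtd.WTParams(
        W0=c.get("W0", 0.5),
        hill_width=c.get("hill_width", 0.1),
        delta_T=c.get("delta_T", 1500.0),
        deposit_stride=c.get("stride", 200),
    )
    barrier = c.get("barrier", 3.0)
    potential = mtd.double_well(barrier=barrier)
    walls = mtd.WallSpec(*c.get("walls", (-1.6, 1.6)), c.get("wall_k", 10.0))
    lang = mtd.LangevinSpec(
        dt=c.get("dt", 5e-3),
        n_steps=c.get("n_steps", 200_000),
        x0=c.get("x0", -1.0),
        seed=config["seeds"]["metad"],
    )
    _, hills = mtd.run_sampler(potential, params, walls, lang)
    grid = np.arange(walls.lower, walls.upper + 1e-9, params.hill_width / 2.0)
    pmf = mtd.pmf_time_averaged(hills, params, grid)
    ref = potential.reference_pmf(grid)
    pd.DataFrame({"cv": grid, "pmf_kcal_mol": pmf, "reference_kcal_mol": ref}).to_csv(
        outdir / "metad_pmf.csv", index=False
    )
    np.savetxt(
        outdir / "metad_hills.txt",
        hills.to_table(),
        header="index center height width",
        comments="# ",
    )
    inner = np.abs(grid) <= 1.2
    est_barrier = float(pmf[np.abs(grid) < 0.15].max() - pmf[inner].min())
    return {
        "n_hills": hills.n_hills,
        "barrier_true_kcal_mol": barrier,
        "barrier_est_kcal_mol": est_barrier,
        "pmf_scale": params.pmf_scale,
    }


def stage_rdmodel(config: dict, outdir: Path) -> dict:
    c = config.get("rdmodel", {})
    kp = np.logspace(
        np.log10(c.get("kp_min", 1e-2)), np.log10(c.get("kp_max", 1e6)), c.get("n_kp", 49)
    )
    d2 = np.asarray(c.get("d2_list", [4.1e-8, 1e-9, 1e-10]), dtype=float)
    sweep = rd.f2_sweep(kp, d2)
    sweep.to_csv(outdir / "f2_sweep.csv", index=False)
    return {"f2_at_kp1_measured_d2": float(rd.f2(rd.RDParams()))}


def stage_energetics(config: dict, outdir: Path) -> dict:
    c = config.get("energetics", {})
    seed = config["seeds"]["energetics"]
    n = c.get("n_frames", 2048)
    base = {p: (-50.0, -20.0) for p in ene.PAIR_VOCABULARY}
    shifted = dict(base)
    shifted["toxin-membrane"] = (-80.0, -35.0)
    shifted["toxin-water"] = (-30.0, -10.0)
    bound = syn.make_pair_energy_table(shifted, n_frames=n, seed=seed)
    unbound = syn.make_pair_energy_table(base, n_frames=n, seed=seed + 1)
    report = ene.energy_decomposition(bound, unbound)
    report.to_csv(outdir / "energy_decomposition.csv", index=False)
    return dict(zip(report["component"], report["delta_kcal_mol"]))


STAGES = {
    "simulate": stage_simulate,
    "insertion": stage_insertion,
    "dipole": stage_dipole,
    "diffusion": stage_diffusion,
    "metad": stage_metad,
    "rdmodel": stage_rdmodel,
    "energetics": stage_energetics,
}


def run_pipeline(config: dict, stages: list[str] | None = None) -> dict:
    """Run the requested stages in order and write a machine-readable manifest.

    Returns the combined per-stage summary. A stage failure is logged with the
    stage name and re-raised after the manifest records the partial results.
    """
    validate_config(config)
    outdir = Path(config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    todo = stages if stages is not None else list(STAGES)
    summary: dict = {}
    failed: str | None = None
    try:
        for name in todo:
            log.info("running stage %s", name)
            summary[name] = STAGES[name](config, outdir)
    except Exception:
        failed = name
        log.exception("stage %s failed", name)
        raise
    finally:
        manifest = {
            "config_sha256": config_hash(config),
            "seeds": config.get("seeds", {}),
            "stages_completed": list(summary),
            "failed_stage": failed,
            "versions": {
                "toxmem": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "python": sys.version.split()[0],
            },
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
    return summary


# ------------------------------------------------------------------ CLI

@click.group()
@click.option("--log-level", default="INFO", show_default=True)
def cli(log_level: str) -> None:
    """Peptide-membrane partitioning analysis toolkit."""
    logging.basicConfig(level=getattr(logging, log_level.upper(), logging.INFO))


def _single_stage(name: str):
    @click.command(name=name, help=f"Run the {name} stage.")
    @click.option("--config", "config_path", type=click.Path(exists=True), default=None,
                  help="YAML run config (default: packaged demo config).")
    @click.option("--output-dir", default=None, help="Override the config output_dir.")
    def _cmd(config_path, output_dir):
        config = load_config(config_path)
        if output_dir is not None:
            config["output_dir"] = output_dir
        summary = run_pipeline(config, stages=[name])
        click.echo(json.dumps(summary, indent=1, default=str))

    return _cmd


for _name in STAGES:
    cli.add_command(_single_stage(_name))


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None,
              help="YAML run config (default: packaged demo config).")
@click.option("--output-dir", default=None, help="Override the config output_dir.")
def pipeline(config_path, output_dir):
    """Run every stage end to end."""
    config = load_config(config_path)
    if output_dir is not None:
        config["output_dir"] = output_dir
    summary = run_pipeline(config)
    click.echo(json.dumps(summary, indent=1, default=str))


if __name__ == "__main__":
    cli()
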