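"""End-to-end adsorption pipeline: build -> sample -> wham -> observables
-> edwards -> report.

Each stage is idempotent: it writes its artifacts under the configured
output directory, tagged with the configuration hash and master seed, and
a re-run with the identical configuration reuses what is already on disk.
All tables are TSV with 0-based indices, energies in kBT and distances in
nm; the final report is a single JSON aggregating the adsorption free
energy, contact numbers, gyration ratios and the Edwards overlay per
attraction strength.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import observables as obs
from . import sampler, wham_pmf
from .config import RunConfig, config_hash, spawn_seeds
from .edwards import free_energy_scan
from .fragments import make_fragment
from .surface import wall_minimum

log = logging.getLogger("rnadsorb")

__all__ = ["run_pipeline", "stage_build", "stage_sample", "stage_wham",
           "stage_observables", "stage_edwards", "stage_report"]


class PipelineError(RuntimeError):
    def __init__(self, stage, message):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _outdir(config: RunConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_meta(config: RunConfig, out: Path) -> None:
    (out / "config.json").write_text(config.canonical_json())
    (out / "run_meta.json").write_text(json.dumps(
        {"config_hash": config_hash(config), "seed": config.seed}, indent=1))


def _check_meta(config: RunConfig, out: Path) -> bool:
    meta = out / "run_meta.json"
    if not meta.exists():
        return False
    try:
        data = json.loads(meta.read_text())
    except json.JSONDecodeError:
        return False
    return (data.get("config_hash") == config_hash(config)
            and data.get("seed") == config.seed)


def stage_build(config: RunConfig):
    out = _outdir(config)
    frag = make_fragment(config.fragment.label, config.fragment.structured,
                         seed=config.seed)
    frag.conformation.to_pdb(out / "fragment.pdb")
    (out / "fragment.dbn").write_text(frag.topology.dotbracket + "\n")
    if frag.topology.sequence:
        (out / "fragment.fasta").write_text(
            f">{config.fragment.label}\n{frag.topology.sequence}\n")
    log.info("build: %s (%s), %d nt, %d pairs",
             config.fragment.label,
             "wiss" if config.fragment.structured else "noss",
             frag.topology.n_nucleotides, len(frag.topology.base_pairs))
    return frag


def _window_dir(out: Path, eps: float) -> Path:
    d = out / "windows" / f"eps{eps:.4f}"
    d.mkdir(parents=True, exist_ok=True)
    return d


def stage_sample(config: RunConfig, frag) -> dict:
    """Umbrella sampling for every attraction strength; cached per window."""
    out = _outdir(config)
    chash = config_hash(config)
    centers = config.windows.resolved_centers()
    all_samples: dict[float, list[sampler.WindowSamples]] = {}
    for eps in config.wall.eps_surf:
        wall = config.wall.build(eps)
        wdir = _window_dir(out, eps)
        seeds = spawn_seeds(config.seed, len(centers), salt=f"eps{eps:.6f}")
        samples: dict[int, sampler.WindowSamples] = {}
        # windows are run outside-in, each seeded by the previous window's
        # final conformation, so near-wall windows start well relaxed
        order = np.argsort([-c for c in centers])
        conf = frag.conformation
        for k in order:
            k = int(k)
            c, s = centers[k], seeds[k]
            win = sampler.UmbrellaWindow(
                center=c, spring=config.windows.spring,
                n_equil=config.windows.n_equil, n_prod=config.windows.n_prod,
                sample_stride=config.windows.sample_stride, seed=s)
            tsv = wdir / f"win{k:02d}.tsv"
            meta = wdir / f"win{k:02d}.json"
            snap_file = wdir / f"win{k:02d}_snaps.npy"
            if tsv.exists() and meta.exists() and snap_file.exists():
                info = json.loads(meta.read_text())
                if info.get("config_hash") == chash:
                    log.info("sample: reusing cached window %d (eps=%.3f)", k, eps)
                    df = pd.read_csv(tsv, sep="\t")
                    snaps = np.load(snap_file)
                    samples[k] = sampler.WindowSamples(
                        window=win, cv_series=df["d_cm"].to_numpy(),
                        conformations=snaps,
                        acceptance=info.get("acceptance", {}))
                    if snaps.size:
                        conf = sampler.Conformation(snaps[-1].copy())
                    continue
            ws = sampler.run_window(frag.topology, None, wall, win,
                                    conf, frag.template)
            conf = ws.final_conformation
            pd.DataFrame({"sweep": np.arange(len(ws.cv_series)),
                          "d_cm": ws.cv_series}).to_csv(tsv, sep="\t", index=False)
            np.save(snap_file, ws.conformations)
            meta.write_text(json.dumps({
                "config_hash": chash, "seed": s, "center": c,
                "acceptance": {k_: float(v) for k_, v in ws.acceptance.items()},
                "max_stem_ermsd": (float(np.max(ws.ermsd_trace))
                                   if ws.ermsd_trace is not None else None),
            }, indent=1))
            samples[k] = ws
        all_samples[eps] = [samples[i] for i in range(len(centers))]
    _write_meta(config, out)
    return all_samples


def stage_wham(config: RunConfig, all_samples: dict) -> dict:
    out = _outdir(config)
    profiles = {}
    for eps, samples in all_samples.items():
        try:
            pmf = wham_pmf.pmf_from_samples(samples)
        except ValueError as err:
            raise PipelineError("wham", str(err)) from err
        cv_sets = [ws.cv_series for ws in samples]
        biases = [(lambda d, k=ws.window.spring, c=ws.window.center:
                   0.5 * k * (d - c) ** 2) for ws in samples]
        errs = wham_pmf.bootstrap_pmf(cv_sets, biases, n_boot=20,
                                      seed=config.seed)
        pd.DataFrame({"d_cm": pmf.bin_centers, "F": pmf.free_energy,
                      "err": errs}).to_csv(
            out / f"pmf_eps{eps:.4f}.tsv", sep="\t", index=False)
        profiles[eps] = pmf
    return profiles


def stage_observables(config: RunConfig, frag, all_samples: dict) -> pd.DataFrame:
    """Bound-state observables from dedicated *unbiased* runs.

    Umbrella snapshots are bias-weighted, so densities, contacts and
    gyration components are measured on a fresh unbiased trajectory per
    attraction strength, started from the innermost window's final
    (adsorbed) conformation.
    """
    out = _outdir(config)
    rows = []
    n_p = frag.topology.n_nucleotides
    for eps, samples in all_samples.items():
        wall = config.wall.build(eps)
        inner = min(samples, key=lambda ws: ws.window.center)
        if inner.final_conformation is not None:
            start = inner.final_conformation
        elif inner.conformations.size:
            start = sampler.Conformation(inner.conformations[-1].copy())
        else:
            raise PipelineError(
                "observables",
                f"no conformations available for eps={eps}; re-run 'sample'")
        seed = spawn_seeds(config.seed, 1, salt=f"obs{eps:.6f}")[0]
        unb = sampler.run_unbiased(
            frag.topology, None, wall, start,
            n_equil=config.windows.n_equil,
            n_prod=4 * config.windows.n_prod,
            seed=seed, sample_stride=config.windows.sample_stride,
            template=frag.template)
        try:
            dens = obs.monomer_density([unb], wall)
            contact = obs.contact_number(dens, wall, n_p)
            gyr = obs.ensemble_gyration(unb.conformations, wall,
                                        bound_only=True)
        except ValueError as err:
            raise PipelineError("observables", str(err)) from err
        wm = wall_minimum(wall)
        rows.append({
            "fragment": config.fragment.label,
            "structured": config.fragment.structured,
            "eps_surf": eps,
            "eps_min": wm.eps_min if wm else 0.0,
            "seed": config.seed,
            "contact_fraction": contact.contact_fraction,
            "contact_number": contact.contact_number,
            "rg2_parallel": gyr.rg2_parallel,
            "rg2_perpendicular": gyr.rg2_perpendicular,
            "rg_ratio": gyr.ratio,
        })
    df = pd.DataFrame(rows)
    df.to_csv(out / "observables.tsv", sep="\t", index=False)
    return df


def stage_edwards(config: RunConfig) -> pd.DataFrame | None:
    if not config.edwards.enabled:
        return None
    out = _outdir(config)
    walls = [config.wall.build(e) for e in config.wall.eps_surf]
    df = free_energy_scan(walls, kuhn_length=config.edwards.kuhn_length,
                          z_max=config.edwards.z_max, dz=config.edwards.dz)
    df.to_csv(out / "edwards.tsv", sep="\t", index=False)
    return df


def stage_report(config: RunConfig, frag, profiles: dict,
                 observables_df: pd.DataFrame,
                 edwards_df: pd.DataFrame | None) -> dict:
    out = _outdir(config)
    n = frag.topology.n_nucleotides
    per_eps = []
    for eps, pmf in profiles.items():
        fm = wham_pmf.adsorption_free_energy(pmf)
        row = observables_df[observables_df.eps_surf == eps].iloc[0]
        entry = {
            "eps_surf": eps,
            "eps_min": float(row.eps_min),
            "F_m": fm,
            "F_m_per_nt": fm / n,
            "pmf_min_location": float(
                pmf.bin_centers[int(np.nanargmin(pmf.free_energy))]),
            "closest_approach": wham_pmf.closest_approach(pmf),
            "contact_fraction": float(row.contact_fraction),
            "contact_number": float(row.contact_number),
            "rg_ratio": float(row.rg_ratio),
        }
        if edwards_df is not None:
            match = edwards_df[np.isclose(edwards_df.eps_surf, eps)]
            if len(match):
                entry["edwards_f_per_monomer"] = float(match.iloc[0].f)
        per_eps.append(entry)
    report = {
        "fragment": config.fragment.label,
        "structured": config.fragment.structured,
        "n_nucleotides": n,
        "paired_fraction": frag.topology.paired_fraction,
        "seed": config.seed,
        "config_hash": config_hash(config),
        "scan": sorted(per_eps, key=lambda r: r["eps_surf"]),
    }
    (out / "summary.json").write_text(json.dumps(report, indent=1))
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages in order and return the aggregated report."""
    frag = stage_build(config)
    all_samples = stage_sample(config, frag)
    profiles = stage_wham(config, all_samples)
    observables_df = stage_observables(config, frag, all_samples)
    edwards_df = stage_edwards(config)
    return stage_report(config, frag, profiles, observables_df, edwards_df)
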