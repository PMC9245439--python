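"""Top-level analysis pipeline: generate/read -> shape -> sasa ->
scattering -> ions -> report.

A run is described by a structured config (YAML file or dict) and writes
CSV/JSON outputs plus a machine-readable ``manifest.json`` (package and
library versions, seed, cutoffs, stages) to an output directory.  The
manifest and outputs are deterministic for a fixed config, so a run is
reproducible bit for bit from the manifest alone; stage timings go to the
log, not the manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, ions, reporting, sasa, scattering, shape
from .model import ChainSequence, MicelleSystem, select, unwrap_frame
from .synthetic import SyntheticMicelleSpec, generate_micelle, preset_spec

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "load_config", "build_system"]

_ALL_STAGES = ("shape", "sasa", "scattering", "ions", "report")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def load_config(source) -> dict:
    if isinstance(source, dict):
        return dict(source)
    with open(source) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def _spec_from_config(gen_cfg: dict, seed: int) -> SyntheticMicelleSpec:
    cfg = dict(gen_cfg)
    preset = cfg.pop("preset", None)
    charges = cfg.pop("charge_positions", None)
    if charges is not None:
        cfg["sequence"] = ChainSequence.from_charge_positions(
            charges, one_based=True)
    cfg.setdefault("seed", seed)
    if preset is not None:
        return preset_spec(preset, **cfg)
    return SyntheticMicelleSpec(**cfg)


def build_system(config: dict, seed: int) -> MicelleSystem:
    if "generator" in config:
        spec = _spec_from_config(config["generator"], seed)
        return generate_micelle(spec)
    if "input" in config:
        frames = io.read_trajectory(config["input"],
                                    format=config.get("format"))
        return MicelleSystem.from_frames(frames)
    raise ValueError("config needs a 'generator' spec or an 'input' path")


def _stage_shape(system, cfg, out_dir) -> pd.DataFrame:
    shell_cutoff = float(cfg.get("shell_cutoff", 0.35))
    include_shell = bool(cfg.get("include_shell", False))
    results = shape.analyze_frames(
        system,
        selection=cfg.get("selection", "micelle"),
        weighting=cfg.get("weighting", "mass"),
        include_shell=include_shell,
        shell_cutoff=shell_cutoff,
        include_rgb=bool(cfg.get("include_rgb", True)),
    )
    df = pd.DataFrame([{
        "frame": r.frame_index,
        "lambda1": r.eigenvalues[0],
        "lambda2": r.eigenvalues[1],
        "lambda3": r.eigenvalues[2],
        "rg": r.rg,
        "rgb": r.rgb if r.rgb is not None else np.nan,
        "asphericity": r.asphericity,
        "shape": r.shape,
        "l2_l1": r.ratios[0],
        "l3_l1": r.ratios[1],
    } for r in results])
    df.to_csv(out_dir / "shape.csv", index=False, float_format="%.8g")
    return df


def _stage_sasa(system, cfg, out_dir) -> pd.DataFrame:
    rows = []
    for k, frame in enumerate(system.frames):
        solute = select(unwrap_frame(frame), cfg.get("selection", "micelle"))
        res = sasa.compute_sasa(
            solute,
            probe_radius=float(cfg.get("probe_radius", 0.14)),
            n_sphere_points=int(cfg.get("n_points", 960)))
        rows.append({"frame": k, "total": res.total,
                     "per_chain": res.per_chain})
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "sasa.csv", index=False, float_format="%.8g")
    return df


def _stage_scattering(system, cfg, out_dir) -> dict:
    frame = unwrap_frame(system.frames[0])
    solute = select(frame, cfg.get("selection", "micelle"))
    box = frame.box
    r_max = float(cfg.get("r_max", 3.0))
    if box is not None:
        r_max = min(r_max, float(box.min()) / 2.0 - 1e-9)
    table = scattering.ScatteringLengthTable()
    if cfg.get("deuterate", False):
        table = table.deuterated()
    q = np.linspace(float(cfg.get("q_min", 0.01)),
                    float(cfg.get("q_max", 0.3)),
                    int(cfg.get("n_q", 100)))
    partials = scattering.element_partials(
        solute, r_max=r_max, bin_width=float(cfg.get("bin_width", 0.02)))
    total = scattering.total_weighted_rdf(partials, table)
    rho = len(solute) / float(np.prod(box))
    profile = scattering.structure_factor(
        total, rho, q, window=cfg.get("window", "lorch"))
    pd.DataFrame({"r_nm": total.r_mid, "g": total.g}).to_csv(
        out_dir / "rdf_total.csv", index=False, float_format="%.8g")
    pd.DataFrame({"q_invA": profile.q, "s": profile.s}).to_csv(
        out_dir / "sq.csv", index=False, float_format="%.8g")
    try:
        rg = scattering.guinier_rg(profile,
                                   q_max=float(cfg.get("guinier_q_max",
                                                       0.1)))
    except ValueError as exc:
        logger.warning("Guinier fit unavailable: %s", exc)
        rg = None
    return {"guinier_rg_nm": rg, "r_max_nm": r_max}


def _stage_ions(system, cfg, out_dir) -> dict:
    coord_cut = float(cfg.get("coordination_cutoff", 0.35))
    result = {}
    for partner in ("sodium", "water_oxygen"):
        hist = ions.coordination_histogram(system, partner=partner,
                                           cutoff=coord_cut)
        pd.DataFrame(
            {"n_c": list(hist.probabilities),
             "probability": list(hist.probabilities.values())}
        ).to_csv(out_dir / f"coordination_{partner}.csv", index=False,
                 float_format="%.8g")
        result[f"mean_coordination_{partner}"] = hist.mean
    dist = ions.nearest_interchain_carboxylate(system)
    pd.DataFrame({"distance_nm": dist.distances}).to_csv(
        out_dir / "cc_neighbor.csv", index=False, float_format="%.8g")
    report = ions.salt_bridges(
        system,
        bridge_cutoff=float(cfg.get("bridge_cutoff", 0.5)),
        site=cfg.get("bridge_site", "carbon"),
        condensation_cutoff=float(cfg.get("condensation_cutoff", 0.35)))
    payload = dataclasses.asdict(report)
    (out_dir / "salt_bridges.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True))
    result.update({
        "fraction_05": report.fraction_05,
        "fraction_10": report.fraction_10,
        "condensed_fraction": report.condensed_fraction,
    })
    return result


def _stage_report(tables: dict, cfg, out_dir) -> dict:
    shape_df = tables.get("shape")
    sasa_df = tables.get("sasa")
    if shape_df is None:
        raise ValueError("report stage needs the shape stage")
    series = {
        "rg": shape_df["rg"].to_numpy(),
        "asphericity": shape_df["asphericity"].to_numpy(),
        "shape": shape_df["shape"].to_numpy(),
    }
    if sasa_df is not None:
        series["sasa"] = sasa_df["total"].to_numpy()
    n_frames = len(series["rg"])
    n_blocks = min(int(cfg.get("n_blocks", 10)), n_frames)
    summary = {}
    for name, values in series.items():
        s = reporting.summarize(values, name=name, n_blocks=n_blocks)
        summary[name] = {"mean": s.mean, "se": s.se,
                         "quartiles": list(s.quartiles)}
    corr = {}
    if n_frames >= 3:
        table = reporting.correlate(series)
        corr = {f"{a}~{b}": (None if np.isnan(v) else v)
                for (a, b), v in table.r.items()}
    payload = {"summaries": summary, "correlations": corr,
               "n_blocks": n_blocks}
    (out_dir / "report.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True))
    return payload


def run_pipeline(config, out_dir) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    cfg = load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stages = list(cfg.get("analyses", _ALL_STAGES))
    unknown = set(stages) - set(_ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown analyses: {sorted(unknown)}")

    t0 = time.perf_counter()
    try:
        system = build_system(cfg, seed)
    except Exception as exc:
        raise StageError("build", str(exc)) from exc
    logger.info("stage build: %d frames, %d atoms (%.2f s)",
                system.n_frames, len(system.frames[0]),
                time.perf_counter() - t0)

    if cfg.get("write_configuration"):
        io.write_configuration(system.frames,
                               str(out_dir / cfg["write_configuration"]))

    manifest = {
        "package": "micellometrics",
        "version": __version__,
        "versions": {"numpy": np.__version__,
                     "pandas": pd.__version__},
        "seed": seed,
        "config": _jsonable(cfg),
        "stages": stages,
        "results": {},
    }
    tables: dict[str, pd.DataFrame] = {}
    runners = {
        "shape": lambda: tables.__setitem__(
            "shape", _stage_shape(system, cfg.get("shape", cfg), out_dir)),
        "sasa": lambda: tables.__setitem__(
            "sasa", _stage_sasa(system, cfg.get("sasa", {}), out_dir)),
        "scattering": lambda: manifest["results"].update(
            scattering=_stage_scattering(system, cfg.get("scattering", {}),
                                         out_dir)),
        "ions": lambda: manifest["results"].update(
            ions=_stage_ions(system, cfg.get("ions", {}), out_dir)),
        "report": lambda: manifest["results"].update(
            report=_stage_report(tables, cfg.get("report", {}), out_dir)),
    }
    for stage in _ALL_STAGES:
        if stage not in stages:
            continue
        t = time.perf_counter()
        try:
            runners[stage]()
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
        logger.info("stage %s done (%.2f s)", stage,
                    time.perf_counter() - t)
    if "shape" in tables:
        manifest["results"]["shape"] = {
            "mean_rg_nm": float(tables["shape"]["rg"].mean()),
            "mean_asphericity":
                float(tables["shape"]["asphericity"].mean()),
        }
    if "sasa" in tables:
        manifest["results"]["sasa"] = {
            "mean_total_nm2": float(tables["sasa"]["total"].mean()),
            "mean_per_chain_nm2":
                float(tables["sasa"]["per_chain"].mean()),
        }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj
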