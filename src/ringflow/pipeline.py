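"""Pipeline orchestration: synthetic population → aligned averages → fits.

The pipeline runs in "table mode" by default — trajectories, flow fields
and intensity series are produced directly by the generator — with an
optional image stage that renders a subset of embryos as TIFF stacks and
runs the segmentation/ring-fitting algorithms on them.  Every stage writes
plain CSV/JSON artifacts into the configured output directory and reports
its timing and warnings in a structured report.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import alignment as al
from . import flowmap as fmap
from . import geometry as geo
from . import kinematics as kin
from . import model as fm
from . import photometry as ph
from . import synthetic as syn

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "validate_inputs"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Declarative configuration; round-trips through YAML losslessly."""

    out_dir: str = "results/pipeline"
    seed: int = 0
    n_embryos: int = 20
    noise_sd: float = 0.05
    trajectory_noise_um: float = 0.15
    flow_noise_sd: float = 0.05
    sample_interval_s: float = 36.0
    render_images: bool = False
    n_render: int = 3
    t_hat_budget_start: float = -0.2
    input_rings_csv: Optional[str] = None
    stages: List[str] = field(
        default_factory=lambda: [
            "simulate",
            "align",
            "flowmap",
            "budget",
            "photometry",
            "model",
        ]
    )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def validate_inputs(paths: Dict[str, str]) -> List[Dict[str, str]]:
    """Check readability and schemas of declared inputs; never raises.

    ``paths`` maps kinds (``rings_csv``, ``flow_csv``, ``tiff``) to file
    paths.  Returns a list of issues, each naming the file and problem.
    """
    issues: List[Dict[str, str]] = []
    schemas = {
        "rings_csv": ["time_s", "radius_um", "rbar"],
        "flow_csv": ["t_s", "x_um", "theta_deg", "vx_um_s", "vtheta_um_s"],
    }
    for kind, path in paths.items():
        p = Path(path)
        if not p.exists():
            issues.append({"file": str(p), "issue": "missing file"})
            continue
        if kind in schemas:
            try:
                df = pd.read_csv(p, nrows=5)
            except Exception as exc:  # noqa: BLE001 - report, don't throw
                issues.append({"file": str(p), "issue": f"unreadable CSV: {exc}"})
                continue
            for col in schemas[kind]:
                if col not in df.columns:
                    issues.append({"file": str(p), "issue": f"missing column {col!r}"})
        elif kind == "tiff":
            try:
                import tifffile

                tifffile.imread(p)
            except Exception as exc:  # noqa: BLE001
                issues.append(
                    {
                        "file": str(p),
                        "issue": f"unreadable TIFF near byte {p.stat().st_size}: {exc}",
                    }
                )
        else:
            issues.append({"file": str(p), "issue": f"unknown input kind {kind!r}"})
    return issues


def run_pipeline(config: PipelineConfig) -> Dict:
    """Run the configured stages; returns the report dict.

    Raises :class:`PipelineError` naming the failing stage.  With a fixed
    seed and config the written artifacts are bit-identical across runs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: Dict = {"config": dataclasses.asdict(config), "stages": {}}
    state: Dict = {}

    stage_fns = {
        "simulate": _stage_simulate,
        "align": _stage_align,
        "flowmap": _stage_flowmap,
        "budget": _stage_budget,
        "photometry": _stage_photometry,
        "model": _stage_model,
        "geometry": _stage_geometry,
    }
    stages = list(config.stages)
    if config.render_images and "geometry" not in stages:
        stages.insert(1, "geometry")

    for name in stages:
        fn = stage_fns.get(name)
        if fn is None:
            raise PipelineError(f"stage {name!r}: unknown stage")
        t0 = time.perf_counter()
        try:
            info = fn(config, state, out)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        report["stages"][name] = {
            "seconds": round(time.perf_counter() - t0, 3),
            **(info or {}),
        }

    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    lines = [f"ringflow pipeline report (seed={config.seed})"]
    for name, info in report["stages"].items():
        extras = ", ".join(f"{k}={v}" for k, v in info.items() if k != "seconds")
        lines.append(f"  {name:<12s} {info['seconds']:7.2f} s  {extras}")
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return report


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, state: Dict, out: Path) -> Dict:
    if cfg.input_rings_csv is not None and not Path(cfg.input_rings_csv).exists():
        raise FileNotFoundError(f"input path not found: {cfg.input_rings_csv}")
    means = syn.EmbryoSpec(noise_sd=cfg.noise_sd)
    pop = syn.make_population(cfg.n_embryos, spec_means=means, seed=cfg.seed)
    state["population"] = pop
    rows = []
    trajs = []
    for i, (spec, gt) in enumerate(pop):
        times = np.arange(
            spec.onset_time - cfg.sample_interval_s,
            gt.frame.t0 + gt.frame.t_ck + 1.0,
            cfg.sample_interval_s,
        )
        rings = syn.make_ring_trajectory(
            spec, gt.params, times, noise_sd_um=cfg.trajectory_noise_um
        )
        trajs.append(rings)
        for r in rings:
            rows.append(
                {
                    "embryo_id": i,
                    "time_s": r.time,
                    "radius_um": r.radius,
                    "rbar": r.rbar,
                    "center_x_um": r.center_end_on[0],
                    "center_y_um": r.center_end_on[1],
                }
            )
    state["trajectories"] = trajs
    pd.DataFrame(rows).to_csv(out / "rings.csv", index=False)
    return {"n_embryos": len(pop)}


def _stage_geometry(cfg: PipelineConfig, state: Dict, out: Path) -> Dict:
    pop = state["population"][: cfg.n_render]
    fitted = []
    for spec, gt in pop:
        rng = spec.rng(salt=7)
        rot = float(rng.uniform(0.0, 360.0))
        stack = syn.render_embryo_stack(spec, rotation_deg=rot)
        pose = geo.orient_embryo(stack, pixel_size=0.1)
        pose = geo.fit_embryo_circle(stack, pose, pixel_size=0.1, dz_um=2.0)
        fitted.append(
            {
                "true_radius_um": spec.embryo_radius,
                "fitted_radius_um": pose.embryo_radius_um,
                "true_rotation_deg": rot,
                "fitted_rotation_deg": pose.rotation_angle,
            }
        )
    df = pd.DataFrame(fitted)
    df.to_csv(out / "geometry_check.csv", index=False)
    err = float(np.mean(np.abs(df.fitted_radius_um - df.true_radius_um)))
    return {"n_rendered": len(fitted), "mean_abs_radius_error_um": round(err, 3)}


def _stage_align(cfg: PipelineConfig, state: Dict, out: Path) -> Dict:
    series = [
        (np.array([r.time for r in rings]), np.array([r.rbar for r in rings]))
        for rings in state["trajectories"]
    ]
    frames, curve = al.refine_alignment(series)
    state["frames"] = frames
    state["curve"] = curve
    pd.DataFrame(
        {
            "embryo_id": range(len(frames)),
            "t0_s": [f.t0 for f in frames],
            "tck_s": [f.t_ck for f in frames],
        }
    ).to_csv(out / "alignment.csv", index=False)
    pd.DataFrame(
        {"t_hat": curve.t_hat, "rbar_mean": curve.rbar, "n": curve.count}
    ).to_csv(out / "average_curve.csv", index=False)
    mean_tck = float(np.mean([f.t_ck for f in frames]))
    return {"mean_tck_s": round(mean_tck, 1)}


def _stage_flowmap(cfg: PipelineConfig, state: Dict, out: Path) -> Dict:
    embryos = []
    for (spec, gt), frame in zip(state["population"], state["frames"]):
        times = np.arange(gt.frame.t0 - 0.25 * gt.frame.t_ck, gt.frame.t0 + 1.05 * gt.frame.t_ck, 12.0)
        fields = [
            syn.make_flow_field(spec, gt.params, t, noise_sd=cfg.flow_noise_sd)
            for t in times
        ]
        embryos.append(
            {
                "t0": frame.t0,
                "t_ck": frame.t_ck,
                "r_emb": spec.embryo_radius,
                "times": times,
                "fields": fields,
            }
        )
    flow_map = fmap.normalize_and_average(embryos)
    state["flowmap"] = flow_map
    rows = []
    tc, xc, thc = flow_map.t_hat_centers, flow_map.x_centers, flow_map.theta_centers
    it_grid, ix_grid, ith_grid = np.meshgrid(
        range(len(tc)), range(len(xc)), range(len(thc)), indexing="ij"
    )
    df = pd.DataFrame(
        {
            "t_hat": tc[it_grid.ravel()],
            "x_um": xc[ix_grid.ravel()],
            "theta_deg": thc[ith_grid.ravel()],
            "fx": flow_map.fx.ravel(),
            "ftheta": flow_map.ftheta.ravel(),
            "n_embryos": flow_map.count.ravel(),
        }
    )
    df.to_csv(out / "flowmap.csv", index=False)
    return {"covered_cells": int((flow_map.count > 0).sum())}


def _stage_budget(cfg: PipelineConfig, state: Dict, out: Path) -> Dict:
    budget = kin.surface_budget(
        state["flowmap"], state["curve"], t_hat0=cfg.t_hat_budget_start, t_hat_end=0.95
    )
    budget.to_frame().to_csv(out / "budget.csv", index=False)
    state["budget"] = budget
    ratio = budget.a_surf[-1] / max(budget.a_div[-1], 1e-9)
    return {"final_area_ratio": round(float(ratio), 2)}


def _stage_photometry(cfg: PipelineConfig, state: Dict, out: Path) -> Dict:
    profiles = syn.make_attenuation_profiles(
        n=13, noise_sd=cfg.noise_sd, seed=cfg.seed + 17
    )
    model = ph.fit_attenuation(profiles)
    state["attenuation"] = model

    rows = []
    series = {}
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 31]))
    for name in ("myosin", "anillin", "constriction_rate", "compression_rate"):
        ts, ys = [], []
        for (spec, gt), frame in zip(state["population"], state["frames"]):
            t = np.arange(gt.frame.t0 + 0.05 * gt.frame.t_ck, gt.frame.t0 + 0.95 * gt.frame.t_ck, 30.0)
            y = getattr(gt, f"{name}_series")(t)
            y = y * (1.0 + rng.normal(0.0, cfg.noise_sd, y.shape))
            ts.append(frame.t_hat(t))
            ys.append(y)
        t_all = np.concatenate(ts)
        y_all = np.concatenate(ys)
        order = np.argsort(t_all)
        series[name] = (t_all[order], y_all[order])
        rows += [
            {"series": name, "t_hat": tt, "value": vv}
            for tt, vv in zip(t_all[order], y_all[order])
        ]
    state["series"] = series
    pd.DataFrame(rows).to_csv(out / "intensity.csv", index=False)
    return {"z_att_um": round(model.z_att, 2)}


def _stage_model(cfg: PipelineConfig, state: Dict, out: Path) -> Dict:
    curve = state["curve"]
    ok = np.isfinite(curve.rbar) & (curve.t_hat > 0.02) & (curve.t_hat < 0.98)
    rbar = (curve.t_hat[ok], curve.rbar[ok])
    mean_tck = float(np.mean([f.t_ck for f in state["frames"]]))
    comparison = fm.compare_models(state["series"], rbar=rbar, t_ck=mean_tck)
    feedback, retention = comparison.feedback, comparison.retention
    fits = {
        "feedback": {
            "tau_s": feedback.tau,
            "k": feedback.k,
            "t_hat_half": feedback.t_hat_half,
            "amplitudes": feedback.amplitudes,
            "baselines": feedback.baselines,
            "beta_per_s_per_amount": feedback.beta(),
            "alpha_um_s_per_amount": feedback.alpha(),
            "ssr": feedback.ssr,
            "aicc": feedback.aicc,
        },
        "retention": {
            "amplitudes": retention.amplitudes,
            "baselines": retention.baselines,
            "ssr": retention.ssr,
            "aicc": retention.aicc,
        },
        "preferred": comparison.preferred,
    }
    (out / "fits.json").write_text(json.dumps(fits, indent=2, default=float))
    state["fits"] = fits

    params = state["population"][0][1].params
    pred = fm.predict_bleach(params, bleach_tbar=-0.6, model="feedback")
    pred_r = fm.predict_bleach(params, bleach_tbar=-0.6, model="retention")
    pd.DataFrame(
        {
            "tbar": pred["tbar"],
            "feedback_control": pred["control"],
            "feedback_difference": pred["difference"],
            "retention_control": pred_r["control"],
            "retention_difference": pred_r["difference"],
        }
    ).to_csv(out / "bleach_predictions.csv", index=False)
    return {
        "tau_fit_s": round(float(feedback.tau), 1),
        "preferred": fits["preferred"],
    }
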