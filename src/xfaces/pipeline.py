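"""End-to-end orchestration: simulate → styles → equilibrate → fit →
tuning → compare, with a run manifest and a Markdown report.

A run is driven by a small YAML/JSON config (schema version 1; unknown keys
are rejected). One integer seed governs every stochastic stage; rerunning
the same config reproduces byte-identical numeric artifacts.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comparison import compare_conditions
from .discriminant import (
    DEFAULT_CANDIDATE_SETS,
    attach_flow,
    fit_multinomial,
    predict_surface,
    stepwise_compare,
)
from .expressiveness import equilibrate_prototypes, grid_measure_sd, optic_flow_OF
from .style import PROTOTYPE_ORDER, build_style_grid, bilinear_weights, neutral_morph
from .synthetic import (
    ObserverConfig,
    PrototypeSet,
    PrototypeSpec,
    default_beta_true,
    gen_observer_responses,
    gen_prototype_trajectories,
    render_frames,
)
from .trajectory import time_normalize, write_trajectory_csv
from .tuning import marginal_tuning

__all__ = ["RunManifest", "run_pipeline", "validate_inputs", "load_config"]

_SCHEMA = {
    "schema_version": None,
    "seed": None,
    "simulate": {
        "n_participants",
        "n_reps",
        "slope",
        "marker_count",
        "duration_s",
        "frame_rate",
        "amplitude",
        "noise_amplitude",
    },
    "styles": {"steps_per_axis", "target_frames"},
    "equilibrate": {"enabled", "measure", "lam_steps"},
    "fit": {"predictors"},
    "stepwise": {"enabled", "include_flow", "flow_frame_stride", "flow_image_size"},
    "tuning": {"nodes"},
    "compare": {"enabled", "alpha", "bootstrap_reps", "grid_resolution"},
    "report": {"enabled", "figures"},
}

_DEFAULTS = {
    "schema_version": 1,
    "seed": 7,
    "simulate": {
        "n_participants": 20,
        "n_reps": 10,
        "slope": 4.0,
        "marker_count": 43,
        "duration_s": 5.0,
        "frame_rate": 30.0,
        "amplitude": 10.0,
        "noise_amplitude": 0.0,
    },
    "styles": {"steps_per_axis": 5, "target_frames": 150},
    "equilibrate": {"enabled": True, "measure": "MF", "lam_steps": 11},
    "fit": {"predictors": ["1", "e", "s"]},
    "stepwise": {
        "enabled": True,
        "include_flow": True,
        "flow_frame_stride": 10,
        "flow_image_size": 48,
    },
    "tuning": {"nodes": 101},
    "compare": {"enabled": True, "alpha": 0.05, "bootstrap_reps": 2000, "grid_resolution": 101},
    "report": {"enabled": True, "figures": True},
}


class ConfigError(ValueError):
    """Raised for malformed, unknown-key or wrong-version configs."""


def load_config(source: str | Path | dict) -> dict:
    """Load and validate a run config (YAML or JSON syntax)."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        raw = yaml.safe_load(text) or {}
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(raw) - set(_SCHEMA)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = json.loads(json.dumps(_DEFAULTS))  # deep copy
    for section, value in raw.items():
        allowed = _SCHEMA[section]
        if allowed is None:
            cfg[section] = value
            continue
        if not isinstance(value, dict):
            raise ConfigError(f"config section {section!r} must be a mapping")
        bad = set(value) - allowed
        if bad:
            raise ConfigError(f"unknown keys in section {section!r}: {sorted(bad)}")
        cfg[section].update(value)
    if cfg["schema_version"] != 1:
        raise ConfigError(f"unsupported schema_version {cfg['schema_version']!r} (expected 1)")
    if not isinstance(cfg["seed"], int):
        raise ConfigError("seed must be an integer")
    return cfg


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    seed: int
    version: str
    stages: list[str] = field(default_factory=list)
    digests: dict[str, str] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def write(self, path: Path) -> None:
        payload = {
            "config": self.config,
            "seed": self.seed,
            "version": self.version,
            "stages": self.stages,
            "digests": self.digests,
            "timings_s": {k: round(v, 3) for k, v in self.timings_s.items()},
            "warnings": self.warnings,
            "summary": self.summary,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _equilibrated_prototypes(protos: PrototypeSet, result) -> PrototypeSet:
    new = {
        name: neutral_morph(traj, protos.neutral, result.lambda_per_prototype[name])
        for name, traj in protos.prototypes.items()
    }
    return PrototypeSet(new, protos.neutral, protos.spec, protos.seed)


def _grid_flow_by_cell(grid, stride: int, image_size: int) -> dict:
    """Mean Horn–Schunck optic flow per grid clip (temporally strided)."""
    flow = {}
    for point, traj in zip(grid.points, grid.trajectories):
        pos = traj.positions[::stride]
        sub = traj.with_positions(pos)
        frames = render_frames(sub, image_size=image_size)
        flow[(point.e, point.s)] = optic_flow_OF(frames, iterations=60).value
    return flow


def run_pipeline(config: str | Path | dict, out_dir: str | Path) -> RunManifest:
    """Execute the enabled stages in order, writing artifacts to ``out_dir``.

    Any stage failure aborts the run with the failing stage named; artifacts
    of completed stages are retained. Returns the run manifest (also written
    to ``out_dir/manifest.json``).
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    manifest = RunManifest(config=cfg, seed=seed, version=__version__)
    artifacts: list[Path] = []

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as err:
                manifest.warnings.append(f"stage {name} failed: {err}")
                manifest.write(out / "manifest.json")
                raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
            manifest.stages.append(name)
            manifest.timings_s[name] = time.perf_counter() - t0

        return deco

    state: dict = {}

    @stage("simulate")
    def _simulate():
        sim = cfg["simulate"]
        spec = PrototypeSpec(
            marker_count=sim["marker_count"],
            duration_s=sim["duration_s"],
            frame_rate=sim["frame_rate"],
            amplitude=sim["amplitude"],
            noise_amplitude=sim["noise_amplitude"],
        )
        protos = gen_prototype_trajectories(spec, seed=seed)
        state["prototypes"] = protos
        pdir = out / "prototypes"
        pdir.mkdir(exist_ok=True)
        for name, traj in {**protos.prototypes, "neutral": protos.neutral}.items():
            path = pdir / f"{name}.csv"
            write_trajectory_csv(traj, path)
            artifacts.append(path)

    @stage("styles")
    def _styles():
        st = cfg["styles"]
        protos = state["prototypes"]
        grid = build_style_grid(protos.prototypes, st["steps_per_axis"], st["target_frames"])
        state["grid"] = grid
        entries = [
            {
                "e": p.e,
                "s": p.s,
                "weights": dict(
                    zip(PROTOTYPE_ORDER, bilinear_weights(p).as_array().tolist())
                ),
            }
            for p in grid.points
        ]
        path = out / "grid_manifest.json"
        path.write_text(json.dumps({"steps_per_axis": st["steps_per_axis"], "points": entries}, indent=2))
        artifacts.append(path)

    if cfg["equilibrate"]["enabled"]:

        @stage("equilibrate")
        def _equilibrate():
            eq_cfg = cfg["equilibrate"]
            protos = state["prototypes"]
            res = equilibrate_prototypes(
                protos, eq_cfg["measure"], lam_grid=eq_cfg["lam_steps"]
            )
            eq_protos = _equilibrated_prototypes(protos, res)
            st = cfg["styles"]
            eq_grid = build_style_grid(
                eq_protos.prototypes, st["steps_per_axis"], st["target_frames"]
            )
            sd_before = grid_measure_sd(
                state["grid"].trajectories, protos.neutral_pose, eq_cfg["measure"]
            )
            sd_after = grid_measure_sd(
                eq_grid.trajectories, protos.neutral_pose, eq_cfg["measure"]
            )
            state["equilibration"] = res
            state["grid_equilibrated"] = eq_grid
            rows = [
                {
                    "prototype": name,
                    "measure_kind": res.measure_kind,
                    "lambda": res.lambda_per_prototype[name],
                    "M": res.achieved_M[name],
                }
                for name in res.lambda_per_prototype
            ]
            path = out / "equilibration.tsv"
            pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
            artifacts.append(path)
            manifest.summary["equilibration"] = {
                "target_M": res.target_M,
                "grid_sd_before": sd_before,
                "grid_sd_after": sd_after,
                "sd_reduction_percent": 100.0 * (1.0 - sd_after / sd_before)
                if sd_before > 0
                else 0.0,
            }
            if not res.within_tolerance():
                manifest.warnings.append("equilibration outside 1% tolerance")

    @stage("responses")
    def _responses():
        sim = cfg["simulate"]
        obs = ObserverConfig(
            beta_true=default_beta_true(sim["slope"]),
            n_participants=sim["n_participants"],
            n_reps=sim["n_reps"],
            seed=seed,
        )
        pts = sorted({(p.e, p.s) for p in state["grid"].points})
        resp = gen_observer_responses(pts, obs)
        state["responses"] = resp
        path = out / "responses.csv"
        resp.to_csv(path, index=False)
        artifacts.append(path)

    @stage("fit")
    def _fit():
        resp = state["responses"]
        predictors = tuple(cfg["fit"]["predictors"])
        conds = sorted(map(tuple, resp[["avatar", "view_deg"]].drop_duplicates().to_numpy()), key=str)
        coef = {}
        for cond in conds:
            sub = resp[(resp["avatar"] == cond[0]) & (resp["view_deg"] == cond[1])]
            m = fit_multinomial(sub, predictors)
            coef[f"{cond[0]}_{cond[1]}"] = {
                "beta": m.beta.tolist(),
                "predictors": m.predictor_names,
                "bic": m.bic,
                "accuracy": m.accuracy,
                "log_likelihood": m.log_likelihood,
                "separation": m.separation_flag,
            }
            state.setdefault("models", {})[cond] = m
            if m.separation_flag:
                manifest.warnings.append(f"separation fallback in condition {cond}")
        path = out / "models.json"
        path.write_text(json.dumps(coef, indent=2, sort_keys=True))
        artifacts.append(path)

    if cfg["stepwise"]["enabled"]:

        @stage("stepwise")
        def _stepwise():
            resp = state["responses"]
            sets = DEFAULT_CANDIDATE_SETS
            if cfg["stepwise"]["include_flow"]:
                flow = _grid_flow_by_cell(
                    state["grid"],
                    cfg["stepwise"]["flow_frame_stride"],
                    cfg["stepwise"]["flow_image_size"],
                )
                resp = attach_flow(resp, flow)
            else:
                sets = tuple(s for s in sets if "flow" not in s)
            table, best = stepwise_compare(resp, sets)
            path = out / "stepwise.tsv"
            table.to_csv(path, sep="\t", index=False)
            artifacts.append(path)
            manifest.summary["stepwise_selected"] = table.attrs["selected"]

    @stage("tuning")
    def _tuning():
        rows = []
        for cond, m in state["models"].items():
            fit_m, fit_h = marginal_tuning(m, cfg["tuning"]["nodes"])
            state.setdefault("tuning", {})[cond] = (fit_m, fit_h)
            for fit in (fit_m, fit_h):
                rows.append(
                    {
                        "avatar": cond[0],
                        "view_deg": cond[1],
                        "species": fit.species,
                        "theta": fit.theta,
                        "omega": fit.omega,
                        "steepness_at_threshold": fit.steepness_at_threshold,
                        "degenerate": fit.degenerate,
                    }
                )
                if fit.degenerate:
                    manifest.warnings.append(f"degenerate tuning for {cond} {fit.species}")
        path = out / "tuning.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        artifacts.append(path)

    if cfg["compare"]["enabled"]:

        @stage("compare")
        def _compare():
            cmp_cfg = cfg["compare"]
            cc = compare_conditions(
                state["responses"],
                predictor_set=tuple(cfg["fit"]["predictors"]),
                alpha=cmp_cfg["alpha"],
                grid_resolution=cmp_cfg["grid_resolution"],
                bootstrap_reps=cmp_cfg["bootstrap_reps"],
                seed=seed,
            )
            state["comparison"] = cc
            path = out / "comparison_cells.tsv"
            cc.cell_table.to_csv(path, sep="\t", index=False)
            artifacts.append(path)
            manifest.summary["q_percent"] = cc.q_percent
            manifest.summary["n_significant_cells"] = cc.n_significant

    if cfg["report"]["enabled"]:

        @stage("report")
        def _report():
            _write_report(out, cfg, state, manifest)

    for path in artifacts:
        manifest.digests[str(path.relative_to(out))] = _digest(path)
    manifest.write(out / "manifest.json")
    return manifest


def _write_report(out: Path, cfg: dict, state: dict, manifest: RunManifest) -> None:
    lines = ["# xfaces run report", ""]
    lines.append(f"Seed: {manifest.seed}; package version {manifest.version}.")
    lines.append("")
    figures = cfg["report"]["figures"]
    if figures:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig_dir = out / "figures"
        fig_dir.mkdir(exist_ok=True)
        # discriminant surfaces per condition
        for cond, m in state.get("models", {}).items():
            surf = predict_surface(m, 61)
            fig, axes = plt.subplots(1, 4, figsize=(12, 3), constrained_layout=True)
            for j, ax in enumerate(axes):
                im = ax.imshow(
                    surf["P"][j], origin="lower", extent=[0, 1, 0, 1], vmin=0, vmax=1,
                    cmap="viridis",
                )
                ax.set_title(f"P{j + 1}")
                ax.set_xlabel("e")
            axes[0].set_ylabel("s")
            fig.colorbar(im, ax=axes, shrink=0.8)
            name = f"surfaces_{cond[0]}_{cond[1]}.png"
            fig.savefig(fig_dir / name, dpi=100)
            plt.close(fig)
            lines.append(f"![Discriminant surfaces {cond}](figures/{name})")
        # tuning curves
        if state.get("tuning"):
            fig, ax = plt.subplots(figsize=(5, 4))
            for cond, (fm, fh) in state["tuning"].items():
                ax.plot(fm.s_grid, fm.samples, label=f"{cond} monkey")
                ax.plot(fh.s_grid, fh.samples, "--", label=f"{cond} human")
            ax.axhline(0.5, color="gray", lw=0.5)
            ax.set_xlabel("s (flipped for human)")
            ax.set_ylabel("D(s)")
            ax.legend(fontsize=6)
            fig.savefig(fig_dir / "tuning.png", dpi=100)
            plt.close(fig)
            lines.append("![Tuning functions](figures/tuning.png)")
    lines.append("")
    if "equilibration" in manifest.summary:
        eq = manifest.summary["equilibration"]
        lines.append(
            f"Equilibration ({cfg['equilibrate']['measure']}): grid SD "
            f"{eq['grid_sd_before']:.3g} → {eq['grid_sd_after']:.3g} "
            f"({eq['sd_reduction_percent']:.1f}% reduction)."
        )
    if "q_percent" in manifest.summary:
        lines.append(
            f"Variance ratio across conditions: q = {manifest.summary['q_percent']:.3g}%; "
            f"{manifest.summary['n_significant_cells']} lattice cells significantly "
            f"different after Bonferroni correction."
        )
    if "stepwise_selected" in manifest.summary:
        lines.append(f"Stepwise selection kept: {manifest.summary['stepwise_selected']}.")
    if manifest.warnings:
        lines.append("")
        lines.append("Warnings: " + "; ".join(manifest.warnings))
    (out / "report.md").write_text("\n".join(lines) + "\n")


def validate_inputs(paths: list[str | Path]) -> list[str]:
    """Schema checks on trajectory / response CSVs; returns diagnostics."""
    diags: list[str] = []
    for p in map(Path, paths):
        if not p.exists():
            diags.append(f"{p}: file not found")
            continue
        try:
            df = pd.read_csv(p)
        except Exception as err:
            diags.append(f"{p}: unreadable ({err})")
            continue
        cols = set(df.columns)
        if {"frame", "marker_id", "x", "y", "z"} <= cols:
            per_frame = df.groupby("frame")["marker_id"].nunique()
            if per_frame.nunique() > 1:
                diags.append(f"{p}: marker count varies across frames")
            if df[["x", "y", "z"]].isna().any().any():
                diags.append(f"{p}: missing coordinate values")
        elif {"participant_id", "avatar", "view_deg", "e", "s", "rep", "response_class"} <= cols:
            bad = df.index[~df["response_class"].isin([1, 2, 3, 4])]
            for i in bad[:5]:
                diags.append(f"{p}: response_class out of range in row {i}")
            es = df[["e", "s"]].drop_duplicates()
            for axis in ("e", "s"):
                vals = np.sort(es[axis].unique())
                if len(vals) >= 2:
                    expected = np.linspace(vals.min(), vals.max(), len(vals))
                    if not np.allclose(vals, expected, atol=1e-9):
                        diags.append(f"{p}: {axis} values are not an equidistant lattice")
            lattice = {(a, b) for a in es["e"].unique() for b in es["s"].unique()}
            present = set(map(tuple, es.to_numpy()))
            for cell in sorted(lattice - present):
                diags.append(f"{p}: missing lattice cell (e={cell[0]}, s={cell[1]})")
        else:
            diags.append(f"{p}: unrecognized schema (columns {sorted(cols)[:8]})")
    return diags
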