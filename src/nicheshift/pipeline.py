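"""End-to-end orchestration: scene -> strata -> counts -> fits -> projections.

A single :class:`RunConfig` drives the whole analysis; every randomized
stage receives an explicit seed and the effective configuration is echoed
into the run directory, alongside a JSON manifest of all artifacts with
content hashes (so reruns can be verified byte-for-byte).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic_scene as scene_mod
from .abundance_model import (CLIMATE_COVARIATES, climate_optimum, compare_aic,
                              fit_covariate_suite, nakagawa_r2, wald_table)
from .range_projection import run_scenarios
from .spatial_diagnostics import has_spatial_dependence, pearson_residuals, spline_correlogram
from .survey_data import build_count_table, survey_summary
from .synthetic_scene import DEFAULT_SCENARIOS, SceneSpec, shift_future_climate

log = logging.getLogger("nicheshift")

__all__ = ["RunConfig", "run_pipeline", "write_report"]


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    out_dir: str
    seed: int = 0
    scene: SceneSpec = field(default_factory=SceneSpec)
    species: tuple[str, ...] = ("marula", "knobthorn")
    size_classes: tuple[str, ...] = ("adult", "young")
    covariates: tuple[str, ...] = tuple(CLIMATE_COVARIATES)
    count_mode: str = "offset"
    prediction_level: str = "population"
    presence_threshold: float = 1.0
    scenarios: dict = field(default_factory=lambda: dict(DEFAULT_SCENARIOS))
    n_boot: int = 500
    nodes: int = 15

    def __post_init__(self) -> None:
        if self.count_mode not in ("paper", "offset"):
            raise ValueError("count_mode must be 'paper' or 'offset'")
        if self.prediction_level not in ("population", "marginal"):
            raise ValueError("prediction_level must be 'population' or 'marginal'")
        if self.presence_threshold < 0:
            raise ValueError("presence threshold must be non-negative")
        for label, (dt, pf) in self.scenarios.items():
            if pf < 0:
                raise ValueError(f"scenario {label!r}: precipitation factor must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "scene" in raw:
            raw["scene"] = SceneSpec(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in raw["scene"].items()
            })
        if "scenarios" in raw:
            raw["scenarios"] = {k: tuple(v) for k, v in raw["scenarios"].items()}
        for key in ("species", "size_classes", "covariates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage in order; halt with a stage-named error on failure.

    Stages: simulate -> stratify (inside the scene) -> counts -> fit suite ->
    compare -> project baseline -> scenarios -> diagnostics -> manifest.
    Returns the run directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    artifacts: list[Path] = [out / "config.yaml"]

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("simulate")
        spec = dataclasses.replace(config.scene, seed=config.seed)
        sc = scene_mod.make_scene(spec)
        sc.write(out / "scene")
        artifacts += sorted((out / "scene").rglob("*.*"))
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    try:
        stage("counts")
        table = build_count_table(sc.records, sc.design, sc.stack, mode=config.count_mode)
        table.to_csv(out / "counts.csv", index=False)
        artifacts.append(out / "counts.csv")
        summaries = survey_summary(table)
        (out / "survey_summary.json").write_text(
            json.dumps([dataclasses.asdict(s) for s in summaries], indent=2, default=float))
        artifacts.append(out / "survey_summary.json")
    except Exception as exc:
        raise RuntimeError(f"stage 'counts' failed: {exc}") from exc

    fits_by_response: dict[tuple[str, str], list] = {}
    best_fits: dict[tuple[str, str], object] = {}
    try:
        stage("fit")
        (out / "fits").mkdir(exist_ok=True)
        comp_rows = []
        for sp in config.species:
            for cls in config.size_classes:
                fits = fit_covariate_suite(sp, cls, table, list(config.covariates),
                                           mode=config.count_mode, nodes=config.nodes)
                fits_by_response[(sp, cls)] = fits
                comp = compare_aic(fits)
                comp.insert(0, "size_class", cls)
                comp.insert(0, "species", sp)
                comp_rows.append(comp)
                best = fits[int(np.argmin([f.aic for f in fits]))]
                best_fits[(sp, cls)] = best
                for f in fits:
                    (out / "fits" / f"{sp}_{cls}_{f.spec.covariate}.json").write_text(
                        json.dumps(f.to_dict(), indent=2))
        comparison = pd.concat(comp_rows, ignore_index=True)
        comparison.to_csv(out / "model_comparison.csv", index=False)
        artifacts += sorted((out / "fits").glob("*.json")) + [out / "model_comparison.csv"]
    except Exception as exc:
        raise RuntimeError(f"stage 'fit' failed: {exc}") from exc

    try:
        stage("inference")
        rows = []
        for (sp, cls), fit in best_fits.items():
            opt = climate_optimum(fit)
            try:
                r2m, r2c = nakagawa_r2(fit, table)
            except ValueError:
                r2m = r2c = float("nan")
            rows.append({
                "species": sp, "size_class": cls, "covariate": fit.spec.covariate,
                "aic": fit.aic, "optimum": opt["optimum"], "optimum_se": opt["se"],
                "monotone": opt["monotone"], "r2_marginal": r2m, "r2_conditional": r2c,
                "converged": fit.converged,
            })
            wald_table(fit).to_csv(out / "fits" / f"wald_{sp}_{cls}.csv", index=False)
            artifacts.append(out / "fits" / f"wald_{sp}_{cls}.csv")
        pd.DataFrame(rows).to_csv(out / "best_models.csv", index=False)
        artifacts.append(out / "best_models.csv")
    except Exception as exc:
        raise RuntimeError(f"stage 'inference' failed: {exc}") from exc

    try:
        stage("project")
        surf_dir = out / "surfaces"
        surf_dir.mkdir(exist_ok=True)
        from .range_projection import (binarize_presence, project_abundance,
                                       recruitment_change)

        presences: dict[tuple[str, str], object] = {}
        for (sp, cls), fit in best_fits.items():
            surf = project_abundance(fit, sc.stack, level=config.prediction_level)
            surf.raster.write_ascii(surf_dir / f"abundance_{sp}_{cls}.asc")
            pres = binarize_presence(surf, config.presence_threshold)
            pres.raster.write_ascii(surf_dir / f"presence_{sp}_{cls}.asc")
            presences[(sp, cls)] = pres
        for sp in config.species:
            if ("young" in config.size_classes) and ("adult" in config.size_classes):
                cm = recruitment_change(presences[(sp, "young")], presences[(sp, "adult")])
                cm.raster.write_ascii(surf_dir / f"change_{sp}.asc")
        artifacts += sorted(surf_dir.glob("*.asc")) + sorted(surf_dir.glob("*.json"))
    except Exception as exc:
        raise RuntimeError(f"stage 'project' failed: {exc}") from exc

    try:
        stage("scenarios")
        stacks = {"baseline": sc.stack}
        for label, (dt, pf) in config.scenarios.items():
            stacks[label] = shift_future_climate(sc.stack, dt, pf, label=label)
        area_table = run_scenarios(
            {k: v for k, v in best_fits.items()}, stacks,
            threshold=config.presence_threshold, level=config.prediction_level,
        )
        area_table.to_csv(out / "area_table.csv", index=False)
        artifacts.append(out / "area_table.csv")
    except Exception as exc:
        raise RuntimeError(f"stage 'scenarios' failed: {exc}") from exc

    try:
        stage("diagnostics")
        diag = {}
        for (sp, cls), fit in best_fits.items():
            resid = pearson_residuals(fit, table)
            sub = table[(table["species"] == sp)]
            if cls != "total":
                sub = sub[sub["size_class"] == cls]
            sub = sub.sort_values(["grid_id", "transect_id"])
            coords = sub[["mid_x", "mid_y"]].to_numpy()
            cg = spline_correlogram(resid, coords, n_boot=config.n_boot,
                                    seed=config.seed + 17)
            flag, report = has_spatial_dependence(cg, short_range_m=cg.distances[-1] / 2)
            diag[f"{sp}:{cls}"] = {"spatial_dependence": flag, **report}
            pd.DataFrame({
                "distance_m": cg.distances, "estimate": cg.estimate,
                "lower": cg.lower, "upper": cg.upper,
            }).to_csv(out / f"correlogram_{sp}_{cls}.csv", index=False)
            artifacts.append(out / f"correlogram_{sp}_{cls}.csv")
        (out / "diagnostics.json").write_text(json.dumps(diag, indent=2))
        artifacts.append(out / "diagnostics.json")
    except Exception as exc:
        raise RuntimeError(f"stage 'diagnostics' failed: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "artifacts": {str(p.relative_to(out)): _sha256(p) for p in artifacts if p.is_file()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def write_report(run_dir: str | Path) -> Path:
    """Render a Markdown report of a completed run (idempotent)."""
    run_dir = Path(run_dir)
    for required in ("best_models.csv", "model_comparison.csv", "area_table.csv",
                     "diagnostics.json"):
        if not (run_dir / required).exists():
            raise FileNotFoundError(f"incomplete run: {required} missing")
    best = pd.read_csv(run_dir / "best_models.csv")
    comp = pd.read_csv(run_dir / "model_comparison.csv")
    areas = pd.read_csv(run_dir / "area_table.csv")
    diag = json.loads((run_dir / "diagnostics.json").read_text())

    lines = ["# Range-shift analysis report", ""]
    lines += ["## Best models and climatic optima", ""]
    for _, r in best.iterrows():
        if pd.notna(r["optimum"]):
            se = f" (SE {r['optimum_se']:.2f})" if pd.notna(r["optimum_se"]) else ""
            opt = f"optimum at {r['optimum']:.2f}{se}"
        else:
            opt = f"no interior optimum (response {r['monotone']})"
        lines.append(
            f"- **{r['species']} {r['size_class']}** ~ {r['covariate']}: {opt}; "
            f"AIC {r['aic']:.1f}, R2m {r['r2_marginal']:.2f}, R2c {r['r2_conditional']:.2f}"
        )
    lines += ["", "## Model comparison (delta AIC)", "", comp.to_markdown(index=False)]
    lines += ["", "## Gained / lost recruitment area (km2)", "", areas.to_markdown(index=False)]

    lines += ["", "## Range overlap and decoupling", ""]
    base = areas[areas["scenario"] == "baseline"]
    for sp, sub in base.groupby("species"):
        gained = float(sub.loc[sub.category == "gained", "area_km2"].iloc[0])
        lost = float(sub.loc[sub.category == "lost", "area_km2"].iloc[0])
        init = float(sub["initial_area_km2"].iloc[0])
        co = init - lost
        lines.append(
            f"- **{sp}**: adult range {init:.1f} km2, seedling/adult overlap "
            f"{co:.1f} km2, gained {gained:.1f} km2, lost {lost:.1f} km2 "
            f"({100 * lost / init if init else float('nan'):.0f}% of initial)"
        )
    lines += ["", "## Spatial diagnostics", ""]
    for key, rep in diag.items():
        verdict = "spatial dependence detected" if rep["spatial_dependence"] \
            else "no evidence of spatial dependence"
        lines.append(f"- {key}: {verdict} (band level {rep['level']:.0%})")
    report = run_dir / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report
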