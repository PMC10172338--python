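"""Suitability surfaces, presence maps, and recruitment-change accounting.

A fitted abundance model is projected per-pixel onto a climate raster,
thresholded into presence/absence, and the seedling surface is differenced
against the adult surface: pixels with seedlings but no adults are *Gained*
(the regeneration niche extends beyond the realized adult niche), pixels
with adults but no seedlings are *Lost*.  Areas come from pixel counts in a
projected CRS.  A scenario runner repeats the whole chain under shifted
climates and assembles the gained/lost area table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance_model import FitResult, predict_expected
from .rasters import ClimateStack, Raster

__all__ = [
    "CHANGE_CLASSES",
    "AbundanceSurface",
    "PresenceSurface",
    "ChangeMap",
    "AreaSummary",
    "project_abundance",
    "binarize_presence",
    "recruitment_change",
    "summarize_areas",
    "run_scenarios",
]

#: integer codes of the change map; classes partition all non-missing pixels
CHANGE_CLASSES = {"absent": 0, "gained": 1, "lost": 2, "co_occur": 3}


@dataclass
class AbundanceSurface:
    raster: Raster
    fit_label: str
    scenario: str
    level: str  # prediction mode


@dataclass
class PresenceSurface:
    raster: Raster  # values in {0,1} plus NaN
    threshold: float
    fit_label: str = ""
    scenario: str = ""

    def area_km2(self) -> float:
        return float(np.nansum(self.raster.data)) * self.raster.pixel_area_km2


@dataclass
class ChangeMap:
    raster: Raster  # CHANGE_CLASSES codes, NaN missing
    provenance: dict = field(default_factory=dict)

    def class_mask(self, name: str) -> np.ndarray:
        return self.raster.data == CHANGE_CLASSES[name]


@dataclass
class AreaSummary:
    pixel_counts: dict[str, int]
    areas_km2: dict[str, float]
    initial_area_km2: float
    ratios_pct: dict[str, float]  # class area as % of the initial adult range

    def printed(self, cls: str) -> str:
        """Area to one decimal km2 and integer percent, as reported tables do."""
        return f"{self.areas_km2[cls]:.1f} km2 (~ {round(self.ratios_pct[cls]):d}%)"


def project_abundance(
    fit: FitResult,
    stack: ClimateStack,
    scenario_label: str = "baseline",
    level: str = "population",
) -> AbundanceSurface:
    """Per-pixel expected abundance from the fit's covariate layer.

    Missing climate propagates to missing prediction.  Projection suppresses
    the extrapolation warning guard — scenario climates intentionally extend
    beyond the sampled range — but the provenance records the fitted range.
    """
    if fit.spec.covariate not in stack:
        raise KeyError(f"covariate layer {fit.spec.covariate!r} absent from stack")
    layer = stack[fit.spec.covariate]
    pred = np.full(layer.shape, np.nan)
    ok = np.isfinite(layer.data)
    pred[ok] = predict_expected(fit, layer.data[ok], level=level,
                                extrapolation_guard=np.inf)
    return AbundanceSurface(
        raster=layer.like(pred, units="expected count / transect"),
        fit_label=fit.spec.label, scenario=scenario_label, level=level,
    )


def binarize_presence(surface: AbundanceSurface, threshold: float = 1.0) -> PresenceSurface:
    """Presence iff predicted abundance >= threshold (default: one expected
    individual per reference transect strip).  Idempotent for thresholds in
    (0, 1] when re-applied to its own output."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    data = surface.raster.data
    out = np.where(np.isfinite(data), (data >= threshold).astype(float), np.nan)
    return PresenceSurface(
        raster=surface.raster.like(out, units="presence"),
        threshold=threshold, fit_label=surface.fit_label, scenario=surface.scenario,
    )


def recruitment_change(seedling: PresenceSurface, adult: PresenceSurface) -> ChangeMap:
    """Difference the seedling and adult presence surfaces into change classes.

    gained = seedling & ~adult, lost = adult & ~seedling, co_occur = both,
    absent = neither; missing wherever either input is missing.
    """
    if not seedling.raster.same_grid(adult.raster):
        raise ValueError("presence surfaces are not co-registered")
    s, a = seedling.raster.data, adult.raster.data
    ok = np.isfinite(s) & np.isfinite(a)
    out = np.full(s.shape, np.nan)
    sb, ab = s == 1, a == 1
    out[ok] = CHANGE_CLASSES["absent"]
    out[ok & sb & ~ab] = CHANGE_CLASSES["gained"]
    out[ok & ~sb & ab] = CHANGE_CLASSES["lost"]
    out[ok & sb & ab] = CHANGE_CLASSES["co_occur"]
    return ChangeMap(
        raster=seedling.raster.like(out, units="change class"),
        provenance={"seedling": seedling.fit_label, "adult": adult.fit_label,
                    "threshold": seedling.threshold, "scenario": seedling.scenario},
    )


def summarize_areas(
    change: ChangeMap,
    pixel_area_km2: float | None = None,
    initial_area_km2: float | None = None,
) -> AreaSummary:
    """Pixel counts and km2 per change class, plus ratios to the initial range.

    ``initial_area_km2`` is the baseline adult-range area; by default it is
    reconstructed from the map itself (lost + co_occur = adult presence).
    """
    if pixel_area_km2 is None:
        pixel_area_km2 = change.raster.pixel_area_km2
    if pixel_area_km2 <= 0:
        raise ValueError("pixel area must be positive")
    counts = {name: int(np.nansum(change.raster.data == code))
              for name, code in CHANGE_CLASSES.items()}
    areas = {name: c * pixel_area_km2 for name, c in counts.items()}
    if initial_area_km2 is None:
        initial_area_km2 = areas["lost"] + areas["co_occur"]
    ratios = {
        name: (100.0 * a / initial_area_km2 if initial_area_km2 > 0 else float("nan"))
        for name, a in areas.items()
    }
    return AreaSummary(pixel_counts=counts, areas_km2=areas,
                       initial_area_km2=float(initial_area_km2), ratios_pct=ratios)


def run_scenarios(
    fits: dict[tuple[str, str], FitResult],
    scenarios: dict[str, ClimateStack],
    baseline: str = "baseline",
    threshold: float = 1.0,
    level: str = "population",
    compare: str = "within",
) -> pd.DataFrame:
    """Project every species under every scenario and account gained/lost areas.

    ``fits`` maps (species, size_class in {"young", "adult"}) to a FitResult.
    Under the default ``compare="within"`` the seedling surface is differenced
    against the adult surface *of the same scenario*; ``compare="baseline"``
    differences each scenario's seedling surface against the baseline adult
    surface instead.  Initial (denominator) areas are the baseline adult
    ranges, computed once.

    Returns one row per species x scenario x {gained, lost} with columns
    species, scenario, category, area_km2, pct_of_initial, threshold.
    """
    if baseline not in scenarios:
        raise ValueError(f"scenario set lacks the baseline {baseline!r}")
    if compare not in ("within", "baseline"):
        raise ValueError("compare must be 'within' or 'baseline'")
    species = sorted({sp for sp, _ in fits})
    for sp in species:
        for cls in ("young", "adult"):
            if (sp, cls) not in fits:
                raise ValueError(f"missing fit for ({sp!r}, {cls!r})")

    def presence(sp, cls, label):
        fit = fits[(sp, cls)]
        stack = scenarios[label]
        return binarize_presence(
            project_abundance(fit, stack, scenario_label=label, level=level), threshold
        )

    initial = {sp: presence(sp, "adult", baseline).area_km2() for sp in species}
    rows = []
    order = [baseline] + [s for s in scenarios if s != baseline]
    for sp in species:
        base_adult = presence(sp, "adult", baseline)
        for label in order:
            seed = presence(sp, "young", label)
            adult = base_adult if (compare == "baseline" and label != baseline) \
                else presence(sp, "adult", label)
            summary = summarize_areas(recruitment_change(seed, adult),
                                      initial_area_km2=initial[sp])
            for cat in ("gained", "lost"):
                rows.append({
                    "species": sp, "scenario": label, "category": cat,
                    "area_km2": summary.areas_km2[cat],
                    "pct_of_initial": summary.ratios_pct[cat],
                    "initial_area_km2": initial[sp],
                    "threshold": threshold,
                })
    return pd.DataFrame(rows)
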