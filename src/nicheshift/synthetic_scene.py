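"""Synthetic landscapes, survey designs and tree records.

Emulates a small-country savanna field study: two correlated climate
gradients over a rectangular landscape, a savanna land-cover mask, grids of
three 400 m transects stratified along the gradient, and per-transect
zero-inflated negative-binomial counts of two species x two size classes
with hump-shaped (quadratic, log-link) responses to climate and grid-level
random intercepts.

Everything is driven by a :class:`SceneSpec` plus a seed; the same spec and
seed reproduce the scene bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .rasters import ClimateStack, Raster, layer_kind
from .survey_data import classify_size_class

__all__ = [
    "TruthParams",
    "SceneSpec",
    "SurveyDesign",
    "SyntheticScene",
    "make_climate_stack",
    "make_landcover",
    "place_grids",
    "simulate_trees",
    "shift_future_climate",
    "make_scene",
    "DEFAULT_SCENARIOS",
    "default_truth",
]

SAVANNA = 1
NON_SAVANNA = 0

#: named climate-change scenarios: (delta_T degC, precipitation factor).
#: RCP8.5 values are the projected Eswatini means (+2.3 degC / -3.4% by
#: mid-century, +4.4 degC / -8.7% by late century); RCP4.5 values are set to
#: roughly two-thirds of the RCP8.5 signal, typical of downscaled regional
#: means for southern Africa.
DEFAULT_SCENARIOS: dict[str, tuple[float, float]] = {
    "rcp45_2041_2070": (1.5, 0.978),
    "rcp85_2041_2070": (2.3, 0.966),
    "rcp45_2071_2100": (2.9, 0.942),
    "rcp85_2071_2100": (4.4, 0.913),
}


@dataclass
class TruthParams:
    """Generative parameters for one species x size class response.

    The mean count on a full-width transect strip is
    ``exp(beta0 + beta1*x + beta2*x**2 + u_g)`` with ``beta1 = -2*beta2*x_opt``,
    so ``x_opt`` is the covariate value of peak abundance and ``beta2 < 0``
    sets how sharply abundance falls away from it.
    """

    species: str
    size_class: str  # "adult" | "young"
    beta0: float  # log mean count at x = x_opt minus beta2*x_opt**2 ... intercept, log scale
    x_opt: float  # covariate units (e.g. degC)
    beta2: float  # curvature, < 0 for a hump-shaped response
    sigma_u: float = 0.0  # SD of the grid random intercept
    theta: float = 1.5  # NB dispersion (var = mu + mu^2/theta)
    pi: float = 0.0  # structural-zero probability
    covariate: str = "annual_mean_temp"

    def __post_init__(self) -> None:
        if self.beta2 >= 0:
            raise ValueError("an optimum requires beta2 < 0")
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must lie in [0, 1]")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be non-negative")

    @property
    def beta1(self) -> float:
        return -2.0 * self.beta2 * self.x_opt

    def mean_at(self, x: np.ndarray | float, u: float = 0.0) -> np.ndarray | float:
        return np.exp(self.beta0 + self.beta1 * np.asarray(x) + self.beta2 * np.asarray(x) ** 2 + u)


@dataclass
class SceneSpec:
    """Landscape + survey-design parameters (a stated world, not a dial)."""

    extent_m: tuple[float, float] = (100_000.0, 100_000.0)  # (width, height)
    pixel_size_m: float = 1000.0
    temp_endpoints: tuple[float, float] = (14.0, 26.0)  # degC, west -> east
    precip_endpoints: tuple[float, float] = (600.0, 1400.0)  # mm (low, high)
    temp_precip_corr: float = -0.85  # hotter lowveld is drier
    noise_scale: float = 0.15  # SD of pixel noise on the unit gradient
    savanna_fraction: float = 0.8
    grids_per_stratum: int = 7  # 6-8 in the field design; 40 grids total
    min_grid_separation_m: float = 10_000.0
    transects_per_grid: int = 3
    transect_length_m: float = 400.0
    transect_spacing_m: float = 200.0
    strip_width_young_m: float = 2.0  # 1 m either side for trees < 1 m
    strip_width_adult_m: float = 40.0  # 20 m either side
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_m <= 0:
            raise ValueError("pixel size must be positive")
        for name in ("transect_length_m", "transect_spacing_m",
                     "strip_width_young_m", "strip_width_adult_m",
                     "min_grid_separation_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.savanna_fraction <= 1.0:
            raise ValueError("savanna fraction must lie in [0, 1]")
        if not -1.0 <= self.temp_precip_corr <= 1.0:
            raise ValueError("correlation must lie in [-1, 1]")


@dataclass
class SurveyDesign:
    """Placed sampling grids and their transects."""

    grids: pd.DataFrame  # grid_id, stratum, cx, cy
    transects: pd.DataFrame  # transect_id, grid_id, x0, y0, x1, y1, mid_x, mid_y
    species: tuple[str, ...] = ("marula", "knobthorn")

    @property
    def n_grids(self) -> int:
        return len(self.grids)

    def min_pairwise_separation(self) -> float:
        from scipy.spatial.distance import pdist

        pts = self.grids[["cx", "cy"]].to_numpy()
        return float(pdist(pts).min()) if len(pts) > 1 else np.inf

    def to_geojson(self) -> dict:
        feats = []
        for _, g in self.grids.iterrows():
            feats.append({
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [g.cx, g.cy]},
                "properties": {"grid_id": g.grid_id, "stratum": int(g.stratum), "kind": "grid"},
            })
        for _, t in self.transects.iterrows():
            feats.append({
                "type": "Feature",
                "geometry": {"type": "LineString",
                             "coordinates": [[t.x0, t.y0], [t.x1, t.y1]]},
                "properties": {"transect_id": t.transect_id, "grid_id": t.grid_id,
                               "kind": "transect"},
            })
        return {"type": "FeatureCollection", "features": feats}


@dataclass
class SyntheticScene:
    """A fully simulated landscape + survey, ready for the analysis stages."""

    spec: SceneSpec
    stack: ClimateStack
    landcover: Raster
    savanna_mask: Raster
    strata: "object"  # StrataMap
    design: SurveyDesign
    records: pd.DataFrame
    truth: list[TruthParams]
    seed: int

    def provenance(self) -> dict:
        return {"scene_spec": asdict(self.spec), "seed": self.seed,
                "truth": [asdict(t) for t in self.truth]}

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.stack.write(directory / "climate")
        self.landcover.write_ascii(directory / "landcover.asc")
        self.savanna_mask.write_ascii(directory / "savanna_mask.asc")
        self.records.to_csv(directory / "tree_records.csv", index=False)
        self.design.grids.to_csv(directory / "grids.csv", index=False)
        self.design.transects.to_csv(directory / "transects.csv", index=False)
        (directory / "design.geojson").write_text(json.dumps(self.design.to_geojson()))
        import yaml

        (directory / "provenance.yaml").write_text(yaml.safe_dump(self.provenance()))


# ---------------------------------------------------------------------------
# landscape generation
# ---------------------------------------------------------------------------

def make_climate_stack(spec: SceneSpec, seed: int | None = None) -> ClimateStack:
    """Correlated temperature/precipitation gradients plus derived layers.

    Annual mean temperature follows a west-east linear gradient spanning the
    requested endpoints exactly when ``noise_scale`` is zero.  Annual
    precipitation is a correlated field: a mixture of the standardized
    temperature field and independent noise tuned to the requested
    correlation, rescaled to span the precipitation endpoints.  The other
    four bioclim-style layers are affine functions of these two plus small
    noise; their recipes are recorded on the stack so scenario shifts can
    propagate.
    """
    t0, t1 = spec.temp_endpoints
    if t0 == t1:
        raise ValueError("temperature endpoints must differ")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    ncol = int(round(spec.extent_m[0] / spec.pixel_size_m))
    nrow = int(round(spec.extent_m[1] / spec.pixel_size_m))
    if ncol < 2 or nrow < 2:
        raise ValueError("landscape too small for the requested pixel size")

    g = np.tile(np.linspace(0.0, 1.0, ncol), (nrow, 1))  # west -> east ramp
    noise_t = rng.standard_normal((nrow, ncol))
    temp_raw = g + spec.noise_scale * noise_t
    temp = _rescale(temp_raw, t0, t1)

    p_lo, p_hi = sorted(spec.precip_endpoints)
    rho = spec.temp_precip_corr
    t_std = (temp_raw - temp_raw.mean()) / temp_raw.std()
    if spec.noise_scale > 0:
        h = rng.standard_normal((nrow, ncol))
        h = (h - h.mean()) / h.std()
        mix = rho * t_std + np.sqrt(max(0.0, 1.0 - rho**2)) * h
    else:  # degenerate noiseless case: perfectly (anti)correlated
        mix = np.sign(rho if rho != 0 else 1.0) * t_std
    precip = _rescale(mix, p_lo, p_hi)

    origin = (0.0, spec.extent_m[1])
    px = spec.pixel_size_m

    def ras(data, units):
        return Raster(data=data, origin=origin, pixel_size=px, units=units)

    # derived-layer noise keeps inter-covariate correlations in the realistic
    # 0.6-1.0 band (perfect collinearity would make model selection vacuous);
    # proportional to noise_scale so a noiseless spec gives exact affine layers
    sc = spec.noise_scale / 0.15 if spec.noise_scale > 0 else 0.0
    layers = {
        "annual_mean_temp": ras(temp, "degC"),
        "annual_precip": ras(precip, "mm"),
        "max_temp_warmest_month": ras(temp + 8.0 + 1.0 * sc * rng.standard_normal(temp.shape), "degC"),
        "min_temp_coldest_month": ras(temp - 12.0 + 1.2 * sc * rng.standard_normal(temp.shape), "degC"),
        "precip_wettest_month": ras(0.22 * precip + 35.0 * sc * rng.standard_normal(temp.shape), "mm"),
        "pet": ras(55.0 * temp + 0.15 * precip + 250.0
                   + 60.0 * sc * rng.standard_normal(temp.shape), "mm"),
    }
    derived = {
        "max_temp_warmest_month": {"annual_mean_temp": 1.0},
        "min_temp_coldest_month": {"annual_mean_temp": 1.0},
        "precip_wettest_month": {"annual_precip": 0.22},
        "pet": {"annual_mean_temp": 55.0, "annual_precip": 0.15},
    }
    return ClimateStack(layers=layers, derived=derived,
                        meta={"scenario": "baseline", "seed": int(spec.seed if seed is None else seed)})


def _rescale(arr: np.ndarray, lo: float, hi: float) -> np.ndarray:
    a, b = arr.min(), arr.max()
    return lo + (hi - lo) * (arr - a) / (b - a)


def make_landcover(spec: SceneSpec, stack: ClimateStack, seed: int | None = None) -> Raster:
    """Categorical savanna / non-savanna raster at the requested cover fraction.

    Non-savanna patches are seeded as random blobs (smoothed noise threshold)
    so the mask has spatial structure rather than salt-and-pepper holes.
    """
    frac = spec.savanna_fraction
    if not 0.0 <= frac <= 1.0:
        raise ValueError("savanna fraction must lie in [0, 1]")
    rng = np.random.default_rng((spec.seed if seed is None else seed) + 1)
    grid = stack.grid
    shape = grid.shape
    if frac >= 1.0:
        data = np.full(shape, SAVANNA, dtype=float)
    elif frac <= 0.0:
        data = np.full(shape, NON_SAVANNA, dtype=float)
    else:
        from scipy.ndimage import gaussian_filter

        noise = gaussian_filter(rng.standard_normal(shape), sigma=2.0)
        cut = np.quantile(noise, 1.0 - frac)
        data = np.where(noise >= cut, SAVANNA, NON_SAVANNA).astype(float)
    return grid.like(data, units="class")


# ---------------------------------------------------------------------------
# survey design
# ---------------------------------------------------------------------------

def place_grids(
    strata_map,
    mask: Raster,
    spec: SceneSpec,
    strata_labels: list[int] | None = None,
    seed: int | None = None,
    max_retries: int = 10_000,
) -> SurveyDesign:
    """Rejection-sample grid centroids per stratum under the separation rule.

    Each grid hosts ``transects_per_grid`` parallel north-south transects of
    ``transect_length_m`` spaced ``transect_spacing_m`` apart, centred on the
    grid centroid; every transect endpoint and midpoint must fall in masked
    savanna cells.  Raises after ``max_retries`` failed draws — deterministic
    failure beats a silent violation of the separation rule.
    """
    if not strata_map.labels.same_grid(mask):
        raise ValueError("strata map and mask must share the climate grid")
    rng = np.random.default_rng((spec.seed if seed is None else seed) + 2)
    labels = strata_map.labels.data
    masked = mask.data == 1
    if strata_labels is None:
        from .climate_gradient import sampleable_strata

        strata_labels = sampleable_strata(strata_map, mask)
        if not strata_labels:
            raise ValueError("no sampleable area: no stratum fits a grid footprint")
    half_len = spec.transect_length_m / 2.0
    offsets = (np.arange(spec.transects_per_grid) - (spec.transects_per_grid - 1) / 2.0) \
        * spec.transect_spacing_m

    px = mask.pixel_size
    centers: list[tuple[float, float, int]] = []
    for stratum in strata_labels:
        cells = np.argwhere((labels == stratum) & masked)
        if cells.size == 0:
            raise ValueError(f"stratum {stratum} has no sampleable (savanna) area")
        placed = 0
        tries = 0
        while placed < spec.grids_per_stratum:
            tries += 1
            if tries > max_retries:
                raise RuntimeError(
                    f"could not place {spec.grids_per_stratum} grids in stratum "
                    f"{stratum} after {max_retries} tries "
                    f"(separation {spec.min_grid_separation_m} m may be infeasible)"
                )
            row, col = cells[rng.integers(len(cells))]
            cx = mask.origin[0] + (col + rng.random()) * px
            cy = mask.origin[1] - (row + rng.random()) * px
            if not _footprint_ok(cx, cy, offsets, half_len, mask):
                continue
            if any((cx - ox) ** 2 + (cy - oy) ** 2 < spec.min_grid_separation_m**2
                   for ox, oy, _ in centers):
                continue
            centers.append((cx, cy, int(stratum)))
            placed += 1

    grids = pd.DataFrame(
        [{"grid_id": f"G{i + 1:02d}", "stratum": s, "cx": cx, "cy": cy}
         for i, (cx, cy, s) in enumerate(centers)]
    )
    t_rows = []
    for _, grow in grids.iterrows():
        for j, off in enumerate(offsets):
            x = grow.cx + off
            t_rows.append({
                "transect_id": f"{grow.grid_id}-T{j + 1}",
                "grid_id": grow.grid_id,
                "x0": x, "y0": grow.cy - half_len,
                "x1": x, "y1": grow.cy + half_len,
                "mid_x": x, "mid_y": grow.cy,
            })
    return SurveyDesign(grids=grids, transects=pd.DataFrame(t_rows))


def _footprint_ok(cx, cy, offsets, half_len, mask: Raster) -> bool:
    for off in offsets:
        x = cx + off
        for y in (cy - half_len, cy, cy + half_len):
            try:
                row, col = mask.index_of(x, y)
            except IndexError:
                return False
            if mask.data[row, col] != 1:
                return False
    return True


# ---------------------------------------------------------------------------
# tree simulation
# ---------------------------------------------------------------------------

def simulate_trees(
    design: SurveyDesign,
    truth: list[TruthParams],
    stack: ClimateStack,
    spec: SceneSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw individual tree records from the generative ZINB model.

    For each grid a shared random intercept ``u_g ~ N(0, sigma_u^2)`` is
    drawn once per TruthParams entry; transect counts are zero-inflated
    negative binomial around ``exp(beta0 + beta1*x + beta2*x^2 + u_g)`` with
    ``x`` the named covariate at the transect midpoint.  Young-tree counts
    are generated on the narrow 2 m strip (expected value mu * 2/40), so the
    x20 detection correction is exercised downstream exactly as with field
    data.  Heights and stem diameters are drawn consistently with the
    generating size class.
    """
    spec = spec or SceneSpec()
    rng = np.random.default_rng(seed + 3)
    grid_ids = list(design.grids["grid_id"])
    rows: list[dict] = []
    for tp in truth:
        u_by_grid = dict(zip(grid_ids, rng.normal(0.0, tp.sigma_u, size=len(grid_ids))))
        strip = spec.strip_width_adult_m if tp.size_class == "adult" else spec.strip_width_young_m
        strip_factor = strip / spec.strip_width_adult_m
        for _, t in design.transects.iterrows():
            try:
                x = stack[tp.covariate].sample(t.mid_x, t.mid_y)
            except IndexError as exc:
                raise ValueError(
                    f"covariate {tp.covariate!r} missing at transect {t.transect_id!r}"
                ) from exc
            if np.isnan(x):
                raise ValueError(
                    f"covariate {tp.covariate!r} missing at transect {t.transect_id!r}")
            mu = float(tp.mean_at(x, u_by_grid[t.grid_id])) * strip_factor
            if rng.random() < tp.pi:
                n = 0
            else:
                lam = rng.gamma(shape=tp.theta, scale=mu / tp.theta)
                n = int(rng.poisson(lam))
            for _ in range(n):
                rows.append(_individual(tp, t, rng))
    cols = ["species", "size_class", "height_m", "stem_diam_cm",
            "transect_id", "grid_id", "x", "y"]
    return pd.DataFrame(rows, columns=cols)


def _individual(tp: TruthParams, transect, rng) -> dict:
    if tp.size_class == "adult":
        height = float(rng.uniform(3.0, 12.0))
        diam = float(rng.uniform(15.0, 80.0))
    else:  # narrow-strip seedlings: < 1 m tall, basal diameter
        height = float(rng.uniform(0.1, 0.95))
        diam = float(rng.uniform(0.2, 4.0))
    assert classify_size_class(height, diam) == tp.size_class
    frac = rng.random()
    return {
        "species": tp.species,
        "size_class": tp.size_class,
        "height_m": round(height, 2),
        "stem_diam_cm": round(diam, 1),
        "transect_id": transect.transect_id,
        "grid_id": transect.grid_id,
        "x": transect.x0 + frac * (transect.x1 - transect.x0),
        "y": transect.y0 + frac * (transect.y1 - transect.y0),
    }


# ---------------------------------------------------------------------------
# future climate
# ---------------------------------------------------------------------------

def shift_future_climate(
    stack: ClimateStack,
    delta_T: float,
    precip_factor: float,
    label: str = "scenario",
) -> ClimateStack:
    """Apply a uniform climate-change signal to a stack.

    Temperature-kind layers shift additively by ``delta_T``; precipitation
    -kind layers scale multiplicatively by ``precip_factor``; derived layers
    (PET, and any layer with a recorded affine recipe) are recomputed from
    the recipe deltas so their noise component is preserved.  Negative
    precipitation is clipped to zero with a warning.
    """
    import warnings

    out = stack.copy()
    deltas: dict[str, np.ndarray] = {}
    for name, r in out.layers.items():
        kind = layer_kind(name, r.units)
        if name in out.derived:
            continue  # handled below from recipes
        if kind == "temperature":
            deltas[name] = np.full(r.shape, delta_T)
        elif kind == "precipitation":
            deltas[name] = r.data * (precip_factor - 1.0)
    for name, recipe in out.derived.items():
        d = np.zeros(out.layers[name].shape)
        for base, coef in recipe.items():
            if base in deltas:
                d += coef * deltas[base]
            else:  # derived-of-derived not supported; base shifted by kind
                kind = layer_kind(base, out.layers[base].units if base in out.layers else "")
                if kind == "temperature":
                    d += coef * delta_T
        deltas[name] = d
    for name, d in deltas.items():
        r = out.layers[name]
        new = r.data + d
        if layer_kind(name, r.units) == "precipitation" and np.nanmin(new) < 0:
            warnings.warn(f"negative precipitation in {name!r} clipped to 0")
            new = np.clip(new, 0.0, None)
        out.layers[name] = r.like(new)
    out.meta = dict(out.meta, scenario=label, delta_T=delta_T, precip_factor=precip_factor)
    return out


# ---------------------------------------------------------------------------
# full scene
# ---------------------------------------------------------------------------

def default_truth() -> list[TruthParams]:
    """Default generative parameters for the two species x two size classes.

    Optima sit inside the simulated 16-24 degC annual-mean-temperature range.
    Marula's seedling optimum is 2 degC cooler than its adult optimum (the
    range-shift / decoupling signature); knobthorn's seedling optimum nearly
    coincides with its adult optimum but with a narrower, sparser seedling
    distribution (regeneration confined within the adult range).
    """
    return [
        TruthParams("marula", "adult", beta0=-43.7, x_opt=21.2, beta2=-0.10,
                    sigma_u=0.4, theta=1.5, pi=0.2),
        # seedlings dense at the peak but steeply curved, so the presence
        # band (on the reference-strip scale) is as wide as the adults' and
        # shifted 2 degC cooler
        TruthParams("marula", "young", beta0=-143.6, x_opt=19.2, beta2=-0.40,
                    sigma_u=0.5, theta=1.0, pi=0.25),
        TruthParams("knobthorn", "adult", beta0=-120.6, x_opt=22.1, beta2=-0.25,
                    sigma_u=0.4, theta=1.5, pi=0.2),
        # regeneration confined well inside the adult range: same optimum,
        # much narrower presence band
        TruthParams("knobthorn", "young", beta0=-389.5, x_opt=22.2, beta2=-0.80,
                    sigma_u=0.5, theta=1.0, pi=0.3),
    ]


def make_scene(
    spec: SceneSpec | None = None,
    truth: list[TruthParams] | None = None,
    n_strata: int | None = 6,
) -> SyntheticScene:
    """Generate a complete scene: climate, land cover, strata, design, trees."""
    from .climate_gradient import (discretize_gradient, focal_cover_filter,
                                   pca_gradient, sampleable_strata)

    spec = spec or SceneSpec()
    truth = truth if truth is not None else default_truth()
    stack = make_climate_stack(spec)
    landcover = make_landcover(spec, stack)
    if not (landcover.data == SAVANNA).any():
        raise ValueError("no sampleable area: landscape contains no savanna")
    mask = focal_cover_filter(landcover, SAVANNA, radius_m=1000.0, threshold=1.0)
    pca = pca_gradient(stack)
    strata = discretize_gradient(pca.pc1, bin_width=1.0)
    ok = sampleable_strata(strata, mask)
    masked = mask.data == 1
    px_km2 = mask.pixel_area_km2
    areas = {lab: ((strata.labels.data == lab) & masked).sum() * px_km2 for lab in ok}
    # a stratum must plausibly hold the requested grids at the separation
    # rule: ~0.5 * n * d^2 of masked area (loose hexagonal-packing bound)
    need_km2 = 0.5 * spec.grids_per_stratum * (spec.min_grid_separation_m / 1000.0) ** 2
    feasible = [lab for lab in ok if areas[lab] >= need_km2]
    if feasible:
        ok = feasible
    if n_strata is not None and len(ok) > n_strata:
        # keep the largest-area strata, in gradient order
        ok = sorted(sorted(ok, key=lambda l: -areas[l])[:n_strata])
    if not ok:
        raise ValueError("no sampleable area: savanna mask too restrictive")
    design = place_grids(strata, mask, spec, strata_labels=ok)
    records = simulate_trees(design, truth, stack, spec, seed=spec.seed)
    return SyntheticScene(
        spec=spec, stack=stack, landcover=landcover, savanna_mask=mask,
        strata=strata, design=design, records=records, truth=truth, seed=spec.seed,
    )
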