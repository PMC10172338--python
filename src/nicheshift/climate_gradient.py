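"""Climate gradient construction: PCA score surface, sampling strata, savanna mask.

The sampling design stratifies a landscape along a single synthetic axis of
temperature and precipitation.  The axis is the first principal component of
the standardized annual-mean-temperature and annual-precipitation layers;
its scores are discretized into unit-width bins to form strata, and a moving
-window land-cover filter restricts sampling to contiguous savanna.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rasters import ClimateStack, Raster

__all__ = [
    "PCAResult",
    "StrataMap",
    "standardize_layer",
    "pca_gradient",
    "discretize_gradient",
    "focal_cover_filter",
    "sampleable_strata",
]


@dataclass
class PCAResult:
    loadings: dict[str, np.ndarray]  # layer name -> loading vector per PC (columns = PCs)
    explained: np.ndarray  # variance fractions, non-increasing
    pc1: Raster  # PC1 score surface (unitless)

    def __post_init__(self) -> None:
        if not np.isclose(self.explained.sum(), 1.0, atol=1e-9):
            raise ValueError("explained variance fractions must sum to 1")
        if np.any(np.diff(self.explained) > 1e-12):
            raise ValueError("explained variance fractions must be non-increasing")


@dataclass
class StrataMap:
    labels: Raster  # integer labels from 1, NaN = unassigned
    edges: np.ndarray  # bin edges, len = n_strata + 1

    @property
    def n_strata(self) -> int:
        return len(self.edges) - 1

    def pixel_counts(self) -> dict[int, int]:
        vals = self.labels.data[np.isfinite(self.labels.data)].astype(int)
        return {int(k): int(v) for k, v in zip(*np.unique(vals, return_counts=True))}


def standardize_layer(layer: Raster) -> Raster:
    """Center/scale to mean 0, population SD 1 over non-missing cells."""
    vals = layer.data[np.isfinite(layer.data)]
    if vals.size < 2 or np.unique(vals).size < 2:
        raise ValueError("cannot standardize a constant (or empty) layer")
    sd = vals.std()  # population convention (ddof=0)
    return layer.like((layer.data - vals.mean()) / sd, units="z-score")


def pca_gradient(
    stack: ClimateStack,
    layer_names: tuple[str, str] = ("annual_mean_temp", "annual_precip"),
) -> PCAResult:
    """PCA of two standardized climate layers; PC1 scores as a raster.

    Standardization makes this a correlation PCA, appropriate because the
    inputs carry incommensurable units (degC vs mm).  Sign convention: the
    PC1 loading on the first (temperature) layer is non-negative, so higher
    scores always mean hotter.
    """
    a, b = layer_names
    za, zb = standardize_layer(stack[a]), standardize_layer(stack[b])
    ok = np.isfinite(za.data) & np.isfinite(zb.data)
    if not ok.any():
        raise ValueError("no overlapping non-missing cells")
    X = np.column_stack([za.data[ok], zb.data[ok]])
    X = X - X.mean(axis=0)
    cov = X.T @ X / X.shape[0]
    eigval, eigvec = np.linalg.eigh(cov)  # ascending
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if eigvec[0, 0] < 0:  # fix sign: temperature loading >= 0 on PC1
        eigvec[:, 0] *= -1
    if eigvec[0, 1] < 0:
        eigvec[:, 1] *= -1
    scores = np.full(za.data.shape, np.nan)
    scores[ok] = X @ eigvec[:, 0]
    frac = eigval / eigval.sum()
    return PCAResult(
        loadings={a: eigvec[0], b: eigvec[1]},
        explained=frac,
        pc1=za.like(scores, units="pc1-score"),
    )


def discretize_gradient(pc1: Raster, bin_width: float = 1.0) -> StrataMap:
    """Cut the continuous gradient into half-open bins of fixed width.

    Bins are anchored at the observed minimum score; the count is
    ceil(range / width) and the maximum value falls in the top bin.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    vals = pc1.data[np.isfinite(pc1.data)]
    if vals.size == 0:
        raise ValueError("gradient raster has no finite values")
    lo, hi = float(vals.min()), float(vals.max())
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width - 1e-12)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    labels = np.full(pc1.data.shape, np.nan)
    ok = np.isfinite(pc1.data)
    # half-open [edge, edge+width); top bin additionally absorbs the max
    idx = np.floor((pc1.data[ok] - lo) / bin_width).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    labels[ok] = idx + 1
    return StrataMap(labels=pc1.like(labels, units="stratum"), edges=edges)


def focal_cover_filter(
    landcover: Raster,
    target_class: int,
    radius_m: float = 1000.0,
    threshold: float = 1.0,
) -> Raster:
    """Moving-window cover filter: cell passes iff the fraction of
    target-class cells with centers within ``radius_m`` is >= ``threshold``.

    The neighborhood is circular (cell-center distance), boundary cells use
    only in-bounds neighbors.  Implemented by FFT-free summed convolution of
    the binary class map with the disc kernel.
    """
    if radius_m <= 0:
        raise ValueError("radius must be positive")
    classes = np.unique(landcover.data[np.isfinite(landcover.data)])
    if target_class not in classes:
        raise ValueError(f"class {target_class!r} absent from land-cover raster")
    px = landcover.pixel_size
    r_cells = int(np.floor(radius_m / px))
    offsets = np.arange(-r_cells, r_cells + 1)
    dy, dx = np.meshgrid(offsets, offsets, indexing="ij")
    kernel = ((dy * px) ** 2 + (dx * px) ** 2) <= radius_m**2

    from scipy.ndimage import convolve

    is_target = (landcover.data == target_class).astype(float)
    valid = np.isfinite(landcover.data).astype(float)
    hits = convolve(is_target, kernel.astype(float), mode="constant", cval=0.0)
    total = convolve(valid, kernel.astype(float), mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = hits / total
    passed = np.where(total > 0, (frac >= threshold - 1e-12).astype(float), np.nan)
    passed[~np.isfinite(landcover.data)] = np.nan
    return landcover.like(passed, units="mask")


def sampleable_strata(
    strata: StrataMap,
    mask: Raster,
    grid_area_km2: float = 2.5,
) -> list[int]:
    """Strata whose masked area admits at least one square sampling-grid footprint.

    Two tests: total masked area >= grid area, and a binary-erosion footprint
    test with the grid's bounding square (so thin slivers of large total area
    are excluded).
    """
    if not strata.labels.same_grid(mask):
        raise ValueError("strata map and mask must share the grid")
    from scipy.ndimage import binary_erosion

    side_m = np.sqrt(grid_area_km2) * 1000.0
    side_cells = max(1, int(np.ceil(side_m / mask.pixel_size)))
    footprint = np.ones((side_cells, side_cells), dtype=bool)
    ok: list[int] = []
    masked = mask.data == 1
    for label in sorted(strata.pixel_counts()):
        cells = (strata.labels.data == label) & masked
        area = cells.sum() * mask.pixel_area_km2
        if area < grid_area_km2:
            continue
        if binary_erosion(cells, structure=footprint).any():
            ok.append(label)
    return ok
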