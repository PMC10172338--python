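"""Lightweight single-band rasters and named climate stacks.

The analysis operates on small, projected, north-up landscapes (pixel sizes
in metres), so a raster is just a 2-D float array plus an affine anchor:
``origin`` is the outer corner of the top-left cell and rows run southward.
Missing data are NaN.  I/O uses the ESRI ASCII grid format (plain text) with
an optional JSON sidecar for units and provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = ["Raster", "ClimateStack", "BIOCLIM_LAYERS"]

#: canonical layer names -> (units, kind); kind drives future-climate shifts
BIOCLIM_LAYERS = {
    "annual_mean_temp": ("degC", "temperature"),
    "max_temp_warmest_month": ("degC", "temperature"),
    "min_temp_coldest_month": ("degC", "temperature"),
    "annual_precip": ("mm", "precipitation"),
    "precip_wettest_month": ("mm", "precipitation"),
    "pet": ("mm", "pet"),
}


@dataclass
class Raster:
    """A single-band grid in a projected CRS (units: metres)."""

    data: np.ndarray  # 2-D float array, NaN = missing
    origin: tuple[float, float]  # (x, y) of the top-left corner
    pixel_size: float  # metres, square pixels
    crs: str = "local-metric"
    units: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full grid."""
        nrow, ncol = self.data.shape
        x0, y0 = self.origin
        return (x0, y0 - nrow * self.pixel_size, x0 + ncol * self.pixel_size, y0)

    def same_grid(self, other: "Raster") -> bool:
        return (
            self.data.shape == other.data.shape
            and np.allclose(self.origin, other.origin)
            and np.isclose(self.pixel_size, other.pixel_size)
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of cell-center coordinates, same shape as data."""
        nrow, ncol = self.data.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncol) + 0.5) * self.pixel_size
        ys = y0 - (np.arange(nrow) + 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing point (x, y); raises if outside."""
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.pixel_size))
        row = int(np.floor((y0 - y) / self.pixel_size))
        nrow, ncol = self.data.shape
        if not (0 <= row < nrow and 0 <= col < ncol):
            raise IndexError(f"point ({x}, {y}) outside raster bounds {self.bounds}")
        return row, col

    def sample(self, x: float, y: float) -> float:
        row, col = self.index_of(x, y)
        return float(self.data[row, col])

    def like(self, data: np.ndarray, units: str | None = None) -> "Raster":
        """New raster on this grid with different data."""
        return Raster(
            data=np.asarray(data, dtype=float),
            origin=self.origin,
            pixel_size=self.pixel_size,
            crs=self.crs,
            units=self.units if units is None else units,
        )

    def copy(self) -> "Raster":
        return self.like(self.data.copy())

    @property
    def pixel_area_km2(self) -> float:
        return (self.pixel_size / 1000.0) ** 2

    # -- I/O (ESRI ASCII grid; text-only deliverable) -----------------------
    def write_ascii(self, path: str | Path, nodata: float = -9999.0) -> None:
        path = Path(path)
        nrow, ncol = self.data.shape
        x0, y0 = self.origin
        header = (
            f"ncols {ncol}\nnrows {nrow}\n"
            f"xllcorner {x0}\nyllcorner {y0 - nrow * self.pixel_size}\n"
            f"cellsize {self.pixel_size}\nNODATA_value {nodata}\n"
        )
        body = np.where(np.isnan(self.data), nodata, self.data)
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, body, fmt="%.8g")
        sidecar = {"crs": self.crs, "units": self.units}
        Path(str(path) + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def read_ascii(cls, path: str | Path) -> "Raster":
        path = Path(path)
        meta: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)
        data[data == meta["nodata_value"]] = np.nan
        nrow = int(meta["nrows"])
        origin = (meta["xllcorner"], meta["yllcorner"] + nrow * meta["cellsize"])
        crs, units = "local-metric", ""
        side = Path(str(path) + ".json")
        if side.exists():
            sc = json.loads(side.read_text())
            crs, units = sc.get("crs", crs), sc.get("units", units)
        return cls(data=data, origin=origin, pixel_size=meta["cellsize"], crs=crs, units=units)


@dataclass
class ClimateStack:
    """Named covariate rasters sharing one grid.

    ``derived`` records affine recipes for layers computed from others
    (e.g. PET from temperature and precipitation) so that scenario shifts
    can propagate consistently; ``meta`` carries scenario labels/provenance.
    """

    layers: dict[str, Raster]
    derived: dict[str, dict] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rasters = list(self.layers.values())
        if not rasters:
            raise ValueError("a ClimateStack needs at least one layer")
        ref = rasters[0]
        for r in rasters[1:]:
            if not ref.same_grid(r):
                raise ValueError("all layers must share the same grid")

    def __getitem__(self, name: str) -> Raster:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __iter__(self) -> Iterator[str]:
        return iter(self.layers)

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def grid(self) -> Raster:
        return next(iter(self.layers.values()))

    def sample(self, x: float, y: float) -> dict[str, float]:
        return {name: r.sample(x, y) for name, r in self.layers.items()}

    def copy(self) -> "ClimateStack":
        return ClimateStack(
            layers={k: v.copy() for k, v in self.layers.items()},
            derived=json.loads(json.dumps(self.derived)),
            meta=dict(self.meta),
        )

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, r in self.layers.items():
            r.write_ascii(directory / f"{name}.asc")
        (directory / "stack.json").write_text(
            json.dumps({"layers": self.names, "derived": self.derived, "meta": self.meta}, indent=2)
        )

    @classmethod
    def read(cls, directory: str | Path) -> "ClimateStack":
        directory = Path(directory)
        info = json.loads((directory / "stack.json").read_text())
        layers = {name: Raster.read_ascii(directory / f"{name}.asc") for name in info["layers"]}
        return cls(layers=layers, derived=info.get("derived", {}), meta=info.get("meta", {}))


def layer_kind(name: str, units: str = "") -> str:
    """Classify a layer for scenario shifting: temperature / precipitation / pet / other."""
    if name in BIOCLIM_LAYERS:
        return BIOCLIM_LAYERS[name][1]
    if units == "degC":
        return "temperature"
    if units == "mm":
        return "precipitation"
    return "other"
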