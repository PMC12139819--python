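"""Rangewide projection: the best-performing genotype per raster cell.

For every grid cell of an MCMT raster within the trained climate range, the
overall fitness proxy of every genotype is evaluated at that cell's MCMT
(fixed effects only, each genotype with its own home climate and PC scores)
and the argmax genotype and its ancestry proportion are recorded.  Cells
outside the mask bounds (default: the climate range spanned by the training
gardens) or with nodata are masked.  Comparing a historic and a future map
summarizes where the best genotype switches.

Raster formats: ESRI ASCII grids (plain text) are parsed directly;
single-band GeoTIFFs are read and written through ``tifffile`` using the
standard pixel-scale / tiepoint / GDAL-nodata tags.  Coordinate reference
handling is a string passthrough.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path


import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigurationError, FormatError
from .prediction import PredictionRequest, predict_components
from .zig_engine import FittedZIG

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass
class ClimateGrid:
    """Single-band MCMT raster with GDAL-style affine geotransform."""

    mcmt: np.ndarray  # (nrows, ncols), degC
    geotransform: tuple  # (x0, dx, 0, y0, 0, -dy); row 0 is the north edge
    crs: str = "unspecified"
    nodata: float = -9999.0

    def __post_init__(self):
        self.mcmt = np.asarray(self.mcmt, float)
        if self.mcmt.ndim != 2:
            raise FormatError("climate grid must be a 2-D array")
        if self.geotransform[1] == 0 or self.geotransform[5] == 0:
            raise FormatError("geotransform is not invertible")

    @property
    def valid(self) -> np.ndarray:
        return ~np.isclose(self.mcmt, self.nodata) & np.isfinite(self.mcmt)


@dataclass
class BestGenotypeMap:
    """Argmax-fitness genotype per cell, with its ancestry proportion."""

    best_genotype_index: np.ndarray  # int, -1 where masked
    best_ancestry_q: np.ndarray  # float, NaN where masked
    masked: np.ndarray  # bool
    geotransform: tuple
    crs: str
    genotype_ids: tuple
    provenance: dict = field(default_factory=dict)


def read_climate_grid(path) -> ClimateGrid:
    """Read a single-band raster (ESRI ASCII grid or GeoTIFF)."""
    path = Path(path)
    if path.suffix.lower() in (".asc", ".agr", ".grd", ".txt"):
        return _read_ascii_grid(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return _read_geotiff(path)
    raise FormatError(f"unsupported raster format: {path.suffix!r}")


def write_climate_grid(grid: ClimateGrid, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".asc", ".agr", ".grd", ".txt"):
        _write_ascii_grid(grid, path)
    elif path.suffix.lower() in (".tif", ".tiff"):
        _write_geotiff(grid.mcmt.astype(np.float32), grid.geotransform, grid.nodata, path)
    else:
        raise FormatError(f"unsupported raster format: {path.suffix!r}")


def _read_ascii_grid(path) -> ClimateGrid:
    header = {}
    data_lines = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter", "yllcenter",
                "cellsize", "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                data_lines.append(parts)
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise FormatError(f"ASCII grid is missing header field {req!r}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cell = header["cellsize"]
    nodata = header.get("nodata_value", -9999.0)
    vals = np.array([float(v) for row in data_lines for v in row])
    if vals.size != nrows * ncols:
        raise FormatError(f"expected {nrows * ncols} cells, found {vals.size}")
    if "xllcorner" in header:
        x0 = header["xllcorner"]
        ytop = header.get("yllcorner", 0.0) + nrows * cell
    else:
        x0 = header.get("xllcenter", 0.0) - cell / 2
        ytop = header.get("yllcenter", 0.0) - cell / 2 + nrows * cell
    gt = (x0, cell, 0.0, ytop, 0.0, -cell)
    return ClimateGrid(mcmt=vals.reshape(nrows, ncols), geotransform=gt, nodata=nodata)


def _write_ascii_grid(grid: ClimateGrid, path) -> None:
    x0, dx, _, y0, _, dy = grid.geotransform
    if abs(dx) != abs(dy):
        raise FormatError("ASCII grids require square cells")
    nrows, ncols = grid.mcmt.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {x0!r}\n")
        fh.write(f"yllcorner {y0 + nrows * dy!r}\n")
        fh.write(f"cellsize {dx!r}\n")
        fh.write(f"nodata_value {grid.nodata!r}\n")
        for row in grid.mcmt:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _read_geotiff(path) -> ClimateGrid:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        if len(tf.pages) != 1:
            raise FormatError("only single-band, single-page GeoTIFFs are supported")
        page = tf.pages[0]
        if page.samplesperpixel != 1:
            raise FormatError("only single-band GeoTIFFs are supported")
        arr = page.asarray().astype(float)
        tags = page.tags
        try:
            sx, sy, _ = tags[_TAG_PIXEL_SCALE].value[:3]
            tp = tags[_TAG_TIEPOINT].value
        except KeyError as e:
            raise FormatError("GeoTIFF lacks pixel-scale/tiepoint georeferencing") from e
        # tiepoint maps raster (i, j, k) -> model (x, y, z)
        i, j, _, x, y, _ = tp[:6]
        gt = (x - i * sx, sx, 0.0, y + j * sy, 0.0, -sy)
        nodata = -9999.0
        if _TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00"))
    return ClimateGrid(mcmt=arr, geotransform=gt, nodata=nodata)


def _write_geotiff(array: np.ndarray, geotransform, nodata, path) -> None:
    import tifffile

    x0, dx, _, y0, _, dy = geotransform
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (dx, -dy, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    tifffile.imwrite(path, array, extratags=extratags)


def project_best_genotype(
    fit: FittedZIG,
    genotypes: pd.DataFrame,
    grid: ClimateGrid,
    mask_bounds: tuple,
    quantize: float = 0.01,
    back_transform: str = "naive",
) -> BestGenotypeMap:
    """Assign each unmasked cell the genotype with maximal overall fitness.

    Cell MCMT values are quantized (default 0.01 degC) *before* prediction,
    so the unique-value lookup is exact.  Argmax ties break toward the
    lowest genotype index (table row order).  ``mask_bounds = (low, high)``
    masks cells whose MCMT falls outside the trained climate range.
    """
    if len(genotypes) == 0:
        raise ConfigurationError("empty genotype collection")
    low, high = mask_bounds
    if not low < high:
        raise ConfigurationError("mask bounds must satisfy low < high")
    t = np.round(grid.mcmt / quantize) * quantize
    valid = grid.valid
    in_range = (t >= low) & (t <= high) & valid
    masked = ~in_range

    uniq, inverse = np.unique(t[in_range], return_inverse=True)
    fitness = np.empty((len(genotypes), uniq.size))
    for gi, (_, row) in enumerate(genotypes.iterrows()):
        req = PredictionRequest(
            garden_mcmt=uniq,
            home_mcmt=row.get("home_mcmt"),
            pc1=row.get("pc1"),
            pc2=row.get("pc2"),
            pc3=row.get("pc3"),
        )
        comp = predict_components(fit, req, back_transform=back_transform)
        fitness[gi] = comp.overall
    best = np.argmax(fitness, axis=0)  # first maximum = lowest index

    idx_map = np.full(grid.mcmt.shape, -1, dtype=np.int64)
    q_map = np.full(grid.mcmt.shape, np.nan)
    idx_map[in_range] = best[inverse]
    qvals = genotypes["ancestry_q"].to_numpy(float)
    q_map[in_range] = qvals[best[inverse]]
    return BestGenotypeMap(
        best_genotype_index=idx_map,
        best_ancestry_q=q_map,
        masked=masked,
        geotransform=grid.geotransform,
        crs=grid.crs,
        genotype_ids=tuple(genotypes["genotype_id"].astype(str)),
        provenance={
            "mask_bounds": [float(low), float(high)],
            "quantize": quantize,
            "back_transform": back_transform,
            "n_genotypes": int(len(genotypes)),
        },
    )


def shift_summary(historic: BestGenotypeMap, future: BestGenotypeMap):
    """Cellwise change between two projections sharing grid and genotypes.

    Returns ``(table, aggregates)``: a per-cell frame (row, col, historic /
    future ancestry, delta_q, switched) over cells unmasked in both, and a
    dict with the switched fraction and mean ancestry change.
    """
    if historic.best_genotype_index.shape != future.best_genotype_index.shape:
        raise AlignmentError("projection maps have different shapes")
    if not np.allclose(historic.geotransform, future.geotransform) or (
        historic.crs != future.crs
    ):
        raise AlignmentError("projection maps have different geotransform/CRS")
    if historic.genotype_ids != future.genotype_ids:
        raise AlignmentError("projection maps use different genotype sets")
    both = ~historic.masked & ~future.masked
    rows, cols = np.nonzero(both)
    hi = historic.best_genotype_index[both]
    fi = future.best_genotype_index[both]
    hq = historic.best_ancestry_q[both]
    fq = future.best_ancestry_q[both]
    switched = hi != fi
    table = pd.DataFrame(
        {
            "row": rows,
            "col": cols,
            "historic_genotype": [historic.genotype_ids[i] for i in hi],
            "future_genotype": [future.genotype_ids[i] for i in fi],
            "historic_q": hq,
            "future_q": fq,
            "delta_q": fq - hq,
            "switched": switched,
        }
    )
    aggregates = {
        "n_compared": int(both.sum()),
        "switched_fraction": float(np.mean(switched)) if both.any() else np.nan,
        "mean_delta_q": float(np.mean(fq - hq)) if both.any() else np.nan,
    }
    return table, aggregates


def write_best_genotype_map(bmap: BestGenotypeMap, out_dir, stem: str) -> dict:
    """Write ancestry and genotype-index rasters (GeoTIFF) + provenance JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    q = np.where(bmap.masked, -9999.0, bmap.best_ancestry_q).astype(np.float32)
    idx = np.where(bmap.masked, -1, bmap.best_genotype_index).astype(np.int32)
    paths = {
        "ancestry": out / f"{stem}_best_ancestry_q.tif",
        "genotype_index": out / f"{stem}_best_genotype.tif",
        "provenance": out / f"{stem}_provenance.json",
    }
    _write_geotiff(q, bmap.geotransform, -9999.0, paths["ancestry"])
    _write_geotiff(idx, bmap.geotransform, -1, paths["genotype_index"])
    with open(paths["provenance"], "w") as fh:
        json.dump(
            {**bmap.provenance, "crs": bmap.crs, "genotype_ids": list(bmap.genotype_ids)},
            fh,
            indent=1,
        )
    return paths
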