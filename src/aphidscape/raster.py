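"""Categorical land-cover rasters and the operations that prepare them for metrics.

A :class:`LandscapeRaster` is a planar grid of integer category codes with a
resolution in meters per pixel and an origin at the lower-left corner, in planar
meters.  Row 0 of the ``codes`` array is the *top* row of the map (image
convention); the y coordinate of a pixel center therefore decreases with row
index.

Rasters are stored on disk in a plain-text grid dialect::

    ncols 120
    nrows 100
    cellsize 30.0
    xllcorner 0.0
    yllcorner 0.0
    <nrows lines of ncols space-separated integer codes>

Out-of-buffer pixels are marked with the sentinel code ``OUTSIDE`` (-1), which
is never a legal category code.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: sentinel code for pixels outside a clipped buffer
OUTSIDE = -1


class RasterFormatError(ValueError):
    """Raised when a plain-text grid file violates the dialect."""


class LegendError(KeyError):
    """Raised when a raster contains codes absent from the legend."""


@dataclass(frozen=True)
class LandscapeRaster:
    """Planar grid of integer category codes.

    Parameters
    ----------
    codes : ndarray of int, shape (nrows, ncols)
        Category codes; ``OUTSIDE`` marks clipped pixels.
    resolution : float
        Pixel edge length in meters; must be > 0.
    origin : tuple of float
        (x, y) of the grid's lower-left corner in planar meters.
    """

    codes: np.ndarray
    resolution: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes)
        if codes.ndim != 2:
            raise ValueError(f"codes must be 2-D, got shape {codes.shape}")
        if not np.issubdtype(codes.dtype, np.integer):
            raise ValueError("codes must be an integer array")
        if not self.resolution > 0:
            raise ValueError(f"resolution must be > 0, got {self.resolution}")
        object.__setattr__(self, "codes", codes)

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) arrays of pixel-center coordinates in planar meters."""
        nrows, ncols = self.codes.shape
        x0, y0 = self.origin
        res = self.resolution
        xs = x0 + (np.arange(ncols) + 0.5) * res
        # row 0 is the top row
        ys = y0 + (nrows - np.arange(nrows) - 0.5) * res
        return np.meshgrid(xs, ys)


@dataclass(frozen=True)
class CategoryLegend:
    """Total mapping from raw land-cover codes to composite categories.

    ``mapping`` takes each raw code to a composite category name; exactly one
    category is the background (non-habitat / unclassified) category, excluded
    from landscape area in all downstream metrics.
    """

    mapping: dict[int, str]
    background: str
    _codes: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.background not in set(self.mapping.values()):
            raise ValueError(
                f"background category {self.background!r} not among mapped categories"
            )
        # stable composite codes: background -> 0, others in sorted name order
        names = sorted(set(self.mapping.values()) - {self.background})
        codes = {self.background: 0}
        codes.update({name: i + 1 for i, name in enumerate(names)})
        object.__setattr__(self, "_codes", codes)

    @property
    def categories(self) -> list[str]:
        """All composite category names, background first."""
        return sorted(self._codes, key=self._codes.get)

    def code_of(self, category: str) -> int:
        return self._codes[category]

    def category_of(self, code: int) -> str:
        for name, c in self._codes.items():
            if c == code:
                return name
        raise LegendError(f"no composite category with code {code}")


def read_legend_csv(path: str | Path) -> CategoryLegend:
    """Read a legend CSV with columns raw_code, category, is_background."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"raw_code", "category", "is_background"}
    if not required.issubset(df.columns):
        raise RasterFormatError(
            f"legend {path}: missing columns {sorted(required - set(df.columns))}"
        )
    background = df.loc[df["is_background"].astype(bool), "category"].unique()
    if len(background) != 1:
        raise RasterFormatError(
            f"legend {path}: exactly one background category required, got {list(background)}"
        )
    mapping = dict(zip(df["raw_code"].astype(int), df["category"]))
    return CategoryLegend(mapping=mapping, background=background[0])


def write_legend_csv(legend: CategoryLegend, path: str | Path) -> None:
    import pandas as pd

    rows = [
        {"raw_code": raw, "category": cat, "is_background": cat == legend.background}
        for raw, cat in sorted(legend.mapping.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# plain-text grid I/O


def write_raster(raster: LandscapeRaster, path: str | Path) -> None:
    """Write a raster in the plain-text grid dialect."""
    nrows, ncols = raster.codes.shape
    buf = io.StringIO()
    buf.write(f"ncols {ncols}\n")
    buf.write(f"nrows {nrows}\n")
    buf.write(f"cellsize {float(raster.resolution)!r}\n")
    buf.write(f"xllcorner {float(raster.origin[0])!r}\n")
    buf.write(f"yllcorner {float(raster.origin[1])!r}\n")
    np.savetxt(buf, raster.codes, fmt="%d")
    Path(path).write_text(buf.getvalue())


def read_raster(path: str | Path) -> LandscapeRaster:
    """Read a plain-text grid file, validating header/body consistency."""
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(lines[:5]):
        parts = line.split()
        if len(parts) != 2:
            raise RasterFormatError(f"{path}: line {i + 1}: malformed header {line!r}")
        key, value = parts
        try:
            header[key.lower()] = float(value)
        except ValueError as exc:
            raise RasterFormatError(
                f"{path}: line {i + 1}: non-numeric header value {value!r}"
            ) from exc
        body_start = i + 1
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise RasterFormatError(f"{path}: missing header field {key!r}")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    body = [ln for ln in lines[body_start:] if ln.strip()]
    if len(body) != nrows:
        raise RasterFormatError(
            f"{path}: line {body_start + 1}: header declares nrows={nrows} "
            f"but body has {len(body)} rows"
        )
    rows = []
    for j, line in enumerate(body):
        vals = line.split()
        if len(vals) != ncols:
            raise RasterFormatError(
                f"{path}: line {body_start + j + 1}: expected {ncols} columns, "
                f"got {len(vals)}"
            )
        try:
            rows.append([int(v) for v in vals])
        except ValueError as exc:
            raise RasterFormatError(
                f"{path}: line {body_start + j + 1}: non-integer code"
            ) from exc
    return LandscapeRaster(
        codes=np.array(rows, dtype=np.int64),
        resolution=header["cellsize"],
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
    )


# ---------------------------------------------------------------------------
# operations


def reclassify(raster: LandscapeRaster, legend: CategoryLegend) -> LandscapeRaster:
    """Map raw codes to composite-category codes; geometry unchanged.

    Raises :class:`LegendError` naming any raster code absent from the legend.
    Pixels already marked ``OUTSIDE`` pass through.
    """
    codes = raster.codes
    present = np.unique(codes)
    unmapped = [int(c) for c in present if c != OUTSIDE and int(c) not in legend.mapping]
    if unmapped:
        raise LegendError(f"raster codes not in legend: {unmapped}")
    lut = {raw: legend.code_of(cat) for raw, cat in legend.mapping.items()}
    lut[OUTSIDE] = OUTSIDE
    out = np.vectorize(lut.__getitem__, otypes=[np.int64])(codes)
    return LandscapeRaster(out, raster.resolution, raster.origin)


@dataclass(frozen=True)
class Buffer:
    """Circular landscape window centered on a sampled field."""

    center: tuple[float, float]
    radius: float = 5000.0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")


class EmptyBufferError(ValueError):
    """No pixel centers fall inside the buffer."""


def clip_buffer(raster: LandscapeRaster, buffer: Buffer) -> LandscapeRaster:
    """Mark pixels whose centers fall outside the buffer circle as ``OUTSIDE``.

    A pixel is kept iff its center lies within ``buffer.radius`` of
    ``buffer.center`` (pixel-center-in-circle rule).
    """
    X, Y = raster.pixel_centers()
    cx, cy = buffer.center
    inside = (X - cx) ** 2 + (Y - cy) ** 2 <= buffer.radius**2
    if not inside.any():
        raise EmptyBufferError(
            f"no pixel centers within radius {buffer.radius} of {buffer.center}"
        )
    out = np.where(inside, raster.codes, OUTSIDE)
    return LandscapeRaster(out, raster.resolution, raster.origin)


def buffer_area_ha(clipped: LandscapeRaster) -> float:
    """Area of the clipped buffer in hectares (kept pixels x pixel area)."""
    kept = int((clipped.codes != OUTSIDE).sum())
    return kept * clipped.resolution**2 / 1e4
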