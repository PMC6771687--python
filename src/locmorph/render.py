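"""Super-resolution image rendering from localization tables.

Localizations are rendered as a 2-D counts histogram on a fixed
nm-per-pixel grid (default 10 nm).  Pixel (row i, col j) covers the
half-open nm square [origin_x + j*px, origin_x + (j+1)*px) x
[origin_y + i*px, origin_y + (i+1)*px); a localization exactly on an
interior pixel boundary therefore lands in the higher-index pixel
(floor convention).  Pixel centres sit at origin + (index + 0.5)*px,
the convention shared by the morphometry and registration code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile

from .loc_table import LocalizationTable


@dataclass(frozen=True)
class RenderSpec:
    """Rendering geometry: pixel size (nm) and field extent (nm).

    ``extent`` is (x_min, x_max, y_min, y_max) in nm; the grid has
    ceil((max-min)/pixel_size) pixels per axis.
    """

    pixel_size: float = 10.0
    extent: tuple = (0.0, 10000.0, 0.0, 10000.0)
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        x0, x1, y0, y1 = self.extent
        if not (x1 > x0 and y1 > y0):
            raise ValueError("field extent is degenerate")
        if self.mode != "counts":
            raise ValueError("only counts-histogram rendering is supported")

    @property
    def shape(self) -> tuple:
        x0, x1, y0, y1 = self.extent
        return (
            int(np.ceil((y1 - y0) / self.pixel_size)),
            int(np.ceil((x1 - x0) / self.pixel_size)),
        )


@dataclass
class RenderedImage:
    """A 2-D intensity grid with physical pixel size and nm origin.

    ``grid[i, j]`` is the intensity of the pixel whose upper-left nm
    corner is ``(origin[0] + j*pixel_size, origin[1] + i*pixel_size)``
    (origin is (x, y) of pixel (0, 0)).
    """

    grid: np.ndarray
    pixel_size: float
    origin: tuple = (0.0, 0.0)
    n_out_of_field: int = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-D")
        if (self.grid < 0).any():
            raise ValueError("intensities must be >= 0")

    @property
    def shape(self) -> tuple:
        return self.grid.shape

    def same_geometry(self, other: "RenderedImage") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.pixel_size, other.pixel_size)
            and np.allclose(self.origin, other.origin)
        )

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x_centers, y_centers) in nm, lengths (ncols, nrows)."""
        ny, nx = self.shape
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.pixel_size
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.pixel_size
        return xs, ys

    def to_tiff(self, path) -> None:
        tifffile.imwrite(
            path,
            self.grid.astype(np.float32),
            metadata={"pixel_size_nm": self.pixel_size, "origin_nm": list(self.origin)},
        )


def render_histogram(table: LocalizationTable, spec: RenderSpec) -> RenderedImage:
    """Render a counts histogram: each in-field localization increments
    exactly one pixel; the in-field grid sum equals the number of
    in-field localizations.  Out-of-field localizations are counted on
    the returned image (``n_out_of_field``)."""
    x0, x1, y0, y1 = spec.extent
    ny, nx = spec.shape
    xy = table.xy
    jj = np.floor((xy[:, 0] - x0) / spec.pixel_size).astype(np.int64)
    ii = np.floor((xy[:, 1] - y0) / spec.pixel_size).astype(np.int64)
    ok = (jj >= 0) & (jj < nx) & (ii >= 0) & (ii < ny)
    grid = np.zeros((ny, nx), dtype=np.float64)
    np.add.at(grid, (ii[ok], jj[ok]), 1.0)
    return RenderedImage(
        grid=grid,
        pixel_size=spec.pixel_size,
        origin=(x0, y0),
        n_out_of_field=int((~ok).sum()),
    )


def median_filter_image(image: RenderedImage, radius: int) -> RenderedImage:
    """Post-localization median filter with radius 0 or 1 pixel.

    Radius 0 is the identity; radius 1 replaces each pixel by the
    median of its 3x3 neighbourhood, where edge pixels use only the
    in-image part of the neighbourhood.  Used on the Rab5 channel to
    suppress the sparse monomeric cytosolic signal, which renders as
    isolated single-count pixels.
    """
    if radius not in (0, 1):
        raise ValueError("median filter radius must be 0 or 1")
    if radius == 0:
        return RenderedImage(image.grid.copy(), image.pixel_size, image.origin)
    g = image.grid
    padded = np.full((g.shape[0] + 2, g.shape[1] + 2), np.nan)
    padded[1:-1, 1:-1] = g
    stack = np.empty((9,) + g.shape)
    k = 0
    for di in (0, 1, 2):
        for dj in (0, 1, 2):
            stack[k] = padded[di : di + g.shape[0], dj : dj + g.shape[1]]
            k += 1
    out = np.nanmedian(stack, axis=0)
    return RenderedImage(out, image.pixel_size, image.origin)


def combine_channels(
    images: list[RenderedImage], norm_percentile: float = 100.0
) -> RenderedImage:
    """Combine channels into a single endosome-area proxy image.

    Each channel is normalized to [0, 1] (so no channel's dynamic
    range dominates), then combined by the pixel-wise maximum.  With
    the default ``norm_percentile=100`` the scale is the channel
    maximum; a high percentile of the *positive* pixels (e.g. 99.5,
    values above clipped to 1) gives a robust scale for count
    histograms, where the single brightest pixel is an unstable
    normalizer.  The operation is commutative and, on already
    normalized inputs, idempotent.  All-zero channels pass through as
    zeros.
    """
    if not images:
        raise ValueError("need at least one image")
    if not 0 < norm_percentile <= 100:
        raise ValueError("norm_percentile must be in (0, 100]")
    ref = images[0]
    for im in images[1:]:
        if not ref.same_geometry(im):
            raise ValueError("channel images differ in shape, pixel size or origin")
    out = np.zeros_like(ref.grid)
    for im in images:
        pos = im.grid[im.grid > 0]
        m = float(np.percentile(pos, norm_percentile)) if len(pos) else 0.0
        norm = np.clip(im.grid / m, 0.0, 1.0) if m > 0 else im.grid
        np.maximum(out, norm, out=out)
    return RenderedImage(out, ref.pixel_size, ref.origin)
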