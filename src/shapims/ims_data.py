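"""Data model and I/O for peak-picked imaging mass spectrometry datasets.

An IMS experiment yields one mass spectrum per pixel of a tissue grid. After
peak picking, the experiment is a dense intensity matrix ``X`` of shape
``(m pixels, n m/z features)`` together with the integer grid coordinate of
every pixel and the m/z value of every feature. This module defines that
container (:class:`IMSDataset`), per-pixel class annotations
(:class:`AnnotationMask`), spatial rasters (:class:`SpatialImage`), and a
plain-text interchange bundle for all three.

Intensities are accepted as already peak-picked and normalized upstream; no
transformation is applied on load. Coordinates are 0-based ``(row, col)``
and the canonical pixel order is row-major.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "IMSDataset",
    "SpatialImage",
    "AnnotationMask",
    "Label",
    "load_dataset",
    "write_dataset",
    "ion_image",
    "load_mask",
    "write_mask",
]


class Label(enum.IntEnum):
    """Per-pixel annotation code for one one-vs-all class."""

    POS = 1
    NEG = 0
    EXCLUDED = -1


@dataclass(frozen=True)
class IMSDataset:
    """A peak-picked IMS dataset: intensity matrix, pixel grid, m/z axis.

    Parameters
    ----------
    intensities
        ``(m, n)`` array of finite, non-negative ion intensities
        (arbitrary units). Row ``i`` is the spectrum of pixel ``i``.
    pixel_coords
        ``(m, 2)`` integer array of 0-based ``(row, col)`` grid positions,
        unique per pixel.
    mz_values
        ``(n,)`` strictly increasing positive m/z values in Da.
    name
        Free-text dataset identifier.
    """

    intensities: np.ndarray
    pixel_coords: np.ndarray
    mz_values: np.ndarray
    name: str = "unnamed"

    def __post_init__(self) -> None:
        X = np.asarray(self.intensities, dtype=float)
        coords = np.asarray(self.pixel_coords, dtype=int)
        mz = np.asarray(self.mz_values, dtype=float)
        object.__setattr__(self, "intensities", X)
        object.__setattr__(self, "pixel_coords", coords)
        object.__setattr__(self, "mz_values", mz)
        if X.ndim != 2 or X.shape[0] == 0 or X.shape[1] == 0:
            raise ValueError("intensity matrix must be 2-D and non-empty")
        if not np.isfinite(X).all():
            raise ValueError("intensity matrix contains NaN or Inf")
        if (X < 0).any():
            raise ValueError("intensities must be non-negative")
        if coords.shape != (X.shape[0], 2):
            raise ValueError(
                f"coordinate table shape {coords.shape} does not match "
                f"{X.shape[0]} pixels"
            )
        if (coords < 0).any():
            raise ValueError("pixel coordinates must be non-negative")
        uniq, counts = np.unique(coords, axis=0, return_counts=True)
        if (counts > 1).any():
            r, c = uniq[np.argmax(counts > 1)]
            raise ValueError(f"duplicate pixel coordinate ({r}, {c})")
        if mz.shape != (X.shape[1],):
            raise ValueError(
                f"m/z list length {mz.shape[0]} does not match "
                f"{X.shape[1]} features"
            )
        if (mz <= 0).any():
            raise ValueError("m/z values must be positive")
        if not (np.diff(mz) > 0).all():
            raise ValueError("m/z not strictly increasing")

    @property
    def n_pixels(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def grid_shape(self) -> tuple[int, int]:
        """``(H, W)`` of the smallest grid containing every pixel."""
        return (
            int(self.pixel_coords[:, 0].max()) + 1,
            int(self.pixel_coords[:, 1].max()) + 1,
        )

    def ion_image(self, feature_index: int) -> "SpatialImage":
        return ion_image(self, feature_index)


@dataclass(frozen=True)
class SpatialImage:
    """A value per grid cell; cells not covered by any pixel are NaN."""

    values: np.ndarray  # (H, W) float array, NaN = missing
    legend: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.size == 0:
            raise ValueError("image grid must be 2-D and non-empty")
        if not np.isfinite(v).any():
            raise ValueError("image has no covered cells")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_csv(self, path: str | Path) -> Path:
        """Write the grid as CSV with ``NA`` for missing cells."""
        path = Path(path)
        pd.DataFrame(self.values).to_csv(
            path, header=False, index=False, na_rep="NA", float_format="%.12g"
        )
        return path


@dataclass(frozen=True)
class AnnotationMask:
    """POS/NEG/EXCLUDED labels for one one-vs-all class, in pixel order."""

    class_name: str
    labels: np.ndarray = field(repr=False)  # (m,) of Label codes

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", lab)
        bad = ~np.isin(lab, [Label.POS, Label.NEG, Label.EXCLUDED])
        if bad.any():
            raise ValueError(f"unknown label code {lab[bad][0]}")

    @property
    def n_pos(self) -> int:
        return int((self.labels == Label.POS).sum())

    @property
    def n_neg(self) -> int:
        return int((self.labels == Label.NEG).sum())


def _grid_index(ds: IMSDataset) -> tuple[np.ndarray, np.ndarray]:
    rows = ds.pixel_coords[:, 0]
    cols = ds.pixel_coords[:, 1]
    return rows, cols


def ion_image(ds: IMSDataset, feature_index: int) -> SpatialImage:
    """Place one feature's intensities on the pixel grid.

    Cells not covered by any pixel of the dataset are NaN, so tissue
    background is distinguishable from a true zero intensity.
    """
    if not 0 <= feature_index < ds.n_features:
        raise IndexError(
            f"feature index {feature_index} out of range [0, {ds.n_features})"
        )
    grid = np.full(ds.grid_shape, np.nan)
    rows, cols = _grid_index(ds)
    grid[rows, cols] = ds.intensities[:, feature_index]
    mz = ds.mz_values[feature_index]
    return SpatialImage(grid, legend=f"ion image m/z {mz:.4f}")


def values_image(ds: IMSDataset, values: np.ndarray, legend: str = "",
                 pixel_indices: np.ndarray | None = None) -> SpatialImage:
    """Place an arbitrary per-pixel vector on the dataset grid."""
    values = np.asarray(values, dtype=float)
    rows, cols = _grid_index(ds)
    if pixel_indices is not None:
        rows = rows[pixel_indices]
        cols = cols[pixel_indices]
    if values.shape != rows.shape:
        raise ValueError("value vector does not match pixel count")
    grid = np.full(ds.grid_shape, np.nan)
    grid[rows, cols] = values
    return SpatialImage(grid, legend=legend)


# ---------------------------------------------------------------------------
# Delimited-text bundle I/O
#
# A dataset directory holds intensities.csv (m rows x n cols, header = m/z),
# pixels.csv (columns row,col) and mz.csv (one m/z per line); masks are
# mask_<class>.csv integer grids with codes 1 / 0 / -1.
# ---------------------------------------------------------------------------

def load_dataset(bundle: str | Path, name: str | None = None) -> IMSDataset:
    """Load and validate a dataset bundle directory."""
    bundle = Path(bundle)
    inten_path = bundle / "intensities.csv"
    pix_path = bundle / "pixels.csv"
    mz_path = bundle / "mz.csv"
    for p in (inten_path, pix_path, mz_path):
        if not p.is_file():
            raise FileNotFoundError(f"bundle is missing {p.name}")
    X = pd.read_csv(inten_path).to_numpy(dtype=float)
    pix = pd.read_csv(pix_path)
    if list(pix.columns) != ["row", "col"]:
        raise ValueError("pixels.csv must have columns row,col")
    mz = pd.read_csv(mz_path, header=None).to_numpy(dtype=float).ravel()
    return IMSDataset(X, pix.to_numpy(dtype=int), mz,
                      name=name or bundle.name)


def write_dataset(ds: IMSDataset, directory: str | Path) -> Path:
    """Write a dataset bundle; round-trips through :func:`load_dataset`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    header = [f"{v:.6f}" for v in ds.mz_values]
    pd.DataFrame(ds.intensities, columns=header).to_csv(
        directory / "intensities.csv", index=False, float_format="%.17g"
    )
    pd.DataFrame(ds.pixel_coords, columns=["row", "col"]).to_csv(
        directory / "pixels.csv", index=False
    )
    pd.DataFrame(ds.mz_values).to_csv(
        directory / "mz.csv", index=False, header=False, float_format="%.17g"
    )
    return directory


def load_mask(path: str | Path, ds: IMSDataset,
              class_name: str | None = None) -> AnnotationMask:
    """Load a ``mask_<class>.csv`` integer grid and align it to ``ds``.

    Grid cells encode 1 = POS, 0 = NEG, -1 = EXCLUDED. The grid must cover
    every pixel of the dataset.
    """
    path = Path(path)
    grid = pd.read_csv(path, header=None).to_numpy(dtype=int)
    bad = ~np.isin(grid, [1, 0, -1])
    if bad.any():
        raise ValueError(f"unknown label code {grid[bad][0]} in {path.name}")
    rows, cols = _grid_index(ds)
    if grid.shape[0] <= rows.max() or grid.shape[1] <= cols.max():
        raise ValueError(
            f"mask grid {grid.shape} too small for dataset grid "
            f"{ds.grid_shape}"
        )
    if class_name is None:
        stem = path.stem
        class_name = stem[5:] if stem.startswith("mask_") else stem
    return AnnotationMask(class_name, grid[rows, cols])


def write_mask(mask: AnnotationMask, ds: IMSDataset,
               directory: str | Path) -> Path:
    """Write a mask as an integer grid aligned to the dataset's grid.

    Cells not covered by a pixel are written as EXCLUDED (-1).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    grid = np.full(ds.grid_shape, int(Label.EXCLUDED), dtype=int)
    rows, cols = _grid_index(ds)
    grid[rows, cols] = mask.labels
    out = directory / f"mask_{mask.class_name}.csv"
    pd.DataFrame(grid).to_csv(out, index=False, header=False)
    return out
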