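"""Grid-patch feature extraction from registered embryo images.

The pipeline starts from registered, background-free grayscale images of
single embryos (one image per in situ hybridization assay, tagged with the
gene it probes).  Each image is linearly rescaled to a fixed resolution, a
regular grid of patches is laid over it, and the mean intensity of every
patch becomes one feature.  Stacking the patch means row-major (top-left
patch first) yields one feature vector per image; the vectors form the
rows of the data matrix X that the factor model decomposes.

Conventions
-----------
* Intensities live in [0, 1] with higher values meaning stronger staining;
  loaders invert dark-on-light images when asked to.
* Patch stacking is row-major so a feature vector can always be folded
  back into an image of shape (n_rows, n_cols).
* Rows of X are mean-centered before factor analysis ("gene patterns
  normalized to zero mean"); the flag on :class:`FeatureMatrix` records
  whether that has happened.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize

__all__ = [
    "RegisteredImage",
    "GridSpec",
    "FeatureMatrix",
    "load_registered_images",
    "rescale_image",
    "extract_grid_features",
    "center_gene_patterns",
    "assemble_feature_matrix",
    "save_feature_matrix",
    "load_feature_matrix",
]

ORIENTATIONS = ("lateral", "dorsal_ventral", "unknown")


@dataclass
class RegisteredImage:
    """A registered single-embryo grayscale image with its metadata."""

    image_id: str
    gene_id: str
    pixels: np.ndarray  # (height, width), float in [0, 1]
    orientation_tag: str = "unknown"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError(f"image {self.image_id}: pixels must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError(f"image {self.image_id}: non-finite pixel values")
        if self.pixels.min() < -1e-12 or self.pixels.max() > 1 + 1e-12:
            raise ValueError(f"image {self.image_id}: intensities outside [0, 1]")
        if self.orientation_tag not in ORIENTATIONS:
            raise ValueError(f"unknown orientation tag {self.orientation_tag!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class GridSpec:
    """Patch grid: ``n_cols`` patches along width, ``n_rows`` along height."""

    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid dimensions must be >= 1")

    @property
    def n_features(self) -> int:
        return self.n_cols * self.n_rows


@dataclass
class FeatureMatrix:
    """N x P matrix of patch-mean features with per-row image metadata."""

    X: np.ndarray
    row_meta: list[tuple[str, str]]  # (image_id, gene_id)
    grid: GridSpec
    centered: bool = False

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[0] != len(self.row_meta):
            raise ValueError("row_meta length must equal the number of rows of X")
        if self.X.shape[1] != self.grid.n_features:
            raise ValueError("X width must equal grid.n_rows * grid.n_cols")
        if self.centered:
            rowmeans = self.X.mean(axis=1)
            if self.X.shape[1] > 0 and np.abs(rowmeans).max(initial=0.0) > 1e-10:
                raise ValueError("centered flag set but row means exceed 1e-10")

    @property
    def image_ids(self) -> list[str]:
        return [m[0] for m in self.row_meta]

    @property
    def gene_ids(self) -> list[str]:
        return [m[1] for m in self.row_meta]

    @property
    def n_images(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def _to_unit_interval(raw: np.ndarray) -> np.ndarray:
    """Linearly rescale a raster array to [0, 1] based on its dtype range."""
    if raw.ndim == 3:  # collapse RGB(A) to luminance-style mean over channels
        raw = raw[..., :3].mean(axis=2)
    raw = np.asarray(raw, dtype=float)
    if np.issubdtype(np.asarray(raw).dtype, np.floating):
        top = max(raw.max(initial=0.0), 1.0)
        return np.clip(raw / top, 0.0, 1.0)
    return raw


def load_registered_images(
    paths: Sequence[str | os.PathLike],
    metadata: pd.DataFrame,
    invert: bool = False,
) -> list[RegisteredImage]:
    """Load grayscale raster files and join gene metadata.

    ``metadata`` must carry columns ``file``, ``image_id``, ``gene_id`` and
    optionally ``orientation``.  Intensities are rescaled linearly to
    [0, 1] (8-bit 255 -> 1.0); ``invert`` flips dark-on-light staining so
    that stronger staining is always the larger value.  The result is
    sorted by ``image_id`` so downstream matrices are deterministic.
    """
    required = {"file", "image_id", "gene_id"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    meta_by_file = {os.path.basename(str(f)): row for f, row in zip(metadata["file"], metadata.to_dict("records"))}

    images: list[RegisteredImage] = []
    for path in paths:
        key = os.path.basename(os.fspath(path))
        if key not in meta_by_file:
            raise ValueError(f"no metadata row for image file {key!r}")
        try:
            raw = iio.imread(path)
        except Exception as exc:  # plugin backends raise heterogeneous types
            raise OSError(f"cannot read image file {os.fspath(path)!r}: {exc}") from exc
        dtype = raw.dtype
        arr = np.asarray(raw, dtype=float)
        if arr.ndim == 3:
            arr = arr[..., :3].mean(axis=2)
        if np.issubdtype(dtype, np.integer):
            arr = arr / float(np.iinfo(dtype).max)
        arr = np.clip(arr, 0.0, 1.0)
        if invert:
            arr = 1.0 - arr
        row = meta_by_file[key]
        images.append(
            RegisteredImage(
                image_id=str(row["image_id"]),
                gene_id=str(row["gene_id"]),
                pixels=arr,
                orientation_tag=str(row.get("orientation", "unknown") or "unknown"),
            )
        )
    images.sort(key=lambda im: im.image_id)
    return images


def rescale_image(img: RegisteredImage, target_width: int, target_height: int) -> RegisteredImage:
    """Bilinearly resample an image to (target_height, target_width).

    Edge pixels are clamped (no reflection) so constants are preserved
    exactly and intensities stay inside [0, 1].
    """
    if target_width < 1 or target_height < 1:
        raise ValueError("target dimensions must be >= 1")
    if img.shape == (target_height, target_width):
        return replace(img, pixels=img.pixels.copy())
    out = resize(
        img.pixels,
        (target_height, target_width),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return replace(img, pixels=np.clip(out, 0.0, 1.0))


def extract_grid_features(img: RegisteredImage, grid: GridSpec) -> np.ndarray:
    """Mean pixel value within each grid patch, stacked row-major.

    Entry ``r * n_cols + c`` is the mean over patch (r, c).  The image
    dimensions must be divisible by the grid dimensions; rescale first if
    they are not.
    """
    h, w = img.shape
    if h % grid.n_rows or w % grid.n_cols:
        raise ValueError(
            f"image shape {img.shape} not divisible by grid "
            f"({grid.n_rows} rows x {grid.n_cols} cols); rescale the image first"
        )
    ph, pw = h // grid.n_rows, w // grid.n_cols
    blocks = img.pixels.reshape(grid.n_rows, ph, grid.n_cols, pw)
    return blocks.mean(axis=(1, 3)).ravel()


def center_gene_patterns(fm: FeatureMatrix) -> FeatureMatrix:
    """Subtract each row's mean (zero-mean gene patterns). Idempotent-safe."""
    if fm.centered:
        raise ValueError("feature matrix is already centered")
    Xc = fm.X - fm.X.mean(axis=1, keepdims=True)
    return FeatureMatrix(X=Xc, row_meta=list(fm.row_meta), grid=fm.grid, centered=True)


def assemble_feature_matrix(
    images: Iterable[RegisteredImage],
    grid: GridSpec,
    center: bool = True,
) -> FeatureMatrix:
    """Extract grid features for every image and stack them into X."""
    images = list(images)
    if not images:
        raise ValueError("empty image list")
    shapes = {im.shape for im in images}
    if len(shapes) != 1:
        raise ValueError(f"images have inconsistent dimensions: {sorted(shapes)}")
    X = np.stack([extract_grid_features(im, grid) for im in images])
    fm = FeatureMatrix(
        X=X,
        row_meta=[(im.image_id, im.gene_id) for im in images],
        grid=grid,
        centered=False,
    )
    return center_gene_patterns(fm) if center else fm


# --- TSV round-trip -------------------------------------------------------

def save_feature_matrix(fm: FeatureMatrix, path: str | os.PathLike) -> None:
    """Write X as TSV with a sidecar header line recording the grid."""
    with open(path, "w") as fh:
        fh.write(f"#grid_rows={fm.grid.n_rows}\tgrid_cols={fm.grid.n_cols}\tcentered={int(fm.centered)}\n")
        width = len(str(fm.n_features))
        cols = [f"f_{i + 1:0{max(4, width)}d}" for i in range(fm.n_features)]
        df = pd.DataFrame(fm.X, columns=cols)
        df.insert(0, "image_id", fm.image_ids)
        df.insert(1, "gene_id", fm.gene_ids)
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def load_feature_matrix(path: str | os.PathLike) -> FeatureMatrix:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{os.fspath(path)!r}: missing grid header line")
        kv = dict(item.split("=", 1) for item in header[1:].strip().split("\t"))
        grid = GridSpec(n_cols=int(kv["grid_cols"]), n_rows=int(kv["grid_rows"]))
        centered = bool(int(kv["centered"]))
        df = pd.read_csv(fh, sep="\t")
    X = df.drop(columns=["image_id", "gene_id"]).to_numpy(dtype=float)
    meta = list(zip(df["image_id"].astype(str), df["gene_id"].astype(str)))
    return FeatureMatrix(X=X, row_meta=meta, grid=grid, centered=centered)
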