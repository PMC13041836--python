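"""Low-level image model and operators shared by every assay pipeline.

The quantification pipelines all compose the same small set of classical
operations: Z-projection, top-hat background suppression, Gaussian blur,
thresholding, connected-component labeling, distance-transform watershed and
per-object measurement.  This module defines the in-memory types (a
multi-channel Z-stack with physical pixel size, 2-D images, binary and
labeled masks) and those operators with explicit, deterministic semantics.

Conventions
-----------
* 0-based ``(y, x)`` raster indexing; stacks are indexed ``(z, channel, y, x)``.
* Areas and distances are reported in micrometres using ``pixel_size_um``
  (isotropic in x/y).  Pixel size is a required acquisition input — it cannot
  be recovered from the pixel data.
* Thresholding uses strict ``>`` so a zero threshold on an integer image does
  not flood the foreground.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage import measure as skmeasure
from skimage import morphology as skmorph
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed as sk_watershed

from .provenance import ProvenanceLog

__all__ = [
    "ImageStack",
    "Image2D",
    "BinaryMask",
    "LabeledMask",
    "load_stack",
    "save_stack",
    "max_project",
    "sum_project",
    "tophat",
    "gaussian_blur",
    "threshold_binarize",
    "connected_components",
    "watershed_split",
    "measure_objects",
]

_STRUCT_8 = np.ones((3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ImageStack:
    """Multi-channel fluorescence Z-stack with physical calibration.

    Parameters
    ----------
    pixels
        4-D non-negative intensity array indexed ``(z, channel, y, x)``.
    pixel_size_um
        Micrometres per pixel edge, isotropic in x/y.
    z_step_um
        Micrometres between consecutive Z slices.
    channel_roles
        Map from role tag (``"dapi"``, ``"gfp"``, ``"mcherry"``, ``"tmre"``,
        ``"mtg"``, ``"lamp1"``, ...) to channel index.  Each role maps to
        exactly one channel.
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel_roles: Mapping[str, int]
    z_step_um: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise ValueError("stack pixels must be 4-D (z, channel, y, x)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("stack intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("stack intensities must be non-negative")
        n_channels = self.pixels.shape[1]
        idx = list(self.channel_roles.values())
        if len(set(idx)) != len(idx):
            raise ValueError("each role must map to a distinct channel index")
        for role, i in self.channel_roles.items():
            if not 0 <= int(i) < n_channels:
                raise ValueError(f"role {role!r} maps to channel {i} outside 0..{n_channels - 1}")

    @property
    def n_z(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.pixels.shape[2], self.pixels.shape[3]

    def channel_index(self, role: str) -> int:
        try:
            return int(self.channel_roles[role])
        except KeyError:
            raise KeyError(f"unknown channel role {role!r}; known: {sorted(self.channel_roles)}") from None


@dataclass
class Image2D:
    """Single-channel 2-D image on the same grid convention as its stack."""

    pixels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("Image2D pixels must be 2-D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """2-D boolean foreground mask."""

    pixels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != bool:
            raise ValueError("BinaryMask pixels must be boolean")
        if self.pixels.ndim != 2:
            raise ValueError("BinaryMask pixels must be 2-D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LabeledMask:
    """2-D integer object labeling; 0 is background, objects are 1..n."""

    labels: np.ndarray
    pixel_size_um: float
    n_objects: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        present = np.unique(self.labels)
        present = present[present > 0]
        if present.size and present.max() > self.n_objects:
            raise ValueError("label values exceed n_objects")
        if present.size != self.n_objects:
            raise ValueError("every label 1..n_objects must occur at least once")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def object_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def load_stack(
    path: str | Path,
    channel_roles: Mapping[str, int],
    pixel_size_um: float,
    z_step_um: float = 1.0,
    plane_order: str = "zc",
) -> ImageStack:
    """Read a multi-page TIFF into an :class:`ImageStack`.

    Pages are one plane per (z, channel) pair.  ``plane_order="zc"`` means
    z-major page ordering (all channels of slice 0, then slice 1, ...);
    ``"cz"`` means channel-major.  Pixels are returned exactly as stored —
    no rescaling.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    if plane_order not in ("zc", "cz"):
        raise ValueError("plane_order must be 'zc' or 'cz'")
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if not np.issubdtype(data.dtype, np.number):
        raise ValueError("non-numeric pixel data")
    n_channels = int(max(channel_roles.values())) + 1
    if data.ndim == 4:
        # shaped TIFF: the (z, c) layout is stored in the file
        if plane_order == "cz":
            data = data.transpose(1, 0, 2, 3)
        if data.shape[1] != n_channels:
            raise ValueError(
                f"channel-count mismatch: file has {data.shape[1]} channels, "
                f"{n_channels} declared"
            )
        pixels = data
    elif data.ndim == 3:
        n_pages = data.shape[0]
        if n_pages % n_channels != 0:
            raise ValueError(
                f"channel-count mismatch: {n_pages} pages not divisible by "
                f"{n_channels} declared channels"
            )
        n_z = n_pages // n_channels
        if plane_order == "zc":
            pixels = data.reshape(n_z, n_channels, *data.shape[1:])
        else:
            pixels = data.reshape(n_channels, n_z, *data.shape[1:]).transpose(1, 0, 2, 3)
    else:
        raise ValueError(f"expected a stack of 2-D pages, got shape {data.shape}")
    return ImageStack(
        pixels=pixels.astype(float),
        pixel_size_um=pixel_size_um,
        channel_roles=dict(channel_roles),
        z_step_um=z_step_um,
    )


def save_stack(stack: ImageStack, path: str | Path, plane_order: str = "zc") -> None:
    """Write an :class:`ImageStack` as a shaped float32 TIFF (one page per plane)."""
    if plane_order not in ("zc", "cz"):
        raise ValueError("plane_order must be 'zc' or 'cz'")
    px = stack.pixels
    if plane_order == "cz":
        px = px.transpose(1, 0, 2, 3)
    tifffile.imwrite(Path(path), px.astype(np.float32), photometric="minisblack")


# ---------------------------------------------------------------------------
# Projections and filters
# ---------------------------------------------------------------------------


def _channel_planes(stack: ImageStack, role: str) -> np.ndarray:
    return stack.pixels[:, stack.channel_index(role), :, :]


def max_project(stack: ImageStack, role: str) -> Image2D:
    """Maximum Z-projection of one channel (morphology/counting channels)."""
    return Image2D(_channel_planes(stack, role).max(axis=0), stack.pixel_size_um)


def sum_project(stack: ImageStack, role: str) -> Image2D:
    """Sum Z-projection of one channel (intensity-quantification channels)."""
    return Image2D(_channel_planes(stack, role).sum(axis=0), stack.pixel_size_um)


def tophat(image: Image2D, radius_px: int) -> Image2D:
    """White top-hat: image minus its opening with a disk structuring element.

    Suppresses broad background while preserving features smaller than the
    disk.  Boundary handling clamps to the edge value, so the opening is
    pointwise <= the image and the result is everywhere >= 0.
    """
    if radius_px < 1:
        raise ValueError("tophat radius_px must be >= 1")
    footprint = skmorph.disk(int(radius_px))
    eroded = ndi.grey_erosion(image.pixels, footprint=footprint, mode="nearest")
    opened = ndi.grey_dilation(eroded, footprint=footprint, mode="nearest")
    return Image2D(image.pixels - opened, image.pixel_size_um)


def gaussian_blur(image: Image2D, sigma_px: float) -> Image2D:
    """Gaussian convolution with reflect boundary handling."""
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    return Image2D(ndi.gaussian_filter(image.pixels, sigma=sigma_px, mode="reflect"), image.pixel_size_um)


def threshold_binarize(
    image: Image2D,
    method: str = "otsu",
    value: float | None = None,
    log: ProvenanceLog | None = None,
) -> BinaryMask:
    """Binarize with a fixed or Otsu threshold; pixel is foreground iff ``> t``.

    The applied threshold is recorded in the provenance log so interactive
    threshold choices are reproducible.
    """
    if method == "fixed":
        if value is None:
            raise ValueError("method 'fixed' requires a threshold value")
        t = float(value)
    elif method == "otsu":
        flat = image.pixels.ravel()
        if np.unique(flat).size < 2:
            raise ValueError("Otsu thresholding requires at least 2 distinct intensities")
        t = float(threshold_otsu(flat))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    if log is not None:
        log.record("threshold_binarize", {"method": method}, {"threshold": t})
    return BinaryMask(image.pixels > t, image.pixel_size_um)


# ---------------------------------------------------------------------------
# Labeling
# ---------------------------------------------------------------------------


def _relabel_raster_order(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Relabel objects 1..n in raster-scan order of each object's first pixel."""
    ids, first = np.unique(labels.ravel(), return_index=True)
    keep = ids > 0
    ids, first = ids[keep], first[keep]
    order = np.argsort(first, kind="stable")
    mapping = np.zeros(int(labels.max()) + 1 if labels.size else 1, dtype=labels.dtype)
    for new, old in enumerate(ids[order], start=1):
        mapping[old] = new
    return mapping[labels], int(ids.size)


def connected_components(mask: BinaryMask, connectivity: int = 8) -> LabeledMask:
    """Label maximal connected foreground regions 1..n in raster-scan order."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    raw = skmeasure.label(mask.pixels, connectivity=1 if connectivity == 4 else 2)
    lab, n = _relabel_raster_order(raw)
    return LabeledMask(lab.astype(np.int32), mask.pixel_size_um, n)


def watershed_split(mask: BinaryMask, min_seed_distance_px: float = 3.0) -> LabeledMask:
    """Split merged blobs by a distance-transform-seeded watershed.

    Seeds are local maxima of the Euclidean distance transform separated by
    at least ``min_seed_distance_px``.  Every foreground pixel is assigned to
    exactly one label; the union of the labels equals the input mask.  Mask
    components left unreached by any seed (degenerate plateaus) are labeled
    as their own objects.
    """
    m = mask.pixels
    if not m.any():
        return LabeledMask(np.zeros(m.shape, dtype=np.int32), mask.pixel_size_um, 0)
    edt = ndi.distance_transform_edt(m)
    comp = skmeasure.label(m, connectivity=2)
    coords = peak_local_max(
        edt,
        min_distance=max(1, int(np.ceil(min_seed_distance_px))),
        exclude_border=False,
        labels=comp,
    )
    seeds = np.zeros(m.shape, dtype=bool)
    seeds[tuple(coords.T)] = True
    markers, _ = ndi.label(seeds, structure=_STRUCT_8)
    lab = sk_watershed(-edt, markers=markers, mask=m)
    leftover = m & (lab == 0)
    if leftover.any():
        extra = skmeasure.label(leftover, connectivity=2)
        lab = lab + np.where(extra > 0, extra + lab.max(), 0)
    lab, n = _relabel_raster_order(lab)
    return LabeledMask(lab.astype(np.int32), mask.pixel_size_um, n)


# ---------------------------------------------------------------------------
# Measurement
# ---------------------------------------------------------------------------


def _centroid_pixel(cy: float, cx: float, shape: tuple[int, int]) -> tuple[int, int]:
    y = int(np.clip(np.round(cy), 0, shape[0] - 1))
    x = int(np.clip(np.round(cx), 0, shape[1] - 1))
    return y, x


def measure_objects(
    labels: LabeledMask,
    intensity_images: Mapping[str, Image2D] | None = None,
    cell_labels: LabeledMask | None = None,
):
    """Measure every labeled object: area, centroid, per-channel intensities.

    Returns a :class:`pandas.DataFrame` with one row per object: ``object_id``,
    ``cell_id`` (cell label at the object's centroid, 0 if unassigned),
    ``area_um2``, ``centroid_y``/``centroid_x`` (pixels), ``touches_edge``,
    and ``mean_<role>`` / ``sum_<role>`` for each intensity image.
    """
    import pandas as pd

    intensity_images = dict(intensity_images or {})
    for role, img in intensity_images.items():
        if img.shape != labels.shape or img.pixel_size_um != labels.pixel_size_um:
            raise ValueError(f"intensity image {role!r} grid does not match labels")
    if cell_labels is not None and cell_labels.shape != labels.shape:
        raise ValueError("cell_labels grid does not match labels")

    ids = labels.object_ids()
    lab = labels.labels
    px_area = labels.pixel_size_um**2
    rows: dict[str, list] = {
        "object_id": [],
        "cell_id": [],
        "area_um2": [],
        "centroid_y": [],
        "centroid_x": [],
        "touches_edge": [],
    }
    counts = ndi.sum_labels(np.ones(lab.shape), lab, ids) if ids.size else np.array([])
    centroids = ndi.center_of_mass(np.ones(lab.shape), lab, ids) if ids.size else []
    border = np.zeros(lab.shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    edge_ids = set(np.unique(lab[border])) - {0}

    per_role_mean: dict[str, np.ndarray] = {}
    per_role_sum: dict[str, np.ndarray] = {}
    for role, img in intensity_images.items():
        if ids.size:
            per_role_sum[role] = ndi.sum_labels(img.pixels, lab, ids)
            per_role_mean[role] = per_role_sum[role] / counts
        else:
            per_role_sum[role] = np.array([])
            per_role_mean[role] = np.array([])

    for i, oid in enumerate(ids):
        cy, cx = centroids[i]
        rows["object_id"].append(int(oid))
        if cell_labels is not None:
            y, x = _centroid_pixel(cy, cx, lab.shape)
            rows["cell_id"].append(int(cell_labels.labels[y, x]))
        else:
            rows["cell_id"].append(0)
        rows["area_um2"].append(float(counts[i] * px_area))
        rows["centroid_y"].append(float(cy))
        rows["centroid_x"].append(float(cx))
        rows["touches_edge"].append(bool(oid in edge_ids))

    table = pd.DataFrame(rows)
    for role in intensity_images:
        table[f"mean_{role}"] = per_role_mean[role]
        table[f"sum_{role}"] = per_role_sum[role]
    return table
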