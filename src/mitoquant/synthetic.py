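"""Synthetic fluorescence fields and traces with known ground truth.

Every assay pipeline in this package is validated against simulated data in
which the quantities being estimated — per-cell mitolysosome counts, numbers
of small depolarized mitochondria, lysosome radial positions, nuclear/
cytoplasmic marker ratios, cristae spacing, respirometry phase levels — are
planted explicitly and recorded in a :class:`GroundTruth` object.

The simulator emulates the *statistical* structure of the assays, not
photorealism: cells are jittered disks on a grid, the mitochondrial network
is a dilated random walk of fixed tubule width, vesicles and mitolysosomes
are Gaussian spots, and the camera model is Poisson shot noise on the signal
plus additive Gaussian read noise.  Each generator is a pure function of its
parameters and seed: the same seed reproduces the field bit-for-bit, and
increasing the noise level changes pixels but never the ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import line as draw_line
from skimage.morphology import disk as disk_footprint

from .image_core import ImageStack
from .respirometry import OCRTrace, PHASES

__all__ = [
    "FieldParams",
    "CellTruth",
    "GroundTruth",
    "PlacementError",
    "generate_mitoqc_pair",
    "generate_tmre_field",
    "generate_lamp1_field",
    "generate_nuclear_marker_field",
    "generate_line_profile",
    "generate_ocr_trace",
]


class PlacementError(RuntimeError):
    """An object could not be placed without overlap after bounded retries."""


# puncta per cell a default-geometry cell can hold with all safety margins
_PUNCTA_CAPACITY = 16


@dataclass
class FieldParams:
    """Geometry, intensity and noise parameters of a simulated field.

    Defaults describe a high-SNR field of 16 fibroblast-like cells on a
    420x420 grid at 0.3 um/px: cell radius 9 um, nucleus 2.5 um, a
    5-segment tubular mitochondrial network of 0.45 um width per cell, and
    Poisson+Gaussian camera noise weak enough that Otsu thresholding
    recovers essentially all planted foreground.
    """

    field_size_px: tuple[int, int] = (420, 420)
    pixel_size_um: float = 0.3
    z_slices: int = 3
    z_step_um: float = 0.5
    n_cells: int = 16
    cell_radius_um: tuple[float, float] = (9.0, 0.5)
    nucleus_radius_um: tuple[float, float] = (2.5, 0.2)
    mito_segments_per_cell: int = 5
    mito_width_um: float = 0.45
    puncta_per_cell: float = 6.0
    puncta_radius_um: float = 0.36
    background_level: float = 5.0
    gaussian_sd: float = 2.0
    poisson_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("pixel sizes must be positive")
        if min(self.field_size_px) <= 0 or self.z_slices < 1:
            raise ValueError("field size and z_slices must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for name in ("cell_radius_um", "nucleus_radius_um"):
            mean, sd = getattr(self, name)
            if mean <= 0 or sd < 0:
                raise ValueError(f"{name} mean must be > 0 and sd >= 0")
        if self.mito_width_um <= 0 or self.puncta_radius_um <= 0:
            raise ValueError("structure widths must be positive")
        if self.puncta_per_cell < 0 or self.background_level < 0 or self.gaussian_sd < 0:
            raise ValueError("rates/levels must be non-negative")


@dataclass
class CellTruth:
    """Planted per-cell ground truth."""

    cell_id: int
    cell_centroid: tuple[float, float]
    nucleus_centroid: tuple[float, float]
    cell_radius_px: float
    nucleus_radius_px: float
    n_mitolysosomes_true: int = 0
    n_touching_true: int = 0
    n_small_mito_true: int = 0
    n_depolarized_true: int = 0
    vesicle_distances_um: list = field(default_factory=list)
    nuclear_marker_mean_true: float = float("nan")
    cyto_marker_mean_true: float = float("nan")
    mito_area_um2_true: float = 0.0


@dataclass
class GroundTruth:
    """Generator record of planted objects and global effect parameters."""

    cells: list = field(default_factory=list)
    cells_plus: list = field(default_factory=list)
    flux_ratio_true: float | None = None
    peripheral_fraction_true: float | None = None
    nuclear_fold_true: float | None = None
    cristae_per_um_true: float | None = None
    peak_positions_um: list = field(default_factory=list)
    ocr_levels_true: dict | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        raw["cells"] = [CellTruth(**{**c, "cell_centroid": tuple(c["cell_centroid"]),
                                     "nucleus_centroid": tuple(c["nucleus_centroid"])})
                        for c in raw.get("cells", [])]
        raw["cells_plus"] = [CellTruth(**{**c, "cell_centroid": tuple(c["cell_centroid"]),
                                          "nucleus_centroid": tuple(c["nucleus_centroid"])})
                             for c in raw.get("cells_plus", [])]
        return cls(**raw)


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def _place_cells(params: FieldParams, rng: np.random.Generator) -> list[CellTruth]:
    """Lay out non-overlapping cells on a jittered grid, away from the border."""
    if params.n_cells == 0:
        return []
    H, W = params.field_size_px
    px = params.pixel_size_um
    r_mean, r_sd = params.cell_radius_um
    n_mean, n_sd = params.nucleus_radius_um
    r_max = (r_mean + 3 * r_sd) / px
    margin = r_max + 12  # keep blurred cytoplasm tails off the border
    g = math.ceil(math.sqrt(params.n_cells))
    pitch_y = (H - 2 * margin) / g
    pitch_x = (W - 2 * margin) / g
    if min(pitch_y, pitch_x) < 2 * r_max + 4:
        raise ValueError("field too small for the requested cell count and radius")
    cells = []
    cid = 0
    for i in range(g):
        for j in range(g):
            if cid >= params.n_cells:
                break
            r = float(np.clip(rng.normal(r_mean, r_sd), 0.5 * r_mean, r_mean + 3 * r_sd)) / px
            nr = float(np.clip(rng.normal(n_mean, n_sd), 0.5 * n_mean, n_mean + 3 * n_sd)) / px
            jit_y = min(pitch_y, pitch_x) / 2 - r - 2
            jit = rng.uniform(-max(jit_y, 0.0), max(jit_y, 0.0), size=2)
            cy = margin + (i + 0.5) * pitch_y + jit[0]
            cx = margin + (j + 0.5) * pitch_x + jit[1]
            cid += 1
            cells.append(
                CellTruth(
                    cell_id=cid,
                    cell_centroid=(float(cy), float(cx)),
                    nucleus_centroid=(float(cy), float(cx)),
                    cell_radius_px=r,
                    nucleus_radius_px=nr,
                )
            )
    return cells


def _draw_network(
    canvas: np.ndarray, cell: CellTruth, params: FieldParams, rng: np.random.Generator
) -> np.ndarray:
    """Random-walk tubules radiating from the nucleus; returns the cell's mask."""
    H, W = canvas.shape
    cy, cx = cell.cell_centroid
    skel = np.zeros_like(canvas, dtype=bool)
    for _ in range(params.mito_segments_per_cell):
        theta = rng.uniform(0, 2 * np.pi)
        r0 = cell.nucleus_radius_px + 2.0
        y, x = cy + r0 * np.sin(theta), cx + r0 * np.cos(theta)
        heading = theta
        for _ in range(10):
            heading += rng.normal(0.0, 0.5)
            ny = y + 2.5 * np.sin(heading)
            nx = x + 2.5 * np.cos(heading)
            if (ny - cy) ** 2 + (nx - cx) ** 2 > (0.85 * cell.cell_radius_px) ** 2:
                heading += np.pi / 2  # deflect back toward the interior
                continue
            rr, cc = draw_line(int(round(y)), int(round(x)), int(round(ny)), int(round(nx)))
            ok = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
            skel[rr[ok], cc[ok]] = True
            y, x = ny, nx
    width_px = max(1, int(round(params.mito_width_um / params.pixel_size_um / 2)))
    tubules = ndi.binary_dilation(skel, structure=disk_footprint(width_px))
    canvas |= tubules
    return tubules


def _add_spot(canvas: np.ndarray, center: tuple[float, float], sigma_px: float, amp: float) -> None:
    H, W = canvas.shape
    cy, cx = center
    r = int(math.ceil(4 * sigma_px))
    y0, y1 = max(0, int(cy) - r), min(H, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(W, int(cx) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    canvas[y0:y1, x0:x1] += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma_px**2))


def _sample_point_in_cell(
    cell: CellTruth,
    rng: np.random.Generator,
    forbidden: np.ndarray,
    shape: tuple[int, int],
    r_min: float | None = None,
    r_max_frac: float = 0.80,
    max_tries: int = 2000,
) -> tuple[float, float]:
    """Uniform position inside the cell avoiding a forbidden mask."""
    cy, cx = cell.cell_centroid
    r_lo = cell.nucleus_radius_px + 2.0 if r_min is None else r_min
    r_hi = r_max_frac * cell.cell_radius_px
    for _ in range(max_tries):
        rad = math.sqrt(rng.uniform(r_lo**2, r_hi**2))
        th = rng.uniform(0, 2 * np.pi)
        y, x = cy + rad * np.sin(th), cx + rad * np.cos(th)
        iy, ix = int(round(y)), int(round(x))
        if 0 <= iy < shape[0] and 0 <= ix < shape[1] and not forbidden[iy, ix]:
            return y, x
    raise PlacementError("could not place object without overlap after bounded retries")


def _assemble_stack(
    canvases: dict[str, np.ndarray],
    params: FieldParams,
    rng: np.random.Generator,
) -> ImageStack:
    """Spread each 2-D ideal channel across Z and apply the camera noise model.

    Z weights peak at 1 in the central slice so a maximum projection recovers
    the ideal image (up to noise); the sum projection scales it by the weight
    total, which is all the intensity assays require.
    """
    base_w = np.array([0.55, 1.0, 0.65])
    if params.z_slices <= 3:
        w = base_w[:params.z_slices]
        w = w / w.max()
    else:
        w = np.interp(np.linspace(0, 2, params.z_slices), [0, 1, 2], base_w)
    roles = sorted(canvases)
    H, W = params.field_size_px
    pixels = np.zeros((params.z_slices, len(roles), H, W), dtype=float)
    for ci, role in enumerate(roles):
        ideal = canvases[role] + params.background_level
        for zi in range(params.z_slices):
            plane = w[zi] * ideal
            if params.poisson_noise:
                plane = rng.poisson(plane).astype(float)
            if params.gaussian_sd > 0:
                plane = plane + rng.normal(0.0, params.gaussian_sd, size=plane.shape)
            pixels[zi, ci] = np.clip(plane, 0.0, None)
    return ImageStack(
        pixels=pixels,
        pixel_size_um=params.pixel_size_um,
        channel_roles={role: i for i, role in enumerate(roles)},
        z_step_um=params.z_step_um,
    )


# Intensity levels of the ideal (pre-noise) channels; arbitrary camera counts.
_LEVELS = {
    "dapi_nucleus": 160.0,
    "cyto_fill": 40.0,
    "network": 150.0,
    "punctum_amp": 220.0,
    "tmre_polarized_amp": 150.0,
    "marker_cyto": 40.0,
}


# ---------------------------------------------------------------------------
# Field generators
# ---------------------------------------------------------------------------


def _mitoqc_field(
    params: FieldParams,
    lam: float,
    touching_fraction: float,
    rng: np.random.Generator,
) -> tuple[ImageStack, list[CellTruth]]:
    H, W = params.field_size_px
    px = params.pixel_size_um
    cells = _place_cells(params, rng)
    dapi = np.zeros((H, W))
    gfp = np.zeros((H, W))
    mcherry = np.zeros((H, W))
    network_all = np.zeros((H, W), dtype=bool)
    sigma_spot = max(params.puncta_radius_um / px, 0.8)

    for cell in cells:
        cell_mask = _disk_mask((H, W), cell.cell_centroid, cell.cell_radius_px)
        nuc_mask = _disk_mask((H, W), cell.nucleus_centroid, cell.nucleus_radius_px)
        dapi[nuc_mask] += _LEVELS["dapi_nucleus"]
        gfp[cell_mask] += _LEVELS["cyto_fill"]
        tubules = _draw_network(network_all, cell, params, rng)
        gfp[tubules] += _LEVELS["network"]
        mcherry[tubules] += _LEVELS["network"]
        cell.mito_area_um2_true = float(tubules.sum()) * px**2

        n_total = int(rng.poisson(lam))
        n_touching = int(rng.binomial(n_total, touching_fraction)) if touching_fraction > 0 else 0
        # Poisson draws are capped at the cell's geometric capacity so the
        # field stays placeable; truth records what was actually planted
        n_free = min(n_total - n_touching, _PUNCTA_CAPACITY)
        # free mitolysosomes: off the network by a safety margin so the
        # detected spot can never become 8-adjacent to the detected network
        forbidden = ndi.binary_dilation(network_all, structure=disk_footprint(4))
        placed = 0
        for _ in range(n_free):
            try:
                y, x = _sample_point_in_cell(cell, rng, forbidden, (H, W))
            except PlacementError:
                break  # cell is full; the planted count is the truth
            _add_spot(mcherry, (y, x), sigma_spot, _LEVELS["punctum_amp"])
            forbidden[_disk_mask((H, W), (y, x), 4.0)] = True
            placed += 1
        cell.n_mitolysosomes_true = placed
        # touching puncta: centered on a network pixel of this cell
        tub_idx = np.argwhere(tubules)
        n_touch_placed = 0
        for _ in range(n_touching):
            if tub_idx.size == 0:
                break
            y, x = tub_idx[rng.integers(len(tub_idx))]
            _add_spot(mcherry, (float(y), float(x)), sigma_spot, _LEVELS["punctum_amp"])
            n_touch_placed += 1
        cell.n_touching_true = n_touch_placed

    stack = _assemble_stack({"dapi": dapi, "gfp": gfp, "mcherry": mcherry}, params, rng)
    return stack, cells


def generate_mitoqc_pair(
    params: FieldParams,
    flux_ratio: float,
    seed: int,
    touching_fraction: float = 0.0,
) -> tuple[ImageStack, ImageStack, GroundTruth]:
    """Paired tandem-reporter fields without/with lysosomal protease inhibitors.

    Both fields carry DAPI, GFP and mCherry channels with the mitochondrial
    network drawn in GFP and mCherry.  The "minus" field plants
    Poisson(``puncta_per_cell``) mCherry-only puncta per cell off the network;
    the "plus" (inhibitor) field plants Poisson(rate x ``flux_ratio``),
    emulating mitolysosome accumulation under blocked degradation.
    ``touching_fraction`` of puncta are instead planted on the network (they
    are not mitolysosomes and must be excluded by the counting rule).
    """
    if flux_ratio < 1:
        raise ValueError("flux_ratio must be >= 1")
    if not 0 <= touching_fraction <= 1:
        raise ValueError("touching_fraction must be in [0, 1]")
    rng_minus = np.random.default_rng([int(seed), 11])
    rng_plus = np.random.default_rng([int(seed), 13])
    stack_minus, cells_minus = _mitoqc_field(params, params.puncta_per_cell, touching_fraction, rng_minus)
    stack_plus, cells_plus = _mitoqc_field(
        params, params.puncta_per_cell * flux_ratio, touching_fraction, rng_plus
    )
    truth = GroundTruth(cells=cells_minus, cells_plus=cells_plus, flux_ratio_true=float(flux_ratio))
    return stack_minus, stack_plus, truth


def generate_tmre_field(
    params: FieldParams,
    n_small: int,
    n_depolarized: int,
    seed: int,
    tmre_background: float = 8.0,
) -> tuple[ImageStack, GroundTruth]:
    """Membrane-potential field: MTG mass channel plus a TMRE potential channel.

    Each cell's MTG channel carries the tubular network plus ``n_small``
    individualized objects of sub-1-um^2 area; ``n_depolarized`` of those get
    TMRE at the background level (depolarized) and the rest get a strong TMRE
    signal, as does the network.  Truth records all three counts per cell.
    """
    if n_small < 0 or n_depolarized < 0 or n_depolarized > n_small:
        raise ValueError("need 0 <= n_depolarized <= n_small")
    rng = np.random.default_rng([int(seed), 17])
    H, W = params.field_size_px
    px = params.pixel_size_um
    cells = _place_cells(params, rng)
    dapi = np.zeros((H, W))
    mtg = np.zeros((H, W))
    tmre = np.full((H, W), float(tmre_background))
    network_all = np.zeros((H, W), dtype=bool)
    # small individualized mitochondria: tight spots whose thresholded area
    # stays well under the 1 um^2 cutoff
    sigma_small = max(0.35 / px / 1.6, 0.7)

    for cell in cells:
        cell_mask = _disk_mask((H, W), cell.cell_centroid, cell.cell_radius_px)
        nuc_mask = _disk_mask((H, W), cell.nucleus_centroid, cell.nucleus_radius_px)
        dapi[nuc_mask] += _LEVELS["dapi_nucleus"]
        mtg[cell_mask] += 30.0  # out-of-focus whole-cell MTG haze; carries cell detection
        tubules = _draw_network(network_all, cell, params, rng)
        mtg[tubules] += _LEVELS["network"]
        tmre[tubules] += _LEVELS["tmre_polarized_amp"]
        cell.mito_area_um2_true = float(tubules.sum()) * px**2

        forbidden = ndi.binary_dilation(network_all, structure=disk_footprint(5))
        for k in range(n_small):
            y, x = _sample_point_in_cell(cell, rng, forbidden, (H, W))
            _add_spot(mtg, (y, x), sigma_small, 140.0)
            if k >= n_depolarized:  # polarized small mitochondria
                _add_spot(tmre, (y, x), sigma_small, _LEVELS["tmre_polarized_amp"])
            forbidden[_disk_mask((H, W), (y, x), 6.0)] = True
        cell.n_small_mito_true = n_small
        cell.n_depolarized_true = n_depolarized

    stack = _assemble_stack({"dapi": dapi, "mtg": mtg, "tmre": tmre}, params, rng)
    return stack, GroundTruth(cells=cells)


def generate_lamp1_field(
    params: FieldParams,
    peripheral_fraction: float,
    seed: int,
) -> tuple[ImageStack, GroundTruth]:
    """Lysosome-distribution field: vesicles at controlled nucleus distances.

    Vesicle distances from the nucleus edge are drawn from a two-component
    radial mixture: a perinuclear component near the nucleus and a peripheral
    component near the cell edge, mixed with weight ``peripheral_fraction``.
    Truth stores every vesicle's planted distance (um) and the mixture weight.
    A mitochondrial-marker channel provides the per-cell mitochondrial area
    used to normalize the peripheral count.
    """
    if not 0 <= peripheral_fraction <= 1:
        raise ValueError("peripheral_fraction must be in [0, 1]")
    rng = np.random.default_rng([int(seed), 19])
    H, W = params.field_size_px
    px = params.pixel_size_um
    cells = _place_cells(params, rng)
    dapi = np.zeros((H, W))
    lamp1 = np.zeros((H, W))
    mito = np.zeros((H, W))
    network_all = np.zeros((H, W), dtype=bool)
    sigma_spot = max(params.puncta_radius_um / px, 0.8)

    for cell in cells:
        cell_mask = _disk_mask((H, W), cell.cell_centroid, cell.cell_radius_px)
        nuc_mask = _disk_mask((H, W), cell.nucleus_centroid, cell.nucleus_radius_px)
        dapi[nuc_mask] += _LEVELS["dapi_nucleus"]
        mito[cell_mask] += 30.0
        tubules = _draw_network(network_all, cell, params, rng)
        mito[tubules] += _LEVELS["network"]
        cell.mito_area_um2_true = float(tubules.sum()) * px**2

        d_max_px = 0.80 * cell.cell_radius_px - cell.nucleus_radius_px - 2.0
        n_ves = int(rng.poisson(params.puncta_per_cell))
        taken = np.zeros((H, W), dtype=bool)
        distances = []
        for _ in range(n_ves):
            peripheral = rng.random() < peripheral_fraction
            placed = False
            for _ in range(400):
                # resample the radial draw each try so crowding in one band
                # cannot exhaust the retries; the component stays fixed
                if peripheral:
                    d = rng.normal(0.85 * d_max_px, 0.06 * d_max_px)
                else:
                    d = abs(rng.normal(0.30 * d_max_px, 0.16 * d_max_px))
                d = float(np.clip(d, 0.5, d_max_px))
                th = rng.uniform(0, 2 * np.pi)
                y = cell.nucleus_centroid[0] + (cell.nucleus_radius_px + d) * np.sin(th)
                x = cell.nucleus_centroid[1] + (cell.nucleus_radius_px + d) * np.cos(th)
                iy, ix = int(round(y)), int(round(x))
                if 0 <= iy < H and 0 <= ix < W and not taken[iy, ix]:
                    placed = True
                    break
            if not placed:
                break  # cell is full; truth keeps only the planted vesicles
            _add_spot(lamp1, (y, x), sigma_spot, _LEVELS["punctum_amp"])
            taken[_disk_mask((H, W), (y, x), sigma_spot + 2)] = True
            distances.append(d * px)
        cell.vesicle_distances_um = distances

    stack = _assemble_stack({"dapi": dapi, "lamp1": lamp1, "mito_marker": mito}, params, rng)
    return stack, GroundTruth(cells=cells, peripheral_fraction_true=float(peripheral_fraction))


def generate_nuclear_marker_field(
    params: FieldParams,
    nuclear_fold: float,
    seed: int,
) -> tuple[ImageStack, GroundTruth]:
    """Nuclear-translocation field: marker at cytoplasm level c, nucleus c*fold.

    The marker channel fills each cell at a constant cytoplasmic level and
    the nucleus (drawn on exactly the DAPI disk) at ``nuclear_fold`` times
    that level, plus camera noise.  Truth records both true means per cell.
    """
    if nuclear_fold <= 0:
        raise ValueError("nuclear_fold must be positive")
    rng = np.random.default_rng([int(seed), 23])
    H, W = params.field_size_px
    cells = _place_cells(params, rng)
    dapi = np.zeros((H, W))
    marker = np.zeros((H, W))
    c = _LEVELS["marker_cyto"]
    # the camera background is added to every channel at assembly time, so
    # plant levels net of background: the *measured* means are then exactly
    # c in the cytoplasm and c*fold in the nucleus
    b = params.background_level
    if c - b <= 0 or c * nuclear_fold - b <= 0:
        raise ValueError("marker level must exceed the background level")
    for cell in cells:
        cell_mask = _disk_mask((H, W), cell.cell_centroid, cell.cell_radius_px)
        nuc_mask = _disk_mask((H, W), cell.nucleus_centroid, cell.nucleus_radius_px)
        dapi[nuc_mask] += _LEVELS["dapi_nucleus"]
        marker[cell_mask & ~nuc_mask] += c - b
        marker[nuc_mask] += c * nuclear_fold - b
        cell.cyto_marker_mean_true = float(c)
        cell.nuclear_marker_mean_true = float(c * nuclear_fold)
    stack = _assemble_stack({"dapi": dapi, "marker": marker}, params, rng)
    return stack, GroundTruth(cells=cells, nuclear_fold_true=float(nuclear_fold))


def generate_line_profile(
    cristae_per_um: float,
    length_um: float,
    pixel_size_um: float,
    noise_sd: float,
    seed: int,
    amplitude: float = 100.0,
    offset: float = 10.0,
) -> tuple[np.ndarray, GroundTruth]:
    """1-D line-profile across cristae: a sinusoid plus Gaussian noise.

    The profile has exactly ``round(cristae_per_um * length_um)`` equally
    spaced peaks, none at the endpoints.  Sampling must respect Nyquist:
    ``pixel_size_um < 1 / (2 * cristae_per_um)``.  Returns the intensity
    samples and truth with the planted peak positions (um).
    """
    if cristae_per_um < 0 or length_um <= 0 or pixel_size_um <= 0 or noise_sd < 0:
        raise ValueError("profile parameters must be non-negative (length/pixel positive)")
    rng = np.random.default_rng([int(seed), 29])
    n = int(round(length_um / pixel_size_um)) + 1
    x = np.arange(n) * pixel_size_um
    length = (n - 1) * pixel_size_um
    if cristae_per_um == 0:
        profile = np.full(n, offset) + rng.normal(0.0, noise_sd, n)
        return profile, GroundTruth(cristae_per_um_true=0.0, peak_positions_um=[])
    if pixel_size_um >= 1.0 / (2.0 * cristae_per_um):
        raise ValueError("Nyquist violation: pixel_size_um must be < 1/(2*cristae_per_um)")
    n_peaks = int(round(cristae_per_um * length))
    spacing = length / n_peaks
    profile = offset + amplitude * 0.5 * (1.0 + np.cos(2 * np.pi * (x / spacing - 0.5)))
    profile = profile + rng.normal(0.0, noise_sd, n)
    positions = [(k + 0.5) * spacing for k in range(n_peaks)]
    return profile, GroundTruth(
        cristae_per_um_true=float(n_peaks / length), peak_positions_um=positions
    )


def generate_ocr_trace(
    levels: dict[str, float],
    n_per_phase: int,
    noise_sd: float,
    seed: int,
    dt_min: float = 6.5,
    well_id: str = "A1",
    group: str = "synthetic",
) -> tuple[OCRTrace, GroundTruth]:
    """Piecewise-constant mito-stress-test OCR trace with Gaussian noise.

    ``levels`` maps the four phases (``basal``, ``oligomycin``, ``fccp``,
    ``rot_aa``) to their noiseless OCR plateaus (pmol O2/min); the phases
    appear in protocol order with ``n_per_phase`` measurements each.
    """
    missing = [p for p in PHASES if p not in levels]
    if missing:
        raise ValueError(f"missing phase level(s): {missing}")
    if n_per_phase < 1:
        raise ValueError("n_per_phase must be >= 1")
    if any(levels[p] < 0 for p in PHASES):
        raise ValueError("phase levels must be >= 0")
    rng = np.random.default_rng([int(seed), 31])
    rows = []
    t = 0.0
    for phase in PHASES:
        for _ in range(n_per_phase):
            ocr = levels[phase] + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append({"time_min": t, "ocr": ocr, "phase": phase})
            t += dt_min
    trace = OCRTrace(data=pd.DataFrame(rows), well_id=well_id, group=group)
    truth = GroundTruth(ocr_levels_true={p: float(levels[p]) for p in PHASES})
    return trace, truth
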