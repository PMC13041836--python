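"""Per-cell organelle statistics: the headline assay quantifications.

Implements the counting and intensity rules shared by the imaging assays:

* mitolysosome counting — tandem-reporter (GFP+mCherry) puncta that are red
  only, i.e. mCherry objects *not touching* the GFP mask;
* mitophagy flux — ratio of mean mitolysosome counts with vs without
  lysosomal protease inhibitors;
* mitochondrial mass — summed mitochondrial mask area per cell;
* depolarized-mitochondria classification — sub-1-um^2 mitochondrial-mass
  objects whose potential-dye intensity falls below a background-derived
  cutoff;
* touching-puncta counts (mitophagosomes, lysosome–mitochondria contacts);
* lysosome spatial distribution — vesicles beyond the 75th-percentile
  nucleus distance, normalized per mitochondrial area;
* masked and nuclear mean intensities (degradative activity, nuclear
  translocation).

"Touching" is one shared predicate throughout: pixel overlap or
8-adjacency.  Mitolysosome counting excludes touching objects, while
mitophagosome counting includes them — the same rule with opposite polarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .image_core import BinaryMask, Image2D, LabeledMask, measure_objects
from .provenance import ProvenanceLog
from .segmentation import CellSegmentation

__all__ = [
    "FluxResult",
    "DepolarizationResult",
    "SpatialDistribution",
    "touching_object_ids",
    "count_mitolysosomes",
    "compute_flux",
    "mito_mass",
    "classify_depolarized",
    "count_touching_puncta",
    "lysosome_distribution",
    "mean_intensity_in_mask",
    "nuclear_mean_intensity",
    "cytoplasmic_mean_intensity",
    "mito_morphology",
]

_STRUCT_8 = np.ones((3, 3), dtype=bool)


@dataclass
class FluxResult:
    """Mitophagy flux: ratio of per-condition mean mitolysosome counts."""

    counts_minus: np.ndarray
    counts_plus: np.ndarray
    mean_minus: float
    mean_plus: float
    flux_ratio: float
    defined: bool
    n_minus: int
    n_plus: int


@dataclass
class DepolarizationResult:
    """Per-cell counts of small (individualized) and depolarized mitochondria."""

    per_cell: pd.DataFrame  # cell_id, n_individualized_small, n_depolarized
    tmre_background_cutoff: float
    area_cutoff_um2: float


@dataclass
class SpatialDistribution:
    """Lysosome radial-distribution statistic relative to the nuclei."""

    distances_um: pd.DataFrame  # cell_id, object_id, distance_um
    percentile_threshold_um: float
    per_cell: pd.DataFrame  # cell_id, peripheral_count, peripheral_per_mito_area
    reference_condition: str


# ---------------------------------------------------------------------------
# Touching predicate
# ---------------------------------------------------------------------------


def touching_object_ids(labels: LabeledMask, mask: BinaryMask) -> set[int]:
    """Ids of labeled objects with any pixel overlapping or 8-adjacent to mask."""
    if labels.shape != mask.shape:
        raise ValueError("label and mask grids differ")
    dilated = ndi.binary_dilation(mask.pixels, structure=_STRUCT_8)
    hit = labels.labels[dilated]
    return set(int(i) for i in np.unique(hit) if i > 0)


def _objects_by_cell(
    labels: LabeledMask, cells: CellSegmentation
) -> pd.DataFrame:
    """Object table with each object assigned to the cell at its centroid."""
    return measure_objects(labels, intensity_images={}, cell_labels=cells.cells)


# ---------------------------------------------------------------------------
# Mitolysosomes and flux
# ---------------------------------------------------------------------------


def count_mitolysosomes(
    cells: CellSegmentation,
    gfp_mask: BinaryMask,
    mcherry_labels: LabeledMask,
) -> pd.DataFrame:
    """Count red-only puncta per retained cell.

    An mCherry object is a mitolysosome iff none of its pixels coincide with
    or are 8-adjacent to a GFP-mask pixel (GFP is quenched in the acidic
    lysosome, so red-only puncta mark mitochondria inside lysosomes).
    Returns one row per retained cell: ``n_puncta`` (all mCherry objects
    assigned to the cell), ``n_touching_gfp`` and ``n_mitolysosomes``; the two
    subsets partition the total.
    """
    retained = cells.retained_ids
    if retained.size == 0:
        raise ValueError("no retained cells")
    if gfp_mask.shape != mcherry_labels.shape:
        raise ValueError("GFP mask and mCherry labels grids differ")
    table = _objects_by_cell(mcherry_labels, cells)
    touching = touching_object_ids(mcherry_labels, gfp_mask)
    rows = []
    for cid in retained:
        objs = table[table["cell_id"] == cid]
        n_touch = int(objs["object_id"].isin(touching).sum())
        rows.append(
            {
                "cell_id": int(cid),
                "n_puncta": int(len(objs)),
                "n_touching_gfp": n_touch,
                "n_mitolysosomes": int(len(objs)) - n_touch,
            }
        )
    return pd.DataFrame(rows)


def compute_flux(
    counts_minus: np.ndarray | pd.Series, counts_plus: np.ndarray | pd.Series
) -> FluxResult:
    """Flux ratio = mean per-cell count with inhibitor / mean without.

    Cells are not paired across wells, so the ratio of per-condition means
    is used (not a mean of per-cell ratios).  The ratio is undefined when
    the uninhibited arm's mean is zero.
    """
    minus = np.asarray(counts_minus, dtype=float)
    plus = np.asarray(counts_plus, dtype=float)
    if minus.size == 0 or plus.size == 0:
        raise ValueError("both arms must be non-empty")
    mean_minus = float(minus.mean())
    mean_plus = float(plus.mean())
    defined = mean_minus > 0
    ratio = mean_plus / mean_minus if defined else float("nan")
    return FluxResult(
        counts_minus=minus,
        counts_plus=plus,
        mean_minus=mean_minus,
        mean_plus=mean_plus,
        flux_ratio=ratio,
        defined=defined,
        n_minus=int(minus.size),
        n_plus=int(plus.size),
    )


def mito_mass(cells: CellSegmentation, mito_mask: BinaryMask) -> pd.Series:
    """Summed mitochondrial-mask area (um^2) per retained cell."""
    if mito_mask.shape != cells.cells.shape:
        raise ValueError("mask grid does not match segmentation")
    retained = cells.retained_ids
    px2 = cells.cells.pixel_size_um**2
    if retained.size == 0:
        return pd.Series(dtype=float, name="mito_area_um2")
    counts = ndi.sum_labels(
        mito_mask.pixels.astype(float), cells.cells.labels, index=retained
    )
    return pd.Series(np.atleast_1d(counts) * px2, index=retained, name="mito_area_um2")


# ---------------------------------------------------------------------------
# Depolarized-mitochondria classification
# ---------------------------------------------------------------------------


def classify_depolarized(
    cells: CellSegmentation,
    mtg_labels: LabeledMask,
    tmre_sum: Image2D,
    area_cutoff_um2: float = 1.0,
    bg_k: float = 3.0,
    log: ProvenanceLog | None = None,
) -> DepolarizationResult:
    """Count small individualized mitochondria and the depolarized subset.

    A mitochondrial-mass object is "individualized small" iff its area is
    below ``area_cutoff_um2`` (default 1 um^2).  The potential-dye cutoff is
    derived from the field itself: mean + ``bg_k`` x SD of the summed TMRE
    projection over non-mitochondrial pixels inside retained cells; a small
    object is depolarized iff its mean TMRE falls below that cutoff.  Both
    counts are invariant to a uniform additive TMRE offset (the cutoff
    shifts equally) and to relabeling of the mass objects.
    """
    if tmre_sum.shape != mtg_labels.shape:
        raise ValueError("TMRE image grid does not match MTG labels")
    cell_mask = cells.retained_cell_mask()
    background = cell_mask & (mtg_labels.labels == 0)
    if not background.any():
        raise ValueError("no background pixels: mitochondrial mask covers all retained cells")
    bg_vals = tmre_sum.pixels[background]
    cutoff = float(bg_vals.mean() + bg_k * bg_vals.std())
    if log is not None:
        log.record(
            "classify_depolarized",
            {"bg_k": bg_k, "area_cutoff_um2": area_cutoff_um2},
            {"tmre_background_cutoff": cutoff},
        )
    table = measure_objects(
        mtg_labels, intensity_images={"tmre": tmre_sum}, cell_labels=cells.cells
    )
    retained = set(int(i) for i in cells.retained_ids)
    rows = []
    for cid in sorted(retained):
        objs = table[table["cell_id"] == cid]
        small = objs[objs["area_um2"] < area_cutoff_um2]
        depol = small[small["mean_tmre"] < cutoff]
        rows.append(
            {
                "cell_id": cid,
                "n_individualized_small": int(len(small)),
                "n_depolarized": int(len(depol)),
            }
        )
    return DepolarizationResult(
        per_cell=pd.DataFrame(rows),
        tmre_background_cutoff=cutoff,
        area_cutoff_um2=float(area_cutoff_um2),
    )


# ---------------------------------------------------------------------------
# Touching puncta (mitophagosomes / contact counting)
# ---------------------------------------------------------------------------


def count_touching_puncta(
    cells: CellSegmentation,
    vesicle_labels: LabeledMask,
    target_mask: BinaryMask,
) -> pd.DataFrame:
    """Count vesicles per retained cell that touch the target mask.

    A vesicle counts iff at least one of its pixels overlaps or is
    8-adjacent to the target (e.g. LC3 vesicles touching the mitochondrial
    mask are mitophagosomes); containment counts once.
    """
    if vesicle_labels.shape != target_mask.shape:
        raise ValueError("vesicle labels and target mask grids differ")
    table = _objects_by_cell(vesicle_labels, cells)
    touching = touching_object_ids(vesicle_labels, target_mask)
    rows = []
    for cid in cells.retained_ids:
        objs = table[table["cell_id"] == cid]
        rows.append(
            {
                "cell_id": int(cid),
                "n_vesicles": int(len(objs)),
                "n_touching": int(objs["object_id"].isin(touching).sum()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Lysosome radial distribution
# ---------------------------------------------------------------------------


def lysosome_distribution(
    cells: CellSegmentation,
    lyso_labels: LabeledMask,
    nuclei: LabeledMask,
    mito_area_per_cell: pd.Series,
    reference_distances: np.ndarray | None = None,
    reference_condition: str = "self",
    log: ProvenanceLog | None = None,
) -> SpatialDistribution:
    """Peripheral-lysosome statistic.

    Each vesicle's distance (um) is from its centroid to the nearest pixel
    of its own cell's nucleus.  The peripheral threshold is the 75th
    percentile (linear interpolation) of ``reference_distances`` when given
    — normally the control condition, so the statistic is comparable across
    arms — otherwise of the pooled distances of this field.  A vesicle is
    peripheral iff its distance is strictly greater than the threshold;
    per-cell counts are normalized by the cell's mitochondrial area.
    """
    if lyso_labels.shape != nuclei.shape:
        raise ValueError("lysosome labels and nuclei grids differ")
    px = lyso_labels.pixel_size_um
    table = _objects_by_cell(lyso_labels, cells)
    retained = set(int(i) for i in cells.retained_ids)
    nuc_ids = set(int(i) for i in nuclei.object_ids())

    recs = []
    for cid in sorted(retained):
        objs = table[table["cell_id"] == cid]
        if len(objs) == 0:
            continue
        if cid not in nuc_ids:
            raise ValueError(f"cell {cid} has no nucleus")
        # distance map to this cell's nucleus
        edt = ndi.distance_transform_edt(nuclei.labels != cid)
        for _, row in objs.iterrows():
            y = int(np.clip(np.round(row["centroid_y"]), 0, edt.shape[0] - 1))
            x = int(np.clip(np.round(row["centroid_x"]), 0, edt.shape[1] - 1))
            recs.append(
                {
                    "cell_id": cid,
                    "object_id": int(row["object_id"]),
                    "distance_um": float(edt[y, x] * px),
                }
            )
    dist_df = pd.DataFrame(recs, columns=["cell_id", "object_id", "distance_um"])
    pooled = dist_df["distance_um"].to_numpy(float)
    if reference_distances is not None:
        ref = np.asarray(reference_distances, dtype=float)
    else:
        ref = pooled
        reference_condition = "self"
    if ref.size == 0:
        raise ValueError("no distances available to set the percentile threshold")
    threshold = float(np.percentile(ref, 75))
    if log is not None:
        log.record(
            "lysosome_distribution",
            {"reference_condition": reference_condition},
            {"percentile_threshold_um": threshold},
        )
    rows = []
    for cid in sorted(retained):
        d = dist_df.loc[dist_df["cell_id"] == cid, "distance_um"].to_numpy(float)
        n_periph = int((d > threshold).sum())
        area = float(mito_area_per_cell.get(cid, float("nan")))
        rows.append(
            {
                "cell_id": cid,
                "peripheral_count": n_periph,
                "peripheral_per_mito_area": n_periph / area if area > 0 else float("nan"),
            }
        )
    return SpatialDistribution(
        distances_um=dist_df,
        percentile_threshold_um=threshold,
        per_cell=pd.DataFrame(rows),
        reference_condition=reference_condition,
    )


# ---------------------------------------------------------------------------
# Intensity statistics
# ---------------------------------------------------------------------------


def mean_intensity_in_mask(
    intensity: Image2D,
    mask: BinaryMask,
    per_cell: bool = False,
    cells: CellSegmentation | None = None,
):
    """Arithmetic mean intensity over mask pixels, optionally per retained cell.

    An empty mask (globally, or within a cell) yields NaN for that value.
    """
    if intensity.shape != mask.shape:
        raise ValueError("intensity and mask grids differ")
    if not per_cell:
        if not mask.pixels.any():
            return float("nan")
        return float(intensity.pixels[mask.pixels].mean())
    if cells is None:
        raise ValueError("per_cell=True requires a CellSegmentation")
    out = {}
    for cid in cells.retained_ids:
        m = mask.pixels & (cells.cells.labels == cid)
        out[int(cid)] = float(intensity.pixels[m].mean()) if m.any() else float("nan")
    return pd.Series(out, name="mean_intensity")


def nuclear_mean_intensity(cells: CellSegmentation, marker: Image2D) -> pd.Series:
    """Mean marker intensity over each retained cell's nucleus mask."""
    if marker.shape != cells.nuclei.shape:
        raise ValueError("marker grid does not match nuclei")
    out = {}
    for cid in cells.retained_ids:
        m = cells.nuclei.labels == cid
        out[int(cid)] = float(marker.pixels[m].mean()) if m.any() else float("nan")
    return pd.Series(out, name="nuclear_mean")


def cytoplasmic_mean_intensity(cells: CellSegmentation, marker: Image2D) -> pd.Series:
    """Mean marker intensity over cell-minus-nucleus pixels per retained cell."""
    if marker.shape != cells.cells.shape:
        raise ValueError("marker grid does not match cells")
    out = {}
    for cid in cells.retained_ids:
        m = (cells.cells.labels == cid) & (cells.nuclei.labels != cid)
        out[int(cid)] = float(marker.pixels[m].mean()) if m.any() else float("nan")
    return pd.Series(out, name="cyto_mean")


def mito_morphology(labels: LabeledMask) -> dict[str, float]:
    """Simple morphology descriptors of a mitochondrial labeling.

    Object count, mean and total object area (um^2), and the area-weighted
    mean aspect ratio of the objects' fitted ellipses.
    """
    from skimage.measure import regionprops

    props = regionprops(labels.labels)
    px2 = labels.pixel_size_um**2
    if not props:
        return {"n_objects": 0, "mean_area_um2": float("nan"), "total_area_um2": 0.0,
                "aspect_ratio_weighted": float("nan")}
    areas = np.array([p.area for p in props], dtype=float)
    aspect = np.array(
        [p.axis_major_length / p.axis_minor_length if p.axis_minor_length > 0 else 1.0 for p in props]
    )
    return {
        "n_objects": int(len(props)),
        "mean_area_um2": float(areas.mean() * px2),
        "total_area_um2": float(areas.sum() * px2),
        "aspect_ratio_weighted": float((areas * aspect).sum() / areas.sum()),
    }
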