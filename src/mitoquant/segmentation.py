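"""Cell-by-cell segmentation: nuclei, cytoplasm partition, exclusions.

The high-content analysis convention implemented here: nuclei are detected
from the DAPI channel (Otsu, hole filling, small-object removal); the
cytoplasm comes from a heavily Gaussian-blurred cell-wide channel; cells are
a nucleus-seeded watershed partition of the cytoplasm mask, so each cell
carries the label of its nucleus.  Cells touching the field border are
excluded (they are not fully depicted), and an optional per-field intensity
gate drops cells with atypically low or high reporter expression so only the
medium-expression population is analyzed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.segmentation import watershed as sk_watershed

from .image_core import Image2D, LabeledMask, gaussian_blur, threshold_binarize
from .provenance import ProvenanceLog

__all__ = [
    "CellSegmentation",
    "segment_nuclei",
    "segment_cells",
    "exclude_edge_cells",
    "gate_cells_by_intensity",
    "per_cell_mean_intensity",
]


@dataclass
class CellSegmentation:
    """Nucleus and cell labelings plus the exclusion bookkeeping.

    Labels are never rewritten on exclusion; excluded ids are recorded in
    ``excluded_edge_ids`` / ``excluded_gate_ids`` and all per-cell statistics
    are computed over :meth:`retained_ids` only.
    """

    nuclei: LabeledMask
    cells: LabeledMask
    excluded_edge_ids: list = field(default_factory=list)
    excluded_gate_ids: list = field(default_factory=list)
    gate_bounds: tuple | None = None
    warnings: list = field(default_factory=list)

    @property
    def retained_ids(self) -> np.ndarray:
        excluded = set(self.excluded_edge_ids) | set(self.excluded_gate_ids)
        ids = self.cells.object_ids()
        return np.array([i for i in ids if i not in excluded], dtype=int)

    def retained_cell_mask(self) -> np.ndarray:
        return np.isin(self.cells.labels, self.retained_ids) & (self.cells.labels > 0)


def _otsu_separability(pixels: np.ndarray, threshold: float) -> float:
    """Otsu's effectiveness metric: between-class variance over total variance."""
    v = pixels.ravel()
    lo, hi = v[v <= threshold], v[v > threshold]
    if lo.size == 0 or hi.size == 0 or v.var() == 0:
        return 0.0
    w0, w1 = lo.size / v.size, hi.size / v.size
    return float(w0 * w1 * (lo.mean() - hi.mean()) ** 2 / v.var())


def segment_nuclei(
    dapi: Image2D,
    min_area_um2: float = 10.0,
    min_separability: float = 0.7,
    log: ProvenanceLog | None = None,
) -> LabeledMask:
    """Nuclei from the DAPI channel: Otsu, fill holes, drop small objects.

    An empty (noise-only) field has no meaningful Otsu threshold; the
    threshold's separability (between-class over total variance) is checked
    against ``min_separability`` and a field below it yields zero nuclei.
    """
    inner = ProvenanceLog()
    mask = threshold_binarize(dapi, method="otsu", log=inner)
    t = inner.records[0]["derived"]["threshold"]
    eta = _otsu_separability(dapi.pixels, t)
    if log is not None:
        log.record(
            "segment_nuclei",
            {"min_area_um2": min_area_um2, "min_separability": min_separability},
            {"threshold": t, "separability": eta},
        )
    if eta < min_separability:
        return LabeledMask(np.zeros(dapi.shape, dtype=np.int32), dapi.pixel_size_um, 0)
    filled = ndi.binary_fill_holes(mask.pixels)
    lab, _ = ndi.label(filled, structure=np.ones((3, 3), bool))
    min_px = min_area_um2 / dapi.pixel_size_um**2
    ids, counts = np.unique(lab[lab > 0], return_counts=True)
    keep = ids[counts >= min_px]
    mapping = np.zeros(int(lab.max()) + 1, dtype=np.int32)
    for new, old in enumerate(keep, start=1):
        mapping[old] = new
    out = mapping[lab]
    return LabeledMask(out, dapi.pixel_size_um, int(keep.size))


def segment_cells(
    cyto: Image2D,
    nuclei: LabeledMask,
    sigma_px: float = 8.0,
    log: ProvenanceLog | None = None,
) -> LabeledMask:
    """Nucleus-seeded watershed of the blurred cytoplasm channel.

    The cytoplasm mask is the Otsu foreground of the Gaussian-blurred
    channel (union the nuclei, which always belong to their cell); each cell
    inherits its seed nucleus label.  Cytoplasm pixels unreachable from any
    seed stay background.  With zero nuclei an empty labeling is returned
    with a warning.
    """
    if nuclei.shape != cyto.shape:
        raise ValueError("nuclei labeling grid does not match cytoplasm image")
    if nuclei.n_objects == 0:
        warnings.warn("segment_cells: no nuclei; returning empty cell labeling")
        return LabeledMask(np.zeros(cyto.shape, dtype=np.int32), cyto.pixel_size_um, 0)
    blurred = gaussian_blur(cyto, sigma_px)
    try:
        fg = threshold_binarize(blurred, method="otsu", log=log).pixels
    except ValueError:  # constant cytoplasm channel: no signal anywhere
        fg = np.zeros(cyto.shape, dtype=bool)
    mask = fg | (nuclei.labels > 0)
    lab = sk_watershed(-blurred.pixels, markers=nuclei.labels, mask=mask)
    # components containing no seed are background by construction
    n = int(len(np.unique(lab[lab > 0])))
    return LabeledMask(lab.astype(np.int32), cyto.pixel_size_um, n)


def exclude_edge_cells(seg: CellSegmentation) -> CellSegmentation:
    """Move every cell with a border pixel to ``excluded_edge_ids`` (idempotent)."""
    lab = seg.cells.labels
    border = np.concatenate([lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]])
    edge_ids = sorted(set(border[border > 0].tolist()))
    merged = sorted(set(seg.excluded_edge_ids) | set(edge_ids))
    return CellSegmentation(
        nuclei=seg.nuclei,
        cells=seg.cells,
        excluded_edge_ids=merged,
        excluded_gate_ids=list(seg.excluded_gate_ids),
        gate_bounds=seg.gate_bounds,
        warnings=list(seg.warnings),
    )


def per_cell_mean_intensity(
    seg: CellSegmentation, channel: Image2D, ids: np.ndarray | None = None
) -> dict[int, float]:
    """Mean channel intensity over each cell's pixels."""
    if channel.shape != seg.cells.shape:
        raise ValueError("channel grid does not match segmentation")
    if ids is None:
        ids = seg.retained_ids
    if len(ids) == 0:
        return {}
    means = ndi.mean(channel.pixels, labels=seg.cells.labels, index=ids)
    return {int(i): float(m) for i, m in zip(ids, np.atleast_1d(means))}


def gate_cells_by_intensity(
    seg: CellSegmentation,
    channel: Image2D,
    low_q: float = 0.10,
    high_q: float = 0.90,
    log: ProvenanceLog | None = None,
) -> CellSegmentation:
    """Exclude cells outside the [low_q, high_q] band of per-cell mean intensity.

    Quantiles are computed over the field's retained-cell distribution with
    linear interpolation; a cell is excluded only if its mean is strictly
    below the low bound or strictly above the high bound, so ties at the
    bounds (and an all-equal field) are retained.
    """
    if not 0 <= low_q < high_q <= 1:
        raise ValueError("need 0 <= low_q < high_q <= 1")
    means = per_cell_mean_intensity(seg, channel)
    if not means:
        return seg
    ids = np.array(sorted(means))
    vals = np.array([means[i] for i in ids])
    low, high = np.quantile(vals, [low_q, high_q])
    gated = sorted(set(seg.excluded_gate_ids) | {int(i) for i, v in zip(ids, vals) if v < low or v > high})
    warn = list(seg.warnings)
    n_left = len(ids) - len([i for i in ids if i in set(gated)])
    if n_left < 3:
        warn.append("fewer than 3 cells retained after intensity gating")
        warnings.warn(warn[-1])
    if log is not None:
        log.record(
            "gate_cells_by_intensity",
            {"low_q": low_q, "high_q": high_q},
            {"low": float(low), "high": float(high), "n_excluded": len(gated)},
        )
    return CellSegmentation(
        nuclei=seg.nuclei,
        cells=seg.cells,
        excluded_edge_ids=list(seg.excluded_edge_ids),
        excluded_gate_ids=gated,
        gate_bounds=(float(low), float(high)),
        warnings=warn,
    )
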