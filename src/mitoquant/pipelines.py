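"""End-to-end assay pipelines composing the low-level operators.

Each function takes an :class:`~mitoquant.image_core.ImageStack` (or a list
of them) and runs the full published recipe for one assay: Z-projection,
cell-by-cell segmentation with edge exclusion and optional reporter-intensity
gating, top-hat / threshold / watershed object detection, and the per-cell
statistic.  The CLI and the acceptance checks are thin wrappers over these.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image_core import (
    BinaryMask,
    ImageStack,
    connected_components,
    max_project,
    sum_project,
    threshold_binarize,
    tophat,
    watershed_split,
)
from .organelles import (
    DepolarizationResult,
    FluxResult,
    SpatialDistribution,
    classify_depolarized,
    compute_flux,
    count_mitolysosomes,
    count_touching_puncta,
    cytoplasmic_mean_intensity,
    lysosome_distribution,
    mean_intensity_in_mask,
    mito_mass,
    nuclear_mean_intensity,
)
from .provenance import ProvenanceLog
from .segmentation import (
    CellSegmentation,
    exclude_edge_cells,
    gate_cells_by_intensity,
    segment_cells,
    segment_nuclei,
)

__all__ = [
    "PipelineParams",
    "match_truth_cells",
    "segment_field",
    "mitoqc_count_field",
    "mitoqc_flux",
    "membrane_potential_field",
    "nuclear_translocation_field",
    "lamp1_distances_field",
    "lysosome_compare",
    "mito_mass_field",
    "dqbsa_field",
    "touching_puncta_field",
]


@dataclass
class PipelineParams:
    """Shared tunables of the classical segmentation pipeline.

    ``tophat_radius_px`` (disk radius of the background-suppression element),
    ``cyto_sigma_px`` (Gaussian sigma for cytoplasm detection),
    ``watershed_min_seed_px`` (minimum seed separation when splitting merged
    puncta), ``min_nucleus_area_um2``, and the reporter-intensity gate
    quantiles (set ``gate=None`` to disable gating).
    """

    tophat_radius_px: int = 5
    cyto_sigma_px: float = 8.0
    watershed_min_seed_px: float = 3.0
    min_nucleus_area_um2: float = 10.0
    gate: tuple[float, float] | None = (0.10, 0.90)


def match_truth_cells(seg: CellSegmentation, truth_cells) -> dict[int, int]:
    """Map ground-truth cell ids to detected cell labels via nucleus centroids.

    Detected labels are assigned in raster order of the nuclei, which need
    not match the generator's cell numbering; the planted nucleus centroid
    identifies each cell unambiguously.  Truth cells whose centroid falls on
    background (e.g. a missed nucleus) are omitted.
    """
    out: dict[int, int] = {}
    lab = seg.nuclei.labels
    for cell in truth_cells:
        y = int(np.clip(round(cell.nucleus_centroid[0]), 0, lab.shape[0] - 1))
        x = int(np.clip(round(cell.nucleus_centroid[1]), 0, lab.shape[1] - 1))
        found = int(lab[y, x])
        if found > 0:
            out[cell.cell_id] = found
    return out


def segment_field(
    stack: ImageStack,
    cyto_role: str,
    params: PipelineParams | None = None,
    gate_role: str | None = None,
    log: ProvenanceLog | None = None,
) -> CellSegmentation:
    """Nuclei + cells from a stack; edge exclusion; optional intensity gate."""
    params = params or PipelineParams()
    dapi = max_project(stack, "dapi")
    cyto = max_project(stack, cyto_role)
    nuclei = segment_nuclei(dapi, params.min_nucleus_area_um2, log=log)
    cell_labels = segment_cells(cyto, nuclei, params.cyto_sigma_px, log=log)
    seg = CellSegmentation(nuclei=nuclei, cells=cell_labels)
    seg = exclude_edge_cells(seg)
    if params.gate is not None and gate_role is not None:
        seg = gate_cells_by_intensity(
            seg, max_project(stack, gate_role), *params.gate, log=log
        )
    return seg


def _puncta_labels(stack: ImageStack, role: str, params: PipelineParams, log=None):
    """Top-hat -> Otsu -> watershed split of one projected channel."""
    img = tophat(max_project(stack, role), params.tophat_radius_px)
    mask = threshold_binarize(img, method="otsu", log=log)
    return watershed_split(mask, params.watershed_min_seed_px)


def _channel_mask(stack: ImageStack, role: str, params: PipelineParams, log=None) -> BinaryMask:
    img = tophat(max_project(stack, role), params.tophat_radius_px)
    return threshold_binarize(img, method="otsu", log=log)


def mitoqc_count_field(
    stack: ImageStack,
    params: PipelineParams | None = None,
    log: ProvenanceLog | None = None,
) -> pd.DataFrame:
    """Mitolysosome counts per retained cell of one tandem-reporter field."""
    params = params or PipelineParams()
    seg = segment_field(stack, cyto_role="gfp", params=params, gate_role="gfp", log=log)
    gfp_mask = _channel_mask(stack, "gfp", params, log=log)
    mcherry_labels = _puncta_labels(stack, "mcherry", params, log=log)
    return count_mitolysosomes(seg, gfp_mask, mcherry_labels)


def mitoqc_flux(
    stacks_minus: list[ImageStack],
    stacks_plus: list[ImageStack],
    params: PipelineParams | None = None,
    log: ProvenanceLog | None = None,
) -> FluxResult:
    """Pooled mitolysosome flux over paired lists of fields (±inhibitor)."""
    counts_minus = pd.concat(
        [mitoqc_count_field(s, params, log) for s in stacks_minus], ignore_index=True
    )["n_mitolysosomes"].to_numpy(float)
    counts_plus = pd.concat(
        [mitoqc_count_field(s, params, log) for s in stacks_plus], ignore_index=True
    )["n_mitolysosomes"].to_numpy(float)
    return compute_flux(counts_minus, counts_plus)


def membrane_potential_field(
    stack: ImageStack,
    params: PipelineParams | None = None,
    area_cutoff_um2: float = 1.0,
    bg_k: float = 3.0,
    log: ProvenanceLog | None = None,
) -> DepolarizationResult:
    """Small/depolarized mitochondria per retained cell of a TMRE/MTG field.

    Mass objects come from the max-projected MTG channel (top-hat, Otsu,
    connected components); intensity from the summed TMRE projection.
    """
    params = params or PipelineParams()
    seg = segment_field(stack, cyto_role="mtg", params=params, gate_role=None, log=log)
    mtg_img = tophat(max_project(stack, "mtg"), params.tophat_radius_px)
    mtg_mask = threshold_binarize(mtg_img, method="otsu", log=log)
    mtg_labels = connected_components(mtg_mask, connectivity=8)
    tmre = sum_project(stack, "tmre")
    return classify_depolarized(seg, mtg_labels, tmre, area_cutoff_um2, bg_k, log=log)


def nuclear_translocation_field(
    stack: ImageStack,
    marker_role: str = "marker",
    params: PipelineParams | None = None,
    log: ProvenanceLog | None = None,
) -> pd.DataFrame:
    """Per-cell nuclear and cytoplasmic marker means of one field."""
    params = params or PipelineParams()
    seg = segment_field(stack, cyto_role=marker_role, params=params, gate_role=None, log=log)
    marker = max_project(stack, marker_role)
    nuc = nuclear_mean_intensity(seg, marker)
    cyt = cytoplasmic_mean_intensity(seg, marker)
    return pd.DataFrame({"nuclear_mean": nuc, "cyto_mean": cyt}).rename_axis("cell_id")


def lamp1_distances_field(
    stack: ImageStack,
    params: PipelineParams | None = None,
    reference_distances: np.ndarray | None = None,
    reference_condition: str = "self",
    log: ProvenanceLog | None = None,
) -> SpatialDistribution:
    """Lysosome nucleus-distance statistic of one LAMP1 field."""
    params = params or PipelineParams()
    seg = segment_field(stack, cyto_role="mito_marker", params=params, gate_role=None, log=log)
    lyso_labels = _puncta_labels(stack, "lamp1", params, log=log)
    mito_mask = _channel_mask(stack, "mito_marker", params, log=log)
    areas = mito_mass(seg, mito_mask)
    return lysosome_distribution(
        seg,
        lyso_labels,
        seg.nuclei,
        areas,
        reference_distances=reference_distances,
        reference_condition=reference_condition,
        log=log,
    )


def lysosome_compare(
    reference_stacks: list[ImageStack],
    test_stacks: list[ImageStack],
    params: PipelineParams | None = None,
    log: ProvenanceLog | None = None,
) -> tuple[SpatialDistribution, SpatialDistribution]:
    """Apply the reference condition's 75th-percentile threshold to both arms."""
    ref_results = [lamp1_distances_field(s, params, log=log) for s in reference_stacks]
    ref_pooled = np.concatenate(
        [r.distances_um["distance_um"].to_numpy(float) for r in ref_results]
    )
    ref = _pooled_distribution(reference_stacks, params, ref_pooled, "reference", log)
    test = _pooled_distribution(test_stacks, params, ref_pooled, "reference", log)
    return ref, test


def _pooled_distribution(stacks, params, ref_distances, tag, log) -> SpatialDistribution:
    results = [
        lamp1_distances_field(s, params, reference_distances=ref_distances,
                              reference_condition=tag, log=log)
        for s in stacks
    ]
    dist = pd.concat([r.distances_um for r in results], ignore_index=True)
    per_cell = pd.concat([r.per_cell for r in results], ignore_index=True)
    return SpatialDistribution(
        distances_um=dist,
        percentile_threshold_um=results[0].percentile_threshold_um,
        per_cell=per_cell,
        reference_condition=tag,
    )


def mito_mass_field(
    stack: ImageStack,
    mito_role: str = "mito_marker",
    params: PipelineParams | None = None,
    log: ProvenanceLog | None = None,
) -> pd.Series:
    """Summed mitochondrial area (um^2) per retained cell of one field."""
    params = params or PipelineParams()
    seg = segment_field(stack, cyto_role=mito_role, params=params, gate_role=None, log=log)
    mask = _channel_mask(stack, mito_role, params, log=log)
    return mito_mass(seg, mask)


def dqbsa_field(
    stack: ImageStack,
    params: PipelineParams | None = None,
    log: ProvenanceLog | None = None,
) -> pd.Series:
    """Lysosomal degradative activity: mean summed DQ-BSA intensity in the
    LAMP1 mask, per retained cell."""
    params = params or PipelineParams()
    seg = segment_field(stack, cyto_role="lamp1", params=params, gate_role=None, log=log)
    lamp1_mask = _channel_mask(stack, "lamp1", params, log=log)
    dq = sum_project(stack, "dqbsa")
    return mean_intensity_in_mask(dq, lamp1_mask, per_cell=True, cells=seg)


def touching_puncta_field(
    stack: ImageStack,
    vesicle_role: str,
    target_role: str,
    params: PipelineParams | None = None,
    log: ProvenanceLog | None = None,
) -> pd.DataFrame:
    """Vesicles touching a target mask per retained cell (mitophagosomes)."""
    params = params or PipelineParams()
    seg = segment_field(stack, cyto_role=target_role, params=params, gate_role=None, log=log)
    vesicles = _puncta_labels(stack, vesicle_role, params, log=log)
    target = _channel_mask(stack, target_role, params, log=log)
    return count_touching_puncta(seg, vesicles, target)
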