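"""Mito-stress-test parameter derivation from oxygen-consumption traces.

The extracellular-flux protocol measures OCR (pmol O2/min) under basal
conditions and after sequential injections of oligomycin (ATP-synthase
inhibitor), FCCP (uncoupler; the two sequential additions are treated as one
phase) and rotenone + antimycin A (complex I/III inhibitors).  Phase
summaries follow the standard conventions:

* basal_raw      = last basal measurement (steady state before injection)
* oligo_raw      = minimum over the oligomycin phase
* fccp_raw       = maximum over the FCCP phase (captures whichever addition peaks)
* non-mito       = mean over the rotenone/AA phase

All parameters except the non-mitochondrial rate itself are corrected by
subtracting the rotenone/AA-insensitive OCR:

    basal       = basal_raw - nonmito
    proton_leak = oligo_raw - nonmito
    atp_linked  = basal - proton_leak
    maximal     = fccp_raw - nonmito
    reserve     = maximal - basal

The OXPHOS-derived ATP production rate converts the oligomycin-sensitive OCR
with 2 O atoms per O2 and a P/O ratio of 2.75 (pmol ATP / pmol O); both
constants are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PHASES",
    "OCRTrace",
    "RespiratoryParameters",
    "parse_trace",
    "respiratory_parameters",
    "atp_production_rate",
    "ecar_phase_means",
]

PHASES = ("basal", "oligomycin", "fccp", "rot_aa")


@dataclass
class OCRTrace:
    """Timestamped OCR (optionally ECAR) measurements annotated with phases."""

    data: pd.DataFrame
    well_id: str = "well"
    group: str = ""

    def __post_init__(self) -> None:
        required = {"time_min", "ocr", "phase"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"trace is missing columns: {sorted(missing)}")
        t = self.data["time_min"].to_numpy(float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        unknown = set(self.data["phase"]) - set(PHASES)
        if unknown:
            raise ValueError(f"unknown phase label(s): {sorted(unknown)}")
        # phases must appear in protocol order (each a contiguous block)
        seq = self.data["phase"].to_list()
        order = [p for i, p in enumerate(seq) if i == 0 or seq[i - 1] != p]
        if order != [p for p in PHASES if p in set(seq)]:
            raise ValueError("phases must appear contiguously in protocol order")

    def phase_values(self, phase: str) -> np.ndarray:
        return self.data.loc[self.data["phase"] == phase, "ocr"].to_numpy(float)


@dataclass
class RespiratoryParameters:
    """Derived mito-stress-test parameters (pmol O2/min except the ATP rate)."""

    nonmito: float
    basal: float
    atp_linked: float
    proton_leak: float
    maximal: float
    reserve_capacity: float
    quality_flag: str = ""

    def as_dict(self) -> dict[str, float]:
        return {
            "nonmito": self.nonmito,
            "basal": self.basal,
            "atp_linked": self.atp_linked,
            "proton_leak": self.proton_leak,
            "maximal": self.maximal,
            "reserve_capacity": self.reserve_capacity,
        }


def parse_trace(
    table: pd.DataFrame,
    injections: Sequence[float] | None = None,
    well_id: str = "well",
    group: str = "",
) -> OCRTrace:
    """Build an :class:`OCRTrace` from a measurement table.

    The table needs ``time_min`` and ``ocr`` columns plus either an explicit
    ``phase`` column or ``injections``: the three injection timestamps
    (oligomycin, FCCP, rotenone/AA).  With injection times, rows are assigned
    to phases by half-open intervals ``[t_inj, next_inj)``; rows before the
    first injection are basal.
    """
    table = table.copy()
    for col in ("time_min", "ocr"):
        if col not in table.columns:
            raise ValueError(f"missing required column {col!r}")
    if "phase" not in table.columns:
        if injections is None:
            raise ValueError("need either a 'phase' column or injection times")
        if len(injections) != 3:
            raise ValueError("expected 3 injection times (oligomycin, FCCP, rot/AA)")
        t = table["time_min"].to_numpy(float)
        edges = np.asarray(list(injections), dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("injection times must be increasing")
        idx = np.searchsorted(edges, t, side="right")  # 0=basal .. 3=rot_aa
        table["phase"] = [PHASES[i] for i in idx]
    missing = [p for p in PHASES if p not in set(table["phase"])]
    if missing:
        raise ValueError(f"missing phase: {missing}")
    return OCRTrace(data=table, well_id=well_id, group=group)


def respiratory_parameters(trace: OCRTrace) -> RespiratoryParameters:
    """Derive the corrected mito-stress-test parameters from one trace."""
    for phase in PHASES:
        if trace.phase_values(phase).size == 0:
            raise ValueError(f"empty phase: {phase}")
    basal_raw = float(trace.phase_values("basal")[-1])
    oligo_raw = float(trace.phase_values("oligomycin").min())
    fccp_raw = float(trace.phase_values("fccp").max())
    nonmito = float(trace.phase_values("rot_aa").mean())

    # basal is assembled from its components so the reported identities
    # basal = atp_linked + proton_leak and reserve = maximal - basal hold
    # bit-exactly, not merely to rounding
    proton_leak = oligo_raw - nonmito
    atp_linked = basal_raw - oligo_raw
    basal = atp_linked + proton_leak
    maximal = fccp_raw - nonmito
    reserve = maximal - basal
    flag = ""
    if min(basal, proton_leak, atp_linked, maximal, reserve) < 0:
        flag = "negative_corrected_rate"
    return RespiratoryParameters(
        nonmito=nonmito,
        basal=basal,
        atp_linked=atp_linked,
        proton_leak=proton_leak,
        maximal=maximal,
        reserve_capacity=reserve,
        quality_flag=flag,
    )


def atp_production_rate(
    trace: OCRTrace, po_ratio: float = 2.75, o2_per_o: float = 2.0
) -> float:
    """OXPHOS ATP production rate (pmol ATP/min) from oligomycin-sensitive OCR."""
    params = respiratory_parameters(trace)
    return params.atp_linked * o2_per_o * po_ratio


def ecar_phase_means(trace: OCRTrace) -> dict[str, float]:
    """Per-phase ECAR means (mpH/min); descriptive summary only."""
    if "ecar" not in trace.data.columns:
        raise ValueError("trace has no 'ecar' column")
    out = {}
    for phase in PHASES:
        vals = trace.data.loc[trace.data["phase"] == phase, "ecar"].to_numpy(float)
        out[phase] = float(vals.mean()) if vals.size else float("nan")
    return out
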