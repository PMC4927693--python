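"""Figures of merit for a separation.

Three quantities summarise how good one set of chromatographic conditions
is for a test mixture:

* width-based peak capacity   P_c = 1 + t_g / mean(w_p)
* resolution-based capacity   P_c = 1 + sum(Rs)  with
  Rs = 2 |t_r,1 - t_r,2| / (w_p,1 + w_p,2) over adjacent peaks
* normalised resolution product  r_ = prod(Rs_i / mean(Rs))  over the
  adjacent-pair resolutions — 1 for perfectly even peak spacing, << 1 for
  bunched peaks, and <= 1 always (AM-GM inequality).

Adjacent pairs are taken in elution order; no chromatogram-boundary terms
are added. r_ is undefined (returned as None) below two adjacent
resolutions, and 0 (with a co-elution warning) if any adjacent Rs is 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import PeakTable
from .peakmetrics import GradientMethod, PeakDescriptor

__all__ = [
    "MeritSummary",
    "resolution",
    "adjacent_resolutions",
    "sum_resolution",
    "peak_capacity_width",
    "peak_capacity_resolution",
    "normalized_resolution_product",
]


@dataclass(frozen=True)
class MeritSummary:
    """Per-condition separation metrics.

    ``nrp`` and ``mean_rs`` are None when fewer than two adjacent
    resolutions exist; ``comparable`` is False when a requested
    comparability subset matched no peaks (width statistics then fall back
    to all peaks and the condition should not enter subset-based
    comparisons).
    """

    condition_id: str
    n_peaks: int
    median_width: float
    mean_width: float
    sum_rs: float
    mean_rs: float | None
    nrp: float | None
    pc_width: float
    pc_rs: float
    n_subset: int = 0
    comparable: bool = True

    def __post_init__(self) -> None:
        if self.sum_rs < 0:
            raise ValueError("sum_rs must be >= 0")
        if self.nrp is not None and self.nrp > 1.0 + 1e-9:
            raise ValueError("normalised resolution product cannot exceed 1")
        if abs(self.pc_rs - (1.0 + self.sum_rs)) > 1e-9 * max(self.pc_rs, 1.0):
            raise ValueError("pc_rs must equal 1 + sum_rs")


def resolution(p1: PeakDescriptor, p2: PeakDescriptor) -> float:
    """Rs between two peaks: 2|Δtr| / (w1 + w2). Symmetric in arguments."""
    total_width = p1.base_width + p2.base_width
    if total_width <= 0:
        raise ValueError("total base width must be > 0")
    return 2.0 * abs(p1.tr - p2.tr) / total_width


def adjacent_resolutions(table: PeakTable) -> list[float]:
    """Rs for each adjacent pair in elution order (empty for < 2 peaks)."""
    return [resolution(a, b) for a, b in zip(table.peaks, table.peaks[1:])]


def sum_resolution(table: PeakTable) -> float:
    """Sum of adjacent-pair resolutions; 0 for a single peak."""
    if len(table) == 0:
        raise ValueError("empty peak table")
    return float(sum(adjacent_resolutions(table)))


def peak_capacity_width(
    gradient: GradientMethod, widths: Sequence[float]
) -> float:
    """Width-based peak capacity: 1 + t_g / mean(w_p)."""
    if len(widths) == 0:
        raise ValueError("need at least one peak width")
    widths = np.asarray(widths, dtype=float)
    if np.any(widths <= 0):
        raise ValueError("all widths must be > 0")
    return float(1.0 + gradient.t_g / widths.mean())


def peak_capacity_resolution(sum_rs: float) -> float:
    """Resolution-based peak capacity: 1 + sum(Rs)."""
    if sum_rs < 0:
        raise ValueError("sum of resolutions must be >= 0")
    return 1.0 + float(sum_rs)


def normalized_resolution_product(table: PeakTable) -> float | None:
    """r_ = prod(Rs_i / mean(Rs)) over adjacent-pair resolutions.

    Returns None for fewer than two adjacent resolutions (< 3 peaks), and
    0.0 with a warning when any adjacent pair fully co-elutes (Rs = 0).
    """
    rs = adjacent_resolutions(table)
    if len(rs) < 2:
        return None
    rs = np.asarray(rs)
    if np.any(rs == 0):
        warnings.warn(
            f"co-eluting adjacent peaks in {table.condition_id}: r_ set to 0",
            stacklevel=2,
        )
        return 0.0
    return float(np.prod(rs / rs.mean()))
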