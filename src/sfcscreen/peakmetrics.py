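"""Peak detection and per-peak chromatographic descriptors.

Given a sampled chromatogram, this module finds peak apexes and computes the
descriptor set used throughout condition screening: retention time (tr),
height, area, base width (w_p, tangent definition), asymmetry (b/a at 10%
height), signal-to-noise (S/N) and the retention factor k = (tr - t0)/t0.

Conventions (stated so results are reproducible across tools):

* base width = distance between the baseline intercepts of the tangents drawn
  through the two inflection points; for a Gaussian this equals 4 sigma.
* asymmetry b/a = trailing/leading half-width measured at 10% of peak height
  above the local baseline.
* S/N = height / (2 * baseline noise standard deviation).
* the baseline under a peak is the straight line joining the detected peak
  start and end points (first samples at or below 0.5% of apex height, or a
  local minimum between overlapping peaks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)

__all__ = [
    "PeakDescriptor",
    "GradientMethod",
    "estimate_baseline_noise",
    "detect_peaks",
    "measure_peak",
    "retention_factor",
    "assign_analytes",
]


@dataclass(frozen=True)
class PeakDescriptor:
    """Descriptors for one chromatographic peak.

    Times are in seconds, intensities in detector units. ``asymmetry``,
    ``snr`` and ``k`` may be ``None`` when the quantity could not be
    determined (e.g. k requires a known dead time).
    """

    analyte_id: str
    tr: float
    height: float
    area: float
    base_width: float
    asymmetry: float | None = None
    snr: float | None = None
    k: float | None = None

    def __post_init__(self) -> None:
        if not self.base_width > 0:
            raise ValueError(f"base_width must be > 0, got {self.base_width}")
        if not self.height > 0:
            raise ValueError(f"height must be > 0, got {self.height}")
        if self.asymmetry is not None and not self.asymmetry > 0:
            raise ValueError(f"asymmetry must be > 0, got {self.asymmetry}")


@dataclass(frozen=True)
class GradientMethod:
    """A gradient elution program.

    t_g : gradient length in seconds (enters the width-based peak capacity).
    t0 : column dead time in seconds (elution time of an unretained marker).
    program : (time, %CO2) pairs with non-decreasing times.
    """

    t_g: float
    t0: float
    program: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.t_g > 0:
            raise ValueError("gradient length t_g must be > 0")
        if not self.t0 > 0:
            raise ValueError("dead time t0 must be > 0")
        times = [t for t, _ in self.program]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("program times must be non-decreasing")


#: The 7.35 min gradient used for the emulated screen: 98% CO2 to 50% CO2 at
#: 4 min, held 1.5 min, back to 98% at 6.3 min, re-equilibration to 7.35 min.
DEFAULT_GRADIENT = GradientMethod(
    t_g=441.0,
    t0=30.0,
    program=((0.0, 98.0), (240.0, 50.0), (330.0, 50.0), (378.0, 98.0), (441.0, 98.0)),
)


def retention_factor(tr: float, t0: float) -> float:
    """Retention factor k = (tr - t0) / t0."""
    if not t0 > 0:
        raise ValueError("dead time t0 must be > 0")
    if tr < t0:
        raise ValueError(f"peak at tr={tr} s elutes before dead time t0={t0} s")
    return (tr - t0) / t0


def estimate_baseline_noise(
    chrom,
    window: tuple[float, float],
    apexes: Sequence[float] = (),
) -> float:
    """Noise standard deviation from a peak-free baseline window.

    The window is linearly detrended (removes baseline drift) before taking
    the sample standard deviation. ``apexes`` are known peak positions; a
    window containing any of them is rejected.
    """
    lo, hi = window
    for apex in apexes:
        if lo <= apex <= hi:
            raise ValueError(f"noise window ({lo}, {hi}) overlaps a peak at {apex} s")
    mask = (chrom.time >= lo) & (chrom.time <= hi)
    t = chrom.time[mask]
    y = chrom.intensity[mask]
    if t.size < 50:
        raise ValueError(f"window too short: {t.size} samples (need >= 50)")
    coeffs = np.polyfit(t, y, 1)
    resid = y - np.polyval(coeffs, t)
    return float(np.std(resid, ddof=1))


def detect_peaks(chrom, min_height: float, min_prominence: float) -> np.ndarray:
    """Apex times of peaks exceeding the height and prominence thresholds.

    Partially co-eluting peaks are reported separately only when both local
    maxima clear the prominence threshold; closer pairs merge into one apex.
    Detection runs on a lightly smoothed trace (~0.5 s moving average) so
    single-sample noise spikes do not register as peaks.
    """
    if not min_height > 0 or not min_prominence > 0:
        raise ValueError("detection thresholds must be > 0")
    idx, _ = find_peaks(
        _smooth(chrom.intensity, chrom.time[1] - chrom.time[0]),
        height=min_height,
        prominence=min_prominence,
    )
    if idx.size:
        gaps = np.diff(chrom.time[idx])
        step = chrom.time[1] - chrom.time[0]
        if np.any(gaps < 10 * step):
            logger.info("adjacent apexes closer than 10 grid steps; possible merge")
    return chrom.time[idx]


def _smooth(y: np.ndarray, step: float, span: float = 0.5) -> np.ndarray:
    """Moving average over ~``span`` seconds (odd window, >= 1 sample)."""
    win = max(1, int(round(span / step)))
    win += 1 - win % 2
    if win == 1:
        return y
    return np.convolve(y, np.full(win, 1.0 / win), mode="same")


def _walk_bound(y: np.ndarray, apex_idx: int, direction: int, rise_tol: float) -> int:
    """Index where the peak meets the baseline, walking from the apex.

    Stops at the first sample at/below 0.5% of apex height, or at a local
    minimum below half the apex (valley between overlapping peaks). A valley
    is only declared once the trace rises more than ``rise_tol`` above the
    running minimum, so baseline noise does not end the walk early.
    """
    thresh = 0.005 * y[apex_idx]
    min_i = apex_idx
    i = apex_idx
    n = y.size
    while True:
        j = i + direction
        if j < 0 or j >= n:
            raise ValueError("truncated peak: trace ends before baseline is reached")
        if y[j] <= thresh:
            return j
        if y[j] < y[min_i]:
            min_i = j
        elif y[min_i] < 0.5 * y[apex_idx] and y[j] > y[min_i] + rise_tol:
            return min_i
        i = j


def measure_peak(
    chrom,
    apex: float,
    noise_sd: float | None = None,
    gradient: GradientMethod | None = None,
    analyte_id: str = "unknown",
) -> PeakDescriptor:
    """Compute the full descriptor set for one detected apex.

    Raises ``ValueError`` ("truncated peak") when the peak runs off either
    end of the trace. ``noise_sd`` enables S/N; ``gradient`` enables k.
    """
    t = chrom.time
    y_raw = chrom.intensity
    step = t[1] - t[0]
    # a short moving average (~0.5 s) stabilises bound-finding, slope and
    # crossing estimates against baseline noise; the raw trace is kept for
    # area integration
    win = max(1, int(round(0.5 / step)))
    win += 1 - win % 2
    y = _smooth(y_raw, step)
    apex_idx = int(np.argmin(np.abs(t - apex)))
    if apex_idx in (0, t.size - 1):
        raise ValueError("truncated peak: apex at trace boundary")
    lo = max(apex_idx - win, 0)
    hi = min(apex_idx + win + 1, t.size)
    apex_idx = lo + int(np.argmax(y[lo:hi]))

    smooth_noise = (noise_sd or 0.0) / np.sqrt(win)
    rise_tol = max(0.02 * y[apex_idx], 3.0 * smooth_noise)
    i0 = _walk_bound(y, apex_idx, -1, rise_tol)
    i1 = _walk_bound(y, apex_idx, +1, rise_tol)

    # baseline: straight line between the peak start and end samples
    b_slope = (y[i1] - y[i0]) / (t[i1] - t[i0])
    b_icpt = y[i0] - b_slope * t[i0]

    def baseline(x: np.ndarray | float):
        return b_icpt + b_slope * x

    # apex refinement: parabola through the three samples around the maximum
    ya = y[apex_idx - 1 : apex_idx + 2] - baseline(t[apex_idx - 1 : apex_idx + 2])
    denom = ya[0] - 2 * ya[1] + ya[2]
    shift = 0.0 if denom == 0 else 0.5 * (ya[0] - ya[2]) / denom
    shift = float(np.clip(shift, -1.0, 1.0))
    tr = float(t[apex_idx] + shift * step)
    height = float(y[apex_idx] - baseline(t[apex_idx]))
    if height <= 0:
        raise ValueError("apex height not above baseline")

    # tangent-at-inflection base width: slope extrema on each flank
    dy = np.gradient(y, t)
    li = i0 + int(np.argmax(dy[i0 : apex_idx + 1]))
    ri = apex_idx + int(np.argmin(dy[apex_idx : i1 + 1]))
    w_left = _tangent_intercept(t[li], y[li], dy[li], b_slope, b_icpt)
    w_right = _tangent_intercept(t[ri], y[ri], dy[ri], b_slope, b_icpt)
    base_width = float(w_right - w_left)
    if base_width <= 0:
        raise ValueError("degenerate peak: non-positive tangent base width")

    # asymmetry b/a at 10% of height above baseline
    level = 0.1 * height
    corr = y[i0 : i1 + 1] - baseline(t[i0 : i1 + 1])
    tt = t[i0 : i1 + 1]
    rel_apex = apex_idx - i0
    t_left = _crossing(tt[: rel_apex + 1], corr[: rel_apex + 1], level, rising=True)
    t_right = _crossing(tt[rel_apex:], corr[rel_apex:], level, rising=False)
    a = tr - t_left
    b = t_right - tr
    asym = float(b / a) if a > 0 else None

    area = float(np.trapezoid(y_raw[i0 : i1 + 1] - baseline(tt), tt))
    snr = float(height / (2.0 * noise_sd)) if noise_sd and noise_sd > 0 else None
    k = None
    if gradient is not None and tr >= gradient.t0:
        k = retention_factor(tr, gradient.t0)

    return PeakDescriptor(
        analyte_id=analyte_id,
        tr=tr,
        height=height,
        area=area,
        base_width=base_width,
        asymmetry=asym,
        snr=snr,
        k=k,
    )


def _tangent_intercept(
    ti: float, yi: float, slope: float, b_slope: float, b_icpt: float
) -> float:
    """Time where the tangent line through (ti, yi) crosses the baseline."""
    if slope == b_slope:
        raise ValueError("tangent parallel to baseline")
    return (b_icpt - yi + slope * ti) / (slope - b_slope)


def _crossing(t: np.ndarray, y: np.ndarray, level: float, rising: bool) -> float:
    """Interpolated time where baseline-corrected y crosses `level`."""
    if rising:
        below = np.nonzero(y < level)[0]
        if below.size == 0:
            return float(t[0])
        i = below[-1]
        j = min(i + 1, y.size - 1)
    else:
        below = np.nonzero(y < level)[0]
        if below.size == 0:
            return float(t[-1])
        j = below[0]
        i = max(j - 1, 0)
    if y[j] == y[i]:
        return float(t[i])
    frac = (level - y[i]) / (y[j] - y[i])
    return float(t[i] + frac * (t[j] - t[i]))


def assign_analytes(
    descriptors: Sequence[PeakDescriptor],
    expected: Mapping[str, float],
    tol: float = 5.0,
) -> list[PeakDescriptor]:
    """Label peaks by the nearest expected retention time within ``tol`` s.

    Each expected analyte is used at most once (best |dt| wins); peaks with
    no expected analyte within tolerance keep the label "unknown".
    """
    from dataclasses import replace

    remaining = dict(expected)
    out: list[PeakDescriptor] = []
    for desc in sorted(descriptors, key=lambda d: d.tr):
        best, best_dt = None, tol
        for name, tr_exp in remaining.items():
            dt = abs(desc.tr - tr_exp)
            if dt <= best_dt:
                best, best_dt = name, dt
        if best is None:
            out.append(replace(desc, analyte_id="unknown"))
        else:
            out.append(replace(desc, analyte_id=best))
            del remaining[best]
    return out
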