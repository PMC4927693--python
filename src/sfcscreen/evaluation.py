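"""Condition-level aggregation, ranking and the end-to-end screen report.

The screen produces one peak table per condition. This module reduces that
to decisions: per-condition merit summaries (widths, ΣRs, r_, peak
capacities), Tukey five-number summaries per factor level (additive, column,
temperature), internal-standard repeatability (RSD of retention time and
area), an explicit lexicographic ranking of conditions, and a reproducible
report object driving all of it.

Width statistics are computed over a *comparability subset* of analytes
that elute acceptably in every condition (so conditions with different
total peak counts compare fairly), while ΣRs and r_ are always computed
over all observed peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import PeakTable
from .merit import (
    MeritSummary,
    adjacent_resolutions,
    normalized_resolution_product,
    peak_capacity_resolution,
    peak_capacity_width,
    sum_resolution,
)
from .peakmetrics import GradientMethod, PeakDescriptor
from .screening import HitCriteria, HitVerdict, evaluate_hit, hit_rate
from .synthdata import Condition, ScreenDataset

__all__ = [
    "Condition",
    "RepeatabilitySummary",
    "TukeyStats",
    "DEFAULT_SUBSET",
    "DEFAULT_OBJECTIVE",
    "tukey_five_number",
    "summarize_condition",
    "aggregate_by_factor",
    "repeatability",
    "rank_conditions",
    "run_screen_evaluation",
    "Report",
]

#: Analytes that elute with acceptable shape and k in every condition; the
#: default subset for width comparisons across conditions.
DEFAULT_SUBSET = (
    "2-aminobutyric acid",
    "adenine",
    "adenosine",
    "creatinine",
    "cytosine",
    "hippuric acid",
    "leucine",
    "proline",
    "uracil",
    "xylitol",
)

#: Lexicographic ranking objective: (MeritSummary field, direction).
DEFAULT_OBJECTIVE = (
    ("median_width", "asc"),
    ("sum_rs", "desc"),
    ("nrp", "desc"),
)


@dataclass(frozen=True)
class RepeatabilitySummary:
    """Within-condition repeatability of the internal standard."""

    rsd_tr: float
    rsd_area: float
    n_replicates: int

    def __post_init__(self) -> None:
        if self.rsd_tr < 0 or self.rsd_area < 0:
            raise ValueError("RSDs must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")


@dataclass(frozen=True)
class TukeyStats:
    """Five-number summary with Tukey whiskers (no outliers retained):
    whiskers sit on the most extreme data point within 1.5*IQR of the
    quartiles. Quartiles use linear interpolation."""

    median: float
    q1: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float
    n: int
    mean: float

    def __post_init__(self) -> None:
        if not self.q1 <= self.median <= self.q3:
            raise ValueError("quartiles out of order")
        if self.whisker_low < self.q1 - 1.5 * self.iqr - 1e-12 or (
            self.whisker_high > self.q3 + 1.5 * self.iqr + 1e-12
        ):
            raise ValueError("whiskers outside the 1.5*IQR fences")


def tukey_five_number(values: Sequence[float]) -> TukeyStats:
    """Tukey boxplot statistics for a sample (n >= 1)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(arr, [25.0, 50.0, 75.0])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    return TukeyStats(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        n=int(arr.size),
        mean=float(arr.mean()),
    )


def _pool_tables(tables: PeakTable | Sequence[PeakTable]) -> list[PeakTable]:
    if isinstance(tables, PeakTable):
        return [tables]
    tables = list(tables)
    if not tables:
        raise ValueError("need at least one peak table")
    return tables


def summarize_condition(
    tables: PeakTable | Sequence[PeakTable],
    gradient: GradientMethod,
    subset: Sequence[str] | None = None,
    condition_id: str | None = None,
) -> MeritSummary:
    """Merit summary for one condition (possibly several test mixtures).

    Width statistics (and the width-based peak capacity) are restricted to
    ``subset`` when given; ΣRs and r_ always use all observed peaks. A
    subset that matches no peak flags the summary as not comparable and
    falls back to all-peak widths.
    """
    tables = _pool_tables(tables)
    cid = condition_id or tables[0].condition_id

    widths_all: list[float] = []
    widths_subset: list[float] = []
    sum_rs = 0.0
    rs_all: list[float] = []
    n_peaks = 0
    for tab in tables:
        if len(tab) == 0:
            continue
        n_peaks += len(tab)
        widths_all.extend(tab.widths())
        if subset is not None:
            widths_subset.extend(tab.widths(subset))
        sum_rs += sum_resolution(tab)
        rs_all.extend(adjacent_resolutions(tab))
    if n_peaks == 0:
        raise ValueError(f"condition {cid}: no peaks in any table")

    comparable = True
    widths = widths_all
    n_subset = 0
    if subset is not None:
        if widths_subset:
            widths = widths_subset
            n_subset = len(widths_subset)
        else:
            comparable = False

    # r_ over the pooled adjacent resolutions (per-mixture adjacency)
    if len(rs_all) < 2:
        nrp = None
        mean_rs = float(np.mean(rs_all)) if rs_all else None
    else:
        rs_arr = np.asarray(rs_all)
        mean_rs = float(rs_arr.mean())
        nrp = 0.0 if np.any(rs_arr == 0) else float(np.prod(rs_arr / rs_arr.mean()))

    return MeritSummary(
        condition_id=cid,
        n_peaks=n_peaks,
        median_width=float(np.median(widths)),
        mean_width=float(np.mean(widths)),
        sum_rs=float(sum_rs),
        mean_rs=mean_rs,
        nrp=nrp,
        pc_width=peak_capacity_width(gradient, widths),
        pc_rs=peak_capacity_resolution(sum_rs),
        n_subset=n_subset,
        comparable=comparable,
    )


_FACTORS = ("additive", "column", "temperature")


def aggregate_by_factor(
    dataset: ScreenDataset,
    factor: str,
    restrict: Callable[[Condition], bool] | None = None,
    subset: Sequence[str] | None = None,
) -> dict[object, TukeyStats]:
    """Tukey statistics of peak base widths per level of one design factor.

    Each level pools every peak record at that level across the other
    factors (optionally filtered by ``restrict`` on the condition and by an
    analyte ``subset``). Returns {level: TukeyStats}; ``n`` per level is the
    pooled record count.
    """
    if factor not in _FACTORS:
        raise ValueError(f"unknown factor {factor!r}; expected one of {_FACTORS}")
    values: dict[object, list[float]] = {}
    for cond in dataset.conditions:
        if restrict is not None and not restrict(cond):
            continue
        level = getattr(cond, factor)
        widths = dataset.tables[cond.condition_id].widths(subset)
        if widths:
            values.setdefault(level, []).extend(widths)
    return {level: tukey_five_number(v) for level, v in sorted(values.items(), key=lambda kv: str(kv[0]))}


def repeatability(standard_peaks: Sequence[PeakDescriptor]) -> RepeatabilitySummary:
    """RSD (100 * sd / mean, sample sd) of internal-standard tr and area."""
    peaks = list(standard_peaks)
    if len(peaks) < 2:
        raise ValueError("need at least 2 internal-standard replicates")

    def rsd(vals: list[float]) -> float:
        arr = np.asarray(vals, dtype=float)
        mean = arr.mean()
        if mean == 0:
            raise ValueError("zero mean; RSD undefined")
        return float(100.0 * arr.std(ddof=1) / mean)

    return RepeatabilitySummary(
        rsd_tr=rsd([p.tr for p in peaks]),
        rsd_area=rsd([p.area for p in peaks]),
        n_replicates=len(peaks),
    )


def rank_conditions(
    summaries: Sequence[MeritSummary],
    objective: Sequence[tuple[str, str]] = DEFAULT_OBJECTIVE,
) -> list[MeritSummary]:
    """Order conditions lexicographically over the objective.

    Each objective entry is (MeritSummary field, 'asc'|'desc'); missing
    values (None) rank last within their criterion, and exact ties fall
    back to condition_id so the ordering is deterministic.
    """
    if not summaries:
        raise ValueError("no summaries to rank")

    def key(s: MeritSummary):
        parts = []
        for name, direction in objective:
            v = getattr(s, name)
            missing = v is None
            if missing:
                parts.append((1, 0.0))
                continue
            parts.append((0, v if direction == "asc" else -v))
        parts.append(s.condition_id)
        return tuple(parts)

    return sorted(summaries, key=key)


@dataclass(frozen=True)
class Report:
    """Everything the screen evaluation computes, reproducible from the
    dataset and the configuration."""

    summaries: tuple[MeritSummary, ...]
    repeatability: Mapping[str, RepeatabilitySummary]
    aggregates: Mapping[str, Mapping[object, TukeyStats]]
    hit_rates: Mapping[str, float]
    ranking: tuple[str, ...]  # condition_ids, best first
    criteria: HitCriteria
    subset: tuple[str, ...] | None
    excluded_columns: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.summaries:
            rep = self.repeatability[s.condition_id]
            rows.append(
                {
                    "condition_id": s.condition_id,
                    "n_peaks": s.n_peaks,
                    "median_width_s": s.median_width,
                    "mean_width_s": s.mean_width,
                    "sum_rs": s.sum_rs,
                    "nrp": s.nrp,
                    "pc_width": s.pc_width,
                    "pc_rs": s.pc_rs,
                    "hit_rate_pct": self.hit_rates[s.condition_id],
                    "rsd_tr_pct": rep.rsd_tr,
                    "rsd_area_pct": rep.rsd_area,
                    "comparable": s.comparable,
                }
            )
        return pd.DataFrame(rows).set_index("condition_id")

    def digest(self, top: int = 10) -> str:
        """Human-readable text summary (stable across reruns)."""
        lines = [
            f"screen evaluation: {len(self.summaries)} conditions",
            f"hit criteria: b/a < {self.criteria.max_asymmetry:g}, "
            f"{self.criteria.k_min:g} <= k <= {self.criteria.k_max:g}, "
            f"S/N >= {self.criteria.min_snr:g}",
            "",
            f"top {min(top, len(self.ranking))} conditions "
            "(median width asc, sum Rs desc, r_ desc):",
        ]
        by_id = {s.condition_id: s for s in self.summaries}
        for cid in self.ranking[:top]:
            s = by_id[cid]
            nrp = "NA" if s.nrp is None else f"{s.nrp:.3f}"
            lines.append(
                f"  {cid}: median w_p {s.median_width:.1f} s, "
                f"sum Rs {s.sum_rs:.2f}, r_ {nrp}, "
                f"hit rate {self.hit_rates[cid]:.0f}%"
            )
        for factor, levels in self.aggregates.items():
            lines.append("")
            lines.append(f"median base width by {factor}:")
            for level, st in levels.items():
                lines.append(
                    f"  {level}: median {st.median:.1f} s "
                    f"(mean {st.mean:.1f} s, n={st.n})"
                )
        return "\n".join(lines) + "\n"


def run_screen_evaluation(
    dataset: ScreenDataset,
    criteria: HitCriteria = HitCriteria(),
    objective: Sequence[tuple[str, str]] = DEFAULT_OBJECTIVE,
    subset: Sequence[str] | None = DEFAULT_SUBSET,
    exclude_columns: Sequence[str] = ("BEH Phenyl",),
) -> Report:
    """Evaluate a full screen dataset end to end.

    Produces per-condition merit and repeatability summaries, hit rates,
    Tukey aggregations per factor level (columns listed in
    ``exclude_columns`` are left out of the column aggregation only — their
    conditions are still summarised and ranked), and the condition ranking.
    """
    summaries: list[MeritSummary] = []
    reps: dict[str, RepeatabilitySummary] = {}
    rates: dict[str, float] = {}
    for cond in dataset.conditions:
        cid = cond.condition_id
        table = dataset.tables[cid]
        summaries.append(
            summarize_condition(table, dataset.gradient, subset=subset, condition_id=cid)
        )
        reps[cid] = repeatability(dataset.standards[cid])
        verdicts: list[HitVerdict] = [evaluate_hit(p, criteria) for p in table.peaks]
        rates[cid] = hit_rate(verdicts) if verdicts else 0.0

    excluded = tuple(exclude_columns)
    aggregates = {
        "additive": aggregate_by_factor(dataset, "additive", subset=subset),
        "column": aggregate_by_factor(
            dataset,
            "column",
            restrict=lambda c: c.column not in excluded,
            subset=subset,
        ),
        "temperature": aggregate_by_factor(dataset, "temperature", subset=subset),
    }
    ranking = tuple(s.condition_id for s in rank_conditions(summaries, objective))
    return Report(
        summaries=tuple(summaries),
        repeatability=reps,
        aggregates=aggregates,
        hit_rates=rates,
        ranking=ranking,
        criteria=criteria,
        subset=tuple(subset) if subset is not None else None,
        excluded_columns=excluded,
    )
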