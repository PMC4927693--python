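"""Hit criteria and responder classification.

A peak is a *hit* when it elutes with acceptable shape and retention:
asymmetry b/a < 4 (strict), retention factor 2 <= k <= 20 (inclusive) and
S/N >= 3 (inclusive) by default. Screening a compound across several
modifiers yields a class:

* responder      — hit in every tested modifier;
* sub-responder  — a peak eluted in every modifier, but at least one
                   verdict fails on k or asymmetry;
* non-responder  — no peak observed in any modifier;
* intermediate   — anything else (patchy elution, or S/N-only failures).

Responders form chromatographic test mixtures; non-responders are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .peakmetrics import PeakDescriptor

__all__ = [
    "HitCriteria",
    "HitVerdict",
    "CompoundClassification",
    "NO_PEAK",
    "evaluate_hit",
    "best_peak",
    "classify_compound",
    "hit_rate",
    "membership_counts",
]

#: Sentinel for "no peak observed" entries in a per-modifier verdict map.
NO_PEAK = "no peak"


@dataclass(frozen=True)
class HitCriteria:
    """Acceptance window for one peak. ``max_asymmetry`` is exclusive;
    the k bounds and ``min_snr`` are inclusive, exactly as stated."""

    max_asymmetry: float = 4.0
    k_min: float = 2.0
    k_max: float = 20.0
    min_snr: float = 3.0

    def __post_init__(self) -> None:
        if not self.k_min < self.k_max:
            raise ValueError("k_min must be < k_max")
        for name in ("max_asymmetry", "k_min", "k_max", "min_snr"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class HitVerdict:
    """Outcome of testing one peak against the criteria; ``failures`` names
    every violated criterion (subset of {'asymmetry', 'retention', 'snr'})."""

    is_hit: bool
    failures: tuple[str, ...] = ()


@dataclass(frozen=True)
class CompoundClassification:
    analyte_id: str
    verdicts: Mapping[str, HitVerdict | str]
    compound_class: str  # responder / sub-responder / non-responder / intermediate


def evaluate_hit(desc: PeakDescriptor, criteria: HitCriteria = HitCriteria()) -> HitVerdict:
    """Test one peak descriptor against the hit criteria.

    All three descriptor fields must be populated; a missing field raises
    with the field's name.
    """
    for name in ("asymmetry", "k", "snr"):
        if getattr(desc, name) is None:
            raise ValueError(f"descriptor field {name!r} is missing for hit evaluation")
    failures = []
    if not desc.asymmetry < criteria.max_asymmetry:
        failures.append("asymmetry")
    if not criteria.k_min <= desc.k <= criteria.k_max:
        failures.append("retention")
    if not desc.snr >= criteria.min_snr:
        failures.append("snr")
    return HitVerdict(is_hit=not failures, failures=tuple(failures))


def best_peak(descs: Sequence[PeakDescriptor]) -> PeakDescriptor:
    """When one analyte matches several peaks, keep the highest-S/N one."""
    if not descs:
        raise ValueError("no peaks to choose from")
    return max(descs, key=lambda d: (d.snr is not None, d.snr or 0.0))


#: Failures that make an always-eluting compound a sub-responder rather
#: than an intermediate (S/N-only failures stay intermediate).
_SHAPE_FAILURES = {"retention", "asymmetry"}


def classify_compound(
    analyte_id: str, per_modifier: Mapping[str, HitVerdict | str]
) -> CompoundClassification:
    """Classify a compound from its per-modifier verdicts.

    ``per_modifier`` maps modifier name to a `HitVerdict`, or to `NO_PEAK`
    when nothing eluted. The result is invariant to modifier order.
    """
    if not per_modifier:
        raise ValueError("need at least one modifier entry")
    verdicts = dict(per_modifier)
    eluted = [v for v in verdicts.values() if isinstance(v, HitVerdict)]
    if not eluted:
        cls = "non-responder"
    elif len(eluted) < len(verdicts):
        cls = "intermediate"
    elif all(v.is_hit for v in eluted):
        cls = "responder"
    elif any(_SHAPE_FAILURES & set(v.failures) for v in eluted):
        cls = "sub-responder"
    else:
        cls = "intermediate"
    return CompoundClassification(
        analyte_id=analyte_id, verdicts=verdicts, compound_class=cls
    )


def hit_rate(verdicts: Iterable[HitVerdict | str | None]) -> float:
    """Hits over the whole panel, as a percentage. Non-hit entries include
    failed verdicts, `NO_PEAK` and None."""
    verdicts = list(verdicts)
    if not verdicts:
        raise ValueError("empty verdict list")
    hits = sum(1 for v in verdicts if isinstance(v, HitVerdict) and v.is_hit)
    return 100.0 * hits / len(verdicts)


def membership_counts(
    hits_by_modifier: Mapping[str, Iterable[str]]
) -> dict[tuple[str, ...], int]:
    """Venn-style membership counts: for each combination of modifiers, the
    number of analytes that are hits in exactly that combination."""
    modifiers = sorted(hits_by_modifier)
    sets = {m: set(hits_by_modifier[m]) for m in modifiers}
    universe = set().union(*sets.values()) if sets else set()
    counts: dict[tuple[str, ...], int] = {}
    for analyte in universe:
        combo = tuple(m for m in modifiers if analyte in sets[m])
        counts[combo] = counts.get(combo, 0) + 1
    return counts
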