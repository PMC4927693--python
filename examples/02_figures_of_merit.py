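"""Figures of merit for a peak table.

Builds two five-peak tables — one evenly spaced, one bunched — and prints
the sum of resolution (ΣRs), both peak-capacity estimates and the
normalised resolution product r_, which is 1 for perfectly even peak
spacing and < 1 otherwise.
"""

from sfcscreen import (
    DEFAULT_GRADIENT,
    PeakDescriptor,
    PeakTable,
    summarize_condition,
)


def table(name, trs):
    return PeakTable(
        condition_id=name,
        peaks=tuple(
            PeakDescriptor(f"p{i}", tr, height=100.0, area=500.0, base_width=10.0)
            for i, tr in enumerate(trs)
        ),
    )


even = table("even", [60, 120, 180, 240, 300])
bunched = table("bunched", [60, 75, 90, 105, 300])

for tab in (even, bunched):
    s = summarize_condition(tab, DEFAULT_GRADIENT)
    print(f"{tab.condition_id}:")
    print(f"  sum Rs            = {s.sum_rs:.2f}")
    print(f"  Pc (widths)       = {s.pc_width:.2f}   # 1 + t_g / mean(w_p)")
    print(f"  Pc (sum Rs)       = {s.pc_rs:.2f}   # 1 + sum Rs")
    print(f"  r_ (evenness)     = {s.nrp:.3f}")

print(
    "\nBoth tables span the same window with the same widths, so their peak\n"
    "capacities are close — but r_ drops sharply for the bunched layout:\n"
    "peak capacity measures how many peaks fit, r_ how evenly they are used."
)
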