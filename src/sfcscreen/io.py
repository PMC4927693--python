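"""Delimited-text readers and writers for the three table formats.

All formats are tab-separated, "." decimal, one header line, with comment
lines starting with "#". Times are serialised in seconds. Chromatograms are
two columns (time_s, intensity); peak tables carry the descriptor set; the
screen design is a small YAML document with one block per screening phase.
Readers validate strictly and writers emit files their readers accept.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .peakmetrics import GradientMethod, PeakDescriptor

logger = logging.getLogger(__name__)

__all__ = [
    "Chromatogram",
    "PeakTable",
    "read_chromatogram",
    "write_chromatogram",
    "read_peak_table",
    "write_peak_table",
    "read_design",
    "write_design",
]


@dataclass(frozen=True)
class Chromatogram:
    """A sampled intensity-vs-time trace for one injection/channel."""

    time: np.ndarray
    intensity: np.ndarray
    channel: str = "MS"
    condition_id: str = "unknown"
    truncated: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "intensity", y)
        if t.size < 2:
            raise ValueError("chromatogram needs at least 2 samples")
        if t.shape != y.shape:
            raise ValueError("time and intensity must have equal length")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise ValueError("chromatogram values must be finite")
        steps = np.diff(t)
        bad = np.nonzero(steps <= 0)[0]
        if bad.size:
            raise ValueError(
                f"time must be strictly increasing; first violation at row {bad[0] + 1}"
            )
        step = steps[0]
        if np.any(np.abs(steps - step) > 1e-9 * max(abs(step), 1.0)):
            raise ValueError("time grid must be uniform")
        if self.channel not in ("MS", "UV"):
            raise ValueError(f"channel must be MS or UV, got {self.channel!r}")

    @property
    def step(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass(frozen=True)
class PeakTable:
    """Peak descriptors for one condition, sorted by retention time."""

    condition_id: str
    peaks: tuple[PeakDescriptor, ...]
    gradient: GradientMethod | None = None

    def __post_init__(self) -> None:
        peaks = tuple(self.peaks)
        trs = [p.tr for p in peaks]
        if trs != sorted(trs):
            logger.info(
                "peak table %s was not sorted by tr; sorting", self.condition_id
            )
            peaks = tuple(sorted(peaks, key=lambda p: p.tr))
        object.__setattr__(self, "peaks", peaks)
        ids = [p.analyte_id for p in peaks]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate analyte ids in peak table: {dup}")

    def __len__(self) -> int:
        return len(self.peaks)

    def widths(self, subset: Sequence[str] | None = None) -> list[float]:
        """Base widths, optionally restricted to a named analyte subset."""
        if subset is None:
            return [p.base_width for p in self.peaks]
        wanted = set(subset)
        return [p.base_width for p in self.peaks if p.analyte_id in wanted]


# ---------------------------------------------------------------------------
# chromatograms

_CHROM_COLUMNS = ("time_s", "intensity")


def write_chromatogram(chrom: Chromatogram, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# condition: {chrom.condition_id}\n")
        fh.write(f"# channel: {chrom.channel}\n")
        fh.write("\t".join(_CHROM_COLUMNS) + "\n")
        for t, y in zip(chrom.time, chrom.intensity):
            fh.write(f"{float(t)!r}\t{float(y)!r}\n")


def read_chromatogram(path: str | Path) -> Chromatogram:
    path = Path(path)
    condition_id, channel = "unknown", "MS"
    rows: list[tuple[float, float]] = []
    linenos: list[int] = []
    header_seen = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("condition:"):
                    condition_id = body.split(":", 1)[1].strip()
                elif body.startswith("channel:"):
                    channel = body.split(":", 1)[1].strip()
                continue
            parts = line.split("\t")
            if not header_seen:
                if tuple(parts) != _CHROM_COLUMNS:
                    raise ValueError(
                        f"{path}: expected header {_CHROM_COLUMNS}, got {parts}"
                    )
                header_seen = True
                continue
            if len(parts) != 2:
                raise ValueError(f"{path}: row {lineno}: expected 2 columns")
            try:
                rows.append((float(parts[0]), float(parts[1])))
                linenos.append(lineno)
            except ValueError as exc:
                raise ValueError(f"{path}: row {lineno}: non-numeric value") from exc
    if not header_seen:
        raise ValueError(f"{path}: no header line")
    if not rows:
        raise ValueError(f"{path}: no samples")
    t = np.array([r[0] for r in rows])
    y = np.array([r[1] for r in rows])
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise ValueError(
            f"{path}: time not strictly increasing at row {linenos[int(bad[0]) + 1]}"
        )
    return Chromatogram(time=t, intensity=y, channel=channel, condition_id=condition_id)


# ---------------------------------------------------------------------------
# peak tables

_PEAK_COLUMNS = ("analyte", "tr_s", "area", "height", "width_s", "asym", "snr", "k")


def write_peak_table(table: PeakTable, path: str | Path) -> None:
    path = Path(path)

    def fmt(v: float | None) -> str:
        return "NA" if v is None else repr(float(v))

    with path.open("w") as fh:
        fh.write(f"# condition: {table.condition_id}\n")
        if table.gradient is not None:
            fh.write(
                f"# gradient: t_g={table.gradient.t_g!r} t0={table.gradient.t0!r}\n"
            )
        fh.write("\t".join(_PEAK_COLUMNS) + "\n")
        for p in table.peaks:
            fh.write(
                "\t".join(
                    [
                        p.analyte_id,
                        repr(float(p.tr)),
                        repr(float(p.area)),
                        repr(float(p.height)),
                        repr(float(p.base_width)),
                        fmt(p.asymmetry),
                        fmt(p.snr),
                        fmt(p.k),
                    ]
                )
                + "\n"
            )


def read_peak_table(path: str | Path) -> PeakTable:
    path = Path(path)
    condition_id = "unknown"
    gradient: GradientMethod | None = None
    with path.open() as fh:
        lines = fh.readlines()
    for line in lines:
        line = line.strip()
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("condition:"):
                condition_id = body.split(":", 1)[1].strip()
            elif body.startswith("gradient:"):
                fields = dict(
                    kv.split("=") for kv in body.split(":", 1)[1].strip().split()
                )
                gradient = GradientMethod(
                    t_g=float(fields["t_g"]), t0=float(fields["t0"])
                )
    df = pd.read_csv(
        path, sep="\t", comment="#", na_values=["NA"], float_precision="round_trip"
    )
    required = set(_PEAK_COLUMNS[:7])  # k column optional
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: peak table header must declare {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    peaks = []
    for _, row in df.iterrows():
        width = float(row["width_s"])
        if width <= 0:
            raise ValueError(
                f"{path}: analyte {row['analyte']!r}: width must be > 0, got {width}"
            )

        def opt(name: str) -> float | None:
            if name not in row or pd.isna(row[name]):
                return None
            return float(row[name])

        peaks.append(
            PeakDescriptor(
                analyte_id=str(row["analyte"]),
                tr=float(row["tr_s"]),
                height=float(row["height"]),
                area=float(row["area"]),
                base_width=width,
                asymmetry=opt("asym"),
                snr=opt("snr"),
                k=opt("k"),
            )
        )
    return PeakTable(condition_id=condition_id, peaks=tuple(peaks), gradient=gradient)


# ---------------------------------------------------------------------------
# screen designs

def _parse_additive(entry) -> str:
    """Additive entries may be plain names or carry a concentration label,
    either as 'name (label)' or a {name: ..., concentration: ...} mapping."""
    if isinstance(entry, dict):
        return str(entry["name"]).strip()
    text = str(entry).strip()
    if "(" in text:
        text = text.split("(", 1)[0].strip()
    return text


def read_design(path: str | Path):
    """Parse a YAML screen-design file into a validated `ScreenDesign`.

    Raises on duplicate conditions, empty block lists, and any explicit
    pairing of an alkylamine additive with MS detection.
    """
    from .synthdata import ALKYLAMINES, DesignBlock, ScreenDesign

    with Path(path).open() as fh:
        doc = yaml.safe_load(fh)
    if not doc or "blocks" not in doc or not doc["blocks"]:
        raise ValueError(f"{path}: design has no blocks")
    blocks = []
    for i, raw in enumerate(doc["blocks"]):
        additives = tuple(_parse_additive(a) for a in raw.get("additives", ()))
        detection = raw.get("detection")
        if detection == "MS":
            amines = sorted(set(additives) & set(ALKYLAMINES))
            if amines:
                raise ValueError(
                    f"{path}: block {i}: alkylamine additives {amines} cannot be "
                    "paired with MS detection (UV-only additives)"
                )
        blocks.append(
            DesignBlock(
                name=str(raw.get("name", f"block{i}")),
                columns=tuple(raw.get("columns", ())),
                additives=additives,
                temperatures=tuple(float(t) for t in raw.get("temperatures", ())),
            )
        )
    return ScreenDesign(blocks=tuple(blocks))


def write_design(design, path: str | Path) -> None:
    from .synthdata import ADDITIVE_CONCENTRATIONS

    doc = {
        "blocks": [
            {
                "name": b.name,
                "columns": list(b.columns),
                "additives": [
                    f"{a} ({ADDITIVE_CONCENTRATIONS.get(a, 'n/a')})"
                    for a in b.additives
                ],
                "temperatures": [float(t) for t in b.temperatures],
            }
            for b in design.blocks
        ]
    }
    with Path(path).open("w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
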