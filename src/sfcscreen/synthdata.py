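"""Synthetic chromatograms and screening datasets.

The screen this package evaluates — 12 SFC stationary phases crossed with 9
methanol-modifier additives and up to 4 column temperatures, 264 unique
conditions in all — produced only vendor-extracted peak tables; no raw data
exists to download. This module therefore generates data with the same
statistical structure, so every downstream stage (descriptor extraction,
figures of merit, hit classification, aggregation, ranking) can be exercised
and validated end to end.

Two layers are provided:

* trace level — exponentially modified Gaussian (EMG) peaks on a uniform
  time grid, plus baseline noise and drift (`make_emg_trace`,
  `simulate_chromatogram`). The EMG is the standard model for tailing
  chromatographic peaks; its tail constant tau controls the asymmetry b/a
  monotonically.
* screen level — descriptor-level peak tables for every condition of a
  `ScreenDesign`, with condition-dependent retention shifts, width
  multipliers, asymmetry factors, per-compound elution probabilities, and
  internal-standard replicates whose area fluctuates per condition (the
  caffeine "spray pulsing" phenomenon at high CO2).

Everything is seeded; a dataset cannot be generated without a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import erfcx

from .peakmetrics import DEFAULT_GRADIENT, GradientMethod, PeakDescriptor

__all__ = [
    "EMGPeakSpec",
    "NoiseModel",
    "CompoundSpec",
    "EffectModel",
    "Condition",
    "DesignBlock",
    "ScreenDesign",
    "ScreenDataset",
    "make_emg_trace",
    "simulate_chromatogram",
    "generate_screen",
    "default_design",
    "default_panel",
    "default_effects",
    "INTERNAL_STANDARD",
    "ALKYLAMINES",
    "TORUS_COLUMNS",
    "COLUMNS",
    "ADDITIVES",
]

# ---------------------------------------------------------------------------
# factor levels

COLUMNS = (
    "BEH 2-EP",
    "BEH",
    "CSH FP",
    "HSS C18 SB",
    "BEH Amide",
    "BEH HILIC",
    "BEH Phenyl",
    "HSS Cyano",
    "2-PIC",
    "Diol",
    "DEA",
    "1-AA",
)
TORUS_COLUMNS = ("2-PIC", "Diol", "DEA", "1-AA")

ADDITIVES = (
    "formic acid",
    "acetic acid",
    "ammonium formate",
    "ammonium acetate",
    "ammonium hydroxide",
    "water",
    "isopropylamine",
    "isobutylamine",
    "isopentylamine",
)
#: Alkylamine additives are incompatible with the MS source and are run with
#: UV detection only.
ALKYLAMINES = ("isopropylamine", "isobutylamine", "isopentylamine")

#: Modifier concentration labels: 0.5% v/v for acids and alkylamines, 20 mM
#: for ammonium salts, 5% v/v for water.
ADDITIVE_CONCENTRATIONS = {
    "formic acid": "0.5% v/v",
    "acetic acid": "0.5% v/v",
    "ammonium formate": "20 mM",
    "ammonium acetate": "20 mM",
    "ammonium hydroxide": "20 mM",
    "water": "5% v/v",
    "isopropylamine": "0.5% v/v",
    "isobutylamine": "0.5% v/v",
    "isopentylamine": "0.5% v/v",
}

TEMPERATURES = (35.0, 40.0, 45.0, 55.0)


def detection_mode(additive: str) -> str:
    """Detector implied by the additive: alkylamines force UV-only."""
    return "UV" if additive in ALKYLAMINES else "MS"


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Condition:
    """One (column, additive, temperature, detection) cell of the screen."""

    column: str
    additive: str
    temperature: float
    detection: str = "MS"

    def __post_init__(self) -> None:
        if self.column not in COLUMNS:
            raise ValueError(f"unknown column {self.column!r}")
        if self.additive not in ADDITIVES:
            raise ValueError(f"unknown additive {self.additive!r}")
        if self.temperature not in TEMPERATURES:
            raise ValueError(f"unknown temperature {self.temperature!r}")
        if self.detection not in ("MS", "UV"):
            raise ValueError(f"detection must be MS or UV, got {self.detection!r}")
        if self.additive in ALKYLAMINES and self.detection != "UV":
            raise ValueError(
                f"alkylamine additive {self.additive!r} requires UV detection"
            )
        if self.temperature == 55.0 and self.column not in TORUS_COLUMNS:
            raise ValueError("only Torus columns are run at 55 °C")

    @property
    def condition_id(self) -> str:
        t = f"{self.temperature:g}"
        return f"{self.column}|{self.additive}|{t}C|{self.detection}"


@dataclass(frozen=True)
class EMGPeakSpec:
    """Exponentially modified Gaussian peak: Gaussian (tr_center, sigma)
    convolved with an exponential decay of time constant tau. ``amplitude``
    is the height of the underlying Gaussian; the area is
    amplitude * sigma * sqrt(2*pi) for every tau."""

    analyte_id: str
    tr_center: float
    sigma: float
    tau: float
    amplitude: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Additive baseline model: white Gaussian noise of sd ``baseline_sd``
    plus a linear drift of ``drift_slope`` intensity units per second."""

    baseline_sd: float = 0.0
    drift_slope: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_sd < 0:
            raise ValueError("baseline_sd must be >= 0")


@dataclass(frozen=True)
class CompoundSpec:
    """Panel metadata for one test analyte (hydrophobicity descriptors are
    metadata only; nothing is predicted from them)."""

    analyte_id: str
    compound_class: str
    clogp: float
    clogd: float
    mw: float
    uv_active: bool

    _CLASSES = (
        "nucleobase/nucleoside",
        "amino acid",
        "organic acid",
        "sugar",
        "amine",
        "other",
    )

    def __post_init__(self) -> None:
        if self.compound_class not in self._CLASSES:
            raise ValueError(f"unknown compound class {self.compound_class!r}")
        if not -7.0 <= self.clogp <= 2.0:
            raise ValueError("clogp outside the emulated panel range [-7, 2]")
        if self.mw > 505:
            raise ValueError("mw above the emulated panel maximum of 505 Da")


@dataclass(frozen=True)
class DesignBlock:
    """One screening phase: a full cross of columns x additives x temps."""

    name: str
    columns: tuple[str, ...]
    additives: tuple[str, ...]
    temperatures: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (self.columns and self.additives and self.temperatures):
            raise ValueError(f"design block {self.name!r} has an empty factor list")


@dataclass(frozen=True)
class ScreenDesign:
    """Factorial screen layout. Detection follows the additive rule
    (alkylamines -> UV); enumerated conditions must be unique."""

    blocks: tuple[DesignBlock, ...]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("design has no blocks")
        self.conditions()  # validates uniqueness and invariants eagerly

    def conditions(self) -> list[Condition]:
        out: list[Condition] = []
        seen: set[tuple] = set()
        for block in self.blocks:
            for col in block.columns:
                for add in block.additives:
                    for temp in block.temperatures:
                        key = (col, add, temp)
                        if key in seen:
                            raise ValueError(f"duplicate condition {key} in design")
                        seen.add(key)
                        out.append(
                            Condition(col, add, temp, detection=detection_mode(add))
                        )
        return out

    def __len__(self) -> int:
        return sum(
            len(b.columns) * len(b.additives) * len(b.temperatures)
            for b in self.blocks
        )


@dataclass(frozen=True)
class ScreenDataset:
    """Generated screen: one peak table and one set of internal-standard
    replicates per condition, plus full provenance (seed, design, effects)."""

    tables: Mapping[str, "PeakTable"]  # condition_id -> PeakTable
    standards: Mapping[str, tuple[PeakDescriptor, ...]]
    conditions: tuple[Condition, ...]
    gradient: GradientMethod
    seed: int
    design: ScreenDesign
    effects: "EffectModel"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a ScreenDataset requires an explicit seed")
        ids = [c.condition_id for c in self.conditions]
        if len(set(ids)) != len(ids):
            raise ValueError("conditions are not unique")
        if set(ids) != set(self.tables) or set(ids) != set(self.standards):
            raise ValueError("tables/standards do not match the condition list")

    def condition(self, condition_id: str) -> Condition:
        for c in self.conditions:
            if c.condition_id == condition_id:
                return c
        raise KeyError(condition_id)


# ---------------------------------------------------------------------------
# EMG trace simulation


def _emg_profile(t: np.ndarray, spec: EMGPeakSpec) -> np.ndarray:
    """Closed-form EMG evaluated stably via the scaled complementary error
    function; reduces to a pure Gaussian as tau -> 0."""
    z = (t - spec.tr_center) / spec.sigma
    gauss = np.exp(-0.5 * z * z)
    if spec.tau < 1e-9 * spec.sigma:
        return spec.amplitude * gauss
    r = spec.sigma / spec.tau
    arg = (r - z) / np.sqrt(2.0)
    out = np.empty_like(z)
    safe = arg > -25.0
    out[safe] = (
        spec.amplitude * r * np.sqrt(np.pi / 2.0) * gauss[safe] * erfcx(arg[safe])
    )
    if np.any(~safe):
        # far right tail: erfcx overflows, use the pure-exponential limit
        expo = 0.5 * r * r - (t[~safe] - spec.tr_center) / spec.tau
        out[~safe] = spec.amplitude * r * np.sqrt(2.0 * np.pi) * np.exp(expo)
    return out


def _check_uniform_grid(grid: np.ndarray) -> float:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("grid must be a 1-D array with at least 2 samples")
    steps = np.diff(grid)
    if np.any(steps <= 0):
        raise ValueError("grid must be strictly increasing")
    step = steps[0]
    if np.any(np.abs(steps - step) > 1e-9 * max(step, 1.0)):
        raise ValueError("grid must be uniformly spaced")
    return float(step)


def make_emg_trace(spec: EMGPeakSpec, grid: np.ndarray) -> np.ndarray:
    """Evaluate one EMG peak on a uniform time grid.

    The trace is non-negative everywhere and its trapezoidal integral tends
    to amplitude * sigma * sqrt(2*pi) (the Gaussian area) for tau -> 0.
    """
    _check_uniform_grid(grid)
    return _emg_profile(np.asarray(grid, dtype=float), spec)


def simulate_chromatogram(
    peaks: Sequence[EMGPeakSpec],
    noise: NoiseModel,
    run_length: float,
    step: float = 0.05,
    condition_id: str = "simulated",
    channel: str = "MS",
):
    """Sum of EMG peaks plus baseline noise and drift on a uniform grid.

    Peaks whose +/- 6*(sigma+tau) support extends outside the run window are
    kept but flagged as truncated (with a warning). Identical inputs and
    seed give bit-identical traces.
    """
    from .io import Chromatogram  # local import: io depends on this module

    grid = np.arange(0.0, run_length + step / 2.0, step)
    intensity = np.zeros_like(grid)
    truncated: list[str] = []
    for spec in peaks:
        pad = 6.0 * (spec.sigma + spec.tau)
        if spec.tr_center - pad < 0.0 or spec.tr_center + pad > run_length:
            warnings.warn(
                f"peak {spec.analyte_id!r} at {spec.tr_center} s is truncated by "
                f"the {run_length} s run window",
                stacklevel=2,
            )
            truncated.append(spec.analyte_id)
        intensity += _emg_profile(grid, spec)
    rng = np.random.default_rng(noise.seed)
    intensity = intensity + rng.normal(0.0, noise.baseline_sd, grid.size)
    intensity = intensity + noise.drift_slope * grid
    return Chromatogram(
        time=grid,
        intensity=intensity,
        channel=channel,
        condition_id=condition_id,
        truncated=tuple(truncated),
    )


# ---------------------------------------------------------------------------
# default screen design, analyte panel, effect model


def default_design() -> ScreenDesign:
    """The emulated method-development layout: an initial block of 8 columns
    x 9 additives x 3 temperatures, plus a later block of the 4 Torus
    columns x the 3 best MS-compatible modifiers x 4 temperatures — 264
    unique conditions."""
    return ScreenDesign(
        blocks=(
            DesignBlock(
                name="initial",
                columns=COLUMNS[:8],
                additives=ADDITIVES,
                temperatures=(35.0, 40.0, 45.0),
            ),
            DesignBlock(
                name="torus",
                columns=TORUS_COLUMNS,
                additives=("water", "ammonium formate", "formic acid"),
                temperatures=(35.0, 40.0, 45.0, 55.0),
            ),
        )
    )


#: Caffeine analogue injected with every mixture to monitor repeatability.
INTERNAL_STANDARD = CompoundSpec(
    "caffeine", "other", clogp=-0.1, clogd=-0.1, mw=194.2, uv_active=True
)

_N = "nucleobase/nucleoside"
_PANEL = (
    # the ten analytes that elute acceptably everywhere form the default
    # comparability subset used for width statistics
    CompoundSpec("2-aminobutyric acid", "organic acid", -2.7, -2.9, 103.1, False),
    CompoundSpec("adenine", _N, -0.1, -0.6, 135.1, True),
    CompoundSpec("adenosine", _N, -1.1, -1.5, 267.2, True),
    CompoundSpec("creatinine", "other", -1.8, -1.8, 113.1, True),
    CompoundSpec("cytosine", _N, -1.7, -2.2, 111.1, True),
    CompoundSpec("hippuric acid", "organic acid", 0.3, -0.9, 179.2, True),
    CompoundSpec("leucine", "amino acid", -1.5, -1.6, 131.2, False),
    CompoundSpec("proline", "amino acid", -2.5, -2.6, 115.1, False),
    CompoundSpec("uracil", _N, -1.1, -1.1, 112.1, True),
    CompoundSpec("xylitol", "sugar", -2.6, -2.6, 152.1, False),
    # the remainder elute everywhere but with k or b/a excursions
    CompoundSpec("cytidine", _N, -2.5, -2.9, 243.2, True),
    CompoundSpec("uridine", _N, -2.3, -2.3, 244.2, False),
    CompoundSpec("methionine", "amino acid", -1.9, -2.0, 149.2, False),
    CompoundSpec("tryptophan", "amino acid", -1.1, -1.3, 204.2, False),
    CompoundSpec("lysine", "amino acid", -3.0, -4.2, 146.2, False),
    CompoundSpec("glucose", "sugar", -2.9, -2.9, 180.2, False),
    CompoundSpec("galactose", "sugar", -2.9, -2.9, 180.2, False),
    CompoundSpec("lactic acid", "organic acid", -0.7, -1.1, 90.1, False),
    CompoundSpec("citric acid", "organic acid", -1.7, -4.7, 192.1, False),
    CompoundSpec("tyramine", "amine", 0.7, -1.0, 137.2, False),
)


def default_panel() -> tuple[CompoundSpec, ...]:
    """The 20-analyte test-mixture panel (11 responder-like + 9
    sub-responder-like polar metabolites)."""
    return _PANEL


@dataclass(frozen=True)
class EffectModel:
    """Generative knobs encoding the condition effects the evaluation must
    recover: multiplicative base-width factors and asymmetry factors per
    factor level, fractional retention shifts, per-compound elution
    probabilities and a per-condition internal-standard area CV.

    Multipliers combine multiplicatively across factors; retention shifts
    add. Levels absent from a mapping default to 1.0 (multipliers) or 0.0
    (shifts).
    """

    width_multipliers: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    tr_shifts: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    asymmetry_factors: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    elution_probability: Mapping[tuple[str, str], float] = field(default_factory=dict)
    default_elution_probability: float = 0.85
    is_area_cv_base: float = 0.08
    is_area_cv_factors: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    tr_jitter_rsd: float = 0.003  # injection-to-injection retention jitter
    width_noise_cv: float = 0.10

    def __post_init__(self) -> None:
        for fac in (self.width_multipliers, self.asymmetry_factors, self.is_area_cv_factors):
            for levels in fac.values():
                if any(m <= 0 for m in levels.values()):
                    raise ValueError("factor multipliers must be > 0")
        if any(not 0.0 <= p <= 1.0 for p in self.elution_probability.values()):
            raise ValueError("elution probabilities must lie in [0, 1]")
        if not 0.0 <= self.default_elution_probability <= 1.0:
            raise ValueError("default elution probability must lie in [0, 1]")
        if self.is_area_cv_base < 0 or self.tr_jitter_rsd < 0 or self.width_noise_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")

    def _factor_product(self, table: Mapping, cond: Condition) -> float:
        out = 1.0
        out *= table.get("column", {}).get(cond.column, 1.0)
        out *= table.get("additive", {}).get(cond.additive, 1.0)
        out *= table.get("temperature", {}).get(cond.temperature, 1.0)
        return out

    def width_multiplier(self, cond: Condition) -> float:
        return self._factor_product(self.width_multipliers, cond)

    def asymmetry_factor(self, cond: Condition) -> float:
        return self._factor_product(self.asymmetry_factors, cond)

    def is_area_cv(self, cond: Condition) -> float:
        return self.is_area_cv_base * self._factor_product(self.is_area_cv_factors, cond)

    def tr_shift(self, cond: Condition) -> float:
        out = 0.0
        out += self.tr_shifts.get("column", {}).get(cond.column, 0.0)
        out += self.tr_shifts.get("additive", {}).get(cond.additive, 0.0)
        out += self.tr_shifts.get("temperature", {}).get(cond.temperature, 0.0)
        return out

    def elution_p(self, analyte_id: str, cond: Condition) -> float:
        return self.elution_probability.get(
            (analyte_id, cond.additive), self.default_elution_probability
        )


def default_effects() -> EffectModel:
    """Default condition effects, chosen to reproduce the qualitative
    structure of the emulated screen: ammonium salts and water narrow peaks
    relative to the acids, alkylamines (UV) narrow them dramatically, the
    Torus phases (Diol foremost) give the narrowest peaks, 55 °C trims
    widths slightly, and the internal-standard area CV is inflated for
    ammonium hydroxide and the Diol/2-PIC phases while BEH 2-EP stays tight.
    """
    return EffectModel(
        width_multipliers={
            "additive": {
                "formic acid": 1.20,
                "acetic acid": 1.10,
                "ammonium formate": 0.69,
                "ammonium acetate": 0.74,
                "ammonium hydroxide": 0.62,
                "water": 0.72,
                "isopropylamine": 0.18,
                "isobutylamine": 0.19,
                "isopentylamine": 0.20,
            },
            "column": {
                "Diol": 0.55,
                "2-PIC": 0.58,
                "DEA": 0.65,
                "1-AA": 0.68,
                "HSS C18 SB": 0.76,
                "BEH 2-EP": 0.76,
                "BEH": 0.90,
                "BEH HILIC": 0.95,
                "HSS Cyano": 0.90,
                "BEH Amide": 1.10,
                "CSH FP": 1.30,
                "BEH Phenyl": 2.00,
            },
            "temperature": {35.0: 1.00, 40.0: 0.99, 45.0: 0.98, 55.0: 0.84},
        },
        tr_shifts={
            "additive": {
                "ammonium formate": -0.04,
                "ammonium acetate": -0.03,
                "ammonium hydroxide": -0.05,
                "formic acid": 0.05,
            },
            "temperature": {55.0: -0.08},
        },
        asymmetry_factors={
            "additive": {
                "formic acid": 1.35,
                "acetic acid": 1.25,
                "ammonium hydroxide": 0.85,
                "ammonium formate": 0.90,
            },
            "column": {"BEH Phenyl": 1.8, "CSH FP": 1.4, "Diol": 0.85, "2-PIC": 0.9},
        },
        is_area_cv_factors={
            "additive": {"ammonium hydroxide": 2.0, "ammonium formate": 1.25},
            "column": {"Diol": 2.1, "2-PIC": 1.7, "BEH 2-EP": 0.30},
        },
    )


# deterministic per-compound base parameters: retention spread over the
# gradient window, width/asymmetry/abundance scales
def _base_params(panel: Sequence[CompoundSpec], gradient: GradientMethod):
    n = len(panel)
    t0 = gradient.t0
    span_lo, span_hi = 2.2 * t0, 0.92 * gradient.t_g
    out = {}
    for i, comp in enumerate(panel):
        frac = i / max(n - 1, 1)
        tr0 = span_lo + frac * (span_hi - span_lo)
        width0 = 28.0 * (0.8 + 0.5 * ((i * 7) % n) / max(n - 1, 1))
        asym0 = 1.2 + 1.2 * ((i * 3) % n) / max(n - 1, 1)
        height0 = 800.0 * (0.5 + ((i * 5) % n) / max(n - 1, 1))
        out[comp.analyte_id] = (tr0, width0, asym0, height0)
    return out


def generate_screen(
    design: ScreenDesign,
    panel: Sequence[CompoundSpec],
    effects: EffectModel,
    seed: int,
    gradient: GradientMethod = DEFAULT_GRADIENT,
    n_is_replicates: int = 4,
    noise_sd: float = 5.0,
) -> ScreenDataset:
    """Draw one full screen dataset: a peak table per condition plus
    internal-standard replicate descriptors.

    Per condition and compound: a Bernoulli elution draw, then retention
    time with multiplicative shift and injection jitter, base width with
    lognormal scatter, asymmetry and abundance. Internal-standard areas are
    drawn lognormally with the condition's area CV (>= ``n_is_replicates``
    replicates, default 4, mimicking repeated 1 uL standard injections).
    Equal (design, panel, effects, seed) give identical datasets.
    """
    from .io import PeakTable  # local import: io depends on this module

    if seed is None:
        raise ValueError("generate_screen requires an explicit seed")
    if not panel:
        raise ValueError("panel must be non-empty")
    if n_is_replicates < 4:
        raise ValueError("need at least 4 internal-standard replicates")

    conditions = design.conditions()
    base = _base_params(panel, gradient)
    is_tr0 = 1.85 * gradient.t0  # early-eluting internal standard
    is_height0 = 1200.0

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(conditions))

    tables: dict[str, PeakTable] = {}
    standards: dict[str, tuple[PeakDescriptor, ...]] = {}
    for cond, child in zip(conditions, children):
        rng = np.random.default_rng(child)
        wmult = effects.width_multiplier(cond)
        afact = effects.asymmetry_factor(cond)
        shift = effects.tr_shift(cond)
        peaks: list[PeakDescriptor] = []
        for comp in panel:
            if rng.random() >= effects.elution_p(comp.analyte_id, cond):
                continue
            if cond.detection == "UV" and not comp.uv_active:
                continue
            tr0, width0, asym0, height0 = base[comp.analyte_id]
            jitter = rng.normal(0.0, effects.tr_jitter_rsd)
            tr = gradient.t0 + (tr0 - gradient.t0) * (1.0 + shift) * (1.0 + jitter)
            width = width0 * wmult * rng.lognormal(0.0, effects.width_noise_cv)
            asym = max(asym0 * afact * rng.lognormal(0.0, 0.05), 0.8)
            height = height0 * rng.lognormal(0.0, 0.15)
            sigma = width / 4.0
            area = height * sigma * np.sqrt(2.0 * np.pi)
            peaks.append(
                PeakDescriptor(
                    analyte_id=comp.analyte_id,
                    tr=float(tr),
                    height=float(height),
                    area=float(area),
                    base_width=float(width),
                    asymmetry=float(asym),
                    snr=float(height / (2.0 * noise_sd)),
                    k=float((tr - gradient.t0) / gradient.t0),
                )
            )
        peaks.sort(key=lambda p: p.tr)
        tables[cond.condition_id] = PeakTable(
            condition_id=cond.condition_id, peaks=tuple(peaks), gradient=gradient
        )

        cv = effects.is_area_cv(cond)
        sigma_ln = np.sqrt(np.log1p(cv * cv))  # lognormal with that CV
        reps = []
        for _ in range(n_is_replicates):
            tr = is_tr0 * (1.0 + rng.normal(0.0, effects.tr_jitter_rsd))
            mult = rng.lognormal(-0.5 * sigma_ln**2, sigma_ln) if cv > 0 else 1.0
            height = is_height0 * mult
            width = 10.0 * wmult
            reps.append(
                PeakDescriptor(
                    analyte_id=INTERNAL_STANDARD.analyte_id,
                    tr=float(tr),
                    height=float(height),
                    area=float(height * (width / 4.0) * np.sqrt(2.0 * np.pi)),
                    base_width=float(width),
                    asymmetry=1.1,
                    snr=float(height / (2.0 * noise_sd)),
                    k=float((tr - gradient.t0) / gradient.t0),
                )
            )
        standards[cond.condition_id] = tuple(reps)

    return ScreenDataset(
        tables=tables,
        standards=standards,
        conditions=tuple(conditions),
        gradient=gradient,
        seed=seed,
        design=design,
        effects=effects,
    )
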