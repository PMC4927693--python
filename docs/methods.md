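# Methods

## Scope and model of the data

`sfcscreen` evaluates factorial chromatographic screens: every condition is
one cell of (stationary phase × modifier additive × column temperature),
run with a fixed gradient, and yields a table of peak descriptors per test
mixture. The package covers the evaluation chain only — descriptor
extraction from traces, hit classification, figures of merit, factor
aggregation, repeatability and ranking. It does not model retention
mechanisms, CO2–methanol thermodynamics or MS ionisation, and it does not
parse vendor raw formats.

The default screen layout crosses 8 columns × 9 additives × 3 temperatures
(35/40/45 °C) in an initial block, plus the 4 Torus-type columns × the 3
best MS-compatible modifiers (water, ammonium formate, formic acid) × 4
temperatures (adding 55 °C) in a second block — 264 unique conditions.
Alkylamine additives (isopropyl-, isobutyl-, isopentylamine) are UV-only:
they suppress ionisation and contaminate an ESI source, so the design
validator rejects any explicit pairing of an alkylamine with MS detection,
and 55 °C is only valid for the Torus phases.

## Peak model and descriptor conventions

Peaks are modelled as exponentially modified Gaussians (EMG): a Gaussian of
width σ convolved with an exponential decay of time constant τ. The EMG is
the standard model for tailing chromatographic peaks; τ controls the
asymmetry b/a monotonically and τ→0 recovers the Gaussian. The closed form
is evaluated through the scaled complementary error function `erfcx` for
numerical stability, with a pure-exponential branch in the far tail where
`erfcx` would overflow. With amplitude defined as the height of the
underlying Gaussian, the area is amplitude·σ·√(2π) for every τ.

Vendor packages disagree on descriptor definitions, so the conventions here
are fixed and stated:

- **base width w_p** — distance between the baseline intercepts of the
  tangents through the two inflection points; exactly 4σ for a Gaussian,
  which gives an analytic oracle for the implementation.
- **asymmetry b/a** — trailing/leading half-width at 10% of peak height
  above the local baseline.
- **S/N** — height / (2 × baseline noise sd), with the noise sd estimated
  as the standard deviation of a linearly detrended peak-free window
  (≥ 50 samples required).
- **baseline under a peak** — the straight line joining the peak start and
  end points: the first samples at or below 0.5% of apex height, or a
  local minimum (valley) between overlapping peaks.
- **retention factor k** — (t_r − t_0)/t_0 with the dead time t_0 a
  gradient parameter (default 30 s, the unretained-marker elution time).

Measurement runs on a ~0.5 s moving-average of the trace for bound-finding,
slope (inflection) estimation, apex refinement and crossings — raw
single-sample noise otherwise masquerades as valleys or inflection points —
while the area is integrated from the raw trace between the bounds. The
smoothing adds (0.5 s)²/12 to the effective peak variance, a < 1% width
bias for σ ≥ 1 s at the default 0.05 s sampling. A valley is only declared
once the smoothed trace rises more than max(2% of apex, 3 × smoothed noise
sd) above the running minimum. Peaks whose support runs off the trace raise
"truncated peak" rather than returning biased numbers.

## Figures of merit

Resolution uses adjacent pairs in elution order, as magnitudes:
Rs = 2|Δt_r|/(w_p,1 + w_p,2). The two peak-capacity estimates are
P_c = 1 + t_g/mean(w_p) and P_c = 1 + ΣRs. The normalised resolution
product r\* = Π(Rs_i/mean(Rs)) quantifies peak-spacing evenness; the
classical formulation also includes chromatogram-boundary terms, but the
adjacent-pairs-only form is used here and documented as such. r\* is
undefined (None, not 0 or 1) below two adjacent resolutions, and 0 with a
co-elution warning when any adjacent pair has Rs = 0. ΣRs and r\* are
always computed over *all* observed peaks of a condition, whereas width
statistics (and the width-based P_c) can be restricted to a comparability
subset — ten analytes that elute acceptably everywhere — so that
conditions with different total peak counts compare fairly.

## Hit criteria and classification

Hit boundary semantics follow the stated criteria exactly: b/a < 4 strict,
2 ≤ k ≤ 20 and S/N ≥ 3 inclusive. Verdicts enumerate every violated
criterion. Classification across modifiers: responder = hit everywhere;
sub-responder = eluted everywhere with at least one k or b/a violation;
non-responder = never observed; everything else (patchy elution, S/N-only
failures) is "intermediate", because an S/N failure reflects detection
rather than separation quality. When several peaks match one analyte, the
highest-S/N peak is evaluated. Hit rates are reported as percentages of
the full panel.

## Aggregation, repeatability, ranking

Factor-level comparisons pool all peak widths at one level of one factor
across the other factors and summarise them as Tukey boxplot statistics:
quartiles by linear interpolation, whiskers on the most extreme data point
within 1.5·IQR of the quartiles, no outliers retained, with n reported per
level. Pooling across mixtures/temperatures is exposed as configuration
(a `restrict` predicate) rather than hard-coded, since more than one
pooling rule is defensible. One column (BEH Phenyl by default) can be
excluded from the column aggregation — its conditions are still summarised
and ranked — and excluding a level provably leaves every other level's
statistics unchanged.

Repeatability is the percent RSD (100·sd/mean, sample sd) of the internal
standard's retention time and area over replicate injections (≥ 2; the
generator emits ≥ 4 per condition, mirroring repeated 1 µL standard
injections).

Ranking is deliberately explicit where practice is informal: a
lexicographic order over (median width ascending, ΣRs descending, r\*
descending) by default, user-configurable, with ties broken by condition
id so reruns are byte-identical. Missing values rank last within their
criterion.

## Synthetic-data generator

No raw data exists for screens of this kind at this scale, so the package
ships a generator with the statistical structure the evaluation assumes.
Two layers:

- **trace level** — EMG peaks on a uniform grid (default 0.05 s step over
  the 441 s / 7.35 min gradient window) plus white baseline noise and
  linear drift, fully seeded.
- **screen level** — descriptor-level peak tables drawn directly per
  condition: retention time = t_0 + (t_r0 − t_0)(1 + shift)(1 + jitter),
  base width = w_0 × (column factor × additive factor × temperature
  factor) × lognormal scatter (CV 10%), asymmetry and abundance likewise,
  a per-compound Bernoulli elution draw, and internal-standard areas drawn
  lognormally with a per-condition CV to mimic the spray-pulsing
  variability of an early-eluting standard at high CO2 fractions.

Default effect sizes reproduce the qualitative field structure: ammonium
salts and water narrow peaks relative to the acids, alkylamines narrow
them dramatically (UV), the Torus phases — Diol foremost — give the
narrowest peaks, 55 °C trims widths moderately, and the
internal-standard area CV (base 8%) is inflated for ammonium hydroxide
(×2.0) and the Diol/2-PIC phases (×2.1/×1.7) while BEH 2-EP stays tight
(×0.3). Retention jitter defaults to 0.3% RSD — small enough that
retention-time RSDs stay well under the 2% that counts as acceptable
repeatability; the true injection-to-injection magnitude in real screens
is not well characterised, so this is a declared default, not a claim.
Dead time defaults to 30 s per column. A dataset cannot be generated
without an explicit seed, and equal (design, panel, effects, seed) give
identical datasets (per-condition child seeds are spawned from one seed
sequence, so the draw order is well-defined).

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: retention correlations between analytes on a
given phase chemistry, peak-shape dependence on analyte concentration,
detector saturation, within-run drift of retention times, and any true
chemistry linking the panel metadata (cLogP, class) to behaviour. Recovery
results demonstrate that the evaluation measures what the generator
planted, not that any real column or additive is superior.

## Numerical choices and degenerate inputs

- Quantiles: linear interpolation throughout (the convention is stated
  because tools differ and the differences are visible at boxplot scale).
- Grids must be strictly increasing and uniform (1e−9 relative
  tolerance); files violating this are rejected with the offending row.
- Single-peak conditions: ΣRs = 0, r\* absent.
- Empty comparability subset: the summary is flagged `comparable=False`
  and width statistics fall back to all peaks.
- Peak tables are serialised as tab-separated text with full float
  precision (`repr` shortest-roundtrip) and re-read with exact-rounding
  parsing, so write→read is an identity.
- Times are seconds everywhere in files and APIs; the CLI converts to
  minutes only at the printing boundary.

## Problem sizes used in the test suite

Property suites run on 50–1000 randomised tables; parameter-recovery
checks use 30 peaks per condition and 100 generator seeds; the end-to-end
evaluation runs the full 264-condition design. All of it completes in a
few seconds on one core, which is the intended scale for a desk-side
evaluation tool.
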