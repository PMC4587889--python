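# Methods

This note records the models implemented, the defaults and why, the
numerical choices, what the synthetic generators do and do not emulate,
and the known limitations.

## Chemical indices

All indices operate on carbon fractions in % dry matter. The total
extractable carbon C_ext, when not measured directly, is defined as
C_fa + C_ha; when supplied it must agree with the parts to within 0.05 %
absolute (alkali extraction followed by acid precipitation partitions
C_ext into exactly these two fractions, so larger disagreement indicates
a data problem). The indices obey the exact identity
P_ha · HR / 100 = HI, which the tests assert to 1e-9 relative, and all of
HR, HI, P_ha and C_ha/C_fa are invariant under a common rescaling of the
carbon measurements.

OM loss from the ash balance, 100 − 100·[X₁(100−X₂)]/[X₂(100−X₁)], is
strictly increasing in the final ash X₂ and zero at X₂ = X₁. A negative
value (ash dilution) is physically suspect but occurs in noisy early-phase
data, so it is returned with a warning rather than raised.

Maturity thresholds default to TOC/TN strictly < 20, WSC ≤ 1.7 %
(inclusive — the guideline is "lower or close to" the reference value)
and germination index strictly > 50 %. Missing inputs yield an explicit
undetermined state, never a silent false. Thresholds are configurable in
the pipeline config.

Worked-example caveats (documented exception list): recomputing the
example table's derived columns from its printed, rounded inputs shifts
the last digit in a few rows (Cha/Cfa for pile A maturity, pile B
initial, pile C thermophilic; the FT-IR 1037/1384 ratio for pile A
thermophilic and pile B end-of-bio-oxidative; Alkyl/O-Alkyl for pile A
maturity, pile B initial, pile C end-of-bio-oxidative) — these rows are
checked at ±0.02 instead of printed precision. Two printed values are
inconsistent with their own row's inputs beyond any rounding and are
excluded from exactness checks: the pile C initial-phase derived columns
(which duplicate pile B's initial row — almost certainly a transcription
error) and pile A's thermophilic Alkyl/O-Alkyl (printed 1.60; the printed
integrals give 1.57 under every rounding of the inputs).

Whether the reported HR/HI used total organic carbon or total carbon as
the denominator cannot be determined from the available information
(per-phase TOC is only reported as TOC/TN); the functions accept either
via the explicit `ct` argument.

## First-order degradation kinetics

OM loss(%) = A·(1 − e^(−kt)) is fitted by nonlinear least squares
(Levenberg–Marquardt family; trust-region reflective when the physical
bounds A ∈ [0, 100] %, k ∈ [0, 10] d⁻¹ are active). Default
initialisation is scale-free: A₀ = 1.1·max(loss), k₀ = ln 2 / t_half with
t_half the first time the series exceeds half its maximum. Reported
statistics follow their least-squares definitions: residual mean square
SS_res/(n−2), SEE = √(SS_res/(n−2)), F = ((SS_tot−SS_res)/2)/(SS_res/(n−2))
referred to F(2, n−2), R² about the mean, and parameter standard errors
from the Jacobian at the optimum.

The "RMS" values reported alongside the example fits (0.878/0.769/0.880
with SEE 4.89/6.45/5.99) cannot equal SS_res/(n−2) under any
degrees-of-freedom choice (that would be SEE²); they numerically resemble
an R²-type statistic. This package therefore reports residual mean
square, SEE and R² separately and does not attempt to reproduce that
column. The example A/k/F/SEE values themselves are not reproducible
either (the underlying OM-loss series was not published); they serve as
forward-evaluation constants and as generating parameters for recovery
tests.

Recovery behaviour: with 16 samples over 168 days and 1 % (absolute)
Gaussian noise, median relative recovery error is ~1.5 % for A and ~4 %
for k over 500 replicates. At 2 % noise the slowest rate
(k ≈ 0.009 d⁻¹, which completes only ~78 % of its rise in 168 days)
degrades to ~8 % median error in k — an identifiability limit of the
model over a finite window, not an optimiser artefact.

## Temperature and the EXothermic Index

Days are half-open bins [d, d+1) with day 0 = pile construction; the
daily reducer is the arithmetic mean (configurable — e.g. daily maximum —
since which daily value the index historically used is not stated). The
bio-oxidative phase ends on the first day from which |pile − ambient|
stays below δ (default 2 °C) for a persistence window (default 7 days),
operationalising "temperature close to ambient without re-heating". EXI
sums the daily differences up to that day. Negative daily terms are kept
by default; `clip_negative` floors them at zero (a strictly exothermic
reading), and clipping can only increase the index. Days with missing
readings are skipped with a warning, never imputed.

The reference EXI values for the example piles (1741/1344/1317
cumulated °C) derive from temperature curves that were never tabulated,
so they are not reproducible from data; the synthetic pile scenarios are
instead constructed so that the qualitative contrast — the grape-marc
pile B most exothermic, piles A and C similar — holds for every seed, and
that is the property tested.

## Thermogravimetry

DTG is −d(mass)/dT (positive = mass-loss rate), computed by
Savitzky–Golay local-polynomial differentiation (default 15-point window,
order 2; window configurable in °C) on the uniform instrument grid, with
a finite-difference fallback for non-uniform grids. The moisture region
(< 150 °C) is excluded from all index computations. Region boundaries are
linearly interpolated on the temperature grid, which makes region mass
losses exactly additive over adjacent regions.

Default index regions follow the DTA exotherm windows: P1 = 250–400 °C
(carbohydrates/aliphatics), P2 = 400–580 °C (complex aromatics). The
reported TG/DTG peak ranges overlap these but are not identical
(e.g. a third DTG peak at 450–500 °C), so the windows are configurable
and every report records the windows used. R1 is the P2/P1 mass-loss
ratio, R2 the P2/P1 DTA peak-area ratio.

DTA peak areas use a straight-line baseline joining the signal at the
region edges (default; exactly invariant to a constant signal offset) or
a horizontal line at the in-region minimum. A linear-endpoint baseline
necessarily clips the part of a peak's own tails lying inside the window:
for a Gaussian exotherm whose centre clears both edges by ≥ 3.5σ the
clipped fraction is far below 1 %, which is the geometry the synthetic
oracle tests use.

## FT-IR

Band height = in-window maximum (window: nominal ± 10 cm⁻¹, tolerating
calibration shifts such as 1420 vs 1428 cm⁻¹ for the carboxylate/CH₂
band — the band set uses 1420, the position under which the reference
profiles are tabulated) minus a local linear baseline through two anchor
points. Anchors default to nominal ± 30 cm⁻¹ at fixed positions, which
makes the height exactly invariant under adding any linear function of
wavenumber; optional valley-snapping (`snap_to_valley`) trades that exact
invariance for robustness to curved backgrounds. Because 1420 and 1384
are only 36 cm⁻¹ apart, their default definitions share an anchor at the
1402 cm⁻¹ valley between them. The reference baseline treatment (vendor
software, unspecified) is unknown; the linear-anchor rule is this
package's documented choice. No ATR-vs-transmission correction is
applied. rA profiles sum to exactly 100 by construction and are invariant
to global intensity scaling.

## ¹³C NMR

Region integrals are trapezoidal with interpolated boundaries (exactly
additive over adjacent regions), optionally after subtracting a constant
baseline estimated as the median intensity over a signal-free window
(default 215–230 ppm when present). Negative region integrals (noisy
tails) are floored at zero with a warning before normalising to 100.
Relative intensities are reported uncorrected for observability, matching
how such tables are constructed; spin counting is exposed separately as
C_obs = 100·(sample signal per mg C per scan)/(standard signal per mg C
per scan), with a warning outside the plausible 40–110 % range (CP-MAS
typically observes 60–66 % for composts). Relaxation-parameter
experiments (T₁H, T₁ρH) are not modelled.

## Synthetic data

Generators use Gaussian components throughout — spectral bands, DTG
mass-loss events, DTA exotherms — because Gaussian integrals have closed
forms, so every generator doubles as an exact oracle. Real band shapes
(Lorentzian/Voigt), abscissa jitter, multiplicative noise and correlated
baselines are deliberately not modelled: passing recovery tests shows the
analysis is correct on data with the assumed statistical shape, not that
it is robust to every instrumental artefact.

Scenario defaults: the three stock scenarios carry each pile's reported
first-order parameters (A = 49.6/44.2/50.4 %, k = 0.0131/0.0215/0.0091
d⁻¹) and a heating parameterisation in which the effective amplitude
grows with the labile-carbon fraction (B: fraction 0.60, amplitude 30 °C;
A: 0.35/24 °C; C: 0.30/23 °C), with a rise time shrinking as labile C
grows and six turning-triggered re-heating spikes (days 7–77, decay
4 days) on a 35-day envelope. Ambient is a slow sinusoid around 16 °C.
These values were fixed once to reproduce the described qualitative
behaviour (B fastest and hottest; A ≈ C; C slowest to start) and are not
calibrated to any numeric temperature data. FT-IR bands default to
σ = 6 cm⁻¹ (FWHM ≈ 14 cm⁻¹, realistic at 4 cm⁻¹ resolution); NMR regions
get one Gaussian centred mid-region with σ = width/12, so < 1e-6 of each
component leaks into neighbouring regions; noise is additive Gaussian on
the ordinate, seeded, and every generator is bit-deterministic under a
fixed seed.

Problem sizes used by the test suite and acceptance script — 16-point
kinetic series, 110–120-day temperature series, 0.5 °C thermogram grids,
2 cm⁻¹/0.2 ppm spectral grids, 300–500 Monte-Carlo replicates — were
chosen as representative of the instrument exports and trial designs the
package targets.

## Numerical conventions

- Quadrature is trapezoidal everywhere; region/band boundaries are
  linearly interpolated onto the grid.
- Axes are normalised to the field's plotting conventions (descending
  wavenumber and ppm) on construction; integration re-sorts internally.
- Rounding (2 d.p. ratios, 1 d.p. percentages) happens only at
  serialisation; in-memory values keep full precision.
- Optimiser bounds keep kinetic fits physical; fits on degenerate
  (all-zero) series return a warned degenerate result rather than raising.
- Pipeline reports contain no timestamps and serialise with sorted keys,
  so identical inputs give byte-identical outputs.

## Limitations

- The JCAMP-DX reader covers uncompressed AFFN `(X++(Y..Y))` and
  `XYPOINTS` forms only; SQZ/DIF/DUP compression is rejected with a
  message.
- No kinetic deconvolution of DTG curves, no evolved-gas analysis, no
  DTA enthalpy calibration, no full-spectrum chemometrics, no NMR peak
  assignment or spinning-sideband correction — single-number indices and
  region/band summaries only.
- The maturity flags implement guideline thresholds, not a regulatory
  compliance check.
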