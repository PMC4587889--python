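# compostom

Multi-technique assessment of organic-matter (OM) biodegradation during
composting, built for environmental-biotechnology practitioners who follow
compost stability and maturity with a combination of classical chemical
indices and instrumental techniques (thermal analysis, FT-IR, solid-state
¹³C NMR).

Composting transforms residual organic matter — here typified by
winery–distillery wastes (grape marc, exhausted grape marc) co-composted
with animal manures — into a stabilised amendment. No single parameter
certifies maturity, so practice combines several measurements. This
package implements the full panel as a tested, reusable pipeline:

**Chemical indices** (`compostom.chem_indices`), all on % dry matter:

- humification ratio HR = 100·C_ext/C_T, humification index
  HI = 100·C_ha/C_T, percentage of humic acids P_ha = 100·C_ha/C_ext,
  polymerisation rate C_ha/C_fa;
- OM loss from the ash mass balance,
  OM loss (%) = 100 − 100·[X₁(100−X₂)]/[X₂(100−X₁)];
- TOC/TN and WSC/TN ratios and maturity flags
  (TOC/TN < 20, WSC ≤ 1.7 %, germination index > 50 %).

**Degradation kinetics** (`compostom.kinetics`): nonlinear least-squares
fit of the first-order model OM loss(%) = A·(1 − e^(−kt)), with parameter
standard errors, residual mean square, SEE, F statistic and its p-value
against F(2, n−2).

**Temperature** (`compostom.temperature`): daily reduction of pile and
ambient series, detection of the end of the bio-oxidative phase (pile
stays within δ of ambient for a persistence window without re-heating)
and the EXothermic Index, EXI = Σ_d (T_pile,d − T_ambient,d) in
cumulated °C over the bio-oxidative phase.

**Thermogravimetry** (`compostom.thermogravimetry`): DTG by
Savitzky–Golay differentiation, peak detection, region mass losses and
baseline-corrected DTA peak areas over the two main exothermic regions
(labile, 250–400 °C; recalcitrant, 400–580 °C), and the stability indices
R1 = P2/P1 mass losses and R2 = P2/P1 peak areas — both rise as OM
stabilises.

**FT-IR** (`compostom.ftir`): baseline-corrected band heights over an
eight-band panel (2927, 2854, 1640, 1548, 1420, 1384, 1037, 875 cm⁻¹),
relative absorbance rA_i = 100·h_i/Σh_j and the 1037/1384 ratio.

**¹³C NMR** (`compostom.nmr`): CPMAS spectral distribution over seven
chemical-shift regions (carbonyl 210–165, O-aromatic 165–145, aromatic
145–110, O₂-alkyl 110–95, O-alkyl 95–60, N-alkyl/methoxy 60–45, alkyl
45…−10 ppm), the Alkyl/O-Alkyl recalcitrant-to-labile ratio, and spin
counting (C_obs) against an external glycine standard.

**Synthetic data** (`compostom.synthetic_data`): generators for all five
input kinds with exact ground truth (Gaussian components with closed-form
integrals), parameterised by pile scenarios that mimic a three-pile
winery-waste trial. **Pipeline + CLI** (`compostom.pipeline`,
`compostom` command): TOML-configured orchestration producing
deterministic CSV/JSON reports with a provenance map.

## Worked example

Pile A's initial-phase humic fractions (C_fa = 3.54, C_ha = 2.98 % dm)
and the first-order fit to an OM-loss series generated with pile A's
parameters (A = 49.6 %, k = 0.0131 d⁻¹, 16 samples over 168 days, 1 %
noise):

```python
import numpy as np
from compostom.chem_indices import (HumicFractionSet, polymerisation_rate,
                                    percentage_humic_acids, percent_decrease)
from compostom.kinetics import fit_first_order, fit_summary
from compostom.synthetic_data import SCENARIOS, make_om_loss_series

fr = HumicFractionSet(cfa=3.54, cha=2.98)
print("Cha/Cfa =", round(polymerisation_rate(fr.cha, fr.cfa), 2))
print("Pha     =", round(percentage_humic_acids(fr.cha, fr.cext), 2), "%")
print("WSC/TN decrease =", round(percent_decrease(1.42, 0.42)), "%")

series, _ = make_om_loss_series(SCENARIOS["A"], np.linspace(0, 168, 16),
                                noise_sd=1.0, seed=11)
fit = fit_first_order(series)
s = fit_summary(fit)
print(f"A = {fit.a_max:.1f} +- {fit.a_se:.1f} %, k = {fit.k_rate:.4f} +- {fit.k_se:.4f} 1/d")
print(f"SEE = {fit.see:.2f}, F = {fit.f_value:.1f}, p = {s['p_value']:.2e}")
```

prints

```
Cha/Cfa = 0.84
Pha     = 45.71 %
WSC/TN decrease = 70 %
A = 49.6 +- 1.1 %, k = 0.0132 +- 0.0006 1/d
SEE = 0.90, F = 1701.2, p = 1.94e-17
```

The Cha/Cfa of 0.84 and Pha of 45.7 % reproduce the example table's
printed values; the WSC/TN decrease of 70 % is the classical maturity
signal; the fit recovers the generating parameters within one standard
error and is significant far below p < 0.001.

From the shell, the same stages run as:

```sh
compostom generate --kind all --seed 1 --out fixtures/
compostom run --config cfg.toml --out results/
compostom analyze-tg fixtures/tg_A_initial.csv --p1 250:400 --p2 400:580
```

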