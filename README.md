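# chemshield

Profiling of small-molecule drug candidates along two independent axes:
how well they attenuate gamma radiation, and how they behave as
antimicrobial agents. The package grew around a panel of six
bis-piperazine Schiff bases (`2a`–`2f`, C30H44N6O2 … C35H54N6O2) and is
aimed at researchers who characterise such candidate compounds with a
mix of photon-physics codes, docking engines and broth-microdilution
assays, and want the downstream arithmetic reproducible and tested.

Four analysis stages, each a library module with a CLI subcommand:

* **Attenuation** — elemental mass fractions from a molecular formula,
  the mixture rule `(mu/rho) = sum_i W_i (mu/rho)_i(E)` over tabulated
  photon cross sections (log-log interpolated), and the derived
  thickness parameters `LAC = (mu/rho)·rho`, `HVL = ln2/LAC`,
  `MFP = 1/LAC`. Densities may be back-solved from a single published
  LAC anchor (`infer_density`).
* **Buildup** — equivalent atomic number via the log-ratio
  interpolation of Compton/total attenuation ratios, and
  geometric-progression buildup factors
  `B = 1 + (b−1)(K^x−1)/(K−1)`, `K = c x^a + d·[tanh(x/Xk−2) −
  tanh(−2)]/[1 − tanh(−2)]` for depths up to 40 mean free paths
  (EBF and EABF by parameter table).
* **Binding** — docking post-analysis: `Ki = exp(dG/RT)` with
  R = 1.98722×10⁻³ kcal/(mol·K), T = 298.15 K, complex ranking, MM/PBSA
  component sums with error propagation, per-residue contribution
  ranking.
* **MIC statistics** — 2-fold dilution-ladder validation, per-organism
  best compounds, one-way ANOVA and Tukey HSD on log2 MICs, with the
  studentized-range distribution evaluated in-package by quadrature.

A fifth module, `chemshield.synthetic`, generates closed-form inputs
for every stage (power-law cross sections, log-linear G-P surfaces,
docking tables with known dG, MIC matrices with known effects) so the
whole pipeline is testable offline against analytic oracles.

## Worked example

```python
from chemshield import (ki_from_binding_energy, format_ki, infer_density,
                        attenuation_profile, CompoundSpec)
from chemshield.io import load_reference_xs, load_reference_mic
from chemshield.micstats import mic_groups, one_way_anova, tukey_hsd

# docking: strongest complex of the panel (2d vs GlcN-6-P synthase)
print(format_ki(ki_from_binding_energy(-10.90)))

# attenuation: density was never published, so anchor it at the
# reported 662 keV LAC and predict 1173 keV
xs = load_reference_xs()
c2a = CompoundSpec("2a", "C30H44N6O2")
rho = infer_density(c2a, xs, 0.662, 0.1190)
row = attenuation_profile(c2a.with_density(rho), xs, [1.173])[0]
print(f"{rho:.4f} g/cm3 -> LAC {row.lac:.4f} 1/cm, HVL {row.hvl:.3f} cm")

# MIC statistics on the packaged assay matrix
labels, groups = mic_groups(load_reference_mic(), scale="log2")
res = one_way_anova(groups)
print(f"F({res.df_between}, {res.df_within}) = {res.F:.3f}, p = {res.p:.4f}")
print([c.pair for c in tukey_hsd(groups, labels=labels) if c.significant])
```

prints

```
10.24 nM
1.4241 g/cm3 -> LAC 0.0907 1/cm, HVL 7.644 cm
F(5, 48) = 3.081, p = 0.0172
[('2d', '2e'), ('2e', '2f')]
```

The 10.24 nM inhibition constant is the thermodynamic reading of the
−10.90 kcal/mol binding energy; the predicted 1173 keV attenuation
coefficient sits within half a percent of the published 0.0911 1/cm,
validating the formula → mixture-rule → interpolation chain without
knowing the density; and the ANOVA confirms a compound effect on the
MIC panel at the 5% level, with Tukey isolating the weakest compound
(`2e`) from the two strongest (`2d`, `2f`).

The same stages run from the shell:

```sh
chemshield simulate --seed 1 --outdir sim/
chemshield attenuate --compounds compounds.csv --xs sim/xs_synthetic.csv \
    --energy 662 --energy 1173 --kev
chemshield mic --mic mic.csv --scale log2 --out tukey.csv
```

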