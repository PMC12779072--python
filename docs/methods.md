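# Methods

`chemshield` profiles a panel of small organic compounds — the packaged
reference set is six bis-piperazine Schiff bases (`2a`–`2f`,
C30H44N6O2 through C35H54N6O2) — along two independent axes: their
behaviour as gamma-ray shielding materials, and their behaviour as
antimicrobial drug candidates (docking thermodynamics and MIC
statistics). This note records the models, the numerical choices, and
what the synthetic-data tests do and do not establish.

## Photon attenuation

A compound is reduced to elemental mass fractions
`W_i = n_i A_i / MW` from its flat element-count formula. Atomic
weights are a fixed table of IUPAC standard values (H 1.008, C 12.011,
N 14.007, O 15.999, and a handful of common heteroatoms), shipped with
the package so results never depend on an external source. Formula
grammar is deliberately minimal — no parentheses, hydrates, charges or
isotopes — because the compound class analysed here is always written
as a flat formula.

The mixture (additivity) rule gives the mass attenuation coefficient

    (mu/rho)(E) = sum_i W_i (mu/rho)_i(E)        [cm^2/g]

from elemental coefficients tabulated on energy grids. Grids are
interpolated **log-log linearly**, the standard scheme for photon cross
sections: it is exact at grid points and exact on any power law, which
is what makes the synthetic-table oracle tests possible. Energies
outside a grid are rejected rather than extrapolated — silent
extrapolation of cross sections is a classic error source.

Derived thickness parameters use the exact constant `ln 2` (not the
rounded 0.693 that appears in shielding reports):

    LAC = (mu/rho) * rho      [1/cm]
    HVL = ln 2 / LAC          [cm]
    MFP = 1 / LAC             [cm]

The identities `HVL*LAC = ln 2` and `MFP*LAC = 1` are enforced as
invariants on every emitted row.

**Densities.** The mass densities of the reference compounds were never
published; only their LAC values were. The package therefore treats
density as an explicit user input and provides `infer_density`, which
back-solves `rho = LAC/MAC` from a single (energy, LAC) anchor. The
acceptance checks anchor each compound at its published 662 keV LAC and
predict the LAC at a second Compton-regime energy (1173 keV for `2a`,
1332 keV for `2f`); agreement within 2% validates the whole
formula → weight-fraction → mixture → interpolation chain, because the
density cancels out of everything except the anchor. The published
80/120 keV entries for `2a` repeat the same number at both energies and
its 1332 keV entry is inconsistent with the heavier homologue's, so
those cells are treated as suspect and not targeted.

**Reference cross sections.** `data/photon_xs_hcno.csv` carries total
`mu/rho` for H, C, N, O at 24 energies over 0.015–15 MeV, transcribed
from the standard NIST/XCOM photon attenuation tabulation. The
incoherent (Compton) column is *computed* from the Klein–Nishina
free-electron cross section (`sigma_KN * N_A * Z/A`), as stated in the
file header: this neglects electron binding, which is a good
approximation above ~0.1 MeV and progressively overestimates the
incoherent channel below. Consequence: for these four light elements
the Compton/total ratio is nearly 1 in the mid-energy range and its
ordering across Z is not reliable there, so the equivalent-atomic-number
pipeline is exercised on synthetic tables (below), not on this fixture.
The total channel — the only input to the attenuation acceptance
checks — is unaffected.

## Buildup factors

The buildup factor B(E, x) corrects the uncollided exponential for
scattered photons at penetration depth x (in mean free paths). The
package implements the five-parameter geometric-progression (G-P)
representation:

    B = 1 + (b-1)(K^x - 1)/(K - 1)    if K != 1
    B = 1 + (b-1) x                   if K  = 1
    K = c x^a + d [tanh(x/Xk - 2) - tanh(-2)] / [1 - tanh(-2)]

valid for x <= 40 mfp; depths beyond 40 are rejected as outside the
fit's stated domain. `x = 0` is allowed and returns the physical
boundary value B = 1. Near the branch point the geometric form is
numerically singular, so the linear branch is used whenever
|K - 1| < 1e-8; randomized continuity tests show the two branches agree
to better than 1e-6 across that guard. Exposure (EBF) and
energy-absorption (EABF) buildup share the formalism and differ only in
which parameter table is supplied.

G-P parameters for a compound are read at its equivalent atomic number
Zeq — the Z whose Compton-to-total attenuation ratio matches the
compound's at that energy — using the log-ratio interpolation

    Zeq = [Z1(log R2 - log R) + Z2(log R - log R1)] / (log R2 - log R1)

between the two bracketing elements. R outside the elemental span is
rejected, never clamped, and non-monotone elemental ratios are rejected
with a diagnostic. Parameter tables are interpolated in Z with the same
log-weight scheme (the convention of the buildup literature), exactly
reproducing tabulated rows at integer Z; along the energy axis the
tables are interpolated log-linearly, exact at grid energies, so any
query energy inside the grid is usable.

The published EABF/EBF triplets for these compounds (e.g. 2.52 / 3.19 /
3.96 at 10/20/40 mfp) do not state the photon energy at which they were
read, so they cannot serve as numeric targets without guessing. The
buildup stage is instead validated by construction: B >= 1 over
randomized physical parameters, monotone growth with depth when K is
non-decreasing, endpoint and log-midpoint identities for Zeq, and exact
recovery of parameters on surfaces built linear in log Z. G-P parameter
tables are *inputs* (the packaged example is synthetic and labelled as
such); generating them from transport calculations is out of scope.

## Docking thermodynamics

Binding free energies dG (kcal/mol) convert to inhibition constants by

    Ki = exp(dG / (R T)),  R = 1.98722e-3 kcal/(mol K), T = 298.15 K

— the convention of the AutoDock family of scoring engines, whose
report tables pair exactly these two columns. These constants reproduce
all eight printed (dG, Ki) pairs of the packaged docking fixture within
2% relative; the residual tolerance is what a 2-decimal dG implies
(±0.005 kcal/mol is ~0.85% in Ki) plus rounding of the printed Ki
itself. The module post-processes score *tables* only — pose search,
scoring-function evaluation and structure parsing are out of scope.
Ranking picks the most negative binding energy with a deterministic
(ligand, receptor) lexicographic tie-break.

MM/PBSA aggregation is a plain component sum (van der Waals +
electrostatic + polar solvation + nonpolar solvation) with standard
deviations propagated in quadrature for reporting. The polar term may
come from a Poisson–Boltzmann or a Generalized Born model; the sum is
agnostic, and the packaged table's header says which one produced it.
Per-residue decompositions are ranked most-stabilising first with a
stable label tie-break.

## MIC statistics

Broth-microdilution MICs live on a 2-fold concentration ladder; the
packaged assay used 78–1250 ug/mL. Ladder validation flags any tested
value that is not a rung (consecutive rung ratios may fall in
[1.9, 2.1] to absorb integer rounding such as 312 → 625). Summaries
report, per organism, every compound attaining the minimal MIC, and per
compound the count of organisms at each MIC level.

Group comparisons default to the **log2 scale**, where the geometric
ladder is equally spaced; the raw scale remains available
(`--scale raw`) since the original analysis did not state its scale.
The default observational unit is one value per (compound, organism)
with organisms acting as replicates — the published analysis did not
state whether assay triplicates entered individually, and this is the
only layout its table supports. Not-tested cells are dropped pairwise,
never imputed.

The one-way ANOVA is the classical between/within decomposition with
p from the F distribution. Tukey's HSD uses the Tukey–Kramer standard
error `sqrt(MSW/2 (1/n_i + 1/n_j))`, so unbalanced designs are handled
and the balanced case reduces to the textbook form. The
studentized-range distribution is evaluated in-package by
Gauss–Legendre quadrature of its double-integral CDF (96 inner z-nodes
on [-8, 8], 64 outer nodes over the pooled-SD density truncated at
1e-12 tail mass); this reproduces an independent library implementation
to ~1e-6 and a 10^6-draw Monte-Carlo oracle within sampling error, and
critical values are obtained by root-finding on the survival function.

## Synthetic data

The generators produce inputs with the *functional structure* each
consumer assumes, so closed-form oracles exist:

* **Cross sections**: `total = alpha_Z E^(-beta_Z) + gamma_Z`
  (monotone decreasing), Compton channel a fraction
  `f(Z) = 0.98 exp(-0.01 Z)` of total. The fraction is log-linear in Z
  on purpose: the Zeq interpolation is then exact, enabling recovery of
  a planted Zeq to 1e-9.
* **G-P surfaces**: every parameter linear in log Z at each grid
  energy, with smooth energy dependence; `b >= 1`, `c < 1`, `a >= 0`,
  `d >= 0` so K grows with depth and B is provably monotone.
* **Docking tables**: dG uniform on [-15, -5] kcal/mol (the span of
  plausible strong-to-moderate binders), Ki computed by the package's
  own conversion and rounded to report precision — values below 1 in
  their display unit keep 3 significant digits so the printed number
  stays inside the 2% consistency tolerance.
* **MIC matrices**: log2 MIC = organism baseline (default log2 625,
  the modal value of the reference assay) + whole-rung organism offsets
  + compound effect + N(0, sd) noise with sd = 0.25 log2 units
  (moderate replicate scatter: ~1 rung disagreement every ~20 calls),
  snapped to the nearest rung in log2 with ties to the *higher*
  concentration (the conservative direction: a tie reads the compound
  as less active). Default 6 compounds x 9 organisms, the shape of the
  reference assay.

One root seed feeds independent per-generator substreams
(`SeedSequence.spawn`), so each table is bit-reproducible on its own.

What the synthetic tests do **not** show: real cross sections are not
power laws (resonance-free smoothness is assumed), real G-P surfaces
are fits to transport calculations rather than log-linear planes, and
real MIC noise includes plate effects and reader bias that a single
normal term does not capture. Passing the oracle suite demonstrates the
*computational* chain is exact, not that the physical or biological
model is complete.

## Problem sizes

The test and acceptance workloads are sized to run comfortably on one
CPU: 24-point elemental grids, 25-point buildup energy grids, 10^6
Monte-Carlo draws for the studentized-range oracle, 10^4 null
replicates for the ANOVA size check, and 10^3 replicates for the
Tukey power check (a -3 log2-unit effect across 9 organisms, detected
against every competitor in >= 95% of replicates).

## Known limitations

* Attenuation validation is confined to the Compton regime; the
  published 80/120 keV rows are suspect (see above) and photoelectric-
  dominated energies would also stress the Klein–Nishina Compton
  column the most.
* No photon transport, detector response, effective-Z/electron-density
  parameters, or buildup-parameter generation.
* The MIC ANOVA treats organisms as exchangeable replicates; a
  two-way or mixed model would be more faithful but is outside the
  published analysis.
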