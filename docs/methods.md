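# Methods

This note records the models the package implements, the conventions and
defaults it fixes where the underlying study left them implicit, and what
its validation does and does not demonstrate.

## Geometry benchmark

The accuracy metric for a method column against experimental bond lengths
is the ratio-of-means form

    A% = 100 · mean_i |r_calc,i − r_exp,i| / mean_i r_exp,i .

The alternative mean-of-ratios reading (averaging per-bond percentage
deviations) agrees with this one to well under 0.01 on the bundled
12-bond table; the ratio-of-means form is primary because it is the
literal reading of the defining footnote. A% is scale-invariant and
permutation-invariant (property-tested). Recomputing from the 3-decimal
printed bond lengths gives values within ±0.015 of the printed A% row
(e.g. 1.097 vs 1.102 for B3LYP/6-311++G(d,p)); the residual is consistent
with the original computation having used unrounded lengths. Comparisons
therefore use an absolute tolerance of 0.02.

## Global reactivity descriptors

Orbital energies enter in hartree and are converted with
1 hartree = 27.211386 eV. The Koopmans-style identification I = −E_HOMO,
A = −E_LUMO is taken as exact. Derived quantities: Eg = I − A,
χ = (I+A)/2, V = −χ, η = (I−A)/2, S = 1/(2η), ω = χ²/(2η), N = I_TCE − I.

Two conventions deserve comment:

- **Softness.** The package uses S = 1/(2η), the definition consistent
  with every printed softness value (η = 1.73 eV ↔ S = 0.29 eV⁻¹); the
  occasionally-seen S = 1/(2η) vs S = 1/η ambiguity is resolved by the
  data.
- **Nucleophilicity reference.** I_TCE is not printed anywhere in the
  source tables. Back-solving N + I on each of the seven reliable rows
  gives 4.212 ± 0.005 eV, so the default is I_TCE = 4.21 eV. This does
  not match typical computed ionization energies of tetracyanoethylene
  (~11.7 eV experimentally); it is treated as an empirical fitted
  constant, exposed as configuration, with no physical endorsement.

All intermediates stay at full precision; rounding to 2 decimals happens
only at output. This matters: the 9H aqueous electrophilicity is 6.83 eV
from unrounded intermediates but 6.85 eV if χ and η are first rounded.

The bundled orbital table contains a transcription defect: the first 9H
row duplicates the 7H aqueous row verbatim and is phase-labeled
"aqueous", leaving 9H without usable gas-phase orbitals. The row is
stored as printed with `suspect=true`; default loaders and descriptor
tables skip it. Seven reliable rows remain (gas: 2H, 6H, 7H; aqueous:
2H, 6H, 7H, 9H), and every derived cell of those rows reproduces the
printed value within ±0.02 (printed precision is 2 dp).

Solvation energies are aqueous-minus-gas total-energy differences
converted to eV; negative means stabilization in water. All four
derivatives are stabilized by 0.8–1.0 eV.

## Drug-likeness rules

Lipinski thresholds are inclusive (≤), matching the rule's statement;
failure requires more than one violation. Veber thresholds are strict
(<), matching "under 140 Å²" / "under 10". All panel compounds sit far
from every boundary, so the choice is observationally neutral on the
bundled data. The PSA column is treated as TPSA for the Veber test.

The Golden Triangle is not given explicit geometry in the source; the
package defaults to the published construction — vertices (−2, 200),
(5, 200), (1.5, 450) in (logD7.4, MW), boundary inclusive — which
reproduces all three stated classifications (2H inside, 7H inside, 9H
outside) and additionally classifies 6H as outside (a derived outcome the
source is silent on; 6H's MW 404.4 puts it just past the right edge at
its logD). Membership uses the sign-consistent half-plane test, invariant
to vertex ordering and consistent affine rescaling (property-tested).

## Binding thermodynamics

No conversion formula is printed with the docking tables; the package
adopts the AutoDock convention Ki = exp(ΔG/RT) with
R = 1.98720425e−3 kcal mol⁻¹ K⁻¹ and T = 298.15 K, which reproduces all
ten reported Ki values within 0.85% relative. The default verification
tolerance is 1% because rounding ΔG to 2 dp propagates ~±0.85% in Ki at
room temperature — observed directly in the tables, where the same
ΔG = −9.29 kcal/mol is printed with Ki 155.7 nM in one table and
154.3 nM in the other, bracketing the recomputed 155.0 nM.

## QSAR

Four response transforms map IC50 (µM) to the modeled response:
identity, reciprocal, log10(1/IC50) (pIC50), and log10(IC50). The latter
two are exact negations of one another, so their fitted predictions are
sign-flipped copies — an identity the tests enforce.

Fitting is least squares with intercept on raw (unstandardized)
descriptors, since the published equations are in raw units. Orbital
energies enter in eV; logs are base 10. When p + 1 ≥ n or the augmented
design is rank-deficient, `numpy.linalg.lstsq` returns the minimum-norm
solution; the fit is flagged `underdetermined`, its r² (1 up to numerical
noise, since it interpolates) is reported but must not be read as
validation, and standard errors / adjusted r² are withheld. A constant
response defines r² = 0 (no explainable variance). Reported r² is clamped
to [0, 1] with the raw value retained. The validation gate r² > 0.6 is
exposed as a constant and surfaced in fit reports.

**Why the published equations are not certified.** The study's four
printed regression equations were fit on a 4-compound panel with 5–8
descriptors each — necessarily underdetermined, which is incompatible
with their quoted r² of 0.9682/0.9924 (exact interpolation gives 1), and
evaluating the printed coefficients on the panel's own descriptors does
not reproduce the observed activities (the five-term IC50 equation yields
≈ −171 µM for the compound whose measured IC50 is 22.80 µM, under every
natural unit convention). The package therefore treats printed equations
as evaluable artifacts (`apply_model`) and demonstrates estimator
correctness on synthetic data instead. One practical consequence of the
orbital-table defect above: a 4-compound design matrix including quantum
descriptors is only constructible in the aqueous phase, which is what the
tests and the pipeline default use.

Forward stepwise selection adds greedily the candidate maximizing r²,
stopping at `max_terms`, when improvement falls below 1e−6, or when the
next term would make the fit underdetermined; ties break by candidate
order, making selection fully deterministic.

## Synthetic panels

The generator draws descriptors independently and uniformly over
plausibility ranges bracketing the study panel (printed min/max padded by
roughly 10%): orbital energies E_HOMO ∈ [−0.26, −0.19] au,
E_LUMO ∈ [−0.13, −0.09] au (disjoint ranges guarantee E_HOMO < E_LUMO),
logP ∈ [−3.0, 2.1], MW ∈ [355, 407] Da, PSA ∈ [66, 118] Å²,
logD7.4 ∈ [2.0, 2.6], integer counts HBD ∈ {1..5}, HBA ∈ {3..7},
n_rotb ∈ {0..4}, and so on. Global descriptors are derived from the drawn
orbitals, so all descriptor identities (S·η = 1/2, Eg = I − A, V = −χ)
hold by construction. Activities follow a known linear model on the
transformed-response scale plus Gaussian noise; the default true model is
a three-descriptor pIC50 relation with σ = 0.1 response units, a
residual scale typical of a well-behaved small-molecule QSAR. Log-family
transforms guarantee positive IC50 by construction; for identity and
reciprocal responses the noise is rejection-resampled per compound until
the implied IC50 is positive (bounded retries; with sane intercepts the
truncation is never exercised). Censoring marks round(n·fraction)
activities missing, uniformly at random.

What the generator does **not** emulate: inter-descriptor correlation
beyond what the descriptor identities induce (real ADME descriptors are
strongly collinear), measurement error in descriptors, heteroscedastic or
non-Gaussian assay noise, and activity cliffs. Passing recovery tests
therefore demonstrates estimator correctness under a correctly specified
linear model — not that a 4-point real panel supports such a model.

Replicate r of a recovery experiment uses seed `base_seed + r` with
numpy's PCG64 generator; identical seeds yield byte-identical CSVs. The
recovery study conditions (n = 200 compounds, 3 true coefficients,
σ = 0.1, 200 replicates) give per-coefficient |bias| < 0.02 and ~0.95
empirical coverage of the t-based 95% CIs; a smaller grid (n = 50 vs
n = 200 at 40 replicates) checks the σ/√n RMSE scaling within 20%.

## Numerical choices, in brief

- hartree→eV constant 27.211386; descriptor comparisons at ±0.02 (print
  precision); benchmark comparisons at ±0.02; Ki verification at 1%.
- OLS via `numpy.linalg.lstsq` (rcond=None); statsmodels OLS is the
  independent cross-check in the tests, never the implementation.
- Stepwise improvement threshold 1e−6 absolute r².
- Degenerate inputs fail loudly: e_homo ≥ e_lumo, non-positive IC50 under
  log/reciprocal transforms, non-positive Ki or temperature, collinear
  triangle vertices, empty candidate sets.

## Known limitations

- The drug-likeness module consumes precomputed descriptors; it does not
  compute logP/TPSA from structure.
- The thermodynamic conversion assumes the rigid AutoDock convention; no
  entropy decomposition or temperature dependence of ΔG.
- The QSAR module fits and evaluates linear models only; regularized or
  nonlinear variants are out of scope, as are cross-validation and
  y-randomization (no such validation exists for the 4-compound panel to
  begin with).
- Gas-phase reactivity descriptors for compound 9H are unrecoverable from
  the source tables (see the suspect-row note above).
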