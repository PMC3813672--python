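# Methods

`kpath` re-implements, as a tested pipeline, a path-coefficient analysis of
soil potassium status: which soil properties control the three plant-relevant
potassium pools — water-soluble (wsK), exchangeable (eK) and non-exchangeable
(neK) — and in which direction the equilibrium between those pools is moving
in a given soil sample.

## Data model

The analysis unit is the *sample group*: one row of averaged laboratory
measurements per treatment cell (16 groups: rhizosphere vs non-rhizosphere
soil × two cotton genotypes × four fertilization regimes). The packaged
measurement tables are verbatim transcriptions of the source data: elemental
totals (Na, Mg, Al, Si, Fe, Ca, CO3 in mass %; P, S, Cl in ppm), potassium
forms (total K in g/kg; wsK/eK/neK in µg/g), organic-matter fractions
(TC, TN, SOM, PHA, NHA, HMi, HMc in %), physicochemistry (ORP, pH) and
silicate-dissolving bacteria counts. Units are stored exactly as measured;
conversions happen only inside index computations and are logged.

Two transcription decisions deserve note. The elemental table carries two
columns both headed "Mg%"; they are stored as `Mg_a` (≈0.39) and `Mg_b`
(≈1.49). `Mg_a` is the one that reproduces the published ba index (swapping
in `Mg_b` moves ba by >0.3), so `Mg_a` is exposed as the analysis variable
`Mg` and `Mg_b` is carried as data of unknown identity. Blank cells in the
published correlation surface mean "below the display threshold", never zero,
and are stored as explicit nulls.

## Weathering indices

Four indices are rebuilt from elemental totals on a molar-oxide basis: for an
element with atomic mass m whose oxide holds s cations (s = 2 for Al2O3,
Fe2O3, Na2O, K2O; s = 1 for CaO, MgO), oxide moles per 100 g = mass% / m / s.
Total K is converted g/kg → % (÷10) on entry.

- Na/K = Na% / K% (plain mass ratio)
- CIA = 100·Al2O3 / (Al2O3 + CaO + Na2O + K2O)
- saf = SiO2 / (Al2O3 + Fe2O3)
- ba  = (CaO + MgO + Na2O + K2O) / Al2O3

This convention was validated against the published 16-row index table:
Na/K, saf and ba reproduce every printed value within ±0.01 at two-decimal
rounding. CIA does not: recomputed values deviate by up to 0.12 with
alternating signs. Interval analysis shows every printed CIA lies inside the
band implied by ±half-ULP rounding of the printed Al/Ca/Na/K inputs (about
±0.13), so the published CIA was evidently computed from unrounded raw data
and exact two-decimal agreement is unattainable from the published inputs.
The standard silicate correction of CaO (CaO*) is *not* applied — the
uncorrected form is what reproduces the published numbers. ICA is carried as
data only: no tested convention reproduces its printed 1.02–1.08 values.

## Normalization and correlation screening

Variables are standardized to Z scores with the sample (n−1) standard
deviation. Pearson correlations are pairwise-complete; p-values come from
t = r·√((n−2)/(1−r²)) with n−2 df, two-tailed. Significance letters follow
the published caption literally (a: p<0.01, b: p<0.05) even though the
printed matrix demonstrably attaches them the other way round; the
alpha→letter map is configurable. Reports mask |r| < 0.5 (the smallest
magnitude the published matrix prints); the full matrix is always retained.

Recomputation on the 16 group rows reproduces the bulk of the published
correlation surface within ±0.01 — including every potassium-form pair
(wsK–neK 0.77, wsK–eK 0.73, neK–eK 0.98) and the SOM/pH/ORP/TN block. Cells
involving PHA, NHA, the bacteria counts, ORP–CO3 and total K do not
reproduce from the group rows (they were presumably computed on the
unpublished 256-sample data); the comparison report lists every printed
cell with its recomputed value and deviation rather than hiding these. One
printed cell, CIA–Na/K = 0.829, has the wrong sign (the data give −0.829,
magnitude exact).

Parameter selection ranks significant partners of a response by |r|
(lexicographic tie-break) and keeps the top k (default 8).

## Path models

The direct effect of predictor j on response i is the standardized partial
regression coefficient P_ij solving the normal equations R_xx·P = r_xy;
R² = r_xy·P. On the standardized scale the coefficient standard errors are
se_j = √((1−R²)/(n−p−1)·[R_xx⁻¹]_jj), giving coefficient t tests with
n−p−1 df. Each simple correlation decomposes exactly (a property of OLS)
into the direct path plus indirect paths through the other predictors,
r_ij = P_ij + Σ_{k≠j} r_jk·P_ik, and the unexplained part of the response
enters the diagram as the residue e = √(1−R²).

Backward elimination removes, while any coefficient p-value exceeds
`alpha_remove` (default 0.05, configurable — the source states only
"not contributing significantly"), the predictor with the largest p-value;
ties break to the larger p then the lexicographically larger label, making
the trace deterministic. With 16 groups and 8 predictors the full fit has
7 residual df: the module warns below 10 df and refuses below 1. The
predictor correlation matrix is rejected above condition number 1e8 (the
neK–eK correlation of 0.98 makes near-singularity a live concern; it stays
just inside the bound).

The three published response models (wsK, neK, eK — the neK predictor list
deduplicated) are fitted with their full printed predictor sets by default,
so the total-effect column reproduces the simple correlations exactly. The
published coefficient tables are treated as qualitative references only:
their three columns are internally inconsistent (the "direct" column equals
the simple correlations), so the comparison report emits all three candidate
quantities — recomputed simple r, direct P and summed indirect effects — for
every listed variable. One quantitative anchor does hold: the fitted direct
coefficient of neK in the eK model is 1.10, the value quoted in the source
text. Path diagrams are exported as plain DOT text (dashed predictor→response
edges weighted by direct coefficients, double-headed predictor–predictor
edges above the display threshold, residue node `e`).

## Equilibrium shift

For each target pool (neK, eK) two transformation routes are scored by
linear contribution-coefficient functions of the sample's standardized
properties, V_route = Σ_j w_j·Z_j. The packaged default weights are a
*calibration*: the published per-sample route values, together with the
observation that the published Z columns are exactly the z-scores of neK/eK
over the 16 group rows (which also fixes the group↔treatment-label mapping),
admit an essentially exact least-squares reconstruction

    V_wsK→neK = 1.6728·Z(wsK) + 0.6229·Z(NHA)      V_eK→neK = 1.0193·Z(eK)
    V_wsK→eK  = 1.0205·Z(wsK)                      V_neK→eK = 1.6722·Z(neK) + 0.6205·Z(NHA)

reproducing all 64 published V/Z entries to ±0.01. (NHA fits where the
source narrative names PHA; PHA-based fits leave residuals near 1.) Weights
can instead be built from a fitted path model's total contribution
coefficients of the route's source variables, or overridden entirely in the
JSON config.

A sample is *at equilibrium* when its standardized target-pool content lies
within a tolerance (default 0.05 on the Z scale) of the equilibrium
threshold y, taken as the dominant (larger-magnitude) route value. The
dominant-route statistic and the tolerance are design choices exposed in the
config; the source defines the threshold only implicitly.

Direction labels (two symbols from {α, β, γ, χ} for the neK block and
{ε, θ, λ, ω} for the eK block) are produced by a *calibrated decision
table*: the published (V1, V2, Z) triples with their labels, queried by
nearest row (Euclidean distance, earliest row wins ties). This rule is
total and deterministic and reproduces all 32 published labels at distance
zero, but it is a stored calibration, not a derived law: no sign/magnitude
comparison signature separates the published labels without collision
(3 collisions in the neK block, 6 in the eK block), so any analytic rule
claim would be invention. A single-row table degenerates to a constant rule.

## Synthetic data

The generator emulates exactly what the analysis assumes: a multivariate
Gaussian covariate block with a target correlation matrix, plus optional
linear structural responses y = Σ β_j x_j + ε with noise sd √(1−βᵀR_xxβ) so
responses are unit-variance under standardized coefficients (βᵀR_xxβ ≥ 1 is
rejected as infeasible). The default target matrix is the published
correlation surface with blanks filled by 0 (the least-informative value
below the 0.5 display threshold) and repaired to positive definiteness by
eigenvalue clipping at 1e−8 followed by diagonal re-normalization; the
clipped mass is reported. `emulate_study` draws 16 groups over the published
variable set and back-transforms to the packaged tables' means/sds, so the
synthetic table passes through every downstream stage.

What passing tests on this generator do *not* show: real soils have
non-Gaussian marginals, spatial structure and nonlinear couplings; the
generator reproduces second moments only, so parameter-recovery results
speak to the estimator's correctness, not to robustness against
distributional misspecification.

Determinism: one `numpy` Generator seeded from the spec; identical spec and
seed give bit-identical CSV output.

## Problem sizes and numerical choices

Monte-Carlo checks use n = 10,000 with 5 seeds (parameter recovery,
correlation convergence) and 100 seeded random instances (oracle
equivalence, decomposition identity) — sizes at which sampling error is an
order of magnitude below the asserted tolerances while the whole suite runs
in seconds. Exact identities (decomposition totals, residue² + R² = 1,
permutation invariance) are asserted at 1e−8–1e−12. Degenerate inputs are
rejected early with named errors: constant columns, n < 3 tables, duplicate
group ids, collinear predictor sets, infeasible structural coefficients.

## Known limitations

- CIA cannot be matched to two decimals from the published inputs (above).
- The correlation cells that were computed on unpublished per-sample data
  are irreproducible in principle from the packaged tables.
- The equilibrium-shift functional forms and the direction rule are
  calibrations that reproduce the published table; they carry no claim about
  the original analytic definitions, which are not recoverable.
- With 16 groups and 8 predictors the path models are fragile (df = 7);
  coefficient p-values should be read with that in mind.
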