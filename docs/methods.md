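# Methods

`glycosar` implements a design-and-analysis chain for peptide libraries in
which two MHC class II anchor positions (p260 and p263 of the CII259–273
glycopeptide epitope) are varied over sets of natural and unnatural amino
acids. The chain has five stages: geometric culling of docked poses,
per-position consensus scoring, principal-property statistical molecular
design (SMD) with D-optimal subset selection, indicator-variable PLS SAR
modelling, and a combined-response PCA of the biological assay panels.
Docking, force-field minimization and descriptor calculation are external
steps; the package consumes their outputs (score tables, PDB poses,
descriptor tables) and, for testing, generates synthetic stand-ins with
known ground truth.

## Geometric pose filtering

A docked pose is compared to the reference pose by the RMSD of backbone
atoms matched by (residue index, atom role). "Backbone" defaults to
{N, CA, C}; whether CA or the carbonyl O should participate is genuinely
ambiguous, so the role set is an argument. Poses are compared in the shared
receptor frame without superposition, because all poses are docked into one
fixed binding site; an optional Kabsch superposition is available for
frame-free comparisons. Before RMSD the peptides are truncated to the
260–263 fragment, since the unmodified C-terminus varies freely in docking
and would dominate the deviation.

Culling is two-staged and strict: poses with RMSD < 3.0 Å (docked vs
reference) proceed to external energy minimization, and peptides whose
minimized pose has RMSD < 1.5 Å survive to rescoring. Values exactly at a
threshold are culled. A stage-1 survivor lacking minimized coordinates is an
error unless the caller explicitly opts to reuse the docked coordinates
(useful when the minimization step is bypassed).

## Consensus scoring

Each surviving peptide carries one value per scoring function (seven in the
reference workflow). Goldscore ranks by large positive values and is negated
so that every function ranks by minimization. For each residue observed at
an anchor position the summary records its frequency in the culled set and,
per function, the best (minimum) score, the mean and the sample standard
deviation — 1 + 3·7 = 22 parameters. Residues observed once get sd 0 rather
than a missing value so the summary matrix stays complete.

Selection is by PCA on the mean-centered, unit-variance-scaled summary.
The first component is oriented by its loadings so that the positive
direction corresponds to high rank (low scores), high frequency and low
spread; residues with PC1 score above a configurable threshold (default 0)
are selected. The original selection was made visually from score plots;
the sign-oriented PC1 cut is this package's explicit, reproducible
formalization of that rule. In full-factorial synthetic tables the
frequency column is constant and is dropped (with a warning) before
scaling.

## Chemometrics engines

All multivariate models operate on mean-centered, unit-variance-scaled
data; preprocessing state (means, SDs) is recorded and invertible.

**PCA** uses the singular value decomposition; R²X(cum) is the cumulative
share of the total corrected sum of squares. Q²(cum) comes from
element-wise cross-validation: cells are assigned to 7 diagonal-stripe
deletion groups, and for each group the matrix with those cells removed is
refit at the requested rank by iterative-SVD (EM) imputation, the deleted
cells are predicted from the reconstruction, and Q² = 1 − PRESS/SS. The EM
scheme was chosen over missing-value NIPALS because NIPALS on deflated
residual matrices can diverge when a deletion stripe captures most of a
loading's mass. DModX is the per-observation residual standard deviation
divided by the pooled residual SD with SIMCA-style degree-of-freedom
corrections; its mean is ≈1 on unstructured data, and it is defined as 0
when the model explains the data to numerical precision.

**PLS** is NIPALS PLS1. The response is centered and unit-variance-scaled,
as are indicator predictors (configurable off). Coefficients are reported
on the preprocessed scale (unitless bars, as conventional for indicator
SAR plots); `PlsModel.coefficients_raw()` converts to the raw response
scale for quantitative comparisons. Q²(cum) is leave-one-out with the
preprocessing re-estimated inside every fold. The number of latent
variables is chosen by maximizing Q²(cum). Permutation validation refits
the model on `n_perm` (default 100) seeded shuffles of the response and
reports each shuffle's R²Y, Q² and correlation with the original response,
plus the intercepts of the R²/Q² regression lines on |correlation|; the
validity verdict uses the conventional limits R²-intercept < 0.3 and
Q²-intercept < 0.05, which are defaults, not calibrated values.

Indicator matrices for the two-block design have fixed row sums (one 1 per
position block), so coefficients are identified only up to a constant shift
per block: rankings are meaningful within a position, not across positions.
Recovery tests therefore score within-position rank agreement.

## Statistical molecular design

Candidate residues per position are described by physicochemical
descriptors; a per-position PCA compresses these into principal
properties, of which the first k = 4 score vectors enter the design. The
candidate set is the full factorial of selected residues; each model-matrix
row is [1, PP(p260), PP(p263)] (intercept + main effects, 2k+1 columns; no
interaction terms, matching a main-effects SAR model).

D-optimal selection maximizes det(XᵀX) over N-row subsets with classic
single-point Federov exchange: from each seeded random start, the single
in/out swap with the largest determinant gain is applied until no swap
improves, and the best of 20 starts is kept. Ties break toward the lowest
candidate index so seeded runs are bit-reproducible. A ridge of 1e-8 on
XᵀX keeps the criterion finite for singular subsets. On all instances small
enough for exhaustive search the exchange attains the global optimum, and
at the study scale (20 of 49, 9 columns) it dominates the best of 1000
random subsets.

Unconstrained D-optimality can leave a residue level unrepresented. The
coverage check reports per-level counts against a minimum (default 2,
matching the requirement that every level appear at least twice among the
20 selected peptides), and an optional greedy repair pass swaps candidates
to restore coverage at minimal determinant loss. Repair is an extension —
the original balance may have been curated manually — and is off by
default.

## Response panels and response-pattern PCA

The transcribed binding/T-cell tables for peptides 1–21 ship as a TSV
fixture. Ordinal T-cell categories map to the threshold antigen
concentration (µM) needed for 10 % of maximal IL-2 response and then to a
strength −log₁₀(conc); "−" (no response) maps to a floor of 1500 µM (10×
the highest tested concentration, one log-unit below the weakest category;
configurable), and "n.d." is missing. Aq-inactive peptides (< 30 %
inhibition in the screening assay, not re-assayed) enter numeric encodings
as 0 % inhibition.

The combined-response PCA runs on the peptide × response matrix (four
binding columns + eight hybridoma strengths), centered and scaled with
missing-tolerant statistics and mean-imputed after scaling. Peptides are
grouped by average-linkage hierarchical clustering of the first three
component scores (rows are sorted by id first, so grouping is invariant to
input order). The underlying per-concentration dose–response values behind
the original analysis are unpublished; the ordinal-strength encoding is the
package's default, and a per-concentration response matrix can be supplied
instead.

The 20-peptide anchor assignment shipped in `design_assignments.tsv` is
reconstructed from the results narrative; rows whose (p260, p263) pair is
directly stated are marked `confirmed`, the remainder `provisional`
(chosen to satisfy pair uniqueness, the ≥2-per-level balance and the
active/inactive pattern of the tables). It supports qualitative SAR checks
— e.g. Ile carrying the largest positive p260 coefficient for Aq binding —
not quantitative reproduction.

## Synthetic data

The generators emulate the statistical structure of the unavailable
external outputs:

- **Score tables**: peptide score = latent(p260) + latent(p263) + noise,
  with the noise sharing a common factor across scoring functions
  (default variance share 0.6). Latent contributions are Gaussian with SD
  3 around a mean total of −30 score units; scoring noise SD defaults
  to 2.
- **Descriptor tables**: low-rank factor model (default rank 4) plus
  Gaussian noise, so the latent rank is recoverable by PCA.
- **Poses**: per-atom Gaussian displacement of a reference backbone
  (expected RMSD ≈ sd·√3), or exact rigid translations.
- **Binding responses**: y = Xβ + ε clipped to [0, 100] %. Clipping is a
  deliberate departure from pure linearity mimicking the bounded assay
  readout. Default planted effect spread is β ~ N(0, 15²) — the raw-scale
  level effects fitted to the transcribed tables span roughly ±30 % — with
  response noise SD 5, matching the replicate SDs (1–8) reported in the
  assays, and a baseline placing responses near 50 %.

What the generators do **not** emulate: the true score distributions of the
individual docking functions, correlations between pose geometry and score,
descriptor semantics (size/hydrophobicity/flexibility), or assay
saturation curves. Passing property tests therefore demonstrate that the
algorithms recover known structure under the stated noise model, not that
the original docking-based selections would be reproduced — those depend on
unpublished FRED/MOE outputs.

## Problem sizes and numerical choices

The end-to-end driver defaults to a 50 × 50 synthetic library (2500
peptides, 7 scoring functions) with pose noise chosen to pass roughly a
quarter of poses through the 1.5 Å gate; property suites use 8 × 8 to
20 × 20 libraries, 50 replicates for recovery rates and 100 permutations,
which keeps the full test run in well under a minute per suite. Exhaustive
D-optimal verification covers instances up to 12 candidates and subsets of
6. Tolerances: summary-statistic oracle agreement 1e-10, SVD/OLS oracle
agreement 1e-8, exchange-vs-exhaustive determinant agreement 1e-9.
Degenerate inputs fail loudly: constant response vectors, all-constant
matrices, empty score tables, truncations that drop every atom, and
coverage demands exceeding the selection size are all errors.

## Known limitations

- The survivor count of the original screen (1540 of 11025), the 46/52
  residue selections and the published PCA/PLS fit statistics depend on
  unpublished docking scores and MOE descriptors and cannot be recomputed;
  the package reproduces the published count-level, aggregate and
  qualitative patterns and verifies the algorithms on synthetic ground
  truth instead.
- PCA Q²(cum) approximates the cross-validation of commercial
  chemometrics packages; values are comparable in character (high for
  structured data, ≤ 0 for noise) but not numerically identical to their
  output.
- The Federov exchange is a local search; global optimality is verified
  exhaustively only at small sizes, and at study scale optimality is
  supported by multi-start dominance over random subsets.
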