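# Methods

## The estimation problem

AAindex-style scales assign one real value to each of the 20 canonical
amino acids.  To extend such a scale to a non-canonical amino acid, the
package represents every amino-acid-like molecule by 13 integer counts read
off its SMILES string and fits, per property, a sparse linear model of the
property on those counts over the canonical 20.  The model is then a
portable formula: any molecule whose SMILES can be counted gets a predicted
value, with the scale's cross-validated RMSE as its uncertainty.

With only 20 training rows and 13 candidate predictors, the entire design
is about guarding against overfitting: per-coefficient significance gating,
leave-one-out scoring, and domain filtering (molecules containing As, B,
Br, Cl, F, I, P or Se — elements absent from the canonical amino acids —
are refused, since no training signal constrains their effect).

## Component counting semantics

Counting is **literal and case-sensitive on the SMILES string as
distributed** (PDBeChem's OpenEye dialect), not on a perceived molecular
graph.  Single-letter atom components (O, N, n, C, c, S) count atom tokens
with that exact symbol — bracketed atoms (`[C@@H]`, `[NH3+]`, `[nH]`) count
like bare ones, and the `C` of a two-letter element symbol such as `Cl`
never contributes, which the tokenizer enforces by parsing element symbols.
Pattern components are raw substring counts: `=O`+`O=` (double-bonded
oxygen), `=N`+`N=`+`=[N`, `[C@` (chiral centre), `=`, `+`, and an atom
letter from {c, C, n, N, S} immediately followed by the ring digit 1 or 2.
Components deliberately overlap (every `=O` is also an `O`; every chiral
carbon is also a `C`).  Ring closures with digits ≥ 3 or `%nn` labels have
no component and are logged at debug level.  Under this rule a ring
typically contributes 2 to its digit's component when both closure bonds
follow atom letters, and less when a bracket or branch intervenes — the
counts are string facts, not ring counts.  The bundled proline entry is
written in the ring-first form (`C1C[C@H](NC1)C(O)=O`, ring1 = 2);
retraining the bundled hydrophobicity property with this table reproduces
the published 10-predictor coefficient set to its printed six decimals,
which is the package's strongest evidence that table and counting semantics
match the original models.

The tokenizer validates structure only as far as counting requires:
balanced brackets and parentheses, no dangling bond, paired ring-closure
digits, known element symbols.  No canonicalization, aromaticity
perception or 3-D reasoning is done; an empty string is an error, not a
zero vector.

## Regression and predictor selection

`ols_fit` solves the least-squares normal equations with an intercept that
is always present and never gated.  Standard errors use residual variance
`sse / (n − p − 1)`; each predictor's significance is `F = (b / SD)²`, the
squared t statistic.  If `sse/n` falls below `1e−12 · var(y)` the fit is
flagged perfect: the standard errors vanish, the statistic is undefined,
and F values are reported as `+inf` so every predictor trivially passes any
gate.

`stepwise_select` searches for a fixpoint model in which every retained
predictor has `F ≥ F*` after the joint refit.  Forward steps try candidates
in order of decreasing residual sum-of-squares reduction (ties broken by
the fixed component-column order); after each tentative inclusion, backward
elimination repeatedly drops the lowest-F predictor until all survivors
pass the gate.  Visited predictor sets are tracked so the search terminates
at a fixpoint rather than cycling.  Zero-variance columns are excluded from
candidacy per fit — including within each leave-one-out fold, where a
component present in a single amino acid routinely goes constant.  If
nothing survives, the constant-only model (the mean of y) is returned.

Perfect fits need one extra step: with every F infinite, backward
elimination cannot remove predictors that became redundant once the
generating support completed, so a perfect final fit is minimized by
greedily dropping any column whose removal keeps the fit perfect, plus a
pair-for-single swap that handles exact design identities (on the canonical
table, `dbl = dblO + dblN` holds exactly, so `{dbl, dblN}` can impersonate
`{dblO}`).

## Threshold selection and quality scoring

The gate `F*` is chosen from a grid (default 0.5–12.0 in steps of 0.1,
configurable; the original probing was much coarser) by maximizing the
leave-one-out Pearson correlation `r_j-n`, with ties resolved toward the
largest threshold, i.e. the most parsimonious model.  Each fold reselects
predictors from scratch; fold-level selections are not reported, only the
full-data refit at `F*`.  RMSE is computed from the same leave-one-out
prediction vector as `r_j-n` — a deliberate, recorded choice (`rmse_basis:
"loo"` in the model store): held-out error is the honest uncertainty to
attach to predictions for unseen molecules, whereas in-sample residuals
would understate it.  For properties that are perfect linear functions of a
component (e.g. a positive-charge indicator), the threshold is meaningless
and is reported as NaN, with the degenerate flag set; RMSE is then ~0 and
`r_j-n` is still computed by LOO.

Properties with missing (`NA`) values drop the masked amino acids from
training for that property only; `n_used` and the dropped codes are stored
with the model.

## Bundled reference data

The 20-amino-acid SMILES table is assembled by hand in the PDBeChem/CCD
dialect with CCD protonation states (arginine, lysine and histidine carry a
positive charge, which is what lets a charge indicator correlate perfectly
with the `+` component).  The frequent-ncAA table lists the 25 most common
modified residues in the PDB.  The reference hydrophobicity model
(EISD840101) ships with its published coefficients, threshold scan and the
4-hydroxyproline worked example.  The EISD840101 property-value record is a
hand-reconstructed stand-in, labelled synthetic in its filename: only the
proline value is independently confirmed, although the exact reproduction
of all published coefficients when retraining on it argues the remaining 19
values are right.  All fixtures are SHA-256 pinned; a modified file raises
a checksum error.

## Synthetic data: what it does and does not emulate

`generate_property` draws `y = X_s·β + c + N(0, σ)` over the canonical
design matrix with a known sparse support, so selection, fitting and LOO
scoring can be checked against ground truth.  Supports offered by
`well_conditioned_supports` are restricted to (i) submatrices with
condition number < 100, (ii) columns that stay non-constant when any single
row is removed, and (iii) supports whose span contains no other design
column — otherwise recovery is ill-posed (a component present in one amino
acid cannot be predicted for its own held-out fold; exactly collinear
columns admit several exact representations) and a failure would say
nothing about the code.  Real AAindex properties are not linear in the
counts with Gaussian noise and are mutually correlated across the database;
passing synthetic recovery therefore validates the machinery, not the
scientific accuracy of any particular scale.  Measured on the package's own
sweep (100 seeded properties, gate F = 2), noiseless supports are recovered
exactly; at noise σ = 0.1–0.3 the median support Jaccard drops to ~0.6,
mostly through noise predictors slipping past the gate.

## Numerical choices

* Perfect-fit tolerance: `sse/n ≤ 1e−12 · var(y)`.
* Stepwise forward ties: fixed component-column order; backward drops the
  single lowest F.
* Rank-deficient designs raise an error naming the collinear columns;
  fits require `n > p + 1`.
* Grids must be strictly increasing; `r_j-n` ties compare within `1e−12`.
* Undefined correlations (constant LOO vector, e.g. when every fold falls
  back to the training mean) are treated as missing, and such thresholds
  are never selected unless all are undefined.
* Machine output keeps full precision; reports round to 3 decimals.

## Known limitations

* The counter is defined on the distributed SMILES string; a chemically
  identical molecule written in a different SMILES convention can count
  differently.  Inputs should come from the same source dialect as the
  training tables (PDBeChem).
* With 20 training rows, leave-one-out correlations are noisy; published
  per-property `r_j-n` values from the original tool differ at some
  thresholds from this implementation's, consistent with unreported
  search-order details in its stepwise pass, while the final coefficient
  sets agree exactly where comparable.
* Predictions for molecules much larger than amino acids extrapolate far
  outside the training range of the counts and should not be trusted.
* Only AAindex1-style 20-value scales are supported; mutation/contact
  matrices (AAindex2/3) are out of scope, as is fetching data from the
  network.
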