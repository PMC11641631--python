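# ncaaprop

Estimating AAindex physicochemical properties for **non-canonical amino
acids** (ncAAs) from their SMILES strings.

The AAindex database assigns each of its 566 physicochemical scales one
value per canonical amino acid — and nothing for the 1000+ modified residues
found in the PDB. `ncaaprop` extrapolates any such per-residue scale to an
arbitrary amino-acid-like molecule: it trains, per property, a linear model
on the 20 canonical amino acids using 13 integer **component counts** read
off each molecule's SMILES string (oxygen, nitrogen and carbon split by
aromaticity, chiral centres, sulfur, ring closures, double bonds, positive
charges), then evaluates the same counts for an ncAA and applies the model.
It is aimed at protein scientists and method developers who need
hydrophobicity-like descriptors for residues such as 4-hydroxyproline,
methyllysine or phosphosite mimics that no experimental scale covers.

## Model

For a property with values `y` over the canonical amino acids and the
20 × 13 design matrix `X` of component counts,

```
y = Σ_k b_k · x_k + c + ε
```

predictors are chosen by **F-gated stepwise regression**: each coefficient's
significance is `F_k = (b_k / SD_k)²` (its squared t statistic), and a
predictor stays in the model only while `F_k ≥ F*` in the joint fit.  The
threshold `F*` itself is selected by **leave-one-out cross-validation**: for
every grid value, each amino acid in turn is held out, a model is selected
and fitted on the other 19 and used to predict it, and the Pearson
correlation `r_j-n` between held-out predictions and true values scores the
threshold.  The reported quality per property is `r_j-n` together with the
RMSE of the same held-out predictions, which is attached to every ncAA
prediction as its ± uncertainty.  Molecules containing elements foreign to
the canonical amino acids (As, B, Br, Cl, F, I, P, Se) are outside the
training domain and are filtered out.

## Worked example

4-hydroxyproline (HYP), the most common ncAA in collagen, under the
consensus normalized hydrophobicity scale EISD840101:

```
$ ncaaprop featurize --smiles "O[C@H]1CN[C@@H](C1)C(O)=O"
dblO    =O      1
anyO    O       3
aliphN  N       1
aromN   n       0
dblN    =N      0
aliphC  C       5
aromC   c       0
chiralC [C@     2
S       S       0
ring1   C1      1
ring2   C2      0
dbl     =       1
plus    +       0
```

Applying the bundled published EISD840101 coefficient set (10 selected
predictors, constant 1.629829) to this vector gives

```
EISD840101(HYP) = (−0.563688)·3 + (−0.556289)·1 + 0.113070·5
                  + (−0.290756)·1 + 1.629829 = −0.34293
```

reported as **−0.343 ± 0.282** (the ± is the scale's leave-one-out RMSE over
the canonical amino acids).  Proline itself measures −0.07 on this scale, so
hydroxylation makes the residue markedly more hydrophilic — one reason
collagen-like regions confound hydrophobicity-based structure predictors
that treat HYP as proline.  `ncaaprop selftest` runs this example plus a
noiseless synthetic-recovery check and prints pass/fail.

Training and bulk prediction from the shell:

```
ncaaprop train --aaindex aaindex1.txt --out models.json --summary summary.tsv
ncaaprop predict --models models.json --table ncaa_table.tsv --out predictions.tsv
```

or from Python, scikit-learn style:

```python
from ncaaprop import ThresholdSearchRegressor, canonical_table, build_design_matrix

X = build_design_matrix(canonical_table())
est = ThresholdSearchRegressor().fit(X, y)       # y: one AAindex property
est.f_star_, est.r_jn_, est.rmse_, est.selected_
```

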