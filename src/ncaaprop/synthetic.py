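"""Synthetic property vectors and bundled reference fixtures.

The synthetic generator draws property vectors with known sparse linear
structure over the canonical design matrix, ``y = X_s · beta_s + c + noise``,
so that every stage of the pipeline — selection, fitting, leave-one-out
scoring — can be tested against ground truth without any external data.
Supports are restricted to well-conditioned column subsets of the canonical
design (condition number below 100), so a recovery failure indicates a bug
rather than collinearity: the canonical matrix has only 20 rows and some
near-collinear columns.

Bundled fixtures (shipped in ``ncaaprop/data``, SHA-256 pinned):

* the canonical 20 amino-acid SMILES table (PDBeChem/CCD dialect, with CCD
  protonation states — arginine, lysine and protonated histidine carry a
  positive charge);
* the 25 most frequent non-canonical amino acids from the PDB with their
  SMILES;
* the published EISD840101 (consensus normalized hydrophobicity) reference
  model, its 4-hydroxyproline worked example, and its threshold scan;
* a hand-reconstructed stand-in for the EISD840101 AAindex record (labelled
  synthetic; only the proline value is independently confirmed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .components import COMPONENT_KEYS
from .aaindex import load_smiles_table, parse_aaindex1, PropertyRecord

__all__ = [
    "SyntheticSpec",
    "generate_property",
    "well_conditioned_supports",
    "canonical_table",
    "ncaa_table",
    "published_eisd_model",
    "eisd_values_synthetic",
    "selftest",
]

_SHA256 = {
    "canonical_amino_acids.tsv": "5d77d94b236263afb0fa3696ce85e585e5f9ffcf0cbb2eb2bb525ce642d987ab",
    "ncaa_frequent.tsv": "4e978353ca5b1cc292ab612af88ba749d12c553ea0976a7292c7e5436cd3eb51",
    "eisd840101_published_model.json": "2dcb33e72ccccacb15acaba3d62b4eec3ee1da1da7412273612be9df134d42ac",
    "eisd840101_values_synthetic.txt": "cd44550df25ae4f829f9a24459831aee0726d9692b149eb22f0a76a263a0a2c8",
}


class FixtureError(RuntimeError):
    pass


def _load_text(name: str) -> str:
    text = resources.files("ncaaprop.data").joinpath(name).read_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != _SHA256[name]:
        raise FixtureError(
            f"bundled fixture {name} has been modified (sha256 {digest})"
        )
    return text


def canonical_table() -> pd.DataFrame:
    """The 20 canonical amino acids: code, one_letter, name, SMILES."""
    import io

    return load_smiles_table(io.StringIO(_load_text("canonical_amino_acids.tsv")))


def ncaa_table() -> pd.DataFrame:
    """The 25 most frequent non-canonical amino acids in the PDB."""
    import io

    return load_smiles_table(io.StringIO(_load_text("ncaa_frequent.tsv")))


def published_eisd_model() -> dict:
    """Published EISD840101 reference model, worked example and threshold scan."""
    return json.loads(_load_text("eisd840101_published_model.json"))


def eisd_values_synthetic() -> PropertyRecord:
    """Reconstructed stand-in for the EISD840101 AAindex record (synthetic)."""
    return parse_aaindex1(_load_text("eisd840101_values_synthetic.txt"))[0]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic property vector over the canonical design."""

    support: tuple[str, ...]
    beta: tuple[float, ...]
    constant: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.support) != len(self.beta):
            raise ValueError("support and beta must have equal length")
        unknown = set(self.support) - set(COMPONENT_KEYS)
        if unknown:
            raise ValueError(f"unknown component keys in support: {sorted(unknown)}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def generate_property(spec: SyntheticSpec, X: pd.DataFrame) -> pd.Series:
    """Draw ``y = X_support · beta + constant + N(0, noise_sd)``, seeded."""
    missing = set(spec.support) - set(map(str, X.columns))
    if missing:
        raise ValueError(f"support keys absent from design matrix: {sorted(missing)}")
    rng = np.random.default_rng(spec.seed)
    y = X[list(spec.support)].to_numpy(dtype=float) @ np.asarray(spec.beta, dtype=float)
    y = y + spec.constant
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=len(y))
    return pd.Series(y, index=X.index, name="synthetic")


def well_conditioned_supports(
    X: pd.DataFrame, max_size: int = 3, cond_max: float = 100.0,
    loo_safe: bool = True,
) -> list[tuple[str, ...]]:
    """Column subsets whose intercept-augmented submatrix is well conditioned.

    With ``loo_safe`` (default), columns that become constant when any single
    row is removed — near-indicator columns such as a component present in
    only one amino acid — are excluded: no method can predict the held-out
    row of such a column, so they would make leave-one-out recovery fail for
    reasons unrelated to correctness.
    """
    from itertools import combinations

    all_varying = [c for c in X.columns if X[c].nunique() > 1]
    cols = list(all_varying)
    if loo_safe:
        cols = [
            c for c in cols
            if (X[c] != X[c].mode().iloc[0]).sum() >= 2
        ]
    out: list[tuple[str, ...]] = []
    n = len(X)
    ones = np.ones((n, 1))
    Xv = X.to_numpy(dtype=float)
    pos = {c: i for i, c in enumerate(X.columns)}
    for size in range(1, max_size + 1):
        for combo in combinations(cols, size):
            A = np.hstack([ones, X[list(combo)].to_numpy(dtype=float)])
            if np.linalg.matrix_rank(A) < size + 1:
                continue
            if np.linalg.cond(A) >= cond_max:
                continue
            # identifiability: no outside column may lie in span(1, support)
            # (on this design e.g. dbl = dblO + dblN exactly, so supports
            # mixing those columns admit several exact representations)
            ambiguous = False
            for c in all_varying:
                if c in combo:
                    continue
                target = Xv[:, pos[c]]
                resid = target - A @ np.linalg.lstsq(A, target, rcond=None)[0]
                if float(resid @ resid) <= 1e-18 * max(float(target @ target), 1.0):
                    ambiguous = True
                    break
            if not ambiguous:
                out.append(tuple(combo))
    return out


def selftest(verbose: bool = True) -> bool:
    """Run the 4-hydroxyproline worked example and a noiseless recovery check."""
    from .aaindex import build_design_matrix
    from .components import count_components
    from .database import predict_value
    from .selection import TrainedModel, optimize_threshold
    from .stepwise import stepwise_select

    ok = True
    ref = published_eisd_model()
    hyp = ref["hyp_worked_example"]
    counts = count_components(hyp["smiles"])
    if counts != {k: int(v) for k, v in hyp["components"].items()}:
        ok = False
        _report(verbose, "FAIL", "HYP component counts differ from reference")
    else:
        _report(verbose, "ok", f"HYP component vector reproduced ({counts})")

    model = TrainedModel(
        accession=ref["accession"],
        selected=tuple(ref["selected"]),
        b={k: ref["coefficients"][k] for k in ref["selected"]},
        constant=ref["constant"],
        f_star=ref["f_star"],
        r_jn=ref["r_jn"],
        r_insample=ref["r_insample"],
        p_num=ref["p_num"],
        rmse=ref["rmse"],
        n_used=20,
    )
    value = predict_value(model, counts)
    if abs(value - hyp["predicted_value"]) > 5e-6:
        ok = False
        _report(verbose, "FAIL", f"HYP prediction {value} != {hyp['predicted_value']}")
    else:
        _report(
            verbose,
            "ok",
            f"EISD840101(HYP) = {value:.5f} ({value:.3f} ± {model.rmse:.3f})",
        )

    X = build_design_matrix(canonical_table())
    spec = SyntheticSpec(("anyO", "aliphC", "plus"), (1.5, -0.8, 2.0), 0.3)
    y = generate_property(spec, X)
    fit = stepwise_select(X, y, 2.0)
    recovered = set(fit.selected) == set(spec.support)
    coef_ok = recovered and all(
        abs(fit.coef_dict()[k] - b) < 1e-8 for k, b in zip(spec.support, spec.beta)
    )
    trained, _ = optimize_threshold(X, y, grid=[1.0, 2.0, 4.0])
    loo_ok = trained.r_jn > 1 - 1e-9 and trained.rmse < 1e-6
    if not (coef_ok and loo_ok):
        ok = False
        _report(verbose, "FAIL", "noiseless synthetic property not recovered")
    else:
        _report(verbose, "ok", "noiseless synthetic property recovered exactly (r_jn = 1)")
    return ok


def _report(verbose: bool, status: str, message: str) -> None:
    if verbose:
        print(f"[{status}] {message}")
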