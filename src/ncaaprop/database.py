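"""Applying trained property models to non-canonical amino acids.

A trained model predicts a property as the dot product of its coefficients
with the molecule's component counts plus the constant term.  The model's
stored RMSE (over the canonical training set) is attached to every
prediction as its ± uncertainty.  Molecules containing elements absent from
the canonical amino acids (As, B, Br, Cl, F, I, P, Se) are outside the
training domain and are excluded before prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .components import (
    EXCLUDED_ELEMENTS,
    SmilesError,
    count_components,
    element_report,
)
from .selection import TrainedModel

__all__ = [
    "NcaaRecord",
    "predict_value",
    "predict_with_error",
    "build_database",
    "database_frame",
    "write_long_tsv",
    "write_wide_tsv",
]


@dataclass
class NcaaRecord:
    """One non-canonical amino acid with its per-property predictions.

    ``predictions`` maps accession to ``(value, rmse, r_jn)`` and is
    populated only when ``kept`` is true (element filter passed and the
    SMILES parsed).
    """

    code: str
    name: str
    smiles: str
    kept: bool
    offending: frozenset[str] = field(default_factory=frozenset)
    failed: bool = False
    error: str = ""
    predictions: dict[str, tuple[float, float, float]] = field(default_factory=dict)


def predict_value(model: TrainedModel, cv: Mapping[str, int]) -> float:
    """Σ b_k · cv_k over the model's selected components, plus the constant."""
    try:
        return float(sum(model.b[k] * cv[k] for k in model.selected) + model.constant)
    except KeyError as exc:
        raise KeyError(
            f"component {exc.args[0]!r} required by model {model.accession} "
            "is missing from the component vector (schema mismatch)"
        ) from None


def predict_with_error(model: TrainedModel, cv: Mapping[str, int]) -> tuple[float, float]:
    """Predicted value paired with the model's stored RMSE."""
    return predict_value(model, cv), model.rmse


def build_database(
    models: Sequence[TrainedModel],
    table: pd.DataFrame,
    min_rjn: float | None = None,
    excluded: frozenset[str] = EXCLUDED_ELEMENTS,
) -> list[NcaaRecord]:
    """Predict every model's property for every admissible table entry.

    The element filter runs first; excluded entries carry their offending
    elements and get no predictions.  Unparseable SMILES mark the record
    ``failed`` and the run continues.  ``min_rjn`` optionally suppresses
    predictions from models whose LOO correlation falls below the gate.
    Output is deterministic and order-stable.
    """
    use_models = [
        m for m in models if min_rjn is None or (m.r_jn == m.r_jn and m.r_jn >= min_rjn)
    ]
    records: list[NcaaRecord] = []
    for row in table.itertuples(index=False):
        code, name, smiles = str(row.code), str(row.name), str(row.smiles)
        try:
            report = element_report(smiles, excluded)
        except SmilesError as exc:
            records.append(
                NcaaRecord(code, name, smiles, kept=False, failed=True, error=str(exc))
            )
            continue
        if report.excluded_hit:
            records.append(
                NcaaRecord(code, name, smiles, kept=False, offending=report.offending)
            )
            continue
        cv = count_components(smiles)
        rec = NcaaRecord(code, name, smiles, kept=True)
        for m in use_models:
            value, err = predict_with_error(m, cv)
            rec.predictions[m.accession] = (value, err, m.r_jn)
        records.append(rec)
    return records


def database_frame(records: Sequence[NcaaRecord]) -> pd.DataFrame:
    """Long-format table: one row per (ncAA, accession) prediction."""
    rows = [
        {
            "code": rec.code,
            "accession": acc,
            "value": value,
            "rmse": err,
            "r_jn": r_jn,
        }
        for rec in records
        if rec.kept
        for acc, (value, err, r_jn) in rec.predictions.items()
    ]
    return pd.DataFrame(rows, columns=["code", "accession", "value", "rmse", "r_jn"])


def write_long_tsv(records: Sequence[NcaaRecord], path: str | Path) -> None:
    database_frame(records).to_csv(path, sep="\t", index=False)


def write_wide_tsv(records: Sequence[NcaaRecord], path: str | Path) -> None:
    """Wide layout for browsing: ncAA rows, one column per accession."""
    frame = database_frame(records)
    wide = frame.pivot(index="code", columns="accession", values="value")
    wide.to_csv(path, sep="\t")
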