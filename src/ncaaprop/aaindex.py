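"""AAindex1 parsing, SMILES tables, the design matrix, and the model store.

AAindex1 is a flat-file database of per-amino-acid numeric scales: records
are separated by ``//``, the accession sits on the ``H`` line, the free-text
description on ``D`` lines, and the twenty values follow the ``I`` line in
two rows of ten, ordered A R N D C Q E G H I / L K M F P S T W Y V, with the
literal token ``NA`` marking missing values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import pandas as pd

from .components import COMPONENT_KEYS, count_components, tokenize, SmilesError

__all__ = [
    "AAINDEX_ORDER",
    "AAindexFormatError",
    "PropertyRecord",
    "parse_aaindex1",
    "format_aaindex1",
    "load_smiles_table",
    "build_design_matrix",
    "save_models",
    "load_models",
    "MODEL_STORE_VERSION",
]

#: The twenty 1-letter codes in AAindex value order.
AAINDEX_ORDER: str = "ARNDCQEGHILKMFPSTWYV"

MODEL_STORE_VERSION = 1


class AAindexFormatError(ValueError):
    pass


@dataclass
class PropertyRecord:
    """One AAindex1 property: accession, description, 20 values with NA mask.

    ``values`` maps 1-letter amino-acid codes to floats (NaN where masked);
    ``raw`` keeps the original decimal strings so a parsed file can be
    re-emitted without reformatting the numbers.
    """

    accession: str
    description: str = ""
    values: dict[str, float] = field(default_factory=dict)
    na_mask: dict[str, bool] = field(default_factory=dict)
    raw: dict[str, str] = field(default_factory=dict)

    def available(self) -> list[str]:
        """1-letter codes with a usable (non-NA) value, in AAindex order."""
        return [aa for aa in AAINDEX_ORDER if not self.na_mask.get(aa, True)]

    def series(self) -> pd.Series:
        return pd.Series({aa: self.values[aa] for aa in AAINDEX_ORDER})


def _read_text(source: str | Path | IO[str]) -> str:
    if hasattr(source, "read"):
        return source.read()
    path = Path(source)
    if path.exists():
        return path.read_text()
    if isinstance(source, str) and "\n" in source:
        return source
    raise FileNotFoundError(source)


def _parse_i_header(line: str, record_index: int) -> list[tuple[str, str]]:
    pairs = []
    for tok in line.split()[1:]:
        if "/" not in tok:
            raise AAindexFormatError(
                f"record {record_index}: malformed I-line header token {tok!r}"
            )
        a, b = tok.split("/")
        pairs.append((a.strip(), b.strip()))
    if len(pairs) != 10:
        raise AAindexFormatError(
            f"record {record_index}: I-line header must define 10 column pairs"
        )
    return pairs


def parse_aaindex1(source: str | Path | IO[str]) -> list[PropertyRecord]:
    """Parse an AAindex1 flat file into a list of :class:`PropertyRecord`.

    ``source`` may be a path, an open text stream, or the file content
    itself.  Record order is preserved.  A record without an ``H`` or ``I``
    line raises :class:`AAindexFormatError` naming the record index; a value
    token that is neither numeric nor ``NA`` raises ``ValueError``.
    """
    text = _read_text(source)
    records: list[PropertyRecord] = []
    chunks = [c for c in text.split("\n//") if c.strip()]
    for idx, chunk in enumerate(chunks):
        lines = [ln for ln in chunk.splitlines() if ln.strip()]
        accession = None
        description_parts: list[str] = []
        i_at = None
        for k, ln in enumerate(lines):
            tag = ln[:1]
            if tag == "H":
                accession = ln[1:].strip()
            elif tag == "D":
                description_parts.append(ln[1:].strip())
            elif tag == "I":
                i_at = k
                break
        if accession is None:
            raise AAindexFormatError(f"record {idx}: missing H line")
        if i_at is None:
            raise AAindexFormatError(f"record {idx}: missing I line")
        pairs = _parse_i_header(lines[i_at], idx)
        value_rows = lines[i_at + 1 : i_at + 3]
        if len(value_rows) < 2:
            raise AAindexFormatError(
                f"record {idx}: expected two value rows after the I line"
            )
        rec = PropertyRecord(accession, " ".join(description_parts))
        for row_idx, row in enumerate(value_rows):
            tokens = row.split()
            if len(tokens) != 10:
                raise AAindexFormatError(
                    f"record {idx}: value row {row_idx + 1} has "
                    f"{len(tokens)} tokens, expected 10"
                )
            for col, tok in enumerate(tokens):
                aa = pairs[col][row_idx]
                if tok == "NA":
                    rec.values[aa] = math.nan
                    rec.na_mask[aa] = True
                else:
                    try:
                        rec.values[aa] = float(tok)
                    except ValueError:
                        raise ValueError(
                            f"record {idx} ({accession}): bad value token "
                            f"{tok!r} for {aa}"
                        ) from None
                    rec.na_mask[aa] = False
                rec.raw[aa] = tok
        records.append(rec)
    return records


def format_aaindex1(records: Iterable[PropertyRecord]) -> str:
    """Re-emit records in AAindex1 layout, preserving original value strings."""
    out: list[str] = []
    header = "I    " + "     ".join(
        f"{AAINDEX_ORDER[i]}/{AAINDEX_ORDER[i + 10]}" for i in range(10)
    )
    for rec in records:
        out.append(f"H {rec.accession}")
        if rec.description:
            out.append(f"D {rec.description}")
        out.append(header)
        for row in (AAINDEX_ORDER[:10], AAINDEX_ORDER[10:]):
            toks = [rec.raw.get(aa, repr(rec.values[aa])) for aa in row]
            out.append("  " + "  ".join(f"{t:>8s}" for t in toks))
        out.append("//")
    return "\n".join(out) + "\n"


def load_smiles_table(source: str | Path | IO[str]) -> pd.DataFrame:
    """Load a TSV of amino acids (columns ``code``, ``name``, ``smiles``).

    An optional ``one_letter`` column links rows to AAindex slots; extra
    columns pass through.  Codes must be unique and every SMILES must
    tokenize; violations raise ``ValueError`` naming the code.
    """
    if hasattr(source, "read"):
        df = pd.read_csv(source, sep="\t", dtype=str)
    else:
        df = pd.read_csv(Path(source), sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("code", "name", "smiles"):
        if col not in df.columns:
            raise ValueError(f"SMILES table is missing required column {col!r}")
    dupes = df["code"][df["code"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate amino-acid codes: {sorted(set(dupes))}")
    for code, smi in zip(df["code"], df["smiles"]):
        if not isinstance(smi, str) or not smi.strip():
            raise ValueError(f"empty SMILES for code {code}")
        try:
            tokenize(smi)
        except SmilesError as exc:
            raise ValueError(f"SMILES for code {code} does not parse: {exc}") from exc
    return df.reset_index(drop=True)


def build_design_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Component-count matrix: one row per amino acid, 13 fixed columns.

    Rows follow table order and are indexed by ``code``; columns follow the
    canonical component order.  Idempotent and order-stable.
    """
    rows = {code: count_components(smi) for code, smi in zip(table["code"], table["smiles"])}
    X = pd.DataFrame.from_dict(rows, orient="index")
    X.index.name = "code"
    return X[list(COMPONENT_KEYS)].astype(int)


def _model_to_dict(model) -> dict:
    d = model.to_dict() if hasattr(model, "to_dict") else dict(model)
    unknown = set(d.get("selected", ())) - set(COMPONENT_KEYS)
    if unknown:
        raise ValueError(f"model {d.get('accession')}: unknown component keys {sorted(unknown)}")
    return d


def save_models(models: Sequence, path: str | Path, metadata: dict | None = None) -> None:
    """Write trained models to a versioned JSON store."""
    doc = {
        "format": "ncaaprop-models",
        "version": MODEL_STORE_VERSION,
        "metadata": metadata or {},
        "models": [_model_to_dict(m) for m in models],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def load_models(path: str | Path) -> list:
    """Load a model store written by :func:`save_models`.

    Raises ``ValueError`` on a schema-version mismatch or on component keys
    outside the canonical 13.
    """
    from .selection import TrainedModel

    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "ncaaprop-models":
        raise ValueError("not an ncaaprop model store")
    if doc.get("version") != MODEL_STORE_VERSION:
        raise ValueError(
            f"model store version {doc.get('version')!r} is not supported "
            f"(expected {MODEL_STORE_VERSION})"
        )
    models = []
    for d in doc["models"]:
        unknown = (set(d.get("selected", ())) | set(d.get("b", {}))) - set(COMPONENT_KEYS)
        if unknown:
            raise ValueError(
                f"model {d.get('accession')}: unknown component keys {sorted(unknown)}"
            )
        models.append(TrainedModel.from_dict(d))
    return models


def training_xy(
    record: PropertyRecord, table: pd.DataFrame, X: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Align a property record with a canonical SMILES table.

    Returns the design-matrix rows and property values for amino acids that
    are present in the table (via its ``one_letter`` column) and not masked
    NA in the record, plus the list of 1-letter codes that were dropped.
    """
    if "one_letter" not in table.columns:
        raise ValueError("canonical table needs a one_letter column for training")
    if X is None:
        X = build_design_matrix(table)
    by_letter = dict(zip(table["one_letter"], table["code"]))
    keep_letters = [aa for aa in AAINDEX_ORDER if aa in by_letter and not record.na_mask.get(aa, True)]
    dropped = [aa for aa in AAINDEX_ORDER if aa not in keep_letters]
    codes = [by_letter[aa] for aa in keep_letters]
    y = pd.Series([record.values[aa] for aa in keep_letters], index=codes, name=record.accession)
    return X.loc[codes], y, dropped
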