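"""SMILES tokenization and substring-component counting.

The feature set used throughout this package is a vector of 13 small integer
counts read off a SMILES string: oxygen/nitrogen/carbon/sulfur occurrences
(split by aromaticity), chiral centres, double bonds, ring-closure openings
and positive charges.  The counts are defined *on the string as distributed*
(case-sensitive, literal pattern counting) — deliberately not on a perceived
molecular graph — because the regression models downstream were trained on
exactly these literal counts.  No canonicalization or aromaticity perception
is performed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

__all__ = [
    "COMPONENT_KEYS",
    "COMPONENT_LABELS",
    "EXCLUDED_ELEMENTS",
    "SmilesError",
    "Token",
    "ElementReport",
    "tokenize",
    "count_components",
    "element_report",
    "contains_excluded_element",
]

logger = logging.getLogger(__name__)

#: The 13 component keys, in canonical column order.
COMPONENT_KEYS: tuple[str, ...] = (
    "dblO", "anyO", "aliphN", "aromN", "dblN", "aliphC", "aromC",
    "chiralC", "S", "ring1", "ring2", "dbl", "plus",
)

#: Human-readable SMILES pattern label for each component key.
COMPONENT_LABELS: dict[str, str] = {
    "dblO": "=O",
    "anyO": "O",
    "aliphN": "N",
    "aromN": "n",
    "dblN": "=N",
    "aliphC": "C",
    "aromC": "c",
    "chiralC": "[C@",
    "S": "S",
    "ring1": "C1",
    "ring2": "C2",
    "dbl": "=",
    "plus": "+",
}

#: Elements absent from the canonical amino acids.  Molecules containing any
#: of these are outside the training domain of the property models.
EXCLUDED_ELEMENTS: frozenset[str] = frozenset(
    {"As", "B", "Br", "Cl", "F", "I", "P", "Se"}
)

# Element symbols accepted inside bracket atoms.  Wider than the organic
# subset so that arbitrary PDBeChem entries tokenize; the element filter is a
# separate, later step.
_BRACKET_ELEMENTS = {
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne", "Na", "Mg", "Al",
    "Si", "P", "S", "Cl", "Ar", "K", "Ca", "Cr", "Mn", "Fe", "Co", "Ni",
    "Cu", "Zn", "Ga", "Ge", "As", "Se", "Br", "Kr", "Mo", "Ru", "Pd", "Ag",
    "Cd", "Sn", "Sb", "Te", "I", "Xe", "W", "Pt", "Au", "Hg", "Pb", "Bi",
    # aromatic lowercase forms
    "b", "c", "n", "o", "p", "s", "se", "as",
}

_ORGANIC_TWO_LETTER = ("Cl", "Br")
_ORGANIC_ONE_LETTER = set("BCNOPSFI") | set("bcnops")
_BOND_CHARS = set("-=#$:/\\")

_BRACKET_RE = re.compile(
    r"^(?P<isotope>\d*)"
    r"(?P<element>[A-Z][a-z]?|as|se|[bcnops])"
    r"(?P<tail>[^\[\]]*)$"
)


class SmilesError(ValueError):
    """Malformed SMILES input; carries the 0-based offending position."""

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (position {position})"
        super().__init__(message)
        self.position = position


@dataclass(frozen=True)
class Token:
    """One lexical unit of a SMILES string.

    ``kind`` is one of ``atom``, ``bond``, ``ring``, ``branch_open``,
    ``branch_close``, ``dot``.  Atom tokens carry the parsed ``element``
    symbol (aromatic atoms keep their lowercase spelling).
    """

    kind: str
    text: str
    pos: int
    element: str | None = None


@dataclass(frozen=True)
class ElementReport:
    """Elements present in a SMILES string and whether any is out-of-domain."""

    elements: frozenset[str]
    offending: frozenset[str] = field(default_factory=frozenset)

    @property
    def excluded_hit(self) -> bool:
        return bool(self.offending)


def _normalize_element(symbol: str) -> str:
    """Map an element spelling to its standard symbol ('se' -> 'Se')."""
    return symbol if symbol[0].isupper() else symbol.capitalize()


def tokenize(smiles: str) -> list[Token]:
    """Split a SMILES string into atom / bond / ring / branch tokens.

    Concatenating the token texts reproduces the input exactly.  Raises
    :class:`SmilesError` for unbalanced brackets or parentheses, dangling
    bonds, unknown characters, or ring-closure digits left unpaired.
    """
    if not isinstance(smiles, str) or smiles == "":
        raise SmilesError("empty SMILES string", 0)

    tokens: list[Token] = []
    depth_stack: list[int] = []
    ring_counts: dict[str, int] = {}
    ring_last_pos: dict[str, int] = {}
    i = 0
    n = len(smiles)
    while i < n:
        ch = smiles[i]
        if ch == "[":
            j = smiles.find("]", i + 1)
            if j < 0:
                raise SmilesError("unclosed bracket atom", i)
            body = smiles[i + 1 : j]
            m = _BRACKET_RE.match(body)
            if not m or m.group("element") not in _BRACKET_ELEMENTS:
                raise SmilesError(f"cannot parse bracket atom [{body}]", i)
            tokens.append(
                Token("atom", smiles[i : j + 1], i, m.group("element"))
            )
            i = j + 1
        elif ch == "]":
            raise SmilesError("unmatched ']'", i)
        elif smiles[i : i + 2] in _ORGANIC_TWO_LETTER:
            tokens.append(Token("atom", smiles[i : i + 2], i, smiles[i : i + 2]))
            i += 2
        elif ch in _ORGANIC_ONE_LETTER:
            tokens.append(Token("atom", ch, i, ch))
            i += 1
        elif ch in _BOND_CHARS:
            tokens.append(Token("bond", ch, i))
            i += 1
        elif ch.isdigit():
            tokens.append(Token("ring", ch, i))
            ring_counts[ch] = ring_counts.get(ch, 0) + 1
            ring_last_pos[ch] = i
            i += 1
        elif ch == "%":
            if i + 2 >= n or not smiles[i + 1 : i + 3].isdigit():
                raise SmilesError("'%' must introduce a two-digit ring closure", i)
            label = smiles[i : i + 3]
            tokens.append(Token("ring", label, i))
            ring_counts[label] = ring_counts.get(label, 0) + 1
            ring_last_pos[label] = i
            i += 3
        elif ch == "(":
            depth_stack.append(i)
            tokens.append(Token("branch_open", ch, i))
            i += 1
        elif ch == ")":
            if not depth_stack:
                raise SmilesError("unmatched ')'", i)
            depth_stack.pop()
            tokens.append(Token("branch_close", ch, i))
            i += 1
        elif ch == ".":
            tokens.append(Token("dot", ch, i))
            i += 1
        else:
            raise SmilesError(f"unexpected character {ch!r}", i)

    if depth_stack:
        raise SmilesError("unmatched '('", depth_stack[-1])
    if tokens[-1].kind == "bond":
        raise SmilesError("dangling bond at end of string", tokens[-1].pos)
    for label, count in ring_counts.items():
        if count % 2:
            raise SmilesError(
                f"ring closure {label!r} appears an odd number of times",
                ring_last_pos[label],
            )
    return tokens


def count_components(smiles: str) -> dict[str, int]:
    """Count the 13 string components of a SMILES string.

    Counting is case-sensitive and literal.  Single-letter atom components
    (O, N, n, C, c, S) count atom tokens with that exact symbol, so the 'C'
    of a two-letter element such as 'Cl' never contributes; bracketed atoms
    ([C@@H], [NH3+], [nH]) contribute like bare ones.  Pattern components
    are raw substring counts: ``dblO`` = "=O" + "O="; ``dblN`` = "=N" + "N="
    + "=[N"; ``chiralC`` = "[C@"; ``ring1``/``ring2`` = an atom letter in
    {c, C, n, N, S} immediately followed by the digit 1 / 2; ``dbl`` = "=";
    ``plus`` = "+".  Components intentionally overlap (every "=O" is also an
    "O"; every chiral carbon is also a "C").

    Ring closures with digits >= 3 or '%nn' labels have no component and are
    only logged at debug level.
    """
    tokens = tokenize(smiles)

    symbol_counts: dict[str, int] = {}
    for t in tokens:
        if t.kind == "atom":
            symbol_counts[t.element] = symbol_counts.get(t.element, 0) + 1
        elif t.kind == "ring" and (len(t.text) > 1 or t.text not in "12"):
            logger.debug(
                "ring closure %r in %r has no component column", t.text, smiles
            )

    counts = {
        "dblO": smiles.count("=O") + smiles.count("O="),
        "anyO": symbol_counts.get("O", 0),
        "aliphN": symbol_counts.get("N", 0),
        "aromN": symbol_counts.get("n", 0),
        "dblN": smiles.count("=N") + smiles.count("N=") + smiles.count("=[N"),
        "aliphC": symbol_counts.get("C", 0),
        "aromC": symbol_counts.get("c", 0),
        "chiralC": smiles.count("[C@"),
        "S": symbol_counts.get("S", 0),
        "ring1": len(re.findall(r"[cCnNS]1", smiles)),
        "ring2": len(re.findall(r"[cCnNS]2", smiles)),
        "dbl": smiles.count("="),
        "plus": smiles.count("+"),
    }
    return counts


def element_report(
    smiles: str, excluded: frozenset[str] | set[str] = EXCLUDED_ELEMENTS
) -> ElementReport:
    """List the elements in a SMILES string and flag out-of-domain ones.

    Matching is by parsed element symbol, never raw substring: "CSC" contains
    no selenium, "C[Se]C" does; chlorine in "CCl" does not hide behind the
    carbon component.
    """
    elements = frozenset(
        _normalize_element(t.element) for t in tokenize(smiles) if t.kind == "atom"
    )
    return ElementReport(elements, elements & frozenset(excluded))


def contains_excluded_element(
    smiles: str, excluded: frozenset[str] | set[str] = EXCLUDED_ELEMENTS
) -> bool:
    """True iff any atom in ``smiles`` is an element from ``excluded``."""
    return element_report(smiles, excluded).excluded_hit
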