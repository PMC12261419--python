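"""Boolean AND/OR formulas over marker-profile identifiers.

A coarse-grained metabolic function (methanogenesis, sulfate reduction,
...) is called for a taxon when its Boolean formula over marker-enzyme
profiles evaluates true on the set of profiles detected in the taxon's
consensus proteome.  Grammar::

    expr   := term (OR term)*
    term   := factor (AND factor)*
    factor := IDENT | "(" expr ")"

AND binds tighter than OR; identifiers match ``[A-Za-z0-9_./-]+``.
There is deliberately no NOT operator: functions are monotone in the
presence set (an extension point, not an omission).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence, Set, Union

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Leaf",
    "And",
    "Or",
    "RuleFormula",
    "FunctionDefinition",
    "FormulaError",
    "parse_formula",
    "format_formula",
    "evaluate_formula",
    "formula_leaves",
    "load_definitions",
    "default_definitions",
    "call_functions",
    "write_presence_matrix",
]

CYCLES = ("carbon", "nitrogen", "sulfur", "other")


@dataclass(frozen=True)
class Leaf:
    name: str


@dataclass(frozen=True)
class And:
    children: tuple["RuleFormula", ...]


@dataclass(frozen=True)
class Or:
    children: tuple["RuleFormula", ...]


RuleFormula = Union[Leaf, And, Or]


class FormulaError(ValueError):
    """Raised on malformed formula text, with the offending position."""


@dataclass(frozen=True)
class FunctionDefinition:
    function_name: str
    cycle: str
    formula: RuleFormula


_TOKEN = re.compile(r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<word>[A-Za-z0-9_./-]+))")


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise FormulaError(f"unexpected character {text[pos]!r} at position {pos}")
            break
        pos = m.end()
        if m.lastgroup == "lpar":
            tokens.append(("(", "(", m.start()))
        elif m.lastgroup == "rpar":
            tokens.append((")", ")", m.start()))
        else:
            word = m.group("word")
            kind = word if word in ("AND", "OR") else "IDENT"
            tokens.append((kind, word, m.start("word")))
    return tokens


def parse_formula(text: str) -> RuleFormula:
    tokens = _tokenize(text)
    if not tokens:
        raise FormulaError("empty formula")
    pos = 0

    def peek() -> tuple[str, str, int] | None:
        return tokens[pos] if pos < len(tokens) else None

    def expect_factor() -> RuleFormula:
        nonlocal pos
        tok = peek()
        if tok is None:
            raise FormulaError(f"dangling operator at position {tokens[-1][2]}")
        kind, word, at = tok
        if kind == "IDENT":
            pos += 1
            return Leaf(word)
        if kind == "(":
            pos += 1
            inner = expr()
            closing = peek()
            if closing is None or closing[0] != ")":
                raise FormulaError(f"unbalanced parenthesis opened at position {at}")
            pos += 1
            return inner
        raise FormulaError(f"unexpected token {word!r} at position {at}")

    def term() -> RuleFormula:
        nonlocal pos
        parts = [expect_factor()]
        while (tok := peek()) is not None and tok[0] == "AND":
            pos += 1
            parts.append(expect_factor())
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def expr() -> RuleFormula:
        nonlocal pos
        parts = [term()]
        while (tok := peek()) is not None and tok[0] == "OR":
            pos += 1
            parts.append(term())
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    result = expr()
    leftover = peek()
    if leftover is not None:
        raise FormulaError(f"unexpected token {leftover[1]!r} at position {leftover[2]}")
    return result


def format_formula(formula: RuleFormula, _parent: str = "") -> str:
    if isinstance(formula, Leaf):
        return formula.name
    if isinstance(formula, And):
        body = " AND ".join(format_formula(c, "AND") for c in formula.children)
        return f"({body})" if _parent == "AND" else body
    body = " OR ".join(format_formula(c, "OR") for c in formula.children)
    return f"({body})" if _parent else body


def evaluate_formula(formula: RuleFormula, present: Set[str]) -> bool:
    if isinstance(formula, Leaf):
        return formula.name in present
    if isinstance(formula, And):
        return all(evaluate_formula(c, present) for c in formula.children)
    return any(evaluate_formula(c, present) for c in formula.children)


def formula_leaves(formula: RuleFormula) -> set[str]:
    if isinstance(formula, Leaf):
        return {formula.name}
    out: set[str] = set()
    for child in formula.children:
        out |= formula_leaves(child)
    return out


# ---------------------------------------------------------------------------
# Definition sets
# ---------------------------------------------------------------------------

def load_definitions(path: str | Path) -> list[FunctionDefinition]:
    """Load a TSV rule file with columns function_name, cycle, formula."""
    definitions: list[FunctionDefinition] = []
    seen: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#") or line.startswith("function_name\t"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormulaError(f"{path}: line {lineno}: expected 3 columns")
        name, cycle, text = fields[0], fields[1], fields[2]
        if name in seen:
            raise FormulaError(f"{path}: line {lineno}: duplicate function {name!r}")
        seen.add(name)
        if cycle not in CYCLES:
            raise FormulaError(f"{path}: line {lineno}: unknown cycle {cycle!r}")
        definitions.append(
            FunctionDefinition(function_name=name, cycle=cycle, formula=parse_formula(text))
        )
    return definitions


def default_definitions() -> list[FunctionDefinition]:
    """The packaged coarse-grained function set (editable TSV data)."""
    ref = resources.files("taxocycle.data").joinpath("function_rules.tsv")
    with resources.as_file(ref) as path:
        return load_definitions(path)


def call_functions(
    presence_sets: Mapping[str, Set[str]],
    definitions: Sequence[FunctionDefinition],
    known_profiles: Set[str] | None = None,
) -> pd.DataFrame:
    """Evaluate every function formula on every taxon's presence set.

    Returns a boolean DataFrame (rows = taxa/observations in sorted
    order, columns = functions in definition order).  Identifiers absent
    from ``known_profiles`` (the HMM collection actually searched) are
    warned about once and evaluate false.
    """
    if known_profiles is not None:
        unknown: set[str] = set()
        for d in definitions:
            unknown |= formula_leaves(d.formula) - set(known_profiles)
        for ident in sorted(unknown):
            logger.warning(
                "formula identifier %r has no profile in the searched collection; "
                "it evaluates false", ident,
            )
    taxa = sorted(presence_sets)
    columns = [d.function_name for d in definitions]
    data = {
        d.function_name: [evaluate_formula(d.formula, presence_sets[t]) for t in taxa]
        for d in definitions
    }
    return pd.DataFrame(data, index=pd.Index(taxa, name="observation"), columns=columns)


def write_presence_matrix(matrix: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    matrix.astype(int).to_csv(path, sep="\t")
    return path
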