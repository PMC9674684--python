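"""Minimal atom-selection mini-language.

Grammar (whitespace-tokenised, case-sensitive values)::

    expr   := term ("or" term)*
    term   := clause ("and" clause)*
    clause := "all"
            | ("name" | "resname" | "chain") VALUE+
            | "resid" RANGE+          # RANGE is N or N-M (inclusive)

``and`` binds tighter than ``or``.  A clause with several values matches any
of them, e.g. ``name S OW`` selects atoms named S or OW, and
``resname ARG and name NH1 NH2`` the guanidinium nitrogens of arginines.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import SelectionError

_FIELD_KEYWORDS = {"name", "resname", "chain", "resid"}
_OPERATORS = {"and", "or"}


def _parse_resid_token(tok: str) -> tuple[int, int]:
    body = tok
    # allow N, N-M and N:M; a leading '-' would be a negative resid, which the
    # formats we read never produce, so '-' is always a range separator here
    for sep in ("-", ":"):
        if sep in body:
            lo, hi = body.split(sep, 1)
            try:
                return int(lo), int(hi)
            except ValueError as exc:
                raise SelectionError(f"bad resid range {tok!r}") from exc
    try:
        v = int(body)
    except ValueError as exc:
        raise SelectionError(f"bad resid {tok!r}") from exc
    return v, v


class _Parser:
    def __init__(self, tokens: list[str], atoms: pd.DataFrame):
        self.toks = tokens
        self.pos = 0
        self.atoms = atoms

    def peek(self):
        return self.toks[self.pos] if self.pos < len(self.toks) else None

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse_expr(self) -> np.ndarray:
        mask = self.parse_term()
        while self.peek() == "or":
            self.next()
            mask = mask | self.parse_term()
        return mask

    def parse_term(self) -> np.ndarray:
        mask = self.parse_clause()
        while self.peek() == "and":
            self.next()
            mask = mask & self.parse_clause()
        return mask

    def parse_clause(self) -> np.ndarray:
        kw = self.next()
        if kw is None:
            raise SelectionError("unexpected end of selection expression")
        n = len(self.atoms)
        if kw == "all":
            return np.ones(n, dtype=bool)
        if kw not in _FIELD_KEYWORDS:
            raise SelectionError(f"unknown selection keyword {kw!r}")
        values = []
        while self.peek() is not None and self.peek() not in _OPERATORS:
            values.append(self.next())
        if not values:
            raise SelectionError(f"keyword {kw!r} needs at least one value")
        if kw == "resid":
            mask = np.zeros(n, dtype=bool)
            resids = self.atoms["resid"].to_numpy()
            for tok in values:
                lo, hi = _parse_resid_token(tok)
                mask |= (resids >= lo) & (resids <= hi)
            return mask
        column = self.atoms[kw].astype(str).to_numpy()
        return np.isin(column, values)


def select_mask(atoms: pd.DataFrame, expression: str) -> np.ndarray:
    """Boolean mask over the atom table for a selection expression."""
    tokens = expression.split()
    if not tokens:
        raise SelectionError("empty selection expression")
    parser = _Parser(tokens, atoms)
    mask = parser.parse_expr()
    if parser.pos != len(tokens):
        raise SelectionError(
            f"trailing tokens in selection: {' '.join(tokens[parser.pos:])!r}"
        )
    return mask


def select_indices(atoms: pd.DataFrame, expression: str) -> np.ndarray:
    """Atom indices matching a selection; error if the result is empty."""
    idx = np.flatnonzero(select_mask(atoms, expression))
    if idx.size == 0:
        raise SelectionError(f"selection {expression!r} matched no atoms")
    return idx
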