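"""Lipid selections: conjunctions of conditions over type and metrics.

Grammar (AND-only; OR is expressed as multiple queries unioned by the
caller)::

    query     := condition ("and" condition)*
    condition := field op literal
    field     := "resname" | "leaflet" | "apl" | "thickness"
               | "neighbor_count[" RESNAME "]"
    op        := "==" | "!=" | "<" | "<=" | ">" | ">=" | "in"
    literal   := number | word | "(" word ("," word)* ")"

Examples: ``resname == DPPC and apl > 0.6``, ``thickness >= 3.5``,
``neighbor_count[DPPC] >= 4``, ``resname in (DPPC, DOPC)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .metrics import FrameMetrics

NUMERIC_FIELDS = ("apl", "thickness")
STRING_FIELDS = ("resname", "leaflet")
NUMERIC_OPS = ("<", "<=", ">", ">=", "==", "!=")
STRING_OPS = ("==", "!=", "in")


class SelectionError(Exception):
    pass


class SelectionSyntaxError(SelectionError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at character {position})")
        self.position = position


@dataclass(frozen=True)
class Condition:
    field: str  # "resname", "leaflet", "apl", "thickness" or "neighbor_count"
    op: str
    value: object
    resname_arg: str | None = None  # for neighbor_count[RESNAME]


@dataclass(frozen=True)
class SelectionQuery:
    """AND-combination of conditions; built by :func:`parse_query`."""

    conditions: tuple[Condition, ...]


_TOKEN_RE = re.compile(
    r"\s*(?:"
    r"(?P<op><=|>=|==|!=|<|>)"
    r"|(?P<num>[-+]?\d+\.?\d*(?:[eE][-+]?\d+)?)"
    r"|(?P<word>[A-Za-z_]\w*)"
    r"|(?P<punct>[\[\](),])"
    r")"
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            raise SelectionSyntaxError(
                f"unexpected character {stripped[0]!r}",
                len(text) - len(stripped),
            )
        kind = m.lastgroup
        tokens.append((kind, m.group(kind), m.start(kind)))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def _peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def _next(self, expect_kind=None, expect_value=None):
        tok = self._peek()
        if tok is None:
            raise SelectionSyntaxError("unexpected end of query", len(self.text))
        kind, value, pos = tok
        if expect_kind and kind != expect_kind:
            raise SelectionSyntaxError(f"expected {expect_kind}, got {value!r}", pos)
        if expect_value and value != expect_value:
            raise SelectionSyntaxError(f"expected {expect_value!r}, got {value!r}", pos)
        self.i += 1
        return tok

    def parse(self) -> SelectionQuery:
        conditions = [self._condition()]
        while self._peek() is not None:
            kind, value, pos = self._peek()
            if kind == "word" and value == "and":
                self.i += 1
                conditions.append(self._condition())
            else:
                raise SelectionSyntaxError(f"expected 'and', got {value!r}", pos)
        return SelectionQuery(conditions=tuple(conditions))

    def _condition(self) -> Condition:
        kind, fname, pos = self._next(expect_kind="word")
        resname_arg = None
        if fname == "neighbor_count":
            self._next(expect_kind="punct", expect_value="[")
            _, resname_arg, _ = self._next(expect_kind="word")
            self._next(expect_kind="punct", expect_value="]")
        elif fname not in NUMERIC_FIELDS + STRING_FIELDS:
            raise SelectionSyntaxError(f"unknown field {fname!r}", pos)

        tok = self._peek()
        if tok is None:
            raise SelectionSyntaxError("expected operator", len(self.text))
        tkind, tval, tpos = tok
        if tkind == "op":
            op = tval
            self.i += 1
        elif tkind == "word" and tval == "in":
            op = "in"
            self.i += 1
        else:
            raise SelectionSyntaxError(f"expected operator, got {tval!r}", tpos)
        # reject chained operator characters like "apl >> 1"
        nxt = self._peek()
        if nxt is not None and nxt[0] == "op" and op != "in":
            raise SelectionSyntaxError(f"unexpected operator {nxt[1]!r}", nxt[2])

        numeric = fname in NUMERIC_FIELDS or fname == "neighbor_count"
        if op == "in":
            value = tuple(self._word_list())
        else:
            tok = self._next()
            vkind, vval, vpos = tok
            if numeric:
                if vkind != "num":
                    raise SelectionSyntaxError(
                        f"field {fname!r} needs a numeric literal, got {vval!r}", vpos
                    )
                value = float(vval)
            else:
                if vkind not in ("word", "num"):
                    raise SelectionSyntaxError(f"expected value, got {vval!r}", vpos)
                value = vval
        if numeric and op == "in":
            _, _, p = self.tokens[self.i - 1]
            raise SelectionSyntaxError(f"'in' not valid for numeric field {fname!r}", p)
        if not numeric and op not in STRING_OPS:
            _, _, p = self.tokens[self.i - 1]
            raise SelectionSyntaxError(
                f"operator {op!r} not valid for string field {fname!r}", p
            )
        return Condition(
            field="neighbor_count" if resname_arg is not None else fname,
            op=op,
            value=value,
            resname_arg=resname_arg,
        )

    def _word_list(self) -> list[str]:
        self._next(expect_kind="punct", expect_value="(")
        words = [self._next(expect_kind="word")[1]]
        while True:
            kind, value, pos = self._next(expect_kind="punct")
            if value == ")":
                return words
            if value != ",":
                raise SelectionSyntaxError(f"expected ',' or ')', got {value!r}", pos)
            words.append(self._next(expect_kind="word")[1])


def parse_query(text: str) -> SelectionQuery:
    """Parse a selection expression; raises :class:`SelectionSyntaxError`
    with the character position on malformed input."""
    if not text.strip():
        raise SelectionSyntaxError("empty query", 0)
    return _Parser(text).parse()


_OPS = {
    "==": lambda a, b: a == b,
    "!=": lambda a, b: a != b,
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
    "in": lambda a, b: a in b,
}


def _validate(query: SelectionQuery, valid_resnames: set[str]) -> None:
    for cond in query.conditions:
        names: list[str] = []
        if cond.resname_arg is not None:
            names.append(cond.resname_arg)
        if cond.field == "resname":
            names.extend(cond.value if isinstance(cond.value, tuple) else [cond.value])
        for nm in names:
            if nm not in valid_resnames:
                raise SelectionError(
                    f"unknown resname {nm!r}; known: {sorted(valid_resnames)}"
                )
        if cond.field == "leaflet":
            vals = cond.value if isinstance(cond.value, tuple) else [cond.value]
            for v in vals:
                if v not in ("upper", "lower"):
                    raise SelectionError(f"invalid leaflet {v!r}")


def evaluate_selection(
    metrics: FrameMetrics,
    query: SelectionQuery,
    valid_resnames: set[str] | None = None,
) -> set[int]:
    """Lipid ids of one frame satisfying every condition of the query.

    ``valid_resnames`` defaults to the resnames present in the frame; an
    unknown resname or field raises before any row is evaluated.
    """
    table = metrics.table
    if valid_resnames is None:
        valid_resnames = set(table["resname"])
    _validate(query, valid_resnames)

    selected: set[int] = set(int(i) for i in table.index)
    for cond in query.conditions:
        op = _OPS[cond.op]
        hits: set[int] = set()
        for lipid_id, row in table.iterrows():
            if cond.field == "neighbor_count":
                lhs: object = row["neighbors"].get(cond.resname_arg, 0)
            else:
                lhs = row[{"apl": "apl", "thickness": "thickness",
                           "resname": "resname", "leaflet": "leaflet"}[cond.field]]
            if op(lhs, cond.value):
                hits.add(int(lipid_id))
        selected &= hits
    return selected
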