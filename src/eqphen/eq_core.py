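"""Class-expression AST, relation vocabulary, and the textual expression grammar.

Phenotypes are described here as *class expressions*: anonymous classes built
from named ontology classes (CURIEs) with conjunction and existential
relational restrictions, in the conjunctive-existential (EL-style) fragment::

    expr     := conjunct ("and" conjunct)*
    conjunct := CURIE | RELATION "some" filler | "(" expr ")"
    filler   := CURIE | "(" expr ")"

A rendered expression looks like

    phenotype-of some (has-part some (GO:0005618 and has-quality some PATO:0000051))

which reads "a phenotype of something that has a cell wall as part, in which a
morphology quality inheres".  The relation vocabulary is fixed: ``phenotype-of``
links a phenotype to its bearer organism, ``has-part``/``part-of`` carry
mereology (with the usual chain has-part o part-of -> has-part), ``has-quality``
attaches a PATO quality, ``during`` a temporal stage, ``towards`` the second
argument of a relational quality, and the two ``*-in-magnitude-relative-to``
relations express comparative qualifiers against the reference quality
*normal* (PATO:0000461).  ``inheres_in`` belongs to OBO EQ definition blocks
only and never appears in a compiled expression.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Optional

__all__ = [
    "EqphenError",
    "ExpressionParseError",
    "ClassExpression",
    "Atom",
    "And",
    "Some",
    "EQDefinition",
    "render",
    "parse_expression",
    "canonicalize",
    "PHENOTYPE_OF",
    "HAS_PART",
    "PART_OF",
    "HAS_QUALITY",
    "DURING",
    "TOWARDS",
    "INHERES_IN",
    "INCREASED_IN_MAGNITUDE",
    "DECREASED_IN_MAGNITUDE",
    "EXPRESSION_RELATIONS",
    "TRANSITIVE_RELATIONS",
    "REFLEXIVE_RELATIONS",
    "RELATION_CHAINS",
    "NORMAL_QUALITY",
    "CURIE_RE",
    "is_curie",
]


class EqphenError(Exception):
    """Base class for all errors raised by this package."""


class ExpressionParseError(EqphenError):
    """Raised on malformed expression text; carries the character offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


# ---------------------------------------------------------------------------
# Relation vocabulary
# ---------------------------------------------------------------------------

PHENOTYPE_OF = "phenotype-of"
HAS_PART = "has-part"
PART_OF = "part-of"
HAS_QUALITY = "has-quality"
DURING = "during"
TOWARDS = "towards"
INHERES_IN = "inheres_in"
INCREASED_IN_MAGNITUDE = "increased-in-magnitude-relative-to"
DECREASED_IN_MAGNITUDE = "decreased-in-magnitude-relative-to"

#: Relations that may appear in compiled class expressions.
EXPRESSION_RELATIONS = frozenset(
    {
        PHENOTYPE_OF,
        HAS_PART,
        PART_OF,
        HAS_QUALITY,
        DURING,
        TOWARDS,
        INCREASED_IN_MAGNITUDE,
        DECREASED_IN_MAGNITUDE,
    }
)

TRANSITIVE_RELATIONS = frozenset({PART_OF})
REFLEXIVE_RELATIONS = frozenset({PART_OF})

#: Property chains (r1, r2, implied): an r1-edge followed by an r2-edge
#: entails an implied-edge.  has-part absorbs a trailing part-of.
RELATION_CHAINS = ((HAS_PART, PART_OF, HAS_PART),)

#: The reference quality used as the filler of magnitude comparisons.  The
#: source listings write the bare token "normal"; it is resolved to the PATO
#: class *normal* so every atom in a compiled expression is a CURIE.
NORMAL_QUALITY = "PATO:0000461"
_NORMAL_ALIAS = "normal"

CURIE_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*:\d+$")


def is_curie(token: str) -> bool:
    return bool(CURIE_RE.match(token))


# ---------------------------------------------------------------------------
# AST
# ---------------------------------------------------------------------------


class ClassExpression:
    """Base class for expression nodes (Atom | And | Some)."""

    __slots__ = ()


@dataclass(frozen=True)
class Atom(ClassExpression):
    """A named class, identified by its CURIE."""

    curie: str

    def __post_init__(self) -> None:
        if not is_curie(self.curie):
            raise ValueError(f"not a CURIE: {self.curie!r}")


@dataclass(frozen=True)
class Some(ClassExpression):
    """Existential restriction ``relation some filler``."""

    relation: str
    filler: ClassExpression

    def __post_init__(self) -> None:
        if self.relation not in EXPRESSION_RELATIONS:
            raise ValueError(f"unknown relation: {self.relation!r}")


@dataclass(frozen=True)
class And(ClassExpression):
    """Conjunction of two or more operands."""

    operands: tuple[ClassExpression, ...]

    def __init__(self, operands) -> None:
        ops = tuple(operands)
        if len(ops) < 2:
            raise ValueError("And requires at least two operands")
        object.__setattr__(self, "operands", ops)


@dataclass(frozen=True)
class EQDefinition:
    """An entity-quality definition lifted verbatim from an OBO
    ``intersection_of`` block: the genus is the PATO quality, the
    ``inheres_in`` differentium the bearer entity, with optional ``during``
    (temporal stage) and ``towards`` (second argument of a relational
    quality) differentia."""

    quality: str
    bearer: str
    during: Optional[str] = None
    towards: Optional[str] = None


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def render(expr: ClassExpression) -> str:
    """Serialize an expression in the canonical textual grammar.

    Atoms render as their CURIE; ``Some(r, f)`` as ``"r some F"`` with F
    parenthesized unless it is an atom; conjunctions join operands with
    ``" and "``.  Deterministic, single-spaced, no trailing whitespace.
    """
    if isinstance(expr, Atom):
        return expr.curie
    if isinstance(expr, Some):
        filler = render(expr.filler)
        if not isinstance(expr.filler, Atom):
            filler = f"({filler})"
        return f"{expr.relation} some {filler}"
    if isinstance(expr, And):
        return " and ".join(render(op) for op in expr.operands)
    raise TypeError(f"not a class expression: {expr!r}")


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(text: str) -> Iterator[tuple[str, int]]:
    for m in _TOKEN_RE.finditer(text):
        yield m.group(), m.start()


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = list(_tokenize(text))
        self.pos = 0

    def _peek(self) -> Optional[tuple[str, int]]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _next(self) -> tuple[str, int]:
        tok = self._peek()
        if tok is None:
            raise ExpressionParseError("unexpected end of expression", len(self.text))
        self.pos += 1
        return tok

    def parse(self) -> ClassExpression:
        expr = self.expr()
        tok = self._peek()
        if tok is not None:
            raise ExpressionParseError(f"unexpected token {tok[0]!r}", tok[1])
        return expr

    def expr(self) -> ClassExpression:
        operands = [self.conjunct()]
        while True:
            tok = self._peek()
            if tok is None or tok[0] != "and":
                break
            self._next()
            operands.append(self.conjunct())
        if len(operands) == 1:
            return operands[0]
        return And(operands)

    def conjunct(self) -> ClassExpression:
        word, offset = self._next()
        if word == "(":
            inner = self.expr()
            close = self._next()
            if close[0] != ")":
                raise ExpressionParseError("expected ')'", close[1])
            return inner
        if word == ")":
            raise ExpressionParseError("unbalanced ')'", offset)
        if word in EXPRESSION_RELATIONS:
            some, some_off = self._next()
            if some != "some":
                raise ExpressionParseError(
                    f"expected 'some' after relation {word!r}", some_off
                )
            return Some(word, self.filler())
        return self.atom(word, offset)

    def filler(self) -> ClassExpression:
        word, offset = self._next()
        if word == "(":
            inner = self.expr()
            close = self._next()
            if close[0] != ")":
                raise ExpressionParseError("expected ')'", close[1])
            return inner
        return self.atom(word, offset)

    def atom(self, word: str, offset: int) -> Atom:
        if word == _NORMAL_ALIAS:
            return Atom(NORMAL_QUALITY)
        if is_curie(word):
            return Atom(word)
        if word == INHERES_IN:
            raise ExpressionParseError(
                "inheres_in is an OBO EQ relation, not an expression relation", offset
            )
        raise ExpressionParseError(
            f"unknown relation or malformed CURIE {word!r}", offset
        )


def parse_expression(text: str) -> ClassExpression:
    """Parse expression text (tolerant of line breaks and extra whitespace).

    The bare token ``normal`` is accepted as an alias for PATO:0000461.
    Raises :class:`ExpressionParseError` with a character offset on unbalanced
    parentheses, unknown relations, or malformed CURIEs.
    """
    return _Parser(text).parse()


# ---------------------------------------------------------------------------
# Canonical form
# ---------------------------------------------------------------------------


def canonicalize(expr: ClassExpression) -> ClassExpression:
    """Flatten nested conjunctions and sort operands by their rendering.

    Idempotent, and semantically neutral under the structural reasoner
    (conjunction is associative, commutative).
    """
    if isinstance(expr, Atom):
        return expr
    if isinstance(expr, Some):
        return Some(expr.relation, canonicalize(expr.filler))
    if isinstance(expr, And):
        flat: list[ClassExpression] = []
        for op in expr.operands:
            c = canonicalize(op)
            if isinstance(c, And):
                flat.extend(c.operands)
            else:
                flat.append(c)
        flat.sort(key=render)
        return And(flat)
    raise TypeError(f"not a class expression: {expr!r}")
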