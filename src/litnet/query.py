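"""Boolean keyword queries over a local corpus.

Syntax: ``AND`` / ``OR`` / ``NOT`` (case-insensitive standalone tokens, with
precedence NOT > AND > OR, all left-associative), parentheses for grouping,
double quotes for phrases, a trailing ``*`` for truncation, and implicit AND
between adjacent terms.  ``NOT`` is binary (``l NOT r``), mirroring PubMed —
a leading NOT over an unbounded corpus is ill-defined and is a parse error.

Matching happens over case-folded alphanumeric tokens of title + abstract;
hyphenated words split into separate tokens (configurable via
:func:`tokenize_text`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

from .corpus import Corpus
from .errors import QueryParseError

# --- AST -------------------------------------------------------------------


@dataclass(frozen=True)
class Term:
    token: str


@dataclass(frozen=True)
class Phrase:
    tokens: tuple[str, ...]


@dataclass(frozen=True)
class Truncated:
    prefix: str


@dataclass(frozen=True)
class And:
    left: "Node"
    right: "Node"


@dataclass(frozen=True)
class Or:
    left: "Node"
    right: "Node"


@dataclass(frozen=True)
class Not:
    left: "Node"
    right: "Node"


Node = Term | Phrase | Truncated | And | Or | Not

_TOKEN_RE = re.compile(r"[0-9a-z]+")


def tokenize_text(text: str, split_hyphens: bool = True) -> list[str]:
    """Case-folded alphanumeric tokens of free text."""
    folded = text.casefold()
    if not split_hyphens:
        return re.findall(r"[0-9a-z]+(?:-[0-9a-z]+)*", folded)
    return _TOKEN_RE.findall(folded)


# --- lexer -----------------------------------------------------------------

_OPERATORS = {"and": "AND", "or": "OR", "not": "NOT"}


@dataclass(frozen=True)
class _Tok:
    kind: str  # WORD, PHRASE, LPAREN, RPAREN, AND, OR, NOT
    value: str
    pos: int


def _lex(text: str) -> list[_Tok]:
    toks: list[_Tok] = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
        elif c == "(":
            toks.append(_Tok("LPAREN", c, i))
            i += 1
        elif c == ")":
            toks.append(_Tok("RPAREN", c, i))
            i += 1
        elif c == '"':
            j = text.find('"', i + 1)
            if j < 0:
                raise QueryParseError("unbalanced double quote", i)
            toks.append(_Tok("PHRASE", text[i + 1 : j], i))
            i = j + 1
        else:
            j = i
            while j < n and not text[j].isspace() and text[j] not in '()"':
                j += 1
            word = text[i:j]
            op = _OPERATORS.get(word.casefold())
            toks.append(_Tok(op or "WORD", word, i))
            i = j
    return toks


# --- parser ----------------------------------------------------------------


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.toks = _lex(text)
        self.i = 0

    def peek(self) -> _Tok | None:
        return self.toks[self.i] if self.i < len(self.toks) else None

    def next(self) -> _Tok:
        tok = self.peek()
        if tok is None:
            raise QueryParseError("unexpected end of query", len(self.text))
        self.i += 1
        return tok

    def parse(self) -> Node:
        if not self.toks:
            raise QueryParseError("empty query", 0)
        node = self.or_level()
        trailing = self.peek()
        if trailing is not None:
            raise QueryParseError(f"unexpected {trailing.value!r}", trailing.pos)
        return node

    def or_level(self) -> Node:
        node = self.and_level()
        while (tok := self.peek()) is not None and tok.kind == "OR":
            self.next()
            node = Or(node, self.and_level())
        return node

    def and_level(self) -> Node:
        node = self.not_level()
        while (tok := self.peek()) is not None:
            if tok.kind == "AND":
                self.next()
                node = And(node, self.not_level())
            elif tok.kind in ("WORD", "PHRASE", "LPAREN"):
                # implicit AND between adjacent primaries
                node = And(node, self.not_level())
            else:
                break
        return node

    def not_level(self) -> Node:
        node = self.primary()
        while (tok := self.peek()) is not None and tok.kind == "NOT":
            self.next()
            node = Not(node, self.primary())
        return node

    def primary(self) -> Node:
        tok = self.peek()
        if tok is None:
            raise QueryParseError("dangling operator", len(self.text))
        if tok.kind == "LPAREN":
            self.next()
            node = self.or_level()
            closing = self.peek()
            if closing is None or closing.kind != "RPAREN":
                raise QueryParseError("unbalanced parenthesis", tok.pos)
            self.next()
            return node
        if tok.kind == "PHRASE":
            self.next()
            tokens = tuple(tokenize_text(tok.value))
            if not tokens:
                raise QueryParseError("empty phrase", tok.pos)
            return Phrase(tokens)
        if tok.kind == "WORD":
            self.next()
            return _word_node(tok)
        raise QueryParseError(f"operator {tok.value!r} without left operand", tok.pos)


def _word_node(tok: _Tok) -> Node:
    word = tok.value
    truncated = word.endswith("*")
    if truncated:
        word = word[:-1]
    tokens = tokenize_text(word)
    if not tokens:
        raise QueryParseError(f"term {tok.value!r} has no searchable characters", tok.pos)
    if truncated:
        if len(tokens) > 1:
            raise QueryParseError("truncation applies to single terms only", tok.pos)
        return Truncated(tokens[0])
    if len(tokens) > 1:
        # a punctuated word like anti-inflammatory behaves as a phrase
        return Phrase(tuple(tokens))
    return Term(tokens[0])


def parse_query(text: str) -> Node:
    """Parse query text into an AST; raises :class:`QueryParseError` with a
    character position on malformed input."""
    return _Parser(text).parse()


# --- evaluation ------------------------------------------------------------


def _doc_matches(tokens: list[str], node: Node) -> bool:
    if isinstance(node, Term):
        return node.token in tokens
    if isinstance(node, Truncated):
        return any(t.startswith(node.prefix) for t in tokens)
    if isinstance(node, Phrase):
        k = len(node.tokens)
        want = list(node.tokens)
        return any(tokens[i : i + k] == want for i in range(len(tokens) - k + 1))
    raise TypeError(f"not a leaf node: {node}")


def evaluate_query(corpus: Corpus, node: Node, pmids: Iterable[str] | None = None) -> set[str]:
    """Pmids of documents matching the AST, over title + abstract tokens."""
    universe = set(corpus.documents) if pmids is None else set(pmids) & set(corpus.documents)
    token_cache = {p: tokenize_text(corpus[p].text) for p in universe}

    def ev(n: Node) -> set[str]:
        if isinstance(n, And):
            return ev(n.left) & ev(n.right)
        if isinstance(n, Or):
            return ev(n.left) | ev(n.right)
        if isinstance(n, Not):
            return ev(n.left) - ev(n.right)
        return {p for p, toks in token_cache.items() if _doc_matches(toks, n)}

    return ev(node)


def run_query(corpus: Corpus, text: str) -> set[str]:
    """Convenience: parse then evaluate."""
    return evaluate_query(corpus, parse_query(text))
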