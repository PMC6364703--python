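"""Parsing and min/max evaluation of gene-protein-reaction (GPR) rules.

The dialect is boolean expressions over gene ids with case-insensitive
``and`` / ``or`` keywords and parentheses; gene ids are arbitrary
whitespace-delimited tokens (anything that is not a parenthesis or a
keyword). Evaluation over expression ratios follows the standard isozyme /
subunit semantics: OR (isozymes) takes the maximum of its children, AND
(complex subunits) the minimum.
"""

from __future__ import annotations

from typing import Mapping

Node = tuple  # ("gene", id) | ("and", [children]) | ("or", [children])


class GPRParseError(ValueError):
    """Malformed GPR expression; message carries the token position."""


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch in "()":
            tokens.append((ch, i))
            i += 1
        else:
            j = i
            while j < n and not text[j].isspace() and text[j] not in "()":
                j += 1
            tokens.append((text[i:j], i))
            i = j
    return tokens


def parse_gpr(text: str) -> Node:
    """Parse a GPR string into an and/or tree.

    Grammar:  expr := term ("or" term)* ;  term := factor ("and" factor)* ;
    factor := "(" expr ")" | gene.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise GPRParseError("empty GPR expression")
    pos = 0

    def peek() -> tuple[str, int] | None:
        return tokens[pos] if pos < len(tokens) else None

    def fail(msg: str, at: int) -> None:
        raise GPRParseError(f"{msg} at position {at} in {text!r}")

    def parse_expr() -> Node:
        nonlocal pos
        children = [parse_term()]
        while (tok := peek()) is not None and tok[0].lower() == "or":
            pos += 1
            children.append(parse_term())
        return children[0] if len(children) == 1 else ("or", children)

    def parse_term() -> Node:
        nonlocal pos
        children = [parse_factor()]
        while (tok := peek()) is not None and tok[0].lower() == "and":
            pos += 1
            children.append(parse_factor())
        return children[0] if len(children) == 1 else ("and", children)

    def parse_factor() -> Node:
        nonlocal pos
        tok = peek()
        if tok is None:
            fail("unexpected end of expression", len(text))
        word, at = tok
        if word == "(":
            pos += 1
            node = parse_expr()
            closing = peek()
            if closing is None or closing[0] != ")":
                fail("unbalanced parenthesis opened", at)
            pos += 1
            return node
        if word == ")" or word.lower() in ("and", "or"):
            fail(f"unexpected token {word!r}", at)
        pos += 1
        return ("gene", word)

    tree = parse_expr()
    if pos < len(tokens):
        fail(f"trailing token {tokens[pos][0]!r}", tokens[pos][1])
    return tree


def genes(node: Node) -> set[str]:
    kind = node[0]
    if kind == "gene":
        return {node[1]}
    out: set[str] = set()
    for child in node[1]:
        out |= genes(child)
    return out


def evaluate(node: Node, ratios: Mapping[str, float], default: float = 1.0) -> float:
    """Evaluate an and/or tree under min/max algebra.

    Genes absent from ``ratios`` evaluate to ``default`` (unconstrained).
    """
    kind = node[0]
    if kind == "gene":
        return float(ratios.get(node[1], default))
    values = [evaluate(child, ratios, default) for child in node[1]]
    return min(values) if kind == "and" else max(values)


def evaluate_gpr(gpr: str, gene_ratios: Mapping[str, float], default: float = 1.0) -> float:
    """Parse and evaluate a GPR string; empty expressions evaluate to 1."""
    if not gpr.strip():
        return 1.0
    return evaluate(parse_gpr(gpr), gene_ratios, default)
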