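"""Content-MathML expression trees used by kinetic laws.

The AST is deliberately small: numbers, identifier references, the time
symbol, the usual arithmetic/relational/logical operators, piecewise,
the two named constants and application of a model-defined function.
Expressions are immutable; renaming identifiers returns a new tree.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from typing import Callable, Mapping, Union

MATHML_NS = "http://www.w3.org/1998/Math/MathML"
TIME_DEFINITION_URLS = frozenset(
    {
        "http://www.sbml.org/sbml/symbols/time",
        "http://www.sbml.org/symbols/time",
    }
)


class MathParseError(ValueError):
    """Raised when content MathML cannot be turned into an AST."""


class MathEvalError(ValueError):
    """Raised when an expression cannot be evaluated (unresolved leaf,
    division by zero, exhausted piecewise)."""


@dataclass(frozen=True)
class Num:
    value: float


@dataclass(frozen=True)
class Sym:
    name: str


@dataclass(frozen=True)
class TimeSymbol:
    """csymbol bound to integration time."""


@dataclass(frozen=True)
class Const:
    name: str  # "pi" | "exponentiale" | "true" | "false"


@dataclass(frozen=True)
class Apply:
    op: str
    args: tuple["MathExpr", ...]


@dataclass(frozen=True)
class Call:
    func: str
    args: tuple["MathExpr", ...]


@dataclass(frozen=True)
class Piecewise:
    pieces: tuple[tuple["MathExpr", "MathExpr"], ...]  # (value, condition)
    otherwise: Union["MathExpr", None]


MathExpr = Union[Num, Sym, TimeSymbol, Const, Apply, Call, Piecewise]

#: operator element names understood inside <apply>
OPERATORS = frozenset(
    {
        "plus", "minus", "times", "divide", "power", "root",
        "exp", "ln", "log", "abs", "floor", "ceiling",
        "eq", "neq", "lt", "leq", "gt", "geq",
        "and", "or", "not", "xor",
    }
)

_CONSTS = {"pi": math.pi, "exponentiale": math.e, "true": 1.0, "false": 0.0}


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _text(elem: ET.Element) -> str:
    return (elem.text or "").strip()


def parse_mathml(elem: ET.Element) -> MathExpr:
    """Parse a content-MathML element (the ``<math>`` wrapper or any
    expression element below it) into an AST."""
    if _local(elem.tag) == "math":
        children = list(elem)
        if len(children) != 1:
            raise MathParseError(
                f"<math> must contain exactly one expression, found {len(children)}"
            )
        return parse_mathml(children[0])
    return _parse_expr(elem)


def _parse_expr(elem: ET.Element) -> MathExpr:
    tag = _local(elem.tag)
    if tag == "cn":
        return _parse_cn(elem)
    if tag == "ci":
        name = _text(elem)
        if not name:
            raise MathParseError("<ci> without identifier text")
        return Sym(name)
    if tag == "csymbol":
        url = elem.get("definitionURL", "")
        if url in TIME_DEFINITION_URLS:
            return TimeSymbol()
        raise MathParseError(f"unsupported csymbol definitionURL {url!r}")
    if tag in _CONSTS:
        return Const(tag)
    if tag == "apply":
        return _parse_apply(elem)
    if tag == "piecewise":
        return _parse_piecewise(elem)
    raise MathParseError(f"unsupported MathML element <{tag}>")


def _parse_cn(elem: ET.Element) -> Num:
    kind = elem.get("type", "real")
    if kind in ("real", "integer"):
        try:
            return Num(float(_text(elem)))
        except ValueError as exc:
            raise MathParseError(f"bad <cn> literal {_text(elem)!r}") from exc
    # e-notation / rational carry two parts separated by <sep/>
    parts = [_text(elem)]
    for child in elem:
        if _local(child.tag) != "sep":
            raise MathParseError(f"unexpected child <{_local(child.tag)}> in <cn>")
        parts.append((child.tail or "").strip())
    if len(parts) != 2:
        raise MathParseError(f"<cn type={kind!r}> needs mantissa<sep/>exponent")
    a, b = float(parts[0]), float(parts[1])
    if kind == "e-notation":
        return Num(a * 10.0 ** b)
    if kind == "rational":
        return Num(a / b)
    raise MathParseError(f"unsupported <cn> type {kind!r}")


def _parse_apply(elem: ET.Element) -> MathExpr:
    children = list(elem)
    if not children:
        raise MathParseError("empty <apply>")
    head, *rest = children
    head_tag = _local(head.tag)
    if head_tag == "ci":  # application of a model function definition
        return Call(_text(head), tuple(_parse_expr(c) for c in rest))
    if head_tag not in OPERATORS:
        raise MathParseError(f"unsupported operator <{head_tag}>")
    # qualifiers: <degree> for root, <logbase> for log
    args: list[MathExpr] = []
    qualifier: MathExpr | None = None
    for child in rest:
        tag = _local(child.tag)
        if tag in ("degree", "logbase"):
            inner = list(child)
            if len(inner) != 1:
                raise MathParseError(f"<{tag}> must hold one expression")
            qualifier = _parse_expr(inner[0])
        else:
            args.append(_parse_expr(child))
    if head_tag == "root":
        return Apply("root", (qualifier if qualifier is not None else Num(2.0), *args))
    if head_tag == "log":
        return Apply("log", (qualifier if qualifier is not None else Num(10.0), *args))
    if not args:
        raise MathParseError(f"<apply> of <{head_tag}> with no operands")
    return Apply(head_tag, tuple(args))


def _parse_piecewise(elem: ET.Element) -> Piecewise:
    pieces: list[tuple[MathExpr, MathExpr]] = []
    otherwise: MathExpr | None = None
    for child in elem:
        tag = _local(child.tag)
        inner = [_parse_expr(c) for c in child]
        if tag == "piece":
            if len(inner) != 2:
                raise MathParseError("<piece> needs value and condition")
            pieces.append((inner[0], inner[1]))
        elif tag == "otherwise":
            if len(inner) != 1:
                raise MathParseError("<otherwise> needs one expression")
            otherwise = inner[0]
        else:
            raise MathParseError(f"unexpected <{tag}> in <piecewise>")
    return Piecewise(tuple(pieces), otherwise)


# ---------------------------------------------------------------------------
# evaluation

FunctionDef = tuple[tuple[str, ...], MathExpr]  # (parameter names, body)


def evaluate(
    expr: MathExpr,
    env: Mapping[str, float],
    time: float = 0.0,
    functions: Mapping[str, FunctionDef] | None = None,
) -> float:
    """Evaluate ``expr`` against identifier bindings in ``env``.

    ``time`` binds the time csymbol; ``functions`` supplies model-defined
    function bodies for :class:`Call` nodes.
    """
    return _eval(expr, env, time, functions or {}, path="")


def _eval(
    expr: MathExpr,
    env: Mapping[str, float],
    time: float,
    functions: Mapping[str, FunctionDef],
    path: str,
) -> float:
    if isinstance(expr, Num):
        return expr.value
    if isinstance(expr, Sym):
        try:
            return float(env[expr.name])
        except KeyError:
            raise MathEvalError(f"unresolved identifier {expr.name!r} at {path or '<root>'}") from None
    if isinstance(expr, TimeSymbol):
        return time
    if isinstance(expr, Const):
        return _CONSTS[expr.name]
    if isinstance(expr, Piecewise):
        for i, (value, cond) in enumerate(expr.pieces):
            if _eval(cond, env, time, functions, f"{path}/piece[{i}].cond") != 0.0:
                return _eval(value, env, time, functions, f"{path}/piece[{i}]")
        if expr.otherwise is not None:
            return _eval(expr.otherwise, env, time, functions, f"{path}/otherwise")
        raise MathEvalError(f"piecewise exhausted with no true branch at {path or '<root>'}")
    if isinstance(expr, Call):
        try:
            params, body = functions[expr.func]
        except KeyError:
            raise MathEvalError(f"unknown function {expr.func!r} at {path or '<root>'}") from None
        if len(params) != len(expr.args):
            raise MathEvalError(
                f"function {expr.func!r} expects {len(params)} args, got {len(expr.args)}"
            )
        bound = dict(env)
        for name, arg in zip(params, expr.args):
            bound[name] = _eval(arg, env, time, functions, f"{path}/{expr.func}()")
        return _eval(body, bound, time, functions, f"{path}/{expr.func}")
    # Apply
    vals = [
        _eval(a, env, time, functions, f"{path}/{expr.op}[{i}]")
        for i, a in enumerate(expr.args)
    ]
    return _apply_op(expr.op, vals, path)


def _apply_op(op: str, vals: list[float], path: str) -> float:
    if op == "plus":
        return math.fsum(vals)
    if op == "minus":
        return -vals[0] if len(vals) == 1 else vals[0] - vals[1]
    if op == "times":
        out = 1.0
        for v in vals:
            out *= v
        return out
    if op == "divide":
        if vals[1] == 0.0:
            raise MathEvalError(f"division by zero at {path or '<root>'}/divide")
        return vals[0] / vals[1]
    if op == "power":
        return vals[0] ** vals[1]
    if op == "root":
        degree, x = vals
        if degree == 0.0:
            raise MathEvalError(f"zeroth root at {path or '<root>'}/root")
        return x ** (1.0 / degree)
    if op == "exp":
        return math.exp(vals[0])
    if op == "ln":
        return math.log(vals[0])
    if op == "log":
        base, x = vals
        return math.log(x, base)
    if op == "abs":
        return abs(vals[0])
    if op == "floor":
        return float(math.floor(vals[0]))
    if op == "ceiling":
        return float(math.ceil(vals[0]))
    if op == "eq":
        return 1.0 if vals[0] == vals[1] else 0.0
    if op == "neq":
        return 1.0 if vals[0] != vals[1] else 0.0
    if op == "lt":
        return 1.0 if vals[0] < vals[1] else 0.0
    if op == "leq":
        return 1.0 if vals[0] <= vals[1] else 0.0
    if op == "gt":
        return 1.0 if vals[0] > vals[1] else 0.0
    if op == "geq":
        return 1.0 if vals[0] >= vals[1] else 0.0
    if op == "and":
        return 1.0 if all(v != 0.0 for v in vals) else 0.0
    if op == "or":
        return 1.0 if any(v != 0.0 for v in vals) else 0.0
    if op == "not":
        return 1.0 if vals[0] == 0.0 else 0.0
    if op == "xor":
        return 1.0 if sum(1 for v in vals if v != 0.0) % 2 == 1 else 0.0
    raise MathEvalError(f"unknown operator {op!r}")


# ---------------------------------------------------------------------------
# traversal helpers

def identifiers(expr: MathExpr) -> set[str]:
    """All Sym names referenced anywhere in the tree (Call targets excluded)."""
    out: set[str] = set()
    _walk(expr, lambda e: out.add(e.name) if isinstance(e, Sym) else None)
    return out


def _walk(expr: MathExpr, visit: Callable[[MathExpr], None]) -> None:
    visit(expr)
    if isinstance(expr, (Apply, Call)):
        for a in expr.args:
            _walk(a, visit)
    elif isinstance(expr, Piecewise):
        for value, cond in expr.pieces:
            _walk(value, visit)
            _walk(cond, visit)
        if expr.otherwise is not None:
            _walk(expr.otherwise, visit)


def rename(expr: MathExpr, mapping: Mapping[str, str]) -> MathExpr:
    """Return a copy with every identifier leaf mapped through ``mapping``
    (identifiers absent from the map are left alone)."""
    if isinstance(expr, Sym):
        new = mapping.get(expr.name)
        return Sym(new) if new is not None and new != expr.name else expr
    if isinstance(expr, Apply):
        return Apply(expr.op, tuple(rename(a, mapping) for a in expr.args))
    if isinstance(expr, Call):
        return Call(expr.func, tuple(rename(a, mapping) for a in expr.args))
    if isinstance(expr, Piecewise):
        return Piecewise(
            tuple((rename(v, mapping), rename(c, mapping)) for v, c in expr.pieces),
            rename(expr.otherwise, mapping) if expr.otherwise is not None else None,
        )
    return expr


# ---------------------------------------------------------------------------
# serialization

def format_number(x: float) -> str:
    """Shortest decimal that round-trips; integers without trailing '.0'."""
    if x == int(x) and abs(x) < 1e16:
        return str(int(x))
    return repr(float(x))


def to_element(expr: MathExpr) -> ET.Element:
    """Serialize the AST to a ``<math>`` element (MathML namespace)."""
    root = ET.Element(f"{{{MATHML_NS}}}math")
    root.append(_to_elem(expr))
    return root


def _mk(tag: str) -> ET.Element:
    return ET.Element(f"{{{MATHML_NS}}}{tag}")


def _to_elem(expr: MathExpr) -> ET.Element:
    if isinstance(expr, Num):
        e = _mk("cn")
        if expr.value == int(expr.value) and abs(expr.value) < 1e16:
            e.set("type", "integer")
        e.text = f" {format_number(expr.value)} "
        return e
    if isinstance(expr, Sym):
        e = _mk("ci")
        e.text = f" {expr.name} "
        return e
    if isinstance(expr, TimeSymbol):
        e = _mk("csymbol")
        e.set("encoding", "text")
        e.set("definitionURL", "http://www.sbml.org/sbml/symbols/time")
        e.text = " time "
        return e
    if isinstance(expr, Const):
        return _mk(expr.name)
    if isinstance(expr, Apply):
        e = _mk("apply")
        op, args = expr.op, expr.args
        e.append(_mk(op))
        if op in ("root", "log"):
            qual = _mk("degree" if op == "root" else "logbase")
            qual.append(_to_elem(args[0]))
            e.append(qual)
            args = args[1:]
        for a in args:
            e.append(_to_elem(a))
        return e
    if isinstance(expr, Call):
        e = _mk("apply")
        head = _mk("ci")
        head.text = f" {expr.func} "
        e.append(head)
        for a in expr.args:
            e.append(_to_elem(a))
        return e
    if isinstance(expr, Piecewise):
        e = _mk("piecewise")
        for value, cond in expr.pieces:
            p = _mk("piece")
            p.append(_to_elem(value))
            p.append(_to_elem(cond))
            e.append(p)
        if expr.otherwise is not None:
            o = _mk("otherwise")
            o.append(_to_elem(expr.otherwise))
            e.append(o)
        return e
    raise TypeError(f"not a MathExpr: {expr!r}")


_INFIX = {"plus": "+", "minus": "-", "times": "*", "divide": "/", "power": "^"}


def to_infix(expr: MathExpr) -> str:
    """Compact human-readable rendering (for warnings and debugging)."""
    if isinstance(expr, Num):
        return format_number(expr.value)
    if isinstance(expr, Sym):
        return expr.name
    if isinstance(expr, TimeSymbol):
        return "time"
    if isinstance(expr, Const):
        return expr.name
    if isinstance(expr, Apply):
        if expr.op in _INFIX and len(expr.args) >= 2:
            return "(" + f" {_INFIX[expr.op]} ".join(to_infix(a) for a in expr.args) + ")"
        if expr.op == "minus" and len(expr.args) == 1:
            return f"(-{to_infix(expr.args[0])})"
        return f"{expr.op}({', '.join(to_infix(a) for a in expr.args)})"
    if isinstance(expr, Call):
        return f"{expr.func}({', '.join(to_infix(a) for a in expr.args)})"
    if isinstance(expr, Piecewise):
        parts = [f"{to_infix(v)} if {to_infix(c)}" for v, c in expr.pieces]
        if expr.otherwise is not None:
            parts.append(f"else {to_infix(expr.otherwise)}")
        return "piecewise(" + ", ".join(parts) + ")"
    raise TypeError(f"not a MathExpr: {expr!r}")
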