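"""Restricted arithmetic expression parser for model config files.

Model coefficients in config files are written as expressions in a single
time variable, e.g. ``"2/(2+t)"`` or ``"0.5*(1+sin(t))"``.  The grammar is
deliberately tiny — numbers, the time variable, ``+ - * / **`` (``^`` is
accepted as a synonym), unary minus, and a whitelist of functions — so a
model file can be shared and re-run without executing arbitrary code.
"""

from __future__ import annotations

import ast
import math
from typing import Callable

__all__ = ["ExpressionError", "compile_expression", "ALLOWED_FUNCTIONS"]


class ExpressionError(ValueError):
    """Raised when a config expression falls outside the restricted grammar."""


ALLOWED_FUNCTIONS: dict[str, Callable] = {
    "exp": math.exp,
    "sin": math.sin,
    "cos": math.cos,
    "tan": math.tan,
    "log": math.log,
    "sqrt": math.sqrt,
    "abs": abs,
    "min": min,
    "max": max,
}

_ALLOWED_CONSTANTS = {"pi": math.pi, "e": math.e}

_ALLOWED_BINOPS = (ast.Add, ast.Sub, ast.Mult, ast.Div, ast.Pow)
_ALLOWED_UNARYOPS = (ast.UAdd, ast.USub)


def _check_node(node: ast.AST, var: str) -> None:
    if isinstance(node, ast.Expression):
        _check_node(node.body, var)
    elif isinstance(node, ast.Constant):
        if not isinstance(node.value, (int, float)):
            raise ExpressionError(f"non-numeric constant {node.value!r}")
    elif isinstance(node, ast.Name):
        if node.id != var and node.id not in _ALLOWED_CONSTANTS:
            raise ExpressionError(
                f"unknown name {node.id!r} (the time variable is {var!r})"
            )
    elif isinstance(node, ast.BinOp):
        if not isinstance(node.op, _ALLOWED_BINOPS):
            raise ExpressionError(f"operator {type(node.op).__name__} not allowed")
        _check_node(node.left, var)
        _check_node(node.right, var)
    elif isinstance(node, ast.UnaryOp):
        if not isinstance(node.op, _ALLOWED_UNARYOPS):
            raise ExpressionError(f"operator {type(node.op).__name__} not allowed")
        _check_node(node.operand, var)
    elif isinstance(node, ast.Call):
        if not isinstance(node.func, ast.Name) or node.func.id not in ALLOWED_FUNCTIONS:
            raise ExpressionError("only whitelisted function calls are allowed")
        if node.keywords:
            raise ExpressionError("keyword arguments are not allowed")
        for arg in node.args:
            _check_node(arg, var)
    else:
        raise ExpressionError(f"syntax element {type(node).__name__} not allowed")


def compile_expression(expr: str, var: str = "t") -> Callable[[float], float]:
    """Compile a restricted arithmetic expression into a float -> float callable.

    Parameters
    ----------
    expr
        Expression text, e.g. ``"exp(-t)*(2+sin(t))"``.  ``^`` may be used
        for exponentiation.
    var
        Name of the single free variable (``"t"`` for coefficients, ``"s"``
        for initial histories by convention).
    """
    if not isinstance(expr, str) or not expr.strip():
        raise ExpressionError("expression must be a non-empty string")
    source = expr.replace("^", "**")
    try:
        tree = ast.parse(source, mode="eval")
    except SyntaxError as exc:
        raise ExpressionError(f"cannot parse expression {expr!r}: {exc}") from None
    _check_node(tree, var)
    code = compile(tree, filename=f"<expr {expr!r}>", mode="eval")
    namespace = {**ALLOWED_FUNCTIONS, **_ALLOWED_CONSTANTS, "__builtins__": {}}

    def fn(value: float) -> float:
        return float(eval(code, namespace, {var: float(value)}))

    fn.expression = expr  # type: ignore[attr-defined]
    return fn
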