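"""Sparse multivariate polynomial arithmetic over exponent-tuple bases.

A polynomial in k variables is a mapping ``term -> coefficient`` where
``term`` is a length-k tuple of non-negative integer exponents, e.g. for
two factors (A, B): ``(0, 0)`` is the intercept, ``(1, 0)`` is A,
``(1, 1)`` is AB and ``(2, 0)`` is A².  This representation backs both
the coded and actual parameterizations of response-surface models and
the exact affine substitution between them.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np

Term = tuple[int, ...]
Poly = dict[Term, float]

INTERCEPT_2: Term = (0, 0)


def term_degree(term: Term) -> int:
    return sum(term)


def term_name(term: Term, names: Sequence[str]) -> str:
    """Human-readable monomial label, e.g. ``(1, 1) -> 'A*B'``."""
    if all(e == 0 for e in term):
        return "1"
    parts = []
    for e, name in zip(term, names):
        if e == 1:
            parts.append(name)
        elif e > 1:
            parts.append(f"{name}^{e}")
    return "*".join(parts)


def poly_add(p: Mapping[Term, float], q: Mapping[Term, float]) -> Poly:
    out: Poly = dict(p)
    for t, c in q.items():
        out[t] = out.get(t, 0.0) + c
    return out


def poly_scale(p: Mapping[Term, float], s: float) -> Poly:
    return {t: c * s for t, c in p.items()}


def poly_mul(p: Mapping[Term, float], q: Mapping[Term, float]) -> Poly:
    out: Poly = {}
    for t1, c1 in p.items():
        for t2, c2 in q.items():
            t = tuple(a + b for a, b in zip(t1, t2))
            out[t] = out.get(t, 0.0) + c1 * c2
    return out


def poly_pow(p: Mapping[Term, float], n: int) -> Poly:
    if n < 0:
        raise ValueError("negative polynomial power")
    k = len(next(iter(p))) if p else 0
    out: Poly = {tuple([0] * k): 1.0}
    for _ in range(n):
        out = poly_mul(out, p)
    return out


def substitute_affine(
    coefs: Mapping[Term, float],
    offsets: Sequence[float],
    scales: Sequence[float],
) -> Poly:
    """Re-express a polynomial under the variable change v_i = offsets_i + scales_i * u_i.

    Given ``p(v)`` returns the expanded, collected polynomial ``q(u)`` with
    ``q(u) = p(offset + scale * u)`` exactly (no numerical fitting).
    """
    k = len(offsets)
    out: Poly = {}
    for term, coef in coefs.items():
        prod: Poly = {tuple([0] * k): coef}
        for i, e in enumerate(term):
            unit = [0] * k
            unit[i] = 1
            lin: Poly = {tuple([0] * k): offsets[i], tuple(unit): scales[i]}
            prod = poly_mul(prod, poly_pow(lin, e))
        out = poly_add(out, prod)
    return {t: c for t, c in out.items() if c != 0.0 or term_degree(t) == 0}


def evaluate(coefs: Mapping[Term, float], x: Sequence) -> np.ndarray | float:
    """Evaluate the polynomial at a point or at broadcastable coordinate arrays."""
    arrs = [np.asarray(xi, dtype=float) for xi in x]
    total = None
    for term, coef in coefs.items():
        mono = np.asarray(coef, dtype=float)
        for e, a in zip(term, arrs):
            if e:
                mono = mono * a**e
        total = mono if total is None else total + mono
    if total is None:
        return 0.0
    if np.ndim(total) == 0:
        return float(total)
    return total


def design_matrix(terms: Sequence[Term], points: np.ndarray) -> np.ndarray:
    """Model matrix with one column per term evaluated at ``points`` (n x k)."""
    points = np.asarray(points, dtype=float)
    cols = []
    for term in terms:
        col = np.ones(points.shape[0])
        for i, e in enumerate(term):
            if e:
                col = col * points[:, i] ** e
        cols.append(col)
    return np.column_stack(cols)
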