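"""Flat parameter trees.

Model parameters and their gradients are plain ``dict[str, np.ndarray]``
keyed by dotted layer paths.  The helpers here implement the vector-space
operations the optimizers and the meta-learner need, always returning new
dicts so that a shared initialization is never mutated in place.
"""

from __future__ import annotations

import numpy as np

ParamTree = dict[str, np.ndarray]


def copy(p: ParamTree) -> ParamTree:
    return {k: v.copy() for k, v in p.items()}


def zeros_like(p: ParamTree) -> ParamTree:
    return {k: np.zeros_like(v) for k, v in p.items()}


def add(a: ParamTree, b: ParamTree, scale: float = 1.0) -> ParamTree:
    """a + scale * b, key-wise."""
    return {k: a[k] + scale * b[k] for k in a}


def add_(a: ParamTree, b: ParamTree, scale: float = 1.0) -> ParamTree:
    """In-place accumulate scale * b into a; returns a."""
    for k in a:
        a[k] += scale * b[k]
    return a


def scale(a: ParamTree, s: float) -> ParamTree:
    return {k: s * v for k, v in a.items()}


def norm(a: ParamTree) -> float:
    return float(np.sqrt(sum(float(np.sum(v.astype(np.float64) ** 2)) for v in a.values())))


def dot(a: ParamTree, b: ParamTree) -> float:
    return float(sum(float(np.sum(a[k].astype(np.float64) * b[k])) for k in a))


def allfinite(a: ParamTree) -> bool:
    return all(np.all(np.isfinite(v)) for v in a.values())
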