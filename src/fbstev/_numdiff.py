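"""Central finite-difference derivatives.

Steps follow the usual truncation/roundoff balance: h ~ eps^(1/3)·scale for
first derivatives, eps^(1/4)·scale for second derivatives.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

_EPS = np.finfo(float).eps


def _steps(x: np.ndarray, power: float) -> np.ndarray:
    return _EPS ** power * np.maximum(1.0, np.abs(x))


def derivative(f: Callable[[float], float], x: float, order: int = 1) -> float:
    """Central-difference derivative of a scalar function (order 1 or 2)."""
    if order == 1:
        h = float(_steps(np.asarray(x), 1.0 / 3.0))
        return (f(x + h) - f(x - h)) / (2.0 * h)
    if order == 2:
        h = float(_steps(np.asarray(x), 1.0 / 4.0))
        return (f(x + h) - 2.0 * f(x) + f(x - h)) / (h * h)
    raise ValueError("order must be 1 or 2")


def gradient(f: Callable[[np.ndarray], float], x: Sequence[float]) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    h = _steps(x, 1.0 / 3.0)
    g = np.empty_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h[i]
        g[i] = (f(x + e) - f(x - e)) / (2.0 * h[i])
    return g


def jacobian(f: Callable[[np.ndarray], np.ndarray],
             x: Sequence[float]) -> np.ndarray:
    """Central-difference Jacobian of a vector-valued function (rows = outputs)."""
    x = np.asarray(x, dtype=float)
    h = _steps(x, 1.0 / 3.0)
    cols = []
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h[i]
        cols.append((np.asarray(f(x + e)) - np.asarray(f(x - e))) / (2.0 * h[i]))
    return np.column_stack(cols)


def hessian(f: Callable[[np.ndarray], float], x: Sequence[float]) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    n = x.size
    h = _steps(x, 1.0 / 4.0)
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros_like(x)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / (h[i] * h[i])
        for j in range(i + 1, n):
            ej = np.zeros_like(x)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H
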