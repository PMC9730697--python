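"""Three-parameter normal ogive (3PNO) response probabilities and likelihoods.

The 3PNO model for a binary response U_ij of examinee i to item j is

    P(U_ij = 1 | theta_i) = c_j + (1 - c_j) * Phi(a_j theta_i + b_j),

with discrimination a_j > 0, intercept b_j, guessing c_j in (0, 1), and Phi
the standard-normal CDF.  Likelihoods over a latent-trait grid are assembled
as matrix products of the response matrix with a J x Q item log-probability
table, so that the N x Q person-by-grid table costs two GEMMs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp, ndtr

from .grid_spline import Grid, RamsayDensity

__all__ = [
    "Item",
    "ItemSet",
    "ResponseMatrix",
    "prob_correct",
    "item_prob_table",
    "loglik_table",
    "marginal_loglik",
]

PROB_CLIP = 1e-12  # keeps logs finite at extreme grid points


@dataclass(frozen=True)
class Item:
    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"discrimination must be positive, got a={self.a}")
        if not 0.0 < self.c < 1.0:
            raise ValueError(f"guessing must lie in (0,1), got c={self.c}")


class ItemSet:
    """Ordered collection of items with vectorized parameter access."""

    def __init__(self, items=None, *, a=None, b=None, c=None):
        if items is not None:
            items = list(items)
            a = np.array([it.a for it in items], dtype=float)
            b = np.array([it.b for it in items], dtype=float)
            c = np.array([it.c for it in items], dtype=float)
        else:
            a = np.asarray(a, dtype=float)
            b = np.asarray(b, dtype=float)
            c = np.asarray(c, dtype=float)
        if not (a.shape == b.shape == c.shape) or a.ndim != 1 or a.size < 1:
            raise ValueError("a, b, c must be equal-length 1-D arrays, J >= 1")
        if np.any(a <= 0):
            raise ValueError("all discriminations must be positive")
        if np.any((c <= 0) | (c >= 1)):
            raise ValueError("all guessing parameters must lie in (0,1)")
        self.a, self.b, self.c = a, b, c

    @property
    def J(self) -> int:
        return self.a.size

    def __len__(self) -> int:
        return self.J

    def __getitem__(self, j: int) -> Item:
        return Item(a=float(self.a[j]), b=float(self.b[j]), c=float(self.c[j]))

    def __iter__(self):
        return (self[j] for j in range(self.J))

    def as_array(self) -> np.ndarray:
        """J x 3 array with columns (a, b, c)."""
        return np.column_stack([self.a, self.b, self.c])


class ResponseMatrix:
    """N x J matrix of binary item responses with no missing entries."""

    def __init__(self, u: np.ndarray, item_ids=None):
        u = np.asarray(u)
        if u.ndim != 2 or u.shape[0] < 1 or u.shape[1] < 1:
            raise ValueError("responses must form a non-empty 2-D matrix")
        if not np.isin(u, (0, 1)).all():
            raise ValueError("responses must be 0/1 with no missing entries")
        self.u = u.astype(np.int8)
        self.item_ids = (list(item_ids) if item_ids is not None
                         else [f"item{j+1}" for j in range(u.shape[1])])

    @property
    def N(self) -> int:
        return self.u.shape[0]

    @property
    def J(self) -> int:
        return self.u.shape[1]


def prob_correct(item: Item, theta) -> np.ndarray | float:
    """3PNO probability of a correct response."""
    return item.c + (1.0 - item.c) * ndtr(item.a * np.asarray(theta, float)
                                          + item.b)


def item_prob_table(items: ItemSet, grid: Grid) -> np.ndarray:
    """J x Q table of P_j(x_q), clipped away from {0, 1} for log safety."""
    p = items.c[:, None] + (1.0 - items.c[:, None]) * ndtr(
        items.a[:, None] * grid.points[None, :] + items.b[:, None])
    if np.any(p <= PROB_CLIP) or np.any(p >= 1.0 - PROB_CLIP):
        warnings.warn("item probabilities clipped at the grid extremes",
                      RuntimeWarning, stacklevel=2)
    return np.clip(p, PROB_CLIP, 1.0 - PROB_CLIP)


def loglik_table(U: ResponseMatrix, items: ItemSet, grid: Grid) -> np.ndarray:
    """N x Q table of log f(u_i | theta = x_q) under local independence."""
    if U.J != items.J:
        raise ValueError(f"response matrix has J={U.J}, item set J={items.J}")
    p = item_prob_table(items, grid)
    logp = np.log(p)
    log1mp = np.log1p(-p)
    u = U.u.astype(float)
    return u @ logp + (1.0 - u) @ log1mp


def marginal_loglik(U: ResponseMatrix, items: ItemSet,
                    density: RamsayDensity | np.ndarray,
                    grid: Grid | None = None) -> float:
    """Grid-marginalized log-likelihood sum_i log sum_q f(u_i|x_q) g_q."""
    if isinstance(density, RamsayDensity):
        g, grid = density.g, density.grid
    else:
        g = np.asarray(density, float)
        if grid is None:
            raise ValueError("grid required with a raw mass vector")
    table = loglik_table(U, items, grid)
    return float(np.sum(logsumexp(table, axis=1, b=g[None, :])))
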