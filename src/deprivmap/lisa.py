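"""Global and local Moran's I with permutation inference.

Weights are queen-contiguity (any shared boundary point), row-standardized.
The local statistic uses the decomposition-friendly definitions

    I        = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2
    I_i      = z_i * sum_j w_ij z_j / (sum_k z_k^2 / n)

so that the mean of I_i over non-isolates equals the global I exactly when
weights are row-standardized. Pseudo p-values are two-sided: for the global
statistic the data vector is freely permuted; for the local statistic the
focal value is held fixed and neighbour values are drawn from the remaining
units (conditional permutation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import shapely
from scipy import sparse

from .frames import EAFrame

__all__ = ["WeightsMatrix", "LISAResult", "queen_weights", "global_morans_i", "local_morans_i"]


@dataclass
class WeightsMatrix:
    """Row-standardized contiguity weights stored as neighbour index lists."""

    n: int
    neighbours: list[np.ndarray]  # per-unit sorted neighbour indices

    def __post_init__(self) -> None:
        for i, nb in enumerate(self.neighbours):
            if i in nb:
                raise ValueError("a unit cannot neighbour itself")

    @property
    def isolates(self) -> np.ndarray:
        return np.asarray([len(nb) == 0 for nb in self.neighbours])

    @property
    def cardinalities(self) -> np.ndarray:
        return np.asarray([len(nb) for nb in self.neighbours])

    def sparse(self) -> sparse.csr_matrix:
        rows, cols, vals = [], [], []
        for i, nb in enumerate(self.neighbours):
            if len(nb):
                rows.extend([i] * len(nb))
                cols.extend(nb)
                vals.extend([1.0 / len(nb)] * len(nb))
        return sparse.csr_matrix((vals, (rows, cols)), shape=(self.n, self.n))

    @property
    def s0(self) -> float:
        """Sum of all weights = number of non-isolated units (row-standardized)."""
        return float((~self.isolates).sum())


def queen_weights(frame: EAFrame) -> WeightsMatrix:
    """Queen contiguity: i ~ j iff the polygons share at least one boundary point."""
    geoms = frame.geometry
    tree = shapely.STRtree(geoms)
    left, right = tree.query(geoms, predicate="intersects")
    neighbours: list[set] = [set() for _ in range(len(geoms))]
    for i, j in zip(left, right):
        if i != j:
            neighbours[int(i)].add(int(j))
            neighbours[int(j)].add(int(i))
    return WeightsMatrix(
        n=len(geoms), neighbours=[np.asarray(sorted(s), dtype=int) for s in neighbours]
    )


def _check_x(x, n) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[0] != n:
        raise ValueError("x must align with the weights matrix")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 units")
    if np.var(x) == 0:
        raise ValueError("x has zero variance; Moran's I is undefined")
    return x


def _global_i(z: np.ndarray, w: sparse.csr_matrix, s0: float, n: int) -> float:
    return float((n / s0) * z @ (w @ z) / (z @ z))


def global_morans_i(
    x: Sequence[float],
    w: WeightsMatrix,
    n_perm: int = 999,
    seed: int = 0,
    return_null: bool = False,
):
    """Global Moran's I and a two-sided permutation pseudo p-value.

    pseudo_p = (#{permuted |I| >= |observed I|} + 1) / (n_perm + 1). With
    ``return_null`` the vector of permuted statistics is appended (its mean
    approaches the exact null expectation -1/(n-1)).
    """
    x = _check_x(x, w.n)
    z = x - x.mean()
    ws = w.sparse()
    obs = _global_i(z, ws, w.s0, w.n)
    if n_perm < 1:
        return (obs, float("nan"), np.empty(0)) if return_null else (obs, float("nan"))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    null = np.empty(n_perm)
    for s in range(n_perm):
        zp = rng.permutation(z)
        null[s] = _global_i(zp, ws, w.s0, w.n)
    pseudo_p = (int((np.abs(null) >= abs(obs)).sum()) + 1) / (n_perm + 1)
    if return_null:
        return obs, pseudo_p, null
    return obs, pseudo_p


@dataclass
class LISAResult:
    local_i: np.ndarray  # nan for isolates
    pseudo_p: np.ndarray  # nan for isolates
    classes: np.ndarray  # HH / LL / HL / LH / not-significant / isolate
    global_i: float
    global_pseudo_p: float
    n_permutations: int
    seed: int


def local_morans_i(
    x: Sequence[float],
    w: WeightsMatrix,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> LISAResult:
    """Local Moran's I with conditional permutation and quadrant classing.

    For each non-isolate unit i the focal value is held fixed while its
    neighbours' values are resampled (without replacement) from the other
    n - 1 observations; two-sided pseudo p-values as in the global test.
    Significant units are classed HH/LL/HL/LH by the sign of (z_i, lag_i);
    isolates are labelled "isolate" with local_i reported missing.
    """
    x = _check_x(x, w.n)
    n = w.n
    z = x - x.mean()
    m2 = float(z @ z) / n
    iso = w.isolates
    card = w.cardinalities

    lag = np.full(n, np.nan)
    for i, nb in enumerate(w.neighbours):
        if len(nb):
            lag[i] = z[nb].mean()
    local = np.where(iso, np.nan, z * lag / m2)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    max_k = int(card.max()) if n else 0
    pseudo_p = np.full(n, np.nan)
    if n_perm >= 1 and max_k > 0:
        # One shared matrix of permuted positions into the "other units" pool
        # (esda-style): each row is a random draw of max_k distinct indices
        # from range(n - 1).
        pick = np.empty((n_perm, max_k), dtype=int)
        for s in range(n_perm):
            pick[s] = rng.choice(n - 1, size=max_k, replace=False)
        for i in range(n):
            k = card[i]
            if k == 0:
                continue
            others = np.concatenate([z[:i], z[i + 1 :]])
            lag_perm = others[pick[:, :k]].mean(axis=1)
            local_perm = z[i] * lag_perm / m2
            count = int((np.abs(local_perm) >= abs(local[i])).sum())
            pseudo_p[i] = (count + 1) / (n_perm + 1)

    classes = np.empty(n, dtype=object)
    for i in range(n):
        if iso[i]:
            classes[i] = "isolate"
        elif not (pseudo_p[i] < alpha):
            classes[i] = "not-significant"
        elif z[i] >= 0 and lag[i] >= 0:
            classes[i] = "HH"
        elif z[i] < 0 and lag[i] < 0:
            classes[i] = "LL"
        elif z[i] >= 0:
            classes[i] = "HL"
        else:
            classes[i] = "LH"

    g_i, g_p = global_morans_i(x, w, n_perm=n_perm, seed=seed)
    return LISAResult(
        local_i=local,
        pseudo_p=pseudo_p,
        classes=classes,
        global_i=g_i,
        global_pseudo_p=g_p,
        n_permutations=n_perm,
        seed=int(seed),
    )
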