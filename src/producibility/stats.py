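"""Mantel and partial Mantel permutation tests for pairwise matrices.

Correlation (Spearman by default, Pearson optional) is computed over the
off-diagonal cells of two aligned square matrices; significance comes from
permuting the organism labels of the first matrix (rows and columns
simultaneously) and counting permutations whose correlation is stronger in
absolute value.  The p-value is (n_stronger + 1) / (n_perm + 1).

The partial variant correlates x and y while controlling for a third
matrix z through the standard first-order partial-correlation formula;
only x is permuted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class MantelResult:
    rho: float
    p_value: float
    n_perm: int
    n_stronger: int
    method: str
    partial: bool = False

    def __post_init__(self):
        assert self.p_value == (self.n_stronger + 1) / (self.n_perm + 1)


class DegenerateMatrixError(ValueError):
    """Off-diagonal cells are constant (or a control correlation is ±1)."""


def _offdiag_mask(n: int, triangle: str) -> np.ndarray:
    if triangle == "both":
        return ~np.eye(n, dtype=bool)
    if triangle == "upper":
        return np.triu(np.ones((n, n), dtype=bool), k=1)
    raise ValueError(f"triangle must be 'both' or 'upper', got {triangle!r}")


def _check_square(name: str, m: np.ndarray, n: int) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square, got shape {m.shape}")
    if m.shape[0] != n:
        raise ValueError(f"{name} has {m.shape[0]} organisms, expected {n}")
    return m


def _corr(u: np.ndarray, v: np.ndarray, method: str) -> float:
    if method == "spearman":
        u, v = rankdata(u), rankdata(v)
    elif method != "pearson":
        raise ValueError(f"method must be 'spearman' or 'pearson', got {method!r}")
    su, sv = u.std(), v.std()
    if su == 0 or sv == 0:
        raise DegenerateMatrixError("constant off-diagonal values; correlation undefined")
    return float(np.corrcoef(u, v)[0, 1])


def mantel(
    x,
    y,
    n_perm: int = 10_000,
    method: str = "spearman",
    rng: Optional[np.random.Generator] = None,
    triangle: str = "both",
) -> MantelResult:
    """Mantel permutation test between two aligned square matrices."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    x = _check_square("x", x, n)
    y = _check_square("y", y, n)
    if rng is None:
        rng = np.random.default_rng()
    mask = _offdiag_mask(n, triangle)
    rho_obs = _corr(x[mask], y[mask], method)
    yv = y[mask]
    if method == "spearman":
        yv = rankdata(yv)
    n_stronger = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        xp = x[np.ix_(perm, perm)][mask]
        if method == "spearman":
            xp = rankdata(xp)
        r = float(np.corrcoef(xp, yv)[0, 1])
        if abs(r) > abs(rho_obs):
            n_stronger += 1
    return MantelResult(
        rho=rho_obs,
        p_value=(n_stronger + 1) / (n_perm + 1),
        n_perm=n_perm,
        n_stronger=n_stronger,
        method=method,
    )


def _partial(rxy: float, rxz: float, ryz: float) -> float:
    denom = np.sqrt((1 - rxz**2) * (1 - ryz**2))
    if denom == 0:
        raise DegenerateMatrixError("control matrix perfectly correlated; partial undefined")
    return float((rxy - rxz * ryz) / denom)


def partial_mantel(
    x,
    y,
    z,
    n_perm: int = 10_000,
    method: str = "spearman",
    rng: Optional[np.random.Generator] = None,
    triangle: str = "both",
) -> MantelResult:
    """Partial Mantel test of x vs y controlling for z (only x permuted)."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    x = _check_square("x", x, n)
    y = _check_square("y", y, n)
    z = _check_square("z", z, n)
    if rng is None:
        rng = np.random.default_rng()
    mask = _offdiag_mask(n, triangle)
    xv, yv, zv = x[mask], y[mask], z[mask]
    if method == "spearman":
        yr, zr = rankdata(yv), rankdata(zv)
    else:
        yr, zr = yv, zv
    ryz = _corr(yv, zv, method)
    rho_obs = _partial(_corr(xv, yv, method), _corr(xv, zv, method), ryz)
    n_stronger = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        xp = x[np.ix_(perm, perm)][mask]
        if method == "spearman":
            xp = rankdata(xp)
        sx = xp.std()
        if sx == 0:  # pragma: no cover - permutation of non-constant x
            continue
        rxy = float(np.corrcoef(xp, yr)[0, 1])
        rxz = float(np.corrcoef(xp, zr)[0, 1])
        if abs(_partial(rxy, rxz, ryz)) > abs(rho_obs):
            n_stronger += 1
    return MantelResult(
        rho=rho_obs,
        p_value=(n_stronger + 1) / (n_perm + 1),
        n_perm=n_perm,
        n_stronger=n_stronger,
        method=method,
        partial=True,
    )
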