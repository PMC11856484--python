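"""Compositional-data primitives for time-use analysis.

A day of movement behaviour is a *composition*: a vector of non-negative
parts (minutes in sleep, sedentary behaviour, light and moderate-to-vigorous
physical activity) that carries only relative information and is constrained
to a constant total -- 1440 min for a whole day, 390 min for the school
segment.  Standard statistics cannot be applied to the raw parts, so they
are mapped to unconstrained real coordinates with an isometric log-ratio
(ilr) transformation built from a sequential binary partition.  This module
provides the closure operation, zero replacement, the compositional
(geometric) mean, the variation matrix, and pivot-coordinate ilr bases with
forward and inverse transforms.  Everything operates on plain numpy arrays /
pandas DataFrames; a :class:`IlrBasis` carries the part order and contrast
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_PARTS",
    "SCHOOL_PARTS",
    "IlrBasis",
    "close",
    "zero_replace",
    "compositional_mean",
    "variation_matrix",
    "pivot_basis",
    "ilr",
    "ilr_inv",
]

#: canonical part order for whole-day compositions (minutes, total 1440)
DEFAULT_PARTS = ("sleep", "sb", "lpa", "mvpa")
#: part order for the in-school waking composition (minutes, total 390)
SCHOOL_PARTS = ("sb", "lpa", "mvpa")


def _as_2d(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim == 1:
        return x[None, :]
    if x.ndim != 2:
        raise ValueError(f"expected 1-D or 2-D composition array, got ndim={x.ndim}")
    return x


def close(values, total: float = 1.0) -> np.ndarray:
    """Rescale non-negative parts to sum to ``total`` (the closure operation).

    Parameters
    ----------
    values : array-like, shape (D,) or (n, D)
        Non-negative parts; each row must have a positive sum.
    total : float
        Closure constant kappa (e.g. 1440 for daily minutes).

    Returns
    -------
    ndarray with the same shape as ``values``, rows summing to ``total``.
    """
    x = np.asarray(values, dtype=float)
    arr = _as_2d(x)
    if np.any(arr < 0):
        raise ValueError("compositional parts must be non-negative")
    sums = arr.sum(axis=1)
    if np.any(sums <= 0):
        raise ValueError("cannot close a row whose parts are all zero")
    out = arr * (total / sums)[:, None]
    return out.reshape(x.shape)


def zero_replace(values, delta: float = 1.0, total: float | None = None) -> np.ndarray:
    """Multiplicative replacement of essential zeros / values below ``delta``.

    Parts smaller than ``delta`` are set to ``delta`` and the remaining parts
    are multiplicatively shrunk so each row still sums to its original total
    (or ``total`` if given).  With daily minutes the natural ``delta`` is one
    minute.  Rows where every part is below ``delta`` are rejected.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    x = np.asarray(values, dtype=float)
    arr = _as_2d(x).copy()
    totals = arr.sum(axis=1) if total is None else np.full(arr.shape[0], float(total))
    small = arr < delta
    if np.any(small.all(axis=1)):
        raise ValueError("composition with every part below delta cannot be replaced")
    n_small = small.sum(axis=1)
    shrink = (totals - delta * n_small) / totals
    if np.any(shrink <= 0):
        raise ValueError("delta too large for the closure total")
    arr = arr * shrink[:, None]
    arr[small] = delta
    return arr.reshape(x.shape)


def compositional_mean(values, total: float = 1.0) -> np.ndarray:
    """Component-wise geometric mean across rows, closed to ``total``.

    This is the centre of a compositional sample: the back-transformed
    arithmetic mean of the log-ratio coordinates.
    """
    arr = _as_2d(values)
    if np.any(arr <= 0):
        raise ValueError("compositional mean requires strictly positive parts")
    g = np.exp(np.log(arr).mean(axis=0))
    return close(g, total)


def variation_matrix(values) -> np.ndarray:
    """Matrix of variances of all pairwise log-ratios.

    Entry (j, k) is ``var(ln(x_j / x_k))`` over the rows.  Small entries mean
    the two parts are nearly proportional across the sample (high
    co-dependence); the matrix is symmetric with a zero diagonal and is
    invariant to the closure constant.
    """
    arr = _as_2d(values)
    if arr.shape[0] < 2:
        raise ValueError("variation matrix needs at least 2 compositions")
    if np.any(arr <= 0):
        raise ValueError("variation matrix requires strictly positive parts")
    logx = np.log(arr)
    d = logx.shape[1]
    out = np.zeros((d, d))
    for j in range(d):
        for k in range(j + 1, d):
            v = np.var(logx[:, j] - logx[:, k], ddof=1)
            out[j, k] = out[k, j] = v
    return out


@dataclass(frozen=True)
class IlrBasis:
    """An orthonormal ilr basis from a sequential binary partition.

    Attributes
    ----------
    parts : tuple of str
        Part names in the *original* column order of the data.
    contrast : ndarray, shape (D-1, D)
        Orthonormal balance matrix; rows sum to zero, ``B @ B.T = I``.
    pivot : str
        The part isolated by the first coordinate (pivot coordinates), for
        provenance.
    """

    parts: tuple
    contrast: np.ndarray
    pivot: str = field(default="")

    def __post_init__(self):
        B = np.asarray(self.contrast, dtype=float)
        d = len(self.parts)
        if B.shape != (d - 1, d):
            raise ValueError(f"contrast matrix must be ({d - 1}, {d})")
        if not np.allclose(B.sum(axis=1), 0, atol=1e-10):
            raise ValueError("each contrast row must sum to zero")
        if not np.allclose(B @ B.T, np.eye(d - 1), atol=1e-10):
            raise ValueError("contrast rows must be orthonormal")
        object.__setattr__(self, "contrast", B)

    @property
    def n_coords(self) -> int:
        return len(self.parts) - 1

    def coord_names(self) -> list:
        return [f"z{i + 1}" for i in range(self.n_coords)]

    def to_dict(self) -> dict:
        return {
            "parts": list(self.parts),
            "pivot": self.pivot,
            "contrast": self.contrast.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IlrBasis":
        return cls(tuple(d["parts"]), np.asarray(d["contrast"]), d.get("pivot", ""))


def pivot_basis(parts, pivot_part: str | None = None) -> IlrBasis:
    """Pivot-coordinate ilr basis isolating ``pivot_part`` in coordinate 1.

    The sequential binary partition first contrasts the pivot against the
    geometric mean of all remaining parts, then peels off the remaining parts
    one by one in their original order.  Coordinate ``i`` (1-based, in the
    rotated order p_(1)=pivot, p_(2), ..., p_(D)) is::

        z_i = sqrt((D-i)/(D-i+1)) * ln( x_(i) / gmean(x_(i+1..D)) )

    so the first coordinate carries all information about the pivot part
    relative to the rest -- the form used to read "behaviour X versus the
    remaining behaviours" off a regression coefficient.
    """
    parts = tuple(parts)
    d = len(parts)
    if d < 2:
        raise ValueError("need at least two parts")
    if pivot_part is None:
        pivot_part = parts[0]
    if pivot_part not in parts:
        raise ValueError(f"unknown part {pivot_part!r}; parts are {parts}")
    order = [pivot_part] + [p for p in parts if p != pivot_part]
    col = {p: i for i, p in enumerate(parts)}
    B = np.zeros((d - 1, d))
    for i in range(1, d):  # coordinate i contrasts order[i-1] vs order[i:]
        r = d - i  # number of parts in the denominator group
        scale = np.sqrt(r / (r + 1))
        B[i - 1, col[order[i - 1]]] = scale
        for p in order[i:]:
            B[i - 1, col[p]] = -scale / r
    return IlrBasis(parts, B, pivot=pivot_part)


def ilr(values, basis: IlrBasis) -> np.ndarray:
    """Map strictly positive compositions to ilr coordinates ``B @ ln(x)``.

    Scale invariant: the closure constant drops out because the contrast rows
    sum to zero.
    """
    x = np.asarray(values, dtype=float)
    arr = _as_2d(x)
    if arr.shape[1] != len(basis.parts):
        raise ValueError("composition width does not match basis parts")
    if np.any(arr <= 0):
        raise ValueError("ilr requires strictly positive parts")
    z = np.log(arr) @ basis.contrast.T
    return z[0] if x.ndim == 1 else z


def ilr_inv(coords, basis: IlrBasis, total: float = 1.0) -> np.ndarray:
    """Inverse ilr: ``close(exp(B.T @ z), total)``; exact inverse of :func:`ilr`."""
    z = np.asarray(coords, dtype=float)
    zz = z[None, :] if z.ndim == 1 else z
    if zz.shape[1] != basis.n_coords:
        raise ValueError("coordinate width does not match basis")
    comp = np.exp(zz @ basis.contrast)
    comp = close(comp, total)
    return comp[0] if z.ndim == 1 else comp


def compositions_frame(values, parts=DEFAULT_PARTS, ids=None) -> pd.DataFrame:
    """Convenience: wrap a composition matrix in a DataFrame with part columns."""
    arr = _as_2d(values)
    df = pd.DataFrame(arr, columns=list(parts))
    if ids is not None:
        df.insert(0, "id", list(ids))
    return df
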