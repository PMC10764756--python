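"""Affine-subspace geometry in LPC-coefficient space.

Each cognitive group (impaired / normal) is summarized by an affine
subspace: the group mean of its members' LPC coefficient vectors plus
the top-``n`` principal directions of the centered, ``1/sqrt(S-1)``
scaled group matrix (right singular vectors ordered by singular value).

A new recording's coefficient vector ``a`` is scored by its residual
distances to the two subspaces::

    D_c = || (a - m_c) - P_c P_c^T (a - m_c) ||_2

and the single-electrode index is the normalized ratio

    rho = D_imp / (D_imp + D_norm)

so rho is in [0, 1], rho < 0.5 means `a` is closer to the impaired
subspace, and high rho means normal-like. Indices from several
electrodes are combined by their geometric mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AffineSubspace",
    "SubspacePair",
    "IndexResult",
    "fit_affine_subspace",
    "subspace_distance",
    "leapd_index",
    "combine_indices",
]

#: Singular values below this fraction of the largest are treated as zero.
RANK_RTOL = 1e-12


@dataclass
class AffineSubspace:
    """Bias (mean) vector plus n orthonormal basis vectors.

    ``basis`` is stored row-wise with shape (n, K).
    """

    mean: np.ndarray = field(repr=False)
    basis: np.ndarray = field(repr=False)
    n_train: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.basis = np.asarray(self.basis, dtype=float)
        if self.basis.ndim != 2 or self.basis.shape[1] != self.mean.size:
            raise ValueError("basis must be (n, K) matching the mean length")

    @property
    def ambient_dim(self) -> int:
        return self.mean.size

    @property
    def dim(self) -> int:
        return self.basis.shape[0]

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "basis": self.basis.tolist(),
                "n_train": self.n_train}

    @classmethod
    def from_dict(cls, d: dict) -> "AffineSubspace":
        return cls(np.asarray(d["mean"], dtype=float),
                   np.asarray(d["basis"], dtype=float), d["n_train"])


@dataclass
class SubspacePair:
    """The impaired and normal subspaces for one electrode configuration."""

    impaired: AffineSubspace
    normal: AffineSubspace

    def __post_init__(self) -> None:
        if self.impaired.ambient_dim != self.normal.ambient_dim:
            raise ValueError("subspaces live in different ambient dimensions")

    def to_dict(self) -> dict:
        return {"impaired": self.impaired.to_dict(),
                "normal": self.normal.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "SubspacePair":
        return cls(AffineSubspace.from_dict(d["impaired"]),
                   AffineSubspace.from_dict(d["normal"]))


@dataclass
class IndexResult:
    """Per-electrode indices and their geometric-mean combination."""

    per_electrode: dict[str, float]
    combined: float

    @property
    def n_electrodes(self) -> int:
        return len(self.per_electrode)


def fit_affine_subspace(vectors: np.ndarray, n: int) -> AffineSubspace:
    """Fit an n-dimensional affine subspace to S points of dimension K.

    The bias is the column-wise mean; the basis comprises the first
    ``n`` right singular vectors of the centered matrix scaled by
    ``1/sqrt(S-1)`` (the scaling only affects singular values, not the
    span, but is applied verbatim). If the numeric rank of the centered
    cloud falls short of ``n`` the basis is truncated with a warning.
    """
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2:
        raise ValueError("vectors must be (S, K)")
    s_count, k_dim = vectors.shape
    if s_count < 2:
        raise ValueError("need at least 2 training points")
    if not (1 <= n < k_dim):
        raise ValueError(f"subspace dimension n={n} must satisfy 1 <= n < K={k_dim}")
    if n > s_count - 1:
        raise ValueError(f"n={n} too large for S={s_count} points (need n <= S-1)")
    mean = vectors.mean(axis=0)
    scaled = (vectors - mean) / np.sqrt(s_count - 1)
    _, svals, vh = np.linalg.svd(scaled, full_matrices=False)
    rank = int(np.sum(svals > RANK_RTOL * svals[0])) if svals[0] > 0 else 0
    if n > rank:
        warnings.warn(
            f"requested subspace dimension {n} exceeds numeric rank {rank}; "
            "truncating", RuntimeWarning, stacklevel=2)
        n = max(rank, 1)
    return AffineSubspace(mean, vh[:n], s_count)


def subspace_distance(a: np.ndarray, sub: AffineSubspace) -> float:
    """Euclidean residual of ``a`` after projection onto the subspace."""
    a = np.asarray(a, dtype=float)
    if a.shape != (sub.ambient_dim,):
        raise ValueError(
            f"vector of length {a.size} vs subspace in dimension {sub.ambient_dim}")
    resid = a - sub.mean
    coords = sub.basis @ resid
    return float(np.linalg.norm(resid - sub.basis.T @ coords))


def leapd_index(a: np.ndarray, pair: SubspacePair) -> float:
    """Normalized distance ratio rho = D_imp / (D_imp + D_norm) in [0, 1]."""
    d_imp = subspace_distance(a, pair.impaired)
    d_norm = subspace_distance(a, pair.normal)
    total = d_imp + d_norm
    if total == 0.0:
        warnings.warn("point lies in both subspaces; index defined as 0.5",
                      RuntimeWarning, stacklevel=2)
        return 0.5
    return d_imp / total


def combine_indices(values) -> float:
    """Geometric mean of single-electrode indices."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("cannot combine an empty list of indices")
    if ((values < 0) | (values > 1)).any():
        raise ValueError("indices must lie in [0, 1]")
    if (values == 0).any():
        return 0.0
    return float(np.exp(np.mean(np.log(values))))
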