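"""Tensor algebra primitives for the Tucker-2 model.

A multi-subject fMRI dataset is held as a dense three-way array of shape
``(V, T, K)`` — in-brain voxels x time points x subjects.  The Tucker-2
model approximates it as ``X ≈ G x1 S x2 B + E`` where ``S (V x N)`` holds
shared spatial maps, ``B (T x N)`` shared time courses and the core tensor
``G (N x N x K)`` carries the subject-specific spatial-temporal loadings.

Unfolding convention: the mode-n unfolding places mode n on the rows and
flattens the remaining modes in their original order with the *rightmost
remaining mode varying slowest* (Fortran order over the remaining axes).
For mode 1 this gives a ``V x (T*K)`` matrix in which the subject index is
the slowest-varying column index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg


class ShapeError(ValueError):
    """Raised when tensor/matrix operands are not conformable."""


@dataclass
class DataTensor:
    """Observed voxel x time x subject tensor plus optional voxel geometry.

    Parameters
    ----------
    values
        Real array of shape ``(V, T, K)``; every entry must be finite.
    voxel_index
        Optional ``(V, 3)`` integer array mapping each voxel row back to its
        3-D grid coordinate (used when writing maps back to volume space).
    """

    values: np.ndarray
    voxel_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ShapeError(
                f"expected a 3-way (V, T, K) tensor, got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("data tensor contains non-finite entries")
        if self.voxel_index is not None:
            self.voxel_index = np.asarray(self.voxel_index)
            if len(self.voxel_index) != self.n_voxels:
                raise ShapeError(
                    f"voxel_index has {len(self.voxel_index)} rows for "
                    f"{self.n_voxels} voxels"
                )
            uniq = {tuple(row) for row in self.voxel_index}
            if len(uniq) != self.n_voxels:
                raise ValueError("voxel_index is not injective")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class Tucker2Factors:
    """Factors of a Tucker-2 decomposition: S (V x N), B (T x N), G (N x N x K)."""

    S: np.ndarray
    B: np.ndarray
    G: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        n = self.S.shape[1]
        if self.B.shape[1] != n or self.G.shape[0] != n or self.G.shape[1] != n:
            raise ShapeError(
                f"inconsistent model order: S has {n} columns, B has "
                f"{self.B.shape[1]}, core is {self.G.shape[:2]}"
            )
        for name, arr in (("S", self.S), ("B", self.B), ("G", self.G)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"factor {name} contains non-finite entries")

    @property
    def n_components(self) -> int:
        return self.S.shape[1]


def unfold(tensor: np.ndarray, mode: int) -> np.ndarray:
    """Mode-``mode`` unfolding (1-based mode in {1, 2, 3})."""
    tensor = np.asarray(tensor)
    if mode not in (1, 2, 3):
        raise ValueError(f"mode must be 1, 2 or 3, got {mode}")
    axis = mode - 1
    return np.reshape(
        np.moveaxis(tensor, axis, 0), (tensor.shape[axis], -1), order="F"
    )


def fold(matrix: np.ndarray, mode: int, shape: tuple[int, int, int]) -> np.ndarray:
    """Inverse of :func:`unfold` for a target tensor ``shape``."""
    if mode not in (1, 2, 3):
        raise ValueError(f"mode must be 1, 2 or 3, got {mode}")
    axis = mode - 1
    rest = [shape[i] for i in range(3) if i != axis]
    full = np.reshape(matrix, (shape[axis], *rest), order="F")
    return np.moveaxis(full, 0, axis)


def mode_n_product(tensor: np.ndarray, matrix: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n product ``tensor x_mode matrix`` (1-based mode in {1, 2, 3}).

    Multiplies every mode-``mode`` fiber of ``tensor`` by ``matrix``; the
    size along ``mode`` becomes the row count of ``matrix``.
    """
    tensor = np.asarray(tensor, dtype=float)
    matrix = np.asarray(matrix, dtype=float)
    if mode not in (1, 2, 3):
        raise ValueError(f"mode must be 1, 2 or 3, got {mode}")
    if matrix.ndim != 2:
        raise ShapeError(f"mode-{mode} factor must be a matrix, got ndim={matrix.ndim}")
    axis = mode - 1
    if matrix.shape[1] != tensor.shape[axis]:
        raise ShapeError(
            f"mode-{mode} product: matrix has {matrix.shape[1]} columns but "
            f"tensor size along mode {mode} is {tensor.shape[axis]}"
        )
    out_shape = list(tensor.shape)
    out_shape[axis] = matrix.shape[0]
    return fold(matrix @ unfold(tensor, mode), mode, tuple(out_shape))


def tucker2_reconstruct(G: np.ndarray, S: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Evaluate ``G x1 S x2 B``; frontal slice k equals ``S @ G_k @ B.T``."""
    G = np.asarray(G, dtype=float)
    S = np.asarray(S, dtype=float)
    B = np.asarray(B, dtype=float)
    if G.ndim != 3:
        raise ShapeError(f"core must be 3-way, got shape {G.shape}")
    if S.shape[1] != G.shape[0] or B.shape[1] != G.shape[1]:
        raise ShapeError(
            f"cannot reconstruct: S is {S.shape}, B is {B.shape}, core is {G.shape}"
        )
    # Slice-wise GEMMs: K is small, each slice product is a large BLAS call.
    V, T, K = S.shape[0], B.shape[0], G.shape[2]
    out = np.empty((V, T, K))
    SG = np.einsum("vn,nmk->vmk", S, G, optimize=True)
    for k in range(K):
        np.matmul(SG[:, :, k], B.T, out=out[:, :, k])
    return out


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Force the largest-magnitude entry of each column nonnegative."""
    if U.size == 0:
        return U
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs


def _leading_left_singular_vectors(M: np.ndarray, n: int) -> np.ndarray:
    """Leading n left singular vectors of M, zero-padded past its rank."""
    U, s, _ = linalg.svd(M, full_matrices=False)
    tol = max(M.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    if rank < n:
        warnings.warn(
            f"unfolding rank {rank} is below the requested model order {n}; "
            "padding missing singular vectors with zero columns",
            RuntimeWarning,
            stacklevel=3,
        )
    take = min(n, rank)
    out = np.zeros((M.shape[0], n))
    out[:, :take] = _fix_signs(U[:, :take])
    return out


def hosvd_init(X: DataTensor | np.ndarray, N: int) -> Tucker2Factors:
    """Truncated HOSVD initialization of the Tucker-2 factors.

    ``S`` and ``B`` hold the N leading left singular vectors of the mode-1
    and mode-2 unfoldings; the core is the projection ``G_k = S.T X_k B``.
    Singular-vector signs are fixed (largest-magnitude entry nonnegative)
    for run-to-run reproducibility; if an unfolding has rank below N the
    missing columns are zero-padded with a warning.
    """
    values = X.values if isinstance(X, DataTensor) else np.asarray(X, dtype=float)
    V, T, K = values.shape
    if N > min(V, T):
        raise ValueError(f"model order N={N} exceeds min(V, T)={min(V, T)}")
    S = _leading_left_singular_vectors(unfold(values, 1), N)
    B = _leading_left_singular_vectors(unfold(values, 2), N)
    G = np.einsum("vn,vtk,tm->nmk", S, values, B, optimize=True)
    return Tucker2Factors(S=S, B=B, G=G)


def relative_residual(
    X: np.ndarray, G: np.ndarray, S: np.ndarray, B: np.ndarray, E: np.ndarray
) -> float:
    """Relative model residual ``||X - G x1 S x2 B - E||_F / ||X||_F``."""
    X = np.asarray(X, dtype=float)
    norm_x = float(np.linalg.norm(X))
    if norm_x == 0.0:
        raise ZeroDivisionError("relative residual undefined for a zero tensor")
    diff = X - tucker2_reconstruct(G, S, B) - np.asarray(E, dtype=float)
    return float(np.linalg.norm(diff)) / norm_x
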