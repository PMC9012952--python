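"""Performance measures: component matching, correlations, Z-map counts.

Estimated components carry permutation and sign ambiguity, so evaluation
matches each reference spatial map to the estimated column maximising the
absolute Pearson correlation |rho_c| (spatial correlation is the matching
key; the paired time-course correlation is reported, not used for
assignment).  Time courses are detrended by linear baseline correction and
normalised to [-1, 1] before display; activation extent is measured by
Z-scoring a map over in-brain voxels and counting |Z| above threshold,
inside and outside a reference mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment


@dataclass
class MatchResult:
    """Reference-to-estimate assignment with per-component correlations."""

    permutation: np.ndarray   # index into estimate columns, one per reference
    signs: np.ndarray         # +-1 making the matched spatial correlation >= 0
    rho_sm: np.ndarray        # |rho_c| of matched spatial maps
    rho_tc: np.ndarray        # |rho_c| of matched time courses

    @property
    def mean_rho_sm(self) -> float:
        return float(np.mean(self.rho_sm))

    @property
    def mean_rho_tc(self) -> float:
        return float(np.mean(self.rho_tc))


def pearson_abs(x: np.ndarray, y: np.ndarray) -> float:
    """Absolute Pearson correlation |rho_c|; 0 (with warning) for constant input."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape or x.size < 2:
        raise ValueError("inputs must be equal-length vectors of length >= 2")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("constant input to correlation; returning 0", RuntimeWarning, stacklevel=2)
        return 0.0
    return float(abs(stats.pearsonr(x, y)[0]))


def _abs_corr_matrix(ref: np.ndarray, est: np.ndarray) -> np.ndarray:
    """|rho| between every reference column (rows) and estimate column (cols)."""
    ref_c = ref - ref.mean(axis=0)
    est_c = est - est.mean(axis=0)
    ref_n = np.linalg.norm(ref_c, axis=0)
    est_n = np.linalg.norm(est_c, axis=0)
    ref_n[ref_n == 0] = np.inf
    est_n[est_n == 0] = np.inf
    return np.abs((ref_c / ref_n).T @ (est_c / est_n))


def match_components(
    S_est: np.ndarray,
    B_est: np.ndarray,
    S_ref: np.ndarray,
    B_ref: np.ndarray,
    method: str = "greedy",
) -> MatchResult:
    """Assign each reference component a unique estimated component.

    Spatial |rho_c| is the assignment key.  ``method='greedy'`` repeatedly
    takes the globally largest remaining correlation; ``method='optimal'``
    solves the linear assignment problem (Hungarian algorithm).  Signs are
    fixed so the matched spatial correlation is nonnegative.
    """
    n_ref = S_ref.shape[1]
    n_est = S_est.shape[1]
    if n_est < n_ref:
        raise ValueError(f"{n_est} estimates cannot cover {n_ref} references")
    C = _abs_corr_matrix(S_ref, S_est)

    perm = np.full(n_ref, -1, dtype=int)
    if method == "greedy":
        work = C.copy()
        for _ in range(n_ref):
            r, c = np.unravel_index(np.argmax(work), work.shape)
            perm[r] = c
            work[r, :] = -1.0
            work[:, c] = -1.0
    elif method == "optimal":
        rows, cols = linear_sum_assignment(-C)
        perm[rows] = cols
    else:
        raise ValueError(f"unknown matching method {method!r}")

    signs = np.empty(n_ref)
    rho_sm = np.empty(n_ref)
    rho_tc = np.empty(n_ref)
    for r in range(n_ref):
        c = perm[r]
        raw = np.corrcoef(S_ref[:, r], S_est[:, c])[0, 1]
        signs[r] = 1.0 if raw >= 0 else -1.0
        rho_sm[r] = abs(raw) if np.isfinite(raw) else 0.0
        rho_tc[r] = pearson_abs(B_ref[:, r], B_est[:, c])
    return MatchResult(permutation=perm, signs=signs, rho_sm=rho_sm, rho_tc=rho_tc)


def detrend_normalize(tc: np.ndarray, order: int = 1) -> np.ndarray:
    """Remove a least-squares polynomial baseline, then scale to [-1, 1].

    The default order-1 baseline is the standard linear drift correction
    applied to fMRI time courses before display.
    """
    tc = np.asarray(tc, dtype=float).ravel()
    if tc.size < 3:
        raise ValueError("time course must have length >= 3")
    t = np.arange(tc.size, dtype=float)
    coeffs = np.polynomial.polynomial.polyfit(t, tc, order)
    resid = tc - np.polynomial.polynomial.polyval(t, coeffs)
    m = np.max(np.abs(resid))
    if m < 1e-12 * max(1.0, np.max(np.abs(tc))):
        warnings.warn("time course is pure baseline; returning zeros", RuntimeWarning, stacklevel=2)
        return np.zeros_like(tc)
    return resid / m


def zmap_count(
    sm: np.ndarray, threshold: float, reference_mask: np.ndarray | None = None
) -> tuple[int, int]:
    """Z-score a spatial map and count supra-threshold voxels.

    Returns ``(total_active, inside_reference)`` where activity means
    ``|Z| > threshold`` after standardising over the supplied (in-brain)
    voxels.  ``reference_mask=None`` counts only the total.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    sm = np.asarray(sm, dtype=float).ravel()
    sd = np.std(sm)
    if sd == 0:
        raise ValueError("cannot Z-score a zero-variance map")
    z = (sm - np.mean(sm)) / sd
    active = np.abs(z) > threshold
    total = int(np.sum(active))
    if reference_mask is None:
        return total, 0
    reference_mask = np.asarray(reference_mask, dtype=bool).ravel()
    if reference_mask.shape != sm.shape:
        raise ValueError("reference mask shape does not match the map")
    return total, int(np.sum(active & reference_mask))


def aggregate_runs(rho_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and std of per-run |rho_c| values (runs on axis 0)."""
    rho = np.atleast_2d(np.asarray(rho_values, dtype=float))
    return rho.mean(axis=0), rho.std(axis=0, ddof=0)
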