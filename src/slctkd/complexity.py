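"""Analytic per-iteration complexity accounting for the constrained Tucker-2 solver.

Time and space costs per outer iteration, broken down by the updated
variable, as symbolic term sums in the problem sizes (V voxels, T time
points, K subjects, N components).  The lp spatial-sparsity term adds a
V*N cost per subject to the time budget of the S update (the elementwise
Newton steps on the auxiliary map) and a single V*N array to its storage;
the relative overhead of carrying the constraint is therefore

    time:  K*V*N / (K * (N^3 + T*N^2 + V*T + V*T*N))  ~ 1/T
    space: V*N / (T*N + K*N^2 + V*N + K*V*T)          ~ N/(K*T)
"""

from __future__ import annotations

TIME_TERMS = {
    "S": ("K*N^3", "K*T*N^2", "K*V*N(lp)", "K*V*T", "K*V*T*N"),
    "B": ("K*N^3", "K*T*N^2", "K*V*T", "K*V*T*N"),
    "G": ("K*N^2",),
    "E": ("K*V*T", "K*V*N^2", "K*V*T*N"),
}

SPACE_TERMS = {
    "S": ("T*N", "K*N^2", "V*N", "V*N(lp)", "K*V*T"),
    "B": ("T*N", "K*N^2", "V*N", "K*V*T"),
    "G": ("N^2", "K*N^2"),
    "E": ("T*N", "K*N^2", "V*N", "K*V*T"),
}

#: the single additional term contributed by the lp constraint, in both budgets
LP_EXTRA_TERM = "V*N"


def time_complexity_terms(V: int, T: int, K: int, N: int) -> dict[str, int]:
    """Leading-order per-iteration operation counts by updated variable."""
    return {
        "S": K * (N**3 + T * N**2 + V * N + V * T + V * T * N),
        "B": K * (N**3 + T * N**2 + V * T + V * T * N),
        "G": K * N**2,
        "E": K * (V * T + V * N**2 + V * T * N),
    }


def space_complexity_terms(V: int, T: int, K: int, N: int) -> dict[str, int]:
    """Leading-order per-iteration storage by updated variable."""
    base = T * N + K * N**2 + V * N + K * V * T
    return {
        "S": base + V * N,
        "B": base,
        "G": N**2 + K * N**2,
        "E": base,
    }


def lp_time_overhead(V: int, T: int, K: int, N: int) -> float:
    """Fractional time overhead of the lp spatial-sparsity term (~1/T)."""
    base = K * (N**3 + T * N**2 + V * T + V * T * N)
    return (K * V * N) / base


def lp_space_overhead(V: int, T: int, K: int, N: int) -> float:
    """Fractional space overhead of the lp spatial-sparsity term (~N/(K*T))."""
    base = T * N + K * N**2 + V * N + K * V * T
    return (V * N) / base
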