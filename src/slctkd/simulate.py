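"""Synthetic multi-subject fMRI benchmark generator.

Emulates a standard simulated fMRI benchmark: eight sparse spatial sources
on a 60 x 60 grid with 100-point time courses, mixed into K = 10 subjects.
Source roles: one task-related component driven by a block design convolved
with a canonical haemodynamic response, two transiently task-related
components (the same block design active only during a sub-window), and
five artifact-like components (slow drifts and oscillations).  Each subject
randomly loses up to ``dropout_max`` (default 10%) of the active voxels of
every source, and per-subject source amplitudes are jittered so that
subject-specific intensities are non-trivially recoverable.  Gaussian noise
is added at a prescribed SNR, defined as ``20 log10(sigma_s / sigma_n)``
with sigma the temporal standard deviation of signal and noise.

Spatial sources are parameterised Gaussian blobs thresholded to compact
supports covering at most 10% of the grid each, morphologically similar to
the published benchmark images (which are not redistributed here).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tensor_ops import DataTensor


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the synthetic benchmark.

    ``snr_db=None`` (or ``np.inf``) generates noiseless data.  For planted
    two-subgroup experiments, ``subgroup_labels`` assigns each subject to
    group 1 or 2 and ``subgroup_shift`` translates the support of source
    ``subgroup_source`` on the grid for group-2 subjects.
    """

    n_sources: int = 8
    grid: tuple[int, int] = (60, 60)
    n_timepoints: int = 100
    n_subjects: int = 10
    snr_db: float | None = None
    dropout_max: float = 0.10
    scale_jitter: float = 0.2
    subject_scales: np.ndarray | None = None
    subgroup_labels: tuple[int, ...] | None = None
    subgroup_source: int = 0
    subgroup_shift: tuple[int, int] = (12, 12)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_max < 1.0):
            raise ValueError(f"dropout_max must lie in [0, 1), got {self.dropout_max}")
        if self.snr_db is not None and not np.isfinite(self.snr_db) and self.snr_db < 0:
            raise ValueError("snr_db must be finite, +inf or None")
        if self.subgroup_labels is not None and len(self.subgroup_labels) != self.n_subjects:
            raise ValueError("subgroup_labels must have one entry per subject")

    @property
    def n_voxels(self) -> int:
        return self.grid[0] * self.grid[1]


@dataclass
class GroundTruth:
    """True factors and bookkeeping for evaluating a fit."""

    S_true: np.ndarray              # V x n_sources sparse spatial maps
    B_true: np.ndarray              # T x n_sources time courses
    subject_scales: np.ndarray      # K x n_sources amplitudes
    active_masks: np.ndarray        # K x V x n_sources post-dropout supports
    subject_maps: np.ndarray | None = None   # K x V x n_sources maps after dropout
    signal: np.ndarray | None = None         # noiseless V x T x K tensor
    noise: np.ndarray | None = None          # additive noise tensor
    subgroup_labels: np.ndarray | None = None


def hrf_double_gamma(
    t: np.ndarray,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical two-gamma haemodynamic response sampled at times ``t`` (s)."""
    from scipy.stats import gamma as gamma_dist

    peak = gamma_dist.pdf(t, peak_delay / peak_disp, scale=peak_disp)
    under = gamma_dist.pdf(t, undershoot_delay / undershoot_disp, scale=undershoot_disp)
    h = peak - undershoot_ratio * under
    norm = np.max(np.abs(h))
    return h / norm if norm > 0 else h


def _block_design(T: int, period: int = 20, tr: float = 2.0, onset_shift: int = 0) -> np.ndarray:
    """On/off square wave convolved with the canonical HRF, unit peak.

    ``onset_shift`` delays the block onsets by that many samples (a delayed
    neuronal onset), which decorrelates the response from the zero-shift
    design.
    """
    box = (((np.arange(T) - onset_shift) // (period // 2)) % 2 == 0).astype(float)
    if onset_shift > 0:
        box[:onset_shift] = 0.0
    hrf = hrf_double_gamma(np.arange(0, 32.0, tr))
    tc = np.convolve(box, hrf)[:T]
    return tc / np.max(np.abs(tc))


def _gaussian_blob(grid: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rows, cols = np.mgrid[0 : grid[0], 0 : grid[1]]
    d2 = (rows - center[0]) ** 2 + (cols - center[1]) ** 2
    return np.exp(-d2 / (2.0 * radius**2))


def generate_sources(spec: SimulationSpec) -> GroundTruth:
    """Build the true spatial maps and time courses (no subjects yet).

    Spatial maps are Gaussian blobs truncated at 40% of their peak, giving
    compact supports of at most 10% of the grid with limited pairwise
    overlap.  Time courses: source 0 is task-related (full block design),
    sources 1 and 5 are transiently task-related (block design windowed to
    the first/second half), the rest are artifact-like drifts and
    oscillations.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    H, Wd = spec.grid
    V, T, n = spec.n_voxels, spec.n_timepoints, spec.n_sources

    # Blob centres on a jittered lattice so supports barely overlap.
    n_side = int(np.ceil(np.sqrt(n)))
    if H // n_side < 6 or Wd // n_side < 6:
        raise ValueError(
            f"grid {spec.grid} too small to place {n} well-separated sources"
        )
    max_radius = min(H, Wd) / (n_side * 4.5)
    centers = []
    for i in range(n):
        gy, gx = divmod(i, n_side)
        cy = (gy + 0.5) * H / n_side + rng.uniform(-2, 2)
        cx = (gx + 0.5) * Wd / n_side + rng.uniform(-2, 2)
        centers.append((cy, cx))

    # Sources differ in spatial extent, like the heterogeneous benchmark
    # sources (large diffuse regions down to small focal blobs); homogeneous
    # sources would give a near-degenerate singular spectrum no
    # decomposition could resolve.
    S_true = np.zeros((V, n))
    budget = int(0.10 * V)
    extents = np.linspace(0.55, 1.6, n)
    for i, c in enumerate(centers):
        radius = max_radius * extents[i] * rng.uniform(0.9, 1.1)
        blob = _gaussian_blob(spec.grid, c, radius)
        blob[blob < 0.4 * blob.max()] = 0.0
        col = blob.ravel(order="F")
        active = np.flatnonzero(col)
        if active.size > budget:  # trim to the sparsity budget, keep the peak
            order = np.argsort(col[active])[::-1]
            keep = active[order[:budget]]
            trimmed = np.zeros(V)
            trimmed[keep] = col[keep]
            col = trimmed
        S_true[:, i] = col

    B_true = np.zeros((T, n))
    task = _block_design(T)
    B_true[:, 0] = task
    # Transiently task-related: a delayed-onset task response active only in
    # a sub-window (habituating / late-recruiting regions).  The onset delay
    # and the window gaps keep the three task-locked TCs well separated
    # (complementary zero-delay windows would make B_true rank deficient and
    # heavily correlated with the task TC).
    for idx, (lo, hi) in zip((1, 5), ((0, 2 * T // 5), (T // 2, 9 * T // 10))):
        if idx < n:
            win = np.zeros(T)
            win[lo:hi] = 1.0
            tc = _block_design(T, onset_shift=6) * win
            B_true[:, idx] = tc / np.max(np.abs(tc))
    t = np.arange(T)
    artifacts = [i for i in range(n) if i not in (0, 1, 5)]
    # Distinct frequency per artifact (cycles over the run, jittered) keeps
    # the artifact TCs mutually near-orthogonal: slow drifts first, then
    # physiological-like oscillations.  The bands avoid the block-design
    # fundamental (T/period cycles) and its first harmonic, so no artifact
    # masquerades as task-locked.
    base_freqs = np.array([0.75, 2.5, 3.6, 6.5, 8.4, 11.5, 13.0, 14.5])[: len(artifacts)]
    for j, idx in enumerate(artifacts):
        freq = base_freqs[j] * rng.uniform(0.9, 1.1)
        phase = rng.uniform(0, 2 * np.pi)
        tc = np.cos(2 * np.pi * freq * t / T + phase)
        if j == 0:  # lowest-frequency artifact also carries a linear drift
            tc = tc + 0.3 * (t / T - 0.5)
        B_true[:, idx] = tc / np.max(np.abs(tc))

    # Spread the source energies on a geometric ladder, with the
    # task-locked sources on the upper rungs.  Real multi-subject fMRI
    # sources span a wide energy range (dominant drifts and prominent task
    # activity down to weak focal artifacts); near-equal energies would make
    # the mode-1 singular spectrum degenerate and the sources
    # unidentifiable for any subspace-based method.
    ladder_position = np.empty(n)
    ladder_position[0] = n - 1                      # task-related: top rung
    for rank, idx in enumerate((1, 5)):
        if idx < n:
            ladder_position[idx] = n - 3 + rank     # transients just below
    remaining = [i for i in range(n) if i not in (0, 1, 5)]
    for rank, idx in enumerate(remaining):
        ladder_position[idx] = rank
    energy_ratio = 1.45
    for i in range(n):
        norm = np.linalg.norm(S_true[:, i]) * np.linalg.norm(B_true[:, i])
        if norm > 0:
            S_true[:, i] *= energy_ratio ** ladder_position[i] / norm

    scales = spec.subject_scales
    if scales is None:
        jitter = rng.uniform(-spec.scale_jitter, spec.scale_jitter, (spec.n_subjects, n))
        scales = 1.0 + jitter
    scales = np.asarray(scales, dtype=float)
    if scales.shape != (spec.n_subjects, n):
        raise ValueError(
            f"subject_scales must have shape {(spec.n_subjects, n)}, got {scales.shape}"
        )

    labels = (
        np.asarray(spec.subgroup_labels, dtype=int)
        if spec.subgroup_labels is not None
        else None
    )
    return GroundTruth(
        S_true=S_true,
        B_true=B_true,
        subject_scales=scales,
        active_masks=np.zeros((spec.n_subjects, V, n), dtype=bool),
        subgroup_labels=labels,
    )


def _shift_map(col: np.ndarray, grid: tuple[int, int], shift: tuple[int, int]) -> np.ndarray:
    img = col.reshape(grid, order="F")
    return np.roll(np.roll(img, shift[0], axis=0), shift[1], axis=1).ravel(order="F")


def apply_subject_dropout(truth: GroundTruth, spec: SimulationSpec) -> GroundTruth:
    """Per-subject random deactivation of active voxels.

    For every subject k >= 1 and source i, a fraction drawn uniformly from
    ``[0, dropout_max]`` of the active voxels is zeroed.  Subject 0 is kept
    undropped as the reference subject.  If the spec plants two subgroups,
    group-2 subjects first have the designated source's support translated
    on the grid.  Fills ``truth.subject_maps`` and ``truth.active_masks``.
    """
    rng = np.random.default_rng(spec.seed + 1)
    K, V, n = spec.n_subjects, spec.n_voxels, spec.n_sources
    maps = np.empty((K, V, n))
    masks = np.zeros((K, V, n), dtype=bool)
    for k in range(K):
        base = truth.S_true.copy()
        if (
            truth.subgroup_labels is not None
            and truth.subgroup_labels[k] == 2
        ):
            base[:, spec.subgroup_source] = _shift_map(
                base[:, spec.subgroup_source], spec.grid, spec.subgroup_shift
            )
        for i in range(n):
            col = base[:, i].copy()
            active = np.flatnonzero(col)
            if k > 0 and spec.dropout_max > 0 and active.size > 0:
                frac = rng.uniform(0.0, spec.dropout_max)
                n_drop = int(np.floor(frac * active.size))
                if n_drop > 0:
                    drop = rng.choice(active, size=n_drop, replace=False)
                    col[drop] = 0.0
            maps[k, :, i] = col
            masks[k, :, i] = col != 0
    truth.subject_maps = maps
    truth.active_masks = masks
    return truth


def assemble_and_noise(truth: GroundTruth, spec: SimulationSpec) -> tuple[DataTensor, GroundTruth]:
    """Mix maps with time courses per subject and add Gaussian noise at SNR.

    ``X_k = S_k diag(scales_k) B_true' + noise`` with noise standard
    deviation ``sigma_n = sigma_s * 10^(-snr_db/20)``; ``sigma_s`` is the
    temporal standard deviation of the noiseless signal (pooled over voxels
    and subjects).  Signal and noise are stored separately in the returned
    :class:`GroundTruth` so the realised SNR can be verified exactly.
    """
    if truth.subject_maps is None:
        raise ValueError("apply_subject_dropout must run before assembly")
    rng = np.random.default_rng(spec.seed + 2)
    K, V, T = spec.n_subjects, spec.n_voxels, spec.n_timepoints
    signal = np.empty((V, T, K))
    for k in range(K):
        signal[:, :, k] = (truth.subject_maps[k] * truth.subject_scales[k]) @ truth.B_true.T

    if spec.snr_db is None or np.isinf(spec.snr_db):
        noise = np.zeros_like(signal)
    else:
        sigma_s = float(np.std(signal - signal.mean(axis=1, keepdims=True)))
        sigma_n = sigma_s * 10.0 ** (-spec.snr_db / 20.0)
        noise = rng.normal(0.0, sigma_n, size=signal.shape)

    truth.signal = signal
    truth.noise = noise
    coords = np.stack(
        np.unravel_index(np.arange(V), spec.grid, order="F") + (np.zeros(V, dtype=int),),
        axis=1,
    )
    X = DataTensor(values=signal + noise, voxel_index=coords)
    return X, truth


def realized_snr_db(truth: GroundTruth) -> float:
    """Recompute ``20 log10(sigma_s / sigma_n)`` from stored components."""
    if truth.signal is None or truth.noise is None:
        raise ValueError("ground truth does not store signal/noise components")
    sigma_s = float(np.std(truth.signal - truth.signal.mean(axis=1, keepdims=True)))
    sigma_n = float(np.std(truth.noise))
    if sigma_n == 0.0:
        return float("inf")
    return 20.0 * np.log10(sigma_s / sigma_n)


def generate_dataset(spec: SimulationSpec) -> tuple[DataTensor, GroundTruth]:
    """Full pipeline: sources -> subject dropout -> mixing -> noise.

    The default spec yields a 3600 x 100 x 10 tensor with eight sources.
    """
    truth = generate_sources(spec)
    truth = apply_subject_dropout(truth, spec)
    return assemble_and_noise(truth, spec)
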