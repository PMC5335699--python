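"""Attractor counting: are there multiple stable synchronisation patterns?

A dynamical system is simulated repeatedly from random initial phases; each run
stabilises at some synchronisation pattern (the vector of pairwise stroboscopic
indices).  If the system has several attractors, the patterns reached from
different basins form distinct clusters.  The pattern matrix is standardised
column-wise and the cluster count is chosen by k-means with the gap statistic:

    W_k  = sum_r D_r / (2 * n_r)        (D_r = within-cluster sum of pairwise
                                         squared distances, n_r = cluster size)
    Gap(k) = E*[log W_k] - log W_k

with the expectation estimated by Monte-Carlo sampling from a uniform reference
distribution over the per-column range of the data.  The selected k is the
smallest k with Gap(k) >= Gap(k+1) - s_{k+1} (the one-standard-error rule);
k = 1 is an explicit outcome meaning "no multistability".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .kuramoto import DynamicalSystem, simulate
from .synchrony import SyncPattern, sync_pattern

__all__ = [
    "PatternEnsemble",
    "GapCurve",
    "MultistabilityResult",
    "run_ensemble",
    "standardise_columns",
    "gap_statistic_k",
    "assess",
]

K_MAX_DEFAULT = 6
N_REFERENCE_DEFAULT = 50
KMEANS_RESTARTS = 20


@dataclass(frozen=True)
class PatternEnsemble:
    """R x P matrix of synchronisation patterns from R random initialisations."""

    matrix: np.ndarray
    run_seeds: np.ndarray
    system_id: str = ""

    @property
    def n_runs(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.matrix.shape[1]

    def patterns(self, n_nodes: int) -> list[SyncPattern]:
        return [SyncPattern(row, n_nodes) for row in self.matrix]


@dataclass(frozen=True)
class GapCurve:
    """Gap values and reference-dispersion standard errors for k = 1..k_max."""

    ks: np.ndarray
    gap: np.ndarray
    se: np.ndarray
    log_w: np.ndarray
    degenerate: bool = False


@dataclass(frozen=True)
class MultistabilityResult:
    """Outcome of one system's multistability assessment.

    ``optimal_k`` >= 2 means the system is multistable.  ``sort_order`` lists
    the run permutation (grouped by cluster) under which ``pattern_correlation``
    — the R x R Pearson matrix of the sorted raw patterns — shows its diagonal
    blocks.
    """

    optimal_k: int
    labels: np.ndarray
    gap_curve: GapCurve
    pattern_correlation: np.ndarray
    sort_order: np.ndarray
    mean_pattern: np.ndarray = field(repr=False, default=None)
    system_id: str = ""

    @property
    def is_multistable(self) -> bool:
        return self.optimal_k >= 2


def run_ensemble(
    system: DynamicalSystem,
    n_runs: int = 100,
    seed: int | None = None,
    n_steps: int = 2000,
    burn_in: int = 100,
    system_id: str = "",
) -> PatternEnsemble:
    """Simulate ``n_runs`` times from seeded random initial phases.

    Per-run seeds are derived from ``seed`` via a SeedSequence, so any single
    run is replayable in isolation from its recorded seed.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    run_seeds = np.random.SeedSequence(seed).generate_state(n_runs)
    rows = []
    for r, rs in enumerate(run_seeds):
        try:
            traj = simulate(system, n_steps=n_steps, init_phases=int(rs), burn_in=burn_in)
            rows.append(sync_pattern(traj).indices)
        except Exception as exc:
            raise RuntimeError(f"run {r} (seed {rs}) failed: {exc}") from exc
    return PatternEnsemble(np.vstack(rows), run_seeds, system_id)


def standardise_columns(matrix: np.ndarray) -> np.ndarray:
    """Column-wise z-scoring (sample variance); zero-variance columns map to zero.

    Keeping constant columns (rather than dropping them) preserves the pair
    count P and the fixed pair order.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows to standardise")
    mean = matrix.mean(axis=0)
    std = matrix.std(axis=0, ddof=1)
    out = matrix - mean
    nz = std > 0
    out[:, nz] /= std[nz]
    out[:, ~nz] = 0.0
    return out


def _log_wk(data: np.ndarray, k: int, random_state: int) -> tuple[float, np.ndarray]:
    """log W_k via k-means inertia (= sum_r D_r / (2 n_r) for squared Euclidean)."""
    if k == 1:
        labels = np.zeros(data.shape[0], dtype=int)
        w = float(((data - data.mean(axis=0)) ** 2).sum())
    else:
        km = KMeans(
            n_clusters=k, n_init=KMEANS_RESTARTS, random_state=random_state
        ).fit(data)
        labels = km.labels_
        w = float(km.inertia_)
    return np.log(max(w, 1e-300)), labels


def gap_statistic_k(
    data: np.ndarray,
    k_max: int = K_MAX_DEFAULT,
    n_reference: int = N_REFERENCE_DEFAULT,
    seed: int | None = None,
    rule: str = "1se",
) -> tuple[int, GapCurve]:
    """Choose the k-means cluster count by the gap statistic.

    ``rule='1se'`` applies the one-standard-error rule (smallest k whose gap is
    within one standard error of the next gap); ``rule='max'`` takes the
    arg-max of the gap curve.  Data with all rows identical is degenerate and
    returns k = 1 with a flagged curve.
    """
    data = np.asarray(data, dtype=float)
    r = data.shape[0]
    if k_max > r:
        raise ValueError(f"k_max={k_max} exceeds number of rows {r}")
    ks = np.arange(1, k_max + 1)
    if np.allclose(data, data[0], atol=1e-12):
        curve = GapCurve(ks, np.zeros(k_max), np.zeros(k_max), np.zeros(k_max), True)
        return 1, curve
    rng = np.random.default_rng(seed)
    states = rng.integers(0, 2**31 - 1, size=1 + n_reference)

    log_w = np.array([_log_wk(data, k, int(states[0]))[0] for k in ks])

    lo, hi = data.min(axis=0), data.max(axis=0)
    log_w_ref = np.empty((n_reference, k_max))
    for b in range(n_reference):
        ref = rng.uniform(lo, hi, size=data.shape)
        log_w_ref[b] = [_log_wk(ref, k, int(states[1 + b]))[0] for k in ks]

    gap = log_w_ref.mean(axis=0) - log_w
    se = log_w_ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / n_reference)
    curve = GapCurve(ks, gap, se, log_w)

    if rule == "max":
        return int(ks[np.argmax(gap)]), curve
    if rule != "1se":
        raise ValueError(f"unknown selection rule {rule!r}")
    for i in range(k_max - 1):
        if gap[i] >= gap[i + 1] - se[i + 1]:
            return int(ks[i]), curve
    return k_max, curve


def assess(
    system: DynamicalSystem,
    n_runs: int = 100,
    k_max: int = K_MAX_DEFAULT,
    seed: int | None = None,
    n_steps: int = 2000,
    burn_in: int = 100,
    n_reference: int = N_REFERENCE_DEFAULT,
    correlate: str = "raw",
    system_id: str = "",
) -> MultistabilityResult:
    """Full multistability assessment of one dynamical system.

    Chains :func:`run_ensemble` -> :func:`standardise_columns` ->
    :func:`gap_statistic_k` -> a final k-means fit at the selected k; runs are
    then sorted by cluster and the sorted patterns cross-correlated (Pearson)
    to expose attractors as diagonal blocks.  ``correlate`` selects whether the
    raw or the standardised sorted rows are correlated.
    """
    ss = np.random.SeedSequence(seed).generate_state(3)
    ensemble = run_ensemble(
        system, n_runs=n_runs, seed=int(ss[0]), n_steps=n_steps,
        burn_in=burn_in, system_id=system_id,
    )
    std = standardise_columns(ensemble.matrix)
    optimal_k, curve = gap_statistic_k(
        std, k_max=k_max, n_reference=n_reference, seed=int(ss[1])
    )
    if optimal_k == 1 or curve.degenerate:
        labels = np.zeros(n_runs, dtype=int)
    else:
        km = KMeans(
            n_clusters=optimal_k, n_init=KMEANS_RESTARTS, random_state=int(ss[2] % 2**31)
        ).fit(std)
        labels = km.labels_
    order = np.argsort(labels, kind="stable")
    rows = ensemble.matrix if correlate == "raw" else std
    corr = _safe_corrcoef(rows[order])
    return MultistabilityResult(
        optimal_k=int(optimal_k),
        labels=labels,
        gap_curve=curve,
        pattern_correlation=corr,
        sort_order=order,
        mean_pattern=ensemble.matrix.mean(axis=0),
        system_id=system_id,
    )


def _safe_corrcoef(rows: np.ndarray) -> np.ndarray:
    """Pearson correlation of rows; zero-variance rows correlate as 0 off-diagonal."""
    std = rows.std(axis=1)
    corr = np.zeros((rows.shape[0], rows.shape[0]))
    nz = std > 0
    if nz.any():
        sub = np.corrcoef(rows[nz])
        corr[np.ix_(nz, nz)] = np.atleast_2d(sub)
    np.fill_diagonal(corr, 1.0)
    return corr
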