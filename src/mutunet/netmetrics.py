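"""Quantitative architecture metrics for bipartite interaction matrices:
specialization (H2'), weighted connectance, weighted nestedness (WNODF)
and weighted bipartite (Barber) modularity.

All metrics operate directly on real-valued interaction strengths and are
invariant to rescaling the matrix by a positive constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .community import InteractionMatrix

__all__ = [
    "ArchitectureMetrics",
    "specialization_H2",
    "connectance_weighted",
    "wnodf",
    "modularity_weighted",
    "architecture_metrics",
]


def _as_matrix(Q: Union[np.ndarray, InteractionMatrix]) -> np.ndarray:
    if isinstance(Q, InteractionMatrix):
        Q = Q.Q
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2:
        raise ValueError("Q must be a 2-D matrix")
    if np.any(Q < 0):
        raise ValueError("interaction strengths must be non-negative")
    return Q


def _entropy(p: np.ndarray, base: float = np.e) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / np.log(base))


def _h2min_greedy(r: np.ndarray, c: np.ndarray, rng: np.random.Generator,
                  randomize: bool) -> float:
    """Entropy of a greedy minimum-entropy packing with fixed marginals.

    Repeatedly allocates the largest feasible mass min(r_i, c_j) to the
    cell that admits the largest allocation (ties broken at random when
    ``randomize``); each allocation exhausts a row or a column.
    """
    r = r.copy()
    c = c.copy()
    H = 0.0
    live_r = list(np.argsort(-r))
    live_c = list(np.argsort(-c))
    while live_r and live_c:
        rr = np.array([r[i] for i in live_r])
        cc = np.array([c[j] for j in live_c])
        alloc = np.minimum.outer(rr, cc)
        best = alloc.max()
        if best <= 0:
            break
        cand = np.argwhere(alloc >= best * (1 - 1e-12))
        ai, aj = cand[rng.integers(len(cand))] if randomize and len(cand) > 1 \
            else cand[0]
        i, j = live_r[ai], live_c[aj]
        m = min(r[i], c[j])
        H -= m * np.log(m)
        r[i] -= m
        c[j] -= m
        if r[i] <= 1e-15:
            live_r.remove(i)
        if c[j] <= 1e-15:
            live_c.remove(j)
    return H


def specialization_H2(Q, n_restarts: int = 100, seed: int = 0) -> float:
    """Network-level specialization H2' in [0, 1].

    Standardizes the Shannon entropy of the interaction distribution
    between the minimum and maximum achievable under the observed
    marginals: 0 means interactions follow marginal expectation (no
    specialization), 1 means maximal partner exclusiveness.  The entropy
    minimum is located by a greedy largest-allocation packing with seeded
    randomized tie-breaks.
    """
    Q = _as_matrix(Q)
    F = Q.sum()
    if Q.size == 0 or F <= 0:
        raise ValueError("H2' undefined for an empty or all-zero matrix")
    if Q.shape[0] == 1 and Q.shape[1] == 1:
        return 0.0  # no specialization contrast exists
    p = Q / F
    H2 = _entropy(p.ravel())
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    H2max = _entropy(r) + _entropy(c)  # entropy of the marginal outer product
    rng = np.random.default_rng(seed)
    H2min = _h2min_greedy(r, c, rng, randomize=False)
    for _ in range(max(0, n_restarts - 1)):
        H2min = min(H2min, _h2min_greedy(r, c, rng, randomize=True))
    if H2max - H2min <= 1e-12:
        return 0.0
    return float(np.clip((H2max - H2) / (H2max - H2min), 0.0, 1.0))


def connectance_weighted(Q) -> float:
    """Weighted connectance: quantitative linkage density over species count.

    The linkage density is the marginal-weighted mean of the effective
    number of partners per species, 2^H with H the base-2 Shannon entropy
    of each row/column's interaction distribution; dividing by n + m gives
    the quantitative analogue of connectance.
    """
    Q = _as_matrix(Q)
    F = Q.sum()
    if Q.size == 0 or F <= 0:
        raise ValueError("connectance undefined for an all-zero matrix")
    R = Q.sum(axis=1)
    C = Q.sum(axis=0)
    ld = 0.0
    for i in np.nonzero(R)[0]:
        ld += (R[i] / F) * 2.0 ** _entropy(Q[i] / R[i], base=2)
    for j in np.nonzero(C)[0]:
        ld += (C[j] / F) * 2.0 ** _entropy(Q[:, j] / C[j], base=2)
    LDq = 0.5 * ld
    return float(LDq / sum(Q.shape))


def _wnodf_pairs(M: np.ndarray, tol: float = 1e-12) -> float:
    """Summed paired nestedness over ordered row pairs of a sorted matrix."""
    n = M.shape[0]
    fills = (M > 0).sum(axis=1)
    total = 0.0
    for u in range(n):
        for v in range(u + 1, n):
            # decreasing fill is required strictly; equal-fill pairs score 0
            if fills[u] <= fills[v] or fills[v] == 0 or fills[u] == 0:
                continue
            mask = M[v] > 0
            overlap = np.count_nonzero(mask & (M[u] - M[v] > tol))
            total += 100.0 * overlap / fills[v]
    return total


def wnodf(Q) -> float:
    """Weighted nestedness (WNODF) in [0, 100].

    Rows (and columns) are packed by decreasing fill, ties broken by
    decreasing marginal total; an ordered pair contributes only when the
    upper row is strictly more filled, counting the cells where the more
    specialized row interacts with strictly smaller positive strength.
    The index averages over all row pairs and all column pairs, matching
    the reference implementation of the weighted NODF index.
    """
    Q = _as_matrix(Q)
    if Q.shape[0] < 2 or Q.shape[1] < 2:
        raise ValueError("WNODF requires at least 2 rows and 2 columns")
    rfill = (Q > 0).sum(axis=1)
    cfill = (Q > 0).sum(axis=0)
    row_order = np.lexsort((-Q.sum(axis=1), -rfill))
    col_order = np.lexsort((-Q.sum(axis=0), -cfill))
    M = Q[row_order][:, col_order]
    n, m = M.shape
    n_pairs = n * (n - 1) / 2 + m * (m - 1) / 2
    return float((_wnodf_pairs(M) + _wnodf_pairs(M.T)) / n_pairs)


def _barber_matrix(Q: np.ndarray) -> np.ndarray:
    F = Q.sum()
    R = Q.sum(axis=1)
    C = Q.sum(axis=0)
    return Q / F - np.outer(R, C) / F ** 2


def _modularity_value(B: np.ndarray, la: np.ndarray, lp: np.ndarray) -> float:
    return float(sum(B[np.ix_(la == k, lp == k)].sum()
                     for k in np.unique(np.concatenate([la, lp]))))


def _anneal_once(B: np.ndarray, rng: np.random.Generator, steps: int,
                 T0: float, cooling: float):
    n, m = B.shape
    # start from a random coarse partition; moves and merges refine it
    K = max(2, min(n, m, 10))
    la = rng.integers(0, K, size=n)
    lp = rng.integers(0, K, size=m)
    # per-node gains: TA[i, k] = sum of B[i, j] over plants j in module k
    def build_tables():
        TA = np.zeros((n, K))
        TP = np.zeros((m, K))
        for k in range(K):
            TA[:, k] = B[:, lp == k].sum(axis=1)
            TP[:, k] = B[la == k, :].sum(axis=0)
        return TA, TP

    TA, TP = build_tables()
    q = _modularity_value(B, la, lp)
    best_q, best = q, (la.copy(), lp.copy())
    T = T0
    for step in range(steps):
        if rng.random() < 0.98:  # single-node move
            if rng.random() < n / (n + m):
                i = rng.integers(n)
                old = la[i]
                new = rng.integers(K)
                if new == old:
                    T *= cooling
                    continue
                dq = TA[i, new] - TA[i, old]
                if dq > 0 or rng.random() < np.exp(dq / max(T, 1e-12)):
                    la[i] = new
                    TP[:, old] -= B[i, :]
                    TP[:, new] += B[i, :]
                    q += dq
            else:
                j = rng.integers(m)
                old = lp[j]
                new = rng.integers(K)
                if new == old:
                    T *= cooling
                    continue
                dq = TP[j, new] - TP[j, old]
                if dq > 0 or rng.random() < np.exp(dq / max(T, 1e-12)):
                    lp[j] = new
                    TA[:, old] -= B[:, j]
                    TA[:, new] += B[:, j]
                    q += dq
        else:  # module merge proposal
            k1, k2 = rng.integers(K, size=2)
            if k1 != k2:
                dq = TA[la == k1, k2].sum() + TA[la == k2, k1].sum()
                if dq > 0 or rng.random() < np.exp(dq / max(T, 1e-12)):
                    move_a = la == k1
                    move_p = lp == k1
                    la[move_a] = k2
                    lp[move_p] = k2
                    shift_p = B[:, move_p].sum(axis=1)
                    TA[:, k2] += shift_p
                    TA[:, k1] -= shift_p
                    shift_a = B[move_a, :].sum(axis=0)
                    TP[:, k2] += shift_a
                    TP[:, k1] -= shift_a
                    q += dq
        if q > best_q:
            best_q, best = q, (la.copy(), lp.copy())
        T *= cooling
    return best_q, best


@dataclass
class ModularityResult:
    value: float
    animal_modules: np.ndarray
    plant_modules: np.ndarray
    seed: int


def modularity_weighted(Q, seed: int = 0, n_restarts: int = 5,
                        steps: int = 10000, T0: float = 1.0,
                        cooling: float = 0.995) -> ModularityResult:
    """Weighted bipartite (Barber) modularity by simulated annealing.

    Maximizes sum_ij [q_ij/F - R_i C_j / F^2] over joint module labels of
    animals and plants (delta on shared module), using single-node moves
    and module merges under geometric cooling; best of ``n_restarts``
    seeded restarts, deterministic given the seed.
    """
    Q = _as_matrix(Q)
    if Q.sum() <= 0:
        raise ValueError("modularity undefined for an all-zero matrix")
    B = _barber_matrix(Q)
    rng = np.random.default_rng(seed)
    best_q = -np.inf
    best = None
    for _ in range(n_restarts):
        qv, labels = _anneal_once(B, rng, steps, T0, cooling)
        if qv > best_q:
            best_q, best = qv, labels
    la, lp = best
    return ModularityResult(float(best_q), la, lp, seed)


@dataclass
class ArchitectureMetrics:
    """The four architecture metrics of one quantitative network."""

    SPE: float   # specialization H2' in [0, 1]
    CON: float   # weighted connectance
    NEST: float  # WNODF in [0, 100]
    MOD: float   # weighted bipartite modularity
    animal_modules: Optional[np.ndarray] = None
    plant_modules: Optional[np.ndarray] = None
    seed: int = 0


def architecture_metrics(Q, seed: int = 0, **mod_kwargs) -> ArchitectureMetrics:
    """Compute SPE, CON, NEST and MOD for one interaction matrix."""
    Q = _as_matrix(Q)
    mod = modularity_weighted(Q, seed=seed, **mod_kwargs)
    return ArchitectureMetrics(
        SPE=specialization_H2(Q),
        CON=connectance_weighted(Q),
        NEST=wnodf(Q),
        MOD=mod.value,
        animal_modules=mod.animal_modules,
        plant_modules=mod.plant_modules,
        seed=seed,
    )
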