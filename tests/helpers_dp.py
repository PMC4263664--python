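"""Brute-force enumeration oracle for the closed-path dynamic program.

Enumerates every delta-feasible closed path (|row step| <= delta between
adjacent columns, |last - first| <= delta), scores it as the sum of admissible
step costs w*(1-F) plus the closure penalty gamma*|last - first|, and selects
the minimum under the same tie-break order the DP documents: cost, then last
row, then first row, then rows N-2 .. 1 (each toward the smaller index).
Independent of the DP implementation: no recursion sharing, plain cumulative
sums over explicit move sequences.
"""

from functools import lru_cache

import numpy as np


@lru_cache(maxsize=32)
def _move_sequences(delta: int, n_moves: int) -> np.ndarray:
    grids = np.meshgrid(*([np.arange(-delta, delta + 1)] * n_moves),
                        indexing="ij")
    return np.stack(grids, axis=-1).reshape(-1, n_moves).astype(np.int16)


def brute_force_closed_path(F: np.ndarray, B: np.ndarray, delta: int,
                            w: float, gamma: float):
    """Return (path, total_cost) of the optimal closed path, or None."""
    M, N = F.shape
    step = np.where(B, w * (1.0 - F), np.inf)
    moves = _move_sequences(delta, N - 1)
    best_key = None
    best = None
    for start in range(M):
        if not np.isfinite(step[start, 0]):
            continue
        rows = np.empty((moves.shape[0], N), dtype=np.int16)
        rows[:, 0] = start
        np.cumsum(moves, axis=1, out=rows[:, 1:])
        rows[:, 1:] += start
        ok = np.all((rows >= 0) & (rows < M), axis=1)
        ok &= np.abs(rows[:, -1] - rows[:, 0]) <= delta
        rows = rows[ok]
        if rows.size == 0:
            continue
        cost = np.zeros(len(rows))
        for j in range(N):
            cost += step[rows[:, j], j]
        cost += gamma * np.abs(rows[:, -1] - rows[:, 0]).astype(float)
        finite = np.isfinite(cost)
        rows, cost = rows[finite], cost[finite]
        if rows.size == 0:
            continue
        cmin = cost.min()
        ties = cost == cmin
        rows_t, cost_t = rows[ties], cost[ties]
        # lexsort: least-significant key first
        keys = ([rows_t[:, j] for j in range(1, N - 1)]
                + [rows_t[:, 0], rows_t[:, -1], cost_t])
        idx = np.lexsort(keys)[0]
        key = ((cost_t[idx], rows_t[idx, -1], rows_t[idx, 0])
               + tuple(rows_t[idx, N - 2:0:-1]))
        if best_key is None or key < best_key:
            best_key = key
            best = (rows_t[idx].astype(int), float(cost_t[idx]))
    return best


def random_dp_instance(rng: np.random.Generator):
    """A random polar feature map + admissibility mask on a dyadic grid."""
    M = int(rng.integers(5, 9))
    N = int(rng.integers(6, 11))
    delta = int(rng.integers(1, 3))
    gamma = float(rng.choice([0.0, 0.5]))
    F = rng.integers(0, 65, size=(M, N)) / 64.0
    B = rng.random((M, N)) < 0.85
    for j in range(N):
        if not B[:, j].any():
            B[int(rng.integers(0, M)), j] = True
    return F, B, delta, gamma
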