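"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (pair counting, exhaustive sweeps,
depth-3 path enumeration, per-cell stencils, textbook IRLS) kept separate
from the library so each test compares two genuinely different routes to
the same quantity.
"""

from __future__ import annotations

import math

import numpy as np


def auc_pair_counting(scores, labels) -> float:
    """O(n^2) Mann-Whitney AUC: wins + half-credit ties over all pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def tss_exhaustive(scores, labels) -> tuple[float, float]:
    """Exhaustive sweep over every distinct score as a >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    best_tss, best_thr = -np.inf, None
    for thr in sorted(set(scores.tolist())):
        pred = scores >= thr
        sens = np.mean(pred[labels])
        spec = np.mean(~pred[~labels])
        tss = sens + spec - 1.0
        if tss > best_tss:  # strict: first (smallest) threshold wins ties
            best_tss, best_thr = tss, thr
    return float(best_tss), float(best_thr)


def horn_slope_aspect_cell(z3x3: np.ndarray, cell_size: float) -> tuple[float, float, float]:
    """Per-cell Horn stencil: (slope_deg, northness, eastness)."""
    (a, b, c), (d, _, f), (g, h, i) = z3x3
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cell_size)
    dzdy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8 * cell_size)
    grad = math.hypot(dzdx, dzdy)
    slope = math.degrees(math.atan(grad))
    if grad == 0:
        return slope, 0.0, 0.0
    aspect = math.atan2(-dzdx, -dzdy)
    return slope, math.cos(aspect), math.sin(aspect)


def wls_predict(Xc: np.ndarray, y: np.ndarray, w: np.ndarray,
                x_eval: np.ndarray) -> float:
    """Weighted least squares solved via explicit normal equations."""
    Xc1 = np.column_stack([np.ones(len(Xc)), Xc])
    A = Xc1.T @ (w[:, None] * Xc1)
    r = Xc1.T @ (w * y)
    theta = np.linalg.solve(A, r)
    return float(np.concatenate([[1.0], x_eval]) @ theta)


def irls_logistic(X: np.ndarray, y: np.ndarray, tol: float = 1e-12,
                  max_iter: int = 100) -> np.ndarray:
    """Textbook iteratively reweighted least squares for a logistic GLM.

    ``X`` must already include the intercept column.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / np.clip(w, 1e-12, None)
        A = X.T @ (w[:, None] * X)
        beta_new = np.linalg.solve(A, X.T @ (w * z))
        if np.max(np.abs(beta_new - beta)) < tol:
            return beta_new
        beta = beta_new
    return beta


def stepping_stones_dfs(suit: np.ndarray, occ: np.ndarray, adjacency: int = 8
                        ) -> np.ndarray:
    """Depth-3 path enumeration over every cell; suit is (3, nr, nc) booleans."""
    nr, nc = occ.shape
    if adjacency == 8:
        moves = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    else:
        moves = [(-1, 0), (1, 0), (0, -1), (0, 1)]

    def nbrs(r, c):
        for dr, dc in moves:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc:
                yield rr, cc

    out = np.zeros((nr, nc), dtype=bool)
    for r in range(nr):
        for c in range(nc):
            if occ[r, c] or not suit[0, r, c]:
                continue
            if not any(occ[rr, cc] for rr, cc in nbrs(r, c)):
                continue
            found = False
            for r2, c2 in list(nbrs(r, c)) + [(r, c)]:
                if not suit[1, r2, c2]:
                    continue
                for r3, c3 in list(nbrs(r2, c2)) + [(r2, c2)]:
                    if suit[2, r3, c3]:
                        found = True
                        break
                if found:
                    break
            out[r, c] = found
    return out


def nearest_suitable_scan(occ_rc: np.ndarray, suitable: np.ndarray,
                          cell_size: float) -> np.ndarray:
    """Min-over-all-suitable-cells Euclidean centre distance (km)."""
    rows, cols = np.nonzero(suitable)
    out = np.full(len(occ_rc), np.inf)
    for k, (r, c) in enumerate(occ_rc):
        best = np.inf
        for rr, cc in zip(rows, cols):
            d = math.hypot((rr - r) * cell_size, (cc - c) * cell_size)
            best = min(best, d)
        out[k] = best / 1000.0
    return out
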