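"""Uncertainty-weighted positive matrix factorization (PMF).

Receptor-model source apportionment: a nonnegative bilinear decomposition
X ~ G F minimizing the uncertainty-weighted objective

    Q = sum_ij ((x_ij - sum_k g_ik f_kj) / u_ij)^2

solved by alternating exact nonnegative least squares (one weighted NNLS per
sample row / species column), multi-start from random nonnegative
initializations. This is the plain least-squares functional of EPA PMF;
robust reweighting, FPEAK rotations and bootstrap error estimation are
intentionally out of scope.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "PMFInput",
    "PMFResult",
    "build_uncertainty",
    "pmf_fit",
    "q_expected",
    "contributions",
    "match_factors",
    "factor_scan",
]

#: floor applied to uncertainties for zero concentrations
UNCERTAINTY_EPS = 1e-12


@dataclass(frozen=True)
class PMFInput:
    """Sample-by-species concentration matrix with per-cell uncertainties."""

    X: np.ndarray
    U: np.ndarray
    species: tuple[str, ...] = ()
    sample_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        U = np.asarray(self.U, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "U", U)
        if X.ndim != 2 or X.shape != U.shape:
            raise ValueError("X and U must be 2-D with identical shapes")
        if np.any(X < 0):
            raise ValueError("concentrations must be nonnegative")
        if np.any(U <= 0):
            raise ValueError("uncertainties must be strictly positive")
        if not self.species:
            object.__setattr__(
                self, "species", tuple(f"s{j}" for j in range(X.shape[1]))
            )
        if not self.sample_ids:
            object.__setattr__(
                self, "sample_ids", tuple(str(i) for i in range(X.shape[0]))
            )
        if len(self.species) != X.shape[1] or len(self.sample_ids) != X.shape[0]:
            raise ValueError("species / sample_ids lengths must match X")


@dataclass(frozen=True)
class PMFResult:
    """Fitted factorization: G (sample x factor), F (factor x species, rows sum to 1)."""

    G: np.ndarray
    F: np.ndarray
    Q: float
    Q_expected: float
    n_starts: int
    converged: bool
    seed: int
    q_history: tuple[float, ...] = field(repr=False, default=())


def build_uncertainty(
    X: np.ndarray,
    K_map: Mapping[str, float],
    species: Sequence[str],
    eps: float = UNCERTAINTY_EPS,
) -> np.ndarray:
    """Per-cell uncertainty u_ij = K_j * x_ij, floored at ``eps`` where zero.

    K is the relative measurement uncertainty per species (e.g. 0.10 for the
    chromatography/EPR analytes, 0.15 for routinely monitored pollutants).
    """
    X = np.asarray(X, dtype=float)
    missing = [s for s in species if s not in K_map]
    if missing:
        raise KeyError(f"no uncertainty fraction K for species: {missing}")
    K = np.array([K_map[s] for s in species], dtype=float)
    if np.any((K <= 0) | (K >= 1)):
        raise ValueError("K values must lie in (0, 1)")
    U = K[np.newaxis, :] * X
    return np.maximum(U, eps)


def q_value(X: np.ndarray, U: np.ndarray, G: np.ndarray, F: np.ndarray) -> float:
    """The weighted least-squares objective Q."""
    resid = (X - G @ F) / U
    return float(np.sum(resid * resid))


def q_expected(input: PMFInput, k: int) -> float:
    """Degrees-of-freedom expectation of Q: n*m - k*(n+m)."""
    n, m = input.X.shape
    q_exp = n * m - k * (n + m)
    if q_exp <= 0:
        raise ValueError(
            f"k={k} over-parameterizes a {n}x{m} matrix (Q_expected={q_exp})"
        )
    return float(q_exp)


def _update_G(X, W, G, F):
    """Exact weighted NNLS update of each sample row of G."""
    for i in range(X.shape[0]):
        w = W[i]
        A = (F * w).T  # (m, k)
        G[i], _ = nnls(A, X[i] * w)
    return G


def _update_F(X, W, G, F):
    """Exact weighted NNLS update of each species column of F."""
    for j in range(X.shape[1]):
        w = W[:, j]
        A = G * w[:, np.newaxis]  # (n, k)
        F[:, j], _ = nnls(A, X[:, j] * w)
    return F


def _normalize(G: np.ndarray, F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale so F rows sum to 1, absorbing scale into G; drop-dead factors get 0."""
    row_sums = F.sum(axis=1)
    safe = np.where(row_sums > 0, row_sums, 1.0)
    return G * safe[np.newaxis, :], F / safe[:, np.newaxis]


def pmf_fit(
    input: PMFInput,
    k: int,
    n_starts: int = 20,
    seed: int = 0,
    max_iter: int = 5000,
    tol: float = 1e-8,
) -> PMFResult:
    """Fit a k-factor PMF model by multi-start alternating weighted NNLS.

    Each half-update solves its subproblem exactly, so Q is non-increasing
    along every iteration path; the best-Q start wins. Convergence is a
    relative Q change below ``tol``. If no start converges the best effort
    is returned with ``converged=False`` rather than raising.
    """
    X, U = input.X, input.U
    n, m = X.shape
    if not 0 < k < min(n, m):
        raise ValueError(f"k must be in (0, min(n, m)={min(n, m)})")
    W = 1.0 / U
    rng = np.random.default_rng(seed)
    scale = max(X.mean(), np.finfo(float).tiny)

    best: tuple[float, np.ndarray, np.ndarray, bool, tuple[float, ...]] | None = None
    for _ in range(max(n_starts, 1)):
        G = rng.uniform(0.1, 1.0, size=(n, k)) * np.sqrt(scale)
        F = rng.uniform(0.1, 1.0, size=(k, m)) * np.sqrt(scale)
        q_prev = q_value(X, U, G, F)
        history = [q_prev]
        converged = False
        for _ in range(max_iter):
            G = _update_G(X, W, G, F)
            F = _update_F(X, W, G, F)
            q = q_value(X, U, G, F)
            if q >= q_prev:
                # exact-arithmetic ALS cannot increase Q: we are at the
                # floating-point floor. A genuine increase is a fault.
                if q > q_prev * (1 + 1e-6) and q - q_prev > 1e-10 * history[0]:
                    raise AssertionError("Q increased during ALS; numerical fault")
                converged = True
                break
            history.append(q)
            if q_prev - q <= tol * max(q_prev, 1e-300):
                converged = True
                break
            q_prev = q
        if best is None or history[-1] < best[0]:
            best = (history[-1], G, F, converged, tuple(history))

    assert best is not None
    q_best, G, F, converged, history = best
    G, F = _normalize(G, F)
    return PMFResult(
        G=G,
        F=F,
        Q=q_best,
        Q_expected=q_expected(input, k),
        n_starts=n_starts,
        converged=converged,
        seed=seed,
        q_history=history,
    )


def contributions(result: PMFResult, input: PMFInput) -> "pd.DataFrame":
    """Percent contribution of each factor to each species' reconstructed mass.

    contribution(k -> j) = 100 * sum_i g_ik f_kj / sum_i xhat_ij. Columns sum
    to 100 within 0.1 except where the reconstructed total is zero, which is
    reported as NaN (flagged, not hidden).
    """
    import pandas as pd

    G, F = result.G, result.F
    per_factor = G.sum(axis=0)[:, np.newaxis] * F  # (k, m) total mass per factor
    totals = per_factor.sum(axis=0)  # reconstructed species totals
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(totals > 0, 100.0 * per_factor / totals, np.nan)
    return pd.DataFrame(
        pct,
        index=[f"factor_{i + 1}" for i in range(G.shape[1])],
        columns=list(input.species),
    )


def match_factors(
    F_est: np.ndarray, F_true: np.ndarray
) -> tuple[tuple[int, ...], np.ndarray, bool]:
    """Align estimated factors to ground truth by maximal mean cosine similarity.

    Returns (permutation p with F_est[p[i]] ~ F_true[i], per-factor cosines,
    exact flag). Exhaustive search for k <= 8; greedy beyond, flagged by
    ``exact=False``.
    """
    F_est = np.asarray(F_est, dtype=float)
    F_true = np.asarray(F_true, dtype=float)
    if F_est.shape[0] != F_true.shape[0]:
        raise ValueError("factor counts differ")
    k = F_est.shape[0]

    def unit(M):
        norms = np.linalg.norm(M, axis=1, keepdims=True)
        return M / np.where(norms > 0, norms, 1.0)

    S = unit(F_true) @ unit(F_est).T  # S[i, j] = cos(true_i, est_j)
    if k <= 8:
        best_perm, best_score = None, -np.inf
        for perm in itertools.permutations(range(k)):
            score = S[np.arange(k), perm].sum()
            if score > best_score:
                best_perm, best_score = perm, score
        return tuple(best_perm), S[np.arange(k), best_perm], True
    # greedy fallback
    perm = [-1] * k
    taken = set()
    for i in np.argsort(-S.max(axis=1)):
        j = int(np.argmax([S[i, j] if j not in taken else -np.inf for j in range(k)]))
        perm[i] = j
        taken.add(j)
    return tuple(perm), S[np.arange(k), perm], False


def factor_scan(
    input: PMFInput,
    k_range: Sequence[int] = (3, 4, 5, 6, 7),
    n_starts: int = 5,
    seed: int = 0,
) -> "pd.DataFrame":
    """Q / Q_expected diagnostics over a range of factor counts.

    The factor count is a user decision; this scan is the evidence table a
    practitioner reads to pick it.
    """
    import pandas as pd

    rows = []
    for k in k_range:
        res = pmf_fit(input, k=k, n_starts=n_starts, seed=seed)
        rows.append(
            {
                "k": k,
                "Q": res.Q,
                "Q_expected": res.Q_expected,
                "Q_over_Qexp": res.Q / res.Q_expected,
                "converged": res.converged,
            }
        )
    return pd.DataFrame(rows)
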