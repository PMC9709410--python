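"""Analysis (cosparse) representation: sparseness measures and ADLA.

The analysis model seeks a dictionary Omega whose rows "analyse" the signal:
``Omega @ z`` should be sparse (many near-zero analysis coefficients; their
count is the cosparsity).  Dictionary, code and denoised signal are learned
jointly by alternating minimization of

    M(X) + lam * ||T - Z||_F^2 + beta * ||Omega Z - X||_F^2
    subject to ||q_i||_2 = 1 for every row q_i of Omega,

where M is a sparseness measure (l0 / l1 / l2 norms, or the determinant
measure det(Y Y^T) for non-negative row-normalized codes, which is 1 exactly
for mutually orthogonal single-support rows and 0 for rank-deficient ones).

Sub-updates:

* Omega: per-row least squares under an exact unit-norm constraint, solved on
  the eigendecomposition of Z Z^T via the secular equation (trust-region
  style).  A "project" variant (plain least squares, rows rescaled afterwards)
  is also provided; it is cheaper but is not the exact constrained minimizer,
  so only the exact variant guarantees a non-increasing objective.
* X: elementwise proximal step — soft threshold at 1/(2 beta) for l1, hard
  threshold at sqrt(1/beta) for l0, closed-form shrinkage for l2, and a
  projected-gradient ascent on det for the determinant measure.
* Z: the linear system (lam I + beta Omega^T Omega) Z = lam T + beta Omega^T X,
  solved through an LU factorization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy.optimize import brentq

logger = logging.getLogger(__name__)

MEASURES = ("l0", "l1", "l2", "determinant")


class MeasureError(ValueError):
    pass


@dataclass(frozen=True)
class ADLAConfig:
    """Configuration of the alternating dictionary learner.

    ``lam`` weighs data fidelity ||T - Z||, ``beta`` code fidelity
    ||Omega Z - X||; both must be positive.  ``tol`` is the relative change of
    the objective between outer sweeps below which iteration stops.
    """

    n_atoms: int
    lam: float = 1.0
    beta: float = 0.5
    measure: str = "l1"
    max_iter: int = 50
    tol: float = 1e-5
    seed: int = 0
    zero_tol: float = 1e-3
    dict_update: str = "exact"   # "exact" | "project"
    # The plain alternating scheme has a degenerate attractor: every row
    # drifts to the single direction of minimal post-threshold sparsity and
    # the dictionary collapses to one repeated atom.  As in synthesis
    # dictionary learning (unused-atom replacement), near-duplicate rows are
    # re-drawn randomly when enabled; the pure three-sub-update scheme (whose
    # objective is provably non-increasing) is obtained by disabling it.
    replace_duplicate_atoms: bool = True
    duplicate_coherence: float = 0.999

    def __post_init__(self) -> None:
        if self.n_atoms < 1:
            raise ValueError("n_atoms must be >= 1")
        if not (self.lam > 0 and self.beta > 0):
            raise ValueError("lam and beta must be > 0")
        if self.measure not in MEASURES:
            raise MeasureError(
                f"unknown measure {self.measure!r}; valid: {MEASURES}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.tol > 0:
            raise ValueError("tol must be > 0")
        if self.dict_update not in ("exact", "project"):
            raise ValueError("dict_update must be 'exact' or 'project'")


@dataclass
class AnalysisModel:
    """Fitted analysis dictionary with its code and denoised signals."""

    Omega: np.ndarray            # (n_atoms, p), unit-norm rows
    X: np.ndarray                # (n_atoms, N)
    Z: np.ndarray                # (p, N)
    T: np.ndarray                # (p, N) observed signals
    objective_trace: list[float] = field(default_factory=list)
    config: ADLAConfig | None = None

    def encode(self, segments: np.ndarray) -> np.ndarray:
        """Analysis codes Omega @ S^T for row-wise segments (n, p)."""
        return self.Omega @ np.asarray(segments, dtype=float).T


def sparsity_measure(g: np.ndarray, kind: str, zero_tol: float = 1e-9) -> float:
    """Scalar sparseness of a vector: l0 count, l1 sum or l2 norm."""
    g = np.asarray(g, dtype=float)
    if not np.all(np.isfinite(g)):
        raise ValueError("g must be finite")
    if kind == "l0":
        return float(np.count_nonzero(np.abs(g) > zero_tol))
    if kind == "l1":
        return float(np.abs(g).sum())
    if kind == "l2":
        return float(np.linalg.norm(g))
    raise MeasureError(f"unknown kind {kind!r}; valid: ('l0', 'l1', 'l2')")


def determinant_measure(Y: np.ndarray, normalize: bool = True) -> float:
    """det(Y Y^T) of a non-negative matrix, optionally row-normalized.

    For row-normalized input the value lies in [0, 1]: it equals 1 exactly
    when every row has a single non-zero element and the rows are mutually
    orthogonal, and 0 when rows are linearly dependent.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[None, :]
    if np.any(Y < 0):
        raise ValueError("determinant measure requires non-negative entries")
    if normalize:
        norms = np.linalg.norm(Y, axis=1)
        if np.any(norms == 0):
            raise ValueError("cannot row-normalize: zero row present")
        Y = Y / norms[:, None]
    gram = Y @ Y.T
    det = float(np.linalg.det(gram))
    # clamp tiny negative round-off for PSD Gram matrices
    if -1e-12 < det < 0:
        det = 0.0
    return det


def cosparsity(Omega: np.ndarray, z: np.ndarray, zero_tol: float = 1e-9) -> int:
    """Number of near-zero entries of Omega @ z."""
    Omega = np.asarray(Omega, dtype=float)
    z = np.asarray(z, dtype=float)
    if Omega.shape[1] != z.shape[0]:
        raise ValueError(
            f"shape mismatch: Omega is {Omega.shape}, z has length {z.shape[0]}")
    return int(np.count_nonzero(np.abs(Omega @ z) <= zero_tol))


# ---------------------------------------------------------------------------
# sub-updates


def _matrix_measure(X: np.ndarray, measure: str, zero_tol: float) -> float:
    if measure == "determinant":
        # minimized objective uses -det: larger det = sparser
        Xp = np.abs(X)
        norms = np.linalg.norm(Xp, axis=1)
        if np.any(norms == 0):
            return 0.0
        return -determinant_measure(Xp, normalize=True)
    return sparsity_measure(X.ravel(), measure, zero_tol)


def objective(T, Omega, X, Z, config: ADLAConfig) -> float:
    """The regularized analysis-learning objective."""
    fid = np.linalg.norm(T - Z) ** 2
    code = np.linalg.norm(Omega @ Z - X) ** 2
    return _matrix_measure(X, config.measure, config.zero_tol) \
        + config.lam * fid + config.beta * code


def _row_constrained_ls(evals: np.ndarray, U: np.ndarray, b: np.ndarray) -> np.ndarray:
    """argmin_q q^T A q - 2 b^T q  s.t. ||q|| = 1, A = U diag(evals) U^T (PSD).

    Solved through the secular equation ||(A + mu I)^{-1} b|| = 1 on
    mu > -min(evals); the hard case (b orthogonal to the bottom eigenspace)
    falls back to a unit vector in that eigenspace.
    """
    beta_coef = U.T @ b
    lo = evals.min()

    def norm2(mu: float) -> float:
        return float(np.sum((beta_coef / (evals + mu)) ** 2))

    if np.allclose(b, 0):
        return U[:, np.argmin(evals)]

    # norm2 is decreasing in mu on (-lo, inf)
    eps = 1e-12 * max(1.0, abs(lo))
    mu_lo = -lo + eps
    val_lo = norm2(mu_lo)
    if val_lo < 1.0:
        # hard case: even at the boundary the norm is short; pad with the
        # bottom eigenvector to reach the sphere
        mask = np.abs(evals - lo) < 1e-10 * max(1.0, abs(lo))
        q = U @ (beta_coef / (evals - lo + eps))
        deficit = max(1.0 - float(q @ q), 0.0)
        v = U[:, np.argmax(mask)]
        return q + np.sqrt(deficit) * v
    width = 1.0
    mu_hi = mu_lo + width
    while norm2(mu_hi) > 1.0:
        width *= 2.0
        mu_hi = mu_lo + width
    mu = brentq(lambda m: norm2(m) - 1.0, mu_lo, mu_hi, xtol=1e-13)
    q = U @ (beta_coef / (evals + mu))
    return q / np.linalg.norm(q)


def update_dictionary(Z: np.ndarray, X: np.ndarray, method: str = "exact",
                      ridge: float | None = None) -> np.ndarray:
    """Minimize ||Omega Z - X||_F^2 over Omega with unit-norm rows.

    ``method="exact"`` solves each row's norm-constrained least squares
    exactly; ``method="project"`` takes the unconstrained least-squares
    solution X Z^T (Z Z^T)^{-1} and rescales each row to unit norm.
    Rank-deficient Z is ridge-regularized (default 1e-8 * trace(ZZ^T)/p).
    """
    Z = np.asarray(Z, dtype=float)
    X = np.asarray(X, dtype=float)
    p = Z.shape[0]
    G = Z @ Z.T
    if ridge is None:
        rank = np.linalg.matrix_rank(G)
        if rank < p:
            ridge = 1e-8 * np.trace(G) / p
            if ridge == 0:
                raise np.linalg.LinAlgError(
                    "Z has zero energy; dictionary update undefined — "
                    "supply a positive ridge")
            logger.info("update_dictionary: rank-deficient Z, ridge %g", ridge)
        else:
            ridge = 0.0
    G = G + ridge * np.eye(p)
    B = Z @ X.T                          # (p, n_atoms) columns = rhs per row
    if method == "project":
        Omega = np.linalg.solve(G, B).T  # = X Z^T (Z Z^T)^-1
        norms = np.linalg.norm(Omega, axis=1)
        if np.any(norms == 0):
            raise np.linalg.LinAlgError(
                "least-squares dictionary row collapsed to zero; cannot "
                "normalize (degenerate target X)")
        return Omega / norms[:, None]
    if method != "exact":
        raise ValueError("method must be 'exact' or 'project'")
    evals, U = np.linalg.eigh(G)
    rows = [_row_constrained_ls(evals, U, B[:, i]) for i in range(X.shape[0])]
    Omega = np.vstack(rows)
    return Omega / np.linalg.norm(Omega, axis=1)[:, None]


def update_code(Omega: np.ndarray, Z: np.ndarray, measure: str,
                beta: float, zero_tol: float = 1e-3) -> np.ndarray:
    """argmin_X  M(X) + beta ||Omega Z - X||_F^2 (elementwise prox or PGA)."""
    if not beta > 0:
        raise ValueError("beta must be > 0")
    V = Omega @ Z
    if measure == "l1":
        thr = 1.0 / (2.0 * beta)
        return np.sign(V) * np.maximum(np.abs(V) - thr, 0.0)
    if measure == "l0":
        thr = np.sqrt(1.0 / beta)
        return np.where(np.abs(V) > thr, V, 0.0)
    if measure == "l2":
        # min ||X||_2(vec) + beta||V-X||^2: shrink the whole matrix radially
        nv = np.linalg.norm(V)
        if nv == 0:
            return V.copy()
        return max(1.0 - 1.0 / (2.0 * beta * nv), 0.0) * V
    if measure == "determinant":
        return _determinant_code_update(V, beta)
    raise MeasureError(f"unknown measure {measure!r}; valid: {MEASURES}")


def _determinant_code_update(V: np.ndarray, beta: float,
                             max_steps: int = 25) -> np.ndarray:
    """Projected gradient with backtracking on -det(Xn Xn^T) + beta||V-X||^2.

    Codes are kept non-negative (the determinant measure is defined for
    non-negative matrices); Xn denotes X with rows rescaled to unit norm.
    """
    X = np.maximum(V, 0.0)
    if np.any(np.linalg.norm(X, axis=1) == 0):
        # nothing to sharpen in an empty row; keep the projection
        return X

    def f(X_):
        return -determinant_measure(X_, normalize=True) \
            + beta * np.linalg.norm(V - X_) ** 2

    fx = f(X)
    step = 1.0 / (2.0 * beta)
    for _ in range(max_steps):
        norms = np.linalg.norm(X, axis=1)
        Xn = X / norms[:, None]
        G = Xn @ Xn.T
        det = np.linalg.det(G)
        try:
            Ginv = np.linalg.inv(G + 1e-12 * np.eye(G.shape[0]))
        except np.linalg.LinAlgError:
            break
        # d det / d Xn, chained through row normalization
        dXn = 2.0 * det * (Ginv @ Xn)
        inner = np.sum(dXn * Xn, axis=1, keepdims=True)
        ddet_dX = (dXn - inner * Xn) / norms[:, None]
        grad = -ddet_dX + 2.0 * beta * (X - V)
        accepted = False
        s = step
        for _bt in range(12):
            Xc = np.maximum(X - s * grad, 0.0)
            if np.any(np.linalg.norm(Xc, axis=1) == 0):
                s *= 0.5
                continue
            fc = f(Xc)
            if fc < fx - 1e-12:
                X, fx = Xc, fc
                accepted = True
                break
            s *= 0.5
        if not accepted:
            break
    return X


def update_signal(T: np.ndarray, Omega: np.ndarray, X: np.ndarray,
                  lam: float, beta: float) -> np.ndarray:
    """Solve (lam I + beta Omega^T Omega) Z = lam T + beta Omega^T X by LU."""
    if not lam > 0:
        if beta == 0:
            return np.asarray(T, dtype=float).copy()
        raise ValueError("lam must be > 0")
    T = np.asarray(T, dtype=float)
    p = T.shape[0]
    if beta == 0:
        return T.copy()
    A = lam * np.eye(p) + beta * Omega.T @ Omega
    rhs = lam * T + beta * Omega.T @ X
    lu, piv = sla.lu_factor(A)
    Z = sla.lu_solve((lu, piv), rhs)
    resid = np.linalg.norm(A @ Z - rhs) / max(np.linalg.norm(rhs), 1e-300)
    if resid > 1e-8:
        raise np.linalg.LinAlgError(
            f"signal-update linear system poorly solved (relative residual "
            f"{resid:.2e})")
    return Z


def _replace_duplicates(Omega: np.ndarray, rng: np.random.Generator,
                        coherence: float) -> np.ndarray:
    """Re-draw rows nearly collinear with an earlier row (unit-normalized)."""
    Omega = Omega.copy()
    n, p = Omega.shape
    for i in range(1, n):
        while np.max(np.abs(Omega[:i] @ Omega[i])) > coherence:
            row = rng.standard_normal(p)
            Omega[i] = row / np.linalg.norm(row)
    return Omega


def adla_fit(T: np.ndarray, config: ADLAConfig) -> AnalysisModel:
    """Alternating minimization over (Omega, X, Z).

    Initialization: Omega0 random Gaussian rows (unit-normalized, seeded),
    X0 = Omega0 @ T, Z0 = T.  The objective is recorded once at initialization
    and after every full sweep; iteration stops when the relative change drops
    below ``config.tol`` or after ``config.max_iter`` sweeps.
    """
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] < 2:
        raise ValueError("T must be (p, N) with p >= 2")
    if not np.all(np.isfinite(T)):
        raise ValueError("T must be finite")
    p, N = T.shape
    if N < config.n_atoms:
        logger.warning("adla_fit: N=%d < n_atoms=%d; recovery may be poor",
                       N, config.n_atoms)
    rng = np.random.default_rng(config.seed)
    Omega = rng.standard_normal((config.n_atoms, p))
    Omega /= np.linalg.norm(Omega, axis=1)[:, None]
    Z = T.copy()
    X = Omega @ T
    if config.measure == "determinant":
        X = np.maximum(X, 0.0)
    trace = [objective(T, Omega, X, Z, config)]

    for sweep in range(config.max_iter):
        step = "dictionary"
        try:
            Omega = update_dictionary(Z, X, method=config.dict_update)
            if config.replace_duplicate_atoms:
                Omega = _replace_duplicates(Omega, rng,
                                            config.duplicate_coherence)
            step = "code"
            X = update_code(Omega, Z, config.measure, config.beta,
                            config.zero_tol)
            step = "signal"
            Z = update_signal(T, Omega, X, config.lam, config.beta)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"ADLA {step} sub-step failed: {exc}") from exc
        obj = objective(T, Omega, X, Z, config)
        if not np.isfinite(obj):
            raise RuntimeError(
                f"ADLA objective became non-finite after the {step} sub-step "
                f"of sweep {sweep}")
        trace.append(obj)
        # relative change for large objectives, absolute for near-zero ones
        if abs(trace[-2] - trace[-1]) < config.tol * max(1.0, abs(trace[-2])):
            break

    return AnalysisModel(Omega=Omega, X=X, Z=Z, T=T,
                         objective_trace=trace, config=config)


def sparsity_report(model: AnalysisModel, zero_tol: float | None = None) -> dict:
    """Measure value and mean cosparsity of the fitted model's codes."""
    cfg = model.config
    zt = zero_tol if zero_tol is not None else (cfg.zero_tol if cfg else 1e-3)
    measure = cfg.measure if cfg else "l1"
    analysis = model.Omega @ model.Z
    cos = np.count_nonzero(np.abs(analysis) <= zt, axis=0)
    return {
        "measure_name": measure,
        "value": _matrix_measure(model.X, measure, zt),
        "cosparsity": float(np.mean(cos)),
    }
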