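"""Group elastic net solver (ADMM with adaptive penalty).

The optimization problem, for data vectors b_k and design matrices A_k at
p wavelengths and an n x p amplitude matrix X with columns x_{*,k} and rows
x_{j,*}:

    minimize  1/2 sum_k ||b_k - A_k x_{*,k}||_2^2
              + lambda [ omega/2 sum_k ||x_{*,k}||_2^2
                         + (1 - omega) sum_j ||x_{j,*}||_2 ]

with omega = 1 - alpha in [0, 1]: omega = 0 is the pure group lasso (rows
jointly zero or nonzero, i.e. a time constant is shared by all wavelengths),
omega = 1 is pure ridge (dense).  The problem is solved by ADMM on the
splitting X = Z, where the quadratic (misfit + ridge) update acts on X and
the group soft-thresholding acts on Z; the reported solution is the Z block,
which is exactly sparse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
import warnings

import numpy as np
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "ADMMSettings",
    "GenpSolution",
    "GroupElasticNet",
    "group_shrink",
    "lambda_max",
    "solve_genp",
    "genp_objective",
    "fit_mse",
    "kkt_residuals",
]


@dataclass
class ADMMSettings:
    """ADMM controls: initial augmented-Lagrangian penalty rho0, the
    adaptive-update constants (mu, tau_incr, tau_decr) of the standard
    residual-balancing rule, Boyd-style absolute/relative stopping
    tolerances, and the iteration cap."""

    rho0: float = 1.0
    mu: float = 10.0
    tau_incr: float = 2.0
    tau_decr: float = 2.0
    eps_abs: float = 1e-8
    eps_rel: float = 1e-6
    max_iter: int = 5000
    relax: float = 1.0  # over-relaxation factor; 1.0 (plain ADMM) disables

    def __post_init__(self) -> None:
        if min(self.rho0, self.mu, self.eps_abs, self.eps_rel) <= 0:
            raise ValueError("ADMM settings must be positive")
        if self.tau_incr <= 1 or self.tau_decr <= 1:
            raise ValueError("tau_incr and tau_decr must exceed 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not (0 < self.relax < 2):
            raise ValueError("relax must lie in (0, 2)")


@dataclass
class GenpSolution:
    """A solved group elastic net instance: the exactly sparse amplitude
    matrix X (n rows = time constants, p columns = wavelengths) and the
    hyperparameters and convergence record that produced it."""

    X: np.ndarray
    lam: float
    omega: float
    n_iter: int = 0
    primal_residual: float = 0.0
    dual_residual: float = 0.0
    converged: bool = True
    meta: dict = field(default_factory=dict)


def group_shrink(v: np.ndarray, kappa: float) -> np.ndarray:
    """Block soft-thresholding, the proximal operator of kappa * ||.||_2.

    For a 2-D array the operator acts row-wise.  Returns 0 where the row
    norm is <= kappa, otherwise scales the row by (1 - kappa/||row||).
    """
    v = np.asarray(v, dtype=float)
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if kappa == 0:
        return v.copy()
    if v.ndim == 1:
        nrm = np.linalg.norm(v)
        return np.zeros_like(v) if nrm <= kappa else (1.0 - kappa / nrm) * v
    nrm = np.linalg.norm(v, axis=1)
    scale = np.where(nrm > kappa, 1.0 - kappa / np.maximum(nrm, kappa), 0.0)
    return v * scale[:, None]


def _as_lists(designs, B):
    """Normalize inputs to per-wavelength lists of (A_k, b_k).

    ``designs`` may be one DesignMatrix/array shared by all wavelengths or a
    sequence with one entry per wavelength; ``B`` an (m, p) matrix, a vector,
    or a sequence of per-wavelength vectors (lengths may differ when the
    designs differ row-wise, as in cross-validation splits).
    """
    if isinstance(B, np.ndarray) and B.ndim <= 2:
        Bm = np.atleast_2d(np.asarray(B, dtype=float).T).T  # (m, p)
        bs = [Bm[:, k] for k in range(Bm.shape[1])]
    else:
        bs = [np.asarray(b, dtype=float).ravel() for b in B]
    if hasattr(designs, "values") or (
        isinstance(designs, np.ndarray) and designs.ndim == 2
    ):
        A = np.asarray(designs, dtype=float)
        As = [A] * len(bs)
    else:
        As = [np.asarray(A, dtype=float) for A in designs]
        if len(As) == 1 and len(bs) > 1:
            As = As * len(bs)
    if len(As) != len(bs):
        raise ValueError("number of designs does not match number of traces")
    ncols = {A.shape[1] for A in As}
    if len(ncols) != 1:
        raise ValueError("all designs must share the same number of columns")
    for A, b in zip(As, bs):
        if A.shape[0] != b.size:
            raise ValueError("design rows must match trace length")
        if not (np.all(np.isfinite(A)) and np.all(np.isfinite(b))):
            raise ValueError("NaN or inf in data")
    return As, bs


class _QuadSolver:
    """Solver for (A^T A + c I) x = rhs at arbitrary shift c.

    The Gram matrix is eigendecomposed once, so every subsequent solve (at
    any c — the shift changes with the adaptive ADMM penalty) costs only
    matrix products.  The Woodbury identity reduces the factorization to
    the m x m side when the grid is wider than the time axis.
    """

    def __init__(self, A: np.ndarray):
        self.A = A
        self.m, self.n = A.shape
        self.woodbury = self.n > self.m
        gram = A @ A.T if self.woodbury else A.T @ A
        self.s, self.Q = np.linalg.eigh(gram)
        self.s = np.maximum(self.s, 0.0)  # clip tiny negative round-off

    def _inv_apply(self, v: np.ndarray, c: float) -> np.ndarray:
        w = self.Q.T @ v
        return self.Q @ (w / (self.s + c)[:, None] if v.ndim == 2
                         else w / (self.s + c))

    def solve(self, rhs: np.ndarray, c: float) -> np.ndarray:
        if self.woodbury:
            return (rhs - self.A.T @ self._inv_apply(self.A @ rhs, c)) / c
        return self._inv_apply(rhs, c)


class _BatchQuadSolver:
    """Batched solver for p systems (A_k^T A_k + c I) x_k = rhs_k.

    The per-wavelength designs are padded with zero rows to a common row
    count (zero rows add nothing to A^T A or A^T b, so this is exact) and
    the linear algebra runs through numpy's stacked BLAS/LAPACK paths.
    """

    def __init__(self, As):
        m_max = max(A.shape[0] for A in As)
        n = As[0].shape[1]
        stack = np.zeros((len(As), m_max, n))
        for k, A in enumerate(As):
            stack[k, : A.shape[0]] = A
        self.A = stack
        self.At = stack.transpose(0, 2, 1).copy()
        self.m, self.n = m_max, n
        self.woodbury = self.n > self.m
        gram = stack @ self.At if self.woodbury else self.At @ stack
        self.s, self.Q = np.linalg.eigh(gram)  # batched
        self.s = np.maximum(self.s, 0.0)
        self.Qt = self.Q.transpose(0, 2, 1).copy()

    def _inv_apply(self, V: np.ndarray, c: float) -> np.ndarray:
        W = self.Qt @ V
        return self.Q @ (W / (self.s + c)[:, :, None])

    def solve_all(self, rhs: np.ndarray, c: float) -> np.ndarray:
        """rhs: (n, p) -> solution (n, p)."""
        R = rhs.T[:, :, None]  # (p, n, 1)
        if self.woodbury:
            Y = self._inv_apply(self.A @ R, c)
            X = (R - self.At @ Y) / c
        else:
            X = self._inv_apply(R, c)
        return X[:, :, 0].T


def _solve_admm(As, bs, lam, omega, settings, X0=None, U0=None, groups=None):
    """Core ADMM loop on normalized per-wavelength lists.

    ``groups`` optionally partitions the columns into independent
    group-lasso blocks of equal size: the row penalty couples only columns
    within the same block.  This lets several independent instances that
    share a coefficient grid (e.g. the folds of a cross-validation) be
    solved in one batched call; with ``groups=None`` all columns form one
    block (the ordinary multiwavelength problem).
    """
    n = As[0].shape[1]
    p = len(bs)
    # share factorizations when wavelengths reuse the same design object;
    # with several distinct designs, go through the batched path instead
    solver_of: dict[int, _QuadSolver] = {}
    solvers = []
    for A in As:
        key = id(A)
        if key not in solver_of:
            solver_of[key] = _QuadSolver(A)
        solvers.append(solver_of[key])
    batch = _BatchQuadSolver(As) if len(solver_of) > 1 else None
    G = np.column_stack([A.T @ b for A, b in zip(As, bs)])  # (n, p)

    if groups is not None:
        sizes = {len(g) for g in groups}
        if len(sizes) != 1 or sorted(np.concatenate(groups)) != list(range(p)):
            raise ValueError("groups must partition the columns into equal blocks")
        order = np.concatenate(groups)
        if not np.array_equal(order, np.arange(p)):
            raise ValueError("groups must be contiguous and ordered")
        gsize = sizes.pop()

        def shrink(V, kappa):
            V3 = V.reshape(n, len(groups), gsize)
            nrm = np.linalg.norm(V3, axis=2)
            scale = np.where(nrm > kappa, 1.0 - kappa / np.maximum(nrm, kappa), 0.0)
            return (V3 * scale[:, :, None]).reshape(n, p)

    else:
        shrink = group_shrink

    rho = settings.rho0
    X = np.zeros((n, p)) if X0 is None else X0.copy()
    Z = X.copy()
    U = np.zeros((n, p)) if U0 is None else U0.copy()
    total = n * p
    r_norm = s_norm = np.inf
    it = 0
    for it in range(1, settings.max_iter + 1):
        c = lam * omega + rho
        rhs = G + rho * (Z - U)
        if batch is None:
            X = solvers[0].solve(rhs, c)
        else:
            X = batch.solve_all(rhs, c)
        Z_old = Z
        Xh = settings.relax * X + (1.0 - settings.relax) * Z_old
        Z = shrink(Xh + U, lam * (1.0 - omega) / rho)
        U = U + Xh - Z
        r_norm = np.linalg.norm(X - Z)
        s_norm = rho * np.linalg.norm(Z - Z_old)
        eps_pri = np.sqrt(total) * settings.eps_abs + settings.eps_rel * max(
            np.linalg.norm(X), np.linalg.norm(Z)
        )
        eps_dual = np.sqrt(total) * settings.eps_abs + settings.eps_rel * (
            rho * np.linalg.norm(U)
        )
        if it % 100 == 0 and logger.isEnabledFor(logging.DEBUG):
            logger.debug(
                "admm it=%d rho=%.3g primal=%.3e/%.3e dual=%.3e/%.3e",
                it, rho, r_norm, eps_pri, s_norm, eps_dual,
            )
        if r_norm <= eps_pri and s_norm <= eps_dual:
            return Z, dict(
                n_iter=it, primal=r_norm, dual=s_norm, converged=True, U=U, X=X
            )
        # residual balancing (adaptive rho); the scaled dual must be rescaled
        if r_norm > settings.mu * s_norm:
            rho *= settings.tau_incr
            U = U / settings.tau_incr
        elif s_norm > settings.mu * r_norm:
            rho /= settings.tau_decr
            U = U * settings.tau_decr
    warnings.warn(
        f"ADMM did not converge in {settings.max_iter} iterations "
        f"(primal {r_norm:.2e}, dual {s_norm:.2e})",
        RuntimeWarning,
    )
    return Z, dict(n_iter=it, primal=r_norm, dual=s_norm, converged=False, U=U, X=X)


class GroupElasticNet(BaseEstimator):
    """Group elastic net regression over a shared coefficient grid.

    scikit-learn-style estimator: ``fit(A, B)`` takes a design matrix ``A``
    of shape (m, n) — or a list of per-wavelength designs — and a signal
    matrix ``B`` of shape (m, p); the fitted ``coef_`` is the n x p
    amplitude matrix whose rows are jointly zero or jointly nonzero.

    Parameters
    ----------
    lam : float
        Overall penalty weight (lambda > 0).
    omega : float
        Density control in [0, 1]; 0 = pure group lasso, 1 = pure ridge.
    rho0, mu, tau_incr, tau_decr, eps_abs, eps_rel, max_iter :
        ADMM settings, see :class:`ADMMSettings`.
    warm_start : bool
        Reuse the previous solution as the starting point of the next fit.
    """

    def __init__(
        self,
        lam: float = 1.0,
        omega: float = 0.0,
        rho0: float = 1.0,
        mu: float = 10.0,
        tau_incr: float = 2.0,
        tau_decr: float = 2.0,
        eps_abs: float = 1e-8,
        eps_rel: float = 1e-6,
        max_iter: int = 5000,
        relax: float = 1.0,
        warm_start: bool = False,
    ):
        self.lam = lam
        self.omega = omega
        self.rho0 = rho0
        self.mu = mu
        self.tau_incr = tau_incr
        self.tau_decr = tau_decr
        self.eps_abs = eps_abs
        self.eps_rel = eps_rel
        self.max_iter = max_iter
        self.relax = relax
        self.warm_start = warm_start

    def _settings(self) -> ADMMSettings:
        return ADMMSettings(
            rho0=self.rho0,
            mu=self.mu,
            tau_incr=self.tau_incr,
            tau_decr=self.tau_decr,
            eps_abs=self.eps_abs,
            eps_rel=self.eps_rel,
            max_iter=self.max_iter,
            relax=self.relax,
        )

    def fit(self, A, B):
        if not (self.lam > 0):
            raise ValueError("lam must be positive")
        if not (0 <= self.omega <= 1):
            raise ValueError("omega must lie in [0, 1]")
        As, bs = _as_lists(A, B)
        X0 = U0 = None
        if self.warm_start and hasattr(self, "coef_"):
            if self.coef_.shape == (As[0].shape[1], len(bs)):
                X0, U0 = self.coef_, getattr(self, "dual_", None)
        Z, info = _solve_admm(As, bs, self.lam, self.omega, self._settings(), X0, U0)
        self.coef_ = Z
        self.dual_ = info["U"]
        self.n_iter_ = info["n_iter"]
        self.primal_residual_ = info["primal"]
        self.dual_residual_ = info["dual"]
        self.converged_ = info["converged"]
        return self

    def predict(self, A):
        if not hasattr(self, "coef_"):
            raise AttributeError("estimator is not fitted")
        if hasattr(A, "values") or (isinstance(A, np.ndarray) and A.ndim == 2):
            return np.asarray(A, dtype=float) @ self.coef_
        return [
            np.asarray(Ak, dtype=float) @ self.coef_[:, k] for k, Ak in enumerate(A)
        ]

    def solution_(self) -> GenpSolution:
        return GenpSolution(
            X=self.coef_,
            lam=self.lam,
            omega=self.omega,
            n_iter=self.n_iter_,
            primal_residual=self.primal_residual_,
            dual_residual=self.dual_residual_,
            converged=self.converged_,
        )


def solve_genp(
    designs,
    B,
    lam: float,
    omega: float,
    settings: ADMMSettings | None = None,
) -> GenpSolution:
    """Solve one group elastic net instance (thin functional wrapper over
    :class:`GroupElasticNet`)."""
    settings = settings or ADMMSettings()
    est = GroupElasticNet(
        lam=lam,
        omega=omega,
        rho0=settings.rho0,
        mu=settings.mu,
        tau_incr=settings.tau_incr,
        tau_decr=settings.tau_decr,
        eps_abs=settings.eps_abs,
        eps_rel=settings.eps_rel,
        max_iter=settings.max_iter,
        relax=settings.relax,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        est.fit(designs, B)
    return est.solution_()


def lambda_max(designs, B, omega: float = 0.0) -> float:
    """Smallest lambda at which the solution is exactly zero.

    From the KKT conditions at X = 0 the group-lasso term dominates whenever
    lambda (1 - omega) >= max_j ||g_{j,*}||_2 with g = [A_k^T b_k]_k, hence
    lambda_max = max_j ||g_{j,*}|| / (1 - omega).  Undefined at omega = 1
    (pure ridge never produces an exact zero).
    """
    if omega >= 1:
        raise ValueError("lambda_max is undefined for omega = 1 (pure ridge)")
    As, bs = _as_lists(designs, B)
    G = np.column_stack([A.T @ b for A, b in zip(As, bs)])
    return float(np.linalg.norm(G, axis=1).max() / (1.0 - omega))


def genp_objective(designs, B, X, lam: float, omega: float) -> float:
    """Value of the group elastic net objective at X."""
    As, bs = _as_lists(designs, B)
    X = np.atleast_2d(np.asarray(X, dtype=float).T).T
    misfit = 0.5 * sum(
        float(np.sum((b - A @ X[:, k]) ** 2)) for k, (A, b) in enumerate(zip(As, bs))
    )
    ridge = 0.5 * omega * float(np.sum(X**2))
    group = (1.0 - omega) * float(np.linalg.norm(X, axis=1).sum())
    return misfit + lam * (ridge + group)


def fit_mse(designs, B, X) -> float:
    """Mean squared residual of the fit over all (time, wavelength) cells."""
    As, bs = _as_lists(designs, B)
    X = np.atleast_2d(np.asarray(X, dtype=float).T).T
    sq = 0.0
    cells = 0
    for k, (A, b) in enumerate(zip(As, bs)):
        r = b - A @ X[:, k]
        sq += float(r @ r)
        cells += b.size
    return sq / cells


def kkt_residuals(designs, B, X, lam: float, omega: float):
    """KKT certificate of a candidate solution (omega < 1).

    Returns ``(stationarity, zero_excess)``: the largest norm of the
    stationarity residual g_j + lam*omega*x_j + lam*(1-omega)*x_j/||x_j||
    over nonzero rows (g being the stacked misfit gradient rows), and the
    largest amount by which ||g_j|| exceeds lam*(1-omega) over zero rows.
    Both are ~0 at the optimum.
    """
    As, bs = _as_lists(designs, B)
    X = np.atleast_2d(np.asarray(X, dtype=float).T).T
    Grad = np.column_stack(
        [A.T @ (A @ X[:, k] - b) for k, (A, b) in enumerate(zip(As, bs))]
    )
    row_norms = np.linalg.norm(X, axis=1)
    nz = row_norms > 0
    stationarity = 0.0
    if np.any(nz):
        R = (
            Grad[nz]
            + lam * omega * X[nz]
            + lam * (1.0 - omega) * X[nz] / row_norms[nz, None]
        )
        stationarity = float(np.linalg.norm(R, axis=1).max())
    zero_excess = 0.0
    if np.any(~nz):
        zero_excess = float(
            max(0.0, np.linalg.norm(Grad[~nz], axis=1).max() - lam * (1.0 - omega))
        )
    return stationarity, zero_excess
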