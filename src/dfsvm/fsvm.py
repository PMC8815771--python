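"""Cost-sensitive fuzzy support vector machine (FSVM).

A fuzzy SVM attaches a membership value s_i > 0 to every training sample and
scales its misclassification penalty to s_i * C, giving the primal

    min  1/2 ||w||^2 + C * sum_i s_i eps_i
    s.t. y_i (w . phi(x_i) + b) >= 1 - eps_i,   eps_i >= 0

whose dual is the quadratic program

    min  -sum_i alpha_i + 1/2 sum_ij y_i y_j alpha_i alpha_j K(x_i, x_j)
    s.t. sum_i y_i alpha_i = 0,   0 <= alpha_i <= s_i * C.

The only difference from a standard soft-margin SVM is the per-sample box
bound s_i * C, so with s == 1 the model reduces exactly to a C-SVM.  For
imbalanced problems the membership scheme sets s_i = IR (the imbalance
ratio, majority count / minority count) for minority samples and s_i = 1
for majority samples, so a minority misclassification costs IR times more.

The dual is solved by an SMO-style algorithm with maximal-violating-pair
working-set selection; the Gaussian kernel is parameterized as
k(x, x') = exp(-||x - x'||^2 / (2 sigma^2)).  The decision function is
f(x) = sum_i alpha_i y_i k(x_i, x) + b, predicting sign(f); an exact zero
score predicts the minority class (+1), consistent with the cost-sensitive
intent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "membership_values",
    "KernelSpec",
    "kernel_matrix",
    "QPSolution",
    "solve_fsvm_dual",
    "BiasEstimate",
    "compute_bias",
    "FSVM",
]


class ConvergenceError(RuntimeError):
    """SMO failed to reach the requested KKT tolerance."""

    def __init__(self, residual: float, max_iter: int):
        super().__init__(
            f"SMO did not converge within {max_iter} pair updates "
            f"(KKT residual {residual:.3e})"
        )
        self.residual = residual


def membership_values(y, scheme: str = "ir") -> np.ndarray:
    """Per-sample membership (penalty weight) vector.

    Under the ``"ir"`` scheme minority samples (+1) get the imbalance ratio
    n_maj / n_min and majority samples get 1; balanced data therefore
    degenerates to s == 1 (a plain SVM).
    """
    if scheme != "ir":
        raise ValueError(f"unknown membership scheme {scheme!r}")
    y = np.asarray(y)
    n_min = int(np.sum(y == 1))
    n_maj = int(np.sum(y == -1))
    if n_min == 0 or n_maj == 0:
        raise ValueError("both classes must be present to assign memberships")
    ir = n_maj / n_min
    return np.where(y == 1, ir, 1.0)


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian (RBF) kernel k(x,x') = exp(-||x-x'||^2 / (2 sigma^2))."""

    kind: str = "rbf"
    sigma: float = 1.0

    def __post_init__(self):
        if self.kind != "rbf":
            raise ValueError(f"unsupported kernel {self.kind!r}")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


def kernel_matrix(X1: np.ndarray, X2: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Gram matrix between the rows of X1 and X2."""
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.shape[1] != X2.shape[1]:
        raise ValueError("column counts differ")
    sq = cdist(X1, X2, metric="sqeuclidean")
    return np.exp(-sq / (2.0 * spec.sigma**2))


@dataclass
class QPSolution:
    alpha: np.ndarray
    objective: float
    kkt_residual: float
    iterations: int


def solve_fsvm_dual(
    K: np.ndarray,
    y: np.ndarray,
    s: np.ndarray,
    C: float,
    tol: float = 1e-6,
    max_iter: int = 100_000,
) -> QPSolution:
    """Solve the membership-scaled dual QP by maximal-violating-pair SMO.

    Minimizes -1'alpha + 1/2 alpha' (yy' * K) alpha subject to y'alpha = 0
    and 0 <= alpha_i <= s_i * C.  The KKT residual is the violating-pair gap
    m(alpha) - M(alpha); the solver stops when it drops to ``tol``.
    """
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    s = np.asarray(s, dtype=float)
    n = len(y)
    if K.shape != (n, n):
        raise ValueError("K must be n x n")
    if np.any(s <= 0) or C <= 0:
        raise ValueError("memberships and C must be positive")
    u = s * C  # per-sample upper bounds
    alpha = np.zeros(n)
    grad = -np.ones(n)  # gradient of the dual objective: Q alpha - 1
    Q = (y[:, None] * y[None, :]) * K

    it = 0
    gap = np.inf
    for it in range(1, max_iter + 1):
        # -y_i grad_i over the sets allowed to move up / down
        up = ((y > 0) & (alpha < u)) | ((y < 0) & (alpha > 0))
        low = ((y > 0) & (alpha > 0)) | ((y < 0) & (alpha < u))
        yg = -y * grad
        if not up.any() or not low.any():
            gap = 0.0
            break
        yg_up = np.where(up, yg, -np.inf)
        yg_low = np.where(low, yg, np.inf)
        i = int(np.argmax(yg_up))
        j = int(np.argmin(yg_low))
        gap = yg_up[i] - yg_low[j]
        if gap <= tol:
            break
        # direction: alpha_i += y_i t, alpha_j -= y_j t keeps y'alpha fixed
        quad = K[i, i] + K[j, j] - 2.0 * K[i, j]
        t_max_i = (u[i] - alpha[i]) if y[i] > 0 else alpha[i]
        t_max_j = alpha[j] if y[j] > 0 else (u[j] - alpha[j])
        t_max = min(t_max_i, t_max_j)
        t = t_max if quad <= 1e-15 else min(gap / quad, t_max)
        alpha[i] += y[i] * t
        alpha[j] -= y[j] * t
        grad += (y[i] * t) * Q[:, i] - (y[j] * t) * Q[:, j]
    else:
        raise ConvergenceError(gap, max_iter)

    objective = float(-alpha.sum() + 0.5 * alpha @ Q @ alpha)
    return QPSolution(alpha=alpha, objective=objective, kkt_residual=float(max(gap, 0.0)), iterations=it)


@dataclass(frozen=True)
class BiasEstimate:
    """Bias b with provenance: margin-vector average or interval midpoint."""

    value: float
    n_margin_vectors: int
    used_interval_fallback: bool


def compute_bias(
    solution: QPSolution,
    K: np.ndarray,
    y: np.ndarray,
    s: np.ndarray,
    C: float,
    tol: float = 1e-6,
) -> BiasEstimate:
    """Recover b from the complementary-slackness conditions.

    Margin support vectors (tol < alpha_i < s_i C - tol, relative slack)
    satisfy y_i f(x_i) = 1 exactly, so b averages y_i - h_i over them with
    h_i = sum_j alpha_j y_j K_ij.  Without margin vectors, the bound
    constraints imply an interval of feasible b values; its midpoint is
    returned.
    """
    alpha = solution.alpha
    y = np.asarray(y, dtype=float)
    u = np.asarray(s, dtype=float) * C
    h = (alpha * y) @ K
    slack = tol * u
    margin = (alpha > slack) & (alpha < u - slack)
    if margin.any():
        b = float(np.mean(y[margin] - h[margin]))
        return BiasEstimate(b, int(margin.sum()), False)

    # KKT inequalities at the bounds give one-sided constraints on b
    at_zero = alpha <= slack
    at_u = alpha >= u - slack
    lower = -np.inf
    upper = np.inf
    lo_candidates = np.concatenate(
        [(1 - h)[at_zero & (y > 0)], (-1 - h)[at_u & (y < 0)]]
    )
    hi_candidates = np.concatenate(
        [(-1 - h)[at_zero & (y < 0)], (1 - h)[at_u & (y > 0)]]
    )
    if len(lo_candidates):
        lower = float(np.max(lo_candidates))
    if len(hi_candidates):
        upper = float(np.min(hi_candidates))
    if lower > upper + 1e-8:
        raise RuntimeError(
            f"empty feasible bias interval [{lower:.6g}, {upper:.6g}]; "
            "the dual solution violates the KKT bound conditions"
        )
    if np.isinf(lower) and np.isinf(upper):
        b = 0.0
    elif np.isinf(lower):
        b = upper
    elif np.isinf(upper):
        b = lower
    else:
        b = 0.5 * (lower + upper)
    return BiasEstimate(b, 0, True)


class FSVM:
    """Fuzzy SVM classifier with a Gaussian kernel.

    Parameters
    ----------
    C : penalty constant.
    sigma : Gaussian kernel width (1/(2 sigma^2) convention).
    membership : "ir" to derive memberships from the training labels, or
        None for s == 1 (standard SVM).  ``fit`` also accepts an explicit
        membership vector, which takes precedence.
    """

    def __init__(
        self,
        C: float = 1.0,
        sigma: float = 1.0,
        membership: str | None = "ir",
        tol: float = 1e-6,
        max_iter: int = 100_000,
        sv_threshold: float = 1e-8,
    ):
        self.C = C
        self.sigma = sigma
        self.membership = membership
        self.tol = tol
        self.max_iter = max_iter
        self.sv_threshold = sv_threshold

    def fit(self, X: np.ndarray, y: np.ndarray, s: np.ndarray | None = None) -> "FSVM":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if s is None:
            s = membership_values(y) if self.membership == "ir" else np.ones(len(y))
        else:
            s = np.asarray(s, dtype=float)
        kernel = KernelSpec(sigma=self.sigma)
        K = kernel_matrix(X, X, kernel)
        solution = solve_fsvm_dual(K, y, s, self.C, tol=self.tol, max_iter=self.max_iter)
        bias = compute_bias(solution, K, y, s, self.C, tol=self.tol)

        keep = solution.alpha > self.sv_threshold
        self.kernel_ = kernel
        self.solution_ = solution
        self.bias_ = bias
        self.memberships_ = s
        self.sv_X_ = X[keep]
        self.sv_y_ = y[keep]
        self.sv_alpha_ = solution.alpha[keep]
        self.b_ = bias.value
        return self

    def _check_fitted(self):
        if not hasattr(self, "sv_X_"):
            raise RuntimeError("model is not fitted")

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """f(x) = sum over support vectors of alpha_i y_i k(x_i, x) + b."""
        self._check_fitted()
        Kx = kernel_matrix(X, self.sv_X_, self.kernel_)
        return Kx @ (self.sv_alpha_ * self.sv_y_) + self.b_

    def predict(self, X: np.ndarray) -> np.ndarray:
        """sign of the decision value; an exact zero predicts minority (+1)."""
        scores = self.decision_function(X)
        return np.where(scores >= 0, 1, -1)

    def save(self, path: str) -> None:
        self._check_fitted()
        payload = {
            "C": self.C,
            "sigma": self.sigma,
            "b": self.b_,
            "sv_X": self.sv_X_.tolist(),
            "sv_y": self.sv_y_.tolist(),
            "sv_alpha": self.sv_alpha_.tolist(),
            "memberships": np.asarray(self.memberships_).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str) -> "FSVM":
        with open(path) as fh:
            payload = json.load(fh)
        model = cls(C=payload["C"], sigma=payload["sigma"])
        model.kernel_ = KernelSpec(sigma=payload["sigma"])
        model.sv_X_ = np.asarray(payload["sv_X"], dtype=float)
        model.sv_y_ = np.asarray(payload["sv_y"], dtype=int)
        model.sv_alpha_ = np.asarray(payload["sv_alpha"], dtype=float)
        model.b_ = float(payload["b"])
        model.memberships_ = np.asarray(payload["memberships"], dtype=float)
        return model
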