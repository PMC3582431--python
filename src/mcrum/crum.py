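"""The binary classification relevance units machine (CRUM).

A CRUM is a sparse kernel classifier: the positive-class posterior is

    P(C+ | x) = sigmoid( sum_i w_i k(x, u_i) + b )

over a small, fixed set of M relevance units u_i — prototype vectors found
by unsupervised clustering of the training features, not selected from the
training points the way support vectors are.  Given the units, the weights
and bias are the MAP solution of a penalized logistic regression on the
kernel design matrix Phi_nm = k(x_n, u_m):

    L(w, b) = -sum_n [ t_n log p_n + (1 - t_n) log(1 - p_n) ] + (alpha/2) ||w||^2

with the bias unpenalized.  The ridge weight alpha is not user-set: it is
re-estimated between weight solves by the evidence (MacKay) fixed point

    alpha <- gamma_eff / ||w||^2,   gamma_eff = sum_j lambda_j / (lambda_j + alpha)

where lambda_j are the eigenvalues of the unpenalized-loss Hessian restricted
to the weight block.  The weight solve itself is a damped Newton / IRLS
iteration.  Everything is deterministic given the inputs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.spatial.distance import cdist
from scipy.special import expit

logger = logging.getLogger(__name__)

__all__ = [
    "KernelSpec",
    "BinaryCRUM",
    "CrumTrainingError",
    "gaussian_kernel",
    "kernel_matrix",
    "predict_binary",
    "train_binary_crum",
]


class CrumTrainingError(RuntimeError):
    """Raised when the inner weight solve cannot proceed numerically."""


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and parameters.  Only the Gaussian kernel is supported;
    ``kind`` exists as a hook for others."""

    kind: str = "gaussian"
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.kind != "gaussian":
            raise NotImplementedError(f"unsupported kernel kind {self.kind!r}")
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")


def gaussian_kernel(x, u, gamma: float) -> float:
    """exp(-gamma * ||x - u||^2); equals 1 iff x == u, symmetric in (x, u)."""
    x = np.asarray(x, dtype=float).ravel()
    u = np.asarray(u, dtype=float).ravel()
    if x.shape != u.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {u.shape}")
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    d = x - u
    return float(np.exp(-gamma * np.dot(d, d)))


def kernel_matrix(X, U, gamma: float) -> np.ndarray:
    """Gaussian kernel evaluations between the rows of X and the rows of U."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    U = np.atleast_2d(np.asarray(U, dtype=float))
    if X.shape[1] != U.shape[1]:
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs {U.shape[1]}")
    return np.exp(-gamma * cdist(X, U, metric="sqeuclidean"))


@dataclass
class BinaryCRUM:
    """One trained binary CRUM.

    ``history`` holds the penalized-objective trace of each inner Newton
    solve (one list per outer iteration); it is diagnostic only and is not
    serialized.
    """

    units: np.ndarray  # (M, d)
    weights: np.ndarray  # (M,)
    bias: float
    kernel: KernelSpec
    alpha: float
    feature_dim: int
    history: list = field(default_factory=list, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.units = np.atleast_2d(np.asarray(self.units, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if self.units.shape[0] != self.weights.size or self.weights.size < 1:
            raise ValueError("need one weight per relevance unit, at least one unit")
        if self.units.shape[1] != self.feature_dim:
            raise ValueError("units do not match feature_dim")
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")

    @property
    def n_units(self) -> int:
        return self.weights.size

    # ------------------------------------------------------------- JSON form
    def to_dict(self) -> dict:
        return {
            "units": self.units.tolist(),
            "weights": self.weights.tolist(),
            "bias": float(self.bias),
            "kernel": {"kind": self.kernel.kind, "gamma": float(self.kernel.gamma)},
            "alpha": float(self.alpha),
            "feature_dim": int(self.feature_dim),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BinaryCRUM":
        return cls(
            units=np.array(d["units"], dtype=float),
            weights=np.array(d["weights"], dtype=float),
            bias=float(d["bias"]),
            kernel=KernelSpec(d["kernel"]["kind"], d["kernel"]["gamma"]),
            alpha=float(d["alpha"]),
            feature_dim=int(d["feature_dim"]),
        )


def _activation(model: BinaryCRUM, X: np.ndarray) -> np.ndarray:
    Phi = kernel_matrix(X, model.units, model.kernel.gamma)
    return Phi @ model.weights + model.bias


def predict_binary(model: BinaryCRUM, x):
    """Positive-class posterior P(C+ | x), strictly inside (0, 1).

    Accepts a single d-vector (returns a float) or an (N, d) matrix
    (returns an (N,) array).  The negative-class posterior is one minus the
    returned value.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.feature_dim:
        raise ValueError(
            f"input has dimension {X.shape[1]}, model expects {model.feature_dim}"
        )
    p = expit(_activation(model, X))
    tiny = np.finfo(float).tiny
    p = np.clip(p, tiny, 1.0 - np.finfo(float).epsneg)
    return float(p[0]) if single else p


def _penalized_objective(A, t, beta, alpha, M) -> float:
    z = A @ beta
    # -log sigma(z) = softplus(-z) for t=1; -log(1-sigma(z)) = softplus(z) for t=0
    nll = np.sum(np.logaddexp(0.0, np.where(t == 1, -z, z)))
    return float(nll + 0.5 * alpha * np.dot(beta[:M], beta[:M]))


def _penalized_gradient(A, t, beta, alpha, M) -> np.ndarray:
    p = expit(A @ beta)
    g = A.T @ (p - t)
    g[:M] += alpha * beta[:M]
    return g


def _newton_solve(A, t, alpha, beta0, tol, max_iter=100):
    """Damped Newton/IRLS on the penalized log loss at fixed alpha.

    Returns (beta, objective_trace); every accepted step decreases the
    objective (step halving otherwise), so the trace is non-increasing.
    """
    M = A.shape[1] - 1
    beta = beta0.copy()
    obj = _penalized_objective(A, t, beta, alpha, M)
    trace = [obj]
    ridge = np.zeros(M + 1)
    ridge[:M] = alpha
    for _ in range(max_iter):
        g = _penalized_gradient(A, t, beta, alpha, M)
        if np.max(np.abs(g)) <= tol:
            break
        p = expit(A @ beta)
        w = np.maximum(p * (1.0 - p), 1e-10)
        H = (A.T * w) @ A + np.diag(ridge)
        try:
            step = linalg.solve(H, -g, assume_a="pos")
        except linalg.LinAlgError as exc:
            raise CrumTrainingError(
                f"ill-conditioned inner solve (cond ~ {np.linalg.cond(H):.3g})"
            ) from exc
        if not np.all(np.isfinite(step)):
            raise CrumTrainingError("non-finite Newton step")
        eta = 1.0
        accepted = False
        for _ in range(50):
            cand = beta + eta * step
            cand_obj = _penalized_objective(A, t, cand, alpha, M)
            if cand_obj <= obj + 1e-12:
                beta, obj = cand, cand_obj
                trace.append(obj)
                accepted = True
                break
            eta *= 0.5
        if not accepted:
            break  # cannot decrease further: numerically at the optimum
    return beta, trace


def train_binary_crum(
    positive,
    negative,
    units,
    kernel: KernelSpec,
    max_outer: int = 100,
    tol: float = 1e-8,
    alpha0: float = 1.0,
) -> BinaryCRUM:
    """Fit the weights, bias and ridge weight of a binary CRUM.

    Parameters
    ----------
    positive, negative : (n+, d), (n-, d) feature matrices for the two classes.
    units : (M, d) relevance units, fixed during the fit (typically K-means
        centers of the pooled unlabeled features).
    kernel : Gaussian kernel with its width.
    max_outer : cap on alternations of weight solve and alpha update.
    tol : gradient max-norm tolerance of the inner Newton solve.

    The outer loop stops when the relative change of alpha falls below 1e-3;
    a final weight solve at the accepted alpha guarantees the returned
    coefficients are a stationary point of the penalized loss.
    """
    pos = np.atleast_2d(np.asarray(positive, dtype=float))
    neg = np.atleast_2d(np.asarray(negative, dtype=float))
    U = np.atleast_2d(np.asarray(units, dtype=float))
    if pos.shape[0] < 1 or neg.shape[0] < 1:
        raise ValueError("need at least one positive and one negative instance")
    if pos.shape[1] != neg.shape[1] or pos.shape[1] != U.shape[1]:
        raise ValueError("positive, negative and units dimensions disagree")
    if pos.shape[0] == 1 or neg.shape[0] == 1:
        warnings.warn("a class has a single training instance; the fit will be weak",
                      stacklevel=2)
    d = pos.shape[1]
    M = U.shape[0]
    X = np.vstack([pos, neg])
    t = np.concatenate([np.ones(pos.shape[0]), np.zeros(neg.shape[0])])

    Phi = kernel_matrix(X, U, kernel.gamma)
    A = np.column_stack([Phi, np.ones(X.shape[0])])

    alpha = float(alpha0)
    beta = np.zeros(M + 1)
    history: list[list[float]] = []
    converged = False
    for _ in range(max_outer):
        beta, trace = _newton_solve(A, t, alpha, beta, tol)
        history.append(trace)
        # evidence fixed point for alpha at the current mode
        p = expit(A @ beta)
        w_irls = p * (1.0 - p)
        Hw = (Phi.T * w_irls) @ Phi  # unpenalized Hessian, weight block
        lam = np.clip(linalg.eigvalsh(Hw), 0.0, None)
        gamma_eff = float(np.sum(lam / (lam + alpha)))
        wnorm2 = float(np.dot(beta[:M], beta[:M]))
        alpha_new = float(np.clip(gamma_eff / max(wnorm2, 1e-12), 1e-10, 1e10))
        rel = abs(alpha_new - alpha) / max(alpha, 1e-300)
        alpha = alpha_new
        if rel < 1e-3 or wnorm2 < 1e-8:
            # the second case: the evidence has pruned the weights to zero
            # (no usable signal); the bias-only model is the fixed point
            converged = True
            break
    if not converged:
        logger.warning(
            "evidence update did not settle within %d outer iterations "
            "(last alpha %.4g); returning the final iterate", max_outer, alpha,
        )
    beta, trace = _newton_solve(A, t, alpha, beta, tol)
    history.append(trace)
    return BinaryCRUM(
        units=U,
        weights=beta[:M],
        bias=float(beta[M]),
        kernel=kernel,
        alpha=alpha,
        feature_dim=d,
        history=history,
    )
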