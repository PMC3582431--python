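"""Decoders: aggregate L binary posteriors into a multiclass decision.

Three strategies are provided:

* :func:`decode_hard` — binarize the outputs and pick the class whose codeword
  minimizes the modified Hamming distance (nearest-codeword decoding);
* :func:`decode_naive` — treat the binary classifiers as independent and take
  the normalized product of the relevant binary posteriors, computed in log
  space; linear in the number of binary problems L;
* :func:`decode_gbt` — the generalized Bradley-Terry model: find the class
  probability vector p whose induced pairwise/groupwise success ratios
  q_i+/q_i best match the observed binary outputs, by minimizing a weighted
  negative log-likelihood (equivalently a weighted KL divergence) with a
  multiplicative fixed-point update.

The GBT decode must be re-run per input and may need many sweeps, which is
why the naive product decoder exists: on one-versus-rest and all-pairs
decompositions it closely tracks the GBT posteriors at a tiny fraction of
the cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codes import DELTA, ONE, ZERO, CodingMatrix, code_distance

__all__ = [
    "EPS",
    "decode_hard",
    "decode_naive",
    "decode_naive_counted",
    "GBTProblem",
    "GBTResult",
    "decode_gbt",
    "gbt_objective",
]

EPS = 1e-12  # probability clip for logs and q-term floors


def _check_outputs(code: CodingMatrix, g) -> np.ndarray:
    g = np.asarray(g, dtype=float).ravel()
    if g.size != code.L:
        raise ValueError(f"expected {code.L} binary outputs, got {g.size}")
    if np.any(g < 0) or np.any(g > 1):
        raise ValueError("binary outputs must lie in [0, 1]")
    return g


def decode_hard(code: CodingMatrix, g, cutoff: float = 0.5) -> int:
    """Nearest-codeword hard decoding.

    Binarizes the outputs at ``cutoff`` and returns the row index minimizing
    the modified Hamming distance to the binarized output vector.  Ties break
    toward the smallest class index.
    """
    g = _check_outputs(code, g)
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie in (0, 1)")
    word = (g >= cutoff).astype(np.int8)
    dists = [code_distance(code.row(k), word) for k in range(code.K)]
    return int(np.argmin(dists))  # argmin takes the first minimum


def decode_naive(code: CodingMatrix, g) -> np.ndarray:
    """Independence (naive) soft decoding; linear in L.

    Class k scores the log-product, over the columns where its codeword is
    not DELTA, of g_i (codeword 1) or 1 - g_i (codeword 0); the scores are
    exponentiated and normalized with max-subtraction for stability.
    """
    g = _check_outputs(code, g)
    g = np.clip(g, EPS, 1.0 - EPS)
    M = code.entries
    log_g = np.log(g)
    log_1mg = np.log1p(-g)
    scores = (M == ONE) @ log_g + (M == ZERO) @ log_1mg
    scores -= scores.max()
    p = np.exp(scores)
    total = p.sum()
    if not np.isfinite(total) or total <= 0.0:
        raise FloatingPointError("degenerate naive-decoding scores")
    return p / total


def decode_naive_counted(code: CodingMatrix, g) -> tuple[np.ndarray, int]:
    """Pure-Python naive decoder that counts its elementary operations.

    Returns ``(posterior, ops)`` where ``ops`` is the number of per-(class,
    column) log terms accumulated — the quantity that certifies the decoder
    runs in time linear in L for fixed K.  Numerically identical to
    :func:`decode_naive`.
    """
    g = _check_outputs(code, g)
    g = np.clip(g, EPS, 1.0 - EPS)
    ops = 0
    scores = np.zeros(code.K)
    for k in range(code.K):
        for i in range(code.L):
            m = int(code.entries[k, i])
            if m == DELTA:
                continue
            scores[k] += np.log(g[i]) if m == ONE else np.log1p(-g[i])
            ops += 1
    scores -= scores.max()
    p = np.exp(scores)
    return p / p.sum(), ops


# ---------------------------------------------------------------- GBT model


@dataclass
class GBTProblem:
    """One generalized Bradley-Terry decoding instance.

    ``positive_sets[i]`` / ``negative_sets[i]`` are the class-index sets of
    binary problem i; ``weights[i]`` is N_i, the number of training instances
    whose class participates in problem i (so better-supported classifiers
    count more); ``observations[i]`` is the predicted probability of problem
    i's positive side.
    """

    positive_sets: list[np.ndarray]
    negative_sets: list[np.ndarray]
    weights: np.ndarray
    observations: np.ndarray

    def __post_init__(self) -> None:
        self.positive_sets = [np.asarray(s, dtype=int) for s in self.positive_sets]
        self.negative_sets = [np.asarray(s, dtype=int) for s in self.negative_sets]
        self.weights = np.asarray(self.weights, dtype=float)
        self.observations = np.asarray(self.observations, dtype=float).ravel()
        L = len(self.positive_sets)
        if not (len(self.negative_sets) == self.weights.size == self.observations.size == L):
            raise ValueError("positive_sets, negative_sets, weights, observations "
                             "must all have the same length")
        for i, (pos, neg) in enumerate(zip(self.positive_sets, self.negative_sets)):
            if pos.size == 0 or neg.size == 0:
                raise ValueError(f"problem {i}: empty positive or negative set")
            if np.intersect1d(pos, neg).size:
                raise ValueError(f"problem {i}: positive and negative sets overlap")
        if np.any(self.weights <= 0):
            raise ValueError("weights (N_i) must be positive")
        if np.any(self.observations < 0) or np.any(self.observations > 1):
            raise ValueError("observations must lie in [0, 1]")

    @property
    def L(self) -> int:
        return len(self.positive_sets)

    @property
    def K(self) -> int:
        return int(max(max(s.max() for s in self.positive_sets),
                       max(s.max() for s in self.negative_sets))) + 1

    @classmethod
    def from_code(cls, code: CodingMatrix, g, weights=None) -> "GBTProblem":
        """Build the decoding instance for one input from a coding matrix."""
        g = _check_outputs(code, g)
        if weights is None:
            weights = np.ones(code.L)
        return cls(
            positive_sets=[code.positive_classes(i) for i in range(code.L)],
            negative_sets=[code.negative_classes(i) for i in range(code.L)],
            weights=np.asarray(weights, dtype=float),
            observations=g,
        )


@dataclass
class GBTResult:
    posterior: np.ndarray
    n_iter: int
    converged: bool
    objective: list[float] = field(default_factory=list)


def gbt_objective(problem: GBTProblem, p: np.ndarray) -> float:
    """Weighted negative log-likelihood of p under the GBT model.

    Sum over problems of -N_i [ r_i log(q_i+/q_i) + (1-r_i) log(q_i-/q_i) ],
    with the q terms floored to avoid log(0).
    """
    p = np.asarray(p, dtype=float)
    total = 0.0
    for pos, neg, w, r in zip(
        problem.positive_sets, problem.negative_sets,
        problem.weights, problem.observations,
    ):
        qp = max(p[pos].sum(), EPS)
        qn = max(p[neg].sum(), EPS)
        q = max(qp + qn, EPS)
        total -= w * (r * np.log(qp / q) + (1.0 - r) * np.log(qn / q))
    return float(total)


def decode_gbt(
    problem: GBTProblem, max_iter: int = 1000, tol: float = 1e-8,
    track_objective: bool = True,
) -> GBTResult:
    """Generalized Bradley-Terry decoding by multiplicative fixed point.

    Starting from the uniform vector, each sweep rescales

        p_k <- p_k * [ sum_{i: k in I_i+} N_i r_i / q_i+
                       + sum_{i: k in I_i-} N_i (1 - r_i) / q_i- ]
                   / [ sum_{i: k in I_i} N_i / q_i ]

    and renormalizes, with q_i+, q_i-, q_i recomputed from the current p.
    Stops when the largest per-class change falls below ``tol`` or after
    ``max_iter`` sweeps.  Non-convergence is reported, not raised: under a
    general decomposition the iteration need not converge.
    """
    K = problem.K
    p = np.full(K, 1.0 / K)
    result = GBTResult(posterior=p, n_iter=0, converged=False)
    if track_objective:
        result.objective.append(gbt_objective(problem, p))
    for sweep in range(1, max_iter + 1):
        num = np.zeros(K)
        den = np.zeros(K)
        for pos, neg, w, r in zip(
            problem.positive_sets, problem.negative_sets,
            problem.weights, problem.observations,
        ):
            qp = max(p[pos].sum(), EPS)
            qn = max(p[neg].sum(), EPS)
            q = max(qp + qn, EPS)
            num[pos] += w * r / qp
            num[neg] += w * (1.0 - r) / qn
            den[pos] += w / q
            den[neg] += w / q
        new_p = p * num / np.maximum(den, EPS)
        total = new_p.sum()
        if not np.isfinite(total) or total <= 0.0:
            raise FloatingPointError("GBT update produced a degenerate vector")
        new_p /= total
        delta = float(np.max(np.abs(new_p - p)))
        p = new_p
        result.n_iter = sweep
        if track_objective:
            result.objective.append(gbt_objective(problem, p))
        if delta < tol:
            result.converged = True
            break
    result.posterior = p
    return result
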