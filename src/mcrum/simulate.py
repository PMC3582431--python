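"""Seeded synthetic data: every part of the package is testable offline.

Three generators:

* Gaussian class blobs — generic multiclass feature tables;
* consistency-constructed Bradley-Terry observations — binary outputs that
  exactly satisfy the GBT model for a known class-probability vector, the
  recovery oracle for the GBT decoder;
* composition-biased random RNA sequences — per-class first-order
  (dinucleotide) Markov chains, so that k > 1 k-mer features carry class
  signal; bias strength 0 makes all classes identically distributed.

All generators are pure functions of their seed and parameters.  They test
the machinery, not the biology: no attempt is made to mimic real miRNA or
piRNA motif structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codes import CodingMatrix
from .datasets import LabeledDataset
from .decoders import GBTProblem
from .sequences import ALPHABET, NcRnaRecord

__all__ = [
    "BlobSpec",
    "gaussian_blobs",
    "consistent_gbt_observations",
    "synthetic_sequences",
]


@dataclass
class BlobSpec:
    """Isotropic Gaussian blob layout: one center per class."""

    centers: list
    n_per_class: int = 100
    sigma: float = 1.0
    seed: int = 0
    class_names: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be positive")
        if self.class_names is None:
            self.class_names = [f"C{k + 1}" for k in range(self.centers.shape[0])]
        elif len(self.class_names) != self.centers.shape[0]:
            raise ValueError("one class name per center required")

    @property
    def K(self) -> int:
        return self.centers.shape[0]


def gaussian_blobs(spec: BlobSpec) -> LabeledDataset:
    """Sample the blob layout into a labeled feature table."""
    rng = np.random.default_rng(spec.seed)
    feats = []
    labels = []
    for k in range(spec.K):
        feats.append(
            spec.centers[k]
            + spec.sigma * rng.standard_normal((spec.n_per_class, spec.centers.shape[1]))
        )
        labels.extend([spec.class_names[k]] * spec.n_per_class)
    return LabeledDataset(np.vstack(feats), labels, class_names=list(spec.class_names))


def consistent_gbt_observations(
    p_true, code: CodingMatrix, weights=None
) -> GBTProblem:
    """Binary outputs that exactly satisfy the Bradley-Terry relation.

    For each column i the observation is r_i = q_i+ / q_i with the q sums
    taken under ``p_true``, so the GBT decoder applied to the result must
    recover ``p_true`` (up to its convergence tolerance).
    """
    p = np.asarray(p_true, dtype=float).ravel()
    if p.size != code.K:
        raise ValueError("p_true length must equal the number of classes")
    if np.any(p <= 0):
        raise ValueError("p_true must be strictly positive")
    p = p / p.sum()
    obs = np.empty(code.L)
    for i in range(code.L):
        qp = p[code.positive_classes(i)].sum()
        qn = p[code.negative_classes(i)].sum()
        if qp + qn <= 0:
            raise ValueError(f"column {i}: zero total probability mass")
        obs[i] = qp / (qp + qn)
    if weights is None:
        weights = np.ones(code.L)
    return GBTProblem(
        positive_sets=[code.positive_classes(i) for i in range(code.L)],
        negative_sets=[code.negative_classes(i) for i in range(code.L)],
        weights=np.asarray(weights, dtype=float),
        observations=obs,
    )


def _class_transition_matrix(
    rng: np.random.Generator, bias_strength: float
) -> np.ndarray:
    """Row-stochastic 4x4 dinucleotide transition matrix.

    A convex mix of the uniform chain and a class-specific Dirichlet draw;
    bias_strength 0 gives the uniform chain (no class signal), large values
    concentrate on the class's own random profile.
    """
    base = np.full((4, 4), 0.25)
    if bias_strength <= 0:
        return base
    perturb = rng.dirichlet(np.ones(4), size=4)
    t = bias_strength / (1.0 + bias_strength)
    return (1.0 - t) * base + t * perturb


def synthetic_sequences(
    K: int,
    n_per_class: int,
    length_range: tuple[int, int] = (15, 40),
    bias_strength: float = 1.0,
    seed: int = 0,
    class_names: list[str] | None = None,
) -> tuple[list[NcRnaRecord], list[str]]:
    """Composition-biased random RNA sequences, one Markov chain per class.

    Lengths are uniform over ``length_range`` (defaults span the observed
    miRNA 15-33 nt and piRNA 16-40 nt ranges).  Returns (records, labels).
    """
    lo, hi = length_range
    if lo < 5:
        raise ValueError("minimum length must be >= 5 so all k-mer blocks populate")
    if hi < lo:
        raise ValueError("invalid length range")
    rng = np.random.default_rng(seed)
    names = class_names or [f"class{k + 1}" for k in range(K)]
    if len(names) != K:
        raise ValueError("one class name per class required")
    transitions = [_class_transition_matrix(rng, bias_strength) for _ in range(K)]
    stationary_start = np.full(4, 0.25)
    records: list[NcRnaRecord] = []
    labels: list[str] = []
    for k in range(K):
        T = transitions[k]
        for j in range(n_per_class):
            length = int(rng.integers(lo, hi + 1))
            states = np.empty(length, dtype=int)
            states[0] = rng.choice(4, p=stationary_start)
            for s in range(1, length):
                states[s] = rng.choice(4, p=T[states[s - 1]])
            seq = "".join(ALPHABET[s] for s in states)
            records.append(NcRnaRecord(f"{names[k]}_{j}", seq))
            labels.append(names[k])
    return records, labels
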