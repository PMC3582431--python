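"""Coding matrices for error-correcting output codes (ECOC).

A K-class problem is decomposed into L binary problems via a K x L coding
matrix over the symbols {1, 0, DELTA}: column i defines binary problem i,
with 1 marking classes in its positive set, 0 the negative set, and DELTA
classes omitted from its training entirely.  Rows act as per-class codewords;
prediction is (soft or hard) decoding of the observed binary outputs to the
nearest codeword.

Symbols are stored as a small-int array: 1 = positive, 0 = negative,
-1 = DELTA (rendered as ``"D"`` in text form).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

__all__ = [
    "ONE",
    "ZERO",
    "DELTA",
    "CodingMatrix",
    "ovr_matrix",
    "ap_matrix",
    "code_distance",
    "min_row_distance",
    "random_code_candidates",
    "random_code_matrix",
]

ONE: int = 1
ZERO: int = 0
DELTA: int = -1

_SYMBOL_TO_STR = {ONE: "1", ZERO: "0", DELTA: "D"}
_STR_TO_SYMBOL = {v: k for k, v in _SYMBOL_TO_STR.items()}


@dataclass(frozen=True)
class CodingMatrix:
    """K x L matrix over {1, 0, DELTA} defining a binary decomposition.

    Validity constraints (checked on construction):

    1. all rows and all columns are unique;
    2. no row consists solely of DELTA;
    3. every column contains at least one 1 and at least one 0.
    """

    entries: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.entries, dtype=np.int8)
        object.__setattr__(self, "entries", arr)
        if arr.ndim != 2:
            raise ValueError("coding matrix must be 2-D")
        K, L = arr.shape
        if K < 2:
            raise ValueError("need at least two classes (rows)")
        if L < 1:
            raise ValueError("need at least one binary problem (column)")
        bad = set(np.unique(arr)) - {ONE, ZERO, DELTA}
        if bad:
            raise ValueError(f"invalid symbols in coding matrix: {bad}")
        rows = {tuple(r) for r in arr}
        if len(rows) != K:
            raise ValueError("rows of the coding matrix are not unique")
        cols = {tuple(c) for c in arr.T}
        if len(cols) != L:
            raise ValueError("columns of the coding matrix are not unique")
        if np.any(np.all(arr == DELTA, axis=1)):
            raise ValueError("a row consists solely of DELTA")
        has_one = np.any(arr == ONE, axis=0)
        has_zero = np.any(arr == ZERO, axis=0)
        if not (has_one.all() and has_zero.all()):
            raise ValueError("every column needs at least one 1 and one 0")

    @property
    def K(self) -> int:
        return self.entries.shape[0]

    @property
    def L(self) -> int:
        return self.entries.shape[1]

    def row(self, k: int) -> np.ndarray:
        return self.entries[k]

    def positive_classes(self, i: int) -> np.ndarray:
        """Row indices in the positive set of column i."""
        return np.flatnonzero(self.entries[:, i] == ONE)

    def negative_classes(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.entries[:, i] == ZERO)

    # --------------------------------------------------------- text form
    def to_strings(self) -> list[str]:
        """Rows as strings over {1, 0, D}, e.g. ``["11D", "0D1", "D00"]``."""
        return ["".join(_SYMBOL_TO_STR[int(e)] for e in row) for row in self.entries]

    @classmethod
    def from_strings(cls, rows: list[str]) -> "CodingMatrix":
        arr = np.array(
            [[_STR_TO_SYMBOL[ch] for ch in row] for row in rows], dtype=np.int8
        )
        return cls(arr)

    def to_tsv(self, path, class_names: list[str] | None = None) -> None:
        names = class_names or [f"C{k + 1}" for k in range(self.K)]
        with open(path, "w") as fh:
            for name, row in zip(names, self.to_strings()):
                fh.write(f"{name}\t" + "\t".join(row) + "\n")


def ovr_matrix(K: int) -> CodingMatrix:
    """One-versus-rest decomposition: the K x K identity pattern.

    Column k trains class k (positive) against all the others (negative);
    no class is ever omitted.
    """
    if K < 2:
        raise ValueError("K must be at least 2")
    arr = np.full((K, K), ZERO, dtype=np.int8)
    np.fill_diagonal(arr, ONE)
    return CodingMatrix(arr)


def ap_matrix(K: int) -> CodingMatrix:
    """All-pairs decomposition: one column per unordered class pair.

    Columns enumerate pairs (i, j), i < j, in lexicographic order; the column
    for (i, j) has row i = 1, row j = 0 and DELTA everywhere else, so each
    binary problem sees exactly two classes.
    """
    if K < 2:
        raise ValueError("K must be at least 2")
    pairs = list(combinations(range(K), 2))
    arr = np.full((K, len(pairs)), DELTA, dtype=np.int8)
    for col, (i, j) in enumerate(pairs):
        arr[i, col] = ONE
        arr[j, col] = ZERO
    return CodingMatrix(arr)


def code_distance(y, z) -> float:
    """Modified Hamming distance between two code rows.

    Per position: cost 0 if the symbols are equal and neither is DELTA,
    cost 1 if they differ and neither is DELTA, cost 1/2 if either symbol
    is DELTA (including both).
    """
    y = np.asarray(y, dtype=np.int8)
    z = np.asarray(z, dtype=np.int8)
    if y.shape != z.shape:
        raise ValueError(f"row length mismatch: {y.shape} vs {z.shape}")
    either_delta = (y == DELTA) | (z == DELTA)
    differ = (y != z) & ~either_delta
    return float(0.5 * np.count_nonzero(either_delta) + np.count_nonzero(differ))


def min_row_distance(code: CodingMatrix) -> float:
    """Smallest pairwise modified-Hamming distance between code rows."""
    return min(
        code_distance(code.entries[a], code.entries[b])
        for a, b in combinations(range(code.K), 2)
    )


def _sample_column(rng: np.random.Generator, K: int, kind: str) -> np.ndarray:
    if kind == "dense":
        return rng.integers(0, 2, size=K).astype(np.int8)
    # sparse: DELTA w.p. 1/2, ONE and ZERO w.p. 1/4 each
    return rng.choice(
        np.array([DELTA, ZERO, ONE], dtype=np.int8), size=K, p=[0.5, 0.25, 0.25]
    )


def _sample_valid_matrix(
    rng: np.random.Generator, K: int, L: int, kind: str, max_tries: int
) -> CodingMatrix:
    """One valid random matrix; invalid columns/rows are resampled column-wise."""
    cols: list[np.ndarray] = []
    for _ in range(L):
        for _ in range(max_tries):
            c = _sample_column(rng, K, kind)
            if (
                np.any(c == ONE)
                and np.any(c == ZERO)
                and not any(np.array_equal(c, prev) for prev in cols)
            ):
                cols.append(c)
                break
        else:
            raise RuntimeError(
                f"could not sample a valid distinct column for K={K}, kind={kind} "
                f"within {max_tries} tries (L may be too large)"
            )
    arr = np.column_stack(cols)
    # repair row-level violations by resampling columns round-robin
    for attempt in range(max_tries):
        rows_ok = (
            len({tuple(r) for r in arr}) == K
            and not np.any(np.all(arr == DELTA, axis=1))
        )
        if rows_ok:
            return CodingMatrix(arr)
        j = attempt % L
        for _ in range(max_tries):
            c = _sample_column(rng, K, kind)
            others = np.delete(arr, j, axis=1)
            if (
                np.any(c == ONE)
                and np.any(c == ZERO)
                and not any(np.array_equal(c, others[:, t]) for t in range(others.shape[1]))
            ):
                arr = arr.copy()
                arr[:, j] = c
                break
        else:
            raise RuntimeError(
                f"could not repair row constraints for K={K}, L={L}, kind={kind}"
            )
    raise RuntimeError(
        f"no valid {kind} matrix with K={K}, L={L} within the retry budget; "
        "L is likely too small for unique rows"
    )


def random_code_candidates(
    K: int, L: int, kind: str = "dense", n_candidates: int = 100,
    seed: int = 0, max_tries: int = 1000,
) -> list[CodingMatrix]:
    """The full seeded candidate pool behind :func:`random_code_matrix`.

    Exposed so the selection can be audited: re-enumerating the pool with the
    same seed and taking the max-min-row-distance member must reproduce the
    chosen matrix.
    """
    if K < 2:
        raise ValueError("K must be at least 2")
    if n_candidates < 1:
        raise ValueError("need at least one candidate")
    if kind not in ("dense", "sparse"):
        raise ValueError(f"kind must be 'dense' or 'sparse', got {kind!r}")
    rng = np.random.default_rng(seed)
    return [_sample_valid_matrix(rng, K, L, kind, max_tries) for _ in range(n_candidates)]


def random_code_matrix(
    K: int, L: int, kind: str = "dense", n_candidates: int = 100,
    seed: int = 0, max_tries: int = 1000,
) -> CodingMatrix:
    """Best-of-pool random coding matrix.

    Generates ``n_candidates`` valid random matrices (dense: entries uniform
    over {1, 0}; sparse: DELTA w.p. 1/2, 1 and 0 w.p. 1/4 each) and returns
    the one whose minimum pairwise row distance is largest — the standard
    row-separation design criterion.  Ties keep the earliest candidate;
    deterministic given the seed.
    """
    pool = random_code_candidates(K, L, kind, n_candidates, seed, max_tries)
    scores = [min_row_distance(m) for m in pool]
    return pool[int(np.argmax(scores))]
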