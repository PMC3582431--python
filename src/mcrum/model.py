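"""Training and prediction for the multiclass relevance units machine.

Training: one shared clustering of all unlabeled features picks the M
relevance units and the Gaussian kernel width; then one binary CRUM is fit
per column of the coding matrix, using the classes marked 1 as positives,
those marked 0 as negatives, and omitting DELTA classes.  Prediction runs
every binary classifier on the input and hands the vector of binary
posteriors to the chosen decoder; a rejection threshold may leave an input
UNCLASSIFIED when the winning posterior is not confident enough.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .codes import CodingMatrix
from .crum import BinaryCRUM, KernelSpec, predict_binary, train_binary_crum
from .datasets import LabeledDataset
from .decoders import GBTProblem, decode_gbt, decode_hard, decode_naive
from .model_selection import compute_gamma, default_m_grid, kmeans_centers, select_complexity

logger = logging.getLogger(__name__)

__all__ = [
    "UNCLASSIFIED",
    "SCHEMA_VERSION",
    "McRUMModel",
    "Prediction",
    "train_mcrum",
    "binary_outputs",
    "decode_posteriors",
    "predict_mcrum",
    "predict_batch",
    "save_model",
    "load_model",
]

UNCLASSIFIED = "UNCLASSIFIED"
SCHEMA_VERSION = 1


@dataclass
class McRUMModel:
    """A trained multiclass model: coding matrix + L binary CRUMs.

    ``train_counts[i]`` is N_i, the number of training rows participating in
    binary problem i (classes not marked DELTA in column i); the GBT decoder
    uses these as likelihood weights.  ``standardization`` holds per-feature
    (mean, scale) if z-scoring was applied at training time, else None.
    """

    code: CodingMatrix
    classifiers: list[BinaryCRUM]
    class_names: list[str]
    train_counts: list[int]
    standardization: tuple[np.ndarray, np.ndarray] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.classifiers) != self.code.L:
            raise ValueError("one classifier per coding-matrix column required")
        if len(self.class_names) != self.code.K:
            raise ValueError("class_names must match coding-matrix rows")
        if len(self.train_counts) != self.code.L:
            raise ValueError("one training count per column required")
        dims = {c.feature_dim for c in self.classifiers}
        if len(dims) != 1:
            raise ValueError("classifiers disagree on feature dimension")

    @property
    def feature_dim(self) -> int:
        return self.classifiers[0].feature_dim

    def _transform(self, X: np.ndarray) -> np.ndarray:
        if self.standardization is None:
            return X
        mean, scale = self.standardization
        return (X - mean) / scale


@dataclass
class Prediction:
    """Decoded outcome for one input.

    ``label`` is the argmax class when its posterior reaches the threshold,
    else :data:`UNCLASSIFIED`.  Hard decoding carries no posterior.
    """

    posterior: np.ndarray | None
    label: str
    threshold: float


def _column_partitions(data: LabeledDataset, code: CodingMatrix):
    """Per-column (positive rows, negative rows) index arrays per Algorithm-style
    assembly: entry 1 -> positive, 0 -> negative, DELTA omitted."""
    y = data.class_indices()
    for i in range(code.L):
        pos_classes = set(code.positive_classes(i).tolist())
        neg_classes = set(code.negative_classes(i).tolist())
        pos_rows = np.flatnonzero([c in pos_classes for c in y])
        neg_rows = np.flatnonzero([c in neg_classes for c in y])
        yield i, pos_rows, neg_rows


def train_mcrum(
    data: LabeledDataset,
    code: CodingMatrix,
    M: int | str = "auto",
    gamma: float | str = "auto",
    seed: int = 0,
    standardize: bool = True,
    restarts: int = 5,
    max_outer: int = 100,
    tol: float = 1e-8,
) -> McRUMModel:
    """Train one multiclass model.

    M and gamma may be "auto": M is then chosen by K-means + AIC over a
    doubling grid and gamma from the maximum distance between the chosen
    cluster centers.  The same units and width are shared by all L binary
    classifiers.  ``standardize`` z-scores the features (recommended for
    generic tabular data; switch off for already-normalized k-mer
    frequencies).  Deterministic given the seed.
    """
    if data.n_classes != code.K:
        raise ValueError(
            f"dataset has {data.n_classes} classes but the coding matrix has {code.K} rows"
        )
    X = data.features
    standardization = None
    if standardize:
        mean = X.mean(axis=0)
        scale = np.maximum(X.std(axis=0), 1e-12)
        standardization = (mean, scale)
        X = (X - mean) / scale

    if M == "auto":
        grid = default_m_grid(data.n)
        M_sel, clustering = select_complexity(X, grid, seed=seed, restarts=restarts)
    else:
        M_sel = int(M)
        clustering = kmeans_centers(X, M_sel, seed=seed, restarts=restarts)
    units = clustering.centers
    if gamma == "auto":
        gamma_sel = compute_gamma(units)
    else:
        gamma_sel = float(gamma)
    kernel = KernelSpec("gaussian", gamma_sel)
    logger.info("selected M=%d, gamma=%.6g", M_sel, gamma_sel)

    classifiers: list[BinaryCRUM] = []
    counts: list[int] = []
    for i, pos_rows, neg_rows in _column_partitions(data, code):
        if pos_rows.size == 0 or neg_rows.size == 0:
            raise ValueError(
                f"column {i}: no training data on the "
                f"{'positive' if pos_rows.size == 0 else 'negative'} side"
            )
        clf = train_binary_crum(
            X[pos_rows], X[neg_rows], units, kernel, max_outer=max_outer, tol=tol
        )
        classifiers.append(clf)
        counts.append(int(pos_rows.size + neg_rows.size))
        logger.info(
            "column %d: N_i=%d, outer iterations=%d, alpha=%.4g",
            i, counts[-1], len(clf.history), clf.alpha,
        )
    return McRUMModel(
        code=code,
        classifiers=classifiers,
        class_names=list(data.class_names),
        train_counts=counts,
        standardization=standardization,
        metadata={"seed": int(seed), "M": int(M_sel), "gamma": float(gamma_sel)},
    )


def binary_outputs(model: McRUMModel, X) -> np.ndarray:
    """(N, L) matrix of binary posteriors g_i(x) for the rows of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.feature_dim:
        raise ValueError(
            f"input dimension {X.shape[1]} does not match model ({model.feature_dim})"
        )
    Xs = model._transform(X)
    cols = [predict_binary(clf, Xs) for clf in model.classifiers]
    return np.column_stack(cols)


def decode_posteriors(model: McRUMModel, X, decoder: str = "naive") -> np.ndarray:
    """(N, K) decoded class posteriors (decoder "naive" or "gbt")."""
    G = binary_outputs(model, X)
    if decoder == "naive":
        return np.vstack([decode_naive(model.code, g) for g in G])
    if decoder == "gbt":
        out = []
        for g in G:
            prob = GBTProblem.from_code(model.code, g, weights=model.train_counts)
            out.append(decode_gbt(prob, track_objective=False).posterior)
        return np.vstack(out)
    raise ValueError(f"unknown soft decoder {decoder!r}")


def _label_from_posterior(model: McRUMModel, p: np.ndarray, threshold: float) -> str:
    k = int(np.argmax(p))
    if p[k] >= threshold:
        return model.class_names[k]
    return UNCLASSIFIED


def predict_mcrum(
    model: McRUMModel, x, decoder: str = "naive", threshold: float = 0.0
) -> Prediction:
    """Predict one input.

    With a soft decoder the label is the argmax class if its posterior
    reaches ``threshold`` and UNCLASSIFIED otherwise; threshold 0 always
    assigns the argmax.  Hard decoding yields no posterior and therefore
    admits no rejection threshold.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must lie in [0, 1)")
    x = np.asarray(x, dtype=float).ravel()
    if decoder == "hard":
        if threshold > 0.0:
            raise ValueError("hard decoding yields no posterior; threshold must be 0")
        g = binary_outputs(model, x)[0]
        k = decode_hard(model.code, g)
        return Prediction(posterior=None, label=model.class_names[k], threshold=0.0)
    p = decode_posteriors(model, x, decoder=decoder)[0]
    return Prediction(posterior=p, label=_label_from_posterior(model, p, threshold),
                      threshold=threshold)


def predict_batch(
    model: McRUMModel, X, decoder: str = "naive", threshold: float = 0.0
) -> list[Prediction]:
    """Vector of :class:`Prediction` for the rows of X."""
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must lie in [0, 1)")
    if decoder == "hard":
        if threshold > 0.0:
            raise ValueError("hard decoding yields no posterior; threshold must be 0")
        G = binary_outputs(model, X)
        return [
            Prediction(None, model.class_names[decode_hard(model.code, g)], 0.0)
            for g in G
        ]
    P = decode_posteriors(model, X, decoder=decoder)
    return [
        Prediction(p, _label_from_posterior(model, p, threshold), threshold) for p in P
    ]


# -------------------------------------------------------------- persistence


def _model_payload(model: McRUMModel) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "code": model.code.to_strings(),
        "class_names": list(model.class_names),
        "train_counts": [int(c) for c in model.train_counts],
        "classifiers": [c.to_dict() for c in model.classifiers],
        "standardization": None
        if model.standardization is None
        else {
            "mean": model.standardization[0].tolist(),
            "scale": model.standardization[1].tolist(),
        },
        "metadata": model.metadata,
    }


def save_model(model: McRUMModel, path) -> None:
    """Serialize to schema-versioned JSON; floats round-trip losslessly."""
    with open(path, "w") as fh:
        json.dump(_model_payload(model), fh, sort_keys=True, separators=(",", ":"))
        fh.write("\n")


def load_model(path) -> McRUMModel:
    with open(path) as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"not a valid model file: {exc}") from exc
    if not isinstance(d, dict) or "schema_version" not in d:
        raise ValueError("not a model file: missing schema_version")
    if d["schema_version"] != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported model schema version {d['schema_version']} "
            f"(this build reads version {SCHEMA_VERSION})"
        )
    std = d["standardization"]
    return McRUMModel(
        code=CodingMatrix.from_strings(d["code"]),
        classifiers=[BinaryCRUM.from_dict(c) for c in d["classifiers"]],
        class_names=list(d["class_names"]),
        train_counts=[int(c) for c in d["train_counts"]],
        standardization=None
        if std is None
        else (np.array(std["mean"], dtype=float), np.array(std["scale"], dtype=float)),
        metadata=d.get("metadata", {}),
    )
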