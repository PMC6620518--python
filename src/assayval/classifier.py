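"""Transparent linear surrogate classifier.

This is deliberately NOT a re-implementation of any proprietary ensemble
classifier.  It is a ridge-regularized diagonal centroid discriminant — a
linear score on normalized expression with a fixed decision threshold —
chosen so that analytic crossing points exist for limit-of-detection and
interference oracles: the score is exactly linear in the expression
profile, so the score of a convex mixture is the same convex combination
of the parent scores.

Call convention: a sample is called positive iff its score is strictly
above the threshold; a score exactly at the threshold is called negative
(a rule-out test should not emit positive on a knife edge).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import POSITIVE


@dataclass
class ClassifierModel:
    """Linear score ``w . x + intercept`` with decision threshold ``t``."""

    genes: list[str]
    weights: np.ndarray
    intercept: float
    threshold: float
    score_range: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        half = self.score_range / 2
        if not (-half <= self.threshold <= half):
            raise ValueError("threshold must lie inside the declared score range")

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#intercept\t{float(self.intercept)!r}\n")
            fh.write(f"#threshold\t{float(self.threshold)!r}\n")
            fh.write(f"#score_range\t{float(self.score_range)!r}\n")
            fh.write("gene\tweight\n")
            for g, w in zip(self.genes, self.weights):
                fh.write(f"{g}\t{float(w)!r}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ClassifierModel":
        header: dict[str, float] = {}
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for line in lines:
            if not line.startswith("#"):
                break
            key, value = line[1:].strip().split("\t")
            header[key] = float(value)
            body_start += 1
        df = pd.read_csv(path, sep="\t", skiprows=body_start, float_precision="round_trip")
        return cls(
            genes=[str(g) for g in df["gene"]],
            weights=df["weight"].to_numpy(dtype=float),
            intercept=header["intercept"],
            threshold=header["threshold"],
            score_range=header["score_range"],
        )


def train_classifier(
    X: np.ndarray,
    genes: list[str],
    labels: np.ndarray,
    ridge_penalty: float = 1.0,
    score_range: float = 8.0,
    seed: int = 0,
) -> ClassifierModel:
    """Fit the surrogate on a normalized genes-x-samples matrix.

    The direction is the class-centroid difference shrunk gene-wise by the
    ridge penalty, ``w_g = (c_pos - c_neg) / (v_g + penalty)`` with ``v_g``
    the pooled within-class variance.  Scores are affinely rescaled so the
    two class mean scores sit at ±score_range/4 and the threshold at their
    midpoint (0).  ``seed`` is accepted for interface symmetry; the fit is
    deterministic.
    """
    labels = np.asarray(labels)
    X = np.asarray(X, dtype=float)
    pos = labels == POSITIVE
    neg = ~pos
    if not pos.any() or not neg.any():
        raise ValueError("training data must contain both classes")
    if ridge_penalty < 0:
        raise ValueError("ridge_penalty must be >= 0")

    c_pos = X[:, pos].mean(axis=1)
    c_neg = X[:, neg].mean(axis=1)
    v = (X[:, pos].var(axis=1) + X[:, neg].var(axis=1)) / 2
    w = (c_pos - c_neg) / (v + ridge_penalty)

    mid = (w @ c_pos + w @ c_neg) / 2
    sep = w @ c_pos - w @ c_neg
    if sep <= 0:
        raise ValueError("degenerate training data: class centroids coincide")
    scale = (score_range / 2) / sep  # class means land at +/- range/4
    return ClassifierModel(
        genes=list(genes),
        weights=w * scale,
        intercept=-mid * scale,
        threshold=0.0,
        score_range=score_range,
    )


def score_samples(
    model: ClassifierModel, X: np.ndarray, genes: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Score columns of a normalized matrix; returns (scores, calls).

    ``calls`` is boolean, positive iff score strictly exceeds the model
    threshold.  The model's genes must all be present; rows are aligned by
    gene identifier.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(genes) and X.shape[1] == len(genes):
        X = X.T
    index = {g: i for i, g in enumerate(genes)}
    missing = [g for g in model.genes if g not in index]
    if missing:
        raise ValueError(f"matrix is missing model genes: {missing[:10]}")
    rows = [index[g] for g in model.genes]
    scores = model.weights @ X[rows, :] + model.intercept
    calls = scores > model.threshold
    return scores, calls
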