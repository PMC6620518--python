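"""In-silico count mixing, titration grids, and limit-of-detection rules.

A titration mixes a classifier-positive count profile C1 with a
classifier-negative profile C2 at positive-content fraction p:

    C_j = p * C1' + (1 - p) * C2'

where C1', C2' are the parents rescaled to a common total so that p is
interpretable as an RNA mass fraction (physical mixtures combine equal
total RNA mass, not equal sequencing depth).  The mixture is kept
real-valued; no rounding.

The limit of detection (LOD) is the smallest positive-content fraction at
which the classifier still calls the mixture positive — requiring a
correct call at that fraction and at every larger tested fraction, so a
single non-monotone blip cannot shrink the LOD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import ClassifierModel, score_samples
from .containers import CountMatrix
from .normalization import normalize_counts, size_factors


def _rescale_to_common_total(c1: np.ndarray, c2: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    total = (c1.sum() + c2.sum()) / 2
    return c1 * (total / c1.sum()), c2 * (total / c2.sum()), total


def mix_counts(c1: np.ndarray, c2: np.ndarray, p: float) -> np.ndarray:
    """Convex count mixture at positive-mass fraction ``p``.

    Parents are rescaled to a common total first; endpoints are exact up to
    that rescaling (``p=1`` returns rescaled ``c1``, ``p=0`` rescaled
    ``c2``; parents with equal totals are returned unchanged).
    """
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    if c1.shape != c2.shape:
        raise ValueError(f"gene sets differ: {c1.shape} vs {c2.shape}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"mixture fraction must lie in [0, 1], got {p}")
    c1s, c2s, _ = _rescale_to_common_total(c1, c2)
    return p * c1s + (1.0 - p) * c2s


@dataclass
class MixtureSeries:
    """Ordered titration points with scores, calls, and the derived LOD."""

    fractions: np.ndarray  # positive-content fraction p, strictly increasing
    scores: np.ndarray
    calls: np.ndarray  # boolean positive calls
    lod: float | None  # smallest reliably positive fraction, or None
    valid_pair: bool = True  # False if the p=0 negative control called positive
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if np.any(np.diff(self.fractions) <= 0):
            raise ValueError("fractions must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"p": self.fractions, "score": self.scores, "call": self.calls.astype(int)}
        )


def _contiguous_lod(fractions: np.ndarray, calls: np.ndarray) -> float | None:
    """Smallest nonzero fraction positive at itself and all larger fractions."""
    lod = None
    for p, call in sorted(zip(fractions, calls), reverse=True):
        if p == 0.0:
            break
        if not call:
            break
        lod = p
    return lod


def in_silico_titration(
    pos: np.ndarray,
    neg: np.ndarray,
    model: ClassifierModel,
    genes: list[str] | None = None,
    grid_step: float = 0.01,
    transform: str = "log2_mor",
    check_valid_pair: bool = True,
) -> MixtureSeries:
    """Titrate a positive/negative count-profile pair over a fine p grid.

    For each p on ``0, grid_step, ..., 1`` the pair is mixed, the whole
    series (mixtures plus both parents) is normalized with freshly computed
    median-of-ratios size factors, and each point is scored and called.

    ``transform='log2_mor'`` is the standard route (size factors + log2);
    ``transform='identity'`` scores raw mixed counts with unit size
    factors, the mode in which a linear model admits a closed-form
    threshold crossing.

    The p=0 point is a negative control: if it scores positive the pair is
    flagged invalid (``valid_pair=False``, LOD withheld) unless
    ``check_valid_pair=False``.
    """
    if genes is None:
        genes = model.genes
    n_steps = 1.0 / grid_step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(f"grid_step must divide 1 evenly, got {grid_step}")
    if transform not in ("log2_mor", "identity"):
        raise ValueError(f"unknown transform {transform!r}")
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.shape != neg.shape:
        raise ValueError("positive and negative profiles must share the gene set")

    grid = np.round(np.arange(0, round(n_steps) + 1) * grid_step, 10)
    c1, c2, _ = _rescale_to_common_total(pos, neg)
    mixtures = grid[None, :] * c1[:, None] + (1.0 - grid[None, :]) * c2[:, None]

    if transform == "log2_mor":
        cols = [f"p{i}" for i in range(len(grid))] + ["parent_pos", "parent_neg"]
        series = CountMatrix(
            genes=list(genes),
            samples=cols,
            counts=np.column_stack([mixtures, pos, neg]),
        )
        factors = size_factors(series)
        X = normalize_counts(series, factors)[:, : len(grid)]
    else:
        X = mixtures
    scores, calls = score_samples(model, X, list(genes))

    valid = not calls[0]
    lod: float | None = None
    if valid or not check_valid_pair:
        lod = _contiguous_lod(grid, calls)
    return MixtureSeries(
        fractions=grid,
        scores=scores,
        calls=calls,
        lod=lod,
        valid_pair=valid,
        metadata={
            "transform": transform,
            "grid_step": grid_step,
            "normalization_scope": "series_plus_parents" if transform == "log2_mor" else "unit",
        },
    )


def in_vitro_lod(
    levels: np.ndarray,
    calls: np.ndarray,
    expected_class: str = "positive",
) -> dict:
    """LOD from a discrete dilution design.

    ``levels`` are dilution percentages (percent diluent: 0 = pure
    positive sample), ``calls`` booleans for a positive classifier call at
    each level.  The 100% point, if present, is a pure-diluent negative
    control, never an LOD point; a positive call there is reported as a
    control failure.  LOD (percent positive content) = 100 minus the
    largest dilution level at which the call is correct at that level and
    every lower level.
    """
    levels = np.asarray(levels, dtype=float)
    calls = np.asarray(calls, dtype=bool)
    if levels.shape != calls.shape:
        raise ValueError("levels and calls must have equal length")
    if 0.0 not in levels:
        raise ValueError("levels must include the undiluted 0% point")
    order = np.argsort(levels)
    levels, calls = levels[order], calls[order]

    control_failure = False
    if levels[-1] == 100.0:
        control_failure = bool(calls[-1])
        levels, calls = levels[:-1], calls[:-1]

    correct = calls if expected_class == "positive" else ~calls
    max_tolerated = None
    for level, ok in zip(levels, correct):
        if not ok:
            break
        max_tolerated = level
    lod = None if max_tolerated is None else 100.0 - max_tolerated
    return {
        "lod_percent_positive": lod,
        "max_tolerated_dilution": max_tolerated,
        "negative_control_failure": control_failure,
    }
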