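"""Interferent titration analysis: contaminated profiles, sigmoid fits,
and maximum tolerated interference levels.

Blood or genomic-DNA contamination is modeled as a convex mixture of the
sample's count profile with an interferent profile at a given mass
fraction.  Score-versus-fraction curves are summarized with a 4-parameter
logistic (4PL) fit, and the tolerated level is the largest tested fraction
at which the classifier call is still correct, requiring correctness at
all smaller fractions too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .mixing import mix_counts


def make_contaminated(sample: np.ndarray, interferent: np.ndarray, fraction: float) -> np.ndarray:
    """Mix ``fraction`` interferent mass into a sample's count profile.

    Identical contract to :func:`assayval.mixing.mix_counts` with the
    interferent as the p-weighted component: both profiles are rescaled to
    a common total, then combined convexly.
    """
    return mix_counts(interferent, sample, fraction)


def _logistic4(x: np.ndarray, lower: float, upper: float, inflection: float, slope: float) -> np.ndarray:
    return lower + (upper - lower) / (1.0 + np.exp(-slope * (x - inflection)))


@dataclass
class SigmoidFit:
    """4-parameter logistic fit of scores against interferent fraction."""

    lower: float
    upper: float
    inflection: float
    slope: float
    rss: float
    crossing: float | None = None  # fraction where the curve crosses the threshold
    degenerate: bool = False

    def predict(self, fractions: np.ndarray) -> np.ndarray:
        if self.degenerate:
            return np.full_like(np.asarray(fractions, dtype=float), self.lower)
        return _logistic4(np.asarray(fractions, dtype=float), self.lower, self.upper, self.inflection, self.slope)


def fit_sigmoid(
    fractions: np.ndarray,
    scores: np.ndarray,
    threshold: float | None = None,
) -> SigmoidFit:
    """Least-squares 4PL fit in the fraction domain.

    The reported ``lower``/``upper`` always satisfy lower <= upper; a
    decreasing curve is carried by a negative slope.  If ``threshold`` is
    given and the fitted curve crosses it inside [0, 1], the crossing
    fraction is reported.  Non-convergence (or a flat response) falls back
    to a constant fit flagged ``degenerate``.
    """
    x = np.asarray(fractions, dtype=float)
    y = np.asarray(scores, dtype=float)
    if len(np.unique(x)) < 4:
        raise ValueError("sigmoid fit needs at least 4 distinct fractions")

    span = y.max() - y.min()
    if span < 1e-12:
        return SigmoidFit(lower=float(y.mean()), upper=float(y.mean()), inflection=0.5,
                          slope=0.0, rss=float(((y - y.mean()) ** 2).sum()), degenerate=True)

    increasing = y[np.argmax(x)] >= y[np.argmin(x)]
    p0 = [y.min(), y.max(), float(x[np.argsort(x)[len(x) // 2]]), 5.0 if increasing else -5.0]
    try:
        popt, _ = curve_fit(
            _logistic4, x, y, p0=p0, maxfev=20000,
            bounds=([y.min() - 2 * span, y.min() - 2 * span, -1.0, -200.0],
                    [y.max() + 2 * span, y.max() + 2 * span, 2.0, 200.0]),
        )
    except RuntimeError:
        mean = float(y.mean())
        return SigmoidFit(lower=mean, upper=mean, inflection=0.5, slope=0.0,
                          rss=float(((y - mean) ** 2).sum()), degenerate=True)

    lower, upper, inflection, slope = (float(v) for v in popt)
    if lower > upper:  # canonical orientation: flip asymptotes, negate slope
        lower, upper, slope = upper, lower, -slope
    rss = float(((_logistic4(x, lower, upper, inflection, slope) - y) ** 2).sum())

    crossing = None
    if threshold is not None and lower < threshold < upper and abs(slope) > 1e-12:
        ratio = (upper - lower) / (threshold - lower) - 1.0
        if ratio > 0:
            xc = inflection - np.log(ratio) / slope
            if 0.0 <= xc <= 1.0:
                crossing = float(xc)
    return SigmoidFit(lower=lower, upper=upper, inflection=inflection, slope=slope,
                      rss=rss, crossing=crossing)


def max_tolerated_level(
    levels: np.ndarray,
    calls: np.ndarray,
    expected_class: str = "positive",
) -> dict:
    """Largest interference percentage with a correct call (contiguity rule).

    ``levels`` are interferent percentages sorted ascending and including
    0; ``calls`` are positive classifier calls.  The tolerated level is the
    largest level whose call is correct at that level and at every smaller
    level.  An incorrect call at level 0 is a baseline failure (no
    interference present) and is reported as such.
    """
    levels = np.asarray(levels, dtype=float)
    calls = np.asarray(calls, dtype=bool)
    if levels.shape != calls.shape:
        raise ValueError("levels and calls must have equal length")
    if np.any(np.diff(levels) < 0):
        raise ValueError("levels must be sorted ascending")
    if levels[0] != 0.0:
        raise ValueError("levels must include the 0% baseline")

    correct = calls if expected_class == "positive" else ~calls
    if not correct[0]:
        return {"max_tolerated_percent": None, "baseline_failure": True}
    max_level = 0.0
    for level, ok in zip(levels, correct):
        if not ok:
            break
        max_level = level
    return {"max_tolerated_percent": float(max_level), "baseline_failure": False}
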