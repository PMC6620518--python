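"""Diagnostic performance and agreement statistics.

Sensitivity/specificity/PPV/NPV from confusion counts (with optional
re-projection to a supplied prevalence), positive/negative percent
agreement against a reference method, variant-allele-frequency call
thresholding, and paired score correlation with call concordance.

Undefined metrics (zero denominators) are surfaced as ``None`` / NaN,
never silently reported as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise ValueError("confusion counts must total at least 1")

    @classmethod
    def from_calls(cls, truth_positive: np.ndarray, call_positive: np.ndarray) -> "ConfusionCounts":
        t = np.asarray(truth_positive, dtype=bool)
        c = np.asarray(call_positive, dtype=bool)
        if t.shape != c.shape:
            raise ValueError("truth and call vectors must have equal length")
        return cls(
            tp=int(np.sum(t & c)),
            fp=int(np.sum(~t & c)),
            tn=int(np.sum(~t & ~c)),
            fn=int(np.sum(t & ~c)),
        )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def confusion_metrics(c: ConfusionCounts, prevalence: float | None = None) -> dict:
    """Sensitivity, specificity, PPV and NPV from confusion counts.

    With ``prevalence=None`` the predictive values are count-based (sample
    prevalence); with a supplied prevalence they are recomputed from
    sensitivity and specificity via Bayes' rule.  Metrics with empty
    denominators come back as ``None``.
    """
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    if prevalence is None:
        ppv = _ratio(c.tp, c.tp + c.fp)
        npv = _ratio(c.tn, c.tn + c.fn)
    else:
        if not 0.0 <= prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        ppv = npv = None
        if sens is not None and spec is not None:
            p_pos = sens * prevalence + (1 - spec) * (1 - prevalence)
            p_neg = (1 - sens) * prevalence + spec * (1 - prevalence)
            ppv = sens * prevalence / p_pos if p_pos > 0 else None
            npv = spec * (1 - prevalence) / p_neg if p_neg > 0 else None
    return {"sensitivity": sens, "specificity": spec, "ppv": ppv, "npv": npv}


def ppa_npa(ref_calls: np.ndarray, test_calls: np.ndarray) -> dict:
    """Positive / negative percent agreement with a reference method.

    PPA = fraction of reference-positive samples the test calls positive;
    NPA = fraction of reference-negative samples the test calls negative.
    Numerators and denominators are reported alongside the proportions.
    """
    ref = np.asarray(ref_calls, dtype=bool)
    test = np.asarray(test_calls, dtype=bool)
    if ref.shape != test.shape:
        raise ValueError("reference and test call vectors must have equal length")
    n_ref_pos = int(ref.sum())
    n_ref_neg = int((~ref).sum())
    ppa_num = int(np.sum(ref & test))
    npa_num = int(np.sum(~ref & ~test))
    return {
        "ppa": _ratio(ppa_num, n_ref_pos),
        "npa": _ratio(npa_num, n_ref_neg),
        "ppa_counts": (ppa_num, n_ref_pos),
        "npa_counts": (npa_num, n_ref_neg),
    }


@dataclass(frozen=True)
class VariantCall:
    vaf: float
    call: str  # "positive" | "wild-type"
    threshold: float = 0.05


def vaf_call(vaf: float, threshold: float = 0.05) -> VariantCall:
    """Variant call from allele frequency: positive iff ``vaf >= threshold``.

    The threshold is inclusive on the positive side (a VAF of exactly 5%
    is positive; anything below is wild type).
    """
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"VAF must lie in [0, 1], got {vaf}")
    call = "positive" if vaf >= threshold else "wild-type"
    return VariantCall(vaf=vaf, call=call, threshold=threshold)


def paired_correlation_concordance(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    calls_a: np.ndarray,
    calls_b: np.ndarray,
) -> dict:
    """Pearson r, r-squared, and binary-call concordance for paired assays."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    ca = np.asarray(calls_a, dtype=bool)
    cb = np.asarray(calls_b, dtype=bool)
    if not (a.shape == b.shape and ca.shape == cb.shape and a.shape == ca.shape):
        raise ValueError("all four vectors must have equal length")
    if a.size < 3:
        raise ValueError("correlation needs at least 3 pairs")
    if np.std(a) == 0 or np.std(b) == 0:
        r = r2 = None
    else:
        r = float(stats.pearsonr(a, b).statistic)
        r2 = r * r
    concordance = float(np.mean(ca == cb))
    return {"r": r, "r2": r2, "concordance": concordance, "n": int(a.size)}
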