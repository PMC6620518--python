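"""Noise-tolerance simulation for reproducibility acceptance specifications.

A three-step simulation determines how much technical score variability a
classifier can absorb before its clinical performance degrades:

1. Gaussian noise eps ~ N(0, sigma^2) is added to the original classifier
   scores, for each sigma on a grid (default 0.36 to 2.10 in steps of
   0.02).
2. Performance metrics (sensitivity, specificity, PPA, NPA, PPV, NPV) are
   recomputed on the noisy scores at the fixed decision threshold.
3. Steps 1-2 are repeated (default 1,000 times per sigma) and the median
   of each metric across repetitions is taken.

The SD specification is then the largest grid sigma at which every median
metric still meets its pre-specified product requirement (e.g. sensitivity
>= 0.90 and NPV >= 0.90).  Noise is injected into scores only — after the
classifier — never into counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_GRID = np.round(np.arange(18, 106) * 0.02, 10)  # 0.36 .. 2.10 step 0.02
DEFAULT_REQUIREMENTS = {"sensitivity": 0.90, "npv": 0.90}
_METRICS = ["sensitivity", "specificity", "ppa", "npa", "ppv", "npv"]


def default_sigma_grid() -> np.ndarray:
    """The standard sigma grid: 0.36 to 2.10 inclusive, step 0.02."""
    return DEFAULT_GRID.copy()


@dataclass
class NoiseToleranceResult:
    """Per-sigma median metrics and, once determined, the SD specification."""

    grid: np.ndarray
    medians: pd.DataFrame  # index: sigma, columns: metric names
    reps: int
    threshold: float
    prevalence: float
    requirements: dict = field(default_factory=dict)
    sd_spec: float | None = None
    status: str = "not determined"

    def to_frame(self) -> pd.DataFrame:
        out = self.medians.copy()
        out.index.name = "sigma"
        return out


def simulate_noise_grid(
    scores: np.ndarray,
    truth_labels: np.ndarray,
    threshold: float,
    grid: np.ndarray | None = None,
    reps: int = 1000,
    prevalence: float | None = None,
    seed: int = 0,
) -> NoiseToleranceResult:
    """Run the noise-injection simulation over a sigma grid.

    ``truth_labels`` is boolean (True = positive class).  Calls on noisy
    scores are positive iff score > threshold.  PPA/NPA are agreement with
    the truth labels as the reference method and therefore coincide with
    sensitivity/specificity here; NPV and PPV use the supplied prevalence,
    or the sample composition when none is given.  The random stream is
    split per sigma from the master seed so each grid point is
    independently reproducible.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth_labels, dtype=bool)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth labels must have equal length")
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    if grid is None:
        grid = default_sigma_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("sigma grid must be nonempty, positive, strictly increasing")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    prev = n_pos / (n_pos + n_neg) if prevalence is None else float(prevalence)
    if not 0.0 < prev < 1.0:
        raise ValueError("prevalence must lie in (0, 1)")

    streams = np.random.SeedSequence(seed).spawn(grid.size)
    rows = []
    for sigma, ss in zip(grid, streams):
        rng = np.random.default_rng(ss)
        noisy = scores[None, :] + rng.normal(0.0, sigma, size=(reps, scores.size))
        calls = noisy > threshold
        tp = (calls[:, truth]).sum(axis=1)
        fn = n_pos - tp
        fp = (calls[:, ~truth]).sum(axis=1)
        tn = n_neg - fp
        sens = tp / n_pos
        spec = tn / n_neg
        p_pos = sens * prev + (1 - spec) * (1 - prev)
        p_neg = (1 - sens) * prev + spec * (1 - prev)
        with np.errstate(invalid="ignore", divide="ignore"):
            ppv = np.where(p_pos > 0, sens * prev / p_pos, np.nan)
            npv = np.where(p_neg > 0, spec * (1 - prev) / p_neg, np.nan)
        rows.append(
            {
                "sensitivity": np.median(sens),
                "specificity": np.median(spec),
                "ppa": np.median(sens),
                "npa": np.median(spec),
                "ppv": np.nanmedian(ppv),
                "npv": np.nanmedian(npv),
            }
        )
    medians = pd.DataFrame(rows, index=pd.Index(grid, name="sigma"), columns=_METRICS)
    return NoiseToleranceResult(
        grid=grid, medians=medians, reps=reps, threshold=threshold, prevalence=prev
    )


def determine_sd_spec(
    r: NoiseToleranceResult,
    requirements: dict | None = None,
    strict_monotone: bool = False,
) -> NoiseToleranceResult:
    """Determine the SD specification from computed per-sigma medians.

    The specification is the largest grid sigma at which every required
    metric's median meets its minimum.  With ``strict_monotone=True`` the
    largest sigma such that all smaller grid sigmas qualify too is
    returned instead (guards against isolated finite-replicate blips).
    The result is returned with ``sd_spec`` and ``status`` filled in.
    """
    if requirements is None:
        requirements = dict(DEFAULT_REQUIREMENTS)
    unknown = [k for k in requirements if k not in r.medians.columns]
    if unknown:
        raise KeyError(f"requirements name unknown metrics: {unknown}")
    if r.medians.isna().any().any():
        raise ValueError("medians must be computed for every grid sigma")

    ok = np.ones(len(r.grid), dtype=bool)
    for metric, minimum in requirements.items():
        ok &= r.medians[metric].to_numpy() >= minimum
    if strict_monotone:
        ok = np.cumprod(ok).astype(bool)

    r.requirements = dict(requirements)
    if ok.any():
        r.sd_spec = float(r.grid[np.nonzero(ok)[0][-1]])
        r.status = "determined"
    else:
        r.sd_spec = None
        r.status = "below grid minimum"
    return r
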