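"""Synthetic two-class RNA-seq count matrices and replicate score tables.

The generators reproduce the statistical structure the downstream analyses
assume: negative-binomial counts with class-informative genes and
library-size variation, and additively decomposed classifier scores

    S_ijk = mu_i + r_j + (mu_i : r_j) + eps_ijk

with independent centered-Gaussian run, sample-by-run interaction, and
residual effects.  Every generator takes an explicit integer seed; there is
no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import NEGATIVE, POSITIVE, CountMatrix, ScoreTable

BLOOD_MARKER_PREFIX = "g"  # marker genes are the first block of the gene list
BLOOD_MARKER_FRACTION = 0.05  # fraction of genes acting as blood markers
BLOOD_CONCENTRATION = 0.90  # share of blood-profile mass on marker genes


@dataclass(frozen=True)
class GeneratorTruth:
    """Ground-truth parameters for the score-table generator.

    All standard deviations are in classifier score units on a declared
    ``score_range`` (e.g. 8 units for a benign/malignant classifier).
    ``class_mean_separation`` is the distance between the two class mean
    scores, placed symmetric about zero (the decision threshold).
    """

    n_samples_per_class: int = 8
    class_mean_separation: float = 4.0
    sigma_sample: float = 0.8
    sigma_run: float = 0.19
    sigma_interaction: float = 0.19
    sigma_residual: float = 0.069
    score_range: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_sample", "sigma_run", "sigma_interaction", "sigma_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_samples_per_class < 1:
            raise ValueError("n_samples_per_class must be >= 1")
        if self.score_range <= 0:
            raise ValueError("score_range must be > 0")


def gen_count_matrix(
    n_genes: int = 2000,
    n_per_class: int = 20,
    n_informative: int = 200,
    effect_size: float = 1.0,
    dispersion: float = 0.1,
    libsize_cv: float = 0.2,
    seed: int = 0,
) -> CountMatrix:
    """Generate a two-class negative-binomial count matrix.

    Informative genes carry a class-dependent mean (log2-fold change
    ``effect_size`` in the positive class); per-sample library-size factors
    are lognormal with coefficient of variation ``libsize_cv``.

    Parameters
    ----------
    dispersion
        Negative-binomial dispersion alpha, so var = mu + alpha * mu**2.
    """
    if n_genes < 1:
        raise ValueError(f"n_genes must be positive, got {n_genes}")
    if n_per_class < 1:
        raise ValueError(f"n_per_class must be positive, got {n_per_class}")
    if n_informative < 0 or n_informative > n_genes:
        raise ValueError(f"n_informative must lie in [0, n_genes], got {n_informative}")
    if dispersion <= 0:
        raise ValueError(f"dispersion must be > 0, got {dispersion}")
    if libsize_cv < 0:
        raise ValueError(f"libsize_cv must be >= 0, got {libsize_cv}")

    rng = np.random.default_rng(seed)
    n_samples = 2 * n_per_class
    # baseline per-gene expression on a realistic lognormal scale
    base = rng.lognormal(mean=4.0, sigma=1.0, size=n_genes)
    lfc = np.zeros(n_genes)
    lfc[:n_informative] = rng.choice([-1.0, 1.0], size=n_informative) * effect_size
    mean_neg = base
    mean_pos = base * 2.0 ** lfc

    if libsize_cv > 0:
        sig2 = np.log1p(libsize_cv**2)
        libsize = rng.lognormal(mean=-sig2 / 2, sigma=np.sqrt(sig2), size=n_samples)
    else:
        libsize = np.ones(n_samples)

    labels = np.array([POSITIVE] * n_per_class + [NEGATIVE] * n_per_class)
    mu = np.where(labels[None, :] == POSITIVE, mean_pos[:, None], mean_neg[:, None])
    mu = mu * libsize[None, :]
    # NB(r, p): r = 1/alpha, p = r / (r + mu)
    r = 1.0 / dispersion
    counts = rng.negative_binomial(r, r / (r + mu)).astype(float)

    genes = [f"g{i:05d}" for i in range(n_genes)]
    samples = [f"s{i:03d}" for i in range(n_samples)]
    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "true_class": labels,
            "interferent_kind": "none",
            "interferent_fraction": 0.0,
        }
    )
    return CountMatrix(genes=genes, samples=samples, counts=counts, meta=meta)


def gen_score_table(
    truth: GeneratorTruth,
    n_runs: int = 3,
    n_reps: int = 3,
    n_labs: int = 1,
    drop_one: bool = False,
) -> ScoreTable:
    """Generate a fully crossed, balanced replicate score table.

    Scores decompose additively: class mean + per-sample deviation
    (N(0, sigma_sample^2)) + run effect (N(0, sigma_run^2)) + sample-by-run
    interaction (N(0, sigma_interaction^2)) + residual
    (N(0, sigma_residual^2)).  Run and interaction effects are drawn
    independently per lab, and residuals independently per record, so with
    ``n_runs == n_reps == 1`` the residual acts as independent per-lab noise.

    ``drop_one`` removes the last record, mimicking a single assay lost to
    QC in an otherwise balanced design.
    """
    if n_runs < 1 or n_reps < 1 or n_labs < 1:
        raise ValueError("n_runs, n_reps and n_labs must all be >= 1")
    rng = np.random.default_rng(truth.seed)
    n_i = 2 * truth.n_samples_per_class

    class_mean = np.array(
        [truth.class_mean_separation / 2] * truth.n_samples_per_class
        + [-truth.class_mean_separation / 2] * truth.n_samples_per_class
    )
    labels = [POSITIVE] * truth.n_samples_per_class + [NEGATIVE] * truth.n_samples_per_class
    mu = class_mean + rng.normal(0.0, truth.sigma_sample, size=n_i)
    run = rng.normal(0.0, truth.sigma_run, size=(n_labs, n_runs))
    inter = rng.normal(0.0, truth.sigma_interaction, size=(n_labs, n_i, n_runs))
    resid = rng.normal(0.0, truth.sigma_residual, size=(n_labs, n_i, n_runs, n_reps))

    score = (
        mu[None, :, None, None]
        + run[:, None, :, None]
        + inter[:, :, :, None]
        + resid
    )

    lab_ix, i_ix, j_ix, k_ix = np.meshgrid(
        np.arange(n_labs), np.arange(n_i), np.arange(n_runs), np.arange(n_reps),
        indexing="ij",
    )
    df = pd.DataFrame(
        {
            "sample_id": [f"s{i:03d}" for i in i_ix.ravel()],
            "true_class": [labels[i] for i in i_ix.ravel()],
            "condition": "baseline",
            "run_id": [f"run{j + 1}" for j in j_ix.ravel()],
            "lab_id": [f"lab{l + 1}" for l in lab_ix.ravel()],
            "replicate_id": [f"rep{k + 1}" for k in k_ix.ravel()],
            "score": score.ravel(),
        }
    )
    if drop_one:
        df = df.iloc[:-1]
    return ScoreTable(df)


def gen_interference_profile(kind: str, n_genes: int = 2000, seed: int = 0) -> np.ndarray:
    """Generate an interferent expression profile (count vector).

    ``blood`` concentrates most of its mass (90%) on a small marker-gene
    subset, mimicking hemoglobin-dominated whole-blood RNA; ``gDNA``
    produces a near-uniform low-level background, mimicking depth dilution
    by reads from non-transcribed regions.
    """
    if kind not in ("blood", "gDNA"):
        raise ValueError(f"unknown interferent kind {kind!r}; expected 'blood' or 'gDNA'")
    if n_genes < 1:
        raise ValueError(f"n_genes must be positive, got {n_genes}")
    rng = np.random.default_rng(seed)
    total = 1e6
    if kind == "gDNA":
        profile = rng.uniform(0.8, 1.2, size=n_genes)
    else:
        n_marker = max(1, int(round(BLOOD_MARKER_FRACTION * n_genes)))
        profile = rng.uniform(0.8, 1.2, size=n_genes) * (1.0 - BLOOD_CONCENTRATION)
        marker_mass = rng.dirichlet(np.ones(n_marker) * 5.0) * n_genes * BLOOD_CONCENTRATION
        profile[:n_marker] += marker_mass
    return profile * (total / profile.sum())
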