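"""Core data containers: count matrices and replicate-level score tables.

A :class:`CountMatrix` holds a gene-by-sample expression matrix with
per-sample metadata; counts are real-valued (not integer) because in-silico
mixtures are convex combinations of integer count profiles.  A
:class:`ScoreTable` holds long-format classifier scores indexed by the
study-design labels (sample, condition, run, lab, replicate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SCORE_COLUMNS = [
    "sample_id",
    "true_class",
    "condition",
    "run_id",
    "lab_id",
    "replicate_id",
    "score",
]

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass
class CountMatrix:
    """Nonnegative gene-by-sample expression matrix with sample metadata.

    Parameters
    ----------
    genes
        Unique gene identifiers (rows).
    samples
        Unique sample identifiers (columns).
    counts
        Array of shape ``(n_genes, n_samples)``; real-valued and >= 0.
    meta
        One record per sample with at least a ``true_class`` column; the
        generators also record ``interferent_kind`` and
        ``interferent_fraction``.
    """

    genes: list[str]
    samples: list[str]
    counts: np.ndarray
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene identifiers must be unique")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample identifiers must be unique")
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite and nonnegative")
        if self.meta is None:
            self.meta = pd.DataFrame(
                {
                    "sample_id": self.samples,
                    "true_class": [NEGATIVE] * len(self.samples),
                    "interferent_kind": "none",
                    "interferent_fraction": 0.0,
                }
            )
        if list(self.meta["sample_id"]) != list(self.samples):
            raise ValueError("meta must cover every sample exactly once, in order")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def column(self, sample_id: str) -> np.ndarray:
        """Count vector for one sample."""
        try:
            j = self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None
        return self.counts[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.samples)

    # -- TSV round trip (genes in rows, sibling metadata sheet) ------------

    def write_tsv(self, counts_path: str | Path, meta_path: str | Path | None = None) -> None:
        df = self.to_frame()
        df.index.name = "gene"
        df.to_csv(counts_path, sep="\t")
        if meta_path is not None:
            self.meta.to_csv(meta_path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, counts_path: str | Path, meta_path: str | Path | None = None) -> "CountMatrix":
        df = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = None
        if meta_path is not None:
            meta = pd.read_csv(meta_path, sep="\t")
        return cls(
            genes=[str(g) for g in df.index],
            samples=[str(s) for s in df.columns],
            counts=df.to_numpy(dtype=float),
            meta=meta,
        )


@dataclass
class ScoreTable:
    """Long-format replicate-level classifier scores with design labels.

    Each row is one assay: (sample, condition, run, lab, replicate) -> score.
    The (sample, condition, run, lab, replicate) tuple is unique and every
    sample carries a single true class.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SCORE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"score table missing columns: {missing}")
        self.df = self.df[SCORE_COLUMNS].reset_index(drop=True)
        if not np.all(np.isfinite(self.df["score"].to_numpy(dtype=float))):
            raise ValueError("scores must be finite")
        keys = ["sample_id", "condition", "run_id", "lab_id", "replicate_id"]
        if self.df.duplicated(subset=keys).any():
            raise ValueError("(sample, condition, run, lab, replicate) must be unique")
        per_sample = self.df.groupby("sample_id")["true_class"].nunique()
        if (per_sample > 1).any():
            bad = per_sample[per_sample > 1].index.tolist()
            raise ValueError(f"samples with conflicting true_class: {bad}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample_id"].unique())

    def scores(self) -> np.ndarray:
        return self.df["score"].to_numpy(dtype=float)

    def write_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ScoreTable":
        return cls(pd.read_csv(path, sep="\t"))
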