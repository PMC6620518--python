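"""Study configuration: schema, validation, defaults.

A study is described by a small YAML document.  Exactly one input mode is
used per stage: either file inputs (``score_table`` / ``count_matrix`` /
``model`` paths) or synthetic mode (a ``generator`` block of ground-truth
parameters).  Unknown keys are rejected; defaults follow the standard
study design (sigma grid 0.36-2.10 step 0.02, 1,000 noise repetitions,
2,000 bootstrap resamples, VAF threshold 0.05, requirements
sensitivity >= 0.90 and NPV >= 0.90).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

STUDY_KINDS = ("lod", "interference", "effects", "repro", "spec", "full")

_GENERATOR_KEYS = {
    "n_samples_per_class", "class_mean_separation", "sigma_sample", "sigma_run",
    "sigma_interaction", "sigma_residual", "score_range",
    "n_runs", "n_reps", "n_labs",
    "n_genes", "n_per_class", "n_informative", "effect_size", "dispersion", "libsize_cv",
    "condition_shifts", "conditions",
}

_TOP_KEYS = {
    "kind", "seed", "output_dir", "score_table", "count_matrix", "count_meta",
    "model", "generator", "grid", "reps", "bootstrap_B", "vaf_threshold",
    "requirements", "levels", "grid_step", "condition_column", "interferent_kind",
    "prevalence",
}


@dataclass
class StudyConfig:
    kind: str
    seed: int = 0
    output_dir: str = "assayval_out"
    score_table: str | None = None
    count_matrix: str | None = None
    count_meta: str | None = None
    model: str | None = None
    generator: dict = field(default_factory=dict)
    grid: dict = field(default_factory=lambda: {"start": 0.36, "stop": 2.10, "step": 0.02})
    reps: int = 1000
    bootstrap_B: int = 2000
    vaf_threshold: float = 0.05
    requirements: dict = field(default_factory=lambda: {"sensitivity": 0.90, "npv": 0.90})
    levels: list = field(default_factory=lambda: [0, 25, 50, 75, 100])
    grid_step: float = 0.01
    condition_column: str = "condition"
    interferent_kind: str = "blood"
    prevalence: float | None = None


def validate_config(raw: str | dict) -> StudyConfig:
    """Parse and validate a raw YAML config string (or pre-parsed mapping).

    All violations are collected and reported together in a single
    ``ValueError`` naming each offending field.
    """
    data = yaml.safe_load(raw) if isinstance(raw, str) else dict(raw)
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    errors: list[str] = []

    unknown = sorted(set(data) - _TOP_KEYS)
    if unknown:
        errors.append(f"unknown keys: {unknown}")
    kind = data.get("kind")
    if kind not in STUDY_KINDS:
        errors.append(f"kind: must be one of {STUDY_KINDS}, got {kind!r}")

    gen = data.get("generator") or {}
    if not isinstance(gen, dict):
        errors.append("generator: must be a mapping")
        gen = {}
    else:
        bad = sorted(set(gen) - _GENERATOR_KEYS)
        if bad:
            errors.append(f"generator: unknown keys {bad}")

    for key in ("score_table", "count_matrix", "count_meta", "model"):
        path = data.get(key)
        if path is not None and not Path(path).exists():
            errors.append(f"{key}: path does not exist: {path}")

    if data.get("score_table") and gen and kind in ("repro", "effects", "spec"):
        errors.append("exactly one of score_table or generator may be given")

    grid = data.get("grid", {"start": 0.36, "stop": 2.10, "step": 0.02})
    if not isinstance(grid, dict) or set(grid) - {"start", "stop", "step"}:
        errors.append("grid: must be a mapping with keys start, stop, step")
    else:
        step = grid.get("step", 0.02)
        if not isinstance(step, (int, float)) or step <= 0:
            errors.append(f"grid.step: must be > 0, got {step}")
        elif grid.get("start", 0.36) <= 0 or grid.get("stop", 2.10) < grid.get("start", 0.36):
            errors.append("grid: need 0 < start <= stop")

    reps = data.get("reps", 1000)
    if not isinstance(reps, int) or reps < 1:
        errors.append(f"reps: must be a positive integer, got {reps}")
    boot = data.get("bootstrap_B", 2000)
    if not isinstance(boot, int) or boot < 200:
        errors.append(f"bootstrap_B: must be an integer >= 200, got {boot}")
    vaf = data.get("vaf_threshold", 0.05)
    if not 0 <= vaf <= 1:
        errors.append(f"vaf_threshold: must lie in [0, 1], got {vaf}")
    gstep = data.get("grid_step", 0.01)
    if not 0 < gstep <= 1:
        errors.append(f"grid_step: must lie in (0, 1], got {gstep}")
    req = data.get("requirements")
    if req is not None:
        if not isinstance(req, dict) or not all(
            isinstance(v, (int, float)) and 0 <= v <= 1 for v in req.values()
        ):
            errors.append("requirements: must map metric names to minima in [0, 1]")
    if data.get("interferent_kind", "blood") not in ("blood", "gDNA"):
        errors.append(f"interferent_kind: must be blood or gDNA, got {data['interferent_kind']!r}")
    seed = data.get("seed", 0)
    if not isinstance(seed, int):
        errors.append(f"seed: must be an integer, got {seed!r}")

    if errors:
        raise ValueError("invalid config:\n  - " + "\n  - ".join(errors))

    cfg = StudyConfig(kind=kind)
    for key, value in data.items():
        if key == "requirements" and value is None:
            continue
        setattr(cfg, key, value)
    return cfg
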