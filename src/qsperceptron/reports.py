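"""Evaluation reports, fixture generation and the end-to-end pipeline.

Everything here is plumbing over the model modules: reports are pure
functions of stored intermediates, every written artifact carries a
provenance block (config hash, seed, package version), and each pipeline
stage draws from an RNG stream forked from the run seed by stage name so
adding a stage does not perturb earlier stages.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .consortium import (
    ReceiverSpec,
    ResponseMatrix,
    count_unique_products,
    network_from_weights,
    response_matrix,
)
from .hill import default_registry, synth_dose_response
from .patterns import (
    PatternSet,
    TargetSpec,
    enumerate_4bit,
    make_nonbinary,
    make_set,
    zero_fraction,
)
from .training import (
    DEFAULT_PALETTE,
    MulticlassResult,
    TrainingConfig,
    default_target_levels,
    train_multiclass,
)

__all__ = [
    "EvaluationReport",
    "evaluate",
    "make_fixtures",
    "run_pipeline",
    "stage_seed",
    "provenance_block",
]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the run seed and stage name."""
    return (int(seed) * 100_003 + zlib.crc32(stage.encode())) % (2**31)


def provenance_block(config: dict, seed: int) -> dict:
    digest = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    return {"config_hash": digest, "seed": int(seed), "version": __version__}


@dataclass
class EvaluationReport:
    """Classification metrics recomputable from a stored response matrix."""

    margins: dict[str, float]
    misclassified: dict[str, int]
    threshold: float
    unique_product_count: int
    unique_products: list[float]
    sparseness: dict[str, float]
    grid_size: Optional[int] = None
    provenance: dict = field(default_factory=dict)

    @property
    def total_misclassified(self) -> int:
        return sum(self.misclassified.values())

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=float)


def evaluate(
    matrix: ResponseMatrix,
    pattern_set: PatternSet,
    target_spec: TargetSpec,
    categories: Optional[Sequence[str]] = None,
) -> EvaluationReport:
    """Margins, misclassification counts and product degeneracy for a run.

    Rows of ``matrix`` are assumed to correspond to ``categories`` (default:
    the pattern set's categories, in order).  Misclassification uses the H/L
    midpoint threshold: a pattern is predicted "own category" when the
    response is at or above it.
    """
    categories = list(categories or pattern_set.categories)
    if len(categories) != matrix.shape[0]:
        raise ValueError(
            f"{matrix.shape[0]} weight rows but {len(categories)} categories"
        )
    thr = target_spec.threshold
    margins: dict[str, float] = {}
    mis: dict[str, int] = {}
    for i, c in enumerate(categories):
        own = pattern_set.category_mask(c)
        R = matrix.eyfp[i]
        margins[c] = float(np.min(R[own]) - np.max(R[~own]))
        predicted_own = R >= thr
        mis[c] = int(np.sum(predicted_own != own))
    count, values, _ = count_unique_products(matrix)
    sparseness = {
        c: zero_fraction(pattern_set.by_category(c)[0]) for c in categories
        if pattern_set.by_category(c)
    }
    return EvaluationReport(
        margins=margins,
        misclassified=mis,
        threshold=float(thr),
        unique_product_count=int(count),
        unique_products=[float(v) for v in values],
        sparseness=sparseness,
        grid_size=pattern_set.grid_size,
    )


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def make_fixtures(seed: int, out_dir) -> dict[str, str]:
    """Write the synthetic fixture bundle; deterministic under the seed.

    Dose-response tables (noiseless and 5% multiplicative noise) for every
    registry circuit, default binary pattern sets for all grid sizes, the
    graded 5x5 set, the 4-bit enumeration, and a 2-bit separable toy
    dichotomy.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    registry = default_registry()
    for label, params in registry.items():
        clean = synth_dose_response(params)
        p = out / f"dose_response_{label}.csv"
        clean.to_csv(p)
        written[f"dose_response_{label}"] = str(p)
        rng = np.random.default_rng(stage_seed(seed, f"noise:{label}"))
        noisy = synth_dose_response(params, noise_cv=0.05, rng=rng)
        p = out / f"dose_response_{label}_noisy.csv"
        noisy.to_csv(p)
        written[f"dose_response_{label}_noisy"] = str(p)
    for N in (3, 5, 7, 9):
        s = make_set(N)
        p = out / f"patterns_{N}x{N}.csv"
        s.to_csv(p)
        written[f"patterns_{N}x{N}"] = str(p)
    graded = make_nonbinary(make_set(5), seed=stage_seed(seed, "graded:5"))
    p = out / "patterns_5x5_graded.json"
    graded.to_json(p)
    written["patterns_5x5_graded"] = str(p)
    p = out / "patterns_4bit.csv"
    enumerate_4bit().to_csv(p)
    written["patterns_4bit"] = str(p)
    # 2-bit AND-style dichotomy: only [1,1] is High
    high, low = default_target_levels()
    toy = {
        "patterns": [[0, 0], [0, 1], [1, 0], [1, 1]],
        "targets": [low, low, low, high],
        "provenance": provenance_block({"kind": "toy-dichotomy"}, seed),
    }
    p = out / "toy_dichotomy.json"
    with open(p, "w") as fh:
        json.dump(toy, fh, indent=2)
    written["toy_dichotomy"] = str(p)
    return written


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    grid_size: int = 3,
    seed: int = 0,
    out_dir=None,
    graded: bool = False,
    palette: Optional[Sequence[float]] = DEFAULT_PALETTE,
    eta: float = 0.1,
    max_iter: int = 10_000,
) -> tuple[PatternSet, MulticlassResult, ResponseMatrix, EvaluationReport]:
    """patterns -> train -> simulate -> evaluate, optionally writing a bundle.

    Stage seeds are forked from the run seed by stage name; with a fixed seed
    the bundle is byte-identical across runs.
    """
    config = {
        "grid_size": grid_size,
        "graded": graded,
        "palette": list(palette) if palette is not None else None,
        "eta": eta,
        "max_iter": max_iter,
    }
    receiver = ReceiverSpec()
    pattern_set = make_set(grid_size)
    if graded:
        pattern_set = make_nonbinary(
            pattern_set, seed=stage_seed(seed, f"graded:{grid_size}")
        )
    high, low = default_target_levels(receiver)
    target_spec = TargetSpec.one_vs_rest(pattern_set, high, low)
    cfg = TrainingConfig(
        eta=eta, max_iter=max_iter, palette=palette, seed=stage_seed(seed, "train")
    )
    mc = train_multiclass(pattern_set, target_spec, cfg, receiver)
    nets = [network_from_weights(mc.results[c].weights, receiver) for c in pattern_set.categories]
    matrix = response_matrix(nets, pattern_set)
    report = evaluate(matrix, pattern_set, target_spec)
    report.provenance = provenance_block(config, seed)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pattern_set.to_csv(out / "patterns.csv")
        for c, res in mc.results.items():
            res.save(out / f"training_{c}.json")
            pd.DataFrame({"loss": res.loss_trajectory}).to_csv(
                out / f"trajectory_{c}.csv", index_label="iteration"
            )
        matrix.to_csv(out / "response_eyfp.csv", out / "response_sums.csv")
        report.to_json(out / "report.json")
        with open(out / "provenance.json", "w") as fh:
            json.dump({**provenance_block(config, seed), "config": config}, fh, indent=2)
    return pattern_set, mc, matrix, report
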