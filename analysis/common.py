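"""Shared driver plumbing: one cached pipeline run reused by all steps.

The numbered scripts narrate successive stages of the same analysis; the
underlying computation happens once (in the package) and is cached under
scratch/ so each script stays a thin reporting layer.
"""

from __future__ import annotations

import pickle
from pathlib import Path

from lungshape.pipeline import COHORT_FIT_CONFIG, PipelineResults, run_synthetic_pipeline
from lungshape.synthetic import GeneratorConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "analysis_cache"

ANALYSIS_SEED = 20


def get_run(seed: int = ANALYSIS_SEED, refit: bool = True) -> PipelineResults:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    cache = SCRATCH / f"run_seed{seed}_{'fit' if refit else 'truth'}.pkl"
    if cache.exists():
        with open(cache, "rb") as fh:
            return pickle.load(fh)
    res = run_synthetic_pipeline(
        GeneratorConfig(seed=seed), COHORT_FIT_CONFIG, refit=refit
    )
    with open(cache, "wb") as fh:
        pickle.dump(res, fh)
    return res


def ensure_results() -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS
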