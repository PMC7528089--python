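"""End-to-end orchestration: fit -> align -> decompose -> score -> associate.

The same steps run in three guises: programmatically on synthetic cohorts
(tests, acceptance), from the numbered analysis drivers, and from the CLI
``run`` subcommand on files.  All computation lives in the sibling
modules; this module only sequences them and writes artifacts.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alignment import ShapeVector, gpa
from .fitting import FitConfig, FitResult, fit_mesh
from .hermite import MeshTopology
from .io import (
    MESH_SCHEMA_VERSION,
    file_sha256,
    save_model,
    write_covariates,
    write_mesh,
)
from .model import ShapeModel, assemble, build_ssm, score_table, variance_explained
from .stats import association_table
from .synthetic import GeneratorConfig, SyntheticSubject, generate_cohort, template_lung_mesh

log = logging.getLogger(__name__)

ALIGNMENT_MODES = ("size-inclusive", "size-exclusive")

#: standard fitting profile for cohort runs: two project/solve rounds are
#: enough once the template is similarity-pre-aligned, and correspondence
#: quality degrades rather than improves with long re-projection loops
#: (tangential sliding along the surface is data-unconstrained).
COHORT_FIT_CONFIG = FitConfig(max_outer_iterations=2)


@dataclass
class ModeResults:
    """One alignment flavour's outputs."""

    alignment: str
    model: ShapeModel
    mean_shape: ShapeVector
    aligned: list[ShapeVector]
    scores: pd.DataFrame
    associations: pd.DataFrame


@dataclass
class PipelineResults:
    covariates: pd.DataFrame
    fit_results: dict[str, FitResult]
    by_mode: dict[str, ModeResults] = field(default_factory=dict)
    subjects: list[SyntheticSubject] | None = None

    @property
    def fit_rmse(self) -> pd.Series:
        return pd.Series({k: v.rmse for k, v in self.fit_results.items()},
                         name="rmse_mm")


def fit_cohort(
    template: MeshTopology,
    clouds: dict[str, "DataPointSet"],
    fit_config: FitConfig | None = None,
) -> dict[str, FitResult]:
    fit_config = fit_config or COHORT_FIT_CONFIG
    out = {}
    for sid, cloud in clouds.items():
        res = fit_mesh(template, cloud, fit_config)
        log.info("fit %s: RMSE %.3f mm in %d iterations", sid, res.rmse,
                 res.iterations_used)
        out[sid] = res
    return out


def build_mode_results(
    shapes: list[ShapeVector],
    covariates: pd.DataFrame,
    alignment: str,
    n_modes_stats: int = 4,
) -> ModeResults:
    if alignment not in ALIGNMENT_MODES:
        raise ValueError(f"alignment must be one of {ALIGNMENT_MODES}")
    with_scale = alignment == "size-exclusive"
    aligned, mean, _ = gpa(shapes, with_scale=with_scale)
    model = build_ssm(assemble(aligned))
    k = min(n_modes_stats, model.n_modes)
    scores = score_table(model, aligned, n_modes=k)
    associations = association_table(scores, covariates)
    return ModeResults(
        alignment=alignment,
        model=model,
        mean_shape=mean,
        aligned=aligned,
        scores=scores,
        associations=associations,
    )


def run_synthetic_pipeline(
    generator: GeneratorConfig | None = None,
    fit_config: FitConfig | None = None,
    alignments: tuple[str, ...] = ALIGNMENT_MODES,
    n_modes_stats: int = 4,
    refit: bool = True,
) -> PipelineResults:
    """Generate a synthetic cohort and run the full analysis on it.

    With ``refit`` the noisy clouds are fitted with the template (the
    realistic path); without it the ground-truth meshes feed the alignment
    directly (useful to isolate downstream behaviour from fitting error).
    """
    generator = generator or GeneratorConfig()
    template = template_lung_mesh()
    subjects, cov = generate_cohort(generator, template=template)
    if refit:
        clouds = {s.subject_id: s.cloud for s in subjects}
        fits = fit_cohort(template, clouds, fit_config)
        shapes = [
            ShapeVector.from_mesh(fits[s.subject_id].fitted_mesh, s.subject_id)
            for s in subjects
        ]
    else:
        fits = {}
        shapes = [ShapeVector.from_mesh(s.truth_mesh, s.subject_id) for s in subjects]
    results = PipelineResults(covariates=cov, fit_results=fits, subjects=subjects)
    for alignment in alignments:
        results.by_mode[alignment] = build_mode_results(
            shapes, cov, alignment, n_modes_stats
        )
    return results


def aligned_score_sign(scores: pd.DataFrame, mode: int, reference: pd.Series) -> int:
    """Sign that orients a mode's scores to correlate positively with a
    reference quantity (PCA mode signs are arbitrary)."""
    r = np.corrcoef(scores[f"mode{mode}"].to_numpy(), reference.to_numpy())[0, 1]
    return 1 if r >= 0 else -1


def top_mode_for_covariate(
    scores: pd.DataFrame, covariates: pd.DataFrame, covariate: str
) -> tuple[int, float]:
    """(mode index, signed r) of the mode most correlated with a covariate."""
    cov = covariates.set_index("subject_id").loc[scores.index, covariate]
    best_mode, best_r = 1, 0.0
    for col in scores.columns:
        r = np.corrcoef(scores[col].to_numpy(), cov.to_numpy())[0, 1]
        if abs(r) > abs(best_r):
            best_mode, best_r = int(col.removeprefix("mode")), float(r)
    return best_mode, best_r


def write_run_directory(
    out_dir,
    results: PipelineResults,
    inputs: dict[str, str] | None = None,
    seed: int | None = None,
) -> Path:
    """Persist every artifact with a manifest (input hashes, seed, versions)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_covariates(out / "covariates.csv", results.covariates)
    if results.fit_results:
        report = pd.DataFrame(
            {
                "subject_id": list(results.fit_results),
                "rmse_mm": [r.rmse for r in results.fit_results.values()],
                "iterations": [r.iterations_used for r in results.fit_results.values()],
            }
        )
        report.to_csv(out / "fit_report.csv", index=False)
    for alignment, mr in results.by_mode.items():
        tag = alignment.replace("-", "_")
        save_model(out / f"model_{tag}", mr.model, gpa_mode=alignment)
        mr.scores.to_csv(out / f"scores_{tag}.csv")
        mr.associations.to_csv(out / f"associations_{tag}.csv", index=False)
        var_rows = [
            {"mode": i + 1,
             "variance_fraction": float(mr.model.variance_fractions[i]),
             "cumulative_percent": variance_explained(mr.model, i + 1)}
            for i in range(min(10, mr.model.n_modes))
        ]
        pd.DataFrame(var_rows).to_csv(out / f"variance_{tag}.csv", index=False)
    manifest = {
        "package_version": __version__,
        "schema_version": MESH_SCHEMA_VERSION,
        "seed": seed,
        "python": platform.python_version(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "inputs": inputs or {},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def run_file_pipeline(
    template_path,
    cloud_paths: dict[str, str],
    labels_paths: dict[str, str],
    covariates_path,
    out_dir,
    fit_config: FitConfig | None = None,
    alignments: tuple[str, ...] = ALIGNMENT_MODES,
    seed: int | None = None,
) -> PipelineResults:
    """File-driven variant used by the CLI ``run`` subcommand.

    On any stage failure a FAILED marker naming the stage is left in the
    run directory and the exception propagates.
    """
    from .fitting import DataPointSet
    from .io import read_covariates, read_labels, read_mesh, read_point_cloud

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read-inputs"
    try:
        template = read_mesh(template_path)
        cov = read_covariates(covariates_path)
        clouds = {}
        for sid in cov["subject_id"]:
            if sid not in cloud_paths:
                raise FileNotFoundError(f"missing point cloud for subject {sid!r}")
            pts = read_point_cloud(cloud_paths[sid])
            labels = read_labels(labels_paths[sid])["label"].to_numpy(dtype=object)
            clouds[sid] = DataPointSet(points=pts, labels=labels)
        stage = "fit"
        fits = fit_cohort(template, clouds, fit_config)
        shapes = [ShapeVector.from_mesh(fits[sid].fitted_mesh, sid) for sid in clouds]
        for sid in clouds:
            write_mesh(out / f"fitted_{sid}.json", fits[sid].fitted_mesh)
        results = PipelineResults(covariates=cov, fit_results=fits)
        for alignment in alignments:
            stage = alignment
            results.by_mode[alignment] = build_mode_results(shapes, cov, alignment)
        stage = "write"
        inputs = {str(template_path): file_sha256(template_path),
                  str(covariates_path): file_sha256(covariates_path)}
        inputs.update({str(p): file_sha256(p) for p in cloud_paths.values()})
        write_run_directory(out, results, inputs=inputs, seed=seed)
        return results
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\n{exc!r}\n")
        raise
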