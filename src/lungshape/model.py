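"""PCA statistical shape model: training matrix, SVD modes, scores.

The training matrix stacks aligned shape vectors as columns (parameters x
subjects).  Centering each column about the cohort mean and taking the thin
SVD gives orthonormal shape modes (left singular vectors); mode variances
are sigma_l^2 / (N - 1), i.e. the eigenvalues of the sample covariance, so
variance fractions and cumulative variance-explained percentages follow
directly.  Subject scores are centered projections onto the modes,
expressed in SD units of the training cohort (a score of +2.5 reproduces
the conventional "+2.5 SD" mode-shape visualisation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import ShapeVector, gpa

log = logging.getLogger(__name__)


@dataclass
class TrainingMatrix:
    """Parameters x subjects data matrix (columns are subjects)."""

    data: np.ndarray
    subject_ids: list[str]
    centered: bool = False
    mean_vector: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.subject_ids):
            raise ValueError("data must be parameters x subjects")
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 subjects")


def assemble(shapes: list[ShapeVector]) -> TrainingMatrix:
    """Column-stack aligned shape vectors, preserving input order."""
    if not shapes:
        raise ValueError("no shapes to assemble")
    length = shapes[0].values.size
    for s in shapes:
        if s.values.size != length:
            raise ValueError(
                f"subject {s.subject_id!r}: vector length {s.values.size} "
                f"differs from {length}"
            )
    data = np.column_stack([s.values for s in shapes])
    return TrainingMatrix(data=data, subject_ids=[s.subject_id for s in shapes])


@dataclass
class ShapeModel:
    """Mean shape, orthonormal modes and their variances."""

    mean_vector: np.ndarray
    modes: np.ndarray  # parameters x L, orthonormal columns
    singular_values: np.ndarray  # descending
    n_subjects: int
    subject_ids: list[str] = field(default_factory=list)

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    @property
    def eigenvalues(self) -> np.ndarray:
        """Per-mode variances: sigma^2 / (N - 1) (sample covariance eigenvalues)."""
        return self.singular_values**2 / (self.n_subjects - 1)

    @property
    def mode_sds(self) -> np.ndarray:
        return np.sqrt(self.eigenvalues)

    @property
    def nonzero_modes(self) -> np.ndarray:
        """Modes carrying real variance; a centered N-column matrix has rank
        at most N-1, so the trailing singular value is numerical noise."""
        sv = self.singular_values
        return sv > 1e-10 * max(float(sv[0]) if sv.size else 0.0, 1e-300)

    @property
    def variance_fractions(self) -> np.ndarray:
        lam = self.eigenvalues
        total = lam.sum()
        if total == 0:
            return np.zeros_like(lam)
        return lam / total


def build_ssm(matrix: TrainingMatrix) -> ShapeModel:
    """Center columns about the mean and factorise with a thin SVD."""
    mean = matrix.data.mean(axis=1)
    centered = matrix.data - mean[:, None]
    U, sv, Vt = np.linalg.svd(centered, full_matrices=False)
    if np.all(sv < 1e-12 * max(1.0, np.abs(matrix.data).max())):
        log.info("all shapes identical: degenerate model with zero variance")
    # reproducible sign: largest-magnitude loading of each mode positive
    for j in range(U.shape[1]):
        k = np.argmax(np.abs(U[:, j]))
        if U[k, j] < 0:
            U[:, j] = -U[:, j]
    return ShapeModel(
        mean_vector=mean,
        modes=U,
        singular_values=sv,
        n_subjects=matrix.data.shape[1],
        subject_ids=list(matrix.subject_ids),
    )


def variance_explained(model: ShapeModel, m: int) -> float:
    """Cumulative percentage of total variance in the first m modes."""
    if not 1 <= m <= model.n_modes:
        raise ValueError(f"m must be in [1, {model.n_modes}], got {m}")
    return float(100.0 * model.variance_fractions[:m].sum())


def select_modes(model: ShapeModel, cutoff_percent: float) -> int:
    """Smallest m whose cumulative variance percentage reaches the cutoff."""
    if not 0 < cutoff_percent <= 100:
        raise ValueError("cutoff must be in (0, 100]")
    cum = 100.0 * np.cumsum(model.variance_fractions)
    nonzero = max(int(np.sum(model.nonzero_modes)), 1)
    m = int(np.searchsorted(cum, cutoff_percent - 1e-9) + 1)
    return min(m, nonzero)


def mode_shape(model: ShapeModel, l: int, w: float) -> ShapeVector:
    """Mean perturbed along mode ``l`` (1-based) by ``w`` SD units."""
    if not 1 <= l <= model.n_modes:
        raise ValueError(f"mode index out of range: {l}")
    vec = model.mean_vector + w * model.mode_sds[l - 1] * model.modes[:, l - 1]
    return ShapeVector(subject_id=f"mode{l}_{w:+g}sd", values=vec)


def project(model: ShapeModel, shape: ShapeVector) -> np.ndarray:
    """Per-mode scores in SD units of the training cohort."""
    if shape.values.size != model.mean_vector.size:
        raise ValueError(
            f"shape vector length {shape.values.size} does not match model "
            f"({model.mean_vector.size})"
        )
    raw = model.modes.T @ (shape.values - model.mean_vector)
    keep = model.nonzero_modes
    return np.where(keep, raw / np.where(keep, model.mode_sds, 1.0), 0.0)


def project_raw(model: ShapeModel, shape: ShapeVector) -> np.ndarray:
    """Scores in original (mm-level) units: plain centered projections."""
    return model.modes.T @ (shape.values - model.mean_vector)


def reconstruct(model: ShapeModel, scores: np.ndarray, k_modes: int | None = None) -> ShapeVector:
    """Mean plus the weighted sum of the first k modes (scores in SD units)."""
    scores = np.asarray(scores, dtype=float).ravel()
    k = model.n_modes if k_modes is None else int(k_modes)
    if k > model.n_modes:
        raise ValueError("k_modes exceeds available modes")
    vec = model.mean_vector + model.modes[:, :k] @ (
        scores[:k] * model.mode_sds[:k]
    )
    return ShapeVector(subject_id="reconstruction", values=vec)


def score_table(model: ShapeModel, shapes: list[ShapeVector], n_modes: int | None = None) -> pd.DataFrame:
    """Subjects x modes table of SD-unit weights (columns mode1, mode2, ...)."""
    k = n_modes or model.n_modes
    rows = {s.subject_id: project(model, s)[:k] for s in shapes}
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"mode{i+1}" for i in range(k)]
    ).rename_axis("subject_id")


@dataclass
class LooFoldResult:
    left_out: str
    mode_cosines: np.ndarray
    variance_fraction_delta: np.ndarray


def loo_stability(
    shapes: list[ShapeVector],
    with_scale: bool = False,
    n_modes: int = 4,
    realign: bool = True,
) -> pd.DataFrame:
    """Leave-one-out stability of the shape modes.

    Refits the model N times, each time omitting one subject (optionally
    re-running GPA on the reduced cohort), and reports for each retained
    mode the absolute cosine between the fold's mode and the full-cohort
    mode, plus the change in its variance fraction.  Degenerate folds (all
    singular values zero) are flagged with NaN cosines.
    """
    if len(shapes) < 3:
        raise ValueError("leave-one-out needs at least 3 subjects")

    def fit(subset):
        if realign:
            aligned, _, _ = gpa(subset, with_scale=with_scale)
        else:
            aligned = subset
        return build_ssm(assemble(aligned))

    full = fit(shapes)
    k = min(n_modes, full.n_modes - 1)
    records = []
    for i, left_out in enumerate(shapes):
        fold = fit(shapes[:i] + shapes[i + 1 :])
        if np.all(fold.singular_values == 0):
            cos = np.full(k, np.nan)
            dvf = np.full(k, np.nan)
        else:
            kk = min(k, fold.n_modes)
            cos = np.abs(
                np.einsum("pl,pl->l", full.modes[:, :kk], fold.modes[:, :kk])
            )
            dvf = (
                fold.variance_fractions[:kk] - full.variance_fractions[:kk]
            )
        for mode in range(len(cos)):
            records.append(
                {
                    "left_out": left_out.subject_id,
                    "mode": mode + 1,
                    "abs_cosine": cos[mode],
                    "variance_fraction_delta": dvf[mode],
                }
            )
    return pd.DataFrame.from_records(records)
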