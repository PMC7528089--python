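"""Generalized Procrustes alignment of Hermite shape vectors.

A shape vector concatenates all nodal DoFs in the fixed topology order
(node-major: position, d/dxi1, d/dxi2, d2/dxi1dxi2, three components each).
Transform estimation uses positions only — mixing position and derivative
DoFs would mix units — but the estimated similarity is applied to the full
vector: positions map by alpha R x + T, derivative DoFs (direction vectors)
by alpha R alone.

Two alignment flavours are supported: size-inclusive (rotation and
translation only, alpha fixed at 1) and size-exclusive (scaling to the
consensus additionally removes size, so that lung volume does not appear
as a mode of shape variation downstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hermite import DOFS_PER_NODE, MeshTopology


class DegenerateShapeError(ValueError):
    """Point configuration too degenerate for a unique similarity fit."""


class GPAConvergenceError(RuntimeError):
    pass


@dataclass
class ShapeVector:
    """Flat per-subject shape parameter vector.

    For mesh-backed shapes the length is nodes x 12 and the block accessors
    below apply; plain parameter vectors (e.g. toy PCA inputs) are also
    accepted by the statistical layer.
    """

    subject_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in shape vector {self.subject_id}")

    @property
    def n_nodes(self) -> int:
        if self.values.size % DOFS_PER_NODE != 0:
            raise ValueError(
                f"shape vector length {self.values.size} is not a multiple of "
                f"{DOFS_PER_NODE}"
            )
        return self.values.size // DOFS_PER_NODE

    def blocks(self) -> np.ndarray:
        """(n_nodes, 4, 3) view of the DoF blocks."""
        return self.values.reshape(self.n_nodes, 4, 3)

    def positions(self) -> np.ndarray:
        return self.blocks()[:, 0, :]

    @classmethod
    def from_mesh(cls, mesh: MeshTopology, subject_id: str) -> "ShapeVector":
        return cls(subject_id=subject_id, values=mesh.node_dofs.ravel())

    def to_mesh(self, topology: MeshTopology) -> MeshTopology:
        """Pour the vector back into a mesh with the given topology."""
        if self.n_nodes != topology.n_nodes:
            raise ValueError("node count mismatch with topology")
        return topology.with_dofs(self.blocks())


@dataclass
class SimilarityTransform:
    """x -> alpha R x + T with proper rotation R."""

    alpha: float
    R: np.ndarray
    T: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float).reshape(3, 3)
        self.T = np.asarray(self.T, dtype=float).reshape(3)
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if abs(np.linalg.det(self.R) - 1.0) > 1e-8:
            raise ValueError("R must be a proper rotation (det +1)")
        if not np.allclose(self.R.T @ self.R, np.eye(3), atol=1e-8):
            raise ValueError("R must be orthogonal")

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(1.0, np.eye(3), np.zeros(3))

    def apply_points(self, x: np.ndarray) -> np.ndarray:
        return self.alpha * (np.asarray(x) @ self.R.T) + self.T

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Returns the transform equivalent to applying ``other`` first, then self."""
        return SimilarityTransform(
            alpha=self.alpha * other.alpha,
            R=self.R @ other.R,
            T=self.alpha * (self.R @ other.T) + self.T,
        )


def centroid_size(points: np.ndarray) -> float:
    """Root sum of squared distances from the centroid (the standard
    morphometric size measure)."""
    points = np.asarray(points, dtype=float)
    c = points.mean(axis=0)
    return float(np.sqrt(np.sum((points - c) ** 2)))


def optimal_similarity(
    source: np.ndarray, target: np.ndarray, with_scale: bool = False
) -> SimilarityTransform:
    """Least-squares similarity aligning ``source`` points onto ``target``.

    Rotation by SVD of the cross-covariance with a reflection guard
    (Kabsch/Umeyama); scale, when enabled, is the centroid-size ratio.
    """
    src = np.asarray(source, dtype=float).reshape(-1, 3)
    tgt = np.asarray(target, dtype=float).reshape(-1, 3)
    if src.shape != tgt.shape or src.shape[0] < 3:
        raise DegenerateShapeError("need >= 3 corresponding points")
    cs, ct = src.mean(axis=0), tgt.mean(axis=0)
    a = src - cs
    b = tgt - ct
    H = a.T @ b
    U, sv, Vt = np.linalg.svd(H)
    # two near-zero singular values => collinear/degenerate configuration
    if sv[1] <= 1e-12 * max(sv[0], 1.0):
        raise DegenerateShapeError("point configuration is collinear or degenerate")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    if with_scale:
        denom = centroid_size(src)
        if denom == 0:
            raise DegenerateShapeError("zero-size source shape")
        alpha = centroid_size(tgt) / denom
    else:
        alpha = 1.0
    T = ct - alpha * R @ cs
    return SimilarityTransform(alpha=alpha, R=R, T=T)


def apply_to_shape_vector(
    shape: ShapeVector, t: SimilarityTransform
) -> ShapeVector:
    """Positions map by alpha R x + T; derivative DoFs by alpha R only."""
    blocks = shape.blocks().copy()
    blocks = t.alpha * np.einsum("ij,nsj->nsi", t.R, blocks)
    blocks[:, 0, :] += t.T
    return ShapeVector(subject_id=shape.subject_id, values=blocks.ravel())


def gpa(
    shapes: list[ShapeVector],
    with_scale: bool = False,
    tol: float = 1e-6,
    max_iter: int = 100,
):
    """Generalized Procrustes alignment.

    Iteratively aligns every shape to the evolving consensus mean (the
    first shape bootstraps the reference), re-estimates the mean as the
    arithmetic average of the aligned vectors, and — when ``with_scale`` —
    normalises the consensus to unit centroid size so the similarity orbit
    is fully quotiented out.

    Returns (aligned shapes, mean ShapeVector, cumulative transforms).
    """
    if len(shapes) < 2:
        raise ValueError("GPA needs at least 2 shapes")
    n = {s.values.size for s in shapes}
    if len(n) != 1:
        raise ValueError("shape vectors differ in length")
    aligned = [ShapeVector(s.subject_id, s.values.copy()) for s in shapes]
    transforms = [SimilarityTransform.identity() for _ in shapes]
    mean = aligned[0].values.copy()
    if with_scale:
        mean = _normalise_mean(mean)
    for _ in range(max_iter):
        mean_pos = ShapeVector("mean", mean).positions()
        for i, s in enumerate(aligned):
            t = optimal_similarity(s.positions(), mean_pos, with_scale=with_scale)
            aligned[i] = apply_to_shape_vector(s, t)
            transforms[i] = t.compose(transforms[i])
        new_mean = np.mean([s.values for s in aligned], axis=0)
        if with_scale:
            new_mean = _normalise_mean(new_mean)
        change = np.linalg.norm(new_mean - mean) / max(np.linalg.norm(mean), 1e-30)
        mean = new_mean
        if change < tol:
            return aligned, ShapeVector("mean", mean), transforms
    raise GPAConvergenceError(
        f"GPA did not converge in {max_iter} iterations (last change {change:.3e})"
    )


def _normalise_mean(mean_values: np.ndarray) -> np.ndarray:
    """Pre-shape convention: centroid at the origin, unit centroid size.

    Centering before scaling matters: rescaling an off-origin consensus
    moves its centroid every iteration and the alignment never settles.
    """
    sv = ShapeVector("mean", mean_values)
    blocks = sv.blocks().copy()
    blocks[:, 0, :] -= blocks[:, 0, :].mean(axis=0)
    size = centroid_size(blocks[:, 0, :])
    if size == 0:
        raise DegenerateShapeError("zero-size consensus shape")
    return blocks.ravel() / size
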