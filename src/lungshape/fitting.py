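"""Geometry fitting of a template Hermite mesh to segmented surface points.

The fit minimises a total energy: the weighted sum of squared distances
between each data point and its projection onto the surface, plus a
Sobolev-type smoothness penalty on the parametric first and second
derivatives of the geometry.  Because projection sites depend on the
geometry being solved for, the solver alternates (a) projecting every data
point onto the current surface and (b) solving the linear least-squares
system for all nodal DoFs with the projection coordinates frozen.  Both
half-steps decrease the energy, so the outer loop is monotone.

Data points carry a surface label and are only ever matched to elements of
that label — lung-surface points never pull on fissure patches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse
from scipy.spatial import cKDTree

from .hermite import (
    MeshTopology,
    basis_weights,
    gauss_quadrature_2d,
)

log = logging.getLogger(__name__)


class SingularFitError(RuntimeError):
    """Linear system is rank deficient; raise the smoothing weights above zero."""


@dataclass
class DataPointSet:
    """Labeled surface point cloud with per-point weights (gamma)."""

    points: np.ndarray
    labels: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.points.shape[0] == 0:
            raise ValueError("empty point set")
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape[0] != self.points.shape[0]:
            raise ValueError("labels length does not match points")
        if self.weights is None:
            self.weights = np.ones(self.points.shape[0])
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape[0] != self.points.shape[0]:
            raise ValueError("weights length does not match points")
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights < 0):
            raise ValueError("weights must be finite and non-negative")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class FitConfig:
    """Solver settings.

    Smoothing weights are the penalty coefficients on the squared first,
    second and mixed parametric derivatives (mm^2 per unit xi^2 terms);
    zero disables that term.
    """

    smooth_first: float = 0.1
    smooth_second: float = 0.01
    smooth_cross: float = 0.01
    max_outer_iterations: int = 10
    convergence_tol: float = 1e-3  # mm change in RMSE
    projection_grid: int = 8
    newton_iters: int = 15
    #: measure deformation relative to the template ("template") or penalise
    #: the derivative magnitudes themselves ("zero").  The template reference
    #: keeps data-starved DoFs at their generic values instead of flattening
    #: them, which matters for cross-subject statistics.
    smooth_reference: str = "template"
    #: translate and scale the template to the cloud's centroid and centroid
    #: size before fitting; removes the gross size mismatch so the
    #: deformation penalty is measured from a comparable reference.
    initial_similarity: bool = True

    def __post_init__(self) -> None:
        for w in (self.smooth_first, self.smooth_second, self.smooth_cross):
            if w < 0:
                raise ValueError("smoothing weights must be non-negative")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")
        if self.smooth_reference not in ("template", "zero"):
            raise ValueError("smooth_reference must be 'template' or 'zero'")


@dataclass
class FitResult:
    fitted_mesh: MeshTopology
    residuals: np.ndarray
    rmse: float
    iterations_used: int
    energy_history: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# point-to-surface projection


class _SurfaceGrid:
    """Dense xi-grid samples per surface label, KD-indexed for seeding.

    Also caches the per-element DoF blocks (indexed by element id) so the
    Newton refinement can gather them without Python-level loops.
    """

    def __init__(self, mesh: MeshTopology, grid: int):
        self.mesh = mesh
        self.by_label: dict[str, tuple] = {}
        max_id = max(el.id for el in mesh.elements)
        self.dof_lut = np.zeros((max_id + 1, 4, 4, 3))
        for el in mesh.elements:
            self.dof_lut[el.id] = mesh.element_dofs(el.id)
        g = np.linspace(0.0, 1.0, grid)
        X1, X2 = np.meshgrid(g, g, indexing="ij")
        x1, x2 = X1.ravel(), X2.ravel()
        W = basis_weights(x1, x2)  # (g^2, 4, 4)
        for label in mesh.surfaces_present():
            # elements sorted by id so that equidistant ties resolve low-id
            els = sorted(mesh.elements_for_surface(label), key=lambda e: e.id)
            el_ids = np.array([el.id for el in els])
            pts = np.einsum("nks,eksc->enc", W, self.dof_lut[el_ids])
            pts = pts.reshape(-1, 3)
            eids = np.repeat(el_ids, x1.shape[0])
            xs1 = np.tile(x1, len(els))
            xs2 = np.tile(x2, len(els))
            self.by_label[label] = (cKDTree(pts), pts, eids, xs1, xs2)


def _newton_refine(dofs, xi, points, iters):
    """Batch damped Newton on squared distance; xi is (n, 2), updated in place.

    ``dofs`` is the (n, 4, 4, 3) per-point element DoF block.
    """
    from .hermite import _basis_1d, combine_weights

    for _ in range(iters):
        x1, x2 = xi[:, 0], xi[:, 1]
        a0, a1, a2 = (_basis_1d(x1, o) for o in (0, 1, 2))
        b0, b1, b2 = (_basis_1d(x2, o) for o in (0, 1, 2))
        W = np.stack(
            [
                combine_weights(a0, b0),  # f
                combine_weights(a1, b0),  # f_1
                combine_weights(a0, b1),  # f_2
                combine_weights(a2, b0),  # f_11
                combine_weights(a1, b1),  # f_12
                combine_weights(a0, b2),  # f_22
            ]
        )
        f, f1, f2, f11, f12, f22 = np.einsum("wnks,nksc->wnc", W, dofs)
        r = f - points
        g1 = np.einsum("nc,nc->n", r, f1)
        g2 = np.einsum("nc,nc->n", r, f2)
        h11 = np.einsum("nc,nc->n", f1, f1) + np.einsum("nc,nc->n", r, f11)
        h12 = np.einsum("nc,nc->n", f1, f2) + np.einsum("nc,nc->n", r, f12)
        h22 = np.einsum("nc,nc->n", f2, f2) + np.einsum("nc,nc->n", r, f22)
        det = h11 * h22 - h12 * h12
        trace = h11 + h22
        # near-singular Hessians (collapsed pole edges make one parametric
        # direction degenerate): step only along the better-conditioned
        # axis; the degenerate direction does not change the distance
        ok = det > 1e-9 * trace**2
        s1 = np.where(ok, -(h22 * g1 - h12 * g2) / np.where(ok, det, 1.0), 0.0)
        s2 = np.where(ok, -(h11 * g2 - h12 * g1) / np.where(ok, det, 1.0), 0.0)
        use1 = (~ok) & (h11 >= h22) & (h11 > 1e-12)
        use2 = (~ok) & (h22 > h11) & (h22 > 1e-12)
        s1 = np.where(use1, -g1 / np.where(use1, h11, 1.0), s1)
        s2 = np.where(use2, -g2 / np.where(use2, h22, 1.0), s2)
        # damp long steps; keeps the iteration inside the basin
        norm = np.hypot(s1, s2)
        scale = np.where(norm > 0.5, 0.5 / np.where(norm > 0, norm, 1.0), 1.0)
        new1 = np.clip(xi[:, 0] + s1 * scale, 0.0, 1.0)
        new2 = np.clip(xi[:, 1] + s2 * scale, 0.0, 1.0)
        moved = max(np.abs(new1 - xi[:, 0]).max(), np.abs(new2 - xi[:, 1]).max())
        xi[:, 0] = new1
        xi[:, 1] = new2
        if moved < 1e-12:
            break
    f = np.einsum(
        "nks,nksc->nc", basis_weights(xi[:, 0], xi[:, 1]), dofs
    )
    return np.linalg.norm(f - points, axis=1)


def project_points(
    mesh: MeshTopology,
    points: np.ndarray,
    labels: np.ndarray,
    grid: int = 8,
    newton_iters: int = 15,
    _surface_grid: _SurfaceGrid | None = None,
):
    """Project each labeled point onto the nearest element of its surface.

    Returns (element_ids, xi (n, 2), distances).  A coarse per-label grid
    search seeds a damped Newton refinement of the squared distance; if
    Newton fails to improve on the grid seed the seed is kept.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    labels = np.asarray(labels, dtype=object)
    sg = _surface_grid or _SurfaceGrid(mesh, grid)
    n = points.shape[0]
    out_e = np.zeros(n, dtype=int)
    out_xi = np.zeros((n, 2))
    out_d = np.zeros(n)
    for label in np.unique(labels):
        if label not in sg.by_label:
            raise ValueError(
                f"no elements labeled {label!r} in mesh (surfaces: "
                f"{sorted(mesh.surfaces_present())})"
            )
        mask = labels == label
        pts = points[mask]
        tree, gpts, eids, xs1, xs2 = sg.by_label[label]
        k = min(2, gpts.shape[0])
        dists, idx = tree.query(pts, k=k)
        if k == 1:
            dists = dists[:, None]
            idx = idx[:, None]
        sel = idx[:, 0].copy()
        # Equidistant grid seeds (coincident samples at shared corners and
        # collapsed pole edges) are resolved to the lowest (element id, xi)
        # candidate.  The 1e-6 mm window is a geometric tolerance: coincident
        # samples reached through different elements agree only to float
        # round-off, and the choice must not depend on the mesh's pose.
        if k > 1:
            ambiguous = np.where(dists[:, 1] <= dists[:, 0] + 1e-6)[0]
            for j in ambiguous:
                members = tree.query_ball_point(pts[j], dists[j, 0] + 1e-6)
                sel[j] = min(members, key=lambda m: (eids[m], xs1[m], xs2[m]))
        e0 = eids[sel]
        xi = np.column_stack([xs1[sel], xs2[sel]]).copy()
        d0 = np.linalg.norm(gpts[sel] - pts, axis=1)
        xi_ref = xi.copy()
        d_ref = _newton_refine(sg.dof_lut[e0], xi_ref, pts, newton_iters)
        worse = d_ref > d0
        if np.any(worse):
            log.debug("projection Newton fell back to grid for %d points", worse.sum())
        xi_ref[worse] = xi[worse]
        d_ref[worse] = d0[worse]
        out_e[mask] = e0
        out_xi[mask] = xi_ref
        out_d[mask] = d_ref
    return out_e, out_xi, out_d


def project_point(mesh: MeshTopology, point, grid: int = 8):
    """Single-point convenience wrapper; searches all surfaces.

    Returns (element_id, xi1, xi2, distance).
    """
    point = np.asarray(point, dtype=float).reshape(3)
    best = None
    for label in sorted(mesh.surfaces_present()):
        e, xi, d = project_points(
            mesh, point[None, :], np.array([label], dtype=object), grid=grid
        )
        cand = (float(d[0]), int(e[0]), float(xi[0, 0]), float(xi[0, 1]))
        if best is None or cand[0] < best[0] or (
            abs(cand[0] - best[0]) < 1e-12 and cand[1] < best[1]
        ):
            best = cand
    d, e, x1, x2 = best
    return e, x1, x2, d


# ---------------------------------------------------------------------------
# smoothness penalty


def smoothness_matrix(
    mesh: MeshTopology,
    smooth_first: float,
    smooth_second: float,
    smooth_cross: float,
) -> np.ndarray:
    """Symmetric PSD quadratic form over the per-coordinate scalar DoFs.

    4x4 Gauss-Legendre quadrature per element of
    w1 (|f_1|^2 + |f_2|^2) + w2 (|f_11|^2 + |f_22|^2) + wc |f_12|^2
    applied identically to each spatial coordinate; returns the dense
    (4 n_nodes, 4 n_nodes) matrix for a single coordinate.
    """
    ndof = 4 * mesh.n_nodes
    S = np.zeros((ndof, ndof))
    if smooth_first == 0 and smooth_second == 0 and smooth_cross == 0:
        return S
    qp, qw = gauss_quadrature_2d()
    terms = []
    if smooth_first > 0:
        terms += [(1, 0, smooth_first), (0, 1, smooth_first)]
    if smooth_second > 0:
        terms += [(2, 0, smooth_second), (0, 2, smooth_second)]
    if smooth_cross > 0:
        terms += [(1, 1, smooth_cross)]
    # 16x16 element form, identical for every element (unit xi square)
    el_form = np.zeros((16, 16))
    for d1, d2, w in terms:
        B = basis_weights(qp[:, 0], qp[:, 1], d1, d2).reshape(-1, 16)
        el_form += w * (B.T * qw) @ B
    for el in mesh.elements:
        rows = np.array([mesh.node_index(nid) for nid in el.node_ids])
        gdof = (rows[:, None] * 4 + np.arange(4)[None, :]).ravel()
        S[np.ix_(gdof, gdof)] += el_form
    return S


def fit_energy(
    mesh: MeshTopology,
    data: DataPointSet,
    config: FitConfig,
    S: np.ndarray | None = None,
    distances: np.ndarray | None = None,
    reference: MeshTopology | None = None,
) -> float:
    """Total fitting energy: weighted squared misfit + deformation penalty."""
    if distances is None:
        _, _, distances = project_points(
            mesh, data.points, data.labels, config.projection_grid,
            config.newton_iters,
        )
    if S is None:
        S = smoothness_matrix(
            mesh, config.smooth_first, config.smooth_second, config.smooth_cross
        )
    u = mesh.node_dofs.reshape(-1, 3)  # (4n, 3)
    if reference is not None and config.smooth_reference == "template":
        u = u - reference.node_dofs.reshape(-1, 3)
    smooth = float(np.einsum("ic,ij,jc->", u, S, u))
    return float(np.sum(data.weights * distances**2) + smooth)


# ---------------------------------------------------------------------------
# the fit


def _element_gdof_lut(mesh) -> np.ndarray:
    """(max element id + 1, 16) map from element id to global scalar DoF columns."""
    max_id = max(el.id for el in mesh.elements)
    lut = np.zeros((max_id + 1, 16), dtype=int)
    for el in mesh.elements:
        nrows = np.array([mesh.node_index(nid) for nid in el.node_ids])
        lut[el.id] = (nrows[:, None] * 4 + np.arange(4)[None, :]).ravel()
    return lut


def _design_matrix(mesh, eids, xi, n_points, gdof_lut=None):
    """Sparse (n_points, 4 n_nodes) linear map from scalar DoFs to one coordinate."""
    if gdof_lut is None:
        gdof_lut = _element_gdof_lut(mesh)
    rows = np.repeat(np.arange(n_points), 16)
    cols = gdof_lut[np.asarray(eids, dtype=int)].ravel()
    vals = basis_weights(xi[:, 0], xi[:, 1]).reshape(n_points, 16).ravel()
    return scipy.sparse.csr_matrix(
        (vals, (rows, cols)), shape=(n_points, 4 * mesh.n_nodes)
    )


def fit_mesh(
    template: MeshTopology, data: DataPointSet, config: FitConfig | None = None
) -> FitResult:
    """Fit the template to a labeled point cloud.

    Alternates projection and a global linear least-squares solve for all
    nodal DoFs (the three spatial coordinates share one normal matrix).
    Stops when the RMSE change drops below ``convergence_tol`` or the outer
    iteration budget is exhausted.
    """
    config = config or FitConfig()
    template = template.copy()
    if config.initial_similarity:
        from .alignment import centroid_size
        from .hermite import sample_surface

        samples, _ = sample_surface(template, 4)
        # RMS (per-point) size: cloud and template samples differ in count
        s = (centroid_size(data.points) / np.sqrt(data.n_points)) / (
            centroid_size(samples) / np.sqrt(samples.shape[0])
        )
        dofs = template.node_dofs * s
        dofs[:, 0, :] += data.points.mean(axis=0) - s * samples.mean(axis=0)
        template = template.with_dofs(dofs)
    mesh = template.copy()
    S = smoothness_matrix(
        mesh, config.smooth_first, config.smooth_second, config.smooth_cross
    )
    u_ref = (
        template.node_dofs.reshape(-1, 3)
        if config.smooth_reference == "template"
        else np.zeros((4 * template.n_nodes, 3))
    )
    gamma = data.weights
    sg = _SurfaceGrid(mesh, config.projection_grid)
    eids, xi, dist = project_points(
        mesh, data.points, data.labels, config.projection_grid,
        config.newton_iters, _surface_grid=sg,
    )
    energy = [fit_energy(mesh, data, config, S=S, distances=dist, reference=template)]
    rmse_prev = float(np.sqrt(np.mean(dist**2)))
    iterations = 0
    gdof_lut = _element_gdof_lut(mesh)
    for it in range(1, config.max_outer_iterations + 1):
        iterations = it
        A = _design_matrix(mesh, eids, xi, data.n_points, gdof_lut)
        AtG = A.T.multiply(gamma)  # (4n, N) weighted
        M = (AtG @ A).toarray() + S
        rhs = AtG @ data.points + S @ u_ref  # (4n, 3)
        try:
            cho = scipy.linalg.cho_factor(M)
            u = scipy.linalg.cho_solve(cho, rhs)
        except scipy.linalg.LinAlgError as exc:
            raise SingularFitError(
                "fitting system is rank deficient; increase the smoothing "
                "weights above zero or supply more data points"
            ) from exc
        mesh = mesh.with_dofs(u.reshape(mesh.n_nodes, 4, 3))
        sg = _SurfaceGrid(mesh, config.projection_grid)
        eids, xi, dist = project_points(
            mesh, data.points, data.labels, config.projection_grid,
            config.newton_iters, _surface_grid=sg,
        )
        energy.append(
            fit_energy(mesh, data, config, S=S, distances=dist, reference=template)
        )
        rmse = float(np.sqrt(np.mean(dist**2)))
        if abs(rmse_prev - rmse) < config.convergence_tol:
            rmse_prev = rmse
            break
        rmse_prev = rmse
    return FitResult(
        fitted_mesh=mesh,
        residuals=dist,
        rmse=rmse_prev,
        iterations_used=iterations,
        energy_history=energy,
    )
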