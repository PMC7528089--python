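"""Bicubic Hermite surface meshes.

A mesh is a set of nodes, each carrying 12 degrees of freedom (position,
the two first parametric derivatives and the mixed second derivative, three
spatial components each), and quadrilateral elements that interpolate those
nodal data with cubic Hermite tensor-product basis functions.  Because the
basis interpolates derivatives as well as positions, a coarse mesh encodes
surface curvature between nodes; the same node ordering across subjects
gives point-to-point shape correspondence for statistics.

Local element coordinates are (xi1, xi2) in the unit square, corners in the
order (0,0), (1,0), (0,1), (1,1) — xi1 varies fastest.  Derivative DoFs are
stored per unit xi (no arc-length scaling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SURFACE_LABELS = (
    "left_lung",
    "right_lung",
    "left_oblique_fissure",
    "right_oblique_fissure",
    "horizontal_fissure",
)

LANDMARK_KINDS = ("anatomical", "pseudo", "none")

#: number of scalar degrees of freedom per node: 4 per spatial direction
#: (value, d/dxi1, d/dxi2, d2/dxi1 dxi2) times 3 directions.
DOFS_PER_NODE = 12

# DoF slot indices within a node's (4, 3) block.
SLOT_VALUE, SLOT_D1, SLOT_D2, SLOT_D12 = 0, 1, 2, 3


class MeshValidationError(ValueError):
    """Raised when a mesh violates its structural invariants."""


@dataclass
class QuadElement:
    """Four-node quadrilateral patch with a surface label."""

    id: int
    node_ids: tuple[int, int, int, int]
    surface: str

    def __post_init__(self) -> None:
        if len(set(self.node_ids)) != 4:
            raise MeshValidationError(
                f"element {self.id}: node ids must be distinct, got {self.node_ids}"
            )
        if self.surface not in SURFACE_LABELS:
            raise MeshValidationError(
                f"element {self.id}: unknown surface label {self.surface!r}; "
                f"allowed: {', '.join(SURFACE_LABELS)}"
            )


@dataclass
class MeshTopology:
    """Nodes with 12 DoFs each plus labeled quad elements.

    ``node_dofs`` has shape (n_nodes, 4, 3): per node the rows are position,
    d/dxi1, d/dxi2, d2/dxi1dxi2 (mm, mm per unit xi).  ``node_ids`` maps row
    index -> external id; elements reference external ids.
    """

    node_ids: list[int]
    node_dofs: np.ndarray
    elements: list[QuadElement]
    landmarks: list[str] = field(default_factory=list)
    schema_version: str = "1"

    def __post_init__(self) -> None:
        self.node_dofs = np.asarray(self.node_dofs, dtype=float)
        if self.node_dofs.shape != (len(self.node_ids), 4, 3):
            raise MeshValidationError(
                f"node_dofs shape {self.node_dofs.shape} does not match "
                f"{len(self.node_ids)} nodes (expected (n, 4, 3))"
            )
        if not np.all(np.isfinite(self.node_dofs)):
            raise MeshValidationError("node DoFs must all be finite")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise MeshValidationError("duplicate node ids")
        if not self.landmarks:
            self.landmarks = ["none"] * len(self.node_ids)
        for lm in self.landmarks:
            if lm not in LANDMARK_KINDS:
                raise MeshValidationError(f"unknown landmark kind {lm!r}")
        self._index = {nid: i for i, nid in enumerate(self.node_ids)}
        self._eindex = {}
        for el in self.elements:
            for nid in el.node_ids:
                if nid not in self._index:
                    raise MeshValidationError(
                        f"element {el.id} references missing node {nid}"
                    )
            if el.id in self._eindex:
                raise MeshValidationError(f"duplicate element id {el.id}")
            self._eindex[el.id] = el

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def node_index(self, node_id: int) -> int:
        return self._index[node_id]

    def element(self, element_id: int) -> QuadElement:
        try:
            return self._eindex[element_id]
        except KeyError:
            raise KeyError(f"unknown element id {element_id}") from None

    def element_dofs(self, element_id: int) -> np.ndarray:
        """(4 corners, 4 slots, 3 coords) DoF block for one element."""
        el = self.element(element_id)
        rows = [self._index[nid] for nid in el.node_ids]
        return self.node_dofs[rows]

    def positions(self) -> np.ndarray:
        """(n_nodes, 3) nodal positions."""
        return self.node_dofs[:, SLOT_VALUE, :]

    def surfaces_present(self) -> set[str]:
        return {el.surface for el in self.elements}

    def elements_for_surface(self, surface: str) -> list[QuadElement]:
        return [el for el in self.elements if el.surface == surface]

    def copy(self) -> "MeshTopology":
        return MeshTopology(
            node_ids=list(self.node_ids),
            node_dofs=self.node_dofs.copy(),
            elements=[
                QuadElement(el.id, tuple(el.node_ids), el.surface)
                for el in self.elements
            ],
            landmarks=list(self.landmarks),
            schema_version=self.schema_version,
        )

    def with_dofs(self, node_dofs: np.ndarray) -> "MeshTopology":
        """Same topology, new nodal data."""
        out = self.copy()
        out.node_dofs = np.asarray(node_dofs, dtype=float).reshape(
            self.n_nodes, 4, 3
        )
        return out


def hermite_basis(xi: float) -> tuple[float, float, float, float]:
    """The four 1-D cubic Hermite polynomials at ``xi`` in [0, 1].

    Returns (value0, deriv0, value1, deriv1): the functions that
    interpolate, respectively, the value at 0, the derivative at 0, the
    value at 1 and the derivative at 1.
    """
    if not 0.0 <= xi <= 1.0:
        raise ValueError(f"xi must lie in [0, 1], got {xi}")
    t = float(xi)
    return (
        2 * t**3 - 3 * t**2 + 1,
        t**3 - 2 * t**2 + t,
        -2 * t**3 + 3 * t**2,
        t**3 - t**2,
    )


def _basis_1d(t: np.ndarray, order: int) -> np.ndarray:
    """(..., 4) array of the 1-D Hermite basis or its derivatives.

    Column order (value0, deriv0, value1, deriv1); ``order`` is the
    derivative order with respect to xi (0, 1 or 2).
    """
    t = np.asarray(t, dtype=float)
    if order == 0:
        cols = (
            2 * t**3 - 3 * t**2 + 1,
            t**3 - 2 * t**2 + t,
            -2 * t**3 + 3 * t**2,
            t**3 - t**2,
        )
    elif order == 1:
        cols = (
            6 * t**2 - 6 * t,
            3 * t**2 - 4 * t + 1,
            -6 * t**2 + 6 * t,
            3 * t**2 - 2 * t,
        )
    elif order == 2:
        cols = (12 * t - 6, 6 * t - 4, -12 * t + 6, 6 * t - 2)
    else:
        raise ValueError(f"unsupported derivative order {order}")
    return np.stack(cols, axis=-1)


def combine_weights(b1: np.ndarray, b2: np.ndarray) -> np.ndarray:
    """Combine two 1-D basis rows into (..., 4 corners, 4 slots) weights."""
    v1 = b1[..., (0, 2)]  # value basis for end 0/1 along xi1
    g1 = b1[..., (1, 3)]  # derivative basis along xi1
    v2 = b2[..., (0, 2)]
    g2 = b2[..., (1, 3)]
    corners = [(0, 0), (1, 0), (0, 1), (1, 1)]
    out = np.empty(b1.shape[:-1] + (4, 4))
    for k, (a, b) in enumerate(corners):
        out[..., k, SLOT_VALUE] = v1[..., a] * v2[..., b]
        out[..., k, SLOT_D1] = g1[..., a] * v2[..., b]
        out[..., k, SLOT_D2] = v1[..., a] * g2[..., b]
        out[..., k, SLOT_D12] = g1[..., a] * g2[..., b]
    return out


def basis_weights(xi1, xi2, d1: int = 0, d2: int = 0) -> np.ndarray:
    """Tensor-product basis weights for one or many (xi1, xi2) points.

    Returns shape (..., 4 corners, 4 slots); contracting with an element's
    (4, 4, 3) DoF block gives the (d1, d2)-th parametric derivative of the
    surface at those points.
    """
    xi1 = np.asarray(xi1, dtype=float)
    xi2 = np.asarray(xi2, dtype=float)
    # corner (a, b): value slot -> v_a(xi1) v_b(xi2); dxi1 -> d_a v_b; etc.
    return combine_weights(_basis_1d(xi1, d1), _basis_1d(xi2, d2))


def evaluate_surface(
    mesh: MeshTopology,
    element_id: int,
    xi1: float,
    xi2: float,
    order: str = "value",
) -> np.ndarray:
    """Evaluate an element at local coordinates.

    order "value" -> (3,) position; "d1" -> (2, 3) first parametric
    derivatives (d/dxi1, d/dxi2); "d2" -> (3, 3) second derivatives
    (d2/dxi1^2, d2/dxi1 dxi2, d2/dxi2^2).
    """
    if not (0.0 <= xi1 <= 1.0 and 0.0 <= xi2 <= 1.0):
        raise ValueError(f"local coordinates must lie in [0,1]^2, got {(xi1, xi2)}")
    dofs = mesh.element_dofs(element_id)
    if order == "value":
        w = basis_weights(xi1, xi2)
        return np.einsum("ks,ksc->c", w, dofs)
    if order == "d1":
        return np.stack(
            [
                np.einsum("ks,ksc->c", basis_weights(xi1, xi2, 1, 0), dofs),
                np.einsum("ks,ksc->c", basis_weights(xi1, xi2, 0, 1), dofs),
            ]
        )
    if order == "d2":
        return np.stack(
            [
                np.einsum("ks,ksc->c", basis_weights(xi1, xi2, 2, 0), dofs),
                np.einsum("ks,ksc->c", basis_weights(xi1, xi2, 1, 1), dofs),
                np.einsum("ks,ksc->c", basis_weights(xi1, xi2, 0, 2), dofs),
            ]
        )
    raise ValueError(f"unknown order {order!r}; expected value, d1 or d2")


def evaluate_elements(
    mesh: MeshTopology,
    element_ids: np.ndarray,
    xi1: np.ndarray,
    xi2: np.ndarray,
    d1: int = 0,
    d2: int = 0,
) -> np.ndarray:
    """Vectorised evaluation: one (element, xi1, xi2) triple per output row."""
    element_ids = np.asarray(element_ids)
    dofs = np.stack([mesh.element_dofs(int(e)) for e in element_ids])
    w = basis_weights(np.asarray(xi1), np.asarray(xi2), d1, d2)
    return np.einsum("nks,nksc->nc", w, dofs)


def sample_surface(
    mesh: MeshTopology,
    per_element_grid: int,
    surfaces: set[str] | None = None,
):
    """Regular xi-grid samples on every element.

    Returns (points (m, 3), provenance list of (element_id, xi1, xi2)).
    """
    if per_element_grid < 2:
        raise ValueError("per_element_grid must be >= 2")
    g = np.linspace(0.0, 1.0, per_element_grid)
    x1, x2 = np.meshgrid(g, g, indexing="xy")
    x1 = x1.ravel()
    x2 = x2.ravel()
    points = []
    prov = []
    for el in mesh.elements:
        if surfaces is not None and el.surface not in surfaces:
            continue
        dofs = mesh.element_dofs(el.id)
        w = basis_weights(x1, x2)
        pts = np.einsum("nks,ksc->nc", w, dofs)
        points.append(pts)
        prov.extend((el.id, float(a), float(b)) for a, b in zip(x1, x2))
    if not points:
        return np.empty((0, 3)), []
    return np.vstack(points), prov


def surface_normal(mesh: MeshTopology, element_id: int, xi1: float, xi2: float) -> np.ndarray:
    """Unit normal d1 x d2 (right-handed in local coordinates)."""
    d = evaluate_surface(mesh, element_id, xi1, xi2, order="d1")
    n = np.cross(d[0], d[1])
    nn = np.linalg.norm(n)
    if nn == 0:
        raise ValueError("degenerate surface point: zero normal")
    return n / nn


# 4-point Gauss-Legendre rule on [0, 1]
_GL4_X = (np.polynomial.legendre.leggauss(4)[0] + 1.0) / 2.0
_GL4_W = np.polynomial.legendre.leggauss(4)[1] / 2.0


def gauss_quadrature_2d():
    """(points (16, 2), weights (16,)) tensor-product 4x4 rule on the unit square."""
    X1, X2 = np.meshgrid(_GL4_X, _GL4_X, indexing="ij")
    W = np.outer(_GL4_W, _GL4_W)
    return np.column_stack([X1.ravel(), X2.ravel()]), W.ravel()


def mesh_volume(mesh: MeshTopology, surfaces: set[str] | None = None) -> float:
    """Enclosed volume of the (closed, outward-oriented) labeled surfaces.

    Divergence theorem: V = (1/3) integral of p . (dp/dxi1 x dp/dxi2).
    Only meaningful when the selected surfaces are watertight.
    """
    qp, qw = gauss_quadrature_2d()
    vol = 0.0
    for el in mesh.elements:
        if surfaces is not None and el.surface not in surfaces:
            continue
        dofs = mesh.element_dofs(el.id)
        p = np.einsum("nks,ksc->nc", basis_weights(qp[:, 0], qp[:, 1]), dofs)
        t1 = np.einsum("nks,ksc->nc", basis_weights(qp[:, 0], qp[:, 1], 1, 0), dofs)
        t2 = np.einsum("nks,ksc->nc", basis_weights(qp[:, 0], qp[:, 1], 0, 1), dofs)
        vol += np.sum(qw * np.einsum("nc,nc->n", p, np.cross(t1, t2)))
    return float(vol / 3.0)
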