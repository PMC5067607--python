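"""Static spring-network model of a light-activated contractile gel region.

The gel is represented by a regular two-dimensional array of crosslinker
nodes inside a periodic simulation cell.  Every node is permanently
connected to its four nearest neighbours by harmonic springs with vanishing
rest length.  Passive (quiescent) springs carry the weak coefficient ``k_w``;
springs inside the optically activated region are stiffened to
``k_s = k_w / K`` with the spring-coefficient ratio ``K = k_w / k_s <= 1``.

Because all forces are linear in the node positions, the force-free final
state is the solution of a sparse linear system: a weighted graph Laplacian
``A`` (set by topology and the activated-edge choice) and a constant vector
``b`` (from the periodic wrap offsets) give ``x_fin = A^{-1} b``.  For a
circular activated region the model predicts shape-preserving contraction
with final-to-initial radius ratio equal to ``K``; geometries with corners
deform non-affinely (concave edges of a full square, rounding of the inner
boundary of a hollow square).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "SpringNetwork",
    "ActivationGeometry",
    "EquilibriumProblem",
    "ShapeMetrics",
    "build_grid",
    "activate",
    "solve_equilibrium",
    "measure_shape",
    "total_energy",
    "residual_force",
]

#: nodes above this count switch the solver from a direct factorization to CG
_DIRECT_SOLVE_LIMIT = 100_000
_CG_TOL = 1e-10


@dataclass
class SpringNetwork:
    """Periodic 4-neighbour grid of crosslinker nodes joined by springs.

    Node ``(ix, iy)`` sits at ``(ix * spacing, iy * spacing)`` and has flat
    index ``iy * nx + ix``.  ``offsets[e]`` is the lattice translation added
    to the position of ``edges[e, 1]`` when the edge wraps around the
    periodic cell, so the edge vector is ``x_j + offset - x_i``.
    """

    nx: int
    ny: int
    spacing: float
    positions: np.ndarray          # (N, 2) initial node coordinates
    edges: np.ndarray              # (E, 2) int node indices
    offsets: np.ndarray            # (E, 2) wrap translation of endpoint 1
    coefficients: np.ndarray       # (E,) spring coefficient per edge
    k_weak: float = 1.0
    ratio: float = 1.0             # K = k_w / k_s after activation
    activated: np.ndarray = field(default=None)  # (E,) bool

    def __post_init__(self):
        if self.activated is None:
            self.activated = np.zeros(len(self.edges), dtype=bool)

    @property
    def n_nodes(self) -> int:
        return self.nx * self.ny

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        np.add.at(deg, self.edges[:, 0], 1)
        np.add.at(deg, self.edges[:, 1], 1)
        return deg

    @property
    def cell_size(self) -> tuple[float, float]:
        return self.nx * self.spacing, self.ny * self.spacing


@dataclass
class ActivationGeometry:
    """Parametric mask selecting the optically activated part of the gel.

    kind:
        ``circle(radius)``, ``square(half_width)``,
        ``hollow_square(outer_half_width, wall_thickness)``,
        ``rectangle(half_length, half_width)`` or ``raster(mask)`` with a
        boolean (ny, nx) array.  ``center`` defaults to the cell centre.
    """

    kind: Literal["circle", "square", "hollow_square", "rectangle", "raster"]
    radius: Optional[float] = None
    half_width: Optional[float] = None
    outer_half_width: Optional[float] = None
    wall_thickness: Optional[float] = None
    half_length: Optional[float] = None
    center: Optional[tuple[float, float]] = None
    mask: Optional[np.ndarray] = None

    def _center(self, network: SpringNetwork) -> np.ndarray:
        if self.center is not None:
            return np.asarray(self.center, dtype=float)
        lx, ly = network.cell_size
        return np.array([lx / 2.0, ly / 2.0])

    def _extent(self) -> tuple[float, float]:
        """Half-extent (x, y) of the parametric shapes, for the margin check."""
        if self.kind == "circle":
            return self.radius, self.radius
        if self.kind == "square":
            return self.half_width, self.half_width
        if self.kind == "hollow_square":
            return self.outer_half_width, self.outer_half_width
        if self.kind == "rectangle":
            return self.half_length, self.half_width
        return 0.0, 0.0

    def validate(self, network: SpringNetwork) -> None:
        params = {
            "circle": ("radius",),
            "square": ("half_width",),
            "hollow_square": ("outer_half_width", "wall_thickness"),
            "rectangle": ("half_length", "half_width"),
            "raster": ("mask",),
        }
        if self.kind not in params:
            raise ValueError(f"unknown geometry kind {self.kind!r}")
        for name in params[self.kind]:
            value = getattr(self, name)
            if value is None:
                raise ValueError(f"{self.kind} geometry requires {name}")
            if name != "mask" and value <= 0:
                raise ValueError(f"{name} must be positive")
        if self.kind == "raster":
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != (network.ny, network.nx):
                raise ValueError(
                    f"raster mask shape {mask.shape} does not match grid "
                    f"({network.ny}, {network.nx})"
                )
            return
        ex, ey = self._extent()
        cx, cy = self._center(network)
        lx, ly = network.cell_size
        s = network.spacing
        if (cx - ex < s - 1e-9 or cx + ex > lx - s + 1e-9
                or cy - ey < s - 1e-9 or cy + ey > ly - s + 1e-9):
            raise ValueError(
                "geometry must fit inside the periodic cell with a margin of "
                "at least one lattice spacing"
            )

    def node_mask(self, network: SpringNetwork) -> np.ndarray:
        """Boolean flag per node: does the node lie inside the geometry?

        Boundaries are inclusive (``<= radius`` / ``<= half_width``).
        """
        self.validate(network)
        if self.kind == "raster":
            return np.asarray(self.mask, dtype=bool).ravel()
        c = self._center(network)
        d = network.positions - c
        eps = 1e-9 * network.spacing
        if self.kind == "circle":
            return np.hypot(d[:, 0], d[:, 1]) <= self.radius + eps
        if self.kind == "square":
            cheb = np.maximum(np.abs(d[:, 0]), np.abs(d[:, 1]))
            return cheb <= self.half_width + eps
        if self.kind == "hollow_square":
            cheb = np.maximum(np.abs(d[:, 0]), np.abs(d[:, 1]))
            outer = cheb <= self.outer_half_width + eps
            inner = cheb < self.outer_half_width - self.wall_thickness - eps
            return outer & ~inner
        if self.kind == "rectangle":
            return (np.abs(d[:, 0]) <= self.half_length + eps) & (
                np.abs(d[:, 1]) <= self.half_width + eps
            )
        raise AssertionError(self.kind)


@dataclass
class EquilibriumProblem:
    """The sparse linear system describing the relaxation and its solution.

    ``system_matrix`` acts on the 2N displacement coordinates (x block then
    y block); ``constant_vector`` collects the net spring force at the
    initial configuration.  The translational nullspace is removed by
    constraining the mean displacement to zero.
    """

    network: SpringNetwork
    system_matrix: sp.spmatrix
    constant_vector: np.ndarray
    x_init: np.ndarray             # (N, 2)
    x_fin: np.ndarray              # (N, 2)

    @property
    def displacements(self) -> np.ndarray:
        return self.x_fin - self.x_init


@dataclass
class ShapeMetrics:
    """Shape descriptors of the relaxed activated region.

    ``boundary_radius_cv`` is the coefficient of variation of the per-node
    final/initial boundary-radius ratio — a shape-preservation measure that
    is insensitive to the lattice discretization of the initial mask.
    """

    radius_ratio: float                      # mean boundary radius, final/initial
    boundary_radius_cv: float                # std/mean of final boundary radii
    axis_half_lengths: tuple[float, float]   # (X_fin, Y_fin)
    concavity_scores: Optional[np.ndarray]   # per outer edge (bottom,right,top,left)
    inner_circularity_initial: Optional[float]
    inner_circularity_final: Optional[float]
    outer_circularity_final: Optional[float]

    def to_dict(self) -> dict:
        return {
            "radius_ratio": self.radius_ratio,
            "boundary_radius_cv": self.boundary_radius_cv,
            "X_fin": self.axis_half_lengths[0],
            "Y_fin": self.axis_half_lengths[1],
            "concavity_scores": (
                None if self.concavity_scores is None
                else [float(v) for v in self.concavity_scores]
            ),
            "inner_circularity_initial": self.inner_circularity_initial,
            "inner_circularity_final": self.inner_circularity_final,
            "outer_circularity_final": self.outer_circularity_final,
        }


def build_grid(nx: int, ny: int, spacing: float, k_weak: float = 1.0) -> SpringNetwork:
    """Build the periodic 4-neighbour grid with all-weak springs.

    Every node gets one edge to its +x and one to its +y neighbour, so the
    network has ``2 * nx * ny`` edges and every node degree 4.
    """
    if nx < 3 or ny < 3:
        raise ValueError("periodic 4-neighbour grid needs nx, ny >= 3")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny))
    positions = np.column_stack([ix.ravel() * spacing, iy.ravel() * spacing]).astype(float)

    idx = np.arange(nx * ny).reshape(ny, nx)
    right = np.roll(idx, -1, axis=1)
    up = np.roll(idx, -1, axis=0)
    edges = np.concatenate([
        np.column_stack([idx.ravel(), right.ravel()]),
        np.column_stack([idx.ravel(), up.ravel()]),
    ])
    offsets = np.zeros((2 * nx * ny, 2))
    # +x edges leaving the last column wrap by the full cell width; same for +y
    wrap_x = np.zeros((ny, nx), dtype=bool)
    wrap_x[:, -1] = True
    wrap_y = np.zeros((ny, nx), dtype=bool)
    wrap_y[-1, :] = True
    offsets[: nx * ny, 0] = np.where(wrap_x.ravel(), nx * spacing, 0.0)
    offsets[nx * ny:, 1] = np.where(wrap_y.ravel(), ny * spacing, 0.0)

    coefficients = np.full(2 * nx * ny, float(k_weak))
    return SpringNetwork(
        nx=nx, ny=ny, spacing=float(spacing), positions=positions,
        edges=edges, offsets=offsets, coefficients=coefficients,
        k_weak=float(k_weak), ratio=1.0,
    )


def activate(network: SpringNetwork, geometry: ActivationGeometry, K: float) -> SpringNetwork:
    """Stiffen every spring whose both endpoints lie inside the geometry.

    Activated springs get ``k_s = k_w / K``; the rest keep ``k_w``.  Returns
    a new network; the input is not modified.
    """
    if not (0 < K <= 1):
        raise ValueError("spring-coefficient ratio K must satisfy 0 < K <= 1")
    node_in = geometry.node_mask(network)
    edge_in = node_in[network.edges[:, 0]] & node_in[network.edges[:, 1]]
    if not edge_in.any():
        warnings.warn("activation geometry selects no edges; network unchanged",
                      stacklevel=2)
    coefficients = np.where(edge_in, network.k_weak / K, network.k_weak)
    return SpringNetwork(
        nx=network.nx, ny=network.ny, spacing=network.spacing,
        positions=network.positions.copy(), edges=network.edges,
        offsets=network.offsets, coefficients=coefficients,
        k_weak=network.k_weak, ratio=float(K), activated=edge_in,
    )


def _weighted_laplacian(network: SpringNetwork) -> sp.csc_matrix:
    i, j = network.edges[:, 0], network.edges[:, 1]
    k = network.coefficients
    n = network.n_nodes
    rows = np.concatenate([i, j, i, j])
    cols = np.concatenate([i, j, j, i])
    vals = np.concatenate([k, k, -k, -k])
    return sp.csc_matrix((vals, (rows, cols)), shape=(n, n))


def _net_force(network: SpringNetwork, positions: np.ndarray) -> np.ndarray:
    """Net spring force on every node at the given positions, shape (N, 2)."""
    i, j = network.edges[:, 0], network.edges[:, 1]
    vec = positions[j] + network.offsets - positions[i]
    f = network.coefficients[:, None] * vec
    force = np.zeros_like(positions)
    np.add.at(force, i, f)
    np.add.at(force, j, -f)
    return force


def total_energy(network: SpringNetwork, positions: Optional[np.ndarray] = None) -> float:
    """Total elastic energy ½ Σ k_e |x_j + offset - x_i|² of the network."""
    if positions is None:
        positions = network.positions
    i, j = network.edges[:, 0], network.edges[:, 1]
    vec = positions[j] + network.offsets - positions[i]
    return float(0.5 * np.sum(network.coefficients * np.einsum("ij,ij->i", vec, vec)))


def residual_force(problem: EquilibriumProblem) -> float:
    """Max-norm of the net nodal force at the solved final state."""
    return float(np.abs(_net_force(problem.network, problem.x_fin)).max())


def solve_equilibrium(network: SpringNetwork) -> EquilibriumProblem:
    """Solve the force-free equilibrium of the (possibly activated) network.

    With zero rest lengths the x and y displacement components decouple and
    each satisfies ``L u = f`` with the weighted graph Laplacian ``L`` and
    the net initial force ``f``.  The pure-translation nullspace is removed
    by fixing the mean displacement to zero; the cell vectors are held fixed.
    """
    lap = _weighted_laplacian(network)
    f = _net_force(network, network.positions)
    n = network.n_nodes

    # f sums to zero componentwise, so the grounded system is consistent;
    # ground node 0 and restore the zero-mean gauge afterwards.
    keep = np.arange(1, n)
    lap_g = lap[keep][:, keep].tocsc()
    u = np.zeros((n, 2))
    if n <= _DIRECT_SOLVE_LIMIT:
        solve = spla.factorized(lap_g)
        for c in range(2):
            u[keep, c] = solve(f[keep, c])
    else:
        for c in range(2):
            sol, info = spla.cg(lap_g, f[keep, c], rtol=_CG_TOL, maxiter=20 * n)
            if info != 0:
                raise RuntimeError(
                    f"iterative equilibrium solve did not converge (info={info}); "
                    f"residual {np.linalg.norm(lap_g @ sol - f[keep, c]):.3e}"
                )
            u[keep, c] = sol
    u -= u.mean(axis=0)

    x_fin = network.positions + u
    problem = EquilibriumProblem(
        network=network,
        system_matrix=sp.block_diag([lap, lap], format="csc"),
        constant_vector=f.T.ravel(),
        x_init=network.positions.copy(),
        x_fin=x_fin,
    )
    res = residual_force(problem)
    tol = 1e-8 * network.coefficients.max() * network.spacing * max(1.0, math.sqrt(n))
    if res > tol:
        raise RuntimeError(
            f"equilibrium residual {res:.3e} exceeds tolerance {tol:.3e}; "
            "the network topology may be faulty"
        )
    return problem


# ---------------------------------------------------------------------------
# shape measurement


def _boundary_components(network: SpringNetwork, node_in: np.ndarray):
    """Split the mask perimeter into outer- and inner-boundary node sets.

    Returns (outer_idx, inner_idx); inner_idx is empty when the geometry
    encloses no hole.  The hole is identified as any connected component of
    the complement that does not touch the component containing the cell
    corner (the passive surround; the geometry is required to keep a margin,
    so the corner is always passive).
    """
    from scipy import ndimage

    grid = node_in.reshape(network.ny, network.nx)
    comp, n_comp = ndimage.label(~grid)
    surround = comp[0, 0]
    # neighbour labels via periodic rolls
    boundary = np.zeros_like(grid)
    hole_adjacent = np.zeros_like(grid)
    for shift, axis in [(1, 0), (-1, 0), (1, 1), (-1, 1)]:
        nb = np.roll(comp, shift, axis=axis)
        outside = np.roll(~grid, shift, axis=axis)
        boundary |= grid & outside
        hole_adjacent |= grid & outside & (nb != surround) & (nb > 0)
    outer = grid & boundary & ~hole_adjacent
    inner = grid & hole_adjacent
    return np.flatnonzero(outer.ravel()), np.flatnonzero(inner.ravel())


def _polygon_circularity(points: np.ndarray) -> float:
    """4πA/P² of the polygon through the points ordered by angle."""
    c = points.mean(axis=0)
    ang = np.arctan2(points[:, 1] - c[1], points[:, 0] - c[0])
    p = points[np.argsort(ang)]
    x, y = p[:, 0], p[:, 1]
    area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    per = np.sum(np.hypot(np.roll(x, -1) - x, np.roll(y, -1) - y))
    if per == 0:
        return float("nan")
    return float(4 * math.pi * area / per ** 2)


def _edge_concavity(problem: EquilibriumProblem, idx: np.ndarray,
                    center: np.ndarray, hx: float, hy: float) -> np.ndarray:
    """Midpoint-vs-corner inward displacement for the four straight edges.

    Order: bottom (y = -hy), right (x = +hx), top (y = +hy), left (x = -hx).
    Positive score = the edge midpoint moved inward farther than the corners,
    i.e. the edge bowed concavely.
    """
    p0 = problem.x_init[idx] - center
    disp = problem.displacements[idx]
    s = problem.network.spacing
    tol = 0.5 * s
    scores = []
    specs = [  # (on-edge predicate coords, inward normal, tangential coord)
        (np.isclose(p0[:, 1], -hy, atol=tol), np.array([0.0, 1.0]), 0),
        (np.isclose(p0[:, 0], hx, atol=tol), np.array([-1.0, 0.0]), 1),
        (np.isclose(p0[:, 1], hy, atol=tol), np.array([0.0, -1.0]), 0),
        (np.isclose(p0[:, 0], -hx, atol=tol), np.array([1.0, 0.0]), 1),
    ]
    for on_edge, normal, tang in specs:
        sel = np.flatnonzero(on_edge)
        if len(sel) < 3:
            scores.append(np.nan)
            continue
        t = p0[sel, tang]
        inward = disp[sel] @ normal
        mid = inward[np.argmin(np.abs(t))]
        corners = inward[[np.argmin(t), np.argmax(t)]].mean()
        scores.append(mid - corners)
    return np.asarray(scores)


def measure_shape(problem: EquilibriumProblem, geometry: ActivationGeometry) -> ShapeMetrics:
    """Quantify the shape change of the relaxed activated region.

    The boundary node set is the perimeter of the activation mask.  The
    radius ratio is the mean final boundary-to-centroid distance divided by
    the initial one; concavity scores are reported for geometries with
    straight outer edges and inner-boundary circularity for hollow ones
    (``None`` where a geometry has no such feature).
    """
    network = problem.network
    node_in = geometry.node_mask(network)
    if not node_in.any():
        raise ValueError("geometry selects no nodes; nothing to measure")
    outer_idx, inner_idx = _boundary_components(network, node_in)

    init_c = problem.x_init[node_in].mean(axis=0)
    fin_c = problem.x_fin[node_in].mean(axis=0)
    r0 = np.hypot(*(problem.x_init[outer_idx] - init_c).T)
    r1 = np.hypot(*(problem.x_fin[outer_idx] - fin_c).T)
    radius_ratio = float(r1.mean() / r0.mean())
    # spread of the per-node contraction ratio: measures shape preservation
    # without the lattice-discretization spread of the initial radii
    per_node = r1 / r0
    cv = float(per_node.std() / per_node.mean())

    # axis half-lengths from nodes initially on the extreme columns/rows
    d0 = problem.x_init[outer_idx] - init_c
    d1 = problem.x_fin[outer_idx] - fin_c
    s = network.spacing
    on_x = np.abs(np.abs(d0[:, 0]) - np.abs(d0[:, 0]).max()) < 0.5 * s
    on_y = np.abs(np.abs(d0[:, 1]) - np.abs(d0[:, 1]).max()) < 0.5 * s
    x_fin_half = float(np.abs(d1[on_x, 0]).mean())
    y_fin_half = float(np.abs(d1[on_y, 1]).mean())

    concavity = None
    if geometry.kind in ("square", "rectangle", "hollow_square"):
        if geometry.kind == "square":
            hx = hy = geometry.half_width
        elif geometry.kind == "rectangle":
            hx, hy = geometry.half_length, geometry.half_width
        else:
            hx = hy = geometry.outer_half_width
        concavity = _edge_concavity(problem, outer_idx, geometry._center(network), hx, hy)

    inner_c0 = inner_c1 = None
    if len(inner_idx) >= 3:
        inner_c0 = _polygon_circularity(problem.x_init[inner_idx])
        inner_c1 = _polygon_circularity(problem.x_fin[inner_idx])
    outer_c1 = _polygon_circularity(problem.x_fin[outer_idx])

    return ShapeMetrics(
        radius_ratio=radius_ratio,
        boundary_radius_cv=cv,
        axis_half_lengths=(x_fin_half, y_fin_half),
        concavity_scores=concavity,
        inner_circularity_initial=inner_c0,
        inner_circularity_final=inner_c1,
        outer_circularity_final=outer_c1,
    )
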