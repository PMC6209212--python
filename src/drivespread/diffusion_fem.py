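"""1D Galerkin finite-element diffusion with Crank-Nicolson time stepping.

Solves the constant-coefficient heat equation ``du/dt = kappa u_xx`` on
``[0, L]`` with zero-flux (Neumann) boundaries, the diffusion half of the
operator-splitting scheme.  The weak form is discretized with Lagrange
elements (linear or quadratic) giving the system ``M du/dt + kappa K u = 0``
with consistent mass matrix ``M`` and stiffness matrix ``K``; no essential
boundary constraints are imposed, so zero flux is the natural boundary
condition and the discrete total population ``1^T M u`` is conserved
exactly.

The default mesh mirrors the release geometry: three blocks ``[0, 10]``,
``[10, 20]``, ``[20, 30]`` km with 20, 40 and 20 uniformly spaced vertex
nodes respectively, the shared block boundaries counted once (78 vertex
nodes, 77 elements; quadratic interpolation adds one midside node per
element for 155 nodes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

__all__ = [
    "Mesh",
    "SpatialField",
    "build_three_block_mesh",
    "uniform_mesh",
    "assemble_mass",
    "assemble_stiffness",
    "CrankNicolsonDiffusion",
    "crank_nicolson_diffuse",
]

_ORDERS = ("linear", "quadratic")


@dataclass(frozen=True)
class Mesh:
    """Conforming 1D Lagrange mesh on ``[0, L]``.

    ``nodes`` are sorted coordinates (km) including any midside nodes;
    ``elements`` is an ``(n_elements, order+1)`` array of node indices
    ordered left (, mid), right.
    """

    nodes: np.ndarray
    elements: np.ndarray
    order: str = "linear"

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        elements = np.asarray(self.elements, dtype=np.intp)
        if self.order not in _ORDERS:
            raise ValueError(f"element order must be one of {_ORDERS}")
        if nodes.ndim != 1 or nodes.size < 2:
            raise ValueError("mesh needs at least two nodes")
        if nodes[0] != 0.0 or np.any(np.diff(nodes) <= 0):
            raise ValueError("nodes must start at 0 and be strictly increasing")
        npe = 2 if self.order == "linear" else 3
        if elements.ndim != 2 or elements.shape[1] != npe:
            raise ValueError(f"elements must have {npe} nodes each")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "elements", elements)

    @property
    def L(self) -> float:
        return float(self.nodes[-1])

    @property
    def n_nodes(self) -> int:
        return self.nodes.size

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def element_lengths(self) -> np.ndarray:
        return self.nodes[self.elements[:, -1]] - self.nodes[self.elements[:, 0]]


@dataclass
class SpatialField:
    """Per-genotype nodal densities on a mesh, shape ``(3, n_nodes)``."""

    mesh: Mesh
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (3, self.mesh.n_nodes):
            raise ValueError(
                f"values must have shape (3, {self.mesh.n_nodes}), got {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("field values must be finite")
        self.values = values

    def copy(self) -> "SpatialField":
        return SpatialField(self.mesh, self.values.copy())

    def totals(self) -> np.ndarray:
        """Trapezoidal integral of each genotype density over the domain."""
        return np.trapezoid(self.values, self.mesh.nodes, axis=1)


def _mesh_from_vertices(vertices: np.ndarray, order: str) -> Mesh:
    vertices = np.asarray(vertices, dtype=float)
    n_el = vertices.size - 1
    if order == "linear":
        idx = np.arange(n_el)
        elements = np.column_stack([idx, idx + 1])
        return Mesh(nodes=vertices, elements=elements, order="linear")
    # quadratic: interleave midside nodes
    mids = 0.5 * (vertices[:-1] + vertices[1:])
    nodes = np.empty(2 * n_el + 1)
    nodes[0::2] = vertices
    nodes[1::2] = mids
    idx = 2 * np.arange(n_el)
    elements = np.column_stack([idx, idx + 1, idx + 2])
    return Mesh(nodes=nodes, elements=elements, order="quadratic")


def build_three_block_mesh(
    order: str = "linear",
    nodes_per_block: tuple[int, int, int] = (20, 40, 20),
    block_edges: tuple[float, float, float, float] = (0.0, 10.0, 20.0, 30.0),
) -> Mesh:
    """Three-block mesh with per-block uniform vertex spacing.

    Block boundaries are shared between neighbouring blocks, so the default
    (20, 40, 20) layout has 78 distinct vertices and 77 elements.
    """
    if order not in _ORDERS:
        raise ValueError(f"element order must be one of {_ORDERS}")
    pieces = []
    for (x0, x1), n in zip(zip(block_edges[:-1], block_edges[1:]), nodes_per_block):
        if n < 2:
            raise ValueError("each block needs at least two nodes")
        block = np.linspace(x0, x1, n)
        pieces.append(block if not pieces else block[1:])
    return _mesh_from_vertices(np.concatenate(pieces), order)


def uniform_mesh(L: float, n_vertices: int, order: str = "linear") -> Mesh:
    """Single-block uniform mesh, mainly for convergence studies."""
    return _mesh_from_vertices(np.linspace(0.0, L, n_vertices), order)


# Reference element matrices on [0, h]; quadratic node order (left, mid, right).
_MASS_LIN = np.array([[2.0, 1.0], [1.0, 2.0]]) / 6.0
_STIFF_LIN = np.array([[1.0, -1.0], [-1.0, 1.0]])
_MASS_QUAD = np.array([[4.0, 2.0, -1.0], [2.0, 16.0, 2.0], [-1.0, 2.0, 4.0]]) / 30.0
_STIFF_QUAD = np.array([[7.0, -8.0, 1.0], [-8.0, 16.0, -8.0], [1.0, -8.0, 7.0]]) / 3.0


def _assemble(mesh: Mesh, local_mass: bool) -> sp.csr_matrix:
    if mesh.order == "linear":
        ref = _MASS_LIN if local_mass else _STIFF_LIN
    else:
        ref = _MASS_QUAD if local_mass else _STIFF_QUAD
    lengths = mesh.element_lengths()
    scale = lengths if local_mass else 1.0 / lengths
    npe = ref.shape[0]
    rows = np.repeat(mesh.elements, npe, axis=1).ravel()
    cols = np.tile(mesh.elements, (1, npe)).ravel()
    data = (scale[:, None, None] * ref[None, :, :]).ravel()
    n = mesh.n_nodes
    return sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()


def assemble_mass(mesh: Mesh) -> sp.csr_matrix:
    """Consistent Galerkin mass matrix ``M_kl = integral(phi_k phi_l)``."""
    return _assemble(mesh, local_mass=True)


def assemble_stiffness(mesh: Mesh) -> sp.csr_matrix:
    """Stiffness matrix ``K_kl = integral(phi_k' phi_l')``; ``K 1 = 0``."""
    return _assemble(mesh, local_mass=False)


class CrankNicolsonDiffusion:
    """Pre-factorized Crank-Nicolson stepper for fixed mesh, kappa and dt.

    Each step solves ``(M + kappa dt/2 K) u^{n+1} = (M - kappa dt/2 K) u^n``
    per genotype.  ``kappa`` may be a scalar (shared by the three genotypes)
    or a length-3 array; equal coefficients share one LU factorization.
    """

    def __init__(self, mesh: Mesh, kappa, dt: float):
        if dt <= 0:
            raise ValueError("dt must be positive")
        kappa = np.broadcast_to(np.asarray(kappa, dtype=float), (3,)).copy()
        if np.any(kappa <= 0):
            raise ValueError("diffusion coefficients must be positive")
        self.mesh = mesh
        self.kappa = kappa
        self.dt = dt
        M = assemble_mass(mesh)
        K = assemble_stiffness(mesh)
        self._groups = []
        for k in np.unique(kappa):
            idx = np.flatnonzero(kappa == k)
            A = (M + 0.5 * k * dt * K).tocsc()
            B = (M - 0.5 * k * dt * K).tocsr()
            self._groups.append((idx, splu(A), B))

    def step(self, values: np.ndarray, n_steps: int = 1) -> np.ndarray:
        """Advance nodal values (shape ``(3, n)``) by ``n_steps`` CN steps."""
        out = np.asarray(values, dtype=float).copy()
        for _ in range(n_steps):
            for idx, lu, B in self._groups:
                out[idx] = lu.solve((B @ out[idx].T)).T
        return out


def crank_nicolson_diffuse(
    field: SpatialField, kappa, dt: float, n_steps: int = 1
) -> SpatialField:
    """Diffuse a field for ``n_steps`` Crank-Nicolson steps of size ``dt``."""
    stepper = CrankNicolsonDiffusion(field.mesh, kappa, dt)
    return SpatialField(field.mesh, stepper.step(field.values, n_steps))
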