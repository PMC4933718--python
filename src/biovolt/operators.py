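"""Discrete gradient / divergence / Laplacian operators on both grids.

Scalar fields live on nodes (environment grid) or cell centres (cell
grid); vector fields live on the faces between adjacent nodes, or on the
gap-junction edges between adjacent cells.  The divergence is constructed
as the exact negative adjoint of the gradient (up to the face-area /
control-volume weighting), so the assembled Laplacian is exactly
``divergence @ gradient`` and the divergence-free projection built from it
is algebraically idempotent.

The Poisson solver caches one sparse LU factorisation per
(operator, boundary-condition) pair.  The pure-Neumann null space is pinned
by a zero-mean constraint.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import factorized

from .geometry import CellGrid, EnvGrid

__all__ = ["EnvOperators", "CellOperators"]


class _OperatorBase:
    """Shared Poisson / projection machinery over sparse G (gradient) and
    D (divergence) maps with L = D @ G."""

    G: sparse.spmatrix       # nodes -> faces
    D: sparse.spmatrix       # faces -> nodes
    L: sparse.spmatrix       # nodes -> nodes
    n_nodes: int
    n_faces: int

    def __init__(self):
        self._solvers: dict = {}

    def gradient(self, field: np.ndarray) -> np.ndarray:
        field = np.asarray(field, dtype=float)
        if field.shape != (self.n_nodes,):
            raise ValueError(
                f"field length {field.shape} does not match grid "
                f"({self.n_nodes} nodes)")
        return self.G @ field

    def divergence(self, face_field: np.ndarray) -> np.ndarray:
        face_field = np.asarray(face_field, dtype=float)
        if face_field.shape != (self.n_faces,):
            raise ValueError(
                f"vector field length {face_field.shape} does not match "
                f"grid ({self.n_faces} faces)")
        return self.D @ face_field

    def laplacian(self, field: np.ndarray) -> np.ndarray:
        return self.L @ np.asarray(field, dtype=float)

    # -- boundary handling -------------------------------------------------
    def _dirichlet_nodes(self) -> np.ndarray:
        raise NotImplementedError

    def _solver(self, bc: str):
        if bc not in self._solvers:
            if bc == "dirichlet0":
                A = self.L.tolil()
                for i in self._dirichlet_nodes():
                    A.rows[i] = [i]
                    A.data[i] = [1.0]
                self._solvers[bc] = factorized(A.tocsc())
            elif bc == "neumann":
                # bordered system pinning the mean of the solution
                n = self.n_nodes
                one = np.ones((n, 1)) / n
                A = sparse.bmat([[self.L, one], [one.T, None]], format="csc")
                self._solvers[bc] = factorized(A)
            else:
                raise ValueError(f"unknown boundary condition {bc!r}")
        return self._solvers[bc]

    def solve_poisson(self, rhs: np.ndarray, bc: str = "dirichlet0") -> np.ndarray:
        """Solve ``laplacian(phi) = rhs`` under the given boundary condition.

        For ``bc="neumann"`` the right-hand side must be compatible
        (integrate to ~0); the returned solution has zero mean.
        """
        rhs = np.asarray(rhs, dtype=float)
        if not np.all(np.isfinite(rhs)):
            raise ValueError("rhs must be finite")
        if bc == "neumann":
            scale = np.abs(rhs).max()
            if scale > 0 and abs(self._neumann_defect(rhs)) > 1e-9 * scale:
                raise ValueError(
                    "incompatible pure-Neumann rhs (nonzero mean)")
            return self._solve_neumann_raw(rhs)
        b = rhs.copy()
        b[self._dirichlet_nodes()] = 0.0
        return self._solver(bc)(b)

    def _neumann_defect(self, rhs: np.ndarray) -> float:
        """Component of rhs outside the range of the Neumann Laplacian."""
        return float(rhs.mean())

    def _solve_neumann_raw(self, rhs: np.ndarray) -> np.ndarray:
        sol = self._solver("neumann")(np.concatenate([rhs, [0.0]]))
        return sol[:-1]

    def project_divergence_free(self, face_field: np.ndarray,
                                source: np.ndarray | None = None,
                                bc: str | None = None) -> np.ndarray:
        """Helmholtz-type correction ``F - grad(phi)``.

        phi solves ``L phi = div(F) + source``; with ``source=None`` the
        output is divergence-free to solver tolerance, otherwise its
        divergence equals ``-source`` (the continuity-equation correction
        used for currents, where source is the charge-density rate).
        """
        face_field = np.asarray(face_field, dtype=float)
        rhs = self.divergence(face_field)
        if source is not None:
            rhs = rhs + np.asarray(source, dtype=float)
        if bc is None:
            bc = self.default_bc
        if bc == "neumann":
            rhs = rhs - rhs.mean()  # discard the incompatible component
        phi = self.solve_poisson(rhs, bc=bc)
        return face_field - self.gradient(phi)


class EnvOperators(_OperatorBase):
    """Finite-difference operators on the regular environment grid.

    Faces are ordered x-faces first (between horizontally adjacent nodes,
    row-major) then y-faces.  The Laplacian reduces to the standard 5-point
    stencil on the interior with natural (zero-normal-flux) boundaries;
    Dirichlet rows replace the rim for the default boundary condition.
    """

    default_bc = "dirichlet0"

    def __init__(self, grid: EnvGrid):
        super().__init__()
        self.grid = grid
        nx, ny, dx = grid.nx, grid.ny, grid.spacing
        idx = np.arange(nx * ny).reshape(ny, nx)
        ax = idx[:, :-1].ravel()
        bx = idx[:, 1:].ravel()
        ay = idx[:-1, :].ravel()
        by = idx[1:, :].ravel()
        tails = np.concatenate([ax, ay])
        heads = np.concatenate([bx, by])
        self.n_faces = len(tails)
        self.n_nodes = nx * ny
        self.face_tails, self.face_heads = tails, heads
        self.n_x_faces = len(ax)
        self.edge_lengths = np.full(self.n_faces, dx)
        rows = np.repeat(np.arange(self.n_faces), 2)
        cols = np.column_stack([tails, heads]).ravel()
        vals = np.tile([-1.0 / dx, 1.0 / dx], self.n_faces)
        self.G = sparse.csr_matrix((vals, (rows, cols)),
                                   shape=(self.n_faces, self.n_nodes))
        self.D = (-self.G.T).tocsr()
        self.L = (self.D @ self.G).tocsr()

    def _dirichlet_nodes(self) -> np.ndarray:
        return self.grid.boundary_nodes

    def face_vectors(self, face_field: np.ndarray) -> np.ndarray:
        """Average the face components back to (n_nodes, 2) node vectors."""
        out = np.zeros((self.n_nodes, 2))
        cnt = np.zeros((self.n_nodes, 2))
        fx = face_field[:self.n_x_faces]
        fy = face_field[self.n_x_faces:]
        for comp, vals, tails, heads in (
                (0, fx, self.face_tails[:self.n_x_faces],
                 self.face_heads[:self.n_x_faces]),
                (1, fy, self.face_tails[self.n_x_faces:],
                 self.face_heads[self.n_x_faces:])):
            np.add.at(out[:, comp], tails, vals)
            np.add.at(out[:, comp], heads, vals)
            np.add.at(cnt[:, comp], tails, 1.0)
            np.add.at(cnt[:, comp], heads, 1.0)
        cnt[cnt == 0] = 1.0
        return out / cnt


class CellOperators(_OperatorBase):
    """Finite-volume operators on the irregular cell network.

    Edges are the gap-junction pairs; the gradient is the centre-to-centre
    difference quotient and the divergence is the membrane-area-weighted
    flux sum divided by cell volume.  The network has no exterior boundary,
    so the natural boundary condition is pure Neumann.
    """

    default_bc = "neumann"

    def __init__(self, grid: CellGrid):
        super().__init__()
        self.grid = grid
        self.n_nodes = grid.n_cells
        self.n_faces = grid.n_gj
        pairs = grid.gj_cell_pairs
        dist = grid.gj_lengths
        self.edge_lengths = dist
        self.face_tails = pairs[:, 0] if self.n_faces else np.array([], int)
        self.face_heads = pairs[:, 1] if self.n_faces else np.array([], int)
        self.edge_areas = grid.membrane_areas[grid.gj_pairs[:, 0]]
        if self.n_faces:
            rows = np.repeat(np.arange(self.n_faces), 2)
            cols = pairs.ravel()
            vals = np.column_stack([-1.0 / dist, 1.0 / dist]).ravel()
            self.G = sparse.csr_matrix((vals, (rows, cols)),
                                       shape=(self.n_faces, self.n_nodes))
            AoverV = sparse.diags(self.edge_areas)
            Vinv = sparse.diags(1.0 / grid.cell_volumes)
            # flux (per unit area) on edge e leaves pairs[e,0], enters [e,1]
            inc = sparse.csr_matrix(
                (np.column_stack([np.ones(self.n_faces),
                                  -np.ones(self.n_faces)]).ravel(),
                 (rows, cols)),
                shape=(self.n_faces, self.n_nodes))
            self.D = (Vinv @ inc.T @ AoverV).tocsr()
        else:
            self.G = sparse.csr_matrix((0, self.n_nodes))
            self.D = sparse.csr_matrix((self.n_nodes, 0))
        self.L = (self.D @ self.G).tocsr()

    def _dirichlet_nodes(self) -> np.ndarray:
        return np.array([], dtype=int)

    def solve_poisson(self, rhs, bc: str = "neumann"):
        if bc == "dirichlet0":
            raise ValueError("cell network has no Dirichlet boundary")
        return super().solve_poisson(np.asarray(rhs, dtype=float),
                                     bc="neumann")

    def _neumann_defect(self, rhs: np.ndarray) -> float:
        # D carries a 1/volume scaling, so the conserved quantity (and the
        # left null space of L) is volume-weighted
        vol = self.grid.cell_volumes
        return float(np.sum(rhs * vol) / vol.sum())

    def project_divergence_free(self, face_field, source=None, bc=None):
        face_field = np.asarray(face_field, dtype=float)
        rhs = self.divergence(face_field)
        if source is not None:
            rhs = rhs + np.asarray(source, dtype=float)
        rhs = rhs - self._neumann_defect(rhs)  # keep the compatible part
        phi = self._solve_neumann_raw(rhs)
        return face_field - self.gradient(phi)
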