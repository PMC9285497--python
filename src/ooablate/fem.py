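"""Shared axisymmetric P1 finite-element machinery.

Linear triangles on the (r, z) half-plane with 2*pi*r volume weighting
(element integrals use the centroid radius).  The heavy lifting per time
step is a re-assembly of stiffness values on a fixed sparsity pattern, so
this module precomputes, per mesh (and optional element subset):

* element areas, centroid radii, axisymmetric volumes and shape-function
  gradients;
* a canonical CSR pattern together with the scatter map from the 9 entries
  of every element matrix into it (assembly is then a single ``bincount``);
* a Dirichlet reduction: entry classification into free-free (kept) and
  free-Dirichlet (moved to the right-hand side) blocks, again as index
  maps, so each solve touches only numpy kernels plus one sparse LU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .meshing import Mesh

__all__ = ["ElementData", "DirichletSystem"]

TWO_PI = 2.0 * np.pi


class ElementData:
    """Geometric element quantities for (a subset of) a mesh."""

    def __init__(self, mesh: Mesh, element_mask: np.ndarray | None = None):
        self.mesh = mesh
        tris = mesh.triangles if element_mask is None else mesh.triangles[element_mask]
        self.element_mask = element_mask
        self.tris = tris
        p = mesh.nodes[tris]  # (M, 3, 2)
        x, y = p[..., 0], p[..., 1]
        det = (x[:, 1] - x[:, 0]) * (y[:, 2] - y[:, 0]) - (x[:, 2] - x[:, 0]) * (
            y[:, 1] - y[:, 0]
        )
        self.area = 0.5 * det
        if not (self.area > 0).all():
            raise ValueError("element with non-positive area")
        # gradients of the barycentric shape functions
        b = np.empty_like(p)
        b[:, 0, 0] = y[:, 1] - y[:, 2]
        b[:, 1, 0] = y[:, 2] - y[:, 0]
        b[:, 2, 0] = y[:, 0] - y[:, 1]
        b[:, 0, 1] = x[:, 2] - x[:, 1]
        b[:, 1, 1] = x[:, 0] - x[:, 2]
        b[:, 2, 1] = x[:, 1] - x[:, 0]
        self.grad = b / det[:, None, None]  # (M, 3, 2)
        self.r_c = x.mean(axis=1)
        self.volume = TWO_PI * self.r_c * self.area  # m^3 per element
        # geometric stiffness: vol * grad_i . grad_j
        gg = np.einsum("mik,mjk->mij", self.grad, self.grad)
        self.geom_stiff = self.volume[:, None, None] * gg  # (M, 3, 3)

        # canonical CSR pattern + scatter map
        n = mesh.n_nodes
        rows = tris[:, [0, 0, 0, 1, 1, 1, 2, 2, 2]].ravel()
        cols = tris[:, [0, 1, 2, 0, 1, 2, 0, 1, 2]].ravel()
        key = rows.astype(np.int64) * n + cols
        uniq, inv = np.unique(key, return_inverse=True)
        self.n_nodes = n
        self.scatter = inv
        self.nnz = len(uniq)
        self.csr_rows = (uniq // n).astype(np.int32)
        self.csr_cols = (uniq % n).astype(np.int32)
        self.indptr = np.searchsorted(self.csr_rows, np.arange(n + 1)).astype(np.int32)
        # lumped in-plane volume per node (for mass/source terms)
        self.lumped = np.bincount(
            tris.ravel(), weights=np.repeat(self.volume / 3.0, 3), minlength=n
        )
        self.touched = self.lumped > 0

    def assemble_values(self, coef: np.ndarray) -> np.ndarray:
        """CSR data array of the stiffness with per-element coefficient."""
        vals = (coef[:, None, None] * self.geom_stiff).ravel()
        return np.bincount(self.scatter, weights=vals, minlength=self.nnz)

    def csr(self, data: np.ndarray) -> sp.csr_matrix:
        return sp.csr_matrix(
            (data, self.csr_cols, self.indptr), shape=(self.n_nodes, self.n_nodes)
        )

    def lump_source(self, per_element: np.ndarray) -> np.ndarray:
        """Nodal load vector of a piecewise-constant volumetric source."""
        w = np.repeat(per_element * self.volume / 3.0, 3)
        return np.bincount(self.tris.ravel(), weights=w, minlength=self.n_nodes)

    def element_mean(self, nodal: np.ndarray) -> np.ndarray:
        return nodal[self.tris].mean(axis=1)

    def integrate(self, per_element: np.ndarray) -> float:
        """Volume integral of a piecewise-constant field (axisymmetric)."""
        return float(np.dot(per_element, self.volume))


class DirichletSystem:
    """Reduced linear system for a fixed Dirichlet node set.

    Precomputes which CSR entries land in the free-free block and which
    free-row/Dirichlet-column entries fold into the right-hand side.
    """

    def __init__(self, elem: ElementData, dirichlet_mask: np.ndarray):
        self.elem = elem
        n = elem.n_nodes
        self.dirichlet_mask = dirichlet_mask.astype(bool)
        self.free_mask = ~self.dirichlet_mask & elem.touched
        self.free_idx = np.flatnonzero(self.free_mask)
        self.dir_idx = np.flatnonzero(self.dirichlet_mask)
        if len(self.free_idx) == 0:
            raise ValueError("no free unknowns")
        renum = np.full(n, -1, dtype=np.int64)
        renum[self.free_idx] = np.arange(len(self.free_idx))

        r, c = elem.csr_rows, elem.csr_cols
        rf = self.free_mask[r]
        cf = self.free_mask[c]
        self.ff = np.flatnonzero(rf & cf)
        self.fd = np.flatnonzero(rf & self.dirichlet_mask[c])
        self.ff_rows = renum[r[self.ff]].astype(np.int32)
        self.ff_cols = renum[c[self.ff]].astype(np.int32)
        self.fd_rows = renum[r[self.fd]]
        self.fd_cols = c[self.fd]
        nf = len(self.free_idx)
        order = np.lexsort((self.ff_cols, self.ff_rows))
        self.ff = self.ff[order]
        self.ff_rows = self.ff_rows[order]
        self.ff_cols = self.ff_cols[order]
        self.red_indptr = np.searchsorted(self.ff_rows, np.arange(nf + 1)).astype(
            np.int32
        )
        self.nf = nf
        # diagonal entry position (in CSR entry space) per node, for mass terms
        diag = np.flatnonzero(r == c)
        self.diag_entry = np.full(n, -1, dtype=np.int64)
        self.diag_entry[r[diag]] = diag

    def solve(
        self,
        data: np.ndarray,
        rhs: np.ndarray,
        dirichlet_values: np.ndarray,
    ) -> np.ndarray:
        """Solve K x = rhs with x fixed on the Dirichlet set.

        ``data`` is the full-pattern CSR data array from
        :meth:`ElementData.assemble_values` (plus any diagonal additions);
        ``dirichlet_values`` is a full-length nodal array whose values are
        read on the Dirichlet set.
        """
        kff = sp.csr_matrix(
            (data[self.ff], self.ff_cols, self.red_indptr), shape=(self.nf, self.nf)
        )
        b = rhs[self.free_idx] - np.bincount(
            self.fd_rows,
            weights=data[self.fd] * dirichlet_values[self.fd_cols],
            minlength=self.nf,
        )
        xf = spla.spsolve(kff.tocsc(), b)
        if not np.all(np.isfinite(xf)):
            raise FloatingPointError("linear solve produced non-finite values")
        x = np.array(dirichlet_values, dtype=float, copy=True)
        x[~self.dirichlet_mask] = 0.0
        x[self.free_idx] = xf
        return x

    def add_diagonal(self, data: np.ndarray, diag: np.ndarray) -> np.ndarray:
        """Add nodal values onto the matrix diagonal (in entry space)."""
        pos = self.diag_entry
        ok = pos >= 0
        out = data.copy()
        out[pos[ok]] += diag[ok]
        return out

    def reactions(self, data: np.ndarray, x: np.ndarray, rhs: np.ndarray) -> np.ndarray:
        """Residual (K x - rhs) on the Dirichlet rows: the discrete boundary
        flux entering through the Dirichlet set."""
        K = self.elem.csr(data)
        res = K @ x - rhs
        out = np.zeros_like(x)
        out[self.dir_idx] = res[self.dir_idx]
        return out
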