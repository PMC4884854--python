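"""Total-Lagrangian finite-element machinery on a boundary-fitted quad grid.

Internal engine behind :mod:`nlswei.compress`.  Bilinear isoparametric
quadrilateral plane-strain elements on a structured grid; along the curved
top outline the top row of nodes is snapped onto the true surface so the
platen contacts a smooth boundary instead of a staircase (sharp staircase
corners produce spurious tensile contact reactions).  Selective reduced
integration (deviatoric stress at the 2x2 Gauss points, volumetric pressure
at the centroid) avoids volumetric locking at Poisson's ratio 0.495.  The
Newton tangent is assembled by central finite differencing of the element
internal-force vectors, vectorized over all elements at once, and each
Newton step is safeguarded by a backtracking line search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .materials import MaterialParams, _stress_from_F_arrays, invariants_from_F
from .phantom import PhantomModel, BACKGROUND, VOID

__all__ = ["FEMesh", "build_mesh", "NewtonOptions", "newton_solve"]

# 2x2 Gauss points on [-1,1]^2
_GP = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float) / np.sqrt(3.0)


def _dshape(xi: float, eta: float) -> np.ndarray:
    """Derivatives of the 4 bilinear shape functions wrt (xi, eta): (4, 2)."""
    return 0.25 * np.array([
        [-(1 - eta), -(1 - xi)],
        [+(1 - eta), -(1 + xi)],
        [+(1 + eta), +(1 + xi)],
        [-(1 + eta), +(1 - xi)],
    ])


@dataclass
class FEMesh:
    nodes: np.ndarray        # (n_nodes, 2) reference coordinates, mm
    elems: np.ndarray        # (n_elems, 4) node ids, counterclockwise
    elem_label: np.ndarray   # (n_elems,) tissue label per element
    spacing: float
    base_nodes: np.ndarray   # node ids on y = 0
    surface_nodes: np.ndarray  # topmost node id per mesh column (boundary)
    materials: dict          # label -> MaterialParams
    # per-element isoparametric tables, filled in __post_init__
    G_gp: np.ndarray = field(default=None, repr=False)    # (4, E, 4, 2)
    w_gp: np.ndarray = field(default=None, repr=False)    # (4, E)
    G_cen: np.ndarray = field(default=None, repr=False)   # (E, 4, 2)
    w_cen: np.ndarray = field(default=None, repr=False)   # (E,)

    def __post_init__(self) -> None:
        Xe = self.nodes[self.elems]                       # (E, 4, 2)
        E = len(self.elems)
        self.G_gp = np.empty((4, E, 4, 2))
        self.w_gp = np.empty((4, E))
        for g, (xi, eta) in enumerate(_GP):
            G, w = self._grads_at(Xe, xi, eta)
            self.G_gp[g], self.w_gp[g] = G, w
        self.G_cen, self.w_cen = self._grads_at(Xe, 0.0, 0.0)
        self.w_cen = self.w_cen * 4.0                      # 1-point rule weight
        if np.any(self.w_gp <= 0):
            raise ValueError("mesh contains inverted or degenerate elements")

    @staticmethod
    def _grads_at(Xe: np.ndarray, xi: float, eta: float):
        dN = _dshape(xi, eta)                              # (4, 2)
        J = np.einsum("eak,aj->ekj", Xe, dN)               # dx_k/dxi_j
        detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        Jinv = np.empty_like(J)
        Jinv[:, 0, 0] = J[:, 1, 1] / detJ
        Jinv[:, 0, 1] = -J[:, 0, 1] / detJ
        Jinv[:, 1, 0] = -J[:, 1, 0] / detJ
        Jinv[:, 1, 1] = J[:, 0, 0] / detJ
        G = np.einsum("aj,eji->eai", dN, Jinv)             # dN_a/dx_i
        return G, detJ

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def elem_centers(self) -> np.ndarray:
        return self.nodes[self.elems].mean(axis=1)

    @property
    def elem_areas(self) -> np.ndarray:
        return self.w_gp.sum(axis=0)


def build_mesh(phantom: PhantomModel, spacing: float) -> FEMesh:
    """Structured quad mesh of the phantom, boundary-fitted at the top.

    For the semi-elliptical outline each cell column carries
    ``round(H/spacing)`` cells (H the local surface height) and the top
    node of each column is moved onto the outline (clamped to +-0.45
    spacing so elements stay well-shaped); rectangles mesh exactly.
    """
    labels, xc, yc = phantom.rasterize(spacing)
    nx, ny = labels.shape
    h = spacing
    if phantom.shape == "rectangle":
        active = labels != VOID
    else:
        H = phantom.surface_height(xc)
        n_col = np.clip(np.round(np.nan_to_num(H) / h).astype(int), 1, ny)
        active = np.arange(ny)[None, :] < n_col[:, None]
        labels = np.where(active & (labels == VOID), BACKGROUND, labels)
        labels = np.where(~active, VOID, labels)
    if not active.any():
        raise ValueError("phantom rasterizes to an empty mesh at this spacing")

    node_id = -np.ones((nx + 1, ny + 1), dtype=int)
    touch = np.zeros((nx + 1, ny + 1), dtype=bool)
    for di in (0, 1):
        for dj in (0, 1):
            touch[di:nx + di, dj:ny + dj] |= active
    ids = np.flatnonzero(touch.ravel())
    node_id.ravel()[ids] = np.arange(len(ids))
    ii, jj = np.unravel_index(ids, touch.shape)
    x0 = -phantom.width / 2.0
    nodes = np.column_stack([x0 + ii * h, jj * h])

    if phantom.shape != "rectangle":
        # snap each column's top node onto the outline
        top_adj = np.full(nx + 1, -1, dtype=int)
        top_adj[:-1] = np.maximum(top_adj[:-1], n_col)
        top_adj[1:] = np.maximum(top_adj[1:], n_col)
        is_top = jj == top_adj[ii]
        Hn = phantom.surface_height(nodes[:, 0])
        Hn = np.nan_to_num(Hn, nan=0.0)
        y_grid = nodes[:, 1]
        snapped = np.clip(Hn, y_grid - 0.45 * h, y_grid + 0.45 * h)
        nodes[:, 1] = np.where(is_top, snapped, y_grid)

    ei, ej = np.nonzero(active)
    elems = np.column_stack([
        node_id[ei, ej], node_id[ei + 1, ej],
        node_id[ei + 1, ej + 1], node_id[ei, ej + 1]])
    elem_label = labels[ei, ej]

    base = np.flatnonzero(np.abs(nodes[:, 1]) < 1e-9 * max(1.0, h))
    surface = []
    for i in np.unique(ii):
        col = node_id[i]
        col = col[col >= 0]
        surface.append(col[np.argmax(nodes[col, 1])])
    return FEMesh(nodes=nodes, elems=elems, elem_label=elem_label,
                  spacing=h, base_nodes=base,
                  surface_nodes=np.array(surface),
                  materials=dict(phantom.materials))


# -- element forces ------------------------------------------------------

def _piola_inplane(params: MaterialParams, F: np.ndarray, volumetric: bool):
    """In-plane first Piola-Kirchhoff stress for a batch of 2x2 F (E,2,2)."""
    f11, f12 = F[:, 0, 0], F[:, 0, 1]
    f21, f22 = F[:, 1, 0], F[:, 1, 1]
    j = f11 * f22 - f12 * f21
    if volumetric == "only":
        ev = j - 1.0
        p = 2.0 * ev / params.d1 + 4.0 * ev ** 3 / params.d2
        s11 = s22 = p
        s12 = np.zeros_like(p)
    else:
        s11, s12, s22, _ = _stress_from_F_arrays(
            params, f11, f12, f21, f22, isochoric=True, volumetric=volumetric)
    # P = J sigma F^{-T}; J F^{-T} = [[f22, -f21], [-f12, f11]]
    P = np.empty_like(F)
    P[:, 0, 0] = s11 * f22 - s12 * f12
    P[:, 0, 1] = -s11 * f21 + s12 * f11
    P[:, 1, 0] = s12 * f22 - s22 * f12
    P[:, 1, 1] = -s12 * f21 + s22 * f11
    return P


def element_forces(mesh: FEMesh, ue: np.ndarray) -> np.ndarray:
    """Internal nodal forces per element, (E, 4, 2), from element displacements.

    Deviatoric contribution integrated at the 2x2 Gauss points, volumetric
    (pressure) contribution at the centroid (selective reduced integration).
    """
    E = len(mesh.elems)
    f = np.zeros((E, 4, 2))
    eye = np.eye(2)
    for label, params in mesh.materials.items():
        m = mesh.elem_label == label
        if not m.any():
            continue
        u = ue[m]
        fm = np.zeros((m.sum(), 4, 2))
        for g in range(4):
            G = mesh.G_gp[g][m]
            F = eye + np.einsum("eai,eaj->eij", u, G)
            P = _piola_inplane(params, F, volumetric=False)
            fm += mesh.w_gp[g][m][:, None, None] * np.einsum("eij,eaj->eai", P, G)
        Gc = mesh.G_cen[m]
        Fc = eye + np.einsum("eai,eaj->eij", u, Gc)
        Pc = _piola_inplane(params, Fc, volumetric="only")
        fm += mesh.w_cen[m][:, None, None] * np.einsum("eij,eaj->eai", Pc, Gc)
        f[m] = fm
    return f


def stored_energy(mesh: FEMesh, u: np.ndarray) -> float:
    """Total strain energy (kPa * mm^2 per unit thickness)."""
    ue = u[mesh.elems]
    eye = np.eye(2)
    total = 0.0
    for label, params in mesh.materials.items():
        m = mesh.elem_label == label
        if not m.any():
            continue
        uel = ue[m]
        for g in range(4):
            G = mesh.G_gp[g][m]
            F = eye + np.einsum("eai,eaj->eij", uel, G)
            i1, i2, _ = invariants_from_F(F[:, 0, 0], F[:, 0, 1],
                                          F[:, 1, 0], F[:, 1, 1])
            e1, e2 = i1 - 3.0, i2 - 3.0
            u_iso = (params.c10 * e1 + params.c01 * e2 + params.c11 * e1 * e2
                     + params.c20 * e1 ** 2 + params.c02 * e2 ** 2)
            total += (mesh.w_gp[g][m] * u_iso).sum()
        Gc = mesh.G_cen[m]
        Fc = eye + np.einsum("eai,eaj->eij", uel, Gc)
        jc = Fc[:, 0, 0] * Fc[:, 1, 1] - Fc[:, 0, 1] * Fc[:, 1, 0]
        ev = jc - 1.0
        total += (mesh.w_cen[m] * (ev ** 2 / params.d1 + ev ** 4 / params.d2)).sum()
    return float(total)


def internal_force(mesh: FEMesh, u: np.ndarray) -> np.ndarray:
    """Assembled internal force vector, (n_nodes, 2)."""
    fe = element_forces(mesh, u[mesh.elems])
    f = np.zeros((mesh.n_nodes, 2))
    np.add.at(f, mesh.elems.ravel(), fe.reshape(-1, 2))
    return f


def tangent_matrix(mesh: FEMesh, u: np.ndarray, h_fd: float = 1.0e-7) -> sp.csr_matrix:
    """Global tangent stiffness by element-level central differencing.

    ``h_fd`` is the displacement perturbation in mm; with kPa/mm units the
    truncation and round-off errors balance near 1e-7 for these meshes.
    """
    ue = u[mesh.elems]
    E = len(mesh.elems)
    Ke = np.zeros((E, 4, 2, 4, 2))
    for b in range(4):
        for jcomp in range(2):
            up = ue.copy()
            um = ue.copy()
            up[:, b, jcomp] += h_fd
            um[:, b, jcomp] -= h_fd
            Ke[:, :, :, b, jcomp] = (element_forces(mesh, up)
                                     - element_forces(mesh, um)) / (2.0 * h_fd)
    dof = (2 * mesh.elems[:, :, None] + np.arange(2)[None, None, :])  # (E,4,2)
    rows = np.broadcast_to(dof[:, :, :, None, None], Ke.shape).ravel()
    cols = np.broadcast_to(dof[:, None, None, :, :], Ke.shape).ravel()
    n = 2 * mesh.n_nodes
    return sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()


@dataclass
class NewtonOptions:
    tol_rel: float = 1.0e-6
    tol_abs: float = 1.0e-9
    max_iter: int = 60


def newton_solve(mesh: FEMesh, u0: np.ndarray, prescribed: dict[int, float],
                 options: NewtonOptions | None = None):
    """Solve static equilibrium with prescribed displacement DOFs.

    ``prescribed`` maps flat DOF index (2*node + comp) to its value.  Returns
    (u, residual_norm, n_iter); raises RuntimeError on non-convergence.
    """
    opt = options or NewtonOptions()
    n = 2 * mesh.n_nodes
    u = u0.copy()
    uflat = u.ravel()
    pres_idx = np.fromiter(prescribed.keys(), dtype=int) if prescribed else np.empty(0, int)
    pres_val = np.fromiter(prescribed.values(), dtype=float) if prescribed else np.empty(0)
    free = np.ones(n, dtype=bool)
    free[pres_idx] = False
    uflat[pres_idx] = pres_val

    def residual_norm(uvec):
        f = internal_force(mesh, uvec.reshape(-1, 2)).ravel()
        r = np.abs(f[free]).max() if free.any() else 0.0
        scale = np.abs(f[~free]).max() if (~free).any() else np.abs(f).max()
        return f, r, max(scale, 1.0e-12)

    try:
        f, res_norm, scale = residual_norm(uflat)
    except ValueError as err:
        raise RuntimeError(f"degenerate initial state in Newton solve: {err}")
    for it in range(opt.max_iter):
        if res_norm < opt.tol_rel * scale + opt.tol_abs:
            return u, res_norm, it
        K = tangent_matrix(mesh, u)
        Kff = K[free][:, free]
        du = spla.spsolve(Kff.tocsc(), -f[free])
        if not np.all(np.isfinite(du)):
            raise RuntimeError("singular tangent in Newton solve")
        # backtracking line search: the volumetric penalty is strongly
        # nonlinear and full steps can overshoot into J <= 0
        alpha = 1.0
        base = uflat[free].copy()
        for _ in range(12):
            uflat[free] = base + alpha * du
            try:
                f, r, scale = residual_norm(uflat)
            except ValueError:  # degenerate trial state
                alpha *= 0.5
                continue
            if r <= (1.0 - 0.25 * alpha) * res_norm or alpha < 1e-3:
                res_norm = r
                break
            alpha *= 0.5
        else:
            uflat[free] = base
            raise RuntimeError("line search failed in Newton solve")
    raise RuntimeError(
        f"Newton failed to converge: residual {res_norm:.3e} after "
        f"{opt.max_iter} iterations; add load substeps")
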