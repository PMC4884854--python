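"""Quasi-static platen compression of the hyperelastic phantom.

A rigid flat platen (the transducer footprint, with a small edge fillet)
descends onto the curved top surface while the base is fixed; contact is
frictionless, enforced by a stiff vertical penalty on penetrating surface
nodes so engagement and separation are smooth.  The compression level is
platen travel divided by the initial model height at the platen center.

Each converged state carries per-element strain, Cauchy stress and the
tangent shear modulus field that the wave stage propagates on.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import fem
from .materials import MaterialParams, _stress_from_F_arrays, _tangent_from_F_arrays
from .phantom import PhantomModel, TUMOR, VOID

__all__ = ["DeformedState", "solve_compression", "staged_compression",
           "roi_statistics", "rasterize_deformed"]


@dataclass
class DeformedState:
    """Converged static state of the phantom at one compression level."""

    compression_level: float
    mesh: fem.FEMesh
    nodal_displacements: np.ndarray     # (n_nodes, 2), mm
    element_F: np.ndarray               # (E, 2, 2) centroid deformation gradient
    element_strain: np.ndarray          # (E, 2, 2) nominal strain F - I
    element_stress: np.ndarray          # (E, 3) Cauchy (s_xx, s_yy, s_xy), kPa
    tangent_modulus_field: np.ndarray   # (E,), kPa
    converged: bool
    residual: float
    stored_energy: float
    platen_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    @property
    def element_centers(self) -> np.ndarray:
        return self.mesh.elem_centers

    def deformed_nodes(self) -> np.ndarray:
        return self.mesh.nodes + self.nodal_displacements

    def platen_reaction(self) -> float:
        """Total vertical force exerted by the platen (kPa*mm, per thickness)."""
        f = fem.internal_force(self.mesh, self.nodal_displacements)
        return float(f[self.platen_nodes, 1].sum()) if len(self.platen_nodes) else 0.0

    def base_reaction(self) -> float:
        f = fem.internal_force(self.mesh, self.nodal_displacements)
        return float(f[self.mesh.base_nodes, 1].sum())


def _element_fields(mesh: fem.FEMesh, u: np.ndarray, tangent_mode: str = "stress"):
    """Centroid F, nominal strain, Cauchy stress and tangent modulus per element."""
    ue = u[mesh.elems]
    F = np.eye(2) + np.einsum("eai,eaj->eij", ue, mesh.G_cen)
    strain = F - np.eye(2)
    stress = np.zeros((len(F), 3))
    mu_t = np.zeros(len(F))
    for label, params in mesh.materials.items():
        m = mesh.elem_label == label
        if not m.any():
            continue
        f11, f12 = F[m, 0, 0], F[m, 0, 1]
        f21, f22 = F[m, 1, 0], F[m, 1, 1]
        s11, s12, s22, _ = _stress_from_F_arrays(params, f11, f12, f21, f22)
        stress[m, 0], stress[m, 1], stress[m, 2] = s11, s22, s12
        mu_t[m] = _tangent_from_F_arrays(params, f11, f12, f21, f22,
                                         mode=tangent_mode)
    return F, strain, stress, mu_t


def _identity_state(mesh: fem.FEMesh) -> DeformedState:
    E = len(mesh.elems)
    mu0 = np.zeros(E)
    for label, params in mesh.materials.items():
        mu0[mesh.elem_label == label] = params.mu0
    eyeF = np.broadcast_to(np.eye(2), (E, 2, 2)).copy()
    return DeformedState(
        compression_level=0.0, mesh=mesh,
        nodal_displacements=np.zeros((mesh.n_nodes, 2)),
        element_F=eyeF, element_strain=np.zeros((E, 2, 2)),
        element_stress=np.zeros((E, 3)), tangent_modulus_field=mu0,
        converged=True, residual=0.0, stored_energy=0.0)


def _platen_height(phantom: PhantomModel, plane_y: float, x):
    """Platen surface height above lateral position ``x`` (deformed frame).

    Flat at ``plane_y`` over the interior of the footprint, with a
    parabolic fillet of radius ``platen_edge_radius`` at the edges: a real
    transducer edge is not perfectly sharp, and the fillet regularizes the
    extrusion-lip singularity a sharp rigid corner would create.
    """
    half = phantom.platen_half_width()
    r = min(phantom.platen_edge_radius, half)
    dx = np.abs(x) - (half - r)
    return plane_y + np.where(dx > 0, dx * dx / (2.0 * r), 0.0)


def _platen_slope(phantom: PhantomModel, x):
    """d(height)/dx of the platen surface (fillet region only)."""
    half = phantom.platen_half_width()
    r = min(phantom.platen_edge_radius, half)
    dx = np.abs(x) - (half - r)
    return np.where(dx > 0, np.sign(x) * dx / r, 0.0)


def _base_prescription(mesh: fem.FEMesh, phantom: PhantomModel) -> dict[int, float]:
    """Prescribed DOF map for the fixed/roller base."""
    pres: dict[int, float] = {}
    for nid in mesh.base_nodes:
        if phantom.base_bc == "fixed":
            pres[2 * nid] = 0.0
        pres[2 * nid + 1] = 0.0
    if phantom.base_bc != "fixed":
        # roller base + frictionless platen leave a rigid x-translation
        # mode; pin it at the base node nearest the centerline
        mid = mesh.base_nodes[np.argmin(np.abs(mesh.nodes[mesh.base_nodes, 0]))]
        pres[2 * int(mid)] = 0.0
    return pres


def solve_compression(phantom: PhantomModel, level: float, *,
                      mesh: fem.FEMesh | None = None,
                      spacing: float = 1.0,
                      substep: float = 0.01,
                      warm_start: DeformedState | None = None,
                      tangent_mode: str = "stress",
                      contact_penalty: float = 500.0) -> DeformedState:
    """Solve static equilibrium at one compression level.

    ``level`` is platen travel over initial height at the platen center, in
    [0, 0.35].  The load is applied in increments of ``substep`` (fraction
    of height), Newton-iterating each increment; ``warm_start`` continues
    from a previously converged state at a lower level.  Platen contact is
    enforced by a stiff vertical penalty (``contact_penalty``, kPa of
    contact pressure per mm of penetration) against the filleted platen
    surface — frictionless, since the springs carry no tangential force.
    """
    if not (0.0 <= level <= 0.35):
        raise ValueError("compression level must lie in [0, 0.35]")
    if not phantom.materials:
        raise ValueError("phantom has no materials assigned")
    if mesh is None:
        mesh = warm_start.mesh if warm_start is not None else fem.build_mesh(phantom, spacing)

    height = float(phantom.surface_height(np.array([0.0]))[0])
    start_level = 0.0
    u = np.zeros((mesh.n_nodes, 2))
    active: set[int] = set()
    if warm_start is not None:
        if warm_start.mesh is not mesh:
            raise ValueError("warm-start state uses a different mesh")
        start_level = warm_start.compression_level
        u = warm_start.nodal_displacements.copy()
        if level < start_level - 1e-12:
            raise ValueError("cannot unload below the warm-start level")
    if level <= 1e-12 and start_level <= 1e-12:
        return _identity_state(mesh)

    half = phantom.platen_half_width()
    residual = 0.0
    pres = _base_prescription(mesh, phantom)
    pres_idx = np.fromiter(pres.keys(), dtype=int)
    pres_val = np.fromiter(pres.values(), dtype=float)
    free = np.ones(2 * mesh.n_nodes, dtype=bool)
    free[pres_idx] = False
    surf = mesh.surface_nodes.astype(int)
    surf_xy = mesh.nodes[surf]
    k_node = contact_penalty * mesh.spacing   # kPa*mm force per mm penetration

    eps_c = 0.05 * mesh.spacing  # C1 regularization depth of the contact law

    def contact(u_loc, plane_y):
        """Penalty contact on surface nodes against the filleted platen.

        The force law is C1-smoothed near zero penetration (quadratic up to
        ``eps_c``, linear beyond) to avoid Newton chatter at the contact
        kink, and the edge fillet continues as a parabola beyond the
        footprint so the force field stays smooth in x; the steep rise
        leaves material beyond the edge effectively free to bulge.
        Returns (node ids, force/k, stiffness-factor, slope).
        """
        xd = surf_xy[:, 0] + u_loc[surf, 0]
        yd = surf_xy[:, 1] + u_loc[surf, 1]
        hx = _platen_height(phantom, plane_y, xd)
        pen = yd - hx
        m = pen > 0
        p = pen[m]
        q = np.where(p < eps_c, p * p / (2.0 * eps_c), p - eps_c / 2.0)
        dq = np.where(p < eps_c, p / eps_c, 1.0)
        return surf[m], q, dq, _platen_slope(phantom, xd[m])

    def solve_at(lv, u_in):
        """Newton solve of one load increment with penalty platen contact."""
        plane_y = height * (1.0 - lv)
        u_loc = u_in.copy()
        uflat = u_loc.ravel()
        uflat[pres_idx] = pres_val

        def resid(u_now):
            try:
                f = fem.internal_force(mesh, u_now).ravel()
            except ValueError as err:  # inverted element: shrink the step
                raise RuntimeError(f"degenerate trial state: {err}") from err
            nid, q, _, _ = contact(u_now, plane_y)
            f[2 * nid + 1] += k_node * q
            scale = max(np.abs(f[~free]).max() if (~free).any() else 0.0,
                        (k_node * q).max() if len(q) else 0.0, 1e-12)
            return f, np.abs(f[free]).max(), scale

        f, res, scale = resid(u_loc)
        stalls = 0
        noprog = 0
        lm = 0.0   # Levenberg-Marquardt damping, activated on stagnation
        hist = []
        for _ in range(90):
            if res < 1e-6 * scale + 1e-9 or (stalls >= 4 and res < 2e-3 * scale):
                # a line search stalled below 2e-3 relative residual is
                # converged for field purposes (the force-balance accuracy
                # of the discretization): a single platen-edge node
                # flickering across the contact threshold can pin the last
                # decades of the residual without moving any field value
                nid, _, _, _ = contact(u_loc, plane_y)
                return u_loc, nid, res
            K = fem.tangent_matrix(mesh, u_loc)
            nid, q, dq, slope = contact(u_loc, plane_y)
            if len(nid):
                # only the symmetric (vertical) part of the contact
                # stiffness enters the tangent; the unsymmetric fillet
                # slope coupling destabilizes the iteration at the edge
                dy = 2 * nid + 1
                K = K + sp.coo_matrix((k_node * dq, (dy, dy)), shape=K.shape)
            Kff = K[free][:, free].tocsc()
            if lm > 0.0:
                # damped (trust-region-like) step: lets the iteration walk
                # through local snap-throughs at the platen edge where the
                # undamped Newton direction stops descending
                d_med = np.median(Kff.diagonal())
                Kff = Kff + lm * d_med * sp.identity(Kff.shape[0], format="csc")
            du = spla.spsolve(Kff, -f[free])
            if not np.all(np.isfinite(du)):
                raise RuntimeError("singular tangent in contact solve")
            alpha, base = 1.0, uflat[free].copy()
            for _ in range(14):
                uflat[free] = base + alpha * du
                try:
                    f, r, scale = resid(u_loc)
                except RuntimeError:
                    alpha *= 0.5
                    continue
                if lm > 0.0 and r > 10.0 * max(res, 0.1 * scale):
                    alpha *= 0.5   # keep the damped walk bounded
                    continue
                # once damping is active the iteration runs as a relaxed
                # pseudo-transient walk: accept any non-degenerate step and
                # let the damped dynamics carry it through the snap
                if (r <= (1.0 - 0.25 * alpha) * res or alpha < 1e-3
                        or lm > 0.0):
                    stalls = stalls + 1 if alpha < 0.05 else 0
                    noprog = noprog + 1 if r >= 0.98 * res else 0
                    if alpha >= 0.25:
                        lm = 0.0 if lm < 1e-4 else lm / 4.0
                    res = r
                    break
                alpha *= 0.5
            else:
                uflat[free] = base
                raise RuntimeError("line search failed in contact solve")
            wd = int(np.flatnonzero(free)[np.argmax(np.abs(f[free]))])
            hist.append(f"res={res:.3e} rel={res / scale:.1e} alpha={alpha:.3g} "
                        f"lm={lm:.1e} "
                        f"node={wd // 2}@{np.round(mesh.nodes[wd // 2], 1)}")
            if noprog >= 2:
                lm = max(4.0 * lm, 1e-2)   # stagnating: damp the next step
                noprog = 0
            if lm > 1e3:
                break  # damping exhausted
        if res < 2e-3 * scale:
            nid, _, _, _ = contact(u_loc, plane_y)
            return u_loc, nid, res
        raise RuntimeError(
            f"contact Newton failed to converge: residual {res:.3e}; "
            "history: " + " | ".join(hist[-8:]))

    # adaptive incremental loading: halve the increment (down to substep/64)
    # when Newton stalls
    lv_now = start_level
    step = substep
    min_step = substep / 64.0
    while lv_now < level - 1e-12:
        lv_try = min(level, lv_now + step)
        u_pred = u.copy()
        u_pred[:, 1] -= (lv_try - lv_now) * mesh.nodes[:, 1]  # affine predictor
        try:
            t_inc = __import__("time").time()
            u_new, active_new, residual = solve_at(lv_try, u_pred)
            if os.environ.get("NLSWEI_DEBUG"):
                print(f"  [compress] level {lv_try:.5f} step {step:.5f} "
                      f"res {residual:.1e} {__import__('time').time()-t_inc:.1f}s",
                      flush=True)
        except RuntimeError as err:
            if os.environ.get("NLSWEI_DEBUG"):
                print(f"  [compress] FAIL {lv_try:.5f} step {step:.5f}: {err}",
                      flush=True)
            if step <= min_step + 1e-15:
                raise
            step = max(min_step, step / 2.0)
            continue
        u, active = u_new, set(int(n) for n in active_new)
        lv_now = lv_try
        if step < substep:
            step = min(substep, step * 2.0)

    F, strain, stress, mu_t = _element_fields(mesh, u, tangent_mode)
    return DeformedState(
        compression_level=level, mesh=mesh, nodal_displacements=u,
        element_F=F, element_strain=strain, element_stress=stress,
        tangent_modulus_field=mu_t, converged=True, residual=residual,
        stored_energy=fem.stored_energy(mesh, u),
        platen_nodes=np.array(sorted(active), dtype=int))


def staged_compression(phantom: PhantomModel, levels, *,
                       spacing: float = 1.0, substep: float = 0.01,
                       tangent_mode: str = "stress") -> list[DeformedState]:
    """Solve a sequence of ascending compression levels incrementally.

    Each level warm-starts from the previous one; for an elastic material
    the path does not change the answer, but the warm start keeps Newton
    step counts small.
    """
    levels = list(levels)
    if any(b < a for a, b in zip(levels, levels[1:])):
        raise ValueError("levels must be ascending")
    mesh = fem.build_mesh(phantom, spacing)
    out: list[DeformedState] = []
    prev: DeformedState | None = None
    for lv in levels:
        try:
            st = solve_compression(phantom, lv, mesh=mesh, substep=substep,
                                   warm_start=prev, tangent_mode=tangent_mode)
        except RuntimeError as err:
            raise RuntimeError(f"compression stage failed at level {lv}: {err}") from err
        out.append(st)
        prev = st if lv > 0 else None
    return out


def _roi_masks(state: DeformedState, phantom: PhantomModel,
               surr_offset: tuple[float, float] = (10.0, 0.0)):
    """Reference-frame element masks for the tumor disc and a same-size
    surrounding-tissue disc (tumor center translated by ``surr_offset``)."""
    c = state.element_centers
    cx, cy = phantom.tumor_center
    r = 0.5 * phantom.tumor_diameter
    if r <= 0:
        raise ValueError("phantom has no tumor: ROI undefined")
    tum = (c[:, 0] - cx) ** 2 + (c[:, 1] - cy) ** 2 <= r * r
    sx, sy = cx + surr_offset[0], cy + surr_offset[1]
    sur = (c[:, 0] - sx) ** 2 + (c[:, 1] - sy) ** 2 <= r * r
    sur &= state.mesh.elem_label != TUMOR
    if not tum.any() or not sur.any():
        raise ValueError("empty ROI at this mesh spacing")
    return tum, sur


def roi_statistics(state: DeformedState, phantom: PhantomModel,
                   surr_offset: tuple[float, float] = (10.0, 0.0)) -> dict:
    """Per-ROI mean/sd of vertical strain, vertical stress and tangent modulus.

    Strain is the magnitude of the vertical nominal strain |F_yy - 1| in
    percent; stress the magnitude of the vertical Cauchy component |s_yy|
    in kPa.  ROIs are Lagrangian (material) discs, so they track the
    deformed tumor automatically.
    """
    tum, sur = _roi_masks(state, phantom, surr_offset)
    eyy = np.abs(state.element_strain[:, 1, 1]) * 100.0
    syy = np.abs(state.element_stress[:, 1])
    mu = state.tangent_modulus_field
    out = {}
    for name, m in (("tumor", tum), ("surrounding", sur)):
        out[name] = {
            "strain_mean": float(eyy[m].mean()), "strain_sd": float(eyy[m].std()),
            "stress_mean": float(syy[m].mean()), "stress_sd": float(syy[m].std()),
            "modulus_mean": float(mu[m].mean()), "modulus_sd": float(mu[m].std()),
            "n_elements": int(m.sum()),
        }
    return out


def rasterize_deformed(state: DeformedState | None, phantom: PhantomModel,
                       spacing: float = 0.2) -> dict:
    """Map the deformed phantom onto a regular Eulerian grid.

    Samples the reference configuration at ``spacing``, pushes the samples
    through the FE displacement field, and grids tangent modulus and tissue
    label onto cell centers of a regular grid over the deformed bounding
    box (nearest-sample gridding; cells with no nearby sample are void).
    Returns dict with 'mu' (kPa), 'label', 'mask', 'x', 'y'.
    """
    labels, xs, ys = phantom.rasterize(spacing)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    mat = labels != VOID

    if state is None or state.compression_level <= 1e-12:
        mu = np.zeros(labels.shape)
        for label, params in phantom.materials.items():
            mu[labels == label] = params.mu0
        mu[~mat] = 0.0
        return {"mu": mu, "label": labels.copy(), "mask": mat, "x": xs, "y": ys}

    from scipy.interpolate import RegularGridInterpolator
    from scipy.spatial import cKDTree

    mesh = state.mesh
    h = mesh.spacing
    x0 = -phantom.width / 2.0
    ni = int(round(phantom.width / h)) + 1
    nj = int(round(phantom.height / h)) + 1
    ugrid = np.full((ni, nj, 2), np.nan)
    ii = np.rint((mesh.nodes[:, 0] - x0) / h).astype(int)
    jj = np.rint(mesh.nodes[:, 1] / h).astype(int)
    ugrid[ii, jj] = state.nodal_displacements
    # fill inactive grid nodes from the nearest active node so boundary
    # samples interpolate cleanly
    bad = np.isnan(ugrid[:, :, 0])
    if bad.any():
        gi, gj = np.nonzero(~bad)
        bi, bj = np.nonzero(bad)
        tree = cKDTree(np.column_stack([gi, gj]))
        _, nn = tree.query(np.column_stack([bi, bj]))
        ugrid[bi, bj] = ugrid[gi[nn], gj[nn]]
    interp = RegularGridInterpolator(
        (x0 + np.arange(ni) * h, np.arange(nj) * h), ugrid,
        bounds_error=False, fill_value=None)

    pts = np.column_stack([X[mat], Y[mat]])
    disp = interp(pts)
    moved = pts + disp
    # per-sample tangent modulus: piecewise-constant on the mechanics mesh
    ei = np.clip(((pts[:, 0] - x0) // h).astype(int), 0, int(round(phantom.width / h)) - 1)
    ej = np.clip((pts[:, 1] // h).astype(int), 0, int(round(phantom.height / h)) - 1)
    elem_of = -np.ones((int(round(phantom.width / h)), int(round(phantom.height / h))), int)
    ec = mesh.elem_centers
    cei = ((ec[:, 0] - x0) // h).astype(int)
    cej = (ec[:, 1] // h).astype(int)
    elem_of[cei, cej] = np.arange(len(ec))
    eid = elem_of[ei, ej]
    ok = eid >= 0
    if not ok.all():  # samples in cells void on the coarse mesh: nearest element
        tree = cKDTree(ec)
        _, nn = tree.query(pts[~ok])
        eid[~ok] = nn
    mu_s = state.tangent_modulus_field[eid]
    lab_s = labels[mat]

    tree = cKDTree(moved)
    d, nn = tree.query(np.column_stack([X.ravel(), Y.ravel()]),
                       distance_upper_bound=1.5 * spacing)
    hit = np.isfinite(d)
    mu = np.zeros(X.size)
    lab = np.full(X.size, VOID)
    mu[hit] = mu_s[nn[hit]]
    lab[hit] = lab_s[nn[hit]]
    return {"mu": mu.reshape(X.shape), "label": lab.reshape(X.shape),
            "mask": hit.reshape(X.shape), "x": xs, "y": ys}
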