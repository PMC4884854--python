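"""Shear-wave propagation through the (pre-compressed) phantom.

An impulsive body-force push — 3 mm wide, 180 us long, directed downward
through the entire depth of the model — launches planar shear waves that
propagate laterally.  Propagation is linear incremental motion superposed
on the static pre-strain: the local wave-carrying stiffness is the tangent
shear modulus field of the compressed state.  The default engine solves the
scalar vertical-displacement wave equation

    rho * u_tt = div( mu_t grad u ) + f

on the 0.2 mm Eulerian grid of the deformed configuration (an SH-like
model, adequate because the push is vertical and only Y displacement is
analyzed); a small P-SV velocity-stress engine is available behind
``engine="psv"`` for validation.  No attenuation term is included.  The
fixed base reflects, as do the free curved boundaries — the reconstruction
stage removes reflected energy with a directional filter.

Units: mm, ms, kPa, kg/m^3; shear speed in mm/ms (= m/s) is
``sqrt(1000 * mu / rho)``.  Records are sampled at 125 us and 0.2 x 0.2 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .compress import DeformedState, rasterize_deformed
from .phantom import PhantomModel

__all__ = ["ExcitationSpec", "WaveRecord", "simulate_wave", "extract_profiles"]


@dataclass(frozen=True)
class ExcitationSpec:
    """Body-force push emulating an acoustic-radiation-force excitation."""

    center_x: float = 0.0      # mm; model midline by default
    width: float = 3.0         # mm
    duration: float = 0.180    # ms
    amplitude: float = 0.1     # mm/ms^2 (force density / rho); ~10 um peaks
    direction: float = -1.0    # downward

    def __post_init__(self) -> None:
        if self.width <= 0 or self.duration <= 0:
            raise ValueError("excitation width and duration must be positive")


@dataclass
class WaveRecord:
    """Y-displacement space-time record with grid metadata.

    ``displacement_y`` is indexed [time, x, y] in micrometers; ``x``/``y``
    are cell-center coordinates (mm) in the deformed frame; ``dt`` is the
    output sampling interval in ms.  ``label``/``mask`` carry the deformed
    tissue map for downstream ROI work.
    """

    displacement_y: np.ndarray
    dt: float
    x: np.ndarray
    y: np.ndarray
    compression_level: float = 0.0
    label: np.ndarray | None = None
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0]) if len(self.x) > 1 else 0.0

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.displacement_y.shape[0]) * self.dt

    def save(self, path) -> None:
        np.savez_compressed(
            path, displacement_y=self.displacement_y.astype(np.float32),
            dt=self.dt, x=self.x, y=self.y,
            compression_level=self.compression_level,
            label=self.label if self.label is not None else np.empty(0),
            mask=self.mask if self.mask is not None else np.empty(0))

    @classmethod
    def load(cls, path) -> "WaveRecord":
        z = np.load(path)
        lab = z["label"] if z["label"].size else None
        msk = z["mask"] if z["mask"].size else None
        return cls(displacement_y=z["displacement_y"], dt=float(z["dt"]),
                   x=z["x"], y=z["y"],
                   compression_level=float(z["compression_level"]),
                   label=lab, mask=msk)


def _sh_step_fields(mu, mask, rho):
    """Face shear moduli (kPa) for the flux-form SH stencil; void faces 0."""
    mu = np.where(mask, mu, 0.0)
    mux = np.zeros((mu.shape[0] + 1, mu.shape[1]))
    muy = np.zeros((mu.shape[0], mu.shape[1] + 1))
    mux[1:-1, :] = 0.5 * (mu[1:, :] + mu[:-1, :])
    muy[:, 1:-1] = 0.5 * (mu[:, 1:] + mu[:, :-1])
    # fixed base: Dirichlet u = 0 via antisymmetric ghost => face stiffness
    # doubled at the bottom boundary
    muy[:, 0] = 2.0 * mu[:, 0]
    return mux, muy


def simulate_wave(state: DeformedState | None, phantom: PhantomModel,
                  excitation: ExcitationSpec | None = None,
                  record_duration: float = 40.0, *,
                  dt_out: float = 0.125, spacing: float = 0.2,
                  cfl: float = 0.45, engine: str = "sh",
                  density: float | None = None) -> WaveRecord:
    """Propagate shear waves and record Y displacement at 125 us / 0.2 mm.

    ``state`` may be None for the uncompressed phantom (identity fast
    path).  The internal time step subdivides ``dt_out`` to satisfy the CFL
    bound for the stiffest cell; the output record is the sub-sampled field.
    """
    if state is not None and not state.converged:
        raise ValueError("wave stage requires a converged compression state")
    exc = excitation or ExcitationSpec()
    if density is None:
        density = next(iter(phantom.materials.values())).density

    if state is None or state.compression_level <= 1e-12:
        grids = rasterize_deformed(None, phantom, spacing)
        level = 0.0
    else:
        grids = rasterize_deformed(state, phantom, spacing)
        level = state.compression_level
    mu, mask = grids["mu"], grids["mask"]
    xs, ys = grids["x"], grids["y"]
    nx, ny = mu.shape

    if not ((xs[0] < exc.center_x - exc.width / 2) and
            (exc.center_x + exc.width / 2 < xs[-1])):
        raise ValueError("excitation band lies outside the domain")

    c2 = 1000.0 * mu / density            # (mm/ms)^2
    c_max = float(np.sqrt(c2.max()))
    if c_max <= 0:
        raise ValueError("phantom has no positive-stiffness cells")
    dt_cfl = cfl * spacing / (c_max * np.sqrt(2.0))
    n_sub = max(1, int(np.ceil(dt_out / dt_cfl)))
    dt = dt_out / n_sub
    n_out = int(round(record_duration / dt_out)) + 1

    push = (np.abs(xs[:, None] - exc.center_x) <= exc.width / 2.0 + 1e-9) & mask
    accel_push = exc.direction * exc.amplitude  # mm/ms^2

    if engine == "psv":
        uy = _run_psv(mu, mask, density, spacing, dt, n_sub, n_out,
                      push, accel_push, exc.duration)
    elif engine == "sh":
        uy = _run_sh(mu, mask, density, spacing, dt, n_sub, n_out,
                     push, accel_push, exc.duration)
    else:
        raise ValueError(f"unknown wave engine {engine!r}")

    return WaveRecord(displacement_y=uy * 1000.0,  # mm -> um
                      dt=dt_out, x=xs, y=ys, compression_level=level,
                      label=grids["label"], mask=mask,
                      meta={"engine": engine, "dt_internal": dt,
                            "excitation": asdict(exc), "density": density})


def _run_sh(mu, mask, rho, h, dt, n_sub, n_out, push, accel, t_push):
    mux, muy = _sh_step_fields(mu, mask, rho)
    kx = 1000.0 * mux / (rho * h * h) * dt * dt
    ky = 1000.0 * muy / (rho * h * h) * dt * dt
    u = np.zeros(mu.shape)
    u_prev = np.zeros_like(u)
    out = np.zeros((n_out,) + mu.shape, dtype=np.float32)
    t = 0.0
    for n in range(1, n_out):
        for _ in range(n_sub):
            # flux-form stencil; boundary faces carry zero stiffness except
            # the bottom row, where the doubled face stiffness in ky plus a
            # zero ghost value realizes the fixed-base Dirichlet condition
            flux_x = (kx[1:, :] * np.diff(u, axis=0, append=0.0)
                      - kx[:-1, :] * np.diff(u, axis=0, prepend=0.0))
            flux_y = (ky[:, 1:] * np.diff(u, axis=1, append=0.0)
                      - ky[:, :-1] * np.diff(u, axis=1, prepend=0.0))
            u_new = 2.0 * u - u_prev + flux_x + flux_y
            if t < t_push:
                u_new[push] += accel * dt * dt
            u_new[~mask] = 0.0
            u_prev, u = u, u_new
            t += dt
        out[n] = u
    return out.astype(np.float64)


def _run_psv(mu, mask, rho, h, dt, n_sub, n_out, push, accel, t_push):
    """Minimal velocity-stress P-SV engine (staggered grid) for validation.

    First Lame parameter from the Poisson's-ratio-0.495 near-incompressible
    limit: lambda = 2 mu nu / (1 - 2 nu) = 99 mu.  The P-wave CFL is much
    stricter, so the caller's dt is subdivided further here.
    """
    lam = 99.0 * mu
    mu = np.where(mask, mu, 0.0)
    lam = np.where(mask, lam, 0.0)
    cp_max = np.sqrt(1000.0 * (lam + 2 * mu).max() / rho)
    n_extra = max(1, int(np.ceil(dt * cp_max * np.sqrt(2.0) / (0.45 * h))))
    dtl = dt / n_extra
    nx, ny = mu.shape
    vx = np.zeros((nx + 1, ny))
    vy = np.zeros((nx, ny + 1))
    sxx = np.zeros((nx, ny))
    syy = np.zeros((nx, ny))
    sxy = np.zeros((nx + 1, ny + 1))
    uy = np.zeros((nx, ny))
    out = np.zeros((n_out, nx, ny), dtype=np.float32)
    # shear modulus at sxy nodes (corner average)
    mu_n = np.zeros((nx + 1, ny + 1))
    mu_n[1:-1, 1:-1] = 0.25 * (mu[1:, 1:] + mu[:-1, 1:] + mu[1:, :-1] + mu[:-1, :-1])
    t = 0.0
    for n in range(1, n_out):
        for _ in range(n_sub * n_extra):
            dvxdx = np.diff(vx, axis=0) / h
            dvydy = np.diff(vy, axis=1) / h
            sxx += dtl * ((lam + 2 * mu) * dvxdx + lam * dvydy) / 1.0
            syy += dtl * (lam * dvxdx + (lam + 2 * mu) * dvydy)
            dvxdy = np.zeros((nx + 1, ny + 1))
            dvxdy[:, 1:-1] = np.diff(vx, axis=1) / h
            dvydx = np.zeros((nx + 1, ny + 1))
            dvydx[1:-1, :] = np.diff(vy, axis=0) / h
            sxy += dtl * mu_n * (dvxdy + dvydx)
            # velocity updates (kPa -> consistent with mm/ms via factor 1000/rho)
            fac = 1000.0 * dtl / (rho * h)
            vx[1:-1, :] += fac * (np.diff(sxx, axis=0) + np.diff(sxy[1:-1, :], axis=1))
            vy[:, 1:-1] += fac * (np.diff(syy, axis=1) + np.diff(sxy[:, 1:-1], axis=0))
            vy[:, 0] = 0.0  # fixed base
            if t < t_push:
                vyc = vy[:, :-1]
                vyc[push] += accel * dtl
            uy += 0.5 * (vy[:, :-1] + vy[:, 1:]) * dtl
            uy[~mask] = 0.0
            t += dtl
        out[n] = uy
    return out.astype(np.float64)


def extract_profiles(record: WaveRecord, x_positions, y: float) -> dict:
    """Displacement-vs-time traces at given lateral positions and one depth.

    Picks the nearest grid column/row; returns dict with 'time' (ms) and
    one trace (um) per requested position.
    """
    out = {"time": record.times}
    iy = int(np.argmin(np.abs(record.y - y)))
    for xp in x_positions:
        if not (record.x[0] - record.dx / 2 <= xp <= record.x[-1] + record.dx / 2):
            raise ValueError(f"position {xp} mm outside the record extent")
        ix = int(np.argmin(np.abs(record.x - xp)))
        out[xp] = record.displacement_y[:, ix, iy]
    return out
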