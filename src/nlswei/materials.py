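"""Polynomial hyperelastic constitutive model for soft tissue.

Implements the second-order polynomial (generalized Mooney--Rivlin)
strain-energy function

    U = sum_{i+j=1..2} C_ij (I1-3)^i (I2-3)^j + sum_{i=1..2} (1/D_i)(Jel-1)^(2i)

together with its Cauchy stress response and the incremental (tangent)
shear modulus at a finite pre-strain.  The tangent modulus is what carries
small-amplitude shear waves in a pre-compressed medium, and its growth with
compression (strain hardening) is the mechanism that amplifies the
tumor/background modulus contrast under external compression.

Kinematics are plane strain (out-of-plane stretch fixed at 1).  Internal
units: stresses in kPa, lengths in mm, density in kg/m^3; with these, shear
wave speed is ``sqrt(1000*mu/rho)`` in m/s.

By default the deviatoric part of the energy is evaluated on the isochoric
invariants (I1_bar = J^(-2/3) I1, I2_bar = J^(-4/3) I2), the convention of
the "polynomial" model in mainstream FE packages; at Poisson's ratio 0.495
the medium is nearly incompressible and the distinction is numerically
minor.  Raw invariants are available via ``isochoric=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Literal

import numpy as np
import yaml

__all__ = [
    "MaterialParams",
    "StrainState",
    "strain_energy",
    "cauchy_stress",
    "tangent_shear_modulus",
    "uniaxial_response",
    "load_tissue_library",
    "tissue",
]


@dataclass(frozen=True)
class MaterialParams:
    """Hyperelastic parameters for one tissue (stress coefficients in kPa).

    ``c10 .. c02`` are the polynomial coefficients, ``d1``/``d2`` the
    compressibility coefficients (1/kPa).  ``mu0 = 2*(c10+c01)`` is the
    initial (zero-strain) shear modulus; ``k0 = 2/d1`` the initial bulk
    modulus.
    """

    c10: float
    c01: float
    c11: float
    c20: float
    c02: float
    d1: float
    d2: float
    poisson_ratio: float = 0.495
    density: float = 1000.0  # kg/m^3
    label: str = ""

    def __post_init__(self) -> None:
        vals = [self.c10, self.c01, self.c11, self.c20, self.c02,
                self.d1, self.d2, self.poisson_ratio, self.density]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("non-finite material parameter")
        if self.c10 + self.c01 <= 0:
            raise ValueError("c10 + c01 must be positive (mu0 = 2(c10+c01) > 0)")
        if not (0.0 < self.poisson_ratio < 0.5):
            raise ValueError("poisson_ratio must lie in (0, 0.5)")
        if self.d1 <= 0:
            raise ValueError("d1 must be positive for poisson_ratio < 0.5")
        if self.density <= 0:
            raise ValueError("density must be positive")

    @property
    def mu0(self) -> float:
        """Initial shear modulus 2(C10+C01), kPa."""
        return 2.0 * (self.c10 + self.c01)

    @property
    def bulk_modulus0(self) -> float:
        """Initial bulk modulus 2/D1, kPa."""
        return 2.0 / self.d1

    @classmethod
    def from_coefficients(
        cls,
        c10: float,
        c01: float,
        c11: float,
        c20: float,
        c02: float,
        poisson_ratio: float = 0.495,
        density: float = 1000.0,
        label: str = "",
        unit_scale_kpa: float = 1.0,
    ) -> "MaterialParams":
        """Build params from raw coefficients, deriving D1 from Poisson's ratio.

        ``unit_scale_kpa`` converts the coefficient unit to kPa (use 1000.0
        for coefficients quoted in MPa).  D1 comes from the initial-bulk-
        modulus relation K0 = 2 mu0 (1+nu) / (3 (1-2 nu)), K0 = 2/D1; D2 is
        set equal to D1 so the quartic volumetric term stays negligible.
        """
        s = unit_scale_kpa
        mu0 = 2.0 * (c10 + c01) * s
        k0 = 2.0 * mu0 * (1.0 + poisson_ratio) / (3.0 * (1.0 - 2.0 * poisson_ratio))
        d1 = 2.0 / k0
        return cls(c10 * s, c01 * s, c11 * s, c20 * s, c02 * s,
                   d1=d1, d2=d1, poisson_ratio=poisson_ratio,
                   density=density, label=label)

    def scaled(self, k: float) -> "MaterialParams":
        """All stress coefficients multiplied by ``k`` (moduli scale by k)."""
        return replace(self, c10=self.c10 * k, c01=self.c01 * k,
                       c11=self.c11 * k, c20=self.c20 * k, c02=self.c02 * k,
                       d1=self.d1 / k, d2=self.d2 / k)


@dataclass(frozen=True)
class StrainState:
    """Finite-strain state at one material point (plane strain).

    Carries the in-plane deformation gradient together with the invariants
    actually fed to the energy: ``i1``/``i2`` (isochoric by default) and the
    elastic volume ratio ``jel``.
    """

    deformation_gradient: np.ndarray  # 2x2
    i1: float
    i2: float
    jel: float
    isochoric: bool = True

    def __post_init__(self) -> None:
        F = np.asarray(self.deformation_gradient, dtype=float)
        if F.shape != (2, 2) or not np.all(np.isfinite(F)):
            raise ValueError("deformation_gradient must be a finite 2x2 array")
        if not (np.isfinite(self.i1) and np.isfinite(self.i2) and np.isfinite(self.jel)):
            raise ValueError("non-finite strain invariants")
        if self.jel <= 0:
            raise ValueError("jel must be positive (degenerate deformation)")
        object.__setattr__(self, "deformation_gradient", F)

    @classmethod
    def from_deformation_gradient(cls, F: np.ndarray, isochoric: bool = True) -> "StrainState":
        F = np.asarray(F, dtype=float)
        i1, i2, j = invariants_from_F(F[..., 0, 0], F[..., 0, 1],
                                      F[..., 1, 0], F[..., 1, 1],
                                      isochoric=isochoric)
        if F.ndim != 2:
            raise ValueError("use the array helpers for batched states")
        return cls(F, float(i1), float(i2), float(j), isochoric=isochoric)

    @classmethod
    def identity(cls) -> "StrainState":
        return cls(np.eye(2), 3.0, 3.0, 1.0)


def invariants_from_F(f11, f12, f21, f22, isochoric: bool = True):
    """Invariants of the 3D left Cauchy-Green tensor for plane-strain F.

    Works elementwise on arrays.  Returns (i1, i2, J) with the out-of-plane
    stretch fixed at 1; isochoric=True returns I1_bar, I2_bar.
    """
    j = f11 * f22 - f12 * f21
    b11 = f11 * f11 + f12 * f12
    b22 = f21 * f21 + f22 * f22
    b12 = f11 * f21 + f12 * f22
    tr2 = b11 + b22          # in-plane trace of B
    det2 = j * j             # in-plane det of B
    i1 = tr2 + 1.0
    # I2 = 0.5 (I1^2 - tr(B^2)); with b33 = 1: I2 = det2 + tr2
    i2 = det2 + tr2
    if isochoric:
        i1 = i1 * j ** (-2.0 / 3.0)
        i2 = i2 * j ** (-4.0 / 3.0)
    return i1, i2, j


def _check_state(state: StrainState) -> None:
    if state.jel <= 0:
        raise ValueError("degenerate deformation: jel <= 0")


def strain_energy(params: MaterialParams, state: StrainState) -> float:
    """Strain-energy density U (kPa) at the given state; zero at identity."""
    _check_state(state)
    e1 = state.i1 - 3.0
    e2 = state.i2 - 3.0
    ev = state.jel - 1.0
    u = (params.c10 * e1 + params.c01 * e2
         + params.c11 * e1 * e2 + params.c20 * e1 * e1 + params.c02 * e2 * e2
         + ev * ev / params.d1 + ev ** 4 / params.d2)
    if not np.isfinite(u):
        raise ValueError("non-finite strain energy")
    return float(u)


def _stress_from_F_arrays(params: MaterialParams, f11, f12, f21, f22,
                          isochoric: bool = True, volumetric: bool = True):
    """Cauchy stress components for (arrays of) plane-strain F.

    Returns (s11, s12, s22, s33) in kPa.  Vectorized; this is the workhorse
    behind both the scalar API and the per-element FE fields.  With
    ``volumetric=False`` the pressure from the (Jel-1) terms is omitted
    (used by the selective-reduced-integration FE assembly).
    """
    j = f11 * f22 - f12 * f21
    if np.any(j <= 0):
        raise ValueError("degenerate deformation: det F <= 0")
    b11 = f11 * f11 + f12 * f12
    b22 = f21 * f21 + f22 * f22
    b12 = f11 * f21 + f12 * f22
    b33 = np.ones_like(j)
    ev = j - 1.0
    if volumetric:
        p_vol = 2.0 * ev / params.d1 + 4.0 * ev ** 3 / params.d2  # dU_vol/dJ
    else:
        p_vol = np.zeros_like(j)

    if isochoric:
        s = j ** (-2.0 / 3.0)
        bb11, bb22, bb33, bb12 = s * b11, s * b22, s * b33, s * b12
        i1b = bb11 + bb22 + bb33
        i2b = 0.5 * (i1b * i1b - (bb11**2 + bb22**2 + bb33**2 + 2.0 * bb12**2))
        e1, e2 = i1b - 3.0, i2b - 3.0
        w1 = params.c10 + params.c11 * e2 + 2.0 * params.c20 * e1
        w2 = params.c01 + params.c11 * e1 + 2.0 * params.c02 * e2
        # dev part: sigma_iso = (2/J) dev[ (W1 + I1b W2) Bbar - W2 Bbar^2 ]
        a = w1 + i1b * w2
        t11 = a * bb11 - w2 * (bb11**2 + bb12**2)
        t22 = a * bb22 - w2 * (bb22**2 + bb12**2)
        t33 = a * bb33 - w2 * bb33**2
        t12 = a * bb12 - w2 * bb12 * (bb11 + bb22)
        trt = (t11 + t22 + t33) / 3.0
        s11 = 2.0 / j * (t11 - trt) + p_vol
        s22 = 2.0 / j * (t22 - trt) + p_vol
        s33 = 2.0 / j * (t33 - trt) + p_vol
        s12 = 2.0 / j * t12
    else:
        i1 = b11 + b22 + b33
        i2 = 0.5 * (i1 * i1 - (b11**2 + b22**2 + b33**2 + 2.0 * b12**2))
        e1, e2 = i1 - 3.0, i2 - 3.0
        w1 = params.c10 + params.c11 * e2 + 2.0 * params.c20 * e1
        w2 = params.c01 + params.c11 * e1 + 2.0 * params.c02 * e2
        a = w1 + i1 * w2
        s11 = 2.0 / j * (a * b11 - w2 * (b11**2 + b12**2)) + p_vol
        s22 = 2.0 / j * (a * b22 - w2 * (b22**2 + b12**2)) + p_vol
        s33 = 2.0 / j * (a * b33 - w2 * b33**2) + p_vol
        s12 = 2.0 / j * (a * b12 - w2 * b12 * (b11 + b22))
    return s11, s12, s22, s33


def cauchy_stress(params: MaterialParams, state: StrainState) -> np.ndarray:
    """Cauchy stress (kPa) as a symmetric 3x3 array (plane strain).

    The in-plane block is ``sigma[:2, :2]``; ``sigma[2, 2]`` is the
    out-of-plane normal stress needed to maintain plane strain.  Derived
    analytically from the strain-energy function; consistency with the
    numerical gradient of :func:`strain_energy` is a tested invariant.
    """
    _check_state(state)
    F = state.deformation_gradient
    s11, s12, s22, s33 = _stress_from_F_arrays(
        params, F[0, 0], F[0, 1], F[1, 0], F[1, 1], isochoric=state.isochoric)
    return np.array([[s11, s12, 0.0], [s12, s22, 0.0], [0.0, 0.0, s33]], dtype=float)


def _tangent_from_F_arrays(params: MaterialParams, f11, f12, f21, f22,
                           dgamma: float = 1.0e-6, mode: str = "stress",
                           isochoric: bool = True):
    """Tangent shear modulus (kPa) for batched plane-strain F, by central
    differencing under a superposed simple shear in the current frame."""
    f11 = np.asarray(f11, dtype=float)
    g = 0.5 * dgamma

    def sheared(sign):
        # F' = S F with S = I + sign*g * e_y(x)e_x: the incremental shear of a
        # wave propagating along x with vertical (y) polarization
        return (f11, f12, f21 + sign * g * f11, f22 + sign * g * f12)

    if mode == "stress":
        _, sp, _, _ = _stress_from_F_arrays(params, *sheared(+1.0), isochoric=isochoric)
        _, sm, _, _ = _stress_from_F_arrays(params, *sheared(-1.0), isochoric=isochoric)
        return (sp - sm) / dgamma
    if mode == "energy":
        # d^2(U/J)/dgamma^2: energy-based reading, per unit current volume
        dgamma = max(dgamma, 1.0e-4)  # second difference needs a larger step
        def u_of(sign_g):
            a11, a12, a21, a22 = (f11, f12,
                                  f21 + sign_g * f11, f22 + sign_g * f12)
            i1, i2, j = invariants_from_F(a11, a12, a21, a22, isochoric=isochoric)
            e1, e2, ev = i1 - 3.0, i2 - 3.0, j - 1.0
            u = (params.c10 * e1 + params.c01 * e2 + params.c11 * e1 * e2
                 + params.c20 * e1**2 + params.c02 * e2**2
                 + ev**2 / params.d1 + ev**4 / params.d2)
            return u / j
        up, u0, um = u_of(dgamma), u_of(0.0), u_of(-dgamma)
        return (up - 2.0 * u0 + um) / dgamma**2
    raise ValueError(f"unknown tangent mode {mode!r}")


def tangent_shear_modulus(params: MaterialParams, state: StrainState,
                          dgamma: float = 1.0e-6,
                          mode: Literal["stress", "energy"] = "stress") -> float:
    """Incremental shear modulus (kPa) for shear superposed on the pre-strain.

    mode="stress" (default) differentiates the Cauchy shear stress with
    respect to a small simple shear superposed in the current configuration;
    this includes the pre-stress contribution and is the quantity governing
    the speed of a small-amplitude shear wave in the pre-strained medium.
    mode="energy" takes the second derivative of the energy per current
    volume instead.  Both reduce to mu0 = 2(C10+C01) at identity.
    """
    _check_state(state)
    F = state.deformation_gradient
    out = _tangent_from_F_arrays(params, F[0, 0], F[0, 1], F[1, 0], F[1, 1],
                                 dgamma=dgamma, mode=mode, isochoric=state.isochoric)
    return float(out)


def uniaxial_response(params: MaterialParams, strain_grid) -> dict:
    """Nominal stress and tangent modulus under plane-strain uniaxial compression.

    ``strain_grid`` holds compression fractions in [0, 0.5); kinematics are
    incompressible (lateral stretch 1/(1-e)); the lateral Cauchy stress is
    removed via the arbitrary pressure so the response is uniaxial.  Returns
    dict with 'strain', 'nominal_stress' (kPa, compressive magnitude) and
    'tangent_modulus' (kPa).
    """
    e = np.asarray(strain_grid, dtype=float)
    if np.any((e < 0) | (e >= 0.5)):
        raise ValueError("compression fractions must lie in [0, 0.5)")
    lam = 1.0 - e
    f11, f12, f21, f22 = 1.0 / lam, np.zeros_like(lam), np.zeros_like(lam), lam
    s11, s12, s22, _ = _stress_from_F_arrays(params, f11, f12, f21, f22)
    syy = s22 - s11  # subtract pressure so lateral stress vanishes
    nominal = np.abs(syy) * f11  # first Piola: J sigma F^{-T}, J = 1
    mu_t = _tangent_from_F_arrays(params, f11, f12, f21, f22)
    return {"strain": e, "nominal_stress": nominal, "tangent_modulus": np.asarray(mu_t)}


def load_tissue_library(unit_scale_kpa: float | None = None,
                        density: float = 1000.0) -> dict[str, MaterialParams]:
    """Load the packaged tissue parameter sets (malignant tumor / benign breast).

    The shipped coefficients follow published ex vivo breast-tissue polynomial
    fits; the file stores them with an explicit unit scale (default: values
    are in MPa, converted to kPa internally).  Pass ``unit_scale_kpa`` to
    override the file's scale.
    """
    text = resources.files("nlswei.data").joinpath("tissues.yaml").read_text()
    doc = yaml.safe_load(text)
    scale = float(doc.get("unit_scale_kpa", 1.0)) if unit_scale_kpa is None else unit_scale_kpa
    nu = float(doc.get("poisson_ratio", 0.495))
    lib = {}
    for name, row in doc["tissues"].items():
        lib[name] = MaterialParams.from_coefficients(
            c10=row["c10"], c01=row["c01"], c11=row["c11"],
            c20=row["c20"], c02=row["c02"],
            poisson_ratio=nu, density=density, label=name,
            unit_scale_kpa=scale)
    return lib


def tissue(name: str, **kwargs) -> MaterialParams:
    """Convenience accessor: ``tissue('tumor')`` or ``tissue('benign')``."""
    return load_tissue_library(**kwargs)[name]
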