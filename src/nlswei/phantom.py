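"""Breast phantom geometry: semi-elliptical cross-section with a circular tumor.

The default phantom is a 2D plane-strain cross-section 100 mm wide and
40 mm high (half-axes 50 / 40 mm, flat base at the bottom), holding a stiff
circular tumor of diameter 10 mm whose center sits 20 mm above the base and
38 mm left of the rightmost point of the outline.  Coordinates: origin at
the base center, x rightward, y upward, units mm.

The same machinery doubles as the synthetic fixture generator for tests:
small rectangular phantoms that are homogeneous, layered, or carry a single
inclusion, with materials of known analytic properties.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .materials import MaterialParams, tissue

__all__ = ["PhantomModel", "build_phantom", "make_test_fixture"]

VOID = -1
BACKGROUND = 0
TUMOR = 1


@dataclass(frozen=True)
class PhantomModel:
    """Geometry + material assignment of a 2D phantom.

    ``shape`` selects the outline: "semi-ellipse" (flat base, curved top) or
    "rectangle" (test fixtures).  ``label_of(x, y)`` evaluates the label map
    analytically at arbitrary points, so the phantom can be rasterized at
    any grid spacing (the mechanics mesh and the 0.2 mm wave grid differ).
    """

    width: float = 100.0
    height: float = 40.0
    shape: str = "semi-ellipse"
    tumor_center: tuple[float, float] = (12.0, 20.0)
    tumor_diameter: float = 10.0
    grid_spacing: float = 0.2
    platen_width: float = 45.0
    platen_edge_radius: float = 6.0   # fillet at the platen edges, mm
    materials: dict = field(default_factory=dict)
    layer_interface: float | None = None  # rectangle fixtures: y of layer split
    base_bc: str = "fixed"  # "fixed" (all directions) or "roller" (vertical only)

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        if self.tumor_diameter < 0:
            raise ValueError("tumor_diameter must be non-negative")
        if self.tumor_diameter > 0:
            cx, cy = self.tumor_center
            r = 0.5 * self.tumor_diameter
            # tumor disc must sit fully inside the outline
            probes = [(cx + r, cy), (cx - r, cy), (cx, cy + r), (cx, cy - r)]
            if not all(self._inside(np.array([px]), np.array([py]))[0]
                       for px, py in probes):
                raise ValueError("tumor disc extends outside the phantom outline")

    # -- geometry ---------------------------------------------------------
    def _inside(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        if self.shape == "rectangle":
            return ((np.abs(x) <= self.width / 2.0) & (y >= 0.0)
                    & (y <= self.height))
        a, b = self.width / 2.0, self.height
        return (y >= 0.0) & ((x / a) ** 2 + (y / b) ** 2 <= 1.0)

    def surface_height(self, x: np.ndarray) -> np.ndarray:
        """y of the top surface above x (NaN outside the footprint)."""
        x = np.asarray(x, dtype=float)
        if self.shape == "rectangle":
            return np.where(np.abs(x) <= self.width / 2.0, self.height, np.nan)
        a, b = self.width / 2.0, self.height
        t = 1.0 - (x / a) ** 2
        return np.where(t >= 0.0, b * np.sqrt(np.clip(t, 0.0, None)), np.nan)

    def label_of(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Tissue label at points (vectorized): VOID, BACKGROUND or TUMOR."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        lab = np.where(self._inside(x, y), BACKGROUND, VOID)
        if self.layer_interface is not None:
            lab = np.where((lab == BACKGROUND) & (y >= self.layer_interface),
                           TUMOR, lab)
        if self.tumor_diameter > 0:
            cx, cy = self.tumor_center
            r = 0.5 * self.tumor_diameter
            in_tumor = (x - cx) ** 2 + (y - cy) ** 2 <= r * r
            lab = np.where((lab != VOID) & in_tumor, TUMOR, lab)
        return lab

    def rasterize(self, spacing: float | None = None):
        """Cell-centered label map at the given spacing.

        Returns (labels, x_centers, y_centers); labels indexed [ix, iy].
        Cells whose center falls outside the outline are VOID.
        """
        h = self.grid_spacing if spacing is None else spacing
        nx = int(round(self.width / h))
        ny = int(round(self.height / h))
        xc = -self.width / 2.0 + (np.arange(nx) + 0.5) * h
        yc = (np.arange(ny) + 0.5) * h
        X, Y = np.meshgrid(xc, yc, indexing="ij")
        return self.label_of(X, Y), xc, yc

    @property
    def label_map(self) -> np.ndarray:
        labels, _, _ = self.rasterize()
        return labels

    def material_of(self, label: int) -> MaterialParams:
        return self.materials[int(label)]

    def with_materials(self, background: MaterialParams,
                       tumor: MaterialParams | None = None) -> "PhantomModel":
        mats = {BACKGROUND: background,
                TUMOR: tumor if tumor is not None else background}
        return replace(self, materials=mats)

    def platen_half_width(self) -> float:
        return 0.5 * self.platen_width


def build_phantom(
    grid_spacing: float = 0.2,
    tumor_center: tuple[float, float] = (12.0, 20.0),
    tumor_diameter: float = 10.0,
    background: MaterialParams | None = None,
    tumor_material: MaterialParams | None = None,
    platen_width: float = 45.0,
    density: float = 1000.0,
) -> PhantomModel:
    """Build the default breast phantom (semi-ellipse 100 x 40 mm).

    With no materials given, the packaged tumor/benign parameter sets are
    used.  The default tumor center (12, 20) places the disc 20 mm above the
    base and 38 mm left of the right edge of the outline, spanning
    x in [7, 17] mm so the Fig.-2-style sampling positions 10.2 and 13.3 mm
    fall inside it.
    """
    if background is None:
        background = tissue("benign", density=density)
    if tumor_material is None:
        tumor_material = tissue("tumor", density=density)
    ph = PhantomModel(grid_spacing=grid_spacing, tumor_center=tumor_center,
                      tumor_diameter=tumor_diameter, platen_width=platen_width)
    return ph.with_materials(background, tumor_material)


def make_test_fixture(kind: str, *,
                      width: float = 20.0, height: float = 10.0,
                      grid_spacing: float = 0.5,
                      mu0: float = 4.0, mu0_top: float = 16.0,
                      inclusion_diameter: float = 4.0,
                      inclusion_mu0: float | None = None,
                      background: MaterialParams | None = None,
                      inclusion_material: MaterialParams | None = None,
                      density: float = 1000.0,
                      platen_width: float | None = None,
                      base_bc: str = "fixed") -> PhantomModel:
    """Small rectangular phantoms with known analytic properties.

    kind="homogeneous": one neo-Hookean-like material with initial shear
    modulus ``mu0`` (kPa).  kind="layered": bottom layer ``mu0``, top layer
    ``mu0_top`` split at mid-height.  kind="inclusion": centered disc of
    ``inclusion_mu0`` (defaults to ``mu0`` for a contrast-free control).
    The default platen overhangs the fixture so the whole top surface stays
    covered when the specimen bulges laterally under compression.
    """

    def simple(mu, label):
        # linear-in-invariants material: c10=c01=mu/4, no hardening terms
        return MaterialParams.from_coefficients(
            c10=mu / 4.0, c01=mu / 4.0, c11=0.0, c20=0.0, c02=0.0,
            density=density, label=label)

    pw = 2.0 * width if platen_width is None else platen_width
    bg = background if background is not None else simple(mu0, "background")
    if kind == "homogeneous":
        ph = PhantomModel(width=width, height=height, shape="rectangle",
                          tumor_diameter=0.0, grid_spacing=grid_spacing,
                          platen_width=pw, base_bc=base_bc)
        return ph.with_materials(bg)
    if kind == "layered":
        top = simple(mu0_top, "top-layer")
        ph = PhantomModel(width=width, height=height, shape="rectangle",
                          tumor_diameter=0.0, grid_spacing=grid_spacing,
                          platen_width=pw, layer_interface=height / 2.0,
                          base_bc=base_bc)
        return ph.with_materials(bg, top)
    if kind == "inclusion":
        inc = (inclusion_material if inclusion_material is not None
               else simple(mu0 if inclusion_mu0 is None else inclusion_mu0,
                           "inclusion"))
        ph = PhantomModel(width=width, height=height, shape="rectangle",
                          tumor_center=(0.0, height / 2.0),
                          tumor_diameter=inclusion_diameter,
                          grid_spacing=grid_spacing, platen_width=pw,
                          base_bc=base_bc)
        return ph.with_materials(bg, inc)
    raise ValueError(f"unknown fixture kind {kind!r}")
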