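"""Material library and axisymmetric computational domain for cryoballoon PVI.

The physical setting is a pulmonary vein (PV) modeled as concentric cylinders
60 mm long: the blood-filled lumen, the vascular wall, and an outer layer of
pulmonary tissue.  A polyurethane cryoballoon — an ellipsoid 23 mm across its
equator and 20 mm pole-to-pole — sits on the vein axis.  Because the inflated
balloon is wider than every PV ostium, the ellipsoid is clipped by the lumen
cylinder, producing a direct balloon–wall contact band, which is the clinical
intent of occlusive balloon positioning.

Everything here is rotationally symmetric about the vein axis, so the domain
is discretized on a 2-D (r, z) grid of cell-centered finite volumes.  All
lengths at this module's API are millimetres; the discretized domain stores
SI metres and kelvins for the solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import integrate

CELSIUS_OFFSET = 273.15
BODY_TEMPERATURE_C = 36.7
#: Volumetric blood perfusion rate; mL s^-1 cm^-3 is numerically s^-1.
DEFAULT_VOLUMETRIC_PERFUSION = 0.012

# Region label codes for the rasterized domain.
LABEL_BLOOD = 0
LABEL_BALLOON = 1
LABEL_WALL = 2
LABEL_PULMONARY = 3
LABEL_NAMES = {
    LABEL_BLOOD: "blood",
    LABEL_BALLOON: "balloon",
    LABEL_WALL: "vascular_wall",
    LABEL_PULMONARY: "pulmonary_tissue",
}
#: Material key used for each region label.
LABEL_MATERIAL = {
    LABEL_BLOOD: "blood",
    LABEL_BALLOON: "polyurethane",
    LABEL_WALL: "vascular_wall",
    LABEL_PULMONARY: "pulmonary_tissue",
}
#: Tie-break priority at interfaces: balloon > wall > pulmonary > blood.
LABEL_PRIORITY = (LABEL_BALLOON, LABEL_WALL, LABEL_PULMONARY, LABEL_BLOOD)


@dataclass(frozen=True)
class MaterialProperties:
    """Thermal properties of one material region.

    Parameters
    ----------
    thermal_conductivity : W m^-1 K^-1
    specific_heat : J kg^-1 K^-1
    density : kg m^-3
    initial_temperature : K
    """

    name: str
    thermal_conductivity: float
    specific_heat: float
    density: float
    initial_temperature: float

    def __post_init__(self) -> None:
        for f in ("thermal_conductivity", "specific_heat", "density",
                  "initial_temperature"):
            if not getattr(self, f) > 0:
                raise ValueError(f"{self.name}: {f} must be strictly positive")
        if not 150.0 <= self.initial_temperature <= 320.0:
            raise ValueError(
                f"{self.name}: initial_temperature {self.initial_temperature} K "
                "outside plausible range [150, 320] K")

    @property
    def volumetric_heat_capacity(self) -> float:
        """rho * c, J m^-3 K^-1."""
        return self.density * self.specific_heat


@dataclass(frozen=True)
class PerfusionParameters:
    """Blood-perfusion sink and metabolic source of the Pennes equation.

    ``volumetric_perfusion`` is the blood volume flow per unit tissue volume
    (mL s^-1 cm^-3, numerically s^-1); multiplied by blood density it gives
    the mass perfusion rate Wb in kg m^-3 s^-1.  The sink term is
    Wb * Cb * (Ta - T), active while tissue is unfrozen.  Metabolic heat is
    zero for the solid polyurethane balloon.
    """

    volumetric_perfusion: float = DEFAULT_VOLUMETRIC_PERFUSION
    blood_density: float = 1057.0
    blood_specific_heat: float = 4000.0
    arterial_temperature: float = 310.15
    metabolic_heat: float = 0.0

    def __post_init__(self) -> None:
        if self.volumetric_perfusion < 0:
            raise ValueError("volumetric_perfusion must be >= 0")

    @property
    def mass_rate(self) -> float:
        """Wb = volumetric_perfusion * blood_density, kg m^-3 s^-1."""
        return self.volumetric_perfusion * self.blood_density

    @property
    def sink_coefficient(self) -> float:
        """Wb * Cb, W m^-3 K^-1."""
        return self.mass_rate * self.blood_specific_heat


def default_materials() -> dict[str, MaterialProperties]:
    """The four-material library used throughout (SI units, temperatures K)."""
    return {
        "blood": MaterialProperties("blood", 0.54, 4000.0, 1057.0, 310.15),
        "vascular_wall": MaterialProperties("vascular_wall", 1.3, 3600.0, 1200.0, 310.0),
        "polyurethane": MaterialProperties("polyurethane", 0.02, 1500.0, 1110.0, 198.15),
        "pulmonary_tissue": MaterialProperties("pulmonary_tissue", 0.03, 2963.0, 1000.0, 311.0),
    }


def default_perfusion() -> dict[str, PerfusionParameters]:
    """Perfusion parameters per material; the solid balloon is unperfused."""
    tissue = PerfusionParameters()
    return {
        "blood": tissue,
        "vascular_wall": tissue,
        "pulmonary_tissue": tissue,
        "polyurethane": PerfusionParameters(volumetric_perfusion=0.0,
                                            metabolic_heat=0.0),
    }


@dataclass(frozen=True)
class PVGeometry:
    """Pulmonary-vein geometry: concentric cylinders, lengths in mm."""

    name: str
    ostium_diameter: float
    wall_thickness: float
    length: float = 60.0
    pulmonary_layer_thickness: float = 10.0

    def __post_init__(self) -> None:
        if self.ostium_diameter <= 0 or self.wall_thickness <= 0:
            raise ValueError("ostium_diameter and wall_thickness must be > 0")
        if self.length <= 0 or self.pulmonary_layer_thickness <= 0:
            raise ValueError("length and pulmonary_layer_thickness must be > 0")

    @property
    def lumen_radius(self) -> float:
        return self.ostium_diameter / 2.0

    @property
    def wall_outer_radius(self) -> float:
        return self.lumen_radius + self.wall_thickness

    @property
    def outer_radius(self) -> float:
        return self.wall_outer_radius + self.pulmonary_layer_thickness


PV_PRESETS: dict[str, tuple[float, float]] = {
    "right superior": (18.0, 2.7),
    "right inferior": (12.0, 1.8),
    "left superior": (19.0, 2.8),
    "left inferior": (13.0, 1.9),
}


def pv_parameters(name: str, pulmonary_layer_thickness: float = 10.0) -> PVGeometry:
    """Return the preset geometry for one of the four pulmonary veins."""
    key = name.strip().lower().replace("_", " ")
    if key not in PV_PRESETS:
        valid = ", ".join(sorted(PV_PRESETS))
        raise KeyError(f"unknown pulmonary vein {name!r}; valid names: {valid}")
    d, w = PV_PRESETS[key]
    return PVGeometry(key, d, w,
                      pulmonary_layer_thickness=pulmonary_layer_thickness)


@dataclass(frozen=True)
class BalloonSpec:
    """Second-generation 23 mm cryoballoon, modeled as an axis-aligned ellipsoid.

    ``axial_center`` places the balloon equator along the vein axis (mm);
    ``surface_flux_magnitude`` is the boundary heat flux used in the optional
    Neumann mode, interpreted as W m^-2 (negative = heat extracted).
    """

    equatorial_diameter: float = 23.0
    polar_height: float = 20.0
    axial_center: float = 30.0
    minimal_internal_temperature: float = -80.0
    surface_flux_magnitude: float = -151924.04

    def __post_init__(self) -> None:
        if self.equatorial_diameter <= 0 or self.polar_height <= 0:
            raise ValueError("balloon diameters must be > 0")
        if self.minimal_internal_temperature > -30.0:
            raise ValueError("minimal_internal_temperature must be <= -30 degC")

    @property
    def equatorial_radius(self) -> float:
        return self.equatorial_diameter / 2.0

    @property
    def polar_half_height(self) -> float:
        return self.polar_height / 2.0

    def radius_at(self, z: np.ndarray | float) -> np.ndarray | float:
        """Ellipsoid radius (mm) at axial position z (mm); 0 beyond the poles."""
        zeta = (np.asarray(z, dtype=float) - self.axial_center) / self.polar_half_height
        return self.equatorial_radius * np.sqrt(np.clip(1.0 - zeta ** 2, 0.0, None))

    def contact_band_half_height(self, lumen_radius: float) -> float:
        """Axial half-extent (mm) over which the clipped balloon touches the wall.

        Solves the ellipse equation for z where the balloon radius equals the
        lumen radius; zero when the balloon fits inside the lumen.
        """
        if lumen_radius >= self.equatorial_radius:
            return 0.0
        return self.polar_half_height * math.sqrt(
            1.0 - (lumen_radius / self.equatorial_radius) ** 2)


def clipped_balloon_volume(balloon: BalloonSpec, lumen_radius: float) -> float:
    """Volume (mm^3) of the ellipsoid clipped by the lumen cylinder."""

    def area(z: float) -> float:
        r = min(float(balloon.radius_at(z)), lumen_radius)
        return math.pi * r * r

    a = balloon.polar_half_height
    v, _ = integrate.quad(area, balloon.axial_center - a, balloon.axial_center + a,
                          limit=200)
    return v


@dataclass
class ComputationalDomain:
    """Labeled axisymmetric (r, z) grid of cell-centered finite volumes.

    ``labels`` has shape (nr, nz); radial index 0 is adjacent to the axis
    (or to ``r_inner`` for annular verification domains).  Spacings are in
    metres.  ``axisymmetric=False`` switches to a unit-depth planar slab,
    used for 1-D verification against closed-form solutions.
    """

    nr: int
    nz: int
    dr: float
    dz: float
    labels: np.ndarray
    materials: dict[str, MaterialProperties]
    perfusion: dict[str, PerfusionParameters]
    axisymmetric: bool = True
    r_inner: float = 0.0
    pv: Optional[PVGeometry] = None
    balloon: Optional[BalloonSpec] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.shape != (self.nr, self.nz):
            raise ValueError("labels shape must be (nr, nz)")
        if not np.isin(self.labels, list(LABEL_NAMES)).all():
            raise ValueError("labels contain unknown region codes")

    # -- geometry ---------------------------------------------------------
    @property
    def r_centers(self) -> np.ndarray:
        return self.r_inner + (np.arange(self.nr) + 0.5) * self.dr

    @property
    def z_centers(self) -> np.ndarray:
        return (np.arange(self.nz) + 0.5) * self.dz

    @property
    def r_faces(self) -> np.ndarray:
        return self.r_inner + np.arange(self.nr + 1) * self.dr

    def cell_volumes(self) -> np.ndarray:
        """Cell volumes, shape (nr, nz); m^3 (or m^2 per unit depth, planar)."""
        if self.axisymmetric:
            v = 2.0 * math.pi * self.r_centers * self.dr * self.dz
        else:
            v = np.full(self.nr, self.dr * self.dz)
        return np.repeat(v[:, None], self.nz, axis=1)

    def radial_face_areas(self) -> np.ndarray:
        """Area of the nr+1 radial faces (constant along z)."""
        if self.axisymmetric:
            return 2.0 * math.pi * self.r_faces * self.dz
        return np.full(self.nr + 1, self.dz)

    def axial_face_areas(self) -> np.ndarray:
        """Area of axial (z-normal) faces for each radial row."""
        if self.axisymmetric:
            return 2.0 * math.pi * self.r_centers * self.dr
        return np.full(self.nr, self.dr)

    # -- material lookup --------------------------------------------------
    def material_name(self, label: int) -> str:
        return LABEL_MATERIAL[int(label)]

    def property_field(self, attr: str) -> np.ndarray:
        """Per-cell material attribute (e.g. 'thermal_conductivity')."""
        table = np.empty(max(LABEL_NAMES) + 1)
        for code in LABEL_NAMES:
            table[code] = getattr(self.materials[LABEL_MATERIAL[code]], attr)
        return table[self.labels]

    def perfusion_field(self, attr: str) -> np.ndarray:
        table = np.empty(max(LABEL_NAMES) + 1)
        for code in LABEL_NAMES:
            table[code] = getattr(self.perfusion[LABEL_MATERIAL[code]], attr)
        return table[self.labels]

    def initial_temperatures(self) -> np.ndarray:
        """Per-cell initial temperature field (K) from the material library."""
        return self.property_field("initial_temperature")

    # -- masks ------------------------------------------------------------
    @property
    def balloon_mask(self) -> np.ndarray:
        return self.labels == LABEL_BALLOON

    @property
    def tissue_mask(self) -> np.ndarray:
        """Vascular wall + pulmonary tissue (where lesions are measured)."""
        return (self.labels == LABEL_WALL) | (self.labels == LABEL_PULMONARY)

    def region_volume(self, label: int) -> float:
        return float(self.cell_volumes()[self.labels == label].sum())

    def balloon_surface_points(self, n: int = 2000) -> np.ndarray:
        """Dense polyline (mm) sampling the clipped balloon surface in (r, z).

        Covers the ellipsoid arc inside the lumen plus the cylindrical
        contact band; used for normal-distance measurements.
        """
        if self.balloon is None or self.pv is None:
            raise ValueError("domain has no balloon/PV geometry attached")
        b, rl = self.balloon, self.pv.lumen_radius
        a = b.polar_half_height
        z = np.linspace(b.axial_center - a, b.axial_center + a, n)
        r = np.minimum(np.asarray(b.radius_at(z)), rl)
        return np.column_stack([r, z])


def build_domain(pv: PVGeometry, balloon: BalloonSpec | None = None,
                 resolution: float = 0.15,
                 materials: dict[str, MaterialProperties] | None = None,
                 perfusion: dict[str, PerfusionParameters] | None = None,
                 layer_order: tuple[str, str] = ("pulmonary_tissue", "vascular_wall"),
                 ) -> ComputationalDomain:
    """Rasterize the PV + balloon geometry onto an (r, z) grid.

    Parameters
    ----------
    resolution : cell size in mm; must not exceed the wall thickness so the
        wall is resolved by at least one cell.
    layer_order : radial order of the two tissue layers outside the lumen.
        The default places the pulmonary-tissue layer against the lumen with
        the vascular wall outermost; this matches the reported
        balloon-to-wall distances (~4 mm, far larger than the lesion
        half-depths, so the freeze front stops inside the pulmonary layer
        short of the wall).  Passing ``("vascular_wall",
        "pulmonary_tissue")`` selects the anatomical wall-adjacent ordering
        instead.

    Cells are labeled by their center with tie-break priority
    balloon > vascular_wall > pulmonary_tissue > blood.
    """
    if balloon is None:
        balloon = BalloonSpec(axial_center=pv.length / 2.0)
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    if resolution > pv.wall_thickness:
        raise ValueError(
            f"resolution {resolution} mm coarser than wall thickness "
            f"{pv.wall_thickness} mm; the wall must be resolved by >= 1 cell")
    if set(layer_order) != {"vascular_wall", "pulmonary_tissue"}:
        raise ValueError("layer_order must be a permutation of "
                         "('vascular_wall', 'pulmonary_tissue')")

    # Fit the grid exactly to the geometry (cell sizes <= requested, so the
    # rasterized region volumes are consistent across refinement levels).
    nr = int(math.ceil(pv.outer_radius / resolution - 1e-9))
    nz = int(math.ceil(pv.length / resolution - 1e-9))
    dr_mm = pv.outer_radius / nr
    dz_mm = pv.length / nz

    r = (np.arange(nr) + 0.5) * dr_mm
    z = (np.arange(nz) + 0.5) * dz_mm
    R, Z = np.meshgrid(r, z, indexing="ij")

    first_thickness = (pv.wall_thickness if layer_order[0] == "vascular_wall"
                       else pv.pulmonary_layer_thickness)
    inner_outer = pv.lumen_radius + first_thickness
    name_to_label = {"vascular_wall": LABEL_WALL,
                     "pulmonary_tissue": LABEL_PULMONARY}

    labels = np.full((nr, nz), name_to_label[layer_order[1]], dtype=np.int8)
    labels[R <= inner_outer] = name_to_label[layer_order[0]]
    labels[R <= pv.lumen_radius] = LABEL_BLOOD

    # Balloon: ellipsoid clipped by the lumen cylinder; highest priority.
    ell = ((Z - balloon.axial_center) / balloon.polar_half_height) ** 2 \
        + (R / balloon.equatorial_radius) ** 2
    labels[(ell <= 1.0) & (R <= pv.lumen_radius)] = LABEL_BALLOON

    domain = ComputationalDomain(
        nr=nr, nz=nz, dr=dr_mm * 1e-3, dz=dz_mm * 1e-3, labels=labels,
        materials=materials or default_materials(),
        perfusion=perfusion or default_perfusion(),
        axisymmetric=True, pv=pv, balloon=balloon)
    if not domain.balloon_mask.any():
        raise ValueError("rasterized balloon region is empty; refine resolution")
    return domain


def make_slab_domain(nr: int, nz: int, cell_mm: float,
                     labels: np.ndarray | int = LABEL_WALL,
                     materials: dict[str, MaterialProperties] | None = None,
                     perfusion: dict[str, PerfusionParameters] | None = None,
                     axisymmetric: bool = False,
                     r_inner_mm: float = 0.0) -> ComputationalDomain:
    """Uniform rectangular domain for verification studies (slab or annulus)."""
    lab = np.full((nr, nz), labels, dtype=np.int8) if np.isscalar(labels) \
        else np.asarray(labels, dtype=np.int8)
    return ComputationalDomain(
        nr=nr, nz=nz, dr=cell_mm * 1e-3, dz=cell_mm * 1e-3, labels=lab,
        materials=materials or default_materials(),
        perfusion=perfusion or default_perfusion(),
        axisymmetric=axisymmetric, r_inner=r_inner_mm * 1e-3)


def material_at(domain: ComputationalDomain, index: tuple[int, int]
                ) -> tuple[MaterialProperties, PerfusionParameters]:
    """Material and perfusion parameters for one cell (deterministic lookup)."""
    i, j = index
    if not (0 <= i < domain.nr and 0 <= j < domain.nz):
        raise IndexError(f"cell index {index} outside grid "
                         f"({domain.nr} x {domain.nz})")
    name = LABEL_MATERIAL[int(domain.labels[i, j])]
    return domain.materials[name], domain.perfusion[name]
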