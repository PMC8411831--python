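"""Parametric biosensor geometry and voxelization.

The sensor is a spherically capped gold nanorod (cylinder of length D - d
capped by two hemispheres of diameter d) wrapped in a thin dielectric shell,
resting on a glass half-space and immersed in water.  A single analyte
molecule sits on the outer shell surface at a configurable binding site.

Coordinate conventions
----------------------
* rod long axis along +x, centered at x = y = 0;
* substrate surface is the plane z = 0, glass fills z < 0;
* the shell touches the substrate, so the rod axis sits at
  z = d/2 + shell thickness + gap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .materials import MaterialSet

__all__ = [
    "NanorodGeometry",
    "ShellSpec",
    "MoleculeSpec",
    "BindingSite",
    "Scene",
    "DipoleGrid",
    "build_scene",
    "rod_volume",
    "equivalent_radius",
    "sphere_diameter_from_mass",
    "sphere_mass_from_diameter",
    "molecule_shape_solid",
    "voxelize",
]

DALTON_G = 1.66053906660e-24  # g per dalton
MOLECULE_SHAPES = (
    "sphere",
    "hemisphere",
    "spherical_segment",
    "concave_spherical_segment",
)

#: integer material codes used in DipoleGrid
MATERIAL_IDS = {"gold": 1, "shell": 2, "molecule": 3}
ID_TO_MATERIAL = {v: k for k, v in MATERIAL_IDS.items()}


@dataclass(frozen=True)
class NanorodGeometry:
    """Spherically capped cylinder: width (diameter) d and aspect ratio AR."""

    diameter_nm: float
    aspect_ratio: float

    def __post_init__(self) -> None:
        if self.diameter_nm <= 0:
            raise ValueError("diameter must be positive")
        if self.aspect_ratio < 1:
            raise ValueError("aspect ratio must be >= 1 (1 is a sphere)")

    @property
    def length_nm(self) -> float:
        return self.aspect_ratio * self.diameter_nm

    @property
    def half_gap(self) -> float:
        """Half distance between the two hemisphere centers, (D - d)/2."""
        return 0.5 * (self.length_nm - self.diameter_nm)


@dataclass(frozen=True)
class ShellSpec:
    thickness_nm: float = 1.5
    refractive_index: float = 1.45

    def __post_init__(self) -> None:
        if self.thickness_nm < 0:
            raise ValueError("shell thickness must be >= 0")


@dataclass(frozen=True)
class MoleculeSpec:
    """Analyte molecule at fixed volume; shape varies at equal volume.

    ``equivalent_diameter_nm`` is the diameter of the equal-volume sphere
    (default 5 nm, the closely packed streptavidin sphere).
    """

    shape: str = "sphere"
    equivalent_diameter_nm: float = 5.0
    refractive_index: float = 1.57

    def __post_init__(self) -> None:
        if self.shape not in MOLECULE_SHAPES:
            raise ValueError(f"shape must be one of {MOLECULE_SHAPES}")
        if self.equivalent_diameter_nm <= 0:
            raise ValueError("equivalent diameter must be positive")

    @property
    def volume_nm3(self) -> float:
        return np.pi * self.equivalent_diameter_nm**3 / 6.0

    @classmethod
    def from_mass(cls, mass_kda: float, density_g_cm3: float = 1.37, **kw):
        d = sphere_diameter_from_mass(mass_kda, density_g_cm3)
        return cls(equivalent_diameter_nm=d, **kw)


@dataclass(frozen=True)
class BindingSite:
    """Binding position code on the shell surface.

    ``plane`` selects the horizontal side (parallel to the substrate) or the
    vertical ridge (perpendicular, through the substrate normal).  Cap
    positions 0..6 step by 15 degrees from the tip apex (0) to the
    cap-cylinder junction (6); flat positions 7, 8, ... step by 5 nm along
    the cylinder, and the final index is clamped to the rod midpoint.  On the
    vertical plane a negative index points toward the substrate.
    """

    plane: str = "horizontal_side"
    index: int = 0

    CAP_STEP_DEG = 15.0
    FLAT_STEP_NM = 5.0

    def __post_init__(self) -> None:
        if self.plane not in ("horizontal_side", "vertical_ridge"):
            raise ValueError("plane must be horizontal_side or vertical_ridge")
        if self.index < 0 and self.plane != "vertical_ridge":
            raise ValueError("negative site index requires the vertical plane")


def max_site_index(rod: NanorodGeometry) -> int:
    """Largest valid site index: flat steps of 5 nm clamped at the midpoint."""
    n_flat = int(np.ceil(rod.half_gap / BindingSite.FLAT_STEP_NM))
    return 6 + n_flat


def site_frame(rod: NanorodGeometry, shell: ShellSpec, site: BindingSite,
               axis_z: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Anchor point on the outer shell surface, outward normal, cap center.

    Returns ``(anchor, normal, cap_center)``; ``cap_center`` is the +x
    hemisphere center (reference for shapes conforming to the tip).
    """
    idx = abs(site.index)
    if idx > max_site_index(rod):
        raise ValueError(
            f"site index {site.index} beyond rod midpoint "
            f"(max {max_site_index(rod)})"
        )
    sgn = -1.0 if site.index < 0 else 1.0
    rho = rod.diameter_nm / 2.0 + shell.thickness_nm
    cap_center = np.array([rod.half_gap, 0.0, axis_z])
    if idx <= 6:
        theta = np.deg2rad(BindingSite.CAP_STEP_DEG * idx)
        if site.plane == "horizontal_side":
            normal = np.array([np.cos(theta), np.sin(theta), 0.0])
        else:
            normal = np.array([np.cos(theta), 0.0, sgn * np.sin(theta)])
        anchor = cap_center + rho * normal
    else:
        x = rod.half_gap - BindingSite.FLAT_STEP_NM * (idx - 6)
        x = max(x, 0.0)  # clamp to midpoint
        if site.plane == "horizontal_side":
            normal = np.array([0.0, 1.0, 0.0])
        else:
            normal = np.array([0.0, 0.0, sgn * 1.0])
        anchor = np.array([x, 0.0, axis_z]) + rho * normal
    return anchor, normal, cap_center


@dataclass(frozen=True)
class Scene:
    """Validated biosensor scene ready for voxelization."""

    rod: NanorodGeometry
    shell: ShellSpec = field(default_factory=ShellSpec)
    molecule: MoleculeSpec | None = None
    site: BindingSite = field(default_factory=BindingSite)
    materials: MaterialSet = field(default_factory=MaterialSet)
    substrate_enabled: bool = True
    gap_to_substrate_nm: float = 0.0

    @property
    def axis_z(self) -> float:
        """Height of the rod axis above the substrate plane."""
        return (self.rod.diameter_nm / 2.0 + self.shell.thickness_nm
                + self.gap_to_substrate_nm)

    @property
    def axis_point(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.axis_z])

    def without_molecule(self) -> "Scene":
        return replace(self, molecule=None)

    def molecule_center(self) -> np.ndarray:
        """Center of the equal-volume sphere resting on the shell surface."""
        if self.molecule is None:
            raise ValueError("scene has no molecule")
        anchor, normal, _ = site_frame(self.rod, self.shell, self.site,
                                       self.axis_z)
        return anchor + 0.5 * self.molecule.equivalent_diameter_nm * normal


def build_scene(rod: NanorodGeometry,
                shell: ShellSpec | None = None,
                molecule: MoleculeSpec | None = None,
                site: BindingSite | None = None,
                materials: MaterialSet | None = None,
                substrate_enabled: bool = True,
                gap_to_substrate_nm: float = 0.0) -> Scene:
    """Assemble and validate a Scene.

    The molecule is placed along the outward normal of the binding site so
    that its surface touches the outer shell surface; a site index beyond
    the rod midpoint raises a validation error.
    """
    scene = Scene(
        rod=rod,
        shell=shell if shell is not None else ShellSpec(),
        molecule=molecule,
        site=site if site is not None else BindingSite(),
        materials=materials if materials is not None else MaterialSet(),
        substrate_enabled=substrate_enabled,
        gap_to_substrate_nm=gap_to_substrate_nm,
    )
    # raises for invalid site indices
    site_frame(scene.rod, scene.shell, scene.site, scene.axis_z)
    if molecule is not None:
        # molecule sits on the shell; a positive standoff from gold is
        # guaranteed by construction unless the shell has zero thickness
        # and the shape conforms exactly -- still non-overlapping.
        center = scene.molecule_center()
        if _rod_signed_distance(center[None, :], scene) < 0:
            raise ValueError("molecule center inside the gold rod")
    return scene


def scene_permittivity(scene: Scene, material: str, wavelength_nm: float):
    """Permittivity of a named material within a scene.

    The shell and molecule indices of the scene's specs override the
    MaterialSet defaults so that scans varying them take effect.
    """
    if material == "shell":
        n = scene.shell.refractive_index
        return complex(n * n)
    if material == "molecule" and scene.molecule is not None:
        n = scene.molecule.refractive_index
        return complex(n * n)
    return scene.materials.permittivity(material, wavelength_nm)


# ---------------------------------------------------------------------------
# closed-form size conversions


def rod_volume(rod: NanorodGeometry) -> float:
    """Exact capped-cylinder volume pi d^2 (D - d)/4 + pi d^3/6, in nm^3."""
    d, D = rod.diameter_nm, rod.length_nm
    return np.pi * d * d * (D - d) / 4.0 + np.pi * d**3 / 6.0


def equivalent_radius(rod: NanorodGeometry) -> float:
    """Radius of the equal-volume sphere, (3 V / 4 pi)^(1/3), in nm."""
    return float((3.0 * rod_volume(rod) / (4.0 * np.pi)) ** (1.0 / 3.0))


def sphere_diameter_from_mass(mass_kda: float,
                              density_g_cm3: float = 1.37) -> float:
    """Diameter (nm) of the sphere holding ``mass_kda`` at the given density.

    Assumes a closely packed interior; the default density is the standard
    value for folded proteins.
    """
    if mass_kda <= 0 or density_g_cm3 <= 0:
        raise ValueError("mass and density must be positive")
    volume_nm3 = mass_kda * 1e3 * DALTON_G / density_g_cm3 * 1e21
    return float((6.0 * volume_nm3 / np.pi) ** (1.0 / 3.0))


def sphere_mass_from_diameter(diameter_nm: float,
                              density_g_cm3: float = 1.37) -> float:
    """Inverse of :func:`sphere_diameter_from_mass`; returns kDa."""
    volume_nm3 = np.pi * diameter_nm**3 / 6.0
    return float(volume_nm3 * 1e-21 * density_g_cm3 / (1e3 * DALTON_G))


# ---------------------------------------------------------------------------
# solids (point-membership predicates)


def _rod_signed_distance(points: np.ndarray, scene: Scene) -> np.ndarray:
    """Distance from each point to the rod axis segment, minus d/2."""
    p = np.atleast_2d(points) - scene.axis_point
    a = scene.rod.half_gap
    x = np.clip(p[:, 0], -a, a)
    dx = p[:, 0] - x
    return np.sqrt(dx * dx + p[:, 1] ** 2 + p[:, 2] ** 2) - \
        scene.rod.diameter_nm / 2.0


def rod_solid(points: np.ndarray, scene: Scene) -> np.ndarray:
    return _rod_signed_distance(points, scene) <= 0.0


def shell_solid(points: np.ndarray, scene: Scene) -> np.ndarray:
    """Shell region: within `thickness` of the rod surface, outside gold."""
    d = _rod_signed_distance(points, scene)
    return (d > 0.0) & (d <= scene.shell.thickness_nm)


def molecule_shape_solid(spec: MoleculeSpec, scene: Scene):
    """Point-membership predicate for the molecule solid.

    All shapes have the same volume as the reference equal-volume sphere.
    The hemisphere and spherical segment rest base-down on the shell
    surface; the concave spherical segment is a shell-conforming patch whose
    inner face matches the outer shell sphere around the tip cap.
    Returns ``f(points) -> bool array``.
    """
    anchor, normal, cap_center = site_frame(scene.rod, scene.shell,
                                            scene.site, scene.axis_z)
    V = spec.volume_nm3
    if spec.shape == "sphere":
        r = spec.equivalent_diameter_nm / 2.0
        center = anchor + r * normal

        def member(points):
            p = np.atleast_2d(points) - center
            return (p * p).sum(axis=1) <= r * r

    elif spec.shape == "hemisphere":
        # V = (2/3) pi R^3, flat base on the shell surface
        R = (3.0 * V / (2.0 * np.pi)) ** (1.0 / 3.0)

        def member(points):
            p = np.atleast_2d(points) - anchor
            s = p @ normal
            return ((p * p).sum(axis=1) <= R * R) & (s >= 0.0)

    elif spec.shape == "spherical_segment":
        # one-base spherical cap with height h = 0.6 R, flatter than a
        # hemisphere: V = pi h^2 (3R - h)/3 = 0.288 pi R^3
        R = (V / (0.288 * np.pi)) ** (1.0 / 3.0)
        h = 0.6 * R
        center = anchor + (h - R) * normal  # cap occupies s in [0, h]

        def member(points):
            p = np.atleast_2d(points)
            s = (p - anchor) @ normal
            q = p - center
            return ((q * q).sum(axis=1) <= R * R) & (s >= 0.0)

    else:  # concave_spherical_segment
        # patch between the outer shell sphere (radius rho about the cap
        # center) and a concentric sphere rho + h, within half-angle psi of
        # the site normal: V = (2 pi/3) ((rho+h)^3 - rho^3) (1 - cos psi).
        # psi fixed at 20 deg gives a cap-hugging pancake of lateral size
        # comparable to the reference sphere on the 20 nm rod.
        rho = scene.rod.diameter_nm / 2.0 + scene.shell.thickness_nm
        psi = np.deg2rad(20.0)
        outer3 = rho**3 + 3.0 * V / (2.0 * np.pi * (1.0 - np.cos(psi)))
        outer = outer3 ** (1.0 / 3.0)
        cpsi = np.cos(psi)

        def member(points):
            q = np.atleast_2d(points) - cap_center
            r = np.sqrt((q * q).sum(axis=1))
            with np.errstate(invalid="ignore"):
                cang = (q @ normal) / np.where(r > 0, r, 1.0)
            return (r >= rho) & (r <= outer) & (cang >= cpsi)

    return member


# ---------------------------------------------------------------------------
# voxelization


@dataclass
class DipoleGrid:
    """Cubic, axis-aligned voxelization of a scene.

    ``indices`` are integer lattice coordinates of occupied voxels; centers
    are ``origin + (indices + 0.5) * voxel_size``.  ``material_id`` follows
    :data:`MATERIAL_IDS`.  ``point_dipoles`` lists sub-voxel inclusions kept
    as discrete polarizable points: tuples ``(position_nm, material, volume
    _nm3)``.
    """

    voxel_size: float
    origin: np.ndarray
    shape: tuple[int, int, int]
    indices: np.ndarray  # (M, 3) int
    material_id: np.ndarray  # (M,) int
    scene: Scene
    point_dipoles: list = field(default_factory=list)

    @property
    def n_dipoles(self) -> int:
        return len(self.material_id)

    @property
    def centers(self) -> np.ndarray:
        return self.origin + (self.indices + 0.5) * self.voxel_size

    def material_volume(self, material: str) -> float:
        """Total voxel volume assigned to a material, nm^3."""
        mid = MATERIAL_IDS[material]
        return float((self.material_id == mid).sum()) * self.voxel_size**3

    def permittivities(self, wavelength_nm: float) -> np.ndarray:
        """Per-voxel complex relative permittivity at one wavelength.

        Shell and molecule indices come from the scene's ShellSpec /
        MoleculeSpec (scan variables); the MaterialSet provides gold and
        the defaults.
        """
        eps = np.empty(self.n_dipoles, dtype=complex)
        for mid, name in ID_TO_MATERIAL.items():
            sel = self.material_id == mid
            if sel.any():
                eps[sel] = scene_permittivity(self.scene, name,
                                              wavelength_nm)
        return eps

    def to_dataframe(self):
        """Tabular voxel dump (x, y, z, material_id) for debugging."""
        import pandas as pd

        c = self.centers
        return pd.DataFrame({
            "x_nm": c[:, 0], "y_nm": c[:, 1], "z_nm": c[:, 2],
            "material_id": self.material_id,
        })

    def save(self, path) -> None:
        """Compact binary container (npz) for solver hand-off."""
        np.savez_compressed(
            path, voxel_size=self.voxel_size, origin=self.origin,
            shape=np.asarray(self.shape), indices=self.indices,
            material_id=self.material_id)


def voxelize(scene: Scene, voxel_size: float,
             molecule_representation: str = "voxelized") -> DipoleGrid:
    """Discretize a scene into cubic dipoles by center-in-solid membership.

    Material priority at boundaries: gold > molecule > shell > ambient.
    The lattice is mirror-symmetric about the x and y axes so symmetric
    scenes voxelize symmetrically.

    ``molecule_representation='point_dipole'`` keeps the molecule off the
    lattice as a single polarizable point of the equal-volume sphere at the
    molecule center -- intended for coarse lattices where the molecule would
    be smaller than a voxel.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    d = scene.rod.diameter_nm
    if voxel_size > d / 8.0:
        raise ValueError(
            f"voxel_size {voxel_size} nm too coarse for a {d} nm rod "
            f"(need <= d/8 = {d / 8.0:.3g} nm)")
    if voxel_size > d / 16.0:
        warnings.warn("voxel_size above d/16; discretization error may be "
                      "noticeable", stacklevel=2)
    if molecule_representation not in ("voxelized", "point_dipole"):
        raise ValueError("unknown molecule representation")

    h = voxel_size
    rho = d / 2.0 + scene.shell.thickness_nm
    half_x = scene.rod.half_gap + rho
    half_y = rho
    z_lo = scene.gap_to_substrate_nm
    z_hi = scene.axis_z + rho

    voxelize_molecule = (scene.molecule is not None
                        and molecule_representation == "voxelized")
    if voxelize_molecule:
        c = scene.molecule_center()
        r = scene.molecule.equivalent_diameter_nm  # generous pad, any shape
        half_x = max(half_x, abs(c[0]) + r)
        half_y = max(half_y, abs(c[1]) + r)
        z_hi = max(z_hi, c[2] + r)
        z_lo = min(z_lo, max(c[2] - r, scene.gap_to_substrate_nm))

    nx = int(np.ceil(half_x / h))
    ny = int(np.ceil(half_y / h))
    nz = int(np.ceil((z_hi - z_lo) / h))
    origin = np.array([-nx * h, -ny * h, z_lo])
    shape = (2 * nx, 2 * ny, nz)

    ix = np.arange(2 * nx)
    iy = np.arange(2 * ny)
    iz = np.arange(nz)
    IX, IY, IZ = np.meshgrid(ix, iy, iz, indexing="ij")
    idx = np.column_stack([IX.ravel(), IY.ravel(), IZ.ravel()])
    pts = origin + (idx + 0.5) * h

    mat = np.zeros(len(pts), dtype=np.int8)
    in_shell = shell_solid(pts, scene)
    mat[in_shell] = MATERIAL_IDS["shell"]
    if voxelize_molecule:
        member = molecule_shape_solid(scene.molecule, scene)
        mat[member(pts)] = MATERIAL_IDS["molecule"]
    mat[rod_solid(pts, scene)] = MATERIAL_IDS["gold"]

    keep = mat > 0
    if not keep.any():
        raise ValueError("voxelization produced an empty grid")
    grid = DipoleGrid(
        voxel_size=h,
        origin=origin,
        shape=shape,
        indices=idx[keep].astype(np.int32),
        material_id=mat[keep],
        scene=scene,
    )
    if scene.molecule is not None and molecule_representation == "point_dipole":
        grid.point_dipoles.append(
            (scene.molecule_center(), "molecule", scene.molecule.volume_nm3))
    return grid
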