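"""Run configuration: schema-validated YAML, manifests and writers.

A single YAML file describes a full run (materials, scene, solver,
detection, thermal and sweep blocks).  Unknown keys are rejected so typos
fail loudly; every block is optional and falls back to the documented
defaults.  ``write_outputs`` emits CSV/JSON artifacts plus a manifest
embedding the resolved configuration and its content hash, so every
numeric artifact is traceable to the exact configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .dda import SolverSettings
from .geometry import (BindingSite, MoleculeSpec, NanorodGeometry, Scene,
                       ShellSpec, build_scene, sphere_diameter_from_mass)
from .materials import MaterialSet
from .sensing import PhotothermalParams, DetectionConfig
from .sweep import SizeGrid, SpectrumPlan
from .thermal import ThermalParams

__all__ = ["RunConfig", "load_config", "config_hash", "write_outputs"]


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MaterialsBlock(_Model):
    n_water: float = 1.33
    n_glass: float = 1.52
    n_shell: float = 1.45
    n_molecule: float = 1.57


class RodBlock(_Model):
    diameter_nm: float = Field(20.0, gt=0)
    aspect_ratio: float = Field(4.0, ge=1)


class ShellBlock(_Model):
    thickness_nm: float = Field(1.5, ge=0)
    n: float = 1.45


class MoleculeBlock(_Model):
    shape: str = "sphere"
    diameter_nm: float | None = Field(None, gt=0)
    mw_kda: float | None = Field(None, gt=0)
    density_g_cm3: float = 1.37
    n: float = 1.57


class SiteBlock(_Model):
    plane: str = "horizontal_side"
    index: int = 0


class SubstrateBlock(_Model):
    enabled: bool = True
    gap_nm: float = Field(0.0, ge=0)


class SceneBlock(_Model):
    rod: RodBlock = RodBlock()
    shell: ShellBlock = ShellBlock()
    molecule: MoleculeBlock | None = MoleculeBlock()
    site: SiteBlock = SiteBlock()
    substrate: SubstrateBlock = SubstrateBlock()


class SolverBlock(_Model):
    polarizability_model: str = "lattice_dispersion"
    tolerance: float = Field(1e-5, gt=0, lt=1)
    max_iterations: int = Field(4000, gt=0)
    substrate_model: str = "image_quasistatic"
    single_precision: bool = False
    voxel_size_nm: float | None = Field(None, gt=0)
    voxel_fraction: float | None = Field(None, gt=0)
    molecule_representation: str = "voxelized"


class DetectionBlock(_Model):
    intensity_W_m2: float = Field(1e7, gt=0)
    bandwidth_nm: float = Field(1.0, gt=0)
    dt_s: float = Field(1e-2, gt=0)
    a_sys: float = Field(1.0, gt=0, le=1)
    a_det: float = Field(1.0, gt=0, le=1)
    detector_area_m2: float = Field(1e-12, gt=0)
    dark_current: float = Field(0.0, ge=0)
    read_noise: float = Field(0.0, ge=0)
    sigma_sys: float = Field(0.0, ge=0)
    eta: float = Field(0.21, gt=0)


class PhotothermalBlock(_Model):
    c_th: float = Field(1.0, gt=0)
    i_heat: float = Field(1.0, gt=0)
    phi_probe: float = Field(1e25, gt=0)


class ThermalBlock(_Model):
    kappa_w_mk: float = Field(0.6, gt=0)
    dt_target_k: float = Field(1.0, gt=0)
    beta_table: dict[float, float] | None = None


class SweepBlock(_Model):
    widths_nm: list[float] = Field(
        default_factory=lambda: list(map(float, range(10, 41))))
    aspect_ratios: list[float] = Field(
        default_factory=lambda: [round(2.0 + 0.1 * i, 2) for i in range(31)])
    mode: str = "constant_intensity"


class OutputBlock(_Model):
    directory: str = "runs"
    write_spectra: bool = True


class RunConfig(_Model):
    """Validated, fully resolved run configuration."""

    schema_version: int = 1
    seed: int = 0
    materials: MaterialsBlock = MaterialsBlock()
    scene: SceneBlock = SceneBlock()
    solver: SolverBlock = SolverBlock()
    detection: DetectionBlock = DetectionBlock()
    photothermal: PhotothermalBlock = PhotothermalBlock()
    thermal: ThermalBlock = ThermalBlock()
    sweep: SweepBlock = SweepBlock()
    output: OutputBlock = OutputBlock()

    # ---- factories for the domain objects -------------------------------
    def material_set(self) -> MaterialSet:
        m = self.materials
        return MaterialSet(n_water=m.n_water, n_glass=m.n_glass,
                           n_shell=m.n_shell, n_molecule=m.n_molecule)

    def build_scene(self) -> Scene:
        s = self.scene
        molecule = None
        if s.molecule is not None:
            d = s.molecule.diameter_nm
            if d is None:
                d = (sphere_diameter_from_mass(s.molecule.mw_kda,
                                               s.molecule.density_g_cm3)
                     if s.molecule.mw_kda is not None else 5.0)
            molecule = MoleculeSpec(shape=s.molecule.shape,
                                    equivalent_diameter_nm=d,
                                    refractive_index=s.molecule.n)
        return build_scene(
            rod=NanorodGeometry(s.rod.diameter_nm, s.rod.aspect_ratio),
            shell=ShellSpec(s.shell.thickness_nm, s.shell.n),
            molecule=molecule,
            site=BindingSite(plane=s.site.plane, index=s.site.index),
            materials=self.material_set(),
            substrate_enabled=s.substrate.enabled,
            gap_to_substrate_nm=s.substrate.gap_nm,
        )

    def solver_settings(self) -> SolverSettings:
        s = self.solver
        return SolverSettings(
            polarizability_model=s.polarizability_model,
            tolerance=s.tolerance,
            max_iterations=s.max_iterations,
            substrate_model=s.substrate_model,
            single_precision=s.single_precision,
        )

    def spectrum_plan(self) -> SpectrumPlan:
        s = self.solver
        return SpectrumPlan(
            voxel_size_nm=s.voxel_size_nm,
            voxel_fraction=s.voxel_fraction,
            molecule_representation=s.molecule_representation,
            settings=self.solver_settings(),
        )

    def detection_config(self) -> DetectionConfig:
        d = self.detection
        return DetectionConfig(
            intensity_W_m2=d.intensity_W_m2, bandwidth_nm=d.bandwidth_nm,
            dt_s=d.dt_s, a_sys=d.a_sys, a_det=d.a_det,
            detector_area_m2=d.detector_area_m2,
            dark_current_cps=d.dark_current,
            read_noise_counts=d.read_noise,
            sigma_sys_counts=d.sigma_sys,
        )

    def photothermal_params(self) -> PhotothermalParams:
        p = self.photothermal
        return PhotothermalParams(c_th_um2_per_W=p.c_th,
                                  i_heat_W_m2=p.i_heat,
                                  phi_probe=p.phi_probe)

    def thermal_params(self) -> ThermalParams:
        t = self.thermal
        kw = {"kappa_w_m_k": t.kappa_w_mk, "dT_target_K": t.dt_target_k}
        if t.beta_table is not None:
            kw["beta_table"] = {float(k): float(v)
                                for k, v in t.beta_table.items()}
        return ThermalParams(**kw)

    def size_grid(self) -> SizeGrid:
        return SizeGrid(widths_nm=tuple(self.sweep.widths_nm),
                        aspect_ratios=tuple(self.sweep.aspect_ratios))


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML configuration; defaults fill absent keys.

    ``None`` or an empty file yields the all-defaults configuration.
    Schema violations raise with the offending keys named.
    """
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)


def config_hash(config: RunConfig) -> str:
    """Content hash of the resolved configuration (sha256, hex)."""
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def write_outputs(results: dict, out_dir: str | Path,
                  config: RunConfig | None = None,
                  seed: int | None = None) -> dict:
    """Write result artifacts and a provenance manifest.

    ``results`` maps artifact names to pandas DataFrames (written as CSV)
    or JSON-serializable objects (written as JSON).  Returns the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config if config is not None else RunConfig()
    written = {}
    for name, obj in results.items():
        if hasattr(obj, "to_csv"):
            path = out / f"{name}.csv"
            obj.to_csv(path, index=False)
        else:
            path = out / f"{name}.json"
            path.write_text(json.dumps(obj, indent=2, default=float))
        written[name] = path.name
    manifest = {
        "software_version": __version__,
        "config": config.model_dump(mode="json"),
        "config_hash": config_hash(config),
        "seed": config.seed if seed is None else seed,
        "artifacts": written,
        "timestamp_unix": time.time(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
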