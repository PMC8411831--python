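"""Optical material properties: tabulated gold and constant-index dielectrics.

Gold is described by the tabulated complex refractive index of evaporated
films measured by Johnson and Christy (1972); all other materials (water,
glass, functionalization shell, protein) are modelled as non-dispersive,
lossless dielectrics with a single real refractive index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "DielectricTable",
    "MaterialSet",
    "load_gold_table",
    "gold_permittivity",
]

#: Default constant refractive indices (visible/NIR values).
N_WATER = 1.33
N_GLASS = 1.52
N_SHELL = 1.45  # PEG functionalization / passivation layer
N_MOLECULE = 1.57  # water-free streptavidin


@dataclass(frozen=True)
class DielectricTable:
    """Tabulated complex refractive index n + ik versus vacuum wavelength.

    Parameters
    ----------
    wavelengths_nm : ndarray
        Strictly increasing vacuum wavelengths in nm.
    n, k : ndarray
        Real refractive index and extinction coefficient at each node;
        ``k >= 0`` everywhere.
    """

    wavelengths_nm: np.ndarray
    n: np.ndarray
    k: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        n = np.asarray(self.n, dtype=float)
        k = np.asarray(self.k, dtype=float)
        if w.ndim != 1 or w.size < 2:
            raise ValueError("table needs at least two wavelength nodes")
        if not (np.diff(w) > 0).all():
            raise ValueError("wavelengths must be strictly increasing")
        if n.shape != w.shape or k.shape != w.shape:
            raise ValueError("n and k must match the wavelength grid")
        if (k < 0).any():
            raise ValueError("extinction coefficient k must be >= 0")
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "k", k)

    @property
    def band(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])

    def refractive_index(self, wavelength_nm) -> np.ndarray | complex:
        """Linearly interpolated complex refractive index n + ik."""
        lam = np.asarray(wavelength_nm, dtype=float)
        lo, hi = self.band
        if (lam < lo).any() or (lam > hi).any():
            raise ValueError(
                f"wavelength outside tabulated band [{lo:.1f}, {hi:.1f}] nm"
            )
        n = np.interp(lam, self.wavelengths_nm, self.n)
        k = np.interp(lam, self.wavelengths_nm, self.k)
        out = n + 1j * k
        return complex(out) if np.isscalar(wavelength_nm) else out

    def permittivity(self, wavelength_nm):
        """Complex relative permittivity (n + ik)**2."""
        m = self.refractive_index(wavelength_nm)
        return m * m


def load_gold_table() -> DielectricTable:
    """Load the bundled Johnson–Christy gold n, k table."""
    ref = resources.files("plasmonsense.data") / "gold_johnson_christy.txt"
    with resources.as_file(ref) as path:
        data = np.loadtxt(path)
    return DielectricTable(data[:, 0], data[:, 1], data[:, 2])


def gold_permittivity(table: DielectricTable, wavelength_nm):
    """Complex relative permittivity of gold, linearly interpolating n and k.

    Interpolation is linear in n and in k (not in epsilon), which is
    monotone-safe on sparse tables and matches common DDA practice.
    """
    return table.permittivity(wavelength_nm)


@dataclass(frozen=True)
class MaterialSet:
    """All materials of the biosensor model.

    Constant indices are real and >= 1; gold is dispersive and lossy.
    """

    n_water: float = N_WATER
    n_glass: float = N_GLASS
    n_shell: float = N_SHELL
    n_molecule: float = N_MOLECULE
    gold: DielectricTable = field(default_factory=load_gold_table)

    def __post_init__(self) -> None:
        for name in ("n_water", "n_glass", "n_shell", "n_molecule"):
            v = getattr(self, name)
            if not np.isreal(v) or v < 1.0:
                raise ValueError(f"{name} must be real and >= 1, got {v!r}")

    def permittivity(self, material: str, wavelength_nm):
        """Relative permittivity of a named material at a wavelength."""
        if material == "gold":
            return gold_permittivity(self.gold, wavelength_nm)
        try:
            n = {
                "water": self.n_water,
                "glass": self.n_glass,
                "shell": self.n_shell,
                "molecule": self.n_molecule,
            }[material]
        except KeyError:
            raise ValueError(f"unknown material {material!r}") from None
        return complex(n * n)
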