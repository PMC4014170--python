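"""Photon interaction data and the ^125I seed emission spectrum.

The packaged tables cover 2-40 keV for the six materials the phantom
problem needs (water, PMMA, air, GRD glass, titanium, silver).  Each table
carries mass attenuation coefficients split into photoelectric and
incoherent parts (coherent scattering is excluded so the transport engine
and its tables stay self-consistent) plus the mass energy-absorption
coefficient used by the track-length kerma estimator.  Interpolation is
log-log, the convention for photon cross-section data.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["MaterialTable", "PhotonSpectrum", "default_materials", "default_spectrum"]

_COLUMNS = ("mu_pe", "mu_incoh", "mu_total", "mu_en")


def _data_path(name: str):
    return resources.files("brachyfit.data").joinpath(name)


@dataclass
class _Material:
    name: str
    density: float  # g/cm^3
    energy_kev: np.ndarray
    coeffs: dict  # column -> cm^2/g on energy grid


class MaterialTable:
    """Mass attenuation / energy-absorption coefficients for a set of materials."""

    def __init__(self, materials: dict[str, _Material]):
        self._materials = materials
        for m in materials.values():
            self._validate(m)

    @staticmethod
    def _validate(m: _Material) -> None:
        e = m.energy_kev
        if not np.all(np.diff(e) > 0):
            raise ValueError(f"{m.name}: energy grid must be strictly increasing")
        for col in _COLUMNS:
            if np.any(m.coeffs[col] <= 0):
                raise ValueError(f"{m.name}: {col} must be positive everywhere")
        total = m.coeffs["mu_pe"] + m.coeffs["mu_incoh"]
        if np.any(np.abs(total / m.coeffs["mu_total"] - 1.0) > 1e-3):
            raise ValueError(f"{m.name}: mu_total != mu_pe + mu_incoh within 0.1%")

    @classmethod
    def from_package_data(cls, names=("water", "pmma", "air", "glass", "titanium", "silver")):
        mats = {}
        for name in names:
            text = _data_path(f"material_{name}.csv").read_text().splitlines()
            header = {}
            body_start = 0
            for i, line in enumerate(text):
                if line.startswith("#"):
                    if ":" in line:
                        k, _, v = line.lstrip("# ").partition(":")
                        header[k.strip()] = v.strip()
                else:
                    body_start = i
                    break
            import io
            df = pd.read_csv(io.StringIO("\n".join(text[body_start:])))
            mats[name] = _Material(
                name=name,
                density=float(header["density_g_cm3"]),
                energy_kev=df["energy_kev"].to_numpy(),
                coeffs={c: df[c].to_numpy() for c in _COLUMNS},
            )
        return cls(mats)

    @property
    def names(self) -> list[str]:
        return list(self._materials)

    def __contains__(self, name: str) -> bool:
        return name in self._materials

    def density(self, material: str) -> float:
        return self._materials[material].density

    def energy_range_kev(self, material: str) -> tuple[float, float]:
        e = self._materials[material].energy_kev
        return float(e[0]), float(e[-1])

    def _lookup(self, material: str, column: str, e_kev) -> np.ndarray:
        m = self._materials[material]
        e = np.asarray(e_kev, dtype=float)
        lo, hi = m.energy_kev[0], m.energy_kev[-1]
        if np.any(e < lo) or np.any(e > hi):
            raise ValueError(
                f"energy {e} keV outside table range [{lo}, {hi}] for {material}"
            )
        out = np.exp(np.interp(np.log(e), np.log(m.energy_kev), np.log(m.coeffs[column])))
        return out if out.shape else float(out)

    # mass coefficients, cm^2/g
    def mu_total(self, material, e_kev):
        return self._lookup(material, "mu_total", e_kev)

    def mu_pe(self, material, e_kev):
        return self._lookup(material, "mu_pe", e_kev)

    def mu_incoh(self, material, e_kev):
        return self._lookup(material, "mu_incoh", e_kev)

    def mu_en(self, material, e_kev):
        return self._lookup(material, "mu_en", e_kev)

    def mu_linear(self, material, e_kev):
        """Linear attenuation coefficient, 1/cm."""
        return self.mu_total(material, e_kev) * self.density(material)

    def photoelectric_fraction(self, material, e_kev):
        """P(photoelectric | interaction) at energy e_kev."""
        return self.mu_pe(material, e_kev) / self.mu_total(material, e_kev)

    def resample(self, material: str, grid_kev: np.ndarray, column: str) -> np.ndarray:
        """Log-log resample of one coefficient onto an arbitrary grid (engine use)."""
        return np.asarray(self._lookup(material, column, grid_kev), dtype=float)


@dataclass(frozen=True)
class PhotonSpectrum:
    """Discrete photon line spectrum of a sealed source.

    ``yields`` are photons per disintegration escaping the notional bare
    radionuclide; for the packaged 6711 spectrum the total is exactly
    1.5951 photons/disintegration.
    """

    energies_kev: np.ndarray
    yields: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.energies_kev, float)
        y = np.asarray(self.yields, float)
        if e.shape != y.shape or e.ndim != 1:
            raise ValueError("energies and yields must be matching 1-D arrays")
        if np.any(y < 0) or np.any(e <= 0):
            raise ValueError("energies must be positive and yields non-negative")
        object.__setattr__(self, "energies_kev", e)
        object.__setattr__(self, "yields", y)

    @property
    def total_yield(self) -> float:
        return float(self.yields.sum())

    @property
    def probabilities(self) -> np.ndarray:
        return self.yields / self.yields.sum()

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.choice(self.energies_kev, size=n, p=self.probabilities)

    @classmethod
    def from_package_data(cls) -> "PhotonSpectrum":
        with _data_path("i125_6711_spectrum.csv").open() as fh:
            df = pd.read_csv(fh, comment="#")
        return cls(df["energy_kev"].to_numpy(), df["photons_per_decay"].to_numpy())


def default_materials() -> MaterialTable:
    return MaterialTable.from_package_data()


def default_spectrum() -> PhotonSpectrum:
    return PhotonSpectrum.from_package_data()
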