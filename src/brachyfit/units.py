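"""Unit-conversion chain: per-photon dose -> dose per unit air kerma strength.

An MC kernel is scored in Gy per emitted photon.  The chain to Gy per unit
air kerma strength (U = uGy m^2/h) integrated over the exposure is:

    per photon  --x 1.5951-->  per disintegration ("actual activity")
                --x 3.7e7 x 3600 x t_h-->  per mCi of actual activity
                --x 1.8-->  per mCi of apparent activity
                --/ 1.27 (U/mCi)-->  per U

The 1.8 apparent-activity normalization multiplies (one apparent mCi
represents more contained activity than a bare point source would need);
its direction is a configurable convention, see docs/methods.md.  Doses
scored in the GRD glass convert to dose-to-water through the ratio of mass
energy-absorption coefficients at an effective energy (28 keV default).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import MaterialTable, default_materials

__all__ = ["ConversionConstants", "per_photon_to_per_unit_strength",
           "glass_to_water", "DEFAULT_EFFECTIVE_ENERGY_KEV"]

DEFAULT_EFFECTIVE_ENERGY_KEV = 28.0


@dataclass(frozen=True)
class ConversionConstants:
    photons_per_disintegration: float = 1.5951
    apparent_activity_normalization: float = 1.8
    air_kerma_per_mci: float = 1.27  # U per apparent mCi
    disintegrations_per_mci_s: float = 3.7e7

    def __post_init__(self):
        if min(self.photons_per_disintegration, self.apparent_activity_normalization,
               self.air_kerma_per_mci, self.disintegrations_per_mci_s) <= 0:
            raise ValueError("all conversion constants must be positive")


def per_photon_to_per_unit_strength(dose_per_photon,
                                    exposure_time_h: float,
                                    constants: ConversionConstants | None = None):
    """Convert Gy/photon to Gy per U of air kerma strength over the exposure."""
    c = constants or ConversionConstants()
    if exposure_time_h <= 0:
        raise ValueError("exposure time must be positive")
    d = np.asarray(dose_per_photon, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    out = (d * c.photons_per_disintegration * c.disintegrations_per_mci_s
           * 3600.0 * exposure_time_h * c.apparent_activity_normalization
           / c.air_kerma_per_mci)
    return out if out.shape else float(out)


def glass_to_water(dose_glass,
                   e_eff_kev: float = DEFAULT_EFFECTIVE_ENERGY_KEV,
                   materials: MaterialTable | None = None):
    """Absorbed dose to glass -> absorbed dose to water at the effective energy."""
    m = materials or default_materials()
    factor = m.mu_en("water", e_eff_kev) / m.mu_en("glass", e_eff_kev)
    d = np.asarray(dose_glass, dtype=float)
    out = d * factor
    return out if out.shape else float(out)


def water_to_glass(dose_water,
                   e_eff_kev: float = DEFAULT_EFFECTIVE_ENERGY_KEV,
                   materials: MaterialTable | None = None):
    """Inverse of :func:`glass_to_water` (round trip is the identity)."""
    m = materials or default_materials()
    factor = m.mu_en("glass", e_eff_kev) / m.mu_en("water", e_eff_kev)
    d = np.asarray(dose_water, dtype=float)
    out = d * factor
    return out if out.shape else float(out)
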