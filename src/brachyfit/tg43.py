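"""TG-43 point-source dose formalism as a fast analytic kernel backend.

Dose rate at distance r from a seed of air kerma strength S_K:

    Ddot(r) = S_K * Lambda * (r0/r)^2 * g(r) * phi_an(r),        r0 = 1 cm

with the dose-rate constant Lambda [cGy/(h U)], radial dose function g(r)
(g(r0) = 1) and 1-D anisotropy factor phi_an(r) taken from the packaged
consensus-style dataset for the model-6711 seed.  The formalism assumes a
full-scatter water geometry and no interseed attenuation, so it is a quick
forward model and cross-check only: near the phantom surface, where
backscatter is missing, it overestimates dose.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .geometry import (DetectorSite, PhantomLayout, SeedPose,
                       seed_position_cartesian, site_position_cartesian)

__all__ = ["TG43Dataset", "tg43_dose_rate", "tg43_kernel", "load_tg43_dataset"]


@dataclass(frozen=True)
class TG43Dataset:
    dose_rate_constant: float  # cGy / (h U)
    r_cm: np.ndarray
    g: np.ndarray
    phi_an: np.ndarray
    reference_r_cm: float = 1.0

    def __post_init__(self):
        r = np.asarray(self.r_cm, float)
        g = np.asarray(self.g, float)
        p = np.asarray(self.phi_an, float)
        if not np.all(np.diff(r) > 0):
            raise ValueError("r grid must be strictly increasing")
        if np.any(g <= 0) or np.any(p <= 0):
            raise ValueError("g(r) and phi_an(r) must be positive")
        g_at_r0 = np.interp(self.reference_r_cm, r, g)
        if abs(g_at_r0 - 1.0) > 1e-6:
            raise ValueError("g must equal 1 at the reference radius")
        object.__setattr__(self, "r_cm", r)
        object.__setattr__(self, "g", g)
        object.__setattr__(self, "phi_an", p)

    def span(self) -> tuple[float, float]:
        return float(self.r_cm[0]), float(self.r_cm[-1])


def load_tg43_dataset() -> TG43Dataset:
    path = resources.files("brachyfit.data").joinpath("tg43_6711.csv")
    lam = None
    for line in path.read_text().splitlines():
        if line.startswith("#") and "dose_rate_constant_cGy_h_U" in line:
            lam = float(line.split(":")[1])
    if lam is None:
        raise ValueError("dataset file lacks a dose_rate_constant header")
    with path.open() as fh:
        df = pd.read_csv(fh, comment="#")
    return TG43Dataset(lam, df["r_cm"].to_numpy(), df["g"].to_numpy(),
                       df["phi_an"].to_numpy())


def tg43_dose_rate(s_k: float, r_cm, dataset: TG43Dataset | None = None):
    """Dose rate in water, cGy/h, at distance(s) r from a single seed."""
    ds = dataset or load_tg43_dataset()
    if s_k < 0:
        raise ValueError("air kerma strength must be >= 0")
    r = np.asarray(r_cm, dtype=float)
    lo, hi = ds.span()
    if np.any(r < lo) or np.any(r > hi):
        raise ValueError(f"r outside dataset span [{lo}, {hi}] cm")
    g = np.interp(r, ds.r_cm, ds.g)
    phi = np.interp(r, ds.r_cm, ds.phi_an)
    out = s_k * ds.dose_rate_constant * (ds.reference_r_cm / r) ** 2 * g * phi
    return out if out.shape else float(out)


def tg43_kernel(layout: PhantomLayout,
                seeds: list[SeedPose],
                sites: list[DetectorSite],
                exposure_time_h: float = 24.0,
                dataset: TG43Dataset | None = None):
    """Per-site, per-seed dose in Gy for unit S_K over the exposure.

    Superposition without interseed attenuation; returns a
    :class:`~brachyfit.regression.KernelMatrix` (zero model sigma).
    """
    from .regression import KernelMatrix  # deferred: avoid cycle

    ds = dataset or load_tg43_dataset()
    if exposure_time_h <= 0:
        raise ValueError("exposure time must be positive")
    site_pos = np.array([site_position_cartesian(s, layout) for s in sites])
    seed_pos = np.array([seed_position_cartesian(s) for s in seeds])
    dist = np.linalg.norm(site_pos[:, None, :] - seed_pos[None, :, :], axis=2)
    dose = tg43_dose_rate(1.0, dist, ds) * exposure_time_h / 100.0  # cGy -> Gy
    values = pd.DataFrame(dose, index=[s.site_id for s in sites],
                          columns=[s.seed_id for s in seeds])
    sigma = values * 0.0
    return KernelMatrix(values=values, sigma=sigma, exposure_time_h=exposure_time_h)
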