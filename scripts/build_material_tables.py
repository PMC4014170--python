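"""Regenerate the packaged photon-interaction fixture tables (2-40 keV).

Construction (documented in docs/methods.md):

* photoelectric mass attenuation per element: power law anchored at 10 keV,
  tau/rho(E) = tau10 * (10/E)**n, with anchor values consistent with the
  standard compilations; silver carries its K edge at 25.514 keV as a
  two-branch power law.
* incoherent scattering: free-electron Klein-Nishina cross section per
  electron times electrons per gram (binding / scattering-function
  corrections neglected).
* mu_total = mu_pe + mu_incoh (coherent scattering excluded by design, so
  the transport engine and its tables stay self-consistent).
* mu_en = mu_pe + mu_incoh * f_tr(E), where f_tr is the Klein-Nishina mean
  energy-transfer fraction (photoelectric events deposit locally;
  fluorescence escape neglected).

Run from the repository root:  python scripts/build_material_tables.py
"""
from __future__ import annotations

import pathlib

import numpy as np
from scipy.integrate import quad

OUT = pathlib.Path(__file__).resolve().parents[1] / "src" / "brachyfit" / "data"

R_E_CM = 2.8179403262e-13  # classical electron radius
N_A = 6.02214076e23
MEC2_KEV = 510.99895
AG_K_EDGE_KEV = 25.514

# symbol -> (A, tau10 [cm^2/g at 10 keV], n)
ELEMENTS = {
    "H": (1.008, 1.2e-5, 3.30),
    "C": (12.011, 2.08, 3.24),
    "N": (14.007, 3.42, 3.25),
    "O": (15.999, 5.31, 3.25),
    "Na": (22.990, 14.6, 3.20),
    "Al": (26.982, 25.4, 3.18),
    "P": (30.974, 41.0, 3.15),
    "Ar": (39.948, 63.0, 3.10),
    "Ti": (47.867, 108.0, 2.95),
    "Ag": (107.868, 66.0, 2.75),  # below K edge; above handled separately
}

# material -> (density g/cm^3, {element: weight fraction})
MATERIALS = {
    "water": (0.998, {"H": 0.111898, "O": 0.888102}),
    "pmma": (1.190, {"H": 0.080538, "C": 0.599848, "O": 0.319614}),
    "air": (1.205e-3, {"C": 0.000124, "N": 0.755268, "O": 0.231781, "Ar": 0.012827}),
    # GD-302M-type silver-activated phosphate glass
    "glass": (2.610, {"Na": 0.1100, "Al": 0.0612, "P": 0.3155, "O": 0.5116, "Ag": 0.0017}),
    "titanium": (4.506, {"Ti": 1.0}),
    "silver": (10.490, {"Ag": 1.0}),
}


def tau_element(sym: str, e_kev: np.ndarray) -> np.ndarray:
    a, tau10, n = ELEMENTS[sym]
    tau = tau10 * (10.0 / e_kev) ** n
    if sym == "Ag":
        above = e_kev >= AG_K_EDGE_KEV
        tau = np.where(above, 30.0 * (30.0 / e_kev) ** 2.75, tau)
    return tau


def sigma_kn_per_electron(e_kev: np.ndarray) -> np.ndarray:
    """Total Klein-Nishina cross section per free electron [cm^2]."""
    a = np.asarray(e_kev, dtype=float) / MEC2_KEV
    t1 = (1 + a) / a**2 * (2 * (1 + a) / (1 + 2 * a) - np.log(1 + 2 * a) / a)
    t2 = np.log(1 + 2 * a) / (2 * a)
    t3 = (1 + 3 * a) / (1 + 2 * a) ** 2
    return 2 * np.pi * R_E_CM**2 * (t1 + t2 - t3)


def kn_mean_transfer_fraction(e_kev: float) -> float:
    """Mean fraction of photon energy given to the Compton electron."""
    a = e_kev / MEC2_KEV
    xmin = 1.0 / (1.0 + 2.0 * a)

    def f(x):  # dsigma/dx up to a constant; x = E'/E
        cos_t = 1.0 - (1.0 / x - 1.0) / a
        return x + 1.0 / x - (1.0 - cos_t**2)

    norm, _ = quad(f, xmin, 1.0)
    mean_x, _ = quad(lambda x: x * f(x), xmin, 1.0)
    return 1.0 - mean_x / norm


def z_over_a(fracs: dict[str, float]) -> float:
    z_of = {"H": 1, "C": 6, "N": 7, "O": 8, "Na": 11, "Al": 13, "P": 15,
            "Ar": 18, "Ti": 22, "Ag": 47}
    return sum(w * z_of[s] / ELEMENTS[s][0] for s, w in fracs.items())


def energy_grid(fracs: dict[str, float]) -> np.ndarray:
    grid = np.geomspace(2.0, 40.0, 64)
    if "Ag" in fracs:
        grid = np.sort(np.concatenate([grid, [AG_K_EDGE_KEV - 1e-3, AG_K_EDGE_KEV + 1e-3]]))
    return grid


def build() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name, (rho, fracs) in MATERIALS.items():
        e = energy_grid(fracs)
        mu_pe = sum(w * tau_element(s, e) for s, w in fracs.items())
        mu_incoh = N_A * z_over_a(fracs) * sigma_kn_per_electron(e)
        mu_total = mu_pe + mu_incoh
        f_tr = np.array([kn_mean_transfer_fraction(ei) for ei in e])
        mu_en = mu_pe + mu_incoh * f_tr
        path = OUT / f"material_{name}.csv"
        with path.open("w") as fh:
            fh.write(f"# material: {name}\n")
            fh.write(f"# density_g_cm3: {rho}\n")
            fh.write("# built by scripts/build_material_tables.py; coherent scattering excluded\n")
            fh.write("energy_kev,mu_pe,mu_incoh,mu_total,mu_en\n")
            for row in zip(e, mu_pe, mu_incoh, mu_total, mu_en):
                fh.write(",".join(f"{v:.6e}" for v in row) + "\n")
        print(f"wrote {path}")


if __name__ == "__main__":
    build()
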