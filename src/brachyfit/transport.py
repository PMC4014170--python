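"""Monte Carlo photon transport for per-seed unit-emission dose kernels.

Analog photon transport in the two-seed phantom: photons start isotropically
from the emitting seed's silver core surface with line energies drawn from
the ^125I(6711) spectrum, and are tracked through the seed bodies, water,
the PMMA wall and the surrounding air.  Interactions are photoelectric
absorption and incoherent (free-electron Klein-Nishina) scattering; the
kerma approximation applies (secondary electron ranges are tens of microns
at these energies), so absorbed dose in each glass rod dosimeter body is
scored with a track-length kerma estimator,

    D = sum over track segments of  L * E * (mu_en/rho)_glass(E) / V,

reported per emitted photon with a batch-based standard error.  The
non-emitting seed body is kept in the geometry so interseed attenuation is
included (it can be removed for sensitivity checks).

The inner loop is compiled with numba; a fixed rng seed with a fixed
history count reproduces results exactly (single-threaded deterministic
stream).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .geometry import (DetectorSite, PhantomLayout, SeedModel, SeedPose,
                       load_seed_model, seed_position_cartesian,
                       site_position_cartesian)
from .materials import MaterialTable, PhotonSpectrum, default_materials, default_spectrum

__all__ = [
    "TransportConfig", "KernelColumn", "GeometryLeakError",
    "run_kernel", "sample_interaction", "sample_compton",
    "analytic_primary_dose", "point_source_dose_mc",
]

MEC2_KEV = 510.99895
KEV_TO_GY_CM2_G = 1.602176634e-13  # keV * (cm^2/g) -> Gy * cm^2 (per photon/cm^2)

# material indices inside the engine
_MAT_ORDER = ("silver", "titanium", "water", "pmma", "air")
_N_GRID = 512
_EGRID = np.geomspace(2.0, 40.0, _N_GRID)
_LOGE0 = math.log(_EGRID[0])
_DLOGE = (math.log(_EGRID[-1]) - _LOGE0) / (_N_GRID - 1)

_BIG = 1.0e30
_EPS = 1.0e-9


class GeometryLeakError(RuntimeError):
    """A photon inside the geometry found no boundary along its flight path."""


@dataclass(frozen=True)
class TransportConfig:
    n_histories: int = 2_000_000
    rng_seed: int = 12345
    energy_cutoff_kev: float = 2.0
    score_primary_only: bool = False
    include_coherent: bool = False
    include_interseed: bool = True
    n_batches: int = 20

    def __post_init__(self):
        if self.n_histories < 1:
            raise ValueError("n_histories must be >= 1")
        if self.include_coherent:
            raise NotImplementedError(
                "coherent scattering is excluded from the packaged tables; "
                "transport is self-consistent without it")
        if self.n_batches < 2:
            raise ValueError("need at least 2 batches for a standard error")


@dataclass(frozen=True)
class KernelColumn:
    """Dose per emitted photon (to the detector glass) at every site."""

    seed_id: str
    site_ids: tuple
    dose_per_photon: np.ndarray  # Gy/photon
    mc_sigma: np.ndarray  # Gy/photon, batch standard error
    config: TransportConfig

    def __post_init__(self):
        if np.any(self.dose_per_photon < 0) or not np.all(np.isfinite(self.mc_sigma)):
            raise ValueError("doses must be >= 0 and errors finite")


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(inline="always")
def _interp(table, e_kev):
    x = (math.log(e_kev) - _LOGE0) / _DLOGE
    if x < 0.0:
        x = 0.0
    elif x > _N_GRID - 1.000001:
        x = _N_GRID - 1.000001
    i = int(x)
    f = x - i
    return table[i] * (1.0 - f) + table[i + 1] * f


@njit(inline="always")
def _sample_line(line_e, line_cdf):
    u = np.random.random()
    for i in range(line_cdf.shape[0]):
        if u <= line_cdf[i]:
            return line_e[i]
    return line_e[line_cdf.shape[0] - 1]


@njit(inline="always")
def _kn_sample(e_kev):
    """Klein-Nishina rejection sampling; returns (E_scattered, cos theta)."""
    a = e_kev / MEC2_KEV
    xmin = 1.0 / (1.0 + 2.0 * a)
    bound = xmin + 1.0 / xmin
    while True:
        x = xmin + (1.0 - xmin) * np.random.random()
        ct = 1.0 - (1.0 / x - 1.0) / a
        f = x + 1.0 / x - (1.0 - ct * ct)
        if np.random.random() * bound <= f:
            return e_kev * x, ct


@njit(inline="always")
def _isotropic():
    ct = 2.0 * np.random.random() - 1.0
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    ph = 2.0 * math.pi * np.random.random()
    return st * math.cos(ph), st * math.sin(ph), ct


@njit(inline="always")
def _rotate(ux, uy, uz, ct):
    """New unit direction at polar angle acos(ct) from (ux,uy,uz), uniform azimuth."""
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    ph = 2.0 * math.pi * np.random.random()
    cp = math.cos(ph)
    sp = math.sin(ph)
    if abs(uz) < 0.99999:
        s = math.sqrt(ux * ux + uy * uy)
        vx = uy / s
        vy = -ux / s
        vz = 0.0
    else:
        vx = 1.0
        vy = 0.0
        vz = 0.0
    # w = u x v
    wx = uy * vz - uz * vy
    wy = uz * vx - ux * vz
    wz = ux * vy - uy * vx
    nx = ct * ux + st * (cp * vx + sp * wx)
    ny = ct * uy + st * (cp * vy + sp * wy)
    nz = ct * uz + st * (cp * vz + sp * wz)
    n = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / n, ny / n, nz / n


@njit(inline="always")
def _dist_cyl(x, y, ux, uy, cx, cy, rr):
    dx = x - cx
    dy = y - cy
    a = ux * ux + uy * uy
    if a < 1e-20:
        return _BIG
    b = dx * ux + dy * uy
    c = dx * dx + dy * dy - rr * rr
    disc = b * b - a * c
    if disc <= 0.0:
        return _BIG
    sq = math.sqrt(disc)
    t = (-b - sq) / a
    if t > _EPS:
        return t
    t = (-b + sq) / a
    if t > _EPS:
        return t
    return _BIG


@njit(inline="always")
def _dist_plane(z, uz, zp):
    if abs(uz) < 1e-20:
        return _BIG
    t = (zp - z) / uz
    if t > _EPS:
        return t
    return _BIG


@njit
def _classify(x, y, z, seed_xy, seed_z, body_on,
              core_r2, core_hh, cap_r2, cap_hh,
              inner_r2, inner_hh, outer_r2, outer_hh, world_r2, world_hh):
    for i in range(seed_xy.shape[0]):
        if not body_on[i]:
            continue
        dx = x - seed_xy[i, 0]
        dy = y - seed_xy[i, 1]
        dz = abs(z - seed_z[i])
        r2 = dx * dx + dy * dy
        if r2 < core_r2 and dz < core_hh:
            return 0  # silver core
        if r2 < cap_r2 and dz < cap_hh:
            return 1  # titanium capsule
    r2 = x * x + y * y
    az = abs(z)
    if r2 < inner_r2 and az < inner_hh:
        return 2  # water
    if r2 < outer_r2 and az < outer_hh:
        return 3  # pmma
    if r2 < world_r2 and az < world_hh:
        return 4  # air
    return -1  # exterior


@njit
def _boundary_distance(x, y, z, ux, uy, uz, seed_xy, seed_z, body_on,
                       core_r, core_hh, cap_r, cap_hh,
                       inner_r, inner_hh, outer_r, outer_hh, world_r, world_hh):
    d = _BIG
    for i in range(seed_xy.shape[0]):
        if not body_on[i]:
            continue
        cx = seed_xy[i, 0]
        cy = seed_xy[i, 1]
        t = _dist_cyl(x, y, ux, uy, cx, cy, core_r)
        if t < d:
            d = t
        t = _dist_cyl(x, y, ux, uy, cx, cy, cap_r)
        if t < d:
            d = t
        for zp in (seed_z[i] - core_hh, seed_z[i] + core_hh,
                   seed_z[i] - cap_hh, seed_z[i] + cap_hh):
            t = _dist_plane(z, uz, zp)
            if t < d:
                d = t
    t = _dist_cyl(x, y, ux, uy, 0.0, 0.0, inner_r)
    if t < d:
        d = t
    t = _dist_cyl(x, y, ux, uy, 0.0, 0.0, outer_r)
    if t < d:
        d = t
    t = _dist_cyl(x, y, ux, uy, 0.0, 0.0, world_r)
    if t < d:
        d = t
    for zp in (-inner_hh, inner_hh, -outer_hh, outer_hh, -world_hh, world_hh):
        t = _dist_plane(z, uz, zp)
        if t < d:
            d = t
    return d


@njit(inline="always")
def _tally_segment(x, y, z, ux, uy, uz, s, escore,
                   det_xy, det_z, det_r, det_hh, det_inv_vol, tal_row):
    for j in range(det_xy.shape[0]):
        dx = x - det_xy[j, 0]
        dy = y - det_xy[j, 1]
        rj = det_r[j]
        # cheap reject: segment cannot reach the detector circle
        reach = s + rj
        if dx * dx + dy * dy > reach * reach:
            continue
        a = ux * ux + uy * uy
        if a < 1e-20:
            if dx * dx + dy * dy > rj * rj:
                continue
            t1 = 0.0
            t2 = s
        else:
            b = dx * ux + dy * uy
            c = dx * dx + dy * dy - rj * rj
            disc = b * b - a * c
            if disc <= 0.0:
                continue
            sq = math.sqrt(disc)
            t1 = (-b - sq) / a
            t2 = (-b + sq) / a
        # clip with the z slab of the rod
        dzc = det_z[j]
        hh = det_hh[j]
        if abs(uz) < 1e-20:
            if abs(z - dzc) > hh:
                continue
        else:
            tz1 = (dzc - hh - z) / uz
            tz2 = (dzc + hh - z) / uz
            if tz1 > tz2:
                tz1, tz2 = tz2, tz1
            if tz1 > t1:
                t1 = tz1
            if tz2 < t2:
                t2 = tz2
        if t1 < 0.0:
            t1 = 0.0
        if t2 > s:
            t2 = s
        if t2 > t1:
            tal_row[j] += (t2 - t1) * escore * det_inv_vol[j]


@njit
def _run_phantom(n_hist, rng_seed, emit_idx, primary_only, cutoff_kev, n_batches,
                 seed_xy, seed_z, body_on,
                 core_r, core_hh, cap_r, cap_hh,
                 inner_r, inner_hh, outer_r, outer_hh, world_r, world_hh,
                 det_xy, det_z, det_r, det_hh, det_inv_vol,
                 line_e, line_cdf,
                 mu_lin, p_pe, mu_en_det):
    np.random.seed(rng_seed)
    n_det = det_xy.shape[0]
    tal = np.zeros((n_batches, n_det))
    n_leak = 0
    core_r2 = core_r * core_r
    cap_r2 = cap_r * cap_r
    inner_r2 = inner_r * inner_r
    outer_r2 = outer_r * outer_r
    world_r2 = world_r * world_r
    sx = seed_xy[emit_idx, 0]
    sy = seed_xy[emit_idx, 1]
    sz = seed_z[emit_idx]
    area_lat = 2.0 * math.pi * core_r * (2.0 * core_hh)
    area_ends = 2.0 * math.pi * core_r2
    p_lat = area_lat / (area_lat + area_ends)
    r_emit = core_r * (1.0 + 1e-9)
    for h in range(n_hist):
        b = (h * n_batches) // n_hist
        # emission point uniform on the core surface (iodine adsorbed on silver)
        if np.random.random() < p_lat:
            ang = 2.0 * math.pi * np.random.random()
            x = sx + r_emit * math.cos(ang)
            y = sy + r_emit * math.sin(ang)
            z = sz + (2.0 * np.random.random() - 1.0) * core_hh
        else:
            rr = core_r * math.sqrt(np.random.random())
            ang = 2.0 * math.pi * np.random.random()
            x = sx + rr * math.cos(ang)
            y = sy + rr * math.sin(ang)
            z = sz + core_hh * (1.0 + 1e-9) * (1.0 if np.random.random() < 0.5 else -1.0)
        ux, uy, uz = _isotropic()
        e = _sample_line(line_e, line_cdf)
        escore = e * _interp(mu_en_det, e) * KEV_TO_GY_CM2_G
        while True:
            mat = _classify(x, y, z, seed_xy, seed_z, body_on,
                            core_r2, core_hh, cap_r2, cap_hh,
                            inner_r2, inner_hh, outer_r2, outer_hh,
                            world_r2, world_hh)
            if mat < 0:
                break  # escaped the world
            db = _boundary_distance(x, y, z, ux, uy, uz, seed_xy, seed_z, body_on,
                                    core_r, core_hh, cap_r, cap_hh,
                                    inner_r, inner_hh, outer_r, outer_hh,
                                    world_r, world_hh)
            if db >= _BIG:
                n_leak += 1
                break
            mu = _interp(mu_lin[mat], e)
            s_int = -math.log(np.random.random()) / mu
            if s_int < db:
                _tally_segment(x, y, z, ux, uy, uz, s_int, escore,
                               det_xy, det_z, det_r, det_hh, det_inv_vol, tal[b])
                x += s_int * ux
                y += s_int * uy
                z += s_int * uz
                if primary_only:
                    break
                if np.random.random() < _interp(p_pe[mat], e):
                    break  # photoelectric absorption
                e, ct = _kn_sample(e)
                if e < cutoff_kev:
                    break  # residual energy deposited on the spot
                ux, uy, uz = _rotate(ux, uy, uz, ct)
                escore = e * _interp(mu_en_det, e) * KEV_TO_GY_CM2_G
            else:
                _tally_segment(x, y, z, ux, uy, uz, db, escore,
                               det_xy, det_z, det_r, det_hh, det_inv_vol, tal[b])
                step = db + 1e-7
                x += step * ux
                y += step * uy
                z += step * uz
    return tal, n_leak


@njit
def _run_point_source(n_hist, rng_seed, e0, primary_only, cutoff_kev, n_batches,
                      shell_r1, shell_r2, shell_inv_vol,
                      mu_lin_1d, p_pe_1d, mu_en_1d, r_kill):
    """Point isotropic source at the origin of an infinite uniform medium;
    track-length kerma tallies in concentric spherical shells."""
    np.random.seed(rng_seed)
    n_sh = shell_r1.shape[0]
    tal = np.zeros((n_batches, n_sh))
    for h in range(n_hist):
        b = (h * n_batches) // n_hist
        x = 0.0
        y = 0.0
        z = 0.0
        ux, uy, uz = _isotropic()
        e = e0
        escore = e * _interp(mu_en_1d, e) * KEV_TO_GY_CM2_G
        while True:
            mu = _interp(mu_lin_1d, e)
            s = -math.log(np.random.random()) / mu
            # shell tallies along this segment
            b0 = x * ux + y * uy + z * uz
            c0 = x * x + y * y + z * z
            for j in range(n_sh):
                # chord inside outer sphere minus chord inside inner sphere
                lout = 0.0
                lin = 0.0
                disc = b0 * b0 - (c0 - shell_r2[j] * shell_r2[j])
                if disc > 0.0:
                    sq = math.sqrt(disc)
                    t1 = -b0 - sq
                    t2 = -b0 + sq
                    if t1 < 0.0:
                        t1 = 0.0
                    if t2 > s:
                        t2 = s
                    if t2 > t1:
                        lout = t2 - t1
                if lout > 0.0:
                    disc = b0 * b0 - (c0 - shell_r1[j] * shell_r1[j])
                    if disc > 0.0:
                        sq = math.sqrt(disc)
                        t1 = -b0 - sq
                        t2 = -b0 + sq
                        if t1 < 0.0:
                            t1 = 0.0
                        if t2 > s:
                            t2 = s
                        if t2 > t1:
                            lin = t2 - t1
                    tal[b, j] += (lout - lin) * escore * shell_inv_vol[j]
            x += s * ux
            y += s * uy
            z += s * uz
            if primary_only:
                break
            if x * x + y * y + z * z > r_kill * r_kill:
                break
            if np.random.random() < _interp(p_pe_1d, e):
                break
            e, ct = _kn_sample(e)
            if e < cutoff_kev:
                break
            ux, uy, uz = _rotate(ux, uy, uz, ct)
            escore = e * _interp(mu_en_1d, e) * KEV_TO_GY_CM2_G
    return tal


# ---------------------------------------------------------------------------
# python drivers
# ---------------------------------------------------------------------------

def _engine_tables(materials: MaterialTable):
    mu_lin = np.empty((len(_MAT_ORDER), _N_GRID))
    p_pe = np.empty((len(_MAT_ORDER), _N_GRID))
    for i, name in enumerate(_MAT_ORDER):
        rho = materials.density(name)
        mu_lin[i] = materials.resample(name, _EGRID, "mu_total") * rho
        p_pe[i] = (materials.resample(name, _EGRID, "mu_pe")
                   / materials.resample(name, _EGRID, "mu_total"))
    return mu_lin, p_pe


def _batch_stats(tal: np.ndarray, n_hist: int, n_batches: int):
    # batch b holds histories h with (h * n_batches) // n_hist == b, i.e.
    # h in [ceil(b n/nb), ceil((b+1) n/nb))
    edges = -(-np.arange(n_batches + 1) * n_hist // n_batches)
    counts = np.diff(edges).astype(float)
    means = tal / counts[:, None]
    mean = tal.sum(axis=0) / n_hist
    se = means.std(axis=0, ddof=1) / math.sqrt(n_batches)
    return mean, se


def run_kernel(seed_id: str,
               layout: PhantomLayout,
               seeds: list[SeedPose],
               sites: list[DetectorSite],
               config: TransportConfig,
               materials: MaterialTable | None = None,
               spectrum: PhotonSpectrum | None = None,
               seed_model: SeedModel | None = None) -> KernelColumn:
    """Dose per emitted photon at every detector site for one emitting seed.

    Both seed bodies are present in the geometry (interseed attenuation)
    unless ``config.include_interseed`` is False, in which case the
    non-emitting body is replaced by the surrounding water.
    """
    materials = materials or default_materials()
    spectrum = spectrum or default_spectrum()
    seed_model = seed_model or load_seed_model()
    for name in (layout.wall_material, layout.interior_material, layout.exterior_material):
        if name not in materials:
            raise ValueError(f"material {name!r} not in the material table")

    ids = [s.seed_id for s in seeds]
    if seed_id not in ids:
        raise ValueError(f"unknown seed_id {seed_id!r}")
    emit_idx = ids.index(seed_id)

    seed_xy = np.array([seed_position_cartesian(s)[:2] for s in seeds])
    seed_z = np.array([s.z for s in seeds])
    body_on = np.ones(len(seeds), dtype=np.bool_)
    if not config.include_interseed:
        body_on[:] = False
        body_on[emit_idx] = True

    det_pos = np.array([site_position_cartesian(s, layout) for s in sites])
    det_r = np.array([s.body_diameter / 2 for s in sites])
    det_hh = np.array([s.body_length / 2 for s in sites])
    det_inv_vol = 1.0 / (math.pi * det_r**2 * 2 * det_hh)

    mu_lin, p_pe = _engine_tables(materials)
    det_mats = {s.material for s in sites}
    if len(det_mats) != 1:
        raise ValueError("all detector bodies must share one material")
    mu_en_det = materials.resample(det_mats.pop(), _EGRID, "mu_en")

    if config.energy_cutoff_kev >= spectrum.energies_kev.min():
        raise ValueError("energy cutoff must lie below the lowest spectrum line")

    line_cdf = np.cumsum(spectrum.probabilities)
    line_cdf[-1] = 1.0

    tal, n_leak = _run_phantom(
        config.n_histories, config.rng_seed, emit_idx,
        config.score_primary_only, config.energy_cutoff_kev, config.n_batches,
        seed_xy, seed_z, body_on,
        seed_model.core_diameter / 2, seed_model.core_length / 2,
        seed_model.capsule_outer_diameter / 2, seed_model.capsule_length / 2,
        layout.inner_radius, layout.inner_half_length,
        layout.outer_radius, layout.length / 2,
        30.0, 30.0,
        det_pos[:, :2].copy(), det_pos[:, 2].copy(), det_r, det_hh, det_inv_vol,
        spectrum.energies_kev, line_cdf,
        mu_lin, p_pe, mu_en_det)
    if n_leak:
        raise GeometryLeakError(f"{n_leak} photons left the geometry without "
                                "crossing the exterior boundary")
    mean, se = _batch_stats(tal, config.n_histories, config.n_batches)
    return KernelColumn(seed_id=seed_id, site_ids=tuple(s.site_id for s in sites),
                        dose_per_photon=mean, mc_sigma=se, config=config)


def point_source_dose_mc(e_kev: float,
                         radii_cm,
                         material: str = "water",
                         config: TransportConfig | None = None,
                         shell_thickness_cm: float = 0.05,
                         vacuum: bool = False,
                         materials: MaterialTable | None = None):
    """MC dose (Gy/photon) in thin spherical shells around a bare point source.

    Validation driver sharing the engine's collision physics and track-length
    estimator: an isotropic monoenergetic point source in an infinite uniform
    medium.  With ``vacuum=True`` attenuation is switched off (mu ~ 0) and a
    unit energy-absorption coefficient is used, exposing the bare
    inverse-square behaviour of the estimator.
    """
    config = config or TransportConfig()
    materials = materials or default_materials()
    radii = np.atleast_1d(np.asarray(radii_cm, dtype=float))
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    r1 = radii - shell_thickness_cm / 2
    r2 = radii + shell_thickness_cm / 2
    inv_vol = 1.0 / (4.0 / 3.0 * math.pi * (r2**3 - r1**3))
    if vacuum:
        mu_lin_1d = np.full(_N_GRID, 1e-12)
        p_pe_1d = np.ones(_N_GRID)
        mu_en_1d = np.ones(_N_GRID) / (e_kev * KEV_TO_GY_CM2_G)  # unit escore
    else:
        rho = materials.density(material)
        mu_lin_1d = materials.resample(material, _EGRID, "mu_total") * rho
        p_pe_1d = (materials.resample(material, _EGRID, "mu_pe")
                   / materials.resample(material, _EGRID, "mu_total"))
        mu_en_1d = materials.resample(material, _EGRID, "mu_en")
    tal = _run_point_source(
        config.n_histories, config.rng_seed, e_kev,
        config.score_primary_only, config.energy_cutoff_kev, config.n_batches,
        r1, r2, inv_vol, mu_lin_1d, p_pe_1d, mu_en_1d,
        r_kill=float(radii.max() * 3 + 10.0))
    return _batch_stats(tal, config.n_histories, config.n_batches)


def sample_interaction(e_kev: float, material: str, rng: np.random.Generator,
                       materials: MaterialTable | None = None) -> str:
    """Draw the interaction branch at e_kev: 'photoelectric' or 'incoherent'."""
    materials = materials or default_materials()
    frac = materials.photoelectric_fraction(material, e_kev)  # raises out of range
    return "photoelectric" if rng.random() < frac else "incoherent"


def sample_compton(e_kev: float, rng: np.random.Generator) -> tuple[float, float]:
    """Klein-Nishina sample (free electron): (scattered energy keV, cos theta).

    Pure-python twin of the engine's sampler; dsigma/dx with x = E'/E is
    proportional to x + 1/x - sin^2(theta), x in [1/(1+2a), 1].
    """
    if e_kev <= 0:
        raise ValueError("energy must be positive")
    a = e_kev / MEC2_KEV
    xmin = 1.0 / (1.0 + 2.0 * a)
    bound = xmin + 1.0 / xmin
    while True:
        x = xmin + (1.0 - xmin) * rng.random()
        ct = 1.0 - (1.0 / x - 1.0) / a
        f = x + 1.0 / x - (1.0 - ct * ct)
        if rng.random() * bound <= f:
            return e_kev * x, ct


def analytic_primary_dose(e_kev: float, r_cm: float, material: str,
                          materials: MaterialTable | None = None,
                          vacuum: bool = False) -> float:
    """Closed-form primary (uncollided) kerma per emitted photon, Gy.

    E * (mu_en/rho)(E) * exp(-mu(E) r) / (4 pi r^2); with ``vacuum=True`` the
    exponential and mu_en/rho are dropped (pure inverse square, unit escore).
    """
    if r_cm <= 0:
        raise ValueError("r must be positive")
    if vacuum:
        return 1.0 / (4.0 * math.pi * r_cm**2)
    materials = materials or default_materials()
    mu = materials.mu_linear(material, e_kev)
    mu_en = materials.mu_en(material, e_kev)
    return e_kev * KEV_TO_GY_CM2_G * mu_en * math.exp(-mu * r_cm) / (4.0 * math.pi * r_cm**2)
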