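"""Source-strength estimation by linear regression of surface doses.

The measured dose at each surface dosimeter is modelled as a linear
combination of the per-seed unit-strength dose kernels,

    D_exp(site) = sum_i  a_i * D_ical(site),

where the fitted coefficients a_i are the air kerma strengths (U) of the
implanted seeds.  The model is deliberately the same linear superposition
used by treatment planning, so the fitted strengths drop straight back
into the forward dose calculation.

The fit is ordinary or inverse-variance weighted linear least squares.
Uncertainties (coverage factor k = 1) come from the weighted normal
equations with the provided measurement sigmas; they are not rescaled by
the residuals, so simulation-based coverage checks are well defined.

The central objects follow the statsmodels convention: build a
:class:`SourceStrengthModel` from a :class:`MeasurementSet` and a
:class:`KernelMatrix`, call :meth:`~SourceStrengthModel.fit`, and read
estimates, uncertainties and diagnostics off the returned
:class:`SourceStrengthResults`.
"""
from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MeasurementSet", "KernelMatrix", "SourceStrengthModel",
    "SourceStrengthResults", "FitResult", "average_triplets",
    "average_triplets_kernel", "fit_strengths", "ratio_to_stronger",
    "predict_internal_dose",
]

_TRIPLET_RE = re.compile(r"^(?P<base>.+?)(?P<tag>[mcp])$")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class MeasurementSet:
    """Doses with uncertainties at named detector sites.

    ``data`` is indexed by site_id with columns ``dose_gy`` and ``sigma_gy``.
    ``provenance`` is one of 'measured', 'synthetic' or 'predicted';
    predicted sets may carry zero sigmas (a noiseless forward model).
    """

    data: pd.DataFrame
    exposure_time_h: float = 24.0
    provenance: str = "measured"

    def __post_init__(self):
        d = self.data
        if not {"dose_gy", "sigma_gy"} <= set(d.columns):
            raise ValueError("need columns dose_gy, sigma_gy")
        if d.index.has_duplicates:
            raise ValueError("site ids must be unique")
        if (d["dose_gy"] < 0).any():
            raise ValueError("doses must be >= 0")
        sig_ok = (d["sigma_gy"] >= 0) if self.provenance == "predicted" else (d["sigma_gy"] > 0)
        if not sig_ok.all():
            raise ValueError("sigmas must be positive (>= 0 for predictions)")
        if self.exposure_time_h <= 0:
            raise ValueError("exposure time must be positive")

    @classmethod
    def from_arrays(cls, site_ids, dose_gy, sigma_gy, exposure_time_h=24.0,
                    provenance="measured"):
        df = pd.DataFrame({"dose_gy": np.asarray(dose_gy, float),
                           "sigma_gy": np.asarray(sigma_gy, float)},
                          index=pd.Index(site_ids, name="site_id"))
        return cls(df, exposure_time_h, provenance)

    @property
    def site_ids(self):
        return list(self.data.index)

    @property
    def dose(self) -> np.ndarray:
        return self.data["dose_gy"].to_numpy()

    @property
    def sigma(self) -> np.ndarray:
        return self.data["sigma_gy"].to_numpy()

    def select(self, site_ids) -> "MeasurementSet":
        return replace(self, data=self.data.loc[list(site_ids)])

    def write_csv(self, path, header_lines=()):
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write(f"# exposure_time_h: {self.exposure_time_h}\n")
            fh.write(f"# provenance: {self.provenance}\n")
            self.data.rename_axis("site_id").to_csv(fh)

    @classmethod
    def read_csv(cls, path):
        meta = {}
        with open(path) as fh:
            lines = fh.read().splitlines()
        body = []
        for line in lines:
            if line.startswith("#"):
                if ":" in line:
                    k, _, v = line.lstrip("# ").partition(":")
                    meta[k.strip()] = v.strip()
            else:
                body.append(line)
        import io
        df = pd.read_csv(io.StringIO("\n".join(body)), index_col="site_id")
        return cls(df, float(meta.get("exposure_time_h", 24.0)),
                   meta.get("provenance", "measured"))


@dataclass
class KernelMatrix:
    """Calculated dose per unit air kerma strength: sites x seeds, Gy/U.

    ``values`` and ``sigma`` (the MC standard error of each entry) are
    DataFrames indexed by site_id with one column per seed.
    """

    values: pd.DataFrame
    sigma: pd.DataFrame
    exposure_time_h: float = 24.0

    def __post_init__(self):
        if not self.values.index.equals(self.sigma.index) or \
                not self.values.columns.equals(self.sigma.columns):
            raise ValueError("values and sigma must be aligned")
        if (self.values.to_numpy() < 0).any() or (self.sigma.to_numpy() < 0).any():
            raise ValueError("kernel entries and sigmas must be >= 0")

    @property
    def site_ids(self):
        return list(self.values.index)

    @property
    def seed_ids(self):
        return list(self.values.columns)

    def select(self, site_ids) -> "KernelMatrix":
        ids = list(site_ids)
        return KernelMatrix(self.values.loc[ids], self.sigma.loc[ids],
                            self.exposure_time_h)

    def select_prefix(self, prefix: str) -> "KernelMatrix":
        ids = [s for s in self.site_ids if s.startswith(prefix)]
        return self.select(ids)

    def write_csv(self, path, header_lines=()):
        long = (self.values.rename_axis("site_id")
                .melt(ignore_index=False, var_name="seed_id", value_name="dose_per_u")
                .join(self.sigma.rename_axis("site_id")
                      .melt(ignore_index=False, var_name="seed_id", value_name="mc_sigma")
                      .set_index("seed_id", append=True),
                      on=["site_id", "seed_id"]))
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write(f"# exposure_time_h: {self.exposure_time_h}\n")
            long.reset_index().to_csv(fh, index=False)

    @classmethod
    def read_csv(cls, path):
        meta = {}
        with open(path) as fh:
            lines = fh.read().splitlines()
        body = [l for l in lines if not l.startswith("#")]
        for line in lines:
            if line.startswith("#") and ":" in line:
                k, _, v = line.lstrip("# ").partition(":")
                meta[k.strip()] = v.strip()
        import io
        long = pd.read_csv(io.StringIO("\n".join(body)))
        values = long.pivot(index="site_id", columns="seed_id", values="dose_per_u")
        sigma = long.pivot(index="site_id", columns="seed_id", values="mc_sigma")
        # preserve the original site order
        order = long["site_id"].drop_duplicates()
        return cls(values.loc[order], sigma.loc[order],
                   float(meta.get("exposure_time_h", 24.0)))


# ---------------------------------------------------------------------------
# triplet averaging
# ---------------------------------------------------------------------------

def _triplet_map(site_ids) -> dict[str, list[str]]:
    """Map base azimuth id -> [id_m, id_c, id_p] for complete triplets."""
    groups: dict[str, dict[str, str]] = {}
    for sid in site_ids:
        m = _TRIPLET_RE.match(sid)
        if m:
            groups.setdefault(m["base"], {})[m["tag"]] = sid
    out = {}
    for base, tags in groups.items():
        if set(tags) == {"m", "c", "p"}:
            out[base] = [tags["m"], tags["c"], tags["p"]]
        elif len(tags) > 1:
            raise ValueError(f"incomplete dosimeter triplet for {base!r}: {sorted(tags)}")
    return out


def average_triplets(m: MeasurementSet) -> MeasurementSet:
    """Average each surface GRD triplet into one record per azimuth.

    The three side-by-side rods at phi-0.9, phi, phi+0.9 are averaged
    arithmetically; the reported sigma is the standard error of the mean,
    sqrt(sum sigma_i^2)/3.  Sites that are not part of a triplet pass
    through unchanged.
    """
    trip = _triplet_map(m.site_ids)
    if not trip:
        return m
    member_ids = {sid for ids in trip.values() for sid in ids}
    rows = []
    index = []
    for sid in m.site_ids:
        if sid in member_ids:
            base = next((b for b, ids in trip.items() if sid in ids), None)
            if base is None or base in index:
                continue
            sub = m.data.loc[trip[base]]
            rows.append({"dose_gy": sub["dose_gy"].mean(),
                         "sigma_gy": float(np.sqrt((sub["sigma_gy"] ** 2).sum()) / 3.0)})
            index.append(base)
        else:
            rows.append(dict(m.data.loc[sid]))
            index.append(sid)
    df = pd.DataFrame(rows, index=pd.Index(index, name="site_id"))
    return MeasurementSet(df, m.exposure_time_h, m.provenance)


def average_triplets_kernel(k: KernelMatrix) -> KernelMatrix:
    """Triplet averaging of kernel rows, matching :func:`average_triplets`."""
    trip = _triplet_map(k.site_ids)
    if not trip:
        return k
    member_ids = {sid for ids in trip.values() for sid in ids}
    vals = []
    sigs = []
    index = []
    for sid in k.site_ids:
        if sid in member_ids:
            base = next((b for b, ids in trip.items() if sid in ids), None)
            if base is None or base in index:
                continue
            vals.append(k.values.loc[trip[base]].mean(axis=0))
            sigs.append(np.sqrt((k.sigma.loc[trip[base]] ** 2).sum(axis=0)) / 3.0)
            index.append(base)
        else:
            vals.append(k.values.loc[sid])
            sigs.append(k.sigma.loc[sid])
            index.append(sid)
    idx = pd.Index(index, name="site_id")
    return KernelMatrix(pd.DataFrame(vals, index=idx),
                        pd.DataFrame(sigs, index=idx), k.exposure_time_h)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class SourceStrengthModel:
    """Linear model D_exp = sum_i a_i D_ical over the supplied sites.

    Parameters
    ----------
    measurements : MeasurementSet
        Doses (Gy) with k=1 sigmas at the fitting sites (typically the
        triplet-averaged surface azimuths).
    kernels : KernelMatrix
        Unit-strength dose kernels (Gy/U) at the same sites.
    weighting : {'inverse_variance', 'none'}
        'inverse_variance' (default) weights each site by 1/sigma^2.
    """

    def __init__(self, measurements: MeasurementSet, kernels: KernelMatrix,
                 weighting: str = "inverse_variance"):
        if weighting not in ("inverse_variance", "none"):
            raise ValueError("weighting must be 'inverse_variance' or 'none'")
        if set(measurements.site_ids) != set(kernels.site_ids):
            raise ValueError("measurement and kernel site sets differ")
        if len(measurements.site_ids) < len(kernels.seed_ids):
            raise ValueError("need at least as many sites as seeds")
        self.measurements = measurements
        self.kernels = kernels.select(measurements.site_ids)  # align order
        self.weighting = weighting
        x = self.kernels.values.to_numpy()
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError("kernel columns are linearly dependent")

    @classmethod
    def from_files(cls, measurement_csv, kernel_csv, weighting="inverse_variance"):
        return cls(MeasurementSet.read_csv(measurement_csv),
                   KernelMatrix.read_csv(kernel_csv), weighting)

    def fit(self) -> "SourceStrengthResults":
        x = self.kernels.values.to_numpy()
        y = self.measurements.dose
        sig = self.measurements.sigma
        if self.weighting == "inverse_variance":
            w = 1.0 / sig**2
            xtwx = x.T @ (w[:, None] * x)
            params = np.linalg.solve(xtwx, x.T @ (w * y))
            cov = np.linalg.inv(xtwx)
        else:
            xtx = x.T @ x
            params = np.linalg.solve(xtx, x.T @ y)
            bread = np.linalg.inv(xtx)
            cov = bread @ (x.T @ (sig[:, None] ** 2 * x)) @ bread
        cov = 0.5 * (cov + cov.T)
        resid = y - x @ params
        chi2 = float(np.sum((resid / sig) ** 2))
        if np.any(params < 0):
            warnings.warn("negative fitted source strength: the linear model "
                          "does not describe these measurements", stacklevel=2)
        seed_ids = self.kernels.seed_ids
        return SourceStrengthResults(
            model=self,
            params=pd.Series(params, index=seed_ids, name="strength_u"),
            cov_params=pd.DataFrame(cov, index=seed_ids, columns=seed_ids),
            resid=pd.Series(resid, index=self.measurements.site_ids, name="resid_gy"),
            chi2=chi2,
            df_resid=len(y) - len(params),
        )


@dataclass
class SourceStrengthResults:
    """Fitted air kerma strengths with k=1 uncertainties and diagnostics."""

    model: SourceStrengthModel
    params: pd.Series  # U
    cov_params: pd.DataFrame  # U^2
    resid: pd.Series  # Gy
    chi2: float
    df_resid: int

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params.to_numpy())),
                         index=self.params.index, name="sigma_u")

    def ratio_to_stronger(self, rounded: bool = True):
        """Weaker/stronger strength ratio in percent with its k=1 sigma.

        The sigma is propagated through the full fit covariance: the two
        fitted strengths share the same data, so their (negative)
        correlation widens the ratio uncertainty relative to the
        independence quadrature used when only printed values are
        available (module-level :func:`ratio_to_stronger`).
        """
        a = self.params.to_numpy()
        if a.size < 2:
            raise ValueError("need at least two strengths")
        if np.any(a <= 0):
            raise ValueError("strengths must be positive for a ratio")
        c = self.cov_params.to_numpy()
        i = int(np.argmin(a))
        j = int(np.argmax(a))
        ratio = 100.0 * a[i] / a[j]
        var = ratio**2 * (c[i, i] / a[i] ** 2 + c[j, j] / a[j] ** 2
                          - 2.0 * c[i, j] / (a[i] * a[j]))
        sig = math.sqrt(max(var, 0.0))
        if not rounded:
            return ratio, sig
        return _round_half_away(ratio), _round_half_away(sig)

    def predict(self, kernels: KernelMatrix) -> MeasurementSet:
        return predict_internal_dose(kernels, self)

    def summary(self) -> str:
        lines = ["Source strength regression (k=1 uncertainties)",
                 "=" * 47,
                 f"sites: {len(self.resid)}   seeds: {len(self.params)}   "
                 f"weighting: {self.model.weighting}",
                 f"chi-square: {self.chi2:.2f}  (dof {self.df_resid})",
                 "",
                 f"{'seed':<10}{'strength (U)':>14}{'sigma (U)':>12}"]
        for sid, a, s in zip(self.params.index, self.params, self.bse):
            lines.append(f"{sid:<10}{a:>14.4f}{s:>12.4f}")
        if len(self.params) >= 2 and (self.params > 0).all():
            r, sr = self.ratio_to_stronger()
            lines += ["", f"ratio to stronger source: {r} +- {sr} %"]
        return "\n".join(lines)


FitResult = SourceStrengthResults  # spec-facing alias


def fit_strengths(measurements: MeasurementSet, kernels: KernelMatrix,
                  weighting: str = "inverse_variance") -> SourceStrengthResults:
    """Estimate per-seed air kerma strengths from measured doses."""
    return SourceStrengthModel(measurements, kernels, weighting).fit()


def ratio_to_stronger(strengths, sigmas, rounded: bool = True):
    """Ratio of the weaker to the stronger source strength, in percent.

    Returns (ratio %, sigma %), by default rounded to the nearest integer
    (half away from zero).  The sigma combines the two relative errors in
    quadrature, treating them as independent.
    """
    a = np.asarray(strengths, float)
    s = np.asarray(sigmas, float)
    if a.size < 2:
        raise ValueError("need at least two strengths")
    if np.any(a <= 0):
        raise ValueError("strengths must be positive for a ratio")
    i_min = int(np.argmin(a))
    i_max = int(np.argmax(a))
    ratio = 100.0 * a[i_min] / a[i_max]
    sig = ratio * math.sqrt((s[i_min] / a[i_min]) ** 2 + (s[i_max] / a[i_max]) ** 2)
    if not rounded:
        return ratio, sig
    return _round_half_away(ratio), _round_half_away(sig)


def predict_internal_dose(kernels: KernelMatrix,
                          fit: SourceStrengthResults) -> MeasurementSet:
    """Forward-predict doses D = K a with propagated k=1 sigmas.

    The variance combines the fit covariance (through the kernel rows) and
    the per-entry kernel MC sigmas scaled by the strengths.
    """
    if list(kernels.seed_ids) != list(fit.params.index):
        raise ValueError("kernel seed set does not match the fitted strengths")
    k = kernels.values.to_numpy()
    ks = kernels.sigma.to_numpy()
    a = fit.params.to_numpy()
    dose = k @ a
    var = np.einsum("ij,jk,ik->i", k, fit.cov_params.to_numpy(), k)
    var = var + (ks**2) @ (a**2)
    return MeasurementSet.from_arrays(kernels.site_ids, dose, np.sqrt(var),
                                      exposure_time_h=kernels.exposure_time_h,
                                      provenance="predicted")
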