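"""Synthetic GRD measurement sets for the strength-shortage scenarios.

Raw rod-by-rod readings for the phantom experiments are not published, so
downstream stages are exercised on emulated data: the forward model
D = K a_true (the same linear superposition the regression fits) times
independent multiplicative noise with ~10% relative standard deviation,
the reported overall GRD measurement uncertainty.  Noise is applied at
the individual-rod level, before triplet averaging.

The four reference scenarios mimic experiments in which the seed at
position #2 falls short of the planned strength by 48, 31, 22 and 4
percent while the planning system assumes both seeds at the stronger
seed's strength.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .regression import KernelMatrix, MeasurementSet

__all__ = ["Scenario", "reference_scenarios", "generate_measurements"]


@dataclass(frozen=True)
class Scenario:
    scenario_id: str
    true_strengths: tuple  # U, per seed
    planned_strengths: tuple  # U, per seed (what the plan assumes)
    relative_noise: float = 0.10
    rng_seed: int = 20140120
    exposure_time_h: float = 24.0

    def __post_init__(self):
        if any(s < 0 for s in self.true_strengths + self.planned_strengths):
            raise ValueError("strengths must be >= 0")
        if self.relative_noise < 0:
            raise ValueError("noise must be >= 0")
        if len(self.true_strengths) != len(self.planned_strengths):
            raise ValueError("strength tuples must have equal length")


def reference_scenarios() -> list[Scenario]:
    """The four two-seed strength-shortage scenarios (well-chamber values).

    Seed #1 carries the planned strength; seed #2 is short by 48% down to
    4%.  The planned strength for both seeds is the stronger seed's value.
    """
    truths = {
        "test1": (0.253, 0.132),
        "test2": (0.090, 0.062),
        "test3": (0.046, 0.036),
        "test4": (0.030, 0.029),
    }
    return [Scenario(sid, t, (max(t), max(t))) for sid, t in truths.items()]


def generate_measurements(scenario: Scenario,
                          kernels: KernelMatrix,
                          rng: np.random.Generator | None = None) -> MeasurementSet:
    """Emulate GRD doses at every kernel site for one scenario.

    D_site = (K a_true) * eps with eps ~ Normal(1, relative_noise)
    truncated at zero (non-positive draws are redrawn); the recorded sigma
    is relative_noise times the noisy dose.  Passing the same rng state
    reproduces the same data set.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.rng_seed)
    a = np.asarray(scenario.true_strengths, float)
    if len(a) != len(kernels.seed_ids):
        raise ValueError("scenario strength count does not match kernel seeds")
    truth = kernels.values.to_numpy() @ a
    n = truth.size
    eps = rng.normal(1.0, scenario.relative_noise, size=n) if scenario.relative_noise > 0 \
        else np.ones(n)
    while np.any(eps <= 0):
        bad = eps <= 0
        eps[bad] = rng.normal(1.0, scenario.relative_noise, size=int(bad.sum()))
    dose = truth * eps
    if scenario.relative_noise > 0:
        sigma = scenario.relative_noise * dose
        if np.any(dose == 0):
            # a rod that recorded nothing still carries a detection-limit
            # uncertainty; use the noise scale of the largest reading
            floor = scenario.relative_noise * (dose.max() if dose.max() > 0 else 1.0)
            sigma = np.where(dose > 0, sigma, floor)
    else:
        # noiseless sets still need positive sigmas for weighting
        sigma = np.where(dose > 0, dose, 1.0) * 1e-12
    return MeasurementSet.from_arrays(kernels.site_ids, dose, sigma,
                                      exposure_time_h=scenario.exposure_time_h,
                                      provenance="synthetic")
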