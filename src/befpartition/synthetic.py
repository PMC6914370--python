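"""Synthetic communities with known complementarity and selection effects.

The generator builds a fully observed community from two ingredients:

* monoculture biomasses drawn from a lognormal law (strictly positive, with
  realistic right skew for grassland biomass), and
* deviations in relative yield that are linear in M plus Gaussian noise,
  ``dRY_i = a + b * (M_i - mean(M)) + eps_i``.

Centring the slope term on mean(M) gives closed-form control of both
effects: with no residual noise the selection effect is exactly
``Q * b * Var(M)`` (count-denominator variance) and the complementarity
effect is ``Q * a * mean(M)``.  Mixture biomass follows as
``Y_i = M_i * (dRY_i + 1/Q)``, truncated at zero when the linear law
implies a negative biomass; truncations are counted and the "true"
effects reported alongside the community are always recomputed from the
post-truncation data, so they are exact rather than nominal.

Observation error is injected as multiplicative, mean-one lognormal noise
(biomass is positive and replicate spread scales with the mean; additive
noise could go negative).  Averaging ``m_reps`` homogeneous replicates —
repeated measurements of the same community — suppresses it by
``1/sqrt(m_reps)``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .community import CommunitySample, SpeciesRecord
from .partition import partition

__all__ = [
    "CommunityModel",
    "NoiseModel",
    "CommunityTruth",
    "generate_community",
    "add_observation_error",
    "calibrate_cv",
]


@dataclass(frozen=True)
class CommunityModel:
    """Parameters of the synthetic community generator.

    Attributes
    ----------
    pool_size
        Q, number of species (>= 2).
    m_log_mean, m_log_sd
        Location and scale of log monoculture biomass.  The defaults give a
        median of ~150 g/m^2 with roughly 1.7-fold multiplicative spread,
        in the range of temperate grassland monocultures.
    dry_intercept
        ``a``: community-wide mean deviation in relative yield; drives CE.
    dry_slope
        ``b``: change in dRY per unit M; drives SE (= Q * b * Var(M) when
        noiseless).
    resid_sd
        SD of the Gaussian residual around the linear dRY law.
    seed
        RNG seed; same seed reproduces the community bit for bit.
    """

    pool_size: int
    m_log_mean: float = 5.0
    m_log_sd: float = 0.5
    dry_intercept: float = 0.05
    dry_slope: float = 0.002
    resid_sd: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.pool_size < 2:
            raise ValueError("pool_size must be at least 2")
        if self.m_log_sd < 0 or self.resid_sd < 0:
            raise ValueError("m_log_sd and resid_sd must be non-negative")


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative observation error on biomass measurements.

    ``cv`` is the coefficient of variation of a single measurement;
    ``m_reps`` homogeneous replicates are averaged per species.  ``cv = 0``
    is the identity.
    """

    cv: float
    m_reps: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if self.m_reps < 1:
            raise ValueError("m_reps must be at least 1")


@dataclass(frozen=True)
class CommunityTruth:
    """Realized (post-truncation) effects of a generated community."""

    ce: float
    se: float
    net: float
    n_truncated: int


def generate_community(model: CommunityModel) -> tuple[CommunitySample, CommunityTruth]:
    """Draw one fully observed community and its realized truth.

    Returns the community (``N = Q``, all M > 0) and a
    :class:`CommunityTruth` holding CE, SE and the net effect computed on
    the generated data under the partition convention, plus the number of
    species whose implied mixture biomass was truncated at zero.
    """
    q = model.pool_size
    rng = np.random.default_rng(model.seed)
    m = rng.lognormal(model.m_log_mean, model.m_log_sd, size=q)
    eps = rng.normal(0.0, model.resid_sd, size=q) if model.resid_sd > 0 else np.zeros(q)
    dry = model.dry_intercept + model.dry_slope * (m - m.mean()) + eps
    y = m * (dry + 1.0 / q)
    n_truncated = int(np.sum(y < 0))
    y = np.clip(y, 0.0, None)
    sample = CommunitySample.from_arrays(m, y, pool_size=q)
    realized = partition(sample, convention="partition")
    truth = CommunityTruth(
        ce=realized.ce, se=realized.se, net=realized.net, n_truncated=n_truncated
    )
    return sample, truth


def _mean_one_lognormal(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    # lognormal with E[X] = 1 and SD[X]/E[X] = cv
    sigma2 = math.log1p(cv * cv)
    mu = -0.5 * sigma2
    return rng.lognormal(mu, math.sqrt(sigma2), size=size)


def add_observation_error(
    community: CommunitySample, noise: NoiseModel
) -> CommunitySample:
    """Return a noisy measurement of ``community``.

    Every monoculture and mixture biomass is multiplied by independent
    mean-one lognormal noise with coefficient of variation ``cv``; with
    ``m_reps > 1`` the returned biomasses are per-species averages of
    ``m_reps`` independent noisy measurements.  ``cv = 0`` returns the
    input unchanged.
    """
    if noise.cv == 0:
        return community
    rng = np.random.default_rng(noise.seed)
    records = community.records
    n = len(records)
    m_noise = _mean_one_lognormal(rng, noise.cv, (n, noise.m_reps)).mean(axis=1)
    y_noise = _mean_one_lognormal(rng, noise.cv, (n, noise.m_reps)).mean(axis=1)
    noisy = [
        SpeciesRecord(r.species_id, r.monoculture * fm, r.mixture * fy)
        for r, fm, fy in zip(records, m_noise, y_noise, strict=True)
    ]
    return CommunitySample(
        noisy, pool_size=community.pool_size, pool_only=community.pool_only
    )


def calibrate_cv(replicate_measurements) -> float:
    """Pooled coefficient of variation from a species x replicate matrix.

    For each species with at least two finite replicates and a positive
    mean, computes SD(ddof=1)/mean; returns the root-mean-square of those
    per-species CVs.  This is the knob the observation-error model is
    calibrated with from real replicate harvests.
    """
    arr = np.asarray(replicate_measurements, dtype=float)
    if arr.ndim != 2:
        raise ValueError("replicate_measurements must be a species x replicate matrix")
    cvs = []
    for row in arr:
        vals = row[np.isfinite(row)]
        if vals.size < 2:
            continue
        mean = vals.mean()
        if mean > 0:
            cvs.append(np.std(vals, ddof=1) / mean)
    if not cvs:
        raise ValueError(
            "no species has >= 2 replicate measurements with a positive mean"
        )
    return float(np.sqrt(np.mean(np.square(cvs))))
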