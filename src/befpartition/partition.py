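"""Classic additive partition of the net biodiversity effect.

For a fully observed community of ``Q`` species with monoculture biomasses
``M_i`` and mixture biomasses ``Y_i``, the deviation in relative yield is

    dRY_i = Y_i / M_i - 1/Q,

i.e. observed relative yield minus the expected share under proportional
sowing.  The net biodiversity effect

    dY = sum_i (Y_i - M_i/Q) = N * mean(dRY) * mean(M) + N * cov(dRY, M)

splits additively into a complementarity effect CE = N*mean(dRY)*mean(M)
(community-wide overyielding independent of monoculture performance) and a
selection effect SE = N*cov(dRY, M) (overyielding concentrated in species
that do well in monoculture).  The identity is exact when the covariance
uses the count denominator N; the Bessel (N-1) form is what the
incomplete-sampling corrections in :mod:`befpartition.estimators` need, so
both conventions are first-class here and every result records which one
was used.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .community import CONVENTIONS, CommunitySample, Convention, PartitionResult

__all__ = [
    "compute_delta_ry",
    "net_biodiversity_effect",
    "partition",
    "partition_via_ols",
    "exp_shannon_diversity",
]


def _ddof(convention: Convention) -> int:
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}, got {convention!r}")
    return 0 if convention == "partition" else 1


def compute_delta_ry(sample: CommunitySample) -> np.ndarray:
    """Deviation in relative yield ``dRY_i = Y_i/M_i - 1/Q`` per species.

    Only species with ``M > 0`` participate (the ratio is undefined at
    ``M = 0``); the returned vector is aligned with
    ``sample.participating``.  The ``1/Q`` term always uses the *pool*
    size, so subsample values stay comparable with full-community values.
    """
    q = sample.pool_size
    if q < 1:
        raise ValueError("pool size Q must be at least 1")
    bad = [r.species_id for r in sample.zero_monoculture if r.mixture > 0]
    if bad:
        raise ValueError(
            "deviation in relative yield is undefined for species with zero "
            f"monoculture biomass but positive mixture biomass: {bad}"
        )
    m = sample.monoculture
    y = sample.mixture
    if m.size == 0:
        raise ValueError("no species with positive monoculture biomass")
    return y / m - 1.0 / q


def net_biodiversity_effect(sample: CommunitySample) -> float:
    """Net biodiversity effect ``dY = sum_i (Y_i - M_i/Q)`` in g/m^2.

    Equals ``sum_i dRY_i * M_i``; positive when the mixture outyields the
    expectation built from average monoculture performance.
    """
    m = sample.monoculture
    y = sample.mixture
    return float(np.sum(y - m / sample.pool_size))


def partition(
    sample: CommunitySample, convention: Convention = "partition"
) -> PartitionResult:
    """Partition the net biodiversity effect into CE and SE.

    Parameters
    ----------
    sample
        Fully observed or subsampled community (``N >= 2`` required, the
        covariance is undefined below that).
    convention
        ``"partition"`` divides the covariance by N (CE + SE = dY exact);
        ``"estimator"`` divides by N - 1 (the form the incomplete-sampling
        corrections consume).

    Returns
    -------
    PartitionResult
        With ``ce``, ``se``, ``net`` in the input biomass unit.
    """
    ddof = _ddof(convention)
    n = sample.n_species
    if n < 2:
        raise ValueError(f"partition requires at least 2 species with M > 0, got N={n}")
    dry = compute_delta_ry(sample)
    m = sample.monoculture
    cov = float(np.cov(dry, m, ddof=ddof)[0, 1])
    ce = float(n * dry.mean() * m.mean())
    se = float(n * cov)
    return PartitionResult(
        ce=ce,
        se=se,
        net=net_biodiversity_effect(sample),
        n_species=n,
        pool_size=sample.pool_size,
        convention=convention,
    )


def partition_via_ols(
    sample: CommunitySample, convention: Convention = "partition"
) -> PartitionResult:
    """Partition through the point-slope regression of dRY on M.

    Fits ``dRY_i = b0 + b1 * M_i + e_i`` by ordinary least squares and
    returns ``CE = N * mean(M) * (b0 + b1 * mean(M))`` and
    ``SE = N * b1 * Var(M)`` (variance under the chosen convention).  This
    is algebraically identical to :func:`partition`; it exists because the
    regression view makes the sampling bias of the statistics visible (the
    slope is stable under subsampling, the means are not) and serves as an
    independent computational route in tests.

    Raises
    ------
    ValueError
        If ``Var(M) = 0`` — the slope is undefined; use :func:`partition`,
        which handles constant M (SE is exactly 0 there).
    """
    ddof = _ddof(convention)
    n = sample.n_species
    if n < 2:
        raise ValueError(f"regression requires at least 2 species with M > 0, got N={n}")
    m = sample.monoculture
    if np.var(m) == 0:
        raise ValueError(
            "monoculture biomass has zero variance: the regression slope is "
            "undefined; use partition() instead (SE is exactly 0)"
        )
    dry = compute_delta_ry(sample)
    fit = sm.OLS(dry, sm.add_constant(m)).fit()
    b0, b1 = (float(p) for p in fit.params)
    var_m = float(np.var(m, ddof=ddof))
    ce = float(n * m.mean() * (b0 + b1 * m.mean()))
    se = float(n * b1 * var_m)
    return PartitionResult(
        ce=ce,
        se=se,
        net=net_biodiversity_effect(sample),
        n_species=n,
        pool_size=sample.pool_size,
        convention=convention,
    )


def exp_shannon_diversity(biomasses: Sequence[float]) -> float:
    """Exponentiated Shannon diversity ``exp(H)`` of a biomass vector.

    ``exp(-sum p_i ln p_i)`` over species with positive biomass, where
    ``p_i`` is the biomass share: the effective number of equally abundant
    species.  Equals S for S equally abundant species and 1 for a
    monoculture.
    """
    b = np.asarray(biomasses, dtype=float)
    if b.ndim != 1:
        raise ValueError("biomasses must be a 1-d vector")
    if np.any(~np.isfinite(b)) or np.any(b < 0):
        raise ValueError("biomasses must be finite and non-negative")
    b = b[b > 0]
    if b.size == 0:
        raise ValueError("at least one biomass must be positive")
    p = b / b.sum()
    return float(np.exp(-np.sum(p * np.log(p))))
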