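"""Subsampling experiments: bias, sampling error and replication effects.

Everything here treats a fully observed community as the finite population
and draws species subsets from it without replacement, mirroring how an
investigator with monocultures for only N of Q species would be positioned.
The central outputs are bias curves: per subset size N, the mean deviation
of raw and corrected statistics from the population values, with the
spread across draws and across means of heterogeneous replicate blocks.

Bias conventions
----------------
Uncorrected ("sample-level") variants are reported on the per-species
scale, ``CE^S/N - CE^P/Q`` and ``SE^S/N - S_xz`` (``S_xz`` the Bessel-form
population covariance of dRY and M), which is the scale on which the
analytic bias prediction lives.  Corrected variants are reported on the
population scale, ``CE_hat - CE^P`` and ``SE_hat - Q*S_xz``.

Exhaustive enumeration is the oracle for Monte-Carlo: whenever the number
of subsets C(Q, N) is below a threshold, every subset is evaluated exactly
once and the reported means are exact expectations rather than stochastic
estimates.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd

from .community import CommunitySample
from .estimators import estimate_population
from .synthetic import NoiseModel, add_observation_error

__all__ = [
    "SubsamplingDesign",
    "BiasCurve",
    "draw_subsets",
    "subsampling_experiment",
    "predicted_bias",
    "sampling_error_interval",
    "observation_error_experiment",
]

#: Estimator variants tracked by :func:`subsampling_experiment`.
VARIANTS = ("ce_uncorrected", "se_uncorrected", "ce_corrected", "se_corrected")


@dataclass(frozen=True)
class SubsamplingDesign:
    """Design of a subsampling experiment.

    Attributes
    ----------
    n_grid
        Subset sizes N to evaluate, each with 2 <= N <= Q.
    n_draws
        Monte-Carlo draws per N (ignored where exhaustive enumeration
        activates).  Default 20,000, the scale used for the reference
        experiments; scale it down for quick looks.
    n_het_reps
        Heterogeneous replicate counts n to summarise: the draw sequence is
        cut into consecutive disjoint blocks of n draws and the SD of the
        block means is reported, emulating an investigator who averages n
        independent random species draws.
    seed
        Seed of the experiment; per-N substreams are spawned from it so
        results for one N do not depend on the rest of the grid.
    exhaustive_threshold
        Exhaustive enumeration activates when C(Q, N) does not exceed this.
    """

    n_grid: tuple[int, ...]
    n_draws: int = 20_000
    n_het_reps: tuple[int, ...] = (1, 10, 30)
    seed: int | None = None
    exhaustive_threshold: int = 100_000

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_grid", tuple(int(n) for n in self.n_grid))
        object.__setattr__(self, "n_het_reps", tuple(int(n) for n in self.n_het_reps))
        if self.n_draws < 1:
            raise ValueError("n_draws must be at least 1")
        if any(n < 2 for n in self.n_grid):
            raise ValueError("every subset size in n_grid must be >= 2")
        if any(n < 1 for n in self.n_het_reps):
            raise ValueError("heterogeneous replicate counts must be >= 1")


@dataclass(frozen=True)
class BiasCurve:
    """Tidy per-(N, variant, n_het) summary of a subsampling experiment.

    ``table`` columns: ``N``, ``variant``, ``n_het``, ``mean_bias``, ``sd``
    (across draws for n_het = 1, across block means otherwise), ``mc_se``
    (Monte-Carlo standard error of ``mean_bias``), ``predicted_bias``
    (analytic expectation, nonzero only for the uncorrected CE),
    ``n_draws`` and ``exhaustive``.
    """

    table: pd.DataFrame
    pool_size: int
    ce_pop: float
    se_pop: float  # count-denominator (partition-convention) population SE
    se_pop_bessel: float  # Q * Bessel-form population covariance
    seed: int | None = None

    def to_csv(self, path) -> None:
        """Write the tidy table as CSV."""
        self.table.to_csv(path, index=False)

    def select(self, variant: str, n_het: int = 1) -> pd.DataFrame:
        """Rows for one estimator variant at one replication level."""
        t = self.table
        return t[(t["variant"] == variant) & (t["n_het"] == n_het)].reset_index(drop=True)


def _subset_index_matrix(
    n_avail: int,
    n_sub: int,
    n_draws: int,
    rng: np.random.Generator,
    exhaustive: bool,
) -> np.ndarray:
    """(draws x n_sub) index matrix; rows are uniform SRSWOR subsets."""
    if exhaustive:
        return np.fromiter(
            itertools.chain.from_iterable(itertools.combinations(range(n_avail), n_sub)),
            dtype=np.intp,
        ).reshape(-1, n_sub)
    if n_sub == n_avail:
        return np.tile(np.arange(n_avail), (n_draws, 1))
    r = rng.random((n_draws, n_avail))
    return np.argpartition(r, n_sub, axis=1)[:, :n_sub]


def draw_subsets(
    community: CommunitySample,
    n_sub: int,
    n_draws: int,
    seed: int | None = None,
    exhaustive: bool = False,
    exhaustive_threshold: int = 100_000,
) -> list[CommunitySample]:
    """Random (or exhaustive) species subsets of a fully observed community.

    Each subset keeps the original pool size Q, so every derived statistic
    remains commensurate with the full community.  Draws are uniform over
    species combinations, independent across draws (repeats across draws
    are possible); a fixed seed reproduces the sequence exactly.  With
    ``exhaustive=True`` every one of the C(N_avail, n_sub) subsets is
    returned exactly once (requires the count to be within
    ``exhaustive_threshold``).
    """
    n_avail = community.n_species
    if not 2 <= n_sub <= n_avail:
        raise ValueError(
            f"subset size must satisfy 2 <= n_sub <= {n_avail}, got {n_sub}"
        )
    if exhaustive and comb(n_avail, n_sub) > exhaustive_threshold:
        raise ValueError(
            f"C({n_avail}, {n_sub}) = {comb(n_avail, n_sub)} exceeds the "
            f"exhaustive threshold {exhaustive_threshold}"
        )
    rng = np.random.default_rng(seed)
    idx = _subset_index_matrix(n_avail, n_sub, n_draws, rng, exhaustive)
    return [community.subset(row) for row in idx]


def predicted_bias(se_pop_bessel: float, n_sub: int, pool_size: int) -> float:
    """Analytic expected bias of the uncorrected sample-level CE.

    Expected value of ``CE^S/N - CE^P/Q`` under simple random sampling
    without replacement:

        (Q - N)/Q * S_xz / N,   S_xz = se_pop_bessel / Q,

    where ``se_pop_bessel`` is Q times the Bessel-form population
    covariance of dRY and M.  Proportional to the selection effect (no
    selection effect, no CE bias), inversely proportional to N, and zero at
    N = Q.
    """
    if not 2 <= n_sub <= pool_size:
        raise ValueError("n_sub must satisfy 2 <= n_sub <= pool_size")
    s_xz = se_pop_bessel / pool_size
    return (pool_size - n_sub) / pool_size * s_xz / n_sub


def _block_sd(values: np.ndarray, n_het: int) -> float:
    """SD of means of consecutive disjoint blocks of ``n_het`` draws."""
    if np.ptp(values) == 0:
        return 0.0
    n_blocks = values.size // n_het
    if n_blocks < 2:
        return float("nan")
    means = values[: n_blocks * n_het].reshape(n_blocks, n_het).mean(axis=1)
    return float(np.std(means, ddof=1))


def subsampling_experiment(
    community: CommunitySample, design: SubsamplingDesign
) -> BiasCurve:
    """Quantify estimator bias and sampling error across subset sizes.

    For every N in ``design.n_grid``, draws ``design.n_draws`` random
    species subsets (or enumerates all of them when C(Q, N) is within the
    exhaustive threshold), computes the four estimator variants per draw,
    and summarises mean bias, SD across draws, SD across heterogeneous
    replicate block means, and the analytic bias prediction.

    Requires a fully observed community (``N == Q``): the experiment's
    population values must be exact.
    """
    q = community.pool_size
    if community.n_species != q:
        raise ValueError(
            "the subsampling experiment needs a fully observed community "
            f"(all Q pool species with M > 0); got N={community.n_species}, Q={q}"
        )
    if any(n > q for n in design.n_grid):
        raise ValueError("n_grid contains subset sizes larger than the pool")

    m = community.monoculture
    y = community.mixture
    dry = y / m - 1.0 / q
    ce_pop = q * dry.mean() * m.mean()
    s_xz = float(np.cov(dry, m, ddof=1)[0, 1])
    se_pop_bessel = q * s_xz
    se_pop = q * float(np.cov(dry, m, ddof=0)[0, 1])

    streams = np.random.SeedSequence(design.seed).spawn(len(design.n_grid))
    rows = []
    for n_sub, stream in zip(design.n_grid, streams):
        rng = np.random.default_rng(stream)
        exhaustive = comb(q, n_sub) <= design.exhaustive_threshold
        idx = _subset_index_matrix(q, n_sub, design.n_draws, rng, exhaustive)
        ms = m[idx]
        ds = dry[idx]
        mean_m = ms.mean(axis=1)
        mean_d = ds.mean(axis=1)
        ce_s = n_sub * mean_d * mean_m
        cov = ((ms - mean_m[:, None]) * (ds - mean_d[:, None])).sum(axis=1) / (n_sub - 1)
        se_s = n_sub * cov
        ce_hat = q * (ce_s - (q - n_sub) / q * se_s / n_sub) / n_sub
        se_hat = q * se_s / n_sub
        biases = {
            "ce_uncorrected": ce_s / n_sub - ce_pop / q,
            "se_uncorrected": se_s / n_sub - s_xz,
            "ce_corrected": ce_hat - ce_pop,
            "se_corrected": se_hat - se_pop_bessel,
        }
        if exhaustive:
            # enumeration order is not exchangeable; shuffle before blocking
            perm = rng.permutation(idx.shape[0])
            biases = {k: v[perm] for k, v in biases.items()}
        pred_ce = predicted_bias(se_pop_bessel, n_sub, q)
        for variant, values in biases.items():
            mean_bias = float(values.mean())
            mc_se = (
                float(np.std(values, ddof=1) / np.sqrt(values.size))
                if values.size > 1
                else 0.0
            )
            pred = pred_ce if variant == "ce_uncorrected" else 0.0
            for n_het in design.n_het_reps:
                rows.append(
                    {
                        "N": n_sub,
                        "variant": variant,
                        "n_het": n_het,
                        "mean_bias": mean_bias,
                        "sd": _block_sd(values, n_het),
                        "mc_se": mc_se,
                        "predicted_bias": pred,
                        "n_draws": values.size,
                        "exhaustive": exhaustive,
                    }
                )
    return BiasCurve(
        table=pd.DataFrame(rows),
        pool_size=q,
        ce_pop=float(ce_pop),
        se_pop=se_pop,
        se_pop_bessel=se_pop_bessel,
        seed=design.seed,
    )


def sampling_error_interval(
    sample: CommunitySample,
    n_resamples: int = 1000,
    seed: int | None = None,
    n_sub: int | None = None,
) -> tuple[float, float]:
    """SD of the corrected CE and SE attributable to incomplete sampling.

    Approximates the sampling-error SD of ``ce_pop_hat`` and ``se_pop_hat``
    for a sample of N species from a pool of Q by sub-subsampling: draw
    ``n_resamples`` subsets of size ``n_sub`` < N from the observed
    species, apply the finite-Q correction to each (pool size stays Q), and
    rescale the dispersion of those estimates by the square root of the
    ratio of finite-population design factors,

        g(n, pool) = (pool - n) / (pool * n),
        SD_hat = SD_observed * sqrt(g(N, Q) / g(n_sub, N)).

    ``g`` is the factor by which the variance of a mean under simple random
    sampling without replacement scales with sample and pool size; applying
    it to the corrected estimators is an approximation (they are not plain
    means), which is why the sub-subsample size is exposed as a parameter.
    At N = Q the interval is exactly zero: the full community has no
    sampling error.

    Returns ``(sd_ce, sd_se)``.
    """
    n = sample.n_species
    q = sample.pool_size
    if n < 3:
        raise ValueError("sampling-error intervals need at least N = 3 observed species")
    if n_sub is None:
        n_sub = max(2, n // 2)
    if not 2 <= n_sub <= n:
        raise ValueError(f"n_sub must satisfy 2 <= n_sub <= {n}, got {n_sub}")
    g_target = (q - n) / (q * n)
    if g_target == 0:
        return 0.0, 0.0
    g_inner = (n - n_sub) / (n * n_sub)
    if g_inner == 0:
        raise ValueError("n_sub must be smaller than the number of observed species")
    rng = np.random.default_rng(seed)
    idx = _subset_index_matrix(n, n_sub, n_resamples, rng, exhaustive=False)
    ce_vals = np.empty(n_resamples)
    se_vals = np.empty(n_resamples)
    for i, row in enumerate(idx):
        est = estimate_population(sample.subset(row), correction="finite_Q")
        ce_vals[i] = est.ce_pop_hat
        se_vals[i] = est.se_pop_hat
    scale = np.sqrt(g_target / g_inner)
    return (
        float(np.std(ce_vals, ddof=1) * scale),
        float(np.std(se_vals, ddof=1) * scale),
    )


def observation_error_experiment(
    community: CommunitySample,
    cv: float,
    m_reps_list: Sequence[int] = (1, 4),
    n_sub: int | None = None,
    n_draws: int = 200,
    seed: int | None = None,
) -> pd.DataFrame:
    """Effect of homogeneous replication on estimator spread under noise.

    For each replicate count m in ``m_reps_list``, repeatedly (i) injects
    mean-one multiplicative observation error with coefficient of variation
    ``cv``, averaging m independent noisy measurements per species, (ii)
    draws one random subset of ``n_sub`` species (default: the full
    community, which isolates the observation-error component from
    sampling error), and (iii) applies the finite-Q correction.  Returns a
    frame with mean and SD of the corrected CE and SE per m.
    """
    n_avail = community.n_species
    if n_sub is None:
        n_sub = n_avail
    if not 2 <= n_sub <= n_avail:
        raise ValueError(f"n_sub must satisfy 2 <= n_sub <= {n_avail}")
    streams = np.random.SeedSequence(seed).spawn(len(list(m_reps_list)))
    rows = []
    for m_reps, stream in zip(m_reps_list, streams):
        rng = np.random.default_rng(stream)
        ce_vals = np.empty(n_draws)
        se_vals = np.empty(n_draws)
        for i in range(n_draws):
            noisy = add_observation_error(
                community,
                NoiseModel(cv=cv, m_reps=int(m_reps), seed=int(rng.integers(2**31))),
            )
            if n_sub < n_avail:
                sub = noisy.subset(rng.choice(n_avail, size=n_sub, replace=False))
            else:
                sub = noisy
            est = estimate_population(sub, correction="finite_Q")
            ce_vals[i] = est.ce_pop_hat
            se_vals[i] = est.se_pop_hat
        rows.append(
            {
                "m_reps": int(m_reps),
                "cv": cv,
                "n_sub": n_sub,
                "n_draws": n_draws,
                "mean_ce": float(ce_vals.mean()),
                "sd_ce": float(np.std(ce_vals, ddof=1)),
                "mean_se": float(se_vals.mean()),
                "sd_se": float(np.std(se_vals, ddof=1)),
            }
        )
    return pd.DataFrame(rows)
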