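"""Bias-corrected population-level CE/SE from an incomplete random sample.

When only ``N`` of the ``Q`` pool species have monoculture data and those
``N`` are a simple random sample (without replacement) of the pool, the raw
sample-level complementarity effect is biased: covariance between M and dRY
makes the sample means of M and dRY co-deviate, inflating their product.
The selection effect, computed with the Bessel (N-1) covariance, is
unbiased.  The corrections here remove the CE bias:

    SE^P / Q  ~=  SE^S / N                                  (large or small Q)
    CE^P / Q  ~=  (CE^S - SE^S / N) / N                     (large-Q form)
    CE^P / Q  ~=  (CE^S - (Q-N)/Q * SE^S / N) / N           (finite-Q form)

The finite-Q form is exactly unbiased under sampling without replacement
for any Q and collapses to the sample statistic at N = Q; it is the
default.  ``SE^S`` always uses the N-1 denominator here — the identities
only hold for Bessel-corrected covariance — and the expected value of the
corrected SE is Q times the Bessel-form population covariance (a factor
Q/(Q-1) above the count-denominator population SE).
"""
from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .community import CORRECTIONS, CommunitySample, Correction, EstimateResult
from .partition import compute_delta_ry

__all__ = ["sample_statistics", "estimate_population", "aggregate_heterogeneous"]


def sample_statistics(sample: CommunitySample) -> tuple[float, float]:
    """Raw sample-level statistics ``(CE^S, SE^S)`` of a subsample.

    ``CE^S = N * mean(dRY) * mean(M)`` and ``SE^S = N * cov_{N-1}(dRY, M)``
    over the N sampled species; the 1/Q inside dRY uses the *pool* size Q,
    not N, which is what keeps subsample statistics commensurate with the
    full community.
    """
    n = sample.n_species
    if n < 2:
        raise ValueError(f"sample statistics require N >= 2 sampled species, got N={n}")
    dry = compute_delta_ry(sample)
    m = sample.monoculture
    ce_s = float(n * dry.mean() * m.mean())
    se_s = float(n * np.cov(dry, m, ddof=1)[0, 1])
    return ce_s, se_s


def estimate_population(
    sample: CommunitySample, correction: Correction = "finite_Q"
) -> EstimateResult:
    """Estimate the full community's CE and SE from a random subsample.

    Parameters
    ----------
    sample
        N observed species with pool size Q (supplied by the caller from
        sown richness or a survey — never inferred from the table length).
    correction
        ``"finite_Q"`` (default, exactly unbiased for any Q) or
        ``"large_Q"`` (the simpler form, adequate when Q >> N).

    Returns
    -------
    EstimateResult
        Corrected ``ce_pop_hat``/``se_pop_hat`` plus the raw sample-level
        statistics they were built from.

    Notes
    -----
    At ``N = Q`` the finite-Q estimate equals the sample statistic exactly:
    the correction factor (Q-N)/Q vanishes and Q/N = 1.
    """
    if correction not in CORRECTIONS:
        raise ValueError(f"correction must be one of {CORRECTIONS}, got {correction!r}")
    n = sample.n_species
    q = sample.pool_size
    ce_s, se_s = sample_statistics(sample)
    se_hat = q * se_s / n
    if correction == "large_Q":
        ce_hat = q * (ce_s - se_s / n) / n
    else:
        ce_hat = q * (ce_s - (q - n) / q * se_s / n) / n
    return EstimateResult(
        ce_pop_hat=float(ce_hat),
        se_pop_hat=float(se_hat),
        ce_sample=ce_s,
        se_sample=se_s,
        n_sampled=n,
        pool_size=q,
        correction=correction,
    )


def aggregate_heterogeneous(estimates: Iterable[EstimateResult]) -> pd.DataFrame:
    """Summarise heterogeneous replicates (independent random draws).

    Pools ``n`` estimates that come from distinct random species draws of
    the same community and returns, per quantity, the mean, SD (ddof=1; NaN
    when n = 1), standard error of the mean, and n.

    Raises
    ------
    ValueError
        If the estimates do not share a pool size Q (replicates of
        different communities cannot be pooled this way).
    """
    estimates = list(estimates)
    if not estimates:
        raise ValueError("need at least one estimate to aggregate")
    pools = {e.pool_size for e in estimates}
    if len(pools) > 1:
        raise ValueError(f"estimates mix different pool sizes: {sorted(pools)}")
    n = len(estimates)
    data = {
        "ce_pop_hat": [e.ce_pop_hat for e in estimates],
        "se_pop_hat": [e.se_pop_hat for e in estimates],
        "ce_sample": [e.ce_sample for e in estimates],
        "se_sample": [e.se_sample for e in estimates],
    }
    rows = {}
    for name, values in data.items():
        arr = np.asarray(values, dtype=float)
        sd = float(np.std(arr, ddof=1)) if n > 1 else float("nan")
        rows[name] = {
            "mean": float(arr.mean()),
            "sd": sd,
            "sem": sd / np.sqrt(n) if n > 1 else float("nan"),
            "n": n,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "quantity"
    return out
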