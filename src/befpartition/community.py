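"""Data containers shared by every analysis module.

The unit of analysis is a :class:`CommunitySample`: ``N`` species for which
both monoculture biomass ``M`` and mixture biomass ``Y`` are known, embedded
in a species pool of size ``Q >= N`` (the full mixture community, which may
contain species that were never grown in monoculture).  All biomasses are
per-unit-area dry mass; the conventional unit is g/m^2 but every statistic
in the package is unit-covariant.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

#: Covariance-denominator convention for the partition.
#: ``"partition"`` uses the count N (the additivity identity CE + SE = dY is
#: then exact); ``"estimator"`` uses N - 1 (Bessel correction, required by
#: the incomplete-sampling correction formulas).
Convention = Literal["partition", "estimator"]

#: Bias-correction variant for population-level estimates from a subsample.
Correction = Literal["finite_Q", "large_Q"]

CONVENTIONS = ("partition", "estimator")
CORRECTIONS = ("finite_Q", "large_Q")


@dataclass(frozen=True)
class SpeciesRecord:
    """Paired biomass observations for one species.

    Parameters
    ----------
    species_id
        Label for the species.
    monoculture
        Biomass of the species grown alone (``M``), non-negative.
    mixture
        Biomass of the species inside the mixture community (``Y``),
        non-negative.
    """

    species_id: str
    monoculture: float
    mixture: float

    def __post_init__(self) -> None:
        for name in ("monoculture", "mixture"):
            value = float(getattr(self, name))
            if not math.isfinite(value) or value < 0:
                raise ValueError(
                    f"{name} biomass of species {self.species_id!r} must be "
                    f"a finite non-negative number, got {getattr(self, name)!r}"
                )
            object.__setattr__(self, name, value)


class CommunitySample:
    """``N`` observed species embedded in a pool of ``Q`` species.

    Records with ``M > 0`` participate in all statistics; records with
    ``M = 0`` are held separately (they stay in the pool count ``Q`` but a
    deviation in relative yield cannot be computed for them).  Species known
    to be in the pool but never measured in monoculture can be carried as
    ``pool_only`` (id, mixture-biomass) pairs for bookkeeping and round-trip
    I/O; they take no part in any computation.

    Parameters
    ----------
    records
        Iterable of :class:`SpeciesRecord`.
    pool_size
        Total number of species in the mixture community, ``Q``.  Defaults
        to the number of records plus the number of pool-only species.
    pool_only
        Optional ``(species_id, mixture_biomass)`` pairs for pool species
        without monoculture data (mixture biomass may be NaN if unknown).
    """

    def __init__(
        self,
        records: Iterable[SpeciesRecord],
        pool_size: int | None = None,
        pool_only: Sequence[tuple[str, float]] = (),
    ) -> None:
        records = tuple(records)
        if not records:
            raise ValueError("a community sample needs at least one species record")
        seen: set[str] = set()
        for rec in records:
            if rec.species_id in seen:
                raise ValueError(f"duplicate species id {rec.species_id!r}")
            seen.add(rec.species_id)
        self.records: tuple[SpeciesRecord, ...] = records
        self.pool_only: tuple[tuple[str, float], ...] = tuple(
            (str(sid), float(y)) for sid, y in pool_only
        )
        n_known = len(records) + len(self.pool_only)
        if pool_size is None:
            pool_size = n_known
        pool_size = int(pool_size)
        if pool_size < n_known:
            raise ValueError(
                f"pool_size ({pool_size}) smaller than the number of species "
                f"accounted for ({n_known})"
            )
        if pool_size < 1:
            raise ValueError("pool_size must be at least 1")
        self.pool_size: int = pool_size

        self._participating = tuple(r for r in records if r.monoculture > 0)
        self._zero_monoculture = tuple(r for r in records if r.monoculture == 0)
        # replicate matrices (species x replicate), attached by befpartition.io
        self.monoculture_replicates = None
        self.mixture_replicates = None

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        monoculture: Sequence[float],
        mixture: Sequence[float],
        pool_size: int | None = None,
        species_ids: Sequence[str] | None = None,
    ) -> "CommunitySample":
        """Build a sample from parallel ``M`` and ``Y`` arrays."""
        m = np.asarray(monoculture, dtype=float)
        y = np.asarray(mixture, dtype=float)
        if m.shape != y.shape or m.ndim != 1:
            raise ValueError("monoculture and mixture must be 1-d arrays of equal length")
        if species_ids is None:
            species_ids = [f"sp{i + 1}" for i in range(m.size)]
        records = [
            SpeciesRecord(str(sid), float(mi), float(yi))
            for sid, mi, yi in zip(species_ids, m, y, strict=True)
        ]
        return cls(records, pool_size=pool_size)

    # -- views -------------------------------------------------------------
    @property
    def participating(self) -> tuple[SpeciesRecord, ...]:
        """Records with ``M > 0``, the ones statistics are computed from."""
        return self._participating

    @property
    def zero_monoculture(self) -> tuple[SpeciesRecord, ...]:
        """Records with measured ``M = 0`` (in ``Q``, excluded from ``N``)."""
        return self._zero_monoculture

    @property
    def n_species(self) -> int:
        """``N``: number of species participating in the statistics."""
        return len(self._participating)

    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(r.species_id for r in self._participating)

    @property
    def monoculture(self) -> np.ndarray:
        """Vector of participating monoculture biomasses ``M`` (g/m^2)."""
        return np.array([r.monoculture for r in self._participating])

    @property
    def mixture(self) -> np.ndarray:
        """Vector of participating mixture biomasses ``Y`` (g/m^2)."""
        return np.array([r.mixture for r in self._participating])

    def subset(self, indices: Sequence[int]) -> "CommunitySample":
        """Sample the participating species at ``indices``, keeping ``Q``.

        The subset represents an incomplete observation of the same
        community: the pool size is unchanged, so deviations in relative
        yield computed on the subset stay commensurate with the full
        community's.
        """
        idx = np.asarray(indices, dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_species):
            raise IndexError("subset index out of range")
        recs = [self._participating[i] for i in idx]
        return CommunitySample(recs, pool_size=self.pool_size)

    def __len__(self) -> int:
        return self.n_species

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CommunitySample(N={self.n_species}, Q={self.pool_size}, "
            f"zero_M={len(self._zero_monoculture)}, pool_only={len(self.pool_only)})"
        )


@dataclass(frozen=True)
class PartitionResult:
    """Additive partition of the net biodiversity effect.

    ``net = ce + se`` holds exactly under ``convention="partition"``.
    All three effects are in the biomass unit of the input (g/m^2).
    """

    ce: float
    se: float
    net: float
    n_species: int
    pool_size: int
    convention: Convention

    def __iter__(self):
        yield from (self.ce, self.se, self.net)


@dataclass(frozen=True)
class EstimateResult:
    """Population-level CE/SE estimated from an incomplete random sample.

    ``ce_sample`` and ``se_sample`` are the raw sample-level statistics
    (``se_sample`` always under the Bessel/estimator convention);
    ``ce_pop_hat`` and ``se_pop_hat`` are the bias-corrected estimates of
    the full community's effects.
    """

    ce_pop_hat: float
    se_pop_hat: float
    ce_sample: float
    se_sample: float
    n_sampled: int
    pool_size: int
    correction: Correction
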