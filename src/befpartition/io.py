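"""Reading and writing community tables and truth sidecars.

The on-disk format is a header-bearing delimited text table with columns
``species_id``, ``monoculture_biomass``, ``mixture_biomass`` and an
optional ``replicate_id``.  An empty field or ``NA`` in the monoculture
column means "never grown in monoculture" — the species counts toward the
pool size Q but not toward the sampled N — whereas the string ``0`` means
a measured zero.  Rows sharing a species across replicate ids are averaged
before analysis (homogeneous replication); the raw replicate matrices are
kept on the returned sample so the observation-error CV can be calibrated
from them.

The pool size Q should come from the caller (sown richness or a survey):
it is never silently inferred from the row count, because rows cover only
the sampled species.  Passing ``pool_size="infer_with_warning"`` sets
Q to the number of distinct species in the file and warns.
"""
from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .community import CommunitySample, SpeciesRecord
from .synthetic import CommunityModel, CommunityTruth

logger = logging.getLogger(__name__)

__all__ = [
    "read_community",
    "write_community",
    "write_truth_sidecar",
    "read_truth_sidecar",
]

_REQUIRED = ("species_id", "monoculture_biomass", "mixture_biomass")


def read_community(
    path,
    pool_size: int | str = "infer_with_warning",
    delimiter: str = ",",
) -> CommunitySample:
    """Load a community table into a :class:`CommunitySample`.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    pool_size
        Q, the total number of species in the mixture community; must be at
        least the number of distinct species in the file.  The sentinel
        ``"infer_with_warning"`` (default) uses the distinct-species count
        and emits a warning, since the file usually covers only sampled
        species.
    delimiter
        Field separator (``","`` by default; set ``";"`` for European
        exports).
    """
    df = pd.read_csv(
        path,
        sep=delimiter,
        dtype={"species_id": str},
        na_values=["NA"],
        skipinitialspace=True,
        float_precision="round_trip",
    )
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"community table {path} is missing columns: {missing}")

    for col in ("monoculture_biomass", "mixture_biomass"):
        values = df[col]
        bad = values.notna() & ((values < 0) | ~np.isfinite(values.fillna(0.0)))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"negative or non-finite {col} in row {row + 2} of {path} "
                f"(species {df['species_id'].iloc[row]!r})"
            )
    if df["mixture_biomass"].isna().any():
        sp = df.loc[df["mixture_biomass"].isna(), "species_id"].iloc[0]
        raise ValueError(f"missing mixture biomass for species {sp!r} in {path}")

    has_reps = "replicate_id" in df.columns
    if has_reps:
        dup = df.duplicated(subset=["species_id", "replicate_id"])
    else:
        dup = df.duplicated(subset=["species_id"])
    if dup.any():
        sp = df.loc[dup, "species_id"].iloc[0]
        raise ValueError(f"duplicate species {sp!r} within a replicate in {path}")

    mono_reps = mix_reps = None
    if has_reps:
        mono_reps = df.pivot(
            index="species_id", columns="replicate_id", values="monoculture_biomass"
        )
        mix_reps = df.pivot(
            index="species_id", columns="replicate_id", values="mixture_biomass"
        )
        table = pd.DataFrame(
            {
                "monoculture_biomass": mono_reps.mean(axis=1, skipna=True),
                "mixture_biomass": mix_reps.mean(axis=1, skipna=True),
            }
        ).reset_index()
    else:
        table = df[list(_REQUIRED)].copy()

    n_distinct = len(table)
    if pool_size == "infer_with_warning":
        q = n_distinct
        warnings.warn(
            f"pool size Q inferred from the table as {q}; supply the sown or "
            "surveyed pool size if the file covers only sampled species",
            stacklevel=2,
        )
    else:
        q = int(pool_size)
        if q < n_distinct:
            raise ValueError(
                f"pool_size ({q}) is smaller than the number of species in the "
                f"table ({n_distinct})"
            )

    sampled = table[table["monoculture_biomass"].notna()]
    pool_only = [
        (row.species_id, float(row.mixture_biomass))
        for row in table[table["monoculture_biomass"].isna()].itertuples()
    ]
    records = [
        SpeciesRecord(row.species_id, float(row.monoculture_biomass), float(row.mixture_biomass))
        for row in sampled.itertuples()
    ]
    sample = CommunitySample(records, pool_size=q, pool_only=pool_only)
    sample.monoculture_replicates = mono_reps
    sample.mixture_replicates = mix_reps
    logger.info(
        "read %s: N=%d participating species, Q=%d, %d zero-monoculture, "
        "%d pool-only (no monoculture data)",
        path,
        sample.n_species,
        q,
        len(sample.zero_monoculture),
        len(pool_only),
    )
    return sample


def write_community(sample: CommunitySample, path, delimiter: str = ",") -> None:
    """Write a sample back to the community CSV format.

    Records (participating and zero-monoculture) are written in their
    original order with numeric monoculture fields; pool-only species
    follow with an empty monoculture field.  ``read_community`` of the
    result reproduces the sample's values.
    """
    rows = [
        {
            "species_id": r.species_id,
            "monoculture_biomass": r.monoculture,
            "mixture_biomass": r.mixture,
        }
        for r in sample.records
    ]
    rows += [
        {"species_id": sid, "monoculture_biomass": np.nan, "mixture_biomass": y}
        for sid, y in sample.pool_only
    ]
    pd.DataFrame(rows, columns=list(_REQUIRED)).to_csv(
        path, sep=delimiter, index=False, float_format=lambda v: repr(float(v))
    )


def write_truth_sidecar(
    path,
    truth: CommunityTruth,
    model: CommunityModel | None = None,
) -> None:
    """Write realized truth (and generator parameters) as flat key=value text."""
    lines = [
        f"ce={truth.ce!r}",
        f"se={truth.se!r}",
        f"net={truth.net!r}",
        f"n_truncated={truth.n_truncated}",
    ]
    if model is not None:
        for key in (
            "pool_size",
            "m_log_mean",
            "m_log_sd",
            "dry_intercept",
            "dry_slope",
            "resid_sd",
            "seed",
        ):
            lines.append(f"{key}={getattr(model, key)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth_sidecar(path) -> dict:
    """Read a key=value truth sidecar back into a dict of numbers."""
    out: dict = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or "=" not in line:
            continue
        key, _, value = line.partition("=")
        if value == "None":
            out[key] = None
        else:
            num = float(value)
            out[key] = int(num) if num.is_integer() and "." not in value else num
    return out
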