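"""Community time-series data model and I/O.

Long-format observation tables (region, meadow, time, replicate, species,
count) are pooled per sampling time into one abundance vector per time,
giving a times × species matrix per meadow.  An incidence view derives the
quantities every multiple-site dissimilarity is built from: per-time
richness ``S_i``, pooled richness ``S_T`` and the matrix ``b[i][j]`` of
species exclusive to time *i* relative to time *j*.

Replicates (field quadrats collected at the same time) are pooled by
summing counts, which is a union on the incidence scale.  Densities per m²
are available via ``standardize=True`` but are off by default: incidence
and Bray–Curtis statistics are invariant to the constant
``1/(n_replicates × area)`` factor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    LookupError_,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: canonical column names of a long-format replicate table
REQUIRED_COLUMNS = ("region", "meadow", "time", "replicate", "species", "count")

#: quadrat area of the field sampling design, m²
DEFAULT_AREA_M2 = 0.0625

KEY_COLUMNS = ["meadow", "time", "replicate", "species"]


@dataclass(frozen=True)
class ReplicateTable:
    """Validated long-format observations.

    One row per (meadow, time, replicate, species) with a non-negative
    integer count.  ``times`` is the declared, ordered time axis shared by
    all meadows (a time may be absent from a meadow's rows; it then pools
    to an empty assemblage).
    """

    data: pd.DataFrame
    times: tuple = ()

    def __post_init__(self):
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        counts = df["count"]
        bad = counts.isna() | (counts < 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"negative or missing count at row {row}: {df.iloc[row].to_dict()}"
            )
        if (counts.astype(float) % 1 != 0).any():
            row = int(np.flatnonzero((counts.astype(float) % 1 != 0).to_numpy())[0])
            raise ValidationError(f"non-integer count at row {row}")
        dup = df.duplicated(subset=KEY_COLUMNS)
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0])
            key = {k: df.iloc[row][k] for k in KEY_COLUMNS}
            raise ValidationError(f"duplicate (meadow,time,replicate,species) key: {key}")
        if not self.times:
            object.__setattr__(self, "times", _infer_time_order(df["time"]))
        n_times = len(self.times)
        if n_times < 2:
            raise ValidationError(
                f"time axis must have at least 2 times, got {n_times}"
            )
        unknown = set(df["time"]) - set(self.times)
        if unknown:
            raise ValidationError(f"rows reference times outside the declared axis: {sorted(map(str, unknown))}")

    @property
    def meadows(self) -> list:
        return list(pd.unique(self.data["meadow"]))

    @property
    def regions(self) -> list:
        return list(pd.unique(self.data["region"]))

    def region_of(self, meadow) -> str:
        rows = self.data.loc[self.data["meadow"] == meadow, "region"]
        if rows.empty:
            raise LookupError_(f"unknown meadow: {meadow!r}")
        return rows.iloc[0]

    def __len__(self) -> int:
        return len(self.data)


def _infer_time_order(series: pd.Series) -> tuple:
    """Time axis = distinct values, numerically sorted when possible,
    otherwise in order of first appearance."""
    vals = list(pd.unique(series))
    try:
        return tuple(sorted(vals, key=float))
    except (TypeError, ValueError):
        return tuple(vals)


DEFAULT_SCHEMA = {c: c for c in REQUIRED_COLUMNS}


def read_long_table(path, schema: dict | None = None, sep: str = ",",
                    times=None) -> ReplicateTable:
    """Read and validate a long-format community table.

    Parameters
    ----------
    path : str or Path
        UTF-8 delimited text file with a header row.
    schema : dict, optional
        Mapping from canonical names (``region`` … ``count``) to the
        column names used in the file.  Defaults to the identity mapping.
    sep : str
        Field delimiter (``","`` for CSV, ``"\\t"`` for TSV).
    times : sequence, optional
        Declared time axis; inferred from the data when omitted.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, sep=sep, encoding="utf-8")
    missing = [src for src in schema.values() if src not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing mapped column(s): {', '.join(missing)}"
        )
    df = df.rename(columns={v: k for k, v in schema.items()})[list(REQUIRED_COLUMNS)]
    try:
        df["count"] = pd.to_numeric(df["count"], errors="raise")
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: counts do not parse as numbers: {exc}") from exc
    return ReplicateTable(df, times=tuple(times) if times is not None else ())


def write_long_table(table: ReplicateTable, path, sep: str = ",") -> None:
    table.data.to_csv(path, sep=sep, index=False, encoding="utf-8")


@dataclass(frozen=True)
class AssemblageSeries:
    """One meadow's time-ordered abundance matrix after replicate pooling.

    ``abundance[i, k]`` is the pooled count (or density per m² when
    standardized) of species ``species[k]`` at ``times[i]``.  All-zero
    species columns are dropped on construction; empty time rows are kept
    and flagged.
    """

    meadow: str
    times: tuple
    species: tuple
    abundance: np.ndarray          # T × K, non-negative
    area_m2: float = DEFAULT_AREA_M2
    empty_times: tuple = field(default=())

    def __post_init__(self):
        a = np.asarray(self.abundance, dtype=float)
        if a.ndim != 2 or a.shape != (len(self.times), len(self.species)):
            raise ValidationError(
                f"abundance must be {len(self.times)}×{len(self.species)}, got {a.shape}"
            )
        if (a < 0).any():
            raise ValidationError("negative abundance")
        if len(self.times) < 2:
            raise ValidationError("an assemblage series needs at least 2 times")
        keep = a.sum(axis=0) > 0
        if not keep.all():
            a = a[:, keep]
            object.__setattr__(
                self, "species", tuple(s for s, k in zip(self.species, keep) if k)
            )
        object.__setattr__(self, "abundance", a)
        empty = tuple(t for t, row in zip(self.times, a) if row.sum() == 0)
        object.__setattr__(self, "empty_times", empty)
        if empty:
            logger.warning("meadow %s: empty assemblage at time(s) %s", self.meadow, empty)

    @property
    def n_times(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        """Wide matrix, times as rows and species as columns."""
        return pd.DataFrame(self.abundance, index=list(self.times),
                            columns=list(self.species))


@dataclass(frozen=True)
class IncidenceSeries:
    """Presence/absence view of an :class:`AssemblageSeries`.

    ``b[i, j]`` counts species present at time i but absent at time j —
    the 'exclusive' species of the pairwise comparison the multiple-site
    statistics sum over.
    """

    meadow: str
    times: tuple
    species: tuple
    presence: np.ndarray           # T × K, bool

    def __post_init__(self):
        p = np.asarray(self.presence, dtype=bool)
        object.__setattr__(self, "presence", p)

    @property
    def S_i(self) -> np.ndarray:
        """Per-time richness."""
        return self.presence.sum(axis=1)

    @property
    def S_T(self) -> int:
        """Pooled richness over all times."""
        return int(self.presence.any(axis=0).sum())

    @property
    def b(self) -> np.ndarray:
        """b[i, j] = number of species present at time i, absent at time j."""
        p = self.presence.astype(np.int64)
        shared = p @ p.T
        return self.S_i[:, None] - shared

    def shared(self) -> np.ndarray:
        """shared[i, j] = richness common to times i and j."""
        p = self.presence.astype(np.int64)
        return p @ p.T


def pool_replicates(table: ReplicateTable, meadow, *, standardize: bool = False,
                    area_m2: float = DEFAULT_AREA_M2) -> AssemblageSeries:
    """Pool replicate quadrats into one abundance vector per time.

    Counts are summed over replicates per (time, species).  With
    ``standardize=True`` the sums are divided by
    ``n_replicates × area_m2`` to give individuals per m², where
    ``n_replicates`` is the number of distinct replicate ids observed at
    that time.
    """
    sub = table.data[table.data["meadow"] == meadow]
    if sub.empty:
        raise LookupError_(f"unknown meadow: {meadow!r}")
    species = tuple(sorted(pd.unique(sub.loc[sub["count"] > 0, "species"])))
    times = table.times
    sp_index = {s: k for k, s in enumerate(species)}
    t_index = {t: i for i, t in enumerate(times)}
    abundance = np.zeros((len(times), len(species)))
    nrep = np.zeros(len(times), dtype=int)
    for t, grp in sub.groupby("time", sort=False):
        i = t_index[t]
        nrep[i] = grp["replicate"].nunique()
        pos = grp[grp["count"] > 0]
        for s, c in zip(pos["species"], pos["count"]):
            abundance[i, sp_index[s]] += c
    for i, t in enumerate(times):
        if nrep[i] == 0:
            warnings.warn(f"meadow {meadow}: no replicates at time {t}; "
                          f"kept as an empty assemblage", stacklevel=2)
    if standardize:
        denom = np.where(nrep > 0, nrep, 1) * area_m2
        abundance = abundance / denom[:, None]
    return AssemblageSeries(meadow=meadow, times=times, species=species,
                            abundance=abundance, area_m2=area_m2)


def to_incidence(series: AssemblageSeries, threshold: float | None = None) -> IncidenceSeries:
    """Convert abundance to presence/absence.

    With the default ``threshold=None`` any strictly positive abundance is
    a presence; an explicit positive threshold uses ``abundance >= threshold``.
    """
    if threshold is None:
        presence = series.abundance > 0
    else:
        if threshold <= 0:
            raise ValidationError("presence threshold must be > 0")
        presence = series.abundance >= threshold
    return IncidenceSeries(meadow=series.meadow, times=series.times,
                           species=series.species, presence=presence)


def align_species(x1, x2):
    """Check two vectors share one species axis; returns float arrays."""
    a1, a2 = np.asarray(x1, dtype=float), np.asarray(x2, dtype=float)
    if a1.shape != a2.shape:
        raise AlignmentError(f"species axes differ: {a1.shape} vs {a2.shape}")
    return a1, a2
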