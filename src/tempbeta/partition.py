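"""Multiple-site temporal β-diversity and its partition.

Incidence scale (Sørensen family)
---------------------------------
For T assemblages with per-time richness S_i, pooled richness S_T and
pairwise exclusive-species counts b_ij::

    β_SOR = [Σ_{i<j} min(b_ij, b_ji) + Σ_{i<j} max(b_ij, b_ji)]
            / [2(Σ_i S_i − S_T) + Σ_{i<j} min + Σ_{i<j} max]
    β_SIM = Σ_{i<j} min(b_ij, b_ji) / [(Σ_i S_i − S_T) + Σ_{i<j} min]
    β_SNE = β_SOR − β_SIM

β_SIM captures species replacement (turnover) and is insensitive to
richness differences; β_SNE is the nestedness-resultant remainder driven
by ordered species loss.  At T = 2 these reduce to the pairwise Sørensen
and Simpson dissimilarities.

Abundance scale (Bray–Curtis family)
------------------------------------
With A_ij = Σ_k min(x_ik, x_jk) (shared abundance) and exclusive
abundances B_ij = Σ_k x_ik − A_ij, B_ji = Σ_k x_jk − A_ij::

    BC_total = [Σ min(B_ij,B_ji) + Σ max(B_ij,B_ji)]
               / [2 Σ A_ij + Σ min + Σ max]
    BC_bal   = Σ min(B_ij,B_ji) / (Σ A_ij + Σ min)        # balanced variation
    BC_gra   = BC_total − BC_bal                          # abundance gradients

which at T = 2 reduces to the pairwise Bray–Curtis dissimilarity
1 − 2Σmin/Σ(x_i + x_j).  Incidence sums are carried in exact integer
arithmetic up to the final division.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .assemblage import (
    AssemblageSeries,
    IncidenceSeries,
    ReplicateTable,
    align_species,
    pool_replicates,
    to_incidence,
)
from .errors import InsufficientTimesError, UndefinedResultError, ValidationError

__all__ = [
    "BetaPartition",
    "pairwise_sorensen",
    "pairwise_simpson",
    "pairwise_bray_curtis",
    "multi_sorensen",
    "multi_turnover",
    "multi_nestedness",
    "multi_incidence_partition",
    "multi_bray_curtis",
    "partition_all",
]


@dataclass(frozen=True)
class BetaPartition:
    """Per-meadow multiple-site dissimilarity components."""

    meadow: str
    region: str
    beta_sor: float
    beta_sim: float
    beta_sne: float
    bc_total: float
    bc_bal: float
    bc_gra: float
    n_times: int

    def __post_init__(self):
        assert abs(self.beta_sne - (self.beta_sor - self.beta_sim)) < 1e-12
        assert abs(self.bc_gra - (self.bc_total - self.bc_bal)) < 1e-12
        assert -1e-12 <= self.beta_sim <= self.beta_sor <= 1 + 1e-12
        assert -1e-12 <= self.bc_bal <= self.bc_total <= 1 + 1e-12

    def as_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------- pairwise

def pairwise_sorensen(p1, p2) -> float:
    """Sørensen dissimilarity (b12 + b21) / (2a + b12 + b21) of two
    presence vectors; 0 when both are empty."""
    a1, a2 = align_species(p1, p2)
    a1, a2 = a1 > 0, a2 > 0
    a = int((a1 & a2).sum())
    b12 = int((a1 & ~a2).sum())
    b21 = int((a2 & ~a1).sum())
    denom = 2 * a + b12 + b21
    if denom == 0:
        warnings.warn("both assemblages empty; dissimilarity defined as 0", stacklevel=2)
        return 0.0
    return (b12 + b21) / denom


def pairwise_simpson(p1, p2) -> float:
    """Simpson (turnover-only) dissimilarity min(b12,b21)/(a + min(b12,b21))."""
    a1, a2 = align_species(p1, p2)
    a1, a2 = a1 > 0, a2 > 0
    a = int((a1 & a2).sum())
    bmin = min(int((a1 & ~a2).sum()), int((a2 & ~a1).sum()))
    denom = a + bmin
    if denom == 0:
        warnings.warn("both assemblages empty; dissimilarity defined as 0", stacklevel=2)
        return 0.0
    return bmin / denom


def pairwise_bray_curtis(x1, x2) -> float:
    """Bray–Curtis dissimilarity 1 − 2Σmin/Σ(x1 + x2); 0 when both empty."""
    a1, a2 = align_species(x1, x2)
    if (a1 < 0).any() or (a2 < 0).any():
        raise ValidationError("negative abundance")
    total = a1.sum() + a2.sum()
    if total == 0:
        warnings.warn("both assemblages empty; dissimilarity defined as 0", stacklevel=2)
        return 0.0
    return 1.0 - 2.0 * np.minimum(a1, a2).sum() / total


# ------------------------------------------------------------ multiple-site

def _incidence_sums(inc: IncidenceSeries) -> tuple[int, int, int]:
    """(Σ_{i<j} min(b_ij,b_ji), Σ_{i<j} max(b_ij,b_ji), Σ_i S_i − S_T),
    all as exact integers."""
    T = len(inc.times)
    if T < 2:
        raise InsufficientTimesError(f"need at least 2 times, got {T}")
    b = inc.b
    iu = np.triu_indices(T, k=1)
    upper, lower = b[iu], b.T[iu]
    sum_min = int(np.minimum(upper, lower).sum())
    sum_max = int(np.maximum(upper, lower).sum())
    excess = int(inc.S_i.sum()) - inc.S_T
    return sum_min, sum_max, excess


def multi_sorensen(inc: IncidenceSeries) -> float:
    """Multiple-site Sørensen dissimilarity β_SOR."""
    sum_min, sum_max, excess = _incidence_sums(inc)
    denom = 2 * excess + sum_min + sum_max
    if inc.S_T == 0:
        raise UndefinedResultError(
            f"meadow {inc.meadow}: all times empty; β_SOR undefined"
        )
    if denom == 0:          # identical non-empty assemblages
        return 0.0
    return (sum_min + sum_max) / denom


def multi_turnover(inc: IncidenceSeries) -> float:
    """Multiple-site turnover component β_SIM (Simpson-based)."""
    sum_min, _, excess = _incidence_sums(inc)
    if inc.S_T == 0:
        raise UndefinedResultError(
            f"meadow {inc.meadow}: all times empty; β_SIM undefined"
        )
    denom = excess + sum_min
    if denom == 0:
        return 0.0
    return sum_min / denom


def multi_nestedness(inc: IncidenceSeries) -> float:
    """Nestedness-resultant component β_SNE = β_SOR − β_SIM."""
    return multi_sorensen(inc) - multi_turnover(inc)


def multi_incidence_partition(inc: IncidenceSeries) -> tuple[float, float, float]:
    """(β_SOR, β_SIM, β_SNE) with the additive identity exact by construction."""
    sor = multi_sorensen(inc)
    sim = multi_turnover(inc)
    return sor, sim, sor - sim


def multi_bray_curtis(series) -> tuple[float, float, float]:
    """(BC_total, BC_bal, BC_gra) for an :class:`AssemblageSeries` or a
    times × species abundance matrix."""
    x = series.abundance if isinstance(series, AssemblageSeries) else np.asarray(series, dtype=float)
    T = x.shape[0]
    if T < 2:
        raise InsufficientTimesError(f"need at least 2 times, got {T}")
    if (x < 0).any():
        raise ValidationError("negative abundance")
    if x.sum() == 0:
        raise UndefinedResultError("all times empty; Bray–Curtis undefined")
    totals = x.sum(axis=1)
    # A[i, j] = Σ_k min(x_ik, x_jk), accumulated pairwise
    A = np.zeros((T, T))
    for i in range(T):
        A[i] = np.minimum(x[i], x).sum(axis=1)
    B = totals[:, None] - A                 # B[i, j] = exclusive abundance of i vs j
    iu = np.triu_indices(T, k=1)
    upper, lower = B[iu], B.T[iu]
    sum_min = float(np.minimum(upper, lower).sum())
    sum_max = float(np.maximum(upper, lower).sum())
    sum_a = float(A[iu].sum())
    denom_tot = 2 * sum_a + sum_min + sum_max
    bc_total = 0.0 if denom_tot == 0 else (sum_min + sum_max) / denom_tot
    denom_bal = sum_a + sum_min
    bc_bal = 0.0 if denom_bal == 0 else sum_min / denom_bal
    return bc_total, bc_bal, bc_total - bc_bal


# ------------------------------------------------------------------ driver

def partition_meadow(table: ReplicateTable, meadow, *, standardize: bool = False,
                     presence_threshold: float | None = None) -> BetaPartition:
    """Pool one meadow, then compute all six multiple-site statistics."""
    series = pool_replicates(table, meadow, standardize=standardize)
    non_empty = series.n_times - len(series.empty_times)
    if non_empty < 2:
        raise InsufficientTimesError(
            f"meadow {meadow}: needs ≥ 2 non-empty times, has {non_empty}"
        )
    inc = to_incidence(series, threshold=presence_threshold)
    sor, sim, sne = multi_incidence_partition(inc)
    bc_total, bc_bal, bc_gra = multi_bray_curtis(series)
    return BetaPartition(
        meadow=meadow, region=table.region_of(meadow),
        beta_sor=sor, beta_sim=sim, beta_sne=sne,
        bc_total=bc_total, bc_bal=bc_bal, bc_gra=bc_gra,
        n_times=series.n_times,
    )


def partition_all(table: ReplicateTable, *, standardize: bool = False,
                  presence_threshold: float | None = None) -> list[BetaPartition]:
    """One :class:`BetaPartition` per meadow, in table order."""
    out = []
    for meadow in table.meadows:
        try:
            out.append(partition_meadow(table, meadow, standardize=standardize,
                                        presence_threshold=presence_threshold))
        except (InsufficientTimesError, UndefinedResultError) as exc:
            raise type(exc)(f"meadow {meadow}: {exc}") from exc
    return out


def partition_frame(partitions: list[BetaPartition]) -> pd.DataFrame:
    """Report-shaped frame: one row per meadow with the six components."""
    return pd.DataFrame([p.as_dict() for p in partitions])[
        ["region", "meadow", "beta_sor", "beta_sim", "beta_sne",
         "bc_total", "bc_bal", "bc_gra", "n_times"]
    ]
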