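"""Pool-level evaluation statistics for SSR meta-profiling.

Given pools of known parental strains, these metrics quantify (i) how
informative each SSR locus is for telling the pooled strains apart
(discrimination ability, D_a), (ii) how faithfully the pooled
amplification reproduces the expected allele set at each locus (average
locus error, E_a), and (iii) how well a deconvolution recovered the
parental strains (true positive rate and false-positive count).

Definitions
-----------
* A *strain-specific allele* is an allele carried by exactly one of the
  pooled parental strains at the locus.
* ``D_a = S_sa / S_p``: strains identifiable through at least one of
  their specific alleles actually observed in the pool, over the number
  of pooled strains.
* ``E_a = 100 * mean_pools(da_pool / epa_pool)``: per-pool fraction of
  differing alleles at the locus (symmetric difference between observed
  and expected, restricted to the locus) over the expected allele count
  at the locus, averaged over pools.
* ``TPR = 100 * P_p / Q_p``: parental strains correctly called over the
  number of parentals; false positives are called strains that were not
  parental.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .genotype_model import (
    AlleleCall,
    MetaProfile,
    StrainProfile,
    union_profiles,
)

__all__ = [
    "PoolDesign",
    "LocusPerformance",
    "RecoveryStats",
    "strain_specific_alleles",
    "discrimination_ability",
    "average_locus_error",
    "locus_performance",
    "recovery_stats",
]


@dataclass(frozen=True)
class PoolDesign:
    """A pooled sample with known parental strains.

    ``expected`` is the union of the parental profiles; ``observed`` is
    what the (possibly noisy) pooled amplification showed.  For noise-free
    in-silico pools the two coincide.
    """

    pool_id: str
    parental_ids: frozenset[str]
    observed: MetaProfile
    expected: MetaProfile

    def __post_init__(self) -> None:
        object.__setattr__(self, "parental_ids", frozenset(self.parental_ids))
        if len(self.parental_ids) < 2:
            raise ValueError(
                f"pool {self.pool_id!r}: a pool needs >= 2 parental strains")

    @property
    def n_parental(self) -> int:
        return len(self.parental_ids)


@dataclass(frozen=True)
class LocusPerformance:
    """Per-locus summary across a set of pools."""

    locus: str
    e_a: float
    d_a_by_pool: Mapping[str, float]
    n_pools: int
    da_pool: Mapping[str, int]
    epa_pool: Mapping[str, int]


@dataclass(frozen=True)
class RecoveryStats:
    """Recovery of a pool's parental strains by a deconvolution call set."""

    tpr: float
    n_false_positives: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.tpr <= 100.0):
            raise ValueError("tpr must be a percentage in [0, 100]")
        if self.n_false_positives < 0:
            raise ValueError("n_false_positives must be >= 0")


def _parental_profiles(pool: PoolDesign,
                       parental_profiles: Sequence[StrainProfile]
                       ) -> list[StrainProfile]:
    by_id = {p.strain_id: p for p in parental_profiles}
    missing = pool.parental_ids - set(by_id)
    if missing:
        raise ValueError(
            f"pool {pool.pool_id!r}: no profile for parental strain(s) "
            f"{sorted(missing)}")
    return [by_id[sid] for sid in sorted(pool.parental_ids)]


def strain_specific_alleles(pool: PoolDesign,
                            parental_profiles: Sequence[StrainProfile],
                            locus: str) -> dict[str, set[AlleleCall]]:
    """Alleles carried by exactly one parental strain at the locus.

    Returns a mapping strain_id -> its specific alleles; strains without
    any specific allele at the locus are omitted.
    """
    parents = _parental_profiles(pool, parental_profiles)
    carriers: dict[AlleleCall, list[str]] = {}
    for p in parents:
        for call in p.calls_at(locus):
            carriers.setdefault(call, []).append(p.strain_id)
    out: dict[str, set[AlleleCall]] = {}
    for call, owners in carriers.items():
        if len(owners) == 1:
            out.setdefault(owners[0], set()).add(call)
    return out


def discrimination_ability(pool: PoolDesign,
                           parental_profiles: Sequence[StrainProfile],
                           locus: str) -> float:
    """D_a: fraction of pooled strains identifiable at the locus.

    A strain counts only if at least one of its specific alleles is
    actually present in the pool's *observed* profile (an allele lost to
    dropout cannot identify its carrier).
    """
    specific = strain_specific_alleles(pool, parental_profiles, locus)
    observed = pool.observed.calls_at(locus)
    s_sa = sum(1 for alleles in specific.values() if alleles & observed)
    return s_sa / pool.n_parental


def average_locus_error(pools: Sequence[PoolDesign], locus: str) -> float:
    """E_a: mean per-pool percent of differing alleles at the locus.

    Pools with no expected allele at the locus are excluded (with a
    warning) since their per-pool ratio is undefined.
    """
    ratios = []
    n_skipped = 0
    for pool in pools:
        exp = pool.expected.calls_at(locus)
        if not exp:
            n_skipped += 1
            continue
        obs = pool.observed.calls_at(locus)
        ratios.append(len(obs ^ exp) / len(exp))
    if n_skipped:
        warnings.warn(
            f"locus {locus!r}: {n_skipped} pool(s) with no expected allele "
            "excluded from E_a", stacklevel=2)
    if not ratios:
        raise ValueError(f"locus {locus!r}: no pool with expected alleles")
    return 100.0 * sum(ratios) / len(ratios)


def locus_performance(pools: Sequence[PoolDesign],
                      parental_profiles: Sequence[StrainProfile],
                      locus: str) -> LocusPerformance:
    """Bundle E_a and per-pool D_a / allele counts for one locus."""
    d_a = {}
    da_pool = {}
    epa_pool = {}
    for pool in pools:
        d_a[pool.pool_id] = discrimination_ability(pool, parental_profiles, locus)
        exp = pool.expected.calls_at(locus)
        obs = pool.observed.calls_at(locus)
        da_pool[pool.pool_id] = len(obs ^ exp)
        epa_pool[pool.pool_id] = len(exp)
    counted = [p for p in pools if epa_pool[p.pool_id] > 0]
    if counted:
        e_a = 100.0 * sum(da_pool[p.pool_id] / epa_pool[p.pool_id]
                          for p in counted) / len(counted)
    else:
        e_a = 0.0
    return LocusPerformance(locus=locus, e_a=e_a, d_a_by_pool=d_a,
                            n_pools=len(counted), da_pool=da_pool,
                            epa_pool=epa_pool)


def recovery_stats(called: Iterable[str], pool: PoolDesign) -> RecoveryStats:
    """TPR and false-positive count of a call set against the pool truth."""
    called = set(called)
    if not pool.parental_ids:
        raise ValueError("pool has no parental strains")
    tp = len(called & pool.parental_ids)
    fp = len(called - pool.parental_ids)
    return RecoveryStats(tpr=100.0 * tp / pool.n_parental,
                         n_false_positives=fp)


def make_pool(pool_id: str, parental: Sequence[StrainProfile],
              observed: MetaProfile | None = None) -> PoolDesign:
    """Build a PoolDesign from parental profiles (observed defaults to expected)."""
    expected = union_profiles(parental, sample_id=f"{pool_id}:expected")
    if observed is None:
        observed = MetaProfile(f"{pool_id}:observed", expected.calls)
    return PoolDesign(pool_id=pool_id,
                      parental_ids=frozenset(p.strain_id for p in parental),
                      observed=observed, expected=expected)
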