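"""Synthetic SSR reference collections and pooled meta-profiles.

Real strain collections for this problem are typed at a 12-locus SSR
panel, contain a mix of haploid and diploid strains, and show clonal
clusters of near-identical genotypes (strains one repeat-unit step apart
at one or two loci).  Pooled amplifications of such strains lose alleles
at locus-specific rates (allele dropout) and can add stutter artefacts
one repeat unit below a true allele.  The generators here emulate that
statistical structure so that the deconvolution pipeline can be
benchmarked end-to-end without any wet-lab data:

* ``simulate_reference`` draws strain genotypes on per-locus allele
  ladders (lengths spaced by the repeat unit), optionally structured into
  clonal clusters via a stepwise (+/-1 repeat) mutation model around
  founders.
* ``simulate_pool`` unions k strain profiles into an in-silico
  meta-profile (noise-free: observed == expected).
* ``apply_amplification_noise`` corrupts the observed profile with
  per-allele, per-locus dropout and optional stutter.
* ``simulate_experiment`` builds the full benchmark grid (k in 2..6,
  n replicates each, optional locus subset), with per-pool seeds derived
  from a master seed so any single pool is re-generable in isolation.

What this does NOT model: PCR kinetics, peak heights, allele-size
calibration, or the unknown allele-richness of any real collection --
defaults are plausible round numbers, exposed in the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence, Union

import numpy as np

from .genotype_model import (
    DEFAULT_PANEL,
    AlleleCall,
    MetaProfile,
    StrainProfile,
    union_profiles,
)
from .locus_metrics import PoolDesign, make_pool

__all__ = [
    "SimulationConfig",
    "simulate_reference",
    "simulate_pool",
    "apply_amplification_noise",
    "simulate_experiment",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic collection / pool generators.

    Attributes
    ----------
    n_strains
        Collection size.
    loci
        Locus names; defaults to the 12-locus typing panel.
    alleles_per_locus
        Distinct allele-ladder length per locus (default 8).
    repeat_unit
        Base-pair step between adjacent ladder alleles (default 3, a
        trinucleotide motif).
    base_length
        Smallest ladder length in bp (default 100).
    het_prob
        Probability that a strain is heterozygous (two alleles) at a
        locus; 0 gives a fully homozygous/haploid collection.
    n_clusters
        Number of clonal founders; 0 = unstructured collection.
    within_cluster_mut_prob
        Per-locus probability that a cluster member steps one repeat unit
        away (+/-1 on the ladder) from its founder allele.
    dropout_by_locus
        Per-allele dropout probability in pooled amplification, either a
        single float applied to every locus or a locus -> probability
        mapping (default: no dropout).  ``noisy_locus_presets`` gives
        values of the magnitude seen for the weakest loci of the panel.
    stutter_prob
        Probability of adding a spurious allele one repeat unit below a
        surviving true allele.
    seed
        Master seed; every generator output is a pure function of the
        config.
    """

    n_strains: int = 50
    loci: tuple[str, ...] = DEFAULT_PANEL
    alleles_per_locus: int = 8
    repeat_unit: int = 3
    base_length: int = 100
    het_prob: float = 0.5
    n_clusters: int = 0
    within_cluster_mut_prob: float = 0.05
    dropout_by_locus: Union[float, Mapping[str, float]] = 0.0
    stutter_prob: float = 0.0
    seed: int = 0

    #: Dropout rates of the magnitude shown by the panel's weakest loci.
    noisy_locus_presets = {"C6": 0.09, "C8": 0.046}

    @classmethod
    def clonal(cls, n_strains: int = 50, seed: int = 0,
               **overrides) -> "SimulationConfig":
        """Conditions emulating a real typing collection's clonal structure.

        Environmental strain collections are dominated by clonal
        expansions: groups of near-identical genotypes one repeat step
        apart at a locus or two, plus exact re-isolates.  This preset
        draws roughly one founder per 2-3 strains (founders:strains =
        18:50) with a 5% per-locus stepwise mutation rate, which yields
        both exact duplicates (pruned away downstream) and surviving
        near-identical pairs -- the hard case for deconvolution.
        """
        n_clusters = max(1, round(n_strains * 18 / 50))
        defaults = dict(n_strains=n_strains, n_clusters=n_clusters,
                        within_cluster_mut_prob=0.05, seed=seed)
        defaults.update(overrides)
        return cls(**defaults)

    def __post_init__(self) -> None:
        if self.n_strains < 1:
            raise ValueError("n_strains must be >= 1")
        if self.alleles_per_locus < 2:
            raise ValueError("alleles_per_locus must be >= 2")
        if not (0.0 <= self.het_prob <= 1.0):
            raise ValueError("het_prob must be in [0, 1]")
        if not (0.0 <= self.within_cluster_mut_prob <= 1.0):
            raise ValueError("within_cluster_mut_prob must be in [0, 1]")
        if not (0.0 <= self.stutter_prob <= 1.0):
            raise ValueError("stutter_prob must be in [0, 1]")
        for p in self._dropout_map().values():
            if not (0.0 <= p <= 1.0):
                raise ValueError("dropout probabilities must be in [0, 1]")
        if self.repeat_unit < 1 or self.base_length < 1:
            raise ValueError("repeat_unit and base_length must be >= 1")

    def _dropout_map(self) -> dict[str, float]:
        if isinstance(self.dropout_by_locus, Mapping):
            unknown = set(self.dropout_by_locus) - set(self.loci)
            if unknown:
                raise ValueError(f"dropout for unknown locus/loci {sorted(unknown)}")
            return dict(self.dropout_by_locus)
        return {locus: float(self.dropout_by_locus) for locus in self.loci}

    def ladder(self, locus: str) -> list[int]:
        """Allele ladder (fragment lengths) of a locus."""
        return [self.base_length + i * self.repeat_unit
                for i in range(self.alleles_per_locus)]


def _draw_strain(rng: np.random.Generator, config: SimulationConfig,
                 strain_id: str) -> StrainProfile:
    calls = set()
    for locus in config.loci:
        ladder = config.ladder(locus)
        if rng.random() < config.het_prob:
            pair = rng.choice(len(ladder), size=2, replace=False)
            calls.add(AlleleCall(locus, ladder[int(pair[0])]))
            calls.add(AlleleCall(locus, ladder[int(pair[1])]))
        else:
            calls.add(AlleleCall(locus, ladder[int(rng.integers(len(ladder)))]))
    return StrainProfile(strain_id, frozenset(calls))


def _mutate_clone(rng: np.random.Generator, config: SimulationConfig,
                  founder: StrainProfile, strain_id: str) -> StrainProfile:
    """Stepwise (+/-1 repeat) mutation of a founder genotype, per locus."""
    calls = set()
    for locus in config.loci:
        locus_calls = sorted(founder.calls_at(locus))
        lengths = [c.length for c in locus_calls]
        if lengths and rng.random() < config.within_cluster_mut_prob:
            i = int(rng.integers(len(lengths)))
            lo = config.base_length
            hi = config.base_length + (config.alleles_per_locus - 1) * config.repeat_unit
            step = config.repeat_unit if rng.random() < 0.5 else -config.repeat_unit
            new = lengths[i] + step
            if new < lo or new > hi or new in lengths:
                new = lengths[i] - step  # bounce off ladder edge / collision
            if lo <= new <= hi and new not in lengths:
                lengths[i] = new
        for ln in lengths:
            calls.add(AlleleCall(locus, ln))
    return StrainProfile(strain_id, frozenset(calls))


def simulate_reference(config: SimulationConfig) -> list[StrainProfile]:
    """Draw a synthetic reference collection.

    Unstructured mode (``n_clusters == 0``): every strain is an
    independent draw.  Clustered mode: ``n_clusters`` founders are drawn
    independently and members are assigned round-robin, each derived from
    its founder by the stepwise mutation model (with mutation probability
    zero, members replicate the founder exactly).
    """
    if config.alleles_per_locus < 2 and config.het_prob > 0:
        raise ValueError("het_prob > 0 needs at least 2 alleles per locus")
    rng = np.random.default_rng(config.seed)
    width = len(str(config.n_strains))
    ids = [f"S{str(i + 1).zfill(width)}" for i in range(config.n_strains)]
    if config.n_clusters <= 0:
        return [_draw_strain(rng, config, sid) for sid in ids]
    founders = [_draw_strain(rng, config, f"F{c + 1}")
                for c in range(config.n_clusters)]
    strains = []
    for i, sid in enumerate(ids):
        founder = founders[i % config.n_clusters]
        strains.append(_mutate_clone(rng, config, founder, sid))
    return strains


def simulate_pool(collection: Sequence[StrainProfile], k: int,
                  seed: int, pool_id: str | None = None) -> PoolDesign:
    """In-silico pool: union of k strains sampled without replacement.

    Noise-free by construction (observed == expected); apply
    :func:`apply_amplification_noise` separately to corrupt the observed
    profile.
    """
    if k < 2:
        raise ValueError("a pool needs k >= 2 strains")
    if k > len(collection):
        raise ValueError(
            f"pool size k={k} exceeds collection size {len(collection)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(collection), size=k, replace=False)
    parents = [collection[int(i)] for i in sorted(idx)]
    pid = pool_id or f"pool_k{k}_s{seed}"
    return make_pool(pid, parents)


def apply_amplification_noise(pool: PoolDesign, config: SimulationConfig,
                              seed: int) -> PoolDesign:
    """Corrupt a pool's observed profile with dropout and stutter.

    Each observed allele is deleted independently with its locus's
    dropout probability; each surviving allele spawns, with probability
    ``stutter_prob``, a spurious allele one repeat unit shorter.  The
    expected profile (the truth) is untouched.
    """
    rng = np.random.default_rng(seed)
    dropout = config._dropout_map()
    kept: set[AlleleCall] = set()
    stutter: set[AlleleCall] = set()
    for call in sorted(pool.observed.calls):
        if rng.random() < dropout.get(call.locus, 0.0):
            continue
        kept.add(call)
        if config.stutter_prob > 0 and rng.random() < config.stutter_prob:
            shorter = call.length - config.repeat_unit
            if shorter > 0:
                stutter.add(AlleleCall(call.locus, shorter))
    observed = MetaProfile(pool.observed.sample_id, frozenset(kept | stutter))
    return PoolDesign(pool_id=pool.pool_id, parental_ids=pool.parental_ids,
                      observed=observed, expected=pool.expected)


def _pool_seed(master_seed: int, counter: int) -> int:
    """Derived per-pool seed, re-generable in isolation (< 2**31)."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(counter,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def simulate_experiment(collection: Sequence[StrainProfile],
                        k_values: Sequence[int] = (2, 3, 4, 5, 6),
                        n_reps: int = 1000,
                        loci_subset: Sequence[str] | None = None,
                        config: SimulationConfig | None = None
                        ) -> list[PoolDesign]:
    """Benchmark grid of in-silico pools: ``n_reps`` pools per pool size.

    ``loci_subset`` restricts every profile to the named loci *before*
    pooling (e.g. the 10-locus set that drops the two noisiest panel
    loci).  Dropout/stutter from ``config`` (if any) corrupt each pool's
    observed profile.  Per-pool seeds derive from ``config.seed`` via a
    counter, so pool j of the grid can be regenerated alone.
    """
    config = config or SimulationConfig()
    if loci_subset is not None:
        known = {c.locus for p in collection for c in p.calls} | set(config.loci)
        unknown = set(loci_subset) - known
        if unknown:
            raise ValueError(f"unknown locus/loci in subset: {sorted(unknown)}")
        collection = [p.restrict(loci_subset) for p in collection]
    noisy = config.stutter_prob > 0 or any(
        v > 0 for v in config._dropout_map().values())
    pools = []
    counter = 0
    for k in k_values:
        for rep in range(n_reps):
            seed = _pool_seed(config.seed, counter)
            counter += 1
            pool = simulate_pool(collection, k, seed,
                                 pool_id=f"pool_k{k}_r{rep}")
            if noisy:
                pool = apply_amplification_noise(pool, config,
                                                 seed=_pool_seed(config.seed, counter))
                counter += 1
            pools.append(pool)
    return pools
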