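"""Redundancy pruning of a reference strain collection.

A reference collection can contain strains the deconvolution model
cannot tell apart: exact genotype duplicates (re-isolated clones), and
haploid strains whose allele set is a subset of a diploid relative's --
a single-strain query then calls several strains at once.  Pruning makes
every remaining strain self-identify uniquely.

The procedure is recursive: each strain's own profile is used as a query
against the current collection; whenever the call set is not exactly the
strain itself -- more than one strain called, or an exact genotype
equivalent called in its place -- a single representative of the group is
kept and the others are removed.  Passes repeat until a full pass makes
no removal.  The
representative is the query strain itself when it appears in its own
call set, otherwise the called strain with the largest coefficient
(ties resolved by input order) -- a deterministic rule, since the
underlying selection problem has no unique canonical answer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .deconvolution import DeconvolutionConfig, deconvolve
from .genotype_model import MetaProfile, StrainProfile

__all__ = ["PruneReport", "prune_reference"]

_MAX_ROUNDS = 100


@dataclass(frozen=True)
class PruneReport:
    """Audit trail of a pruning run."""

    kept: tuple[str, ...]
    removed: tuple[tuple[str, str, int], ...]  # (removed_id, representative_id, round)
    n_rounds: int


def _self_query(profile: StrainProfile) -> MetaProfile:
    return MetaProfile(f"{profile.strain_id}:self", profile.calls)


def prune_reference(collection: Sequence[StrainProfile],
                    config: DeconvolutionConfig | None = None
                    ) -> tuple[list[StrainProfile], PruneReport]:
    """Prune a collection until every strain self-identifies uniquely.

    Returns the pruned collection (input order preserved) and a
    :class:`PruneReport` mapping each removed strain to the kept
    representative that absorbed it.  Deterministic given the config
    seed.
    """
    if not collection:
        raise ValueError("cannot prune an empty collection")
    config = config or DeconvolutionConfig()
    ids = [p.strain_id for p in collection]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate strain_id in collection")
    order = {sid: i for i, sid in enumerate(ids)}

    kept = list(collection)
    removed: list[tuple[str, str, int]] = []
    for round_index in range(1, _MAX_ROUNDS + 1):
        any_removed = False
        for strain in list(kept):
            if strain not in kept:  # removed earlier in this pass
                continue
            if len(kept) == 1:
                break
            result = deconvolve(kept, _self_query(strain), config)
            called = list(result.selected)
            if called == [strain.strain_id]:
                continue  # unique self-identification: nothing to do
            if len(called) == 1:
                if result.glm_error > 0.0:
                    # a different but inexact strain was picked; removing
                    # either member would lose information
                    continue
                # an exact equivalent was called instead of the query strain
                # (e.g. a genotype duplicate): the called strain represents it
                rep, victims = called[0], [strain.strain_id]
            elif strain.strain_id in called:
                rep = strain.strain_id
                victims = [c for c in called if c != rep]
            else:
                # largest coefficient wins; ties by input order
                rep = max(called,
                          key=lambda s: (result.coefficients.get(s, 0.0),
                                         -order[s]))
                victims = [c for c in called if c != rep]
            for sid in victims:
                victim = next(p for p in kept if p.strain_id == sid)
                kept.remove(victim)
                removed.append((sid, rep, round_index))
                any_removed = True
        if not any_removed:
            return kept, PruneReport(kept=tuple(p.strain_id for p in kept),
                                     removed=tuple(removed),
                                     n_rounds=round_index)
    raise RuntimeError(
        f"pruning did not converge within {_MAX_ROUNDS} rounds")
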