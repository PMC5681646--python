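import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sid.genotype_model import AlleleCall, MetaProfile, StrainProfile

settings.register_profile(
    "default",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_panel():
    return ("L1", "L2", "L3")


def make_strain(strain_id, calls):
    """Build a StrainProfile from (locus, length) pairs."""
    return StrainProfile(strain_id, frozenset(AlleleCall(l, n) for l, n in calls))


def make_meta(sample_id, calls):
    return MetaProfile(sample_id, frozenset(AlleleCall(l, n) for l, n in calls))


@pytest.fixture(scope="session")
def disjoint_reference():
    """Five strains with mutually disjoint allele sets at 12 loci.

    Strain i carries lengths 100+10i and 103+10i at each locus, so no
    allele is shared between strains and every pool is exactly
    resolvable.
    """
    from sid.genotype_model import DEFAULT_PANEL

    strains = []
    for i in range(5):
        calls = []
        for locus in DEFAULT_PANEL:
            calls.append((locus, 100 + 10 * i))
            calls.append((locus, 103 + 10 * i))
        strains.append(make_strain(f"D{i + 1}", calls))
    return strains


def exhaustive_best_subset(reference, query):
    """Brute-force oracle: the smallest |union(subset) symm-diff query|
    over all non-empty strain subsets."""
    from itertools import combinations

    best = None
    for r in range(1, len(reference) + 1):
        for subset in combinations(reference, r):
            union = frozenset().union(*(p.calls for p in subset))
            score = len(union ^ query.calls)
            if best is None or score < best:
                best = score
    return best
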