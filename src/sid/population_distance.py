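"""Genetic distances and trees for SSR strain typing.

Strains are compared with the Cavalli-Sforza & Edwards chord distance,
the standard angular distance for microsatellite data.  Per strain and
locus, allele "frequencies" are taken uniform over the scored alleles
(1.0 for a homozygous/haploid call, 0.5/0.5 for a heterozygous one) --
this convention fixes the distance scale and is documented prominently
because a single strain, unlike a population sample, has no observed
frequencies.  Per locus,

    d_l = (2/pi) * sqrt( 2 * (1 - sum_a sqrt(f_p(a) * f_q(a))) )

and the distance is the mean of d_l over the loci typed in *both*
strains (loci failing in either strain are dropped pairwise, not
imputed).  The distance is bounded by (2/pi)*sqrt(2) ~ 0.9003, attained
when the strains share no allele at any compared locus.

Trees are built by neighbor joining on the resulting distance matrix and
midpoint-rooted; negative NJ branch-length estimates are clamped to zero
with a warning.  scikit-bio provides the NJ agglomeration, tree
structures and Newick serialization.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .genotype_model import StrainProfile

__all__ = [
    "CHORD_MAX",
    "locus_frequencies",
    "chord_distance",
    "chord_distance_matrix",
    "nj_tree",
    "midpoint_root",
    "write_newick",
]

#: Upper bound of the per-locus (and hence averaged) chord distance.
CHORD_MAX = (2.0 / math.pi) * math.sqrt(2.0)


def locus_frequencies(profile: StrainProfile, locus: str
                      ) -> Mapping[int, float]:
    """Uniform per-strain allele frequencies at one locus.

    One allele -> {length: 1.0}; two alleles -> 0.5 each; an (unusual,
    flagged at profile construction) k-allele locus -> 1/k each.  Raises
    if the strain has no scored allele at the locus; callers drop such
    loci pairwise.
    """
    calls = profile.calls_at(locus)
    if not calls:
        raise ValueError(
            f"strain {profile.strain_id!r} has no allele at locus {locus!r}")
    f = 1.0 / len(calls)
    return {c.length: f for c in calls}


def chord_distance(p: StrainProfile, q: StrainProfile) -> float:
    """Cavalli-Sforza & Edwards chord distance, averaged over shared loci."""
    shared = sorted(p.loci() & q.loci())
    if not shared:
        raise ValueError(
            f"strains {p.strain_id!r} and {q.strain_id!r} share no typed locus")
    total = 0.0
    for locus in shared:
        fp = locus_frequencies(p, locus)
        fq = locus_frequencies(q, locus)
        s = sum(math.sqrt(fp[a] * fq[a]) for a in fp.keys() & fq.keys())
        s = min(s, 1.0)  # guard rounding above 1
        total += (2.0 / math.pi) * math.sqrt(2.0 * (1.0 - s))
    return total / len(shared)


def chord_distance_matrix(profiles: Sequence[StrainProfile]) -> DistanceMatrix:
    """Pairwise chord-distance matrix over a strain collection."""
    ids = [p.strain_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate strain_id in collection")
    n = len(profiles)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = chord_distance(profiles[i], profiles[j])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(values, ids)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree (unrooted) from a distance matrix.

    Negative branch-length estimates (which NJ can produce on non-additive
    matrices) are clamped to zero with a warning; additive matrices are
    recovered exactly.
    """
    if dm.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tree = _skbio_nj(dm, neg_as_zero=False)
    n_neg = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            n_neg += 1
    if n_neg:
        warnings.warn(f"clamped {n_neg} negative NJ branch length(s) to zero",
                      stacklevel=2)
    return tree


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path.

    A tree whose branch lengths are all zero has no defined midpoint; the
    root is then placed on an arbitrary internal edge with a warning.
    """
    tips = list(tree.tips())
    if len(tips) < 2:
        raise ValueError("midpoint rooting needs at least 2 leaves")
    lengths = [n.length for n in tree.traverse() if n.length is not None]
    if lengths and max(lengths) == 0.0:
        warnings.warn("all branch lengths are zero: midpoint undefined, "
                      "rooting at an arbitrary internal edge", stacklevel=2)
        return tree.root_at(tips[0].parent)
    if len(tips) == 2:
        # two leaves: the midpoint splits the single path in half
        a, b = tips
        half = (a.length + b.length) / 2.0
        root = TreeNode()
        root.append(TreeNode(name=a.name, length=half))
        root.append(TreeNode(name=b.name, length=half))
        return root
    return tree.root_at_midpoint()


def write_newick(tree: TreeNode, path) -> None:
    """Write a tree as Newick, branch lengths at 6-decimal precision.

    Labels containing spaces or Newick metacharacters are quoted by the
    serializer; the output round-trips through a Newick parse.
    """
    out = tree.copy()
    for node in out.traverse():
        if node.length is not None:
            node.length = round(float(node.length), 6)
    out.write(str(path), format="newick")
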