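"""Core data model for SSR (microsatellite) genotypes.

A genotype here is a set of *allele calls*: one scored PCR fragment length
(in base pairs) at one SSR locus.  Single strains carry 1-2 alleles per
locus (haploid/homozygous vs heterozygous diploid); a mixed sample yields a
*meta-profile* -- the union of all alleles observed across the strains it
contains, with no per-locus bound.

Profiles are converted to presence/absence vectors over an *allele
universe* (the ordered union of all distinct alleles in a reference
collection plus, optionally, a query sample).  The resulting 0/1 matrix
(alleles x strains) is the design matrix of the deconvolution model in
:mod:`sid.deconvolution`.

Allele identity is exact ``(locus, integer length)`` equality; fragment
binning/stutter resolution belongs to upstream peak scoring and is out of
scope.  Loci that failed to amplify simply contribute no calls (zeros in
the encoding), not missing-data codes.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence, Union

import numpy as np
import pandas as pd

#: The 12-locus SSR panel used for S. cerevisiae strain typing.
DEFAULT_PANEL: tuple[str, ...] = (
    "C3", "C4", "C5", "C6", "C8", "C11",
    "SCYOR267C", "SCAAT1", "SCAAT3", "SCAAT5", "YKL172W", "YPL9",
)


class AlleleCall(NamedTuple):
    """One scored fragment length at one SSR locus."""

    locus: str
    length: int

    @staticmethod
    def make(locus: str, length: int) -> "AlleleCall":
        """Validated constructor: non-empty locus, positive integer length."""
        if not isinstance(locus, str) or not locus:
            raise ValueError(f"locus must be a non-empty string, got {locus!r}")
        length = int(length)
        if length <= 0:
            raise ValueError(f"allele length must be a positive integer, got {length}")
        return AlleleCall(locus, length)


def _locus_counts(calls: frozenset[AlleleCall]) -> Counter:
    return Counter(c.locus for c in calls)


@dataclass(frozen=True)
class StrainProfile:
    """SSR genotype of a single strain: a set of allele calls.

    Per-locus allele counts of 0 (failed amplification), 1 (haploid or
    homozygous) and 2 (heterozygous diploid) are expected; higher counts
    trigger a validation warning but are kept, since aneuploid strains and
    scoring artefacts do occur.
    """

    strain_id: str
    calls: frozenset[AlleleCall] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.strain_id:
            raise ValueError("strain_id must be non-empty")
        object.__setattr__(self, "calls", frozenset(
            AlleleCall.make(c[0], c[1]) for c in self.calls))
        for locus, n in _locus_counts(self.calls).items():
            if n > 2:
                warnings.warn(
                    f"strain {self.strain_id!r}: {n} alleles at locus {locus!r} "
                    "(expected at most 2 for a diploid)",
                    stacklevel=2,
                )

    def loci(self) -> set[str]:
        """Loci with at least one scored allele."""
        return {c.locus for c in self.calls}

    def calls_at(self, locus: str) -> set[AlleleCall]:
        return {c for c in self.calls if c.locus == locus}

    def restrict(self, loci: Iterable[str]) -> "StrainProfile":
        """Profile restricted to a locus subset (e.g. dropping noisy loci)."""
        keep = set(loci)
        kept = frozenset(c for c in self.calls if c.locus in keep)
        return StrainProfile(self.strain_id, kept)

    def __len__(self) -> int:
        return len(self.calls)


@dataclass(frozen=True)
class MetaProfile:
    """All SSR alleles observed in a (potentially mixed) sample.

    Unlike a :class:`StrainProfile`, the per-locus allele count is
    unbounded: a pool of k diploid strains can show up to 2k alleles at a
    locus.
    """

    sample_id: str
    calls: frozenset[AlleleCall] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        object.__setattr__(self, "calls", frozenset(
            AlleleCall.make(c[0], c[1]) for c in self.calls))

    def loci(self) -> set[str]:
        return {c.locus for c in self.calls}

    def calls_at(self, locus: str) -> set[AlleleCall]:
        return {c for c in self.calls if c.locus == locus}

    def restrict(self, loci: Iterable[str]) -> "MetaProfile":
        keep = set(loci)
        return MetaProfile(self.sample_id,
                           frozenset(c for c in self.calls if c.locus in keep))

    def __len__(self) -> int:
        return len(self.calls)


Profile = Union[StrainProfile, MetaProfile]


@dataclass(frozen=True)
class AlleleUniverse:
    """Ordered list of the distinct alleles spanned by a set of profiles.

    The deterministic ordering (locus name lexicographic, then length
    ascending) fixes the row order of every encoding and therefore makes
    downstream model fits bit-reproducible.
    """

    entries: tuple[AlleleCall, ...]

    def __post_init__(self) -> None:
        ordered = tuple(sorted(set(self.entries)))
        object.__setattr__(self, "entries", ordered)

    @property
    def index(self) -> Mapping[AlleleCall, int]:
        return {call: i for i, call in enumerate(self.entries)}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, call: AlleleCall) -> bool:
        return call in set(self.entries)

    def __iter__(self):
        return iter(self.entries)


def build_universe(reference: Sequence[StrainProfile],
                   extra: Profile | None = None) -> AlleleUniverse:
    """Allele universe spanning a reference collection plus an optional query.

    Alleles observed only in the query sample (absent from every reference
    strain) ARE included: they become rows of the design matrix that no
    strain can explain, and thus contribute to the model error.
    """
    if not reference and extra is None:
        raise ValueError("cannot build an allele universe from no profiles")
    calls: set[AlleleCall] = set()
    for p in reference:
        calls |= p.calls
    if extra is not None:
        calls |= extra.calls
    return AlleleUniverse(tuple(calls))


def encode(profile: Profile, universe: AlleleUniverse) -> np.ndarray:
    """0/1 presence vector of a profile over the universe rows.

    Raises if the profile carries an allele outside the universe -- the
    caller must rebuild the universe including the profile.
    """
    idx = universe.index
    vec = np.zeros(len(universe), dtype=np.float64)
    for call in profile.calls:
        if call not in idx:
            raise ValueError(
                f"allele {call} not in universe; rebuild the universe "
                "including this profile")
        vec[idx[call]] = 1.0
    return vec


def decode(vector: np.ndarray, universe: AlleleUniverse) -> frozenset[AlleleCall]:
    """Inverse of :func:`encode`: the set of alleles flagged present."""
    if len(vector) != len(universe):
        raise ValueError("vector length does not match universe size")
    return frozenset(call for call, v in zip(universe.entries, vector) if v)


@dataclass(frozen=True)
class BinaryMatrix:
    """Presence/absence design matrix: rows = universe alleles, cols = strains."""

    universe: AlleleUniverse
    strain_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.shape != (len(self.universe), len(self.strain_ids)):
            raise ValueError("matrix shape does not match universe/strains")
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("BinaryMatrix entries must be 0 or 1")
        object.__setattr__(self, "values", vals)

    @classmethod
    def from_profiles(cls, profiles: Sequence[StrainProfile],
                      universe: AlleleUniverse) -> "BinaryMatrix":
        ids = tuple(p.strain_id for p in profiles)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate strain_id in reference collection")
        cols = [encode(p, universe) for p in profiles]
        values = np.column_stack(cols) if cols else np.zeros((len(universe), 0))
        return cls(universe, ids, values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def union_profiles(profiles: Sequence[Profile],
                   sample_id: str | None = None) -> MetaProfile:
    """Expected meta-profile of a pool: the union of its members' alleles."""
    if not profiles:
        raise ValueError("union_profiles requires at least one profile")
    calls: set[AlleleCall] = set()
    for p in profiles:
        calls |= p.calls
    if sample_id is None:
        ids = [getattr(p, "strain_id", None) or getattr(p, "sample_id") for p in profiles]
        sample_id = "+".join(ids)
    return MetaProfile(sample_id, frozenset(calls))


class ProfileDifference(NamedTuple):
    """Size of the symmetric difference between two allele sets."""

    n_diff: int
    n_a: int
    n_b: int


def profile_difference(a: Profile, b: Profile) -> ProfileDifference:
    """Count alleles differing between two profiles (symmetric difference).

    This is the ``da`` quantity of the locus-error and model-error
    statistics: it penalises both alleles missing from ``a`` and alleles
    spurious in ``a`` relative to ``b`` (and vice versa), and is zero iff
    the two allele sets are identical.
    """
    sym = a.calls ^ b.calls
    return ProfileDifference(len(sym), len(a.calls), len(b.calls))


# ---------------------------------------------------------------------------
# genotype-table I/O
#
# Long format, tab-separated: one row per allele call.
#   strain_id <TAB> locus <TAB> length     (reference collections)
#   sample_id <TAB> locus <TAB> length     (query meta-profiles)

def _read_long_table(path, id_column: str, panel: Sequence[str] | None):
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (id_column, "locus", "length"):
        if col not in df.columns:
            raise ValueError(
                f"{path}: missing required column {col!r} "
                f"(found {list(df.columns)})")
    panel_set = set(panel) if panel is not None else None
    groups: dict[str, set[AlleleCall]] = {}
    order: list[str] = []
    for row_i, row in enumerate(df.itertuples(index=False)):
        line_no = row_i + 2  # 1-based, after the header line
        sid = getattr(row, id_column)
        locus = row.locus
        try:
            length = int(str(row.length))
            if length <= 0:
                raise ValueError
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}, line {line_no}: length {row.length!r} is not a "
                "positive integer") from None
        if panel_set is not None and locus not in panel_set:
            raise ValueError(
                f"{path}, line {line_no}: locus {locus!r} not in panel")
        if sid not in groups:
            groups[sid] = set()
            order.append(sid)
        groups[sid].add(AlleleCall.make(locus, length))
    return order, groups


def read_genotype_table(path, panel: Sequence[str] | None = None
                        ) -> list[StrainProfile]:
    """Read a reference genotype table (TSV) into strain profiles.

    Duplicate (strain, locus, length) rows collapse silently (set
    semantics); strain order follows first appearance in the file.
    """
    order, groups = _read_long_table(path, "strain_id", panel)
    return [StrainProfile(sid, frozenset(groups[sid])) for sid in order]


def read_meta_table(path, panel: Sequence[str] | None = None
                    ) -> list[MetaProfile]:
    """Read query meta-profiles (TSV with a ``sample_id`` column)."""
    order, groups = _read_long_table(path, "sample_id", panel)
    return [MetaProfile(sid, frozenset(groups[sid])) for sid in order]


def write_genotype_table(profiles: Sequence[Profile], path) -> None:
    """Write profiles in long TSV format (deterministic row order)."""
    rows = []
    for p in profiles:
        pid = getattr(p, "strain_id", None) or getattr(p, "sample_id")
        col = "strain_id" if isinstance(p, StrainProfile) else "sample_id"
        for call in sorted(p.calls):
            rows.append((pid, call.locus, call.length))
    header = "strain_id" if profiles and isinstance(profiles[0], StrainProfile) \
        else "sample_id"
    df = pd.DataFrame(rows, columns=[header, "locus", "length"])
    df.to_csv(path, sep="\t", index=False)


def read_locus_panel(path) -> list[str]:
    """Read a locus panel file: one locus name per line, blanks ignored."""
    names = [ln.strip() for ln in Path(path).read_text().splitlines()]
    names = [n for n in names if n]
    if not names:
        raise ValueError(f"{path}: empty locus panel")
    if len(set(names)) != len(names):
        raise ValueError(f"{path}: duplicate locus names in panel")
    return names
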