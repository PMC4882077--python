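"""ITS haplotypes over a shared alignment: typing, diagnostic sites, chimeras.

A heterokaryotic mushroom carrying several divergent ITS sequence types yields
clone libraries in which each clone is an exact copy of one type, a minor
variant (PCR substitution noise), or a PCR-mediated chimera spliced from two
types.  This module represents the types as states at polymorphic alignment
columns, classifies clones, locates type-specific and parsimony-informative
positions, tests whether the type counts depart from an equal ratio, and
models the superposition of several (possibly frame-shifted) sequences in a
single Sanger chromatogram, including indel-induced masking of polymorphisms.

Coordinates are 1-based alignment columns; a gap (``-``) is a coded fifth
character throughout.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace

from scipy import stats

GAP = "-"
STATES = "ACGT" + GAP


class CoordinateMismatchError(ValueError):
    """Haplotypes/clones do not share one alignment coordinate system."""


class TruncatedCloneError(ValueError):
    """Clone sequence ends before the last polymorphic column."""


class SpecificityUndefinedError(ValueError):
    """Type-specific sites need at least three haplotypes."""


@dataclass(frozen=True)
class RegionMap:
    """Half-open 1-based column ranges labelling ITS1 / 5.8S / ITS2.

    Boundaries are configuration, not observation: only the region membership
    of the polymorphic columns is constrained by the data.
    """

    regions: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        prev_end = 0
        for label, start, end in self.regions:
            if not (0 < start < end):
                raise ValueError(f"bad region range {label}: [{start}, {end})")
            if start < prev_end:
                raise ValueError("region ranges must be disjoint and ordered")
            prev_end = end

    def label(self, column: int) -> str:
        for name, start, end in self.regions:
            if start <= column < end:
                return name
        return "flank"


#: Default annotation placing the 13 classical polymorphic columns 8/1/4 into
#: ITS1 / 5.8S / ITS2 on the 662-column clone alignment.
DEFAULT_REGIONS = RegionMap((("ITS1", 1, 300), ("5.8S", 300, 440), ("ITS2", 440, 663)))


@dataclass(frozen=True)
class ITSHaplotype:
    """A named ITS sequence type defined by states at alignment columns.

    ``sequence`` optionally carries the full aligned sequence (with gaps);
    when present it must agree with ``states`` at every defined column.
    """

    name: str
    states: dict[int, str]
    sequence: str | None = None

    def __post_init__(self) -> None:
        for col, s in self.states.items():
            if s not in STATES:
                raise ValueError(f"{self.name}: state {s!r} at column {col}")
            if self.sequence is not None and self.sequence[col - 1] != s:
                raise ValueError(
                    f"{self.name}: sequence has {self.sequence[col - 1]!r} at "
                    f"column {col}, states say {s!r}"
                )

    @classmethod
    def from_sequence(cls, name: str, sequence: str, columns: list[int]) -> "ITSHaplotype":
        return cls(name, {c: sequence[c - 1] for c in columns}, sequence)

    def state(self, column: int) -> str:
        if self.sequence is not None:
            return self.sequence[column - 1]
        return self.states[column]

    def defined_columns(self) -> set[int]:
        if self.sequence is not None:
            return set(range(1, len(self.sequence) + 1))
        return set(self.states)


@dataclass
class CloneRecord:
    """One cloned amplicon sequence and its type assignment."""

    id: str
    sequence: str
    assignment: str | None = None  # type-exact | type-variant | chimera | unassigned
    assigned_type: str | None = None  # haplotype name, or "A/C" for a chimera
    variant_positions: tuple[int, ...] = ()
    breakpoint: tuple[int, int] | None = None


@dataclass(frozen=True)
class PolymorphicSite:
    column: int
    states: dict[str, str] = field(hash=False)
    region: str = "flank"


def _comparable_columns(haplotypes) -> list[int]:
    haplotypes = list(haplotypes)
    if len(haplotypes) < 2:
        raise ValueError("need at least two haplotypes")
    lengths = {len(h.sequence) for h in haplotypes if h.sequence is not None}
    if len(lengths) > 1:
        raise CoordinateMismatchError(f"alignment lengths differ: {sorted(lengths)}")
    common = set.intersection(*(h.defined_columns() for h in haplotypes))
    return sorted(common)


def find_polymorphic_sites(haplotypes, regions: RegionMap = DEFAULT_REGIONS) -> list[PolymorphicSite]:
    """Columns where at least two haplotypes differ (gap counts as a state)."""
    haplotypes = list(haplotypes)
    sites = []
    for col in _comparable_columns(haplotypes):
        seen = {h.state(col) for h in haplotypes}
        if len(seen) > 1:
            sites.append(
                PolymorphicSite(col, {h.name: h.state(col) for h in haplotypes}, regions.label(col))
            )
    return sites


def type_specific_sites(haplotypes, focal: str) -> list[int]:
    """Columns where ``focal`` differs from all other haplotypes, which agree.

    These are the bold "characters specific to each type" of a polymorphism
    table; specificity is undefined with fewer than three haplotypes.
    """
    haplotypes = list(haplotypes)
    if len(haplotypes) < 3:
        raise SpecificityUndefinedError("type specificity needs >= 3 haplotypes")
    by_name = {h.name: h for h in haplotypes}
    if focal not in by_name:
        raise KeyError(f"no haplotype named {focal!r}")
    others = [h for h in haplotypes if h.name != focal]
    out = []
    for site in find_polymorphic_sites(haplotypes):
        col = site.column
        other_states = {h.state(col) for h in others}
        if len(other_states) == 1 and by_name[focal].state(col) not in other_states:
            out.append(col)
    return out


def classify_clone(clone: CloneRecord, haplotypes, max_variant_sites: int = 2) -> CloneRecord:
    """Assign a clone to type-exact / type-variant / chimera / unassigned.

    Exact: identical to one haplotype at every column.  Variant: all
    polymorphic columns agree with one type and at most ``max_variant_sites``
    mismatches occur elsewhere.  Chimera: the polymorphic columns split into
    two contiguous donor blocks from two types (single breakpoint).  The
    classification is total and deterministic; checks run in that order.
    """
    haplotypes = list(haplotypes)
    poly = [s.column for s in find_polymorphic_sites(haplotypes)]
    if poly and len(clone.sequence) < max(poly):
        raise TruncatedCloneError(
            f"clone {clone.id}: length {len(clone.sequence)} < last polymorphic column {max(poly)}"
        )

    # exact match anywhere wins immediately (string compare is cheap)
    for h in haplotypes:
        if h.sequence is not None and clone.sequence == h.sequence:
            return replace(clone, assignment="type-exact", assigned_type=h.name,
                           variant_positions=(), breakpoint=None)

    def mismatches(h: ITSHaplotype) -> list[int]:
        if h.sequence is not None:
            return [i + 1 for i, (a, b) in enumerate(zip(clone.sequence, h.sequence)) if a != b]
        return [c for c in poly if clone.sequence[c - 1] != h.state(c)]

    best = None
    for h in haplotypes:
        mm = mismatches(h)
        if not mm:
            return replace(clone, assignment="type-exact", assigned_type=h.name,
                           variant_positions=(), breakpoint=None)
        if all(c not in poly for c in mm) and len(mm) <= max_variant_sites:
            if best is None or len(mm) < len(best[1]):
                best = (h, mm)
    if best is not None:
        h, mm = best
        return replace(clone, assignment="type-variant", assigned_type=h.name,
                       variant_positions=tuple(mm), breakpoint=None)

    # single-breakpoint chimera over the polymorphic columns
    match = {h.name: [clone.sequence[c - 1] == h.state(c) for c in poly] for h in haplotypes}
    for h1, h2 in itertools.permutations(haplotypes, 2):
        m1, m2 = match[h1.name], match[h2.name]
        if not all(a or b for a, b in zip(m1, m2)):
            continue
        only1 = [i for i, (a, b) in enumerate(zip(m1, m2)) if a and not b]
        only2 = [i for i, (a, b) in enumerate(zip(m1, m2)) if b and not a]
        if only1 and only2 and max(only1) < min(only2):
            return replace(
                clone, assignment="chimera", assigned_type=f"{h1.name}/{h2.name}",
                variant_positions=(), breakpoint=(poly[max(only1)], poly[min(only2)]),
            )
    return replace(clone, assignment="unassigned", assigned_type=None,
                   variant_positions=(), breakpoint=None)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    pvalue: float


def equal_ratio_chisq(counts) -> ChiSquareResult:
    """Pearson goodness-of-fit of observed counts against equal expectations.

    No continuity correction; df = k - 1.
    """
    counts = [int(c) for c in counts]
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("chi-square undefined for zero total count")
    stat, p = stats.chisquare(counts)
    return ChiSquareResult(float(stat), len(counts) - 1, float(p))


def parsimony_informative_sites(sequences) -> list[int]:
    """Columns with >= 2 states each present in >= 2 sequences (gaps coded)."""
    sequences = [str(s) for s in sequences]
    if len(sequences) < 4:
        warnings.warn("fewer than 4 sequences: no column can be parsimony informative")
        return []
    if len({len(s) for s in sequences}) > 1:
        raise CoordinateMismatchError("sequences have unequal alignment lengths")
    out = []
    for col in range(1, len(sequences[0]) + 1):
        counts = Counter(s[col - 1] for s in sequences)
        if sum(1 for n in counts.values() if n >= 2) >= 2:
            out.append(col)
    return out


def _parse_state_set(value) -> frozenset[str]:
    if isinstance(value, str):
        return frozenset(v for v in value.split("/") if v)
    return frozenset(value)


def assign_haplotype_group(observed: dict[int, object], haplotypes) -> tuple[str, tuple[str, ...]]:
    """Assign a specimen to a haplotype group from states at diagnostic columns.

    ``observed`` maps column -> state or superposed state set (``"A/G"`` or an
    iterable), as read off a heterokaryon's electropherogram.  Returns
    ``(group, constituents)`` where group is a haplotype name or ``"mixed"``;
    a mixed call lists every haplotype whose state vector is compatible with
    the superposition.  Raises ``ValueError`` when no haplotype fits.
    """
    haplotypes = list(haplotypes)
    obs = {col: _parse_state_set(v) for col, v in observed.items()}
    compatible = []
    for h in haplotypes:
        if all(h.state(col) in states for col, states in obs.items()):
            compatible.append(h.name)
    if not compatible:
        raise ValueError("states match no haplotype group and no superposition")
    # every observed state must be explained by some compatible haplotype
    by_name = {h.name: h for h in haplotypes}
    for col, states in obs.items():
        explained = {by_name[n].state(col) for n in compatible}
        if not states <= explained:
            raise ValueError(f"state(s) {states - explained} at column {col} unexplained")
    if len(compatible) == 1:
        return compatible[0], tuple(compatible)
    return "mixed", tuple(sorted(compatible))


@dataclass(frozen=True)
class TraceProfile:
    """Model of several sequences superposed in one chromatogram.

    ``columns[t-1]`` is the sorted tuple of bases the haplotypes contribute at
    trace position ``t`` (each haplotype reads its own ungapped coordinate, so
    a haplotype downstream of a deletion contributes shifted bases).
    ``detectable`` maps each polymorphic alignment column to whether the
    superposed peak pattern actually reveals it: a column is *masked* when the
    observed peaks are identical to those of an alignment in which all
    haplotypes share a single state there.
    """

    columns: tuple[tuple[str, ...], ...]
    shifts: dict[str, tuple[int, ...]] = field(hash=False)
    detectable: dict[int, bool] = field(hash=False)

    @property
    def masked_columns(self) -> tuple[int, ...]:
        return tuple(sorted(c for c, d in self.detectable.items() if not d))


def _peak_sets(sequences: list[str]) -> list[frozenset[str]]:
    ungapped = [s.replace(GAP, "") for s in sequences]
    n = max((len(u) for u in ungapped), default=0)
    return [frozenset(u[t] for u in ungapped if t < len(u)) for t in range(n)]


def superpose_traces(haplotypes) -> TraceProfile:
    """Superpose aligned haplotypes into a chromatogram-like trace profile."""
    haplotypes = list(haplotypes)
    if not haplotypes:
        return TraceProfile((), {}, {})
    seqs = {h.name: h.sequence for h in haplotypes}
    if any(s is None for s in seqs.values()):
        raise ValueError("superpose_traces needs full aligned sequences")
    if len({len(s) for s in seqs.values()}) > 1:
        raise CoordinateMismatchError("alignment lengths differ")

    ungapped = {n: s.replace(GAP, "") for n, s in seqs.items()}
    n_trace = max(len(u) for u in ungapped.values())
    columns = tuple(
        tuple(sorted(u[t] for u in ungapped.values() if t < len(u))) for t in range(n_trace)
    )
    shifts = {}
    for name, s in seqs.items():
        gaps = 0
        offs = []
        for ch in s:
            if ch == GAP:
                gaps += 1
            offs.append(-gaps)
        shifts[name] = tuple(offs)

    observed = _peak_sets(list(seqs.values()))
    detectable: dict[int, bool] = {}
    if len(haplotypes) > 1:
        for site in find_polymorphic_sites(haplotypes):
            col = site.column
            candidate_states = {h.state(col) for h in haplotypes}
            masked = False
            for s in candidate_states:
                modified = [q[: col - 1] + s + q[col:] for q in seqs.values()]
                if _peak_sets(modified) == observed:
                    masked = True
                    break
            detectable[col] = not masked
    return TraceProfile(columns, shifts, detectable)
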