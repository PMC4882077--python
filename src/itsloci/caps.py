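"""In-silico PCR-RFLP: degenerate site scanning, digestion, gel band rendering.

CAPS (cleaved amplified polymorphic sequence) markers genotype a PCR amplicon
by restriction digestion: a polymorphic base that completes or breaks a
recognition site changes the fragment pattern on an agarose gel.  This module
scans amplicon sequences for degenerate (IUPAC) recognition sites on both
strands, cuts with enzyme-specific offsets (Type IIS enzymes cut outside
their recognition site), and renders multi-allele band patterns with gel
co-migration merging and visibility rules.

Markers can also be defined directly by per-allele cut maps (amplicon length
plus cut coordinates), which is how the packaged fixtures encode loci whose
full sequences are not published.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement

_IUPAC_RE = {code: f"[{vals}]" if len(vals) > 1 else vals
             for code, vals in ambiguous_dna_values.items()}


class EdgeCutWarning(UserWarning):
    """A cut offset fell outside the amplicon; that cut is dropped."""


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction endonuclease with a degenerate recognition pattern.

    ``cut_offset_top`` / ``cut_offset_bottom`` are signed offsets from the 3'
    end of the recognition site on the respective strand: the top-strand cut
    falls after position ``site_end + cut_offset_top`` (1-based).  Type IIS
    enzymes have positive offsets (MboII 8/7, FokI 9/13); within-site cutters
    have negative ones (SalI G^TCGAC is -5).
    """

    name: str
    recognition: str
    cut_offset_top: int = 0
    cut_offset_bottom: int = 0

    def __post_init__(self) -> None:
        for ch in self.recognition.upper():
            if ch not in ambiguous_dna_values:
                raise ValueError(f"{self.name}: non-IUPAC code {ch!r} in recognition pattern")

    def _regex(self, pattern: str) -> re.Pattern:
        return re.compile("(?=" + "".join(_IUPAC_RE[c] for c in pattern.upper()) + ")")


# Canonical enzymes used by the packaged markers.
MBOII = EnzymeSpec("MboII", "GAAGA", 8, 7)
FOKI = EnzymeSpec("FokI", "GGATG", 9, 13)
SALI = EnzymeSpec("SalI", "GTCGAC", -5, -1)
KPNI = EnzymeSpec("KpnI", "GGTACC", -1, -5)
AVAII = EnzymeSpec("AvaII", "GGWCC", -4, -1)

ENZYMES = {e.name: e for e in (MBOII, FOKI, SALI, KPNI, AVAII)}


def find_sites(sequence: str, enzyme: EnzymeSpec) -> list[tuple[int, str]]:
    """All recognition-site matches on both strands, in top-strand coordinates.

    Returns ``(position, strand)`` pairs where position is the 1-based start
    of the match on the top strand and strand is ``'+'`` (pattern itself) or
    ``'-'`` (reverse complement of the pattern).  Overlapping matches are
    reported.  Degenerate bases in the pattern match per IUPAC.
    """
    seq = sequence.upper().replace("U", "T")
    out = [(m.start() + 1, "+") for m in enzyme._regex(enzyme.recognition).finditer(seq)]
    rc = reverse_complement(enzyme.recognition)
    if rc.upper() != enzyme.recognition.upper():  # palindromes match once
        out += [(m.start() + 1, "-") for m in enzyme._regex(rc).finditer(seq)]
    return sorted(out)


def cut_positions(sequence: str, enzyme: EnzymeSpec) -> list[int]:
    """Top-strand cut coordinates (number of bases 5' of the cut)."""
    L = len(enzyme.recognition)
    cuts = set()
    for pos, strand in find_sites(sequence, enzyme):
        if strand == "+":
            cut = pos + L - 1 + enzyme.cut_offset_top
        else:
            cut = pos - 1 - enzyme.cut_offset_top
        if 0 < cut < len(sequence):
            cuts.add(cut)
        else:
            warnings.warn(
                f"{enzyme.name} cut at {cut} falls outside the amplicon; dropped",
                EdgeCutWarning,
            )
    return sorted(cuts)


def fragments_from_cuts(length: int, cuts) -> list[int]:
    """Fragment lengths (descending) from cut coordinates on an amplicon."""
    cuts = sorted({c for c in cuts if 0 < c < length})
    bounds = [0, *cuts, length]
    return sorted((b - a for a, b in zip(bounds, bounds[1:])), reverse=True)


def digest(amplicon: str, enzymes) -> list[int]:
    """Fragment lengths after digesting an amplicon sequence.

    ``enzymes`` is one EnzymeSpec or an iterable (a double digest).  The
    fragments always partition the amplicon: their lengths sum to its length.
    """
    if isinstance(enzymes, EnzymeSpec):
        enzymes = [enzymes]
    cuts: set[int] = set()
    for enz in enzymes:
        cuts.update(cut_positions(amplicon, enz))
    return fragments_from_cuts(len(amplicon), cuts)


@dataclass(frozen=True)
class GelModel:
    """Electrophoresis behaviour of a 2% agarose gel, as scoring rules.

    resolution_rel: minimum resolvable relative length difference between two
        bands; closer bands co-migrate and are scored as one.  The default 2%
        is calibrated to the published patterns: 396/395 and 563/562 (~0.25%)
        co-migrate while 219/210 (~4%) resolve.
    min_visible_bp: smallest scoreable fragment.
    flag_redundant_smallest: when set, the smallest fragment of each
        multi-fragment single-allele digest is flagged uninformative (its
        length is implied by the others and the amplicon length) — the
        convention used when reporting ITS phenotype classes.
    """

    resolution_rel: float = 0.02
    min_visible_bp: int = 150
    flag_redundant_smallest: bool = False

    def __post_init__(self) -> None:
        if self.resolution_rel <= 0 or self.min_visible_bp <= 0:
            raise ValueError("gel parameters must be positive")

    def comigrate(self, a: int, b: int) -> bool:
        return abs(a - b) / ((a + b) / 2) < self.resolution_rel


DEFAULT_GEL = GelModel()


@dataclass(frozen=True)
class Band:
    """One visible gel band: the largest of a co-migrating set of fragments."""

    length: int
    comigrating: tuple[int, ...] = ()
    below_visibility: bool = False
    redundant: bool = False


@dataclass(frozen=True)
class BandPattern:
    """An electrophoretic phenotype: fragments, merged bands, annotations."""

    fragments: tuple[int, ...]
    bands: tuple[Band, ...]

    @property
    def visible(self) -> tuple[int, ...]:
        return tuple(b.length for b in self.bands if not b.below_visibility)

    @property
    def informative(self) -> tuple[int, ...]:
        """Band lengths printed outside parentheses in a phenotype table."""
        return tuple(b.length for b in self.bands if not (b.below_visibility or b.redundant))

    @property
    def parenthesized(self) -> tuple[int, ...]:
        """Co-migrating partners plus invisible or redundant bands."""
        out = []
        for b in self.bands:
            if b.below_visibility or b.redundant:
                out.append(b.length)
            out.extend(b.comigrating)
        return tuple(sorted(set(out), reverse=True))

    def format(self) -> str:
        main = "+".join(str(x) for x in self.informative)
        hidden = self.parenthesized
        if not hidden:
            return main
        return f"{main} (+{'+'.join(str(x) for x in hidden)})" if main else \
            f"(+{'+'.join(str(x) for x in hidden)})"


def render_pattern(fragments, gel: GelModel = DEFAULT_GEL) -> BandPattern:
    """Merge and annotate fragment lengths into a scored band pattern.

    ``fragments`` is either a flat iterable of lengths or a mapping
    ``allele -> lengths``; the mapping form is required for the
    redundant-smallest rule, which needs to know which fragments co-digested
    from one allele.  Duplicate lengths collapse.
    """
    if hasattr(fragments, "items"):
        per_allele = {k: sorted(v, reverse=True) for k, v in fragments.items()}
    else:
        per_allele = {None: sorted(fragments, reverse=True)}
    redundant: set[int] = set()
    if gel.flag_redundant_smallest:
        for frags in per_allele.values():
            if len(frags) > 1:
                redundant.add(min(frags))

    lengths = sorted({f for frags in per_allele.values() for f in frags}, reverse=True)
    if any(f < 1 for f in lengths):
        raise ValueError("fragments must be >= 1 bp")
    bands = []
    cluster: list[int] = []
    for f in lengths:
        if cluster and gel.comigrate(cluster[0], f):
            cluster.append(f)
        else:
            if cluster:
                bands.append(cluster)
            cluster = [f]
    if cluster:
        bands.append(cluster)
    return BandPattern(
        fragments=tuple(lengths),
        bands=tuple(
            Band(
                length=c[0],
                comigrating=tuple(c[1:]),
                below_visibility=c[0] < gel.min_visible_bp,
                redundant=c[0] in redundant and not any(x not in redundant for x in c),
            )
            for c in bands
        ),
    )


def patterns_distinguishable(p1: BandPattern, p2: BandPattern, gel: GelModel = DEFAULT_GEL) -> bool:
    """Whether two rendered patterns can be told apart on the gel.

    Band lists are compared with the gel's co-migration tolerance, using the
    informative bands (what a scorer records).
    """
    a, b = p1.informative, p2.informative
    if len(a) != len(b):
        return True
    return not all(gel.comigrate(x, y) for x, y in zip(a, b))


@dataclass(frozen=True)
class MarkerAllele:
    """One allele of a CAPS marker as a cut map calibrated to the gel tables."""

    name: str
    amplicon_length: int
    cuts: dict[str, tuple[int, ...]] = field(hash=False)  # enzyme name -> cut coords

    def fragments(self, enzyme_names=None) -> list[int]:
        if enzyme_names is None:
            enzyme_names = list(self.cuts)
        elif isinstance(enzyme_names, str):
            enzyme_names = [enzyme_names]
        cuts = {c for e in enzyme_names for c in self.cuts.get(e, ())}
        return fragments_from_cuts(self.amplicon_length, cuts)


@dataclass(frozen=True)
class CAPSMarker:
    """An amplified locus scored by restriction digestion of its alleles."""

    name: str
    enzymes: tuple[EnzymeSpec, ...]
    alleles: dict[str, MarkerAllele] = field(hash=False)
    primers: tuple[str, str] | None = None
    gel: GelModel = DEFAULT_GEL

    def enzyme_names(self) -> list[str]:
        return [e.name for e in self.enzymes]


def _parse_genotype(genotype) -> list[str]:
    if isinstance(genotype, str):
        return [a for a in genotype.split("/") if a]
    return list(genotype)


def genotype_to_phenotype(marker: CAPSMarker, genotype, enzyme: str | None = None) -> BandPattern:
    """Band pattern of a one- or two-allele genotype at a marker.

    A heteroallelic genotype shows the union of both alleles' fragments;
    rendering (merging, visibility, redundancy) happens after the union.
    """
    alleles = _parse_genotype(genotype)
    if not alleles:
        raise ValueError("empty genotype")
    for a in alleles:
        if a not in marker.alleles:
            raise KeyError(f"unknown allele {a!r} for marker {marker.name}")
    enzymes = [enzyme] if enzyme else marker.enzyme_names()
    per_allele = {a: marker.alleles[a].fragments(enzymes) for a in set(alleles)}
    return render_pattern(per_allele, marker.gel)


def its_phenotype(present_types, marker: CAPSMarker) -> tuple[str, dict[str, BandPattern]]:
    """Phenotype class label and per-enzyme band patterns of an ITS type set.

    ``present_types`` is a non-empty subset of the marker's alleles (the ITS
    sequence types present in a mycelium, e.g. ``{"A", "C"}``); the label is
    the bracketed class, e.g. ``"[A+C]"``.  The two-enzyme digest pair is what
    makes all seven classes distinguishable — a single enzyme confounds some.
    """
    types = sorted(set(present_types))
    if not types:
        raise ValueError("empty ITS type set")
    for t in types:
        if t not in marker.alleles:
            raise KeyError(f"unknown ITS type {t!r}")
    label = "[" + "+".join(types) + "]"
    patterns = {
        e: render_pattern({t: marker.alleles[t].fragments(e) for t in types}, marker.gel)
        for e in marker.enzyme_names()
    }
    return label, patterns
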