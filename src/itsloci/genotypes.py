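"""Karyotype classification, two-locus ITS genotype inference, and segregation tests.

Single-spore isolates (SSIs) of an amphithallic basidiomycete are homokaryons
(one haploid nucleus) or heterokaryons (two).  Co-dominant CAPS markers that
are heteroallelic in the parent classify them: heteroallelic at any locus ->
unambiguous heterokaryon; homoallelic at all loci -> putative homokaryon
(sister-nuclei heterokaryons can hide in that class).

The ITS band phenotype of an SSI is then interpreted under a two-locus model:
types A and B are alleles a/b at locus ITSI, type C is allele c at an
unlinked locus ITSII segregating against a null allele n.  Because c/c and
c/n give identical bands, genotypes at ITSII are carried as ambiguity sets.
Mendelian 1:1 segregation and pairwise linkage are tested with uncorrected
chi-square statistics (df = 1, alpha = 0.05).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

from scipy import stats

from .haplotypes import ChiSquareResult

PRS_LOCI = ("PRS016", "PRS049", "PRS088")
PHENOTYPE_CLASSES = ("[A]", "[B]", "[C]", "[A+B]", "[A+C]", "[B+C]", "[A+B+C]")

ALPHA = 0.05


@dataclass(frozen=True)
class LocusCall:
    """Observed alleles of one SSI at one marker locus."""

    locus: str
    alleles: frozenset[str]
    null_possible: bool = False

    def __post_init__(self) -> None:
        if not self.alleles and not self.null_possible:
            raise ValueError(f"{self.locus}: empty allele set at a locus without a null allele")

    @property
    def heteroallelic(self) -> bool:
        return len(self.alleles) >= 2

    @classmethod
    def parse(cls, locus: str, token, null_possible: bool = False) -> "LocusCall | None":
        """Parse a genotype-table token like ``1``, ``1/2``; blank -> None."""
        if token is None:
            return None
        token = str(token).strip()
        if not token or token.lower() in {"nan", "na", "-", "?"}:
            return None
        return cls(locus, frozenset(a for a in token.split("/") if a), null_possible)


@dataclass
class SSIRecord:
    """One single-spore isolate: marker calls plus its ITS band phenotype."""

    id: str
    calls: dict[str, LocusCall | None]
    its_phenotype: str | None = None
    karyotype: str | None = None  # homokaryon | heterokaryon | undetermined


def classify_karyotype(ssi: SSIRecord, loci=PRS_LOCI) -> str:
    """Heteroallelic at >= 1 locus -> heterokaryon; else putative homokaryon.

    Missing calls make the classification undetermined (flagged, since a
    heterozygous call could hide in the gap).
    """
    calls = [ssi.calls.get(locus) for locus in loci]
    if any(c is not None and c.heteroallelic for c in calls):
        ssi.karyotype = "heterokaryon"
    elif any(c is None for c in calls):
        ssi.karyotype = "undetermined"
    else:
        ssi.karyotype = "homokaryon"
    return ssi.karyotype


@dataclass(frozen=True)
class TwoLocusGenotype:
    """Genotype at the two ITS loci; ``itsII`` is an ambiguity set when the
    band phenotype cannot separate c/c from c/n."""

    itsI: str
    itsII: frozenset[str]

    def __str__(self) -> str:
        return f"ITSI={self.itsI}, ITSII={' or '.join(sorted(self.itsII))}"


def _g(itsI: str, *itsII: str) -> TwoLocusGenotype:
    return TwoLocusGenotype(itsI, frozenset(itsII))


_HOMOKARYON_GENOTYPES: dict[str, frozenset[TwoLocusGenotype]] = {
    "[A]": frozenset({_g("a", "n")}),
    "[B]": frozenset({_g("b", "n")}),
    "[C]": frozenset(),  # impossible: every haploid nucleus carries ITSI-a or -b
    "[A+B]": frozenset(),  # impossible: a homokaryon is haploid at ITSI
    "[A+C]": frozenset({_g("a", "c")}),
    "[B+C]": frozenset({_g("b", "c")}),
    "[A+B+C]": frozenset(),
}

_HETEROKARYON_GENOTYPES: dict[str, frozenset[TwoLocusGenotype]] = {
    "[A]": frozenset({_g("a/a", "n/n")}),
    "[B]": frozenset({_g("b/b", "n/n")}),
    "[C]": frozenset(),
    "[A+B]": frozenset({_g("a/b", "n/n")}),
    "[A+C]": frozenset({_g("a/a", "c/n", "c/c")}),
    "[B+C]": frozenset({_g("b/b", "c/n", "c/c")}),
    "[A+B+C]": frozenset({_g("a/b", "c/n", "c/c")}),
}


def infer_its_genotype(phenotype: str, karyotype: str) -> frozenset[TwoLocusGenotype]:
    """All two-locus genotypes consistent with a phenotype class.

    An empty set flags an observation inconsistent with the two-locus model
    (e.g. a pure-[C] or [A+B] homokaryon) — the diagnostic used to reject
    competing interpretations.
    """
    table = {"homokaryon": _HOMOKARYON_GENOTYPES, "heterokaryon": _HETEROKARYON_GENOTYPES}
    if karyotype not in table:
        raise ValueError(f"karyotype must be homokaryon/heterokaryon, got {karyotype!r}")
    if phenotype not in table[karyotype]:
        raise ValueError(f"unknown phenotype class {phenotype!r}")
    return table[karyotype][phenotype]


@dataclass(frozen=True)
class HypothesisVerdict:
    hypothesis: str
    consistent: bool
    witnesses: tuple[tuple[str, int], ...] = ()


def evaluate_hypotheses(homokaryon_counts: dict[str, int],
                        heterokaryon_counts: dict[str, int] | None = None,
                        ) -> dict[str, HypothesisVerdict]:
    """Evaluate the trikaryon vs two-unlinked-loci models against phenotype counts.

    A trikaryon parent (three nucleus types each carrying one ITS type) can
    only throw homokaryons of a single type: any [A+C] / [B+C] / [A+B] /
    [A+B+C] homokaryon is a rejection witness.  The two-locus model forbids
    homokaryon classes with an empty genotype interpretation ([C], [A+B],
    [A+B+C]) and any [C] heterokaryon.  Returns one verdict per hypothesis
    with the witness classes and counts.
    """
    heterokaryon_counts = heterokaryon_counts or {}
    for counts in (homokaryon_counts, heterokaryon_counts):
        for label in counts:
            if label not in PHENOTYPE_CLASSES:
                raise ValueError(f"unknown phenotype class {label!r}")

    tri_witnesses = tuple(
        (label, n) for label, n in homokaryon_counts.items()
        if n > 0 and label not in ("[A]", "[B]", "[C]")
    )
    two_witnesses = tuple(
        (label, n) for label, n in homokaryon_counts.items()
        if n > 0 and not _HOMOKARYON_GENOTYPES[label]
    ) + tuple(
        (label, n) for label, n in heterokaryon_counts.items()
        if n > 0 and not _HETEROKARYON_GENOTYPES[label]
    )
    return {
        "trikaryon": HypothesisVerdict("trikaryon", not tri_witnesses, tri_witnesses),
        "two_locus": HypothesisVerdict("two_locus", not two_witnesses, two_witnesses),
    }


@dataclass(frozen=True)
class SegregationResult(ChiSquareResult):
    counts: tuple[int, int] = (0, 0)
    verdict: str = ""


def segregation_test(counts, alpha: float = ALPHA) -> SegregationResult:
    """1:1 goodness-of-fit chi-square for two allele classes (uncorrected)."""
    counts = tuple(int(c) for c in counts)
    if len(counts) != 2:
        raise ValueError("segregation_test expects exactly two allele classes")
    if sum(counts) == 0:
        raise ValueError("no observations")
    stat, p = stats.chisquare(counts)
    verdict = "1:1 not rejected" if p >= alpha else "1:1 rejected"
    return SegregationResult(float(stat), 1, float(p), counts, verdict)


@dataclass(frozen=True)
class LinkageResult(ChiSquareResult):
    table: tuple[tuple[int, int], tuple[int, int]] = ((0, 0), (0, 0))
    #: The two allele-arrangement counts (a-c/b-n vs a-n/b-c), ascending;
    #: true phase is unknown, so the ratio is reported symmetrically.
    arrangement_counts: tuple[int, int] = (0, 0)
    verdict: str = ""


def linkage_test(table, alpha: float = ALPHA) -> LinkageResult:
    """2x2 contingency chi-square between two loci among haploid offspring.

    ``table`` is ((n_a_c, n_a_n), (n_b_c, n_b_n)): joint haploid two-locus
    class counts.  Independence not rejected => loci unlinked.  The
    parental:recombinant split is the pair of diagonal sums, reported in
    ascending order because allele phase in the parent is unknown.
    """
    (a, b), (c, d) = ((int(x), int(y)) for x, y in table)
    arrangements = tuple(sorted((a + d, b + c)))
    if min(a + b, c + d, a + c, b + d) == 0:
        warnings.warn("a zero margin leaves the linkage statistic undefined")
        return LinkageResult(float("nan"), 1, float("nan"), ((a, b), (c, d)),
                             arrangements, "undefined")
    stat, p, _, _ = stats.chi2_contingency([[a, b], [c, d]], correction=False)
    verdict = "independence not rejected (unlinked)" if p >= alpha else "linked"
    return LinkageResult(float(stat), 1, float(p), ((a, b), (c, d)), arrangements, verdict)


_ITSI_GENOTYPE_BY_CLASS = {
    "[A]": "a/a", "[A+C]": "a/a", "[B]": "b/b", "[B+C]": "b/b",
    "[A+B]": "a/b", "[A+B+C]": "a/b",
}
_ITSII_NULL_HOMOZYGOUS_CLASSES = {"[A]", "[B]", "[A+B]"}


def homozygosity_rate(records, locus: str) -> float:
    """Fraction of heterokaryons homoallelic at a locus.

    For the PRS markers this is read off the allele calls.  For ITSI it is
    derived from the phenotype class (classes without both A and B are a/a or
    b/b).  For ITSII only null homozygosity (n/n) is observable — classes
    containing C are ambiguous c/n-or-c/c and count as not-null-homozygous.
    Records with undetermined information at the locus are excluded from the
    denominator (logged).
    """
    hets = [r for r in records if r.karyotype == "heterokaryon"]
    if not hets:
        raise ValueError("no heterokaryon records")
    n_hom = 0
    denom = 0
    skipped = 0
    for r in hets:
        if locus == "ITSI":
            g = _ITSI_GENOTYPE_BY_CLASS.get(r.its_phenotype or "")
            if g is None:
                skipped += 1
                continue
            denom += 1
            n_hom += g in ("a/a", "b/b")
        elif locus == "ITSII":
            if r.its_phenotype not in PHENOTYPE_CLASSES or r.its_phenotype == "[C]":
                skipped += 1
                continue
            denom += 1
            n_hom += r.its_phenotype in _ITSII_NULL_HOMOZYGOUS_CLASSES
        else:
            call = r.calls.get(locus)
            if call is None:
                skipped += 1
                continue
            denom += 1
            n_hom += not call.heteroallelic
    if skipped:
        warnings.warn(f"{skipped} heterokaryon(s) uninformative at {locus}; excluded")
    if denom == 0:
        raise ValueError(f"no heterokaryon callable at {locus}")
    return n_hom / denom


def allele_counts_from_homokaryons(phenotype_counts: dict[str, int]) -> dict[str, dict[str, int]]:
    """Per-locus allele counts among homokaryons, from phenotype class counts."""
    itsI: dict[str, int] = {"a": 0, "b": 0}
    itsII: dict[str, int] = {"c": 0, "n": 0}
    for label, n in phenotype_counts.items():
        genotypes = infer_its_genotype(label, "homokaryon")
        if not genotypes:
            if n > 0:
                raise ValueError(f"{n} homokaryon(s) with impossible phenotype {label}")
            continue
        (g,) = genotypes
        itsI[g.itsI] += n
        (allele,) = g.itsII
        itsII[allele] += n
    return {"ITSI": itsI, "ITSII": itsII}


def theoretical_type_combinations(present_types) -> list[str]:
    """All non-empty combinations of the parent's ITS types (what offspring
    *could* show if types assorted freely): 2^k - 1 phenotype class labels."""
    types = sorted(set(present_types))
    out = []
    for r in range(1, len(types) + 1):
        for combo in itertools.combinations(types, r):
            out.append("[" + "+".join(combo) + "]")
    return out


def enumerate_offspring_phenotypes(itsI: tuple[str, str] = ("a", "b"),
                                   itsII: tuple[str, str] = ("c", "n"),
                                   type_of_itsI: dict[str, str | None] | None = None,
                                   type_of_itsII: dict[str, str | None] | None = None,
                                   ) -> list[str]:
    """Phenotype classes the parent can actually throw under the two-locus model.

    Enumerates every gamete (haploid nucleus genotype) and every paired-nucleus
    combination, maps each to its set of present ITS types, and returns the
    distinct class labels.  For an a/b, c/n parent this yields six classes:
    pure [C] is impossible because every nucleus carries an ITSI allele.
    """
    type_of_itsI = type_of_itsI or {"a": "A", "b": "B"}
    type_of_itsII = type_of_itsII or {"c": "C", "n": None}
    gametes = list(itertools.product(set(itsI), set(itsII)))

    def types_of(nuclei) -> frozenset[str]:
        present = set()
        for x, y in nuclei:
            for t in (type_of_itsI[x], type_of_itsII[y]):
                if t is not None:
                    present.add(t)
        return frozenset(present)

    combos = {types_of([g]) for g in gametes}
    combos |= {types_of(pair) for pair in itertools.combinations_with_replacement(gametes, 2)}
    return sorted("[" + "+".join(sorted(c)) + "]" for c in combos if c)
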