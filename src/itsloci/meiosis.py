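"""Random tetrasporic meiosis simulator and synthetic-data generator.

In an amphithallic basidiomycete, each basidium carries out one meiosis (four
haploid products); in a variable fraction of basidia a post-meiotic mitosis
duplicates them to eight nuclei and each of the four spores receives two.
Two-nucleus spores are heterokaryotic; under random pairing of distinct
meiotic products, one third of them receive sister nuclei (same second
meiotic division), so the expected loss of parental heterozygosity among
heterokaryotic offspring is 1/3 at any locus — centromere-linked or not.

Crossing over is abstracted per locus into a second-division segregation
(SDS) frequency ``f``: with probability ``f`` both second-division pairs
carry both alleles (the locus recombined away from its centromere), otherwise
each pair is homoallelic.  ``f = 0`` models tight centromere linkage; ``f``
approaches 2/3 for a freely recombining distal locus.

The generators emit clone libraries (FASTA-ready aligned sequences with
substitution noise and PCR chimeras) and single-spore-isolate genotype tables
in the exact shape the inference modules consume, along with hidden truth
tables for parameter-recovery checks.  All randomness flows through one
seeded generator in documented draw order, so identical seeds replay
byte-identically.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import pandas as pd

from . import fixtures
from .caps import its_phenotype as _its_phenotype
from .genotypes import LocusCall, SSIRecord
from .haplotypes import GAP


@dataclass(frozen=True)
class Locus:
    """One heteroallelic locus of the parent: two alleles and an SDS frequency."""

    name: str
    chromosome: str
    alleles: tuple[str, str]
    sds_freq: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sds_freq <= 1.0:
            raise ValueError(f"{self.name}: sds_freq must lie in [0, 1]")
        if len(self.alleles) != 2 or self.alleles[0] == self.alleles[1]:
            raise ValueError(f"{self.name}: need two distinct alleles")


@dataclass(frozen=True)
class ParentGenome:
    """The heterokaryotic parent as a list of heteroallelic loci."""

    loci: tuple[Locus, ...]

    def index(self, name: str) -> int:
        for i, locus in enumerate(self.loci):
            if locus.name == name:
                return i
        raise KeyError(name)


#: ITS allele -> sequence type carried (None = null allele, no ITS copy).
DEFAULT_TYPE_OF_ALLELE = {"ITSI": {"a": "A", "b": "B"}, "ITSII": {"c": "C", "n": None}}


def ca487_parent(f_distal: float = 0.6) -> ParentGenome:
    """The study parent: ITSI (a|b) and ITSII (c|null) on unlinked chromosomes,
    plus three CAPS marker loci, PRS088 tightly centromere-linked (f = 0)."""
    return ParentGenome((
        Locus("ITSI", "chr-ITSI", ("a", "b"), f_distal),
        Locus("ITSII", "chr-ITSII", ("c", "n"), f_distal),
        Locus("PRS016", "chr-X", ("1", "2"), f_distal),
        Locus("PRS049", "chr-III", ("1", "2"), f_distal),
        Locus("PRS088", "chr-I", ("1", "2"), 0.0),
    ))


@dataclass(frozen=True)
class BasidiumModel:
    """Parameters of basidiospore formation.

    p_mitosis: probability a basidium undergoes post-meiotic mitosis (eight
        nuclei, all four spores binucleate) instead of none (four uninucleate
        spores).  Default 0.27, the heterokaryotic-spore rate observed in the
        study offspring; field reports range from 40% to 75%.
    pairing_rule: how the eight post-mitotic nuclei pair into spores.
        ``random_non_twin`` draws, per spore, a uniform unordered pair of
        distinct meiotic products (twins excluded) — sister pairs then make
        up one third; ``sister_bias`` draws a sister pair with probability
        ``beta`` (beta = 1/3 recovers the random rule); ``allow_twin`` draws
        uniformly over all pairs of the eight nuclei, twins included.
    """

    p_mitosis: float = 0.27
    pairing_rule: str = "random_non_twin"
    beta: float = 1 / 3
    spores_per_basidium: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_mitosis <= 1.0:
            raise ValueError("p_mitosis must lie in [0, 1]")
        if self.pairing_rule not in ("random_non_twin", "sister_bias", "allow_twin"):
            raise ValueError(f"unknown pairing rule {self.pairing_rule!r}")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")


@dataclass(frozen=True)
class SimulatedSpore:
    """One basidiospore: 1 or 2 haploid nuclei (allele tuples in locus order)."""

    nuclei: tuple[tuple[str, ...], ...]
    product_indices: tuple[int, ...]  # meiotic products (0,1 = MII pair 1; 2,3 = pair 2)

    @property
    def heterokaryotic(self) -> bool:
        """Received two nuclei (the developmental truth label)."""
        return len(self.nuclei) == 2

    @property
    def genetically_distinct(self) -> bool:
        return len(set(self.nuclei)) == 2

    @property
    def sister_pair(self) -> bool | None:
        if not self.heterokaryotic:
            return None
        i, j = self.product_indices
        return i != j and i // 2 == j // 2

    @property
    def twin_pair(self) -> bool | None:
        if not self.heterokaryotic:
            return None
        i, j = self.product_indices
        return i == j

    def alleles_at(self, locus_index: int) -> frozenset[str]:
        return frozenset(n[locus_index] for n in self.nuclei)


_SISTER_PAIRS = ((0, 1), (2, 3))
_NON_SISTER_PAIRS = ((0, 2), (0, 3), (1, 2), (1, 3))
_ALL_DISTINCT_PAIRS = _SISTER_PAIRS + _NON_SISTER_PAIRS


def simulate_meiosis(parent: ParentGenome, rng: random.Random) -> list[tuple[str, ...]]:
    """Four haploid products of one meiosis; indices 0,1 and 2,3 are the two
    second-division pairs.

    Per chromosome: one MI orientation draw and one crossover uniform shared
    by all its loci (a locus undergoes SDS when the uniform falls below its
    ``f``, so SDS events on one chromosome are nested by map distance).
    """
    chrom_draws: dict[str, tuple[bool, float]] = {}
    columns = []
    for locus in parent.loci:
        if locus.chromosome not in chrom_draws:
            chrom_draws[locus.chromosome] = (rng.random() < 0.5, rng.random())
        flip, u = chrom_draws[locus.chromosome]
        p, q = locus.alleles if not flip else (locus.alleles[1], locus.alleles[0])
        if u < locus.sds_freq:
            pair1 = (p, q) if rng.random() < 0.5 else (q, p)
            pair2 = (p, q) if rng.random() < 0.5 else (q, p)
            columns.append((*pair1, *pair2))
        else:
            columns.append((p, p, q, q))
    return [tuple(col[i] for col in columns) for i in range(4)]


def _draw_pair(model: BasidiumModel, rng: random.Random) -> tuple[int, int]:
    if model.pairing_rule == "random_non_twin":
        return rng.choice(_ALL_DISTINCT_PAIRS)
    if model.pairing_rule == "sister_bias":
        if rng.random() < model.beta:
            return rng.choice(_SISTER_PAIRS)
        return rng.choice(_NON_SISTER_PAIRS)
    # allow_twin: uniform over unordered pairs of the eight post-mitotic nuclei
    i, j = rng.sample(range(8), 2)
    return (i % 4, j % 4)


def simulate_basidium(parent: ParentGenome, model: BasidiumModel,
                      rng: random.Random) -> list[SimulatedSpore]:
    """One basidium: four spores, uninucleate or binucleate per the model."""
    products = simulate_meiosis(parent, rng)
    if rng.random() >= model.p_mitosis:
        return [SimulatedSpore((products[i],), (i,)) for i in range(model.spores_per_basidium)]
    spores = []
    for _ in range(model.spores_per_basidium):
        i, j = _draw_pair(model, rng)
        spores.append(SimulatedSpore((products[i], products[j]), (i, j)))
    return spores


@dataclass(frozen=True)
class MonteCarloEstimate:
    estimate: float
    se: float
    n: int


def estimate_het_loss(parent: ParentGenome, model: BasidiumModel, locus: str,
                      n_basidia: int, seed: int | None = None) -> MonteCarloEstimate:
    """Monte-Carlo fraction of heterokaryotic spores homoallelic at a locus.

    Under random non-twin pairing this is 1/3 regardless of the locus's SDS
    frequency — heterozygosity retention among binucleate spores is 2/3 at
    any locus, centromeres included.
    """
    idx = parent.index(locus)
    rng = random.Random(seed)
    n_het = 0
    n_hom = 0
    for _ in range(n_basidia):
        for spore in simulate_basidium(parent, model, rng):
            if spore.heterokaryotic:
                n_het += 1
                if len(spore.alleles_at(idx)) == 1:
                    n_hom += 1
    if n_het == 0:
        raise ValueError("no heterokaryotic spores produced (p_mitosis too low?)")
    p = n_hom / n_het
    return MonteCarloEstimate(p, math.sqrt(p * (1 - p) / n_het), n_het)


def estimate_misclassification(parent: ParentGenome, model: BasidiumModel,
                               marker_loci, n_basidia: int,
                               seed: int | None = None) -> MonteCarloEstimate:
    """Probability a binucleate (heterokaryotic) spore is homoallelic at ALL
    the marker loci — the multilocus genotype test's blind spot.

    Monotonically non-increasing as markers are added; with no markers every
    heterokaryon is missed (probability 1).
    """
    indices = [parent.index(name) for name in marker_loci]
    rng = random.Random(seed)
    n_het = 0
    n_missed = 0
    for _ in range(n_basidia):
        for spore in simulate_basidium(parent, model, rng):
            if spore.heterokaryotic:
                n_het += 1
                if all(len(spore.alleles_at(i)) == 1 for i in indices):
                    n_missed += 1
    if n_het == 0:
        raise ValueError("no heterokaryotic spores produced")
    p = n_missed / n_het
    return MonteCarloEstimate(p, math.sqrt(p * (1 - p) / max(n_het, 1)), n_het)


@dataclass
class SSIDataset:
    """A simulated single-spore-isolate cohort with its hidden truth table."""

    records: list[SSIRecord]
    table: pd.DataFrame
    truth: pd.DataFrame


def _spore_its_types(spore: SimulatedSpore, parent: ParentGenome,
                     type_of_allele=DEFAULT_TYPE_OF_ALLELE) -> frozenset[str]:
    present = set()
    for locus_name, mapping in type_of_allele.items():
        idx = parent.index(locus_name)
        for nucleus in spore.nuclei:
            t = mapping.get(nucleus[idx])  # unmapped alleles carry no ITS copy
            if t is not None:
                present.add(t)
    return frozenset(present)


def generate_ssi_dataset(parent: ParentGenome, model: BasidiumModel, n_spores: int,
                         seed: int | None = None, markers=None) -> SSIDataset:
    """Germinate ``n_spores`` from simulated basidia into a genotype table.

    Each spore is rendered through the CAPS marker fixtures into allele calls
    at the PRS loci and an ITS band phenotype (MboII + FokI), i.e. the exact
    table the classification/segregation pipeline consumes; a truth table
    records nuclei, karyotype and sister/twin status for recovery tests.
    """
    markers = markers if markers is not None else fixtures.load_markers()
    its = markers["ITS"]
    prs_names = [n for n in ("PRS016", "PRS049", "PRS088")
                 if any(l.name == n for l in parent.loci)]
    rng = random.Random(seed)

    records: list[SSIRecord] = []
    table_rows = []
    truth_rows = []
    spores: list[SimulatedSpore] = []
    while len(spores) < n_spores:
        spores.extend(simulate_basidium(parent, model, rng))
    for k, spore in enumerate(spores[:n_spores], start=1):
        sid = f"SSI-{k:04d}"
        calls = {}
        for name in prs_names:
            alleles = spore.alleles_at(parent.index(name))
            calls[name] = LocusCall(name, alleles)
        types = _spore_its_types(spore, parent)
        if types:
            label, patterns = _its_phenotype(types, its)
            mboii = "+".join(map(str, patterns["MboII"].informative))
            foki = "+".join(map(str, patterns["FokI"].informative))
        else:  # a nucleus set with no ITS copy at all cannot occur for CA487
            label, mboii, foki = None, "", ""
        records.append(SSIRecord(sid, calls, label))
        table_rows.append({
            "id": sid,
            **{name: "/".join(sorted(calls[name].alleles)) for name in prs_names},
            "ITS_MboII": mboii,
            "ITS_FokI": foki,
        })
        truth_rows.append({
            "id": sid,
            "n_nuclei": len(spore.nuclei),
            "heterokaryotic": spore.heterokaryotic,
            "genetically_distinct": spore.genetically_distinct,
            "sister_pair": spore.sister_pair,
            "its_class": label,
            "nuclei": ";".join(",".join(n) for n in spore.nuclei),
        })
    return SSIDataset(records, pd.DataFrame(table_rows), pd.DataFrame(truth_rows))


@dataclass(frozen=True)
class CloneLibraryModel:
    """PCR clone-library noise model.

    Defaults mirror the study library: 284 clones from three equally weighted
    templates (equal rDNA copy numbers give the expected 1:1:1 type ratio),
    a mean of 0.5 random substitutions per clone and a 5% chimera rate, so
    the expected exact-type fraction is (1-0.05)e^{-0.5} ~ 0.58.
    """

    n_clones: int = 284
    weights: dict[str, float] = field(default_factory=lambda: {"A": 1.0, "B": 1.0, "C": 1.0},
                                      hash=False)
    mean_substitutions: float = 0.5
    chimera_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.n_clones < 0 or self.mean_substitutions < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.chimera_rate <= 1.0:
            raise ValueError("chimera_rate must lie in [0, 1]")
        if self.weights and min(self.weights.values()) < 0:
            raise ValueError("weights must be non-negative")


@dataclass(frozen=True)
class GeneratedClone:
    """One simulated clone sequence plus its generative truth."""

    id: str
    sequence: str
    template: str  # template type, or "X/Y" for a chimera
    is_chimera: bool
    breakpoint_column: int | None
    substituted_columns: tuple[int, ...]

    @property
    def effective_chimera(self) -> bool:
        """A chimera whose sequence actually differs from both donors."""
        return self.is_chimera and self.breakpoint_column is not None


def generate_clone_library(model: CloneLibraryModel, haplotypes=None,
                           seed: int | None = None) -> list[GeneratedClone]:
    """Sample an aligned clone library from the haplotype templates.

    Per clone, in draw order: chimera?; template(s); breakpoint or Poisson
    substitution count and columns.  Chimeras splice two distinct templates
    at a uniform alignment column; substitutions hit uniform non-gap columns
    and change the base.  Sequences stay in alignment coordinates (gaps kept)
    so they feed straight into clone classification.
    """
    haplotypes = list(haplotypes) if haplotypes is not None else list(fixtures.builtin_haplotypes())
    by_name = {h.name: h for h in haplotypes}
    names = [n for n in by_name if model.weights.get(n, 0) > 0]
    weights = [model.weights[n] for n in names]
    rng = random.Random(seed)
    clones = []
    for k in range(1, model.n_clones + 1):
        cid = f"clone-{k:04d}"
        if len(names) >= 2 and rng.random() < model.chimera_rate:
            h1, h2 = rng.sample(names, 2)
            ncol = len(by_name[h1].sequence)
            bp = rng.randint(2, ncol - 1)
            seq = by_name[h1].sequence[: bp - 1] + by_name[h2].sequence[bp - 1:]
            effective = seq != by_name[h1].sequence and seq != by_name[h2].sequence
            clones.append(GeneratedClone(cid, seq, f"{h1}/{h2}", True,
                                         bp if effective else None, ()))
            continue
        t = rng.choices(names, weights)[0]
        seq = by_name[t].sequence
        n_subs = _poisson(model.mean_substitutions, rng)
        cols: list[int] = []
        if n_subs:
            candidates = [i + 1 for i, ch in enumerate(seq) if ch != GAP]
            cols = sorted(rng.sample(candidates, min(n_subs, len(candidates))))
            chars = list(seq)
            for c in cols:
                chars[c - 1] = rng.choice([b for b in "ACGT" if b != chars[c - 1]])
            seq = "".join(chars)
        clones.append(GeneratedClone(cid, seq, t, False, None, tuple(cols)))
    return clones


def _poisson(lam: float, rng: random.Random) -> int:
    """Knuth's Poisson sampler (lambda is tiny here)."""
    if lam <= 0:
        return 0
    L = math.exp(-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= L:
            return k
        k += 1
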