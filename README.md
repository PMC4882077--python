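# itsloci

Genetic analysis of intragenomic ITS heterogeneity in amphithallic mushrooms.

Some wild *Agaricus* strains carry **three distinct ITS sequence types** in one
mycelium — direct Sanger sequencing shows stable double and triple peaks. This
package implements the full analysis chain that resolves such a pattern into a
genetic model: two ITS types (A, B) segregating as alleles *a*/*b* at one locus
**ITSI**, and a third type (C) at an unlinked second locus **ITSII** segregating
against a **null allele**, present in only one of the parent's two nuclei.

It is a library for geneticists working with basidiomycete single-spore
progenies and clone libraries, with a thin `itsloci` CLI for the common
file-in/file-out steps.

## What it does

- **Clone-library typing** (`itsloci.haplotypes`): represent ITS haplotypes as
  states at polymorphic alignment columns; classify cloned amplicons as exact
  types, minor variants, or single-breakpoint PCR chimeras; find type-specific
  and parsimony-informative columns; test type counts against a 1:1:1 ratio;
  model superposed chromatograms, including indel-induced masking of peaks.
- **In-silico CAPS / PCR-RFLP** (`itsloci.caps`): scan amplicons for degenerate
  restriction sites on both strands (Type IIS cut offsets included), digest,
  and render multi-allele band patterns with gel co-migration and visibility
  rules. Packaged fixtures reproduce the published marker tables exactly.
- **Karyotype & genotype inference** (`itsloci.genotypes`): the multilocus
  genotype test (heteroallelic at ≥1 locus ⇒ heterokaryon), the phenotype →
  two-locus genotype map with the c/c-vs-c/n ambiguity carried explicitly,
  1:1 segregation and 2×2 linkage chi-square tests, heterokaryon homozygosity
  rates, and formal trikaryon-vs-two-locus hypothesis evaluation with
  rejection witnesses.
- **Meiosis simulator / data generator** (`itsloci.meiosis`): random
  tetrasporic basidia with optional post-meiotic mitosis, random (or biased)
  nucleus pairing, and per-locus second-division segregation frequency *f*;
  emits clone libraries (FASTA) and SSI genotype tables (TSV) with hidden
  truth labels for parameter-recovery testing.

The central theoretical result the simulator reproduces: with post-meiotic
mitosis and random pairing of distinct meiotic products, the expected loss of
parental heterozygosity among heterokaryotic spores is **1/3 at any locus** —
sister pairs (probability 1/3) are homoallelic at centromere-linked loci, and
under second-division segregation crossovers create exactly as much
heterozygosity in sister pairs as they remove from non-sister pairs:
P(heterozygous) = ⅓·f + ⅔·(1 − f/2) = ⅔ for all f.

## Worked example

```python
from collections import Counter
from itsloci import CloneRecord, classify_clone, equal_ratio_chisq
from itsloci.fixtures import builtin_haplotypes
from itsloci.meiosis import CloneLibraryModel, generate_clone_library

haps = builtin_haplotypes()
clones = generate_clone_library(CloneLibraryModel(), seed=1)   # 284 clones
assigned = [classify_clone(CloneRecord(c.id, c.sequence), haps) for c in clones]
counts = Counter(r.assigned_type for r in assigned if r.assignment == "type-exact")
chi = equal_ratio_chisq([counts[t] for t in "ABC"])
print(dict(sorted(counts.items())), f"chi2={chi.statistic:.2f} p={chi.pvalue:.2f}")
```

prints

```
{'A': 59, 'B': 61, 'C': 53} chi2=0.60 p=0.74
```

i.e. of 284 noisy clones, 173 type exactly (59 A : 61 B : 53 C here); the
goodness-of-fit p = 0.74 means the three types are equally abundant, as
expected when the three rDNA arrays have similar copy numbers. The
`examples/` directory has one short script per capability (clone typing,
digestion, offspring genetics, the meiosis model, trace superposition), each
printing its numbers with a line on what they mean. The same steps are
available from the shell:

```sh
itsloci simulate ssis --n 94 --seed 5 --out ssis.tsv
itsloci classify-ssi ssis.tsv
itsloci segtest ssis.tsv
itsloci evaluate-hypotheses ssis.tsv
```

## Layout

```
src/itsloci/       haplotypes, caps, genotypes, meiosis, fixtures, io, cli
src/itsloci/data/  packaged haplotype and marker configs (JSON)
examples/          narrative scripts, one per capability
docs/methods.md    models, assumptions, parameter choices, limitations
tests/             unit, property (hypothesis) and acceptance tests
```
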