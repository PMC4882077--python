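# Methods

## The genetic problem

A heterokaryotic (n+n) basidiomycete mycelium can carry divergent ITS
sequences in several ways: many-to-one variation within one rDNA array,
allelic variation between the two nuclei, or a duplicated ITS locus
elsewhere in the genome. The package's analysis chain separates these by
(i) typing cloned amplicons into discrete sequence types, (ii) scoring the
types in single-spore progeny with CAPS markers, (iii) classifying each
single-spore isolate (SSI) as homo- or heterokaryotic with independent
co-dominant markers, and (iv) testing the segregation of the types among the
homokaryotic offspring, where each isolate is a haploid draw from the
parent's meiosis.

The supported model for the reference strain: types A and B are alleles
*a*/*b* at locus ITSI; type C is allele *c* at an unlinked locus ITSII whose
alternative allele is a null (no ITS copy). Under this model homokaryons can
only show phenotype classes [A], [B], [A+C], [B+C]; a pure [C], an [A+B] or
an [A+B+C] homokaryon is impossible, which is exactly what makes the model
testable. A competing "trikaryon" explanation (three nucleus types, one ITS
type each) predicts only single-type homokaryons, so any multi-type
homokaryon is a rejection witness.

## Haplotypes and clone classification

Haplotypes are states (base or gap; a gap is a coded fifth character) at
1-based columns of a shared 662-column alignment. The built-in A/B/C
haplotypes carry the published states at the 13 polymorphic columns
{39, 114, 122, 130, 145, 146, 200, 269, 334, 466, 475, 559, 649}, with a
1-bp deletion at column 39 in B and C and at column 475 in C. Full
sequences are not published, so the fixtures complete them with a
**synthetic** fixed-seed background shared by all three types; anything that
depends only on the 13 columns is exact, and the background is an arbitrary
but frozen stand-in. ITS1/5.8S/ITS2 boundaries are likewise not published;
the defaults (1–299, 300–439, 440–662) place the polymorphic columns 8/1/4
into the three regions and are configuration, not inference.

Clone classification is deterministic, total and ordered: exact (no
mismatch) → variant (all 13 polymorphic columns agree with one type, ≤ 2
mismatches elsewhere — the cap reflects that minor variants differ "at one
or rarely two" positions) → chimera (polymorphic columns split into two
contiguous donor blocks; the breakpoint interval spans the last strictly-5'
donor column to the first strictly-3' donor column) → unassigned.
Multi-breakpoint mosaics deliberately fall to unassigned.

## Trace superposition and masking

Direct sequencing of a mixed template reads each haplotype in its own
ungapped frame, so downstream of a deletion a haplotype contributes shifted
bases. A polymorphic column is **masked** when the observed per-position
peak sets are identical to those of an alignment in which every haplotype
shares a single state at that column — the operational content of "the peak
is explained by a flanking base of another frame". With the built-in
haplotypes, the B-specific G at column 334 (5.8S) is masked by the flanking
G's of the A/C frames; the other 12 columns stay detectable. With gap-free
haplotypes masking cannot occur (the profile reduces to column-wise state
multisets), which the property tests assert.

## In-silico CAPS

Recognition patterns are IUPAC-degenerate and scanned on both strands
(overlaps included); Type IIS offsets are the canonical MboII 8/7 and FokI
9/13, within-site cuts for SalI/KpnI/AvaII, all configurable because the
published tables print fragment sizes, not cut chemistry. Published markers
ship as **cut maps** (amplicon length + per-allele cut coordinates)
calibrated to reproduce every genotype→fragment row exactly; sequence-level
digestion is exercised against synthetic amplicons built to a target cut
map. Fragment conservation (Σ fragments = amplicon length) holds by
construction and is asserted for every fixture allele.

The gel model scores bands with three rules: bands closer than
`resolution_rel` (relative difference) co-migrate and are reported as the
largest of the set; bands under `min_visible_bp` (150 bp) are invisible;
optionally the smallest fragment of a multi-fragment single-allele digest is
flagged redundant (its length is implied by the others). `resolution_rel`
defaults to 2%: the published patterns resolve 219 vs 210 (4%) but merge
396/395 and 563/562 (0.25%), so the threshold must sit between. The
redundant-smallest flag is on for the ITS marker (matching how its phenotype
classes are reported) and off for the PRS markers. The MboII+FokI pair
distinguishes all seven ITS phenotype classes; MboII alone confounds
[C]/[A+C] and [B+C]/[A+B+C], which the tests verify by exhaustive pairwise
comparison under gel tolerance.

## Statistics

All tests are uncorrected Pearson chi-squares with asymptotic p-values
(scipy), α = 0.05: goodness-of-fit against equal ratios (df = k−1) for clone
counts and allele segregation, and the 2×2 contingency statistic (df = 1)
for pairwise linkage. No Yates correction and no multiple-testing adjustment
are applied — the analysis runs a handful of pre-planned tests. From the
published homokaryon counts these give 0.710 (ITSI 38:31), 1.174 (ITSII
30:39) and 1.464 (2×2 on 19/19/11/20); the source tables print 0.72, 1.18
and 1.43, a last-digit discrepancy consistent with intermediate rounding in
the original calculations, so comparisons against the printed values use a
±0.05 band. Because allele phase in the parent is unknown and the statistic
is symmetric, the parental:recombinant split is reported as the ascending
pair of diagonal sums (30, 39). The ITSII c/c-vs-c/n phenotype ambiguity is
carried as an explicit genotype set and never resolved by guessing; at that
locus only null homozygosity is observable and rates are computed on the
observable classes only.

## The tetrasporic meiosis model

Crossing over is abstracted per locus into a second-division segregation
frequency **f**: with probability f the two meiosis-II pairs each carry both
alleles, otherwise each pair is homoallelic and the pairs carry opposite
alleles. f is the minimal sufficient parameter for every statistic computed
here; no map distances are modelled. Loci on one chromosome share the MI
orientation draw and a single crossover uniform (their SDS events nest);
within-pair orders under SDS are independent per locus, an accepted
abstraction since no within-chromosome phase statistic is computed.

A basidium undergoes post-meiotic mitosis with probability `p_mitosis`
(default 0.27, the binucleate-spore rate of the study offspring; field
reports range 40–75%). With mitosis, each of the four spores draws an
unordered pair of **distinct meiotic products** uniformly (6 pairs, 2 of
them sister pairs — hence the 1/3 sister rate); `sister_bias` reweights
sister pairs (β = 1/3 recovers the random rule) and `allow_twin` permits
genetically identical twin nuclei, for studying apparent-homokaryon excess.
Non-tetrasporic basidia (<1% in the field) are ignored. Under the random
rule, heterozygosity retention among binucleate spores is ⅔ at every locus
(⅓·f + ⅔·(1−f/2)); the observed ~50% loss at distal loci in real offspring
exceeds the model's ⅓ — the sister-bias knob can reproduce such excess but
the package asserts no mechanism for it.

Parent defaults: ITSI, ITSII, PRS016, PRS049 on four unlinked chromosomes
with f = 0.6 (distal loci approach the ⅔ randomness bound; exact values are
unpublished and do not affect aggregate retention), PRS088 with f = 0
(tightly centromere-linked). rDNA copy numbers are equal across a, b, c and
homogeneous within an allele, so clone-template weights default to 1:1:1.

## Synthetic data: what it does and does not emulate

The clone-library generator draws a template per clone (weights ∝ copy
number), adds Poisson(0.5) substitutions at uniform non-gap columns, and
with probability 0.05 instead splices two templates at a uniform breakpoint.
These defaults make the expected exact-type fraction (1−0.05)·e^−0.5 ≈ 0.58,
matching the 164/284 observed. It does not emulate sequencing-quality
gradients, indel errors, template-switching hotspots, or concerted-evolution
dynamics of the array, so a passing recovery test shows the classifier is
correct under the stated noise model — not that real libraries are this
clean. The SSI generator renders each simulated spore through the marker
fixtures into exactly the TSV the inference side reads, plus a hidden truth
table; sister-twin heterokaryons that are homoallelic at every marker are an
irreducible misclassification source that the simulator quantifies (≈5%
with the three default markers) rather than the classifier correcting for.

All randomness flows through one seeded `random.Random` in documented draw
order; identical seeds replay byte-identically.

## Numerical and edge-case choices

Zero totals make ratio tests errors, not NaNs; a zero margin leaves the
linkage statistic undefined with a warning. Cut offsets falling outside an
amplicon drop that cut with a warning. Fewer than four sequences can never
be parsimony-informative (empty result with a warning); type-specificity is
undefined below three haplotypes (error). Clone sequences shorter than the
last polymorphic column raise rather than silently truncate. Problem sizes
in the test suite (10⁵ basidia for the 1/3 expectation, 200 generator runs
at n = 94, 100 seeds × 164 clones) were chosen so Monte-Carlo standard
errors sit well inside the asserted tolerances.

## Known limitations

- No de novo alignment: clones must arrive aligned to the haplotype
  coordinate system. No chromatogram (AB1) parsing — the trace profile is a
  model of superposition, not a base caller.
- Chimera detection assumes a single breakpoint.
- The 120 minor-variant clones of the original library are represented only
  through the substitution/chimera noise model; their true site catalogue is
  unpublished.
- The mapping between alignment columns (662) and amplicon coordinates
  (773/772/771) is a per-marker fixture constant, not derived from sequence.
- Only pairwise linkage tests; no map construction.
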