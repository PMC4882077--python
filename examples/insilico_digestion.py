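"""In-silico CAPS phenotypes: from genotypes and from raw sequence.

Prints the band patterns of the packaged marker fixtures (what each
genotype looks like on a 2% agarose gel) and then digests a synthetic
amplicon sequence to show the scan-and-cut path on real sequence input.
"""

from itsloci import digest, genotype_to_phenotype, its_phenotype
from itsloci.caps import MBOII
from itsloci.fixtures import build_synthetic_amplicon, load_markers

markers = load_markers()

print("PRS marker genotypes -> phenotypes (fragment sizes in bp):")
for name, genotype in [("PRS016", "1/2"), ("PRS049", "2/2"), ("PRS088", "1/1")]:
    pat = genotype_to_phenotype(markers[name], genotype)
    print(f"  {name} {genotype}: {pat.format()}")

print("\nITS phenotype classes (MboII + FokI double scoring):")
for types in ("A", "B", "C", "AC", "BC", "ABC"):
    label, pats = its_phenotype(types, markers["ITS"])
    print(f"  {label:9s} MboII {pats['MboII'].format():28s} FokI {pats['FokI'].format()}")
print("-> parenthesized bands are co-migrating, tiny, or redundant; the enzyme")
print("   pair separates all 7 classes although MboII alone confounds [C]/[A+C].")

seq = build_synthetic_amplicon(773, {"MboII": [(396, "+")]}, seed=4)
print(f"\nMboII digest of a synthetic 773-bp type-A amplicon: {digest(seq, MBOII)}")
print("-> one GAAGA site cut 8 nt downstream gives the 396+377 type-A signature.")
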