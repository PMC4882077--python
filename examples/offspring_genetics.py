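"""Full offspring analysis: karyotypes, genotypes, segregation, hypotheses.

Simulates 94 single-spore isolates from the two-locus heterokaryotic parent
(ITSI a|b, ITSII c|null, three CAPS markers, 27% binucleate spores), then
runs the complete inference chain the wet-lab analysis would run.
"""

from collections import Counter

from itsloci import (classify_karyotype, evaluate_hypotheses, homozygosity_rate,
                     linkage_test, segregation_test)
from itsloci.genotypes import allele_counts_from_homokaryons, infer_its_genotype
from itsloci.meiosis import BasidiumModel, ca487_parent, generate_ssi_dataset

data = generate_ssi_dataset(ca487_parent(), BasidiumModel(p_mitosis=0.27), 94, seed=4)
for r in data.records:
    classify_karyotype(r)

k = Counter(r.karyotype for r in data.records)
print(f"94 SSIs: {k['heterokaryon']} heterokaryons, {k['homokaryon']} putative homokaryons")
print(f"(truly binucleate: {int(data.truth['heterokaryotic'].sum())} — sister twins that are")
print(" homoallelic at every marker hide among the putative homokaryons)")

homos = [r for r in data.records if r.karyotype == "homokaryon"]
pheno = Counter(r.its_phenotype for r in homos)
print("\nhomokaryon ITS phenotype classes:", dict(sorted(pheno.items())))
alleles = allele_counts_from_homokaryons(dict(pheno))
for locus, counts in alleles.items():
    res = segregation_test(list(counts.values()))
    print(f"  {locus} {counts}: chi2={res.statistic:.2f}, p={res.pvalue:.2f} -> {res.verdict}")

joint = Counter()
for r in homos:
    (g,) = infer_its_genotype(r.its_phenotype, "homokaryon")
    joint[(g.itsI, next(iter(g.itsII)))] += 1
link = linkage_test(((joint[("a", "c")], joint[("a", "n")]),
                     (joint[("b", "c")], joint[("b", "n")])))
print(f"  ITSI-ITSII linkage: chi2={link.statistic:.2f}, p={link.pvalue:.2f} -> {link.verdict}")

hets = [r for r in data.records if r.karyotype == "heterokaryon"]
print(f"\nheterokaryon homozygosity: ITSI {homozygosity_rate(hets, 'ITSI'):.0%}, "
      f"ITSII (null) {homozygosity_rate(hets, 'ITSII'):.0%}")

het_pheno = Counter(r.its_phenotype for r in hets)
verdicts = evaluate_hypotheses(dict(pheno), dict(het_pheno))
for name, v in verdicts.items():
    status = "CONSISTENT" if v.consistent else f"REJECTED, witnesses {dict(v.witnesses)}"
    print(f"hypothesis {name}: {status}")
print("-> multi-type homokaryons ([A+C], [B+C]) falsify a trikaryon parent;")
print("   every class fits two unlinked ITS loci with a null allele at the second.")
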