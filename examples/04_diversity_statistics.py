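"""Haplotype diversity, nucleotide diversity and sequence-logo information.

Reproduces the style of a per-species diversity table: N sequences, size
range, haplotype count, unbiased haplotype diversity Hd and nucleotide
diversity pi, plus per-column information content for a sequence logo.
"""
from satlib import (HapRow, HaplotypeTable, align_monomers, haplotype_diversity,
                    logo_matrix, nucleotide_diversity, summarize)

# a small clone set: 3 sequences, two of them identical
rows = [
    HapRow("h1", "ACGTACGTACGTACGTTTGA", 2, "A. paranae", "pcr"),
    HapRow("h2", "ACGTACGAACGTACGTTTGA", 1, "A. paranae", "pcr"),
]
table = HaplotypeTable(rows)
stats = summarize(table)
print(f"{stats.species}: N={stats.n} Hap={stats.hap} "
      f"Hd={stats.hd:.2f} pi={stats.pi:.3f}")
print("  -> Hd = (n/(n-1))(1 - sum p_i^2) = (3/2)(1 - (2/3)^2 - (1/3)^2) = 0.67")

print("worked Hd values for printed (N, Hap) configurations:")
for counts in [(2, 1), (2, 1, 1, 1), (1,) * 9]:
    print(f"  counts {counts}: Hd = {haplotype_diversity(counts):.4g}")

aln = align_monomers(table.sequences())
pi = nucleotide_diversity(aln, table.counts())
print(f"pi (average per-site pairwise difference) = {pi:.4f}")

logo = logo_matrix(aln, table.counts())
print(f"logo: {len(logo)} columns, mean information {logo.R_bits.mean():.2f} bits"
      f" (2 bits = fully conserved, 0 = uniform)")
print(logo.head(3).to_string(index=False))
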