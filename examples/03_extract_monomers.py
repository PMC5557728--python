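"""Cut full-length monomers out of merged reads and run in-silico PCR.

A merged read spanning at least one full repeat unit is cut at consensus unit
origins; every unit is rotated to a canonical phase so identical monomers from
differently-phased reads collapse together. Singletons (variants seen once)
are discarded as likely sequencing errors. A degenerate-primer in-silico PCR
on a tandem array reproduces the ladder pattern seen on agarose gels.
"""
from satlib import (PrimerPair, SatConsensus, in_silico_pcr, extract_monomers,
                    simulate_library, tally_and_filter_singletons)
from satlib._align import revcomp

consensus = SatConsensus("SimSat01-177",
                         simulate_library(1, 177, 0.0, seed=11).sequences[0])
c = consensus.sequence

# a merged read: 30 nt of one unit, one full unit, 20 nt of the next
read = c[-30:] + c + c[:20]
units = extract_monomers(read, consensus, source_id="read1", species="sp")
print(f"read of {len(read)} nt -> {len(units)} full monomer "
      f"({units[0].length} nt, identical to consensus: {units[0].sequence == c})")

units = units * 2 + extract_monomers(
    c[:10] + "T" + c[11:] + c[:5], consensus, source_id="read2", species="sp")
table = tally_and_filter_singletons(units, apply_filter=True)
print(f"tally with singleton filter: {len(table)} haplotype(s) kept "
      f"(the variant seen once was discarded)")

primers = PrimerPair(forward=c[10:33], reverse=revcomp(c[150:170]),
                     max_mismatches=1)
products = in_silico_pcr(c * 4, primers, product_range=(50, 1500))
print("in-silico PCR ladder on a 4-unit array, product lengths:",
      sorted({p[2] for p in products}))
print("  -> bands spaced one unit (177 nt) apart, the classic satDNA ladder")
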