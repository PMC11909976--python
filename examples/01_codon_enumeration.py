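"""Enumerate every possible SNV of a three-codon reading frame.

Builds the toy frame ATG CTG TAA on a small reference, enumerates the 9
single-base changes of each codon with their genomic context triplets and
model mutation rates, and tallies them by consequence class.
"""

from collections import Counter

from sorfconstraint import SORFRecord, enumerate_possible, extract_coding_sequence
from sorfconstraint.mutation_model import MethylationMap
from sorfconstraint.synthetic import toy_rate_table

genome = {"chr1": "A" + "ATGCTGTAA" + "G" + "AAAA"}
sorf = SORFRecord(id="demo", chrom="chr1", strand="+", blocks=((1, 10),))

cds = extract_coding_sequence(genome, sorf)
print(f"coding sequence: {cds.bases}  (codons: ATG / CTG / TAA)")

possible = enumerate_possible(cds, MethylationMap({}), toy_rate_table())
print(f"possible SNVs: {len(possible)}  (9 altered triplets per codon x 3 codons)")

counts = Counter(pv.consequence.value for pv in possible)
rate = sum(pv.rate for pv in possible)
for cls, n in sorted(counts.items()):
    print(f"  {cls:<11} {n:>2} possible variants")
print(f"summed mutation rate of the frame: {rate:.3e} per generation")
print("Counts are the mutational opportunity per class; the rate sum is the")
print("neutral expectation driver used for expected-variant calibration.")
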