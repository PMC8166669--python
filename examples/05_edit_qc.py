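"""Quantify editing outcomes: indel calls, knockout genotypes, mitotic index.

Aligned indel patterns use the dash/lowercase convention: dashes in the
observed read are deletions, lowercase letters opposite reference dashes are
insertions. A net length change that is not a multiple of 3 shifts the
reading frame and (via nonsense-mediated decay) knocks the allele out.
"""

from hemibank import (
    AlleleEditStatus,
    classify_indel,
    indel_frequency,
    knockout_call,
    mitotic_index,
    parse_allele_name,
)

patterns = [
    ("2-nt deletion ", "ACGTACGT", "AC--ACGT"),
    ("3-nt deletion ", "ACGTACGT", "AC---CGT"),
    ("1-nt insertion", "ACG-ACGT", "ACGtACGT"),
]
print("indel classification:")
for name, ref, obs in patterns:
    call = classify_indel(ref, obs)
    print(f"  {name}: net {call.net_change:+d} nt -> "
          f"{'FRAMESHIFT (knockout)' if call.frameshift else 'in-frame (expressed)'}")

freq = indel_frequency(842, 1000)
print(f"\nindel frequency: {freq.n_edited}/{freq.n_total} reads = "
      f"{float(freq):.1%} (low confidence: {freq.low_confidence})")

# hemizygous call: A*03 frameshifted, A*02 intact -> "A02/-"
statuses = [
    AlleleEditStatus(allele=parse_allele_name("A*02"), call="intact"),
    AlleleEditStatus(allele=parse_allele_name("A*03"), call="frameshift"),
]
print(f"knockout genotype at HLA-A: {knockout_call(statuses)}")

print("\nmitotic index (mitotic events per absolute precursor):")
for label, hist in [("undivided", {0: 100}), ("one division", {1: 100}),
                    ("two divisions", {2: 100}), ("mixed", {0: 50, 1: 30, 2: 20})]:
    print(f"  {label:<14} -> {mitotic_index(hist):.3f}")
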