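"""Design allele-discriminating and shared SpCas9 guides.

A hemizygous knockout needs a guide that cuts the target allele but spares
the other: the site must differ in the PAM-proximal seed (or be disrupted by
an indel between the alleles), and the exact spacer must be absent from the
spared allele. A bi-allelic knockout wants the opposite — a site identical
in both alleles ("shared" mode).
"""

from hemibank import AlleleSequencePair, discriminating_guides
from hemibank.simulate import synth_discriminating_fixture

# a synthetic allele pair with one guaranteed NGG site carrying a planted
# seed-region substitution between the two alleles
pair, site_start, planted_offset = synth_discriminating_fixture(seed=5)
print(f"planted NGG site at position {site_start}, allele difference at "
      f"protospacer offset {planted_offset} (seed region)\n")

guides = discriminating_guides(pair, mode="discriminating")
print(f"{len(guides)} discriminating guide(s) on the target allele:")
for g in guides:
    print(f"  {g.spacer} {g.pam} strand={g.strand} start={g.start} "
          f"cut={g.cut_site} seed_mismatches={g.seed_mismatches} "
          f"diff_offsets={g.discriminating_positions}")

# identical alleles: nothing discriminates, every site is shared
same = AlleleSequencePair(
    target_id="allele1", spare_id="allele2",
    target_seq=pair.target_seq, spare_seq=pair.target_seq,
)
print(f"\nidentical alleles: {len(discriminating_guides(same))} "
      f"discriminating, {len(discriminating_guides(same, mode='shared'))} "
      f"shared sites (usable for bi-allelic knockout)")
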