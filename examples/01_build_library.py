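"""Enumerate the hemizygous combo library of a four-line parental panel.

Each line heterozygous at HLA-A and HLA-B yields up to four hemizygous
(mono-allelic knockout) daughter lines: one retained A allele crossed with
one retained B allele. Overlapping products between lines are merged.
"""

from hemibank import build_library, enumerate_combos, synthetic_four_line_panel

panel = synthetic_four_line_panel()
print(f"panel: {', '.join(ln.line_id for ln in panel)}")

for line in panel:
    combos = sorted(c.label for c in enumerate_combos(line))
    print(f"  {line.line_id}: {len(combos)} products -> {', '.join(combos)}")

library = build_library(panel)
print(f"\ndeduplicated library: {len(library)} distinct combos "
      f"(16 raw products, 2 shared between lines)")
for combo in library:
    src = "+".join(sorted(combo.sources))
    print(f"  {combo.label:<14} from {src}")
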