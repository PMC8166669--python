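# Methods

## Matching model

A hemizygous bank line expresses one HLA-A antigen `a` and one HLA-B antigen
`b` (and no HLA-DR, since every line is DRB1-null). A recipient with A
alleles {a1, a2} and B alleles {b1, b2} is *matched* by combo (a, b) iff
`a ∈ {a1, a2}` and `b ∈ {b1, b2}` — allele-level, cross-haplotype allowed.
Only the host-versus-graft direction enters: the graft presents no antigen
outside {a, b}, so the recipient's unshared alleles are irrelevant. A
haplotype-level variant (matched only if one recipient haplotype equals
(a, b) exactly) is implemented for comparison (`model="haplotype"`); it is
strictly more conservative and is not the default, since nothing in the
matching biology ties the two required antigens to the same chromosome.

Matching operates at an explicit field resolution, default **1 field**
(`A*33`, the antigen-group level): bank lines in this design space are
described by one-field names, and allele-group matching is the unit used in
registry practice for A/B. The resolution is a parameter everywhere;
expression suffixes (N, L, …) are parsed, preserved, and ignored for
matching.

## Population model

Recipients follow Hardy–Weinberg equilibrium over an A–B haplotype
distribution p(h): a genotype is two independent haplotype draws. p(h) can
be supplied directly (TSV) or built from per-locus allele frequencies under
linkage equilibrium, p(a,b) = f_a·f_b; the construction is recorded in a
`provenance` tag (`supplied` / `product_LE` / `synthetic`) so results
declare their assumption — real A–B linkage disequilibrium is strong, and
the LE product is an approximation.

Frequency mass not named in a table becomes a reserved `OTHER`
pseudo-allele per locus. `OTHER` never matches any combo, so reported
coverage is an underestimate whenever the source table is incomplete —
the conservative direction for bank planning. A raw frequency sum exceeding
1 (beyond 1e-6) is an error, never rescaled: silent rescaling hides
data-entry bugs. Tables must close to 1 within 1e-9 after the residual is
added.

## Coverage computation

Exact coverage enumerates ordered haplotype pairs:

    C = Σ_{h1,h2} p(h1) p(h2) · 1[∃ combo matching the genotype (h1,h2)]

implemented with boolean indicator matrices per combo: for combo (a,b),
`has_a[i,j] = (a ∈ {A(h_i), A(h_j)})` etc., OR-ed into a matched matrix, so
each combo costs O(|H|²) vectorised boolean work. With |H| ≈ 600–2500
haplotypes and ≲100 combos this runs in seconds to well under a minute on
one CPU. The incremental form (`CoverageState`) supports marginal-gain
queries for the greedy selectors and cumulative-coverage curves without
recomputation from scratch. Coverage values are clipped to [0, 1] against
1e-15-scale float drift.

Validation routes, kept strictly independent of the matrix path:
pure-Python pair enumeration, inclusion–exclusion over combo subsets
(tests only, exponential in library size), the closed form for one combo
under LE — C = (1−(1−f_a)²)(1−(1−f_b)²) — and Monte Carlo simulation of
recipients with binomial standard error. Analytic vs oracle agreement is
asserted at 1e-12; analytic vs Monte Carlo within 4 standard errors.

## Greedy bank selection

Coverage is a monotone submodular function of the combo set (adding a combo
can only convert unmatched genotype mass, and the convertible mass shrinks
as the set grows), so greedy selection carries the standard (1−1/e)
guarantee. Two selection units:

- **combo-level**: add the combo with the largest marginal gain; the
  parental lines needed are derived afterwards by a greedy hitting set over
  each chosen combo's source lines (most-productive line first, ties
  lexicographic).
- **line-level** (default): a candidate line's gain is the joint gain of
  all its combos; after selection, combos are replayed in pick order and
  those with zero marginal gain pruned, yielding the count of daughter
  lines actually worth deriving.

Stopping: first prefix with C ≥ τ (inclusive), or exhaustion of positive
gains (gain ≤ 1e-15 counts as zero). All ties break lexicographically, so
plans are deterministic. `exhaustive_min_lines` searches subsets in
increasing cardinality and is the optimality oracle for panels ≤ 15 lines;
greedy is never asserted optimal, only feasible and ≥ the exhaustive
minimum.

## Guide design

SpCas9 defaults: 20-nt spacer, NGG PAM, blunt cut between spacer positions
17 and 18 (3 nt 5′ of the PAM), seed = PAM-proximal 10 nt. All are module
constants; `min_seed_mismatches` is a parameter (default 1). A target-allele
site is *discriminating* when its aligned spare-allele counterpart has ≥ the
required substitutions inside the seed or the PAM GG, or is disrupted by an
alignment gap — and, additionally, when the exact 20-nt spacer has no
perfect match anywhere in the spare on either strand (checked by string
search, the belt to the seed heuristic's braces). *Shared* sites (for
bi-allelic knockout) must be perfectly identical in both alleles. `N` never
counts as a match and disqualifies a PAM GG. Genome-wide off-target scoring
is out of scope — allele discrimination here is local to the edited locus,
and genome-wide enumeration is the job of dedicated existing tools.

Coordinates are 0-based half-open on the target's + strand; minus-strand
guides are reported in protospacer orientation with their + strand
interval, and `cut_site` is the boundary coordinate (cut between
`cut_site−1` and `cut_site`). Alignments either come in pre-built (gapped
FASTA) or are computed with Biopython's global `PairwiseAligner`
(match 1, mismatch −1, gap open −3, extend −0.5); for the near-identical
allele pairs this module targets, any sane parameterisation yields the same
alignment, so these values are not sensitive knobs.

## Edit QC

Indel patterns are aligned string pairs in dash/lowercase notation
(observed dash = deletion; lowercase opposite a reference dash = insertion;
uppercase mismatch = substitution). Frameshift is decided purely by net
length change mod 3 — the nonsense-mediated-decay rationale for calling
knockouts — and premature-stop detection from translated sequence is
deliberately out of scope. Knockout labels: both alleles frameshifted →
`D-/-` style null; exactly one → hemizygous label retaining the intact
allele's first field in its slot (`A02/-`); an in-frame indel never counts
as knockout and is warned about.

The mitotic index reconstructs precursor arithmetic from a
division-generation histogram: with n_g cells in generation g, absolute
precursors P = Σ n_g·2^(−g), mitotic events M = Σ n_g·(1−2^(−g)), index =
M/P. The source assays report only the ratio definition (events per
precursor from dye-dilution data); the generation-histogram formulation is
this package's choice of input representation, since generations are what
dye-dilution peaks actually resolve. The index is scale-invariant in the
counts and strictly increases as cells move to later generations.

## Synthetic data

The generators stand in for the external inputs a real bank design consumes
(published population frequency tables; HLA-typed registries of established
lines). Defaults model one population at one-field resolution: 20 HLA-A and
30 HLA-B allele groups — the order of distinct one-field groups observed in
single-population A/B tables — with frequencies from a symmetric
Dirichlet(0.5), whose concentration < 1 reproduces the dominance of a few
alleles in real HLA spectra; and a registry of 202 typed lines, the size of
the published line registries this workflow draws on. Haplotype tables come
either as an LE product of two spectra (zero LD by construction) or as a
joint Dirichlet over the allele grid (nonzero LD). Registry draws are
conditioned on fully named haplotypes — real registry lines are completely
typed, so `OTHER` never appears in a panel. Sequence-pair generators return
the planted truth (substitution positions, gap intervals) alongside the
data, so tests assert against known ground truth rather than re-inferring
it.

What the synthetic conditions do **not** model: real skewed Korean/other
population frequencies and their strong A–B LD, registry ascertainment
bias, typing ambiguity, or editing success rates. Passing tests therefore
demonstrate correctness of the computation under the stated model, not any
specific population's coverage numbers; published coverage figures for a
real bank require the corresponding real frequency tables and registry,
which drop in via the TSV interfaces unchanged.

The four-line reference panel (`synthetic_panel.py`) is a synthetic
reconstruction: one line's genotype (H9, A*02/A*03 × B*35/B*44) is
authentic, and the other three are plausible alleles chosen to satisfy the
structural facts of the published mini-library — the A*33/B*44 and
A*33/B*58 combos exist, and exactly two of the 16 raw products coincide,
leaving 14 distinct combos.

## Problem sizes and reproducibility

The acceptance script (`scripts/acceptance.py`) uses the default synthetic
conditions (600-haplotype population, 202-line registry, 200,000 Monte
Carlo recipients, 100 closed-form draws, 10 oracle instances, 100 guide
fixtures) — sizes at which the exact engine answers in seconds while the
statistical checks retain 4-SE discrimination. Every stochastic operation
takes a single integer seed (numpy `default_rng`); derived sub-seeds come
from `SeedSequence` so independent stages get independent streams. Fixed
seed ⇒ bit-identical output, asserted in the test suite.

## Known limitations

- The LE product misstates coverage when real A–B LD matters; supply
  haplotype tables directly when available (the `provenance` tag records
  which was used).
- Greedy plans are near-optimal, not optimal; the exhaustive oracle is
  exponential and capped at 15 lines.
- Guide discrimination is a local seed/PAM criterion, not a genome-wide
  specificity score, and no on-target efficiency model is included.
- Editing efficiency and clone-derivation success are not modelled; a
  "combo count" is a design target, not a guaranteed yield.
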