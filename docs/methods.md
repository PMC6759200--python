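# Methods

This note records the models and procedures the package implements, the
defaults that matter, the synthetic-data generators behind the test suite,
and the numerical/design choices made where the design was genuinely open.

## Tiered presence/absence screening

A subunit is declared present in a target genome as soon as one bait tier
succeeds; tiers are consulted in ascending order and model an escalating
search strategy: tier 1 uses distant canonical baits, tier 2 an annotated
relative from the same order, tier 3 the closest relative that retains the
subunit.

Hit grading uses two thresholds. A *strong* hit has E ≤ 10⁻¹⁰ **and** at
least two aligned regions (HSPs) on the same subject — the two-region
requirement guards against single spurious segments. A *weak* hit has
E ≤ 0.05 (or any E with only a single region) and must pass reciprocal
validation: the hit locus, cut out of the genome with ±300 nt of context,
is searched against an annotated gene set of a relative, and the call
stands only if the top-scoring reference gene is the expected subunit.
Validating the *locus* (a nucleotide segment, compared against reference
proteins through all six frames) rather than the bare translated aligned
columns is deliberate: a chance antisense or off-frame hit inside some
other gene's locus is then attributed to the gene the locus really
encodes, and the validation correctly fails. Anything above E = 0.05 is no
hit. A weak hit that fails validation does not stop the cascade — later
tiers are still tried, mirroring the rationale for escalating baits in the
first place.

Grading considers the whole hit list (strong iff *any* hit qualifies), not
only the single best-E hit: under a literal best-hit rule, adding a
better-E single-region hit could downgrade an otherwise strong call, which
would violate the monotonicity a present/absent caller should have.

### The built-in search engine

The translated engine aligns a protein query locally against all six
reading frames of a subject (Smith–Waterman via Bio.Align.PairwiseAligner;
BLOSUM62, gap open 11, extend 1). Additional HSPs per frame are recovered
by masking each found region and re-aligning (up to 4 regions). Alignments
are split into separate regions wherever a gap exceeds 25 residues: a
bridged jump across unrelated sequence (an intron, a deletion) should not
dilute the identity of an otherwise coherent segment. Region scores are
converted to E-values by E = K·m·n·e^(−λS) with m the query length and n
the total translated subject length, using the standard gapped BLOSUM62
11/1 constants λ = 0.267, K = 0.041. The gapped constants keep the scale
calibrated: in 100 seeded trials of a random 200-residue query against a
random 600 nt subject, at most 5 reach E ≤ 0.05. (The ungapped constants
λ = 0.318, K = 0.13 applied to gapped scores are anti-conservative — 8/100
false hits in the same trial — and are available but not default.) Only
individually callable regions (E ≤ 0.05) are reported, so "multiple
regions" can never be satisfied by chance segments. Identity is computed
over aligned columns, excluding gaps and ambiguity characters.

A nucleotide engine with the same interface (match +2 / mismatch −3, gap
5/2, λ = 0.625, K = 0.41, both strands) serves the duplication screen,
which operates in nucleotide space. Engines are pluggable: the protocol
layer only consumes `SearchHit` lists, and a tabular reader ingests
BLAST-style 12-column hit files in place of either engine.

## Duplication screen

The subunit's coding sequence is searched against its own genome. The
pipeline order is fixed: (1) keep hits with E < 0.001, dropping any hit
overlapping the gene's own annotated locus (without this exclusion every
screen is trivially "duplicated"); (2) drop hits with any region longer
than 200 nt above 98% identity — both inequalities strict — as likely
sequencing/assembly artifacts; (3) retain survivors that are either
already annotated as a paralog of the complex or reciprocally best-match
the expected subunit in a close relative. `duplicated` is true iff the
retained set is non-empty. The artifact filter is idempotent by
construction.

## Dollo loss mapping

States: present / absent / unknown per (taxon, gene); the tree must be
rooted (the root may be assumed ancestrally present, the default, or not).
Under single-gain Dollo parsimony the minimal reconstruction is: presence
is forced at every node with a known-present descendant; one loss is spent
on each highest node whose subtree contains a known-absent tip and no
known-present tip. Unknown tips never force either state — they follow
their parent's label and never cost a loss — and are flagged in the
output. When every constrained tip is absent, the convention is a single
loss on the root edge (if the root is assumed present), or zero losses
with an absent ancestor otherwise.

With fully constrained tips the minimal labeling is unique; with unknown
tips only the loss *count* is unique (a loss can sometimes sit on either
of two edges), which is how the oracle-equivalence tests compare results.
One known boundary: starting from the all-absent state, flipping a tip to
present can raise the count from 1 (the root-edge convention) to 2, so the
"flips never increase the count" property is stated for states with at
least one present tip.

## McDonald–Kreitman test

Codon columns are classified per site: if two or more alleles segregate in
the ingroup, each non-major allele contributes its changes against the
major allele to pN/pS; a monomorphic ingroup differing from the outgroup
consensus contributes to dN/dS; a column both polymorphic and divergent
contributes its polymorphic changes plus the fixed component only when no
ingroup allele equals the outgroup allele. Codons differing at k ≤ 3
positions are resolved by enumerating all k! single-step pathways,
discarding pathways through stop codons, and averaging the per-step
synonymous/nonsynonymous labels over survivors (weights sum to k);
fractional weights are summed and rounded half-up only in the final table,
with the raw sums reported alongside. Columns containing a gap, an
ambiguous base, or a stop in any sequence are skipped and tallied in a QC
report, as are columns where a multi-sequence outgroup has no majority
allele (an unpolarized test cannot classify them). No low-frequency
polymorphism filter is applied.

α = 1 − (dS·pN)/(dN·pS), undefined (reported NA) when dN·pS = 0. The
Fisher exact test on [[dN, dS], [pN, pS]] defaults to **two-sided**; this
is the convention under which published MK tables of this layout
reproduce, verified against an exact hypergeometric enumeration oracle.
One-sided tails are exposed as options.

## Site-model LRT and thresholds

2·(lnL_selection − lnL_neutral), clipped at zero when the selection model
fits worse, is referred to χ² with df = 2 (the standard convention for the
M7/M8 nested pair; configurable). The Bonferroni threshold is
family_alpha/n_tests reported at three significant figures; n_tests
defaults to 12. Whether subunits of one complex constitute independent
hypotheses is genuinely arguable, so the uncorrected readout
(`correct=False`) is equally supported and neither mode is privileged.

## Pairing statistics and probe windows

Wilson score interval: center (p̂ + z²/2n)/(1 + z²/n), half-width
z·√(p̂(1−p̂)/n + z²/4n²)/(1 + z²/n), clamped to exactly 0/1 at the
boundary counts (where the score inversion is exact). Per-species probe
concordance reports the largest gap between probe proportions when a
species has several probes.

Window selection maximizes the count of oligo start positions in a
fixed-length window (300 kb default). Candidate starts are anchored at
oligo positions — sufficient for optimality of a max-count fixed-length
window — with ties broken to the smallest start; a tiled mode (starts at
multiples of the window size) is available behind a flag. "Density" is
count per fixed window, i.e. a constant denominator, so count maximization.

## Synthetic data

All generators draw from named substreams of one root seed (derived via
CRC32 of the stream name), so outputs are byte-stable and adding a
generator never perturbs another's draws. Every generator returns its
ground truth with the data.

*Loss histories*: the gene is present at the root and lost independently
on each edge with a fixed probability (default 0.1); once lost it stays
lost. Inferred minimal losses can only under-count such a history, which
the tests assert.

*Genomes*: present genes are mutated from a family-ancestral protein by a
per-taxon step drawn from the divergence ladder (default 0, 0.1, 0.2,
0.3 — the band within which the screen is expected to be exact),
back-translated with a fixed one-codon-per-residue table, split by a
random frame-shifting spacer (so a full-length bait genuinely yields two
aligned regions), and embedded in random-background contigs with 500 nt
flanks; absent genes are omitted. Optional decoy paralogs (60% diverged)
and exact-repeat artifact fragments exercise the validation and artifact
rules. Codon-usage realism and assembly noise beyond the exact-repeat
injector are non-goals.

*MK alignments* (defaults: 20 ingroup haplotypes, 2000 codons): each codon
site independently takes at most one role — segregating synonymous
(rate 0.15) or nonsynonymous (0.05), neutral fixed synonymous (0.06) or
nonsynonymous (0.02), or adaptive fixed nonsynonymous at rate
0.02·a/(1−a) so the expected adaptive fraction of dN equals a. The neutral
nonsynonymous:synonymous ratio is equal (1:3) in both compartments, making
the null expectation of α zero. Sites are independent (no linkage or
coalescent structure); with these sizes the ratio-estimator bias of α is
about −0.02 at a = 0, well inside the ±0.05 recovery band the tests
assert. Passing recovery shows the counting machinery is calibrated under
the generator's assumptions, not that real data meet those assumptions.

*Pairing*: paired ~ Binomial(n nuclei, p), defaults p = 0.285, n = 200.

## Problem sizes used by the test suite

The screening benchmark uses 20 genomes × 3 gene families at the default
ladder; Dollo oracle equivalence enumerates all internal labelings for 200
random trees of up to 12 leaves; α recovery averages 200 replicates per
adaptive fraction; window selection is checked against brute force on 500
random instances; Wilson coverage uses 10,000 binomial draws per rate.
These sizes were chosen so each check is statistically meaningful while
the whole suite stays desk-scale.

## Known limitations

The engine is desk-scale: contigs of megabase size will work but are not
the target; there is no seeding/heuristic acceleration, no HMM search, and
no bit-compatibility with NCBI statistics. Absence calls inherit the
limits of homology search — a sufficiently diverged ortholog is
indistinguishable from a lost one, and the tests quantify this only within
the generator's divergence ladder. The MK module implements the
unpolarized two-species test only (no polarization, no
frequency-spectrum-based corrections); the LRT module evaluates supplied
log-likelihoods and does not fit site models itself.
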