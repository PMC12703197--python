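# Methods

This note records the models, conventions, and design decisions behind
the package, in the order the pipeline runs.

## Coordinates, alphabets, ambiguity

Alignments are species-by-site character matrices with 1-based site
addressing in every report and API (a reported "site 42" is column 42).
The one exception is MAF input, which keeps its native 0-based,
half-open, strand-relative convention; conversion happens only inside
`extract_maf_codon`. Amino-acid ambiguity codes (`B`, `Z`, `J`, `U`,
`O`) are normalized to the single sentinel `X` on read, and nucleotide
IUPAC codes other than `ACGT` to `N`: a single sentinel per level keeps
the scanning rules simple, at the cost of discarding partial ambiguity
information that the scan could not use anyway. `-` is a first-class
state, never missing data; a species absent from a MAF block is reported
as *missing*, which is a different biological claim than an aligned
deletion.

Translation uses the standard genetic code only (nuclear orthologs are
the intended input). A full-gap codon `---` translates to `-`; any codon
that is not a clean `ACGT` triplet translates to `X`. Alignments with
frameshift artifacts are rejected, never repaired: a frame error is
raised when the length is not divisible by 3, and partial-gap codons are
flagged as ambiguous rather than realigned.

## The scan

At each site the distinct states of group A and group B are collected
(excluded taxa ignored). Any ambiguity sentinel in either group marks
the site unscannable — a hidden state could silently break exclusivity,
so the conservative choice is to skip. Disjoint profiles are typed 1–4
by cardinality (singleton vs larger in each group); types 1–2 are
convergent, 3–4 divergent. The type partition is exhaustive and
exclusive by construction.

**Codon states.** At codon level the two clean states are a full gap
`---` and an `ACGT` triplet; anything else (partial gap, `N`-containing)
is an ambiguous state that makes the site unscannable. This choice is
forced by the cross-level consistency identity the package guarantees:
the amino-acid variant sites of a translated alignment must equal the
nonsynonymous codon variant sites of the codon alignment. A partial-gap
codon translates to `X` (unscannable at the amino-acid level), so it
must also be unscannable at the codon level or the identity would break.

**Synonymy and nucleotide source.** A mutually exclusive codon profile
is nonsynonymous iff its translated profile pair is itself mutually
exclusive (`-` from `---` participates as a residue-level state). For
the nucleotide source, the three codon positions are profiled
separately: if at least one position is itself mutually exclusive the
variant is SNV-sourced — convergent (ConSNV) when group A has exactly
one state at the first such position, divergent (DivSNV) otherwise — and
if no position is exclusive it is a CNENV, exclusivity emerging only
from the nucleotide combination. When several positions qualify, the
lowest-numbered one is reported; this tie-break is arbitrary but
deterministic, which matters more.

**Continuous-variant filter.** Runs of adjacent variant sites are more
plausibly alignment or structural artifacts than independent point
mutations, so maximal runs of ≥ `run_threshold` (default 2) adjacent
variant sites are removed from the variant list and tallied separately.
The threshold is configurable and adjacency is measured within one
level (amino-acid runs on protein columns, codon runs on codon indices)
— the least surprising reading of an exclusion criterion that is
qualitative in origin. Note the default interacts with synonymy at the
codon level: a nonsynonymous variant adjacent to a synonymous one is
filtered at the codon level but not at the amino-acid level, so the
cross-level identity above is guaranteed only for unfiltered scans (or
scans whose variants are non-adjacent).

## Ancestral reconstruction and path labels

Reconstruction is done in-house on the fixed rooted input tree, in two
modes, rather than shelling out to an external phylogenetics binary; an
adapter for externally produced marginal-ancestral-state files exists
for parity checking (`read_marginal_ancestral_states`,
`reinsert_dropped_columns` for tools that drop all-gap columns — we
retain such columns internally, so only the adapter needs coordinate
bookkeeping).

- *Parsimony*: unit-cost Sankoff dynamic programming (up and down
  passes), equivalent to Fitch on binary trees and defined on
  multifurcations. Each node's posterior is uniform over the states
  attainable in at least one most-parsimonious reconstruction.
- *ML*: marginal posteriors under a K-state equal-rates reversible
  model with uniform frequencies (the K-state Jukes–Cantor
  generalization), computed by the pruning recursion plus an outside
  pass. The state space is the set of unambiguous states observed in the
  column (`-` included when present, modeled as an ordinary state);
  ambiguous leaves contribute flat partial likelihoods. Branch lengths
  are expected substitutions per site; a tree whose lengths are all zero
  cannot inform an ML reconstruction and falls back to parsimony with a
  warning. No rate heterogeneity and no GTR parameter estimation: for
  direction-of-change calls at individual sites the equal-rates model is
  testable against closed forms, which we value over model realism here.

MAP ties (posterior gap ≤ 1e-9) are reported as `None`, never broken
arbitrarily: downstream path labels must not depend on iteration order.
Note that on symmetric toy data exact ties are common and correct —
with two states and a topologically symmetric configuration, 0.5/0.5 is
the true marginal.

A variant's evolutionary path is **simple** (parallel) when every target
lineage's origin-branch parent node has the same MAP state and every
node from each lineage MRCA down to its leaves already carries the
lineage's derived state; resolved evidence against this (a differing
parent or within-clade state, or a clade not fixed for one state) makes
it **complex**, and ties yield **unresolved** only when no resolved
evidence already forces "complex" — this precedence makes the label
independent of traversal order. The simple/complex dichotomy is one
consistent formalization of an illustrated, not formally defined,
distinction; it is documented as such.

Indels are encodable as a binary presence/absence matrix
(`encode_indels_binary`) with all columns retained, for running the same
reconstruction machinery on gap characters.

## Combinations and branch features

A subset of k species decomposes into *independent lineages*: maximal
clades whose MRCA has only chosen species as leaf descendants (singleton
lineages allowed; their MRCA is the leaf, walking up through unary
nodes). A subset is polyphyletic when it has ≥2 lineages, which makes
the subset MRCA a strict ancestor of every lineage MRCA. Enumeration
streams `itertools.combinations` in lexicographic order — the
unconstrained 6-of-47 case (10,737,573 subsets) runs in seconds without
materialization — and applies the lineage-count filter via bitmask
ancestor walks when `m` is given. Core controls are combinations shaped
like the focal trait group: exactly three lineages, two inside two
distinct focal clades and one disjoint from all of them.

The origin branch of a lineage is the branch entering its MRCA; a
lineage whose MRCA is the tree root has no origin branch and raises an
error rather than defaulting a length that would poison the POB product
(a zero-length origin branch is allowed but warns, since it zeroes POB).
Features: POB = Π origin-branch lengths (m factors), PTB = Π terminal
branch lengths (k factors), DTB = Σ species root-to-leaf path lengths,
DTN = the same sums stopped at each leaf's parent. DTB − DTN = Σ
terminal branch lengths holds exactly and is tested as an identity.
POB is the feature expected to track chance convergence: long shared
ancestral branches give lineages more time to fix substitutions that
later read as convergent.

## Statistics

Spearman's rho is computed literally as the product moment of mid-ranks
(ties averaged), with the two-sided large-sample t approximation for the
p-value; the implementation is cross-checked against the reference
rank-correlation routine in tests. OLS fits go through statsmodels; the
outlier test Bonferroni-adjusts (multiplier n, capped at 1) the
two-sided p of each externally studentized residual against t(n−3) and
reports at most `n_max` (default 3) observations below alpha, largest
residual first — the documented behavior of the standard
regression-outlier test in the R ecosystem. Gene-set overlap uses the
upper-tail hypergeometric probability, exact against enumeration for
small universes, with Benjamini–Hochberg adjustment across batches.

The species ordination sums BLOSUM62 substitution scores over selected
sites into a symmetric similarity matrix. A gap against anything scores
the matrix minimum (−4) — penalizing indels without introducing a
second gap model — and `X` scores 0; both are configurable. The matrix
is double-centered before spectral decomposition (classical MDS
convention: raw similarity matrices carry a dominant size component that
swamps the first axis); raw decomposition is available via
`center=False`. Coordinates are eigenvector × √eigenvalue over the
non-negative spectrum.

## Synthetic data

The generator evolves a random root sequence down the tree under an
equal-rates process per site (change probability from the same K-state
transition matrix the ML reconstruction uses), then overwrites planted
sites so that group A carries exactly the requested A-states and every
other non-excluded species a B-state, each requested state guaranteed to
appear. Codon plants write whole codons, so amino-acid and codon truth
are jointly consistent. The truth table stores each plant's type,
convergent/divergent label, synonymy, nucleotide source, and whether it
is adjacent to another plant (and hence removed by the run filter).
Plants that cannot realize their type, or adjacent plants not explicitly
allowed, are configuration errors.

In fixture-suite mode (`clean_background=True`) unplanted columns that
come out mutually exclusive by chance are redrawn, so the truth table is
exact by construction and planted-variant recovery can be asserted at
precision = recall = 1. The default leaves chance background variants
in, which is the realistic condition. The generator deliberately does
not emulate rate heterogeneity, codon models, or selection: it exercises
detection logic, not model fit, so passing tests demonstrate correctness
of the scanning and bookkeeping — not robustness to realistic avian
sequence evolution.

Default fixture sizes (8 taxa, 40 amino-acid / 20 codon sites, one plant
per type plus source-coverage plants) are small enough to regenerate
per-test yet cover every classification branch.

## Pipeline

Per-combination scans are independent work units keyed by `combo_id`
(the sorted, `|`-joined species); group B defaults to all species not in
the combination and not excluded, recomputed per combination (an
explicit background list can override). Counts tables carry
ConSAV/DivSAV (amino-acid types 1–2 / 3–4), ConSCV/DivSCV (codon level),
and ConSNV/DivSNV (nucleotide level scans of the in-frame alignment);
the per-variant SNV/CNENV source labels live in the scan reports and are
not double-counted in the table. Optional per-combination JSON
checkpoints make long runs resumable with byte-identical output, and all
outputs are sorted by `combo_id`, so reports are deterministic functions
of inputs and seed.

## Known limitations

- Exclusivity requires every non-excluded species to have a state (gaps
  count as states); taxa missing from an alignment are an error, not
  quietly dropped.
- The ML model's uniform-frequency, single-rate assumption makes
  posteriors symmetric in ways real data are not; for publication-grade
  direction calls, feed externally reconstructed states through the
  adapter and compare.
- The continuous-variant run threshold (default 2) is a heuristic for
  an exclusion criterion that has no quantitative published definition.
- Whether the ordination should center the score matrix is genuinely
  open; both modes are provided and differ for matrices with a strong
  size component.
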