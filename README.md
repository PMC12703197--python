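# convar

Detection and classification of **mutually exclusive sequence variants**
between a polyphyletic target group of species and the remaining
background species, at amino-acid, codon, and nucleotide resolution —
with ancestral-path verification, control-combination enumeration, and
the statistics needed to separate trait-linked convergence from the
background convergence that accrues on long ancestral branches.

The motivating use case is molecular convergence scans such as those for
avian vocal learning, where the target trait evolved independently in
several clades (songbirds, parrots, hummingbirds) and one asks which
alignment sites are fixed differently in all target lineages versus all
other species.

## The method

Given a per-gene multiple sequence alignment, a species partition
(target group A, background group B, optional excluded taxa), and a
rooted species tree with branch lengths:

1. **Scan.** A site is *mutually exclusive* when the set of states seen
   in A and the set seen in B are disjoint (`-` is a state; any
   ambiguity code makes the site unscannable). Each such site is typed
   by profile cardinality:

   | Type | \|states in A\| | \|states in B\| | label |
   |------|------|------|------------|
   | 1 | 1 | 1 | convergent |
   | 2 | 1 | >1 | convergent |
   | 3 | >1 | 1 | divergent |
   | 4 | >1 | >1 | divergent |

   Maximal runs of ≥2 adjacent variant sites are removed as putative
   structural variants. At codon level each variant is further labeled
   synonymous/nonsynonymous (nonsynonymous iff the translated profile
   pair is itself mutually exclusive) and traced to its nucleotide
   source: a single mutually exclusive codon position (ConSNV/DivSNV) or
   complex non-exclusive nucleotide variants (CNENV) whose exclusivity
   emerges only at the whole-codon level.

2. **Ancestral direction.** Marginal ancestral states at variant sites
   are reconstructed on the fixed tree (Felsenstein pruning under an
   equal-rates reversible model, or Fitch/Sankoff parsimony), and each
   target variant's path is labeled *simple* (all target lineages
   changed directly from one shared ancestral state to the derived
   state) or *complex*.

3. **Controls and branch features.** All k-species combinations drawn
   from m independent lineages of the tree are enumerated (streaming,
   lexicographic), and each combination is summarized by
   POB (product of origin-branch lengths), PTB (product of terminal
   branch lengths), DTB (summed root-to-leaf path lengths), and DTN
   (summed root-to-leaf-parent path lengths; DTB − DTN = Σ terminal
   branches exactly).

4. **Statistics.** Spearman rank correlation (mid-ranks,
   product-moment-of-ranks form), OLS with adjusted R², a Bonferroni
   outlier test on externally studentized residuals (t with n−3 df,
   ≤ n_max reported), upper-tail hypergeometric gene-set overlap with
   Benjamini–Hochberg FDR, and a BLOSUM62 summed-score species
   ordination (double-centered spectral decomposition).

A synthetic-data module simulates tree-consistent alignments with
planted variants of every type and source, with a machine-readable truth
table, so the whole pipeline is testable without any external data.

## Worked example

Three vocal-learner analogs carry codon `AAT` (asparagine) where every
background species carries `CAT`/`CAC` (histidine):

```python
from convar import MultipleAlignment, SpeciesPartition, ScanLevel, scan_alignment

codon_rows = {
    "zebra_finch": "ATGAAT", "parrot": "ATGAAT", "hummingbird": "ATGAAT",
    "chicken": "ATGCAT", "eagle": "ATGCAC", "penguin": "ATGCAT",
}
aln = MultipleAlignment(list(codon_rows), list(codon_rows.values()), "nucleotide")
part = SpeciesPartition.against_rest(
    aln.species_ids, {"zebra_finch", "parrot", "hummingbird"}
)
report = scan_alignment(aln, part, ScanLevel.CODON)
for v in report.variants:
    print(v.site_index, v.variant_type, v.con_div, sorted(v.profile.set_a),
          sorted(v.profile.set_b), v.synonymy, v.nt_source, v.snv_position)
```

prints

```
2 2 convergent ['AAT'] ['CAC', 'CAT'] nonsynonymous ConSNV 1
```

i.e. codon site 2 is a Type 2 convergent codon variant (one codon fixed
across the target group, two codons in the background), it changes the
protein (N vs H), and it originates from a single mutually exclusive
nucleotide at codon position 1 (`A` vs `C`) — a convergent single
nucleotide variant. Codon site 1 (`ATG` everywhere) is invariant and
reported as nothing.

The same analyses are scriptable from the shell via the `convar` console
command (`convert`, `scan`, `ancestry`, `enumerate`, `correlate`,
`enrich`, `pca`, `simulate`, `pipeline`); see `convar --help`.

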