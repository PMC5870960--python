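# Methods

## Scope and data flow

`cubkit` operates on codon count tables. A CDS FASTA is read, filtered,
and tallied into a genes × 64 integer matrix (`CodonCountTable`); every
statistic downstream is a function of that matrix (per-gene rows or the
pooled column sum), so any printed number can be re-derived from the same
counts. Pooled values for a gene set are computed from summed counts
(count-weighted), never as means of per-gene values; per-gene averages
are exposed separately because the two genuinely differ (a pooled ENC of
a genome is typically 1–2 units above the mean of per-gene ENCs).

## Filtering

Codon counting is only well defined on clean in-frame CDS, so the default
policy drops sequences whose length is not a multiple of three, that
contain bases outside A/C/G/T, or that contain an in-frame stop before
the final codon. A terminal stop is removed before counting: a stop can
occur exactly once per CDS and so carries no usage information.
Rejections are counted per reason in a `FilterLog` (TSV output), keeping
the choice auditable; nothing is raised for a rejected sequence.

## Index conventions

Two third-position conventions coexist and are deliberately kept apart:

* `GC1/GC2/GC3/GC12` are plain per-position G+C fractions over all sense
  codons (Met/Trp included). `GC12 = (GC1 + GC2)/2` by definition.
* `A3s/T3s/G3s/C3s` are synonymous frequencies with *family-potential*
  denominators: `X3s` divides the count of synonymous codons ending in X
  by the count of synonymous codons whose family offers an X-ending
  synonym. This is the CodonW convention; it is the reason the four X3s
  values of a genome sum to more than 1, and the only convention
  consistent with published tables of this kind. `GC3s` divides by all
  synonymous codons, hence `GC3s ≤ G3s + C3s`.

Undefined quantities (empty denominators — e.g. X3s of a gene consisting
only of Met) are NaN internally and `NA` in every TSV, never zero.

### ENC

Wright's estimator is computed per degeneracy class. Families with usage
below 2 contribute nothing; if the three-fold class (Ile alone in the
standard code) ends up empty its mean homozygosity is imputed as the
average of the two- and four-fold class means — the standard fallback for
an estimator whose class structure is otherwise broken by short genes. An
empty two-, four- or six-fold class leaves ENC undefined with a recorded
reason rather than guessing. Finite-sample estimates can exceed 61 (the
uniform-usage table of the acceptance checks gives a raw 61.04); values
are capped at 61 and the raw value is kept on the result object.
Six-fold families (Leu, Ser, Arg) are treated as single six-member
families, consistent with the RSCU multiplier of 6; tools differ here and
the choice is documented for that reason.

### P2

The eligible codons are derived from the code table rather than
hard-coded: every pair (prefix+C, prefix+T) whose prefix is both-weak
(A/T) or both-strong (G/C) and whose two members are synonymous. In the
standard code this yields exactly the eight prefixes AA, AU, UA, UU, CC,
CG, GC, GG. P2 uses pooled RSCU for a gene set, matching the one-value-
per-genome shape of published tables. The published aggregate quartets
(SSU/WWU/SSC/WWC) for the two diploid cotton genomes reproduce their
printed P2 values to four decimals through `P2Result.from_sums`, which is
what the acceptance script recomputes.

## Optimal codons

The 5% tails of the ENC ranking act as high-/low-expression proxies. Ties
at a cut are resolved by gene id so the partition is stable under input
reordering. ΔRSCU is computed from dataset-pooled RSCU (matching the
single High/Low value per codon that published tables report), while the
significance test is a Welch (unequal-variance) two-sample t-test on
per-gene RSCU values — the safe default given that the two 5% tails have
no reason to share a variance. Genes in which a family is absent
contribute no observation for that family's codons (undefined, not
zero), so short genes cannot deflate RSCU. The ΔRSCU ≥ 0.08 threshold is
inclusive. No multiple-testing correction is applied — the rule is a raw
per-codon P < 0.01 — but raw p-values are reported so users can apply
their own.

## Cross-set statistics

* **Correlations** are Pearson product-moment with two-tailed p-values,
  pairwise-complete over undefined entries; constant columns and pairs
  with fewer than 3 observations yield NaN, and below 10 observations a
  warning is emitted (whole-genome correlations over a handful of sets
  are supported but statistically weak).
* **Duncan's multiple range test** follows the textbook construction:
  pooled error mean square from the one-way ANOVA, harmonic-mean group
  size for unequal `n`, and for a range spanning `p` ordered means a
  critical value from the studentized-range distribution at Duncan's
  protection level `1 − (1 − α)^(p−1)`. A range inside a non-significant
  wider range is never declared significant; letters are assigned by the
  standard descending-means sweep (highest mean gets "a"). Note the
  protection levels make the procedure per-comparison-protected, not
  familywise: with `k` groups under the complete null the probability of
  any letter split is about `1 − (1−α)^(k−1)`, which equals α only for
  `k = 2`; the test suite checks exactly that behaviour.
* **Clustering** of gene sets on pooled 59-long RSCU vectors uses
  Euclidean distance and average linkage (both configurable — the
  upstream tools' defaults are not documented anywhere authoritative).
  Codons undefined in some sets are imputed with the across-set mean;
  labels are processed in sorted order so the Newick serialization is
  invariant under input reordering.

## Synthetic data

The generator emulates the two causal forces the indices are meant to
separate, as an equilibrium snapshot (no generational dynamics):

* Gene length in codons ~ Normal(mean, sd) rounded, floored at 30;
  defaults 400 ± 100, a realistic scale for plant nuclear CDS.
* Amino acids i.i.d.; default uniform over the 18 multi-codon amino
  acids, which isolates synonymous effects from amino-acid composition.
* Mutation: a codon is emitted with probability proportional to the
  mutational probability of its third base, renormalized within the
  family. Each codon carries the full weight of its third base (relevant
  in six-fold families), i.e. the equilibrium of third-position mutation
  acting on distinct sequences. Under uniform base probabilities every
  family is used uniformly — the RSCU = 1, ENC → 61 neutral limit — and
  under a skewed distribution GC3s of neutral genes tracks the configured
  third-base G+C up to family-availability distortions.
* Selection: with per-gene probability `s_g` the designated preferred
  codon of the drawn amino acid is emitted instead. The default `s_g`
  rule is a two-point mixture (0 and 0.8) with exact stratum sizes
  (largest-remainder rounding, rng-permuted): 400 genes with 50 selected
  is the standard study condition for recovery scoring. Probabilistic
  replacement was preferred over Boltzmann-style weighting because it
  gives a single interpretable knob per gene. `s_g = 1` collapses every
  family to its preferred codon and yields ENC = 20 exactly.
* The preferred set defaults to the alphabetically first codon of each
  family — arbitrary, deterministic, and recorded in the truth table.
* ATG is prepended, a uniformly drawn stop appended; both are excluded
  from analysis anyway. All randomness flows from one integer-seeded
  `numpy` generator; identical configs are byte-identical.

What the generator does **not** emulate: amino-acid composition bias,
within-gene positional structure, isochore/GC gradients along genes,
length–bias correlations, and expression-level measurements (selection
strength stands in for expression). Recovery results on synthetic data
therefore validate the machinery — index arithmetic, ranking, testing —
not the biological claim that real high-bias genes are highly expressed.

## Problem sizes and numerical choices

The test-bed exercises the pipeline at a few hundred genes of a few
hundred codons — large enough that binomial noise on RSCU at ~2000
codons/family is a few percent and the neutral ENC band is within 2
units of the expected curve at 1000-codon genes, small enough that the
whole suite runs in minutes. Reported TSVs use `%.6g` floats and `NA`
sentinels so re-runs diff cleanly. Codons print in RNA form (UUU) by
default to match field conventions, with a DNA switch on the CLI.

## Known limitations

* ENC imputation beyond the Ile class is not attempted; very short genes
  simply have undefined ENC and drop out of ENC-ranked analyses.
* Duncan's MRT inherits its weak familywise control by design (it is the
  named method, not a recommendation); users wanting strong control
  should use a different post-hoc procedure.
* The optimal-codon procedure assumes the ENC tails proxy expression;
  with real data, measured expression would be preferable when available.
* P2's codon list is derived from the code table under the weak/strong
  prefix rule; published aggregate values from other scripts may differ
  if they handled the CGN arginine block differently.
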