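# Methods

This note documents the models and procedures implemented in `polyqevo`,
the assumptions behind them, the parameters that matter, and the design
choices made where the design was genuinely open.

## Per-site selection inference (`polyqevo.selection`)

The estimator is a single-ancestor counting method of the SLAC family.
Given a codon alignment and a rooted tree with matching leaf labels:

1. **Ancestral states.** Codons are treated as atomic states and internal
   nodes are assigned by maximum parsimony (unit cost per codon change).
   Ties are not broken: all equally parsimonious assignments are averaged
   uniformly, computed exactly with a Sankoff-style dynamic program that
   carries, per node and state, the number of optimal labelings and the
   accumulated synonymous/non-synonymous mass. A reconstruction that uses
   joint maximum likelihood under a codon model (as the original SLAC
   does) would weight ties by branch lengths; parsimony with uniform tie
   averaging is deterministic and dependency-free, and is the main source
   of (small) divergence from ML-based counting implementations.
2. **Branch counts.** A parent/child codon pair contributes S and N
   averaged over all orderings of its differing positions; any ordering
   passing through a stop codon is excluded (Nei–Gojobori convention).
   If every ordering is blocked, an unordered per-position comparison is
   used and logged — this affects a handful of the 3721 sense-codon pairs
   and none of the common ones.
3. **Expected sites.** Per codon position, the synonymous fraction is
   counted over non-stop single-nucleotide alternatives, so ES + EN = 3
   exactly for every sense codon. Site-level ES/EN average over the
   observed (non-gap, unambiguous) leaf codons at the column.
4. **Test.** With n = round(S_obs + N_obs) and p₀ = ES/(ES+EN), the
   purifying p-value is the upper binomial tail of the observed synonymous
   count (ceiling for fractional counts; the fraction is kept unrounded in
   reports), and symmetrically for the diversifying tail. Default
   alpha = 0.1, configurable; counting tests are conservative, and this
   matches common defaults for the method family.

Missing data: a gap, ambiguous, or stop codon at a leaf makes that leaf
missing for the site; branches incident to dataless subtrees contribute no
counts. Branch lengths are ignored throughout — the counting estimator
needs states, not times.

Calibration is verified empirically: on neutral simulations (ω = 1, 500
sites, 8 taxa) the purifying-call rate stays within alpha plus three
binomial standard errors even under transition-biased mutation
(kappa = 2), and on ω = 0.1 simulations with deep coverage (16 taxa,
about 27 expected mutation events per site) dN/dS falls below 1 at > 90%
of substituted sites with test power above one half.

## Tract statistics (`polyqevo.tracts`)

A polyQ tract is a maximal run of at least 4 consecutive glutamine codons.
Q codons are exactly {CAA, CAG}; ambiguous codons (CAR, CAN, ...) break a
run and are never counted — a "pure glutamine stretch" requires certainty.
Metrics: LQ = codon count, LNI = longest consecutive CAG run (an all-CAA
tract has LNI = 0), PQ = CAG count / LQ.

Ortholog mapping works through the alignment window of the focal tract,
extended across maximal gap-column blocks immediately adjacent to it on
either side (gaps conjoined to the tract); non-adjacent gaps do not extend
the window. Within each ortholog row, candidate runs are maximal Q runs of
the *ungapped* sequence (gap columns do not interrupt a run); the longest
run whose columns intersect the window is taken, ties resolved to the most
5' run for determinism.

z-scores standardize the focal tract against its orthologs with the
sample (n−1) standard deviation, focal value excluded. Zero ortholog
spread makes the score undefined (flagged and excluded from rankings)
rather than infinite; the length-variability filter makes this rare.
Conservation filters are strict: more than 5 primate and more than 5
non-primate ortholog occurrences, and at least two distinct LQ values
(distinctness of full codon strings is available via `variation="codons"`
because "length variability" could be read either way; LQ variation is
the default as the more literal reading). Ranking is per metric,
descending, with percentile = rank / n_defined; genes with several tracts
contribute each tract independently.

## Pseudogene exon rates (`polyqevo.pseudogene`)

Substitutions are assigned to the pseudogene lineage by outgroup
parsimony polarization — focal ≠ reference with reference = outgroup —
rather than ML branch-length estimation under GTR+Γ; at the small
divergences involved the obs/exp *ratio* statistic is insensitive to the
difference, and polarization is deterministic. Columns with any gap are
excluded; columns where the reference changed are tallied separately and
reported but never enter the ratio; columns where focal = reference ≠
outgroup or all three differ are ambiguous and unassigned. Multiple hits
per column are invisible by construction (minimum-change counts).
Exon lengths are measured in gap-excluded analyzable columns so observed
and expected rest on the same base, giving Σexp = Σobs exactly.

## Expression Q-trend (`polyqevo.expression`)

CPM = value × 10⁶ / library size; genes with mean CPM < 1 across all
samples are dropped (kept at exactly 1). Stepwise monotonicity is strict:
genotype means over the ordered genotypes (0, 2, 4, 7 Q) must strictly
increase or strictly decrease; ties fail. Spearman correlation uses
replicate-level values against Q as the ordinal covariate with midranks
for the tied Q values — note that with tied covariates the attainable
|rho| is below 1 even for a perfectly ordered gene. A gene passes when it
is stepwise-monotone and its two-sided p is below alpha (default 0.05).
No multiple-testing correction is applied by default because the joint
stepwise + correlation filter is already far more stringent than the
nominal level (the null pass rate measured on unplanted simulations is
about half of alpha); Benjamini–Hochberg correction is available via
`bh=True`. Differential-expression calling itself (dispersion modelling,
fold-change/FDR thresholds) is consumed as an input table, not
re-implemented; the Jaccard and GO-score utilities operate on such
tables' ranked gene lists.

Row z-scaling for heatmaps uses the population (n denominator) standard
deviation; constant rows are flagged, not scaled.

## Synthetic data (`polyqevo.simulate`)

The generators define the study conditions every verification runs under.

* **Codon evolution.** HKY-style proposals (transitions weighted by
  kappa = 2) at 3·t expected proposals per codon per branch of length t;
  stop-creating proposals are rejected; non-synonymous proposals are
  accepted with probability min(1, ω) of the site's class. This
  acceptance-thinning scheme gives exact syn/nonsyn truth counts without
  codon-rate-matrix exponentiation. Defaults: 16 taxa on a balanced tree,
  branch length 0.1, site classes (ω = 0.1, 50%; ω = 1, 50%).
* **Repeat region.** Per branch, Poisson-distributed expansion (duplicate
  a random unit) and contraction (delete one; skipped at length 1) events
  plus per-unit CAG↔CAA flips — the repeat analogue of the
  instability-of-pure-tracts regime. The repeat block is left-justified
  and gap-padded in the output alignment; since every unit is a Q codon,
  this alignment is exact.
* **Tract tables.** 8 primate + 8 non-primate orthologs per gene, tract
  lengths ~ N(7, 2²) floored at 4 (7 is the murine HTT tract length),
  70% CAG per Q codon; a planted outlier taxon gets +14 Q, pure CAG —
  mirroring a human-HTT-like 21Q pure tract against a 7Q background.
* **Expression.** 0/2/4/7 Q × 3 replicates (the knock-in series design);
  planted genes scale their mean by effect^rank(Q) with per-step effect
  2^(1/3) (a two-fold extreme-genotype contrast, the smallest effect the
  recall target is stated for); log-normal replicate noise with
  sigma = 0.15 (≈ 15% CV, typical of bulk RNA-seq biological replicates);
  gene base means log-normal (log-mean 4, log-sd 1.5).

What the generators deliberately do **not** emulate: alignment error,
indels outside the repeat region, rate variation among branches, codon
usage bias, RNA-seq count overdispersion beyond log-normal noise, batch
effects, and correlated genes. Passing tests therefore certify the
estimators' arithmetic, calibration and recovery behavior under clean
conditions — not robustness to real-data artifacts, which enter through
the I/O layer's explicit gap/ambiguity handling instead.

## Numerical conventions

Coordinates are 0-based half-open internally and 1-based closed in all
user-facing tables and messages. Gap codons must be `---`; codons mixing
gap and nucleotide symbols are rejected at load because they make
per-site counting ill-defined. Terminal stop codons in CDS input are
accepted and trimmed (mRNA predictions commonly include them); internal
stops are errors. Taxon matching is exact string match after whitespace
trimming — no fuzzy matching, since a silent mismatch corrupts counts;
unmatched taxa are reported and pruned. All simulation randomness flows
from explicit seeds through `numpy` generators; no global state.

## Problem sizes

The verification suite and the acceptance script run at desk scale by
design: selection calibration on 500 neutral sites (8 taxa) and power on
200 selected sites (16 taxa); exhaustive-enumeration cross-checks on 100
random alignments of ≤ 6 taxa × 10 codons; 50 seeded tract datasets;
200 pseudogene replicates of 600 columns; expression matrices of
600–1000 genes. These sizes put Monte-Carlo error well inside the stated
bounds while keeping a full run in seconds.
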