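# Methods

## CpG_o/e

For each gene the statistic is computed on the longest coding sequence:

```
CpG_o/e = f_CpG / (f_C · f_G),   f_CpG = n_CG / (L − 1),
                                 f_C = n_C / L,  f_G = n_G / L
```

where `L` is the number of unambiguous (A/C/G/T) positions. The
dinucleotide frequency uses the `L − 1` denominator (number of adjacent
pairs) while the mononucleotide frequencies use `L`; this differs from the
simpler `L · n_CG / (n_C · n_G)` by O(1/L) and is the documented convention
here. Positions outside A/C/G/T are excluded from all counts, and an
excluded position also breaks a potential CG pair spanning it, so runs of N
cannot deflate the statistic. A gene with no C, no G, or fewer than two
counted positions has no defined value and is dropped with a logged count.
Values are retained only on the strict open interval (0, 2) before fitting;
boundary values 0 and 2 are excluded. Genes outside the interval are
excluded from both the fit and the classification.

## Mixture model and threshold

Retained values are modelled as a two-component univariate Gaussian
mixture,

```
p(x) = w0 · N(x; m0, s0²) + w1 · N(x; m1, s1²),
```

fitted by EM. Initialisation is deterministic: the sample is split at its
median and each half supplies the initial weight, mean and standard
deviation of one component. This removes run-to-run variability without a
random seed; for a genuinely bimodal sample the median split lands close
enough to the basin of the global optimum that random restarts add nothing
(the unit tests cross-check the reached optimum against an independent EM
implementation with multiple random starts). Variances are floored at 1e-4
to prevent collapse onto a single point. Iteration stops when the
log-likelihood improves by less than 1e-8 (default cap 500 iterations;
non-convergence returns the current fit with a warning flag). Components
are relabelled so the low-mean component is component 0.

The classification threshold is the intersection of the two scaled
component densities, `w0 · φ(x; m0, s0) = w1 · φ(x; m1, s1)`, solved in
closed form (linear for equal variances, quadratic otherwise) and restricted
to the open interval between the means; if no root lies there (possible for
extreme weight ratios), the point of equal posterior responsibility is
located by bisection instead. Genes with a value strictly below the
threshold are called **low** (putatively methylated); values at or above it
are **high** — the boundary assignment is arbitrary but fixed.

## Orthogroup concordance

Orthogroup membership is consumed from an `Orthogroups.tsv`-dialect table
(orthology inference itself is upstream of this package). An orthogroup's
status in a species is **low** or **high** only when every called member
gene agrees ("always belonged" semantics); disagreement gives **mixed**,
and no members (or no surviving calls after filtering) gives **absent**.
Mixed and absent statuses place the orthogroup in no set, and a
majority-vote variant is available as a flag for sensitivity analysis.
Exclusive intersection counts — the quantities an UpSet plot shows — are
computed by assigning each orthogroup to the exact combination of
(species, category) sets containing it, so counts partition the union of
the sets.

A gene is **species-specific** when it is unassigned to any orthogroup or
its orthogroup contains genes from no other species; the unassigned-genes
convention is this package's definition, stated here because membership
tables do not carry one.

## dN/dS

Protein alignments are back-translated onto their CDS (each non-gap
residue consumes the next codon); columns with a gap in either row or a
non-ACGT base are removed entirely rather than imputed. Pairwise estimates
use the Nei–Gojobori (1986) counting method:

- **Sites.** For each codon position the three single-base mutants are
  enumerated; the synonymous fraction among non-stop mutants is the
  synonymous site weight at that position, and mutants to stop codons are
  excluded from the denominator. Site counts are averaged over the two
  sequences.
- **Differences.** For a codon pair differing at k positions, all k!
  substitution orderings are enumerated; orderings passing through a stop
  codon are excluded and the synonymous/nonsynonymous step counts averaged
  over the remainder. If every ordering is blocked, the unrestricted
  average is used with a warning.
- **Correction.** Observed proportions pS = Sd/S and pN = Nd/N are
  converted to distances with the Jukes–Cantor formula
  d = −(3/4)·ln(1 − 4p/3), undefined at p ≥ 3/4.

Pairs with dN > 2 or dS > 2 are discarded from group comparisons, as are
pairs with dS = 0, where omega is undefined (the zero-dS rule is this
package's choice; only the >2 filter is inherent to the procedure). The
low-vs-high bin contrast uses a two-sided Wilcoxon–Mann–Whitney test:
exact enumeration when both samples have at most 8 values and no ties,
otherwise the normal approximation with tie and continuity corrections.
NG86 was chosen over likelihood codon models (e.g. the yn00 style
estimator) because every intermediate quantity is exactly specifiable and
verifiable against exhaustive enumeration; output metadata names the
estimator so downstream users know omega values are not yn00 values. The
two estimators agree closely in the weak-divergence regime this pipeline
operates in, but no row-for-row equality is claimed.

## GO enrichment

Direct annotations are propagated to all ancestors across is_a and part_of
edges (true-path rule; obsolete terms dropped, cyclic ontologies rejected).
Each term annotated to at least 10 universe genes is tested with the
upper-tail hypergeometric probability P(X ≥ k) for k study-bin genes among
K universe genes annotated, study size n, universe N. Raw p-values are
reported with fixed significance tiers (0.05 / 0.001 / 0.00001) and no
multiple-testing correction. This is the classic Fisher test on propagated
annotations; decorrelation heuristics that down-weight parents of enriched
children (topGO-style weight01/elim) are deliberately out of scope because
their behaviour is not exactly specifiable — rankings agree qualitatively,
not row-for-row. Only the biological_process namespace is tested by
default.

## Synthetic data

The generators produce data with the statistical structure the analysis
assumes, plus planted truth for recovery testing.

**CDS sets.** Codons are sampled sequentially from a base-composition model
(GC content 0.42 by default). For a "methylated" gene, any candidate codon
whose interior or junction with the previous base would create a CG
dinucleotide has its weight multiplied by the depletion factor δ (default
0.3) before renormalisation. Depletion is therefore imposed generatively —
the bimodal CpG_o/e shape is emergent, as in real methylated gene bodies —
rather than by rejection sampling on the realised statistic. The defaults
(δ = 0.3, GC 0.42, mean length 300 codons with CV 0.25, minimum 30) are
tuning constants chosen to place the two modes near 0.4 and 1.0 with a
planted methylated fraction of 0.45. Genes are wrapped into synthetic
scaffolds as two-segment gene models (intron 50–150 nt), half on each
strand, with correct GFF3 phases, so the extraction stage is exercised end
to end.

**Codon-pair divergence.** Two descendants evolve independently from an
ancestor; each branch proposes Poisson(divergence/2 × length) single-base
changes at uniform positions, rejects stop-creating proposals, accepts
synonymous ones, and accepts nonsynonymous ones with probability omega.
Two symmetric branches make the pairwise divergence approximately the
configured total (0.2 substitutions/site by default). Note the proposal
count, not the accepted count, is Poisson, so realised divergence falls
below the nominal value as omega decreases — the recovery tests measure
omega, which is unaffected.

**Orthogroup tables.** Orthogroups are planted with pure per-species
patterns (defaults: 2182 all-low, 728 all-high, and 666 with the first
three species low and the last high — the concordance structure the
pipeline is designed to detect), plus single-species orthogroups and
unassigned genes skewed toward the high bin (P(high) = 0.8), reflecting
the empirical tendency of species-specific genes to be unmethylated.

**GO annotations.** A three-level toy DAG (root, 5 mid terms, 40 leaves);
every gene receives two uniform background leaves; each planted term is
annotated with probability r·q inside the study bin and q outside, with q
set so the expected universe count matches a configured K (default 200 at
relative risk 4 in a 10,000-gene universe).

What the generators do **not** emulate: isochore/GC heterogeneity along
chromosomes, introns with splice signals, indel evolution, repeat content,
annotation error, codon-usage bias beyond base composition, and
between-gene rate variation. Passing recovery tests therefore demonstrate
correctness of the estimators under the assumed generative model, not
robustness to real-data artefacts.

## Numerical and procedural choices

- GFF3 coordinates are 1-based inclusive end to end; the phase column is
  ignored for extraction (segments concatenated as annotated, matching
  common extractor behaviour on well-formed annotations) and a non-zero
  first phase is logged.
- Longest-CDS ties break on lexicographically smallest transcript id.
- Classification at exactly the threshold goes to the high bin.
- Equal component variances are detected at absolute tolerance 1e-12 and
  routed to the linear intersection formula.
- Problem sizes in the test suite and acceptance script: mixture recovery
  at 20,000 values across 10 seeds; CpG_o/e oracle equality on 1,000
  random sequences; NG86 oracle equality on 100 random 50-codon pairs;
  omega recovery at 300 codons × 50 replicates per planted value; the bin
  contrast at 200 pairs per bin × 100 runs; end-to-end fraction recovery
  at 10,000 genes × 5 seeds. These sizes give sampling error comfortably
  inside the asserted tolerances (e.g. ±0.02 on mixture parameters, ±0.05
  on omega, ±0.03 on the recovered fraction).

## Known limitations

- NG86 omega is biased upward at high divergence (Jukes–Cantor ignores
  transition/transversion bias); the pipeline's operating regime
  (divergence ≈ 0.2 substitutions/site) keeps this small, as the recovery
  tests quantify.
- The strict all-members orthogroup status rule discards information in
  mixed orthogroups; the majority-rule flag exists for sensitivity checks
  but no calibration between the two is provided.
- Classic Fisher enrichment inflates parents of genuinely enriched leaf
  terms (the decorrelation problem); interpret parent-term hits
  accordingly.
- The EM fit assumes exactly two components; unimodal or >2-modal inputs
  still return a fit but the threshold is then meaningless. No model
  selection over component count is performed.
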