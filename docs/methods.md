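# Methods

This note documents the models behind each module, the defaults and
why they were chosen, the conventions of the synthetic-data generator,
and the numerical choices that affect results.

## Codon substitution engine

The engine works on the 61 sense codons of the universal genetic code.
Rates follow the Goldman–Yang structure: a change i→j has rate zero
unless the codons differ at exactly one nucleotide; otherwise the rate
is π_j · κ^[transition] · ω^[nonsynonymous], where π are codon
frequencies (uniform, or F3x4 estimated from the data — the default in
fits), κ the transition/transversion rate ratio and ω = dN/dS.  The
chain cannot visit stop codons.

**Scaling.** Generators are normalized so one unit of branch length is
one expected substitution per codon under the *mixture* of site
classes, using each class's background ω.  The simulator uses the same
convention, so simulated and estimated branch lengths are directly
comparable, and the convention is shared between the null and
alternative fits of every LRT.

**Site classes.**

- M0: one ω for all sites.
- M3(K): K discrete classes (p_k, ω_k); default K = 3.
- M7: ω ~ Beta(p, q) on (0, 1), discretized into 10 equal-probability
  categories represented by their category means.
- M8: proportion p0 from the M7 beta plus an extra class at ω_s ≥ 1.
- Branch-site model A: classes 0 (ω0 everywhere), 1 (ω = 1
  everywhere), 2a and 2b in which foreground branches switch to
  ω2 ≥ 1; p2 is split between 2a and 2b in proportion p0 : p1.  The
  null model fixes ω2 = 1.  Foreground edges are marked with the
  `#1` newick label convention or programmatically.

**Likelihood.** Felsenstein pruning over all 61 states with per-node
rescaling; transition matrices come from a symmetric eigendecomposition
of the reversible generator.  Mixture models combine per-class
per-site log-likelihoods by logsumexp.  The engine is verified against
an independent oracle that sums explicitly over every assignment of
codon states to internal nodes (scipy's expm for the matrices), on
instances up to 4 taxa and 3 codons.

**Optimization.** L-BFGS-B on transformed parameters (log for rates,
logistic for proportions, 1 + exp(·) for ω bounded below by 1), with
multi-start (default 3 seeded starts; calibration studies use 1 —
replication across data sets substitutes for restarts), relative
function tolerance 1e-8 and a finite-difference step of 1e-6, which
matches the ~1e-9 relative noise of the rescaled pruning computation.
Branch lengths are taken from the input tree by default and can be
estimated jointly (`optimize_branch_lengths=True`).  Fits report a
convergence flag and flag ω estimates near the 999 upper bound; a
non-converged fit is returned flagged, never silently dropped.

**LRTs.** M0 vs M3 on 2K−2 df, M7 vs M8 on 2 df, branch-site null vs
alternative on 1 df.  For the branch-site test the true null is a
boundary mixture; referring 2ΔlnL to χ²(1) is the conservative common
practice and is what the type-I-error calibration exercises (observed
rejection near 0.03 at nominal 0.05).  2ΔlnL is floored at zero to
absorb optimizer noise.

**Posteriors.** NEB plugs MLEs into Bayes' rule over site classes.
BEB (M8 and branch-site A) averages the NEB posterior over a uniform
grid (10 points per dimension) on the mixture proportions and the
positive ω, weighting grid points by their data likelihood with the
remaining parameters held at their MLEs.  This captures the spirit of
empirical-Bayes integration without the full conjugate machinery; NEB
is the variant exercised by the property tests, and BEB/NEB agreement
is reported rather than asserted.  Stars mark posteriors above 0.95
(*) and 0.99 (**).  Site indices are alignment-relative (0-based).

## Ka/Ks and clock dating

The Ka/Ks estimator is Nei–Gojobori (1986): per-codon synonymous site
fractions (each position contributes the fraction of its three
possible changes that are synonymous; changes to stops count as
nonsynonymous opportunities), averaged over the two sequences; for
codons differing at 2–3 positions all substitution pathways are
enumerated, pathways through stop codons dropped, and the remainder
weighted equally (if every pathway is blocked, all changes count as
nonsynonymous).  Raw proportions are Jukes–Cantor corrected; a
proportion ≥ 3/4 raises a saturation error rather than returning a
number.  Codons with a gap or ambiguity in either row are excluded
pairwise.  The implementation (precomputed 61×61 pathway-count
tables) is checked to 1e-12 against a per-pair recursive enumeration.

The estimator choice is a package decision: published block-level mean
Ks values are reproduced in the dating arithmetic regardless of the
upstream estimator, and a config hook allows substituting another
estimator.

Block dating: anchors with Ks above the saturation cutoff (default
1.0) are discarded; the surviving anchors give mean ± sample sd; the
age is T = K̄s / (2λ) with λ = 6.1 × 10⁻⁹ /site/year (soybean) or
1.5 × 10⁻⁸ (*Arabidopsis*).  Published tables print integer Myr with
round-half-up, and `round_age` follows that convention (0.60 Ks →
49.18 → 49 Myr).  The shipped reference table of 86 soybean WRKY
segmental blocks reproduces its printed ages exactly under this rule.

## Duplication mapping

Tandem: family genes on one chromosome whose ordinal ranks differ by
at most `max_intervening` + 1 (default 10 intervening genes) chain
into maximal clusters; singletons are not reported.  Segmental: for a
focal/candidate pair, an anchor is a gene within ±`window_kb`
(default 100 kb, measured between gene midpoints) of the focal gene
whose best non-self protein match (Smith–Waterman, BLOSUM62, gap open
11 / extend 1, bit scores via the standard gapped Karlin–Altschul
constants λ=0.267, K=0.041; cutoff 50 bits) lies within the window of
the candidate.  `min_anchors` defaults to 3, the smallest anchor count
in the reference block table.  Matches are directional, as "best
non-self match" implies; reciprocity is not required.  Tandem and
segmental flags are independent, so a gene can be `both`; summary
percentages therefore describe potentially overlapping sets, and the
family census counts each gene once.

## Functional divergence

**Type I.** Per-site substitution counts in each cluster come from
Fitch parsimony on the cluster's induced subtree (gaps join any
state), verified against exhaustive minimum-change assignment on trees
up to 6 leaves.  The model: with probability 1−θ a site draws one
rate from Gamma(α, mean 1) shared by both clusters; with probability θ
the clusters draw independent rates.  Counts are Poisson with
cluster intensity d_c (expected substitutions per site at relative
rate 1); θ, α, d1, d2 are estimated jointly by L-BFGS-B with the gamma
discretized into 8 equal-probability categories.  The LRT against
θ = 0 uses χ²(1), conservative at the boundary — the null calibration
test confirms rejection ≤ 10% at nominal 5%.  The standard error
comes from the curvature of the profile log-likelihood in θ.

**Type II.** A deliberate count-category simplification of the full
formulation: sites where both clusters are internally conserved are
trinomial over {same residue, conservative difference, radical
difference}, where radical means crossing the shipped four-class
charge/polarity partition (nonpolar AVLIPMFWG / polar STCYNQ /
positive KRH / negative DE).  Under θ-II = 0 a difference occurs with
probability δ and is radical with the background probability ρ
computed from the partition; θ-II is the extra mass of the radical
category.  A single-class partition makes radical changes undefinable
and forces θ-II = 0, flagged.  Exact reproduction of θ-II values from
the full covarion-style treatment is out of scope and stated so here.

**Qk.**  Posterior that a site is in the divergent state, from the
fitted mixture; sites above the cutoff (default 0.8) are flagged.

## Synthetic data: what it emulates and what it does not

The generator supplies every input with truth tables: birth-death,
balanced and caterpillar trees (mean edge length 0.2
substitutions/codon by default, rescaled or exponential); codon
alignments under M0, discrete and branch-site regimes with true
per-site class labels; genome layouts; expression matrices; promoters.

- `evolve_pair_to_ks` calibrates the branch length so that the
  *expected NG86 estimate* equals the target Ks (solving E[Ks(t)] =
  target on the exact expected difference proportions), because the
  estimator, not the true synonymous divergence, is what downstream
  stages consume.  The mutation process is GY94 with ω = 0.05, so
  divergence is synonymous-biased; targets beyond the Jukes–Cantor
  domain raise a saturation error.
- Genome layouts place ~250–350-codon genes with 9–15 kb intergenic
  gaps, so a ±100 kb window spans roughly ±7 genes; planted tandem
  members diverge at Ks ≈ 0.05 per step, segmental copies at the
  requested target Ks; family genes carry a synthetic WRKY-style
  domain.  No introns' sequence content, transposable elements, or
  indel evolution are modeled; coordinates and truth tables are the
  realistic part, the background sequence is i.i.d.
- Expression: log-normal baselines (log-mean 1.5, tissue noise sd 0.5
  on the log scale) with one peak tissue per group label raised by
  `effect_size` noise-sd units; with seven tissues an effect of 5 sd
  makes the planted tissue the row maximum essentially always.
- Promoters: uniform background over a configurable alphabet with
  planted pattern copies at recorded non-overlapping offsets;
  narrowing the alphabet gives backgrounds provably free of a motif,
  which is how exact-count recovery is tested.

Passing these tests shows the machinery is correct on data generated
by the analysis models themselves; it does not certify performance on
real genomes, where alignment error, assembly gaps, rate variation
beyond the modeled forms, and annotation noise all intrude.

## Expression and promoter conventions

Z-scores use the population standard deviation; constant rows map to
zeros by convention.  Clustering is average linkage on 1 − Pearson
correlation; zero-variance genes are excluded with a warning (they
carry no correlation signal).  Breadth classes are exclusive and
exhaustive with the single-tissue-peak rule (z ≥ 1.5 at the row
maximum) taking precedence over constitutive, since a marked peak is
the more specific description; note that with fewer than four tissues
a z of 1.5 is unattainable and no gene can be a peak.  Element counts
are catalog-relative: the shipped catalog holds best-effort literal
motifs and is meant to be edited, not treated as a database.  Both
strands are scanned by default and a site is counted once even when
the pattern is palindromic (forward-coordinate site sets are merged).

## Pipeline

GFF3 is parsed with 1-based inclusive coordinates preserved; ordinal
indices are assigned per chromosome by start coordinate, not file
order; among multiple mRNAs the longest summed CDS is the
representative; malformed lines raise with their line number.  The
parser is hand-written because the error contract (line numbers) and
the representative-transcript rule are the whole job; sequence I/O
goes through Biopython.  Stage order is classify → dup → date →
selection → diverge → expression/promoters; re-running a configuration
reproduces byte-identical TSVs.  Percentages are always
round(100·count/total, 1).

## Problem sizes in the acceptance script

The script's stochastic studies use: M0 recovery 5 replicates × 500
codons × 8 taxa per true ω; branch-site type-I error 100 replicates at
100 codons × 6 taxa and power 20 replicates at 500 codons × 8 taxa
(the test suite runs the larger 200- and 50-replicate versions);
θ-I recovery 10 replicates × 200 sites with intensities d = 2
substitutions per site, a typical scale for domain-alignment counts;
oracle comparisons 50 sequence pairs and 100 likelihood draws.

## Known limitations

- BEB is a grid approximation; for borderline sites NEB and BEB can
  disagree, and both are reported.
- The branch-site and θ = 0 LRTs are conservative (boundary nulls
  referred to χ²(1)).
- NG86 underestimates divergence at high saturation by construction;
  anchors beyond Ks 1 are discarded rather than corrected.
- Subgroup assignment by nearest labeled reference replaces the
  phylogeny-plus-motif procedure used in the field; it is
  deterministic and testable but inherits the reference set's
  granularity, and ties break alphabetically.
- Whole-genome collinearity chaining (MCScanX-style) is out of scope;
  the anchor test is local to each gene pair's windows.
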