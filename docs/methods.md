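# Methods

`genomeflux` reconstructs how a bacterial lineage lost and gained genes
along its phylogeny and asks whether the lost genes were under weaker
selection than the retained ones.  The package was designed around the
evolution of *Prochlorococcus*, the marine cyanobacterium with the
smallest genome of any photosynthetic organism, and its sister group
*Synechococcus*; every stage also runs on synthetic data with known
ground truth so the whole chain is testable without genome downloads.

## Ortholog table construction

Input is a BLAST-style hit table (query, subject, bit score).  Hits
below a bit-score cutoff (default 40) are dropped.  For each query gene
we keep at most one subject per in-group genome — the highest-scoring
one — and only when that score strictly exceeds the query's best
out-group score; the strict inequality is a deliberately conservative
reading of "superior" and can be relaxed to `>=` via
`strict_superior=False`.  A candidate family (a query's top-hit list
plus the query) is **consistent** when every member genome's own list
reproduces exactly the same set.  Inconsistent candidates are grouped by
shared membership and resolved by majority rule: the gene most often
nominated per genome becomes the consensus ortholog, with ties broken by
total bit score and then lexicographic gene id.  Paralogs are accepted
only when the identical candidate set is nominated at least twice *and*
every paralog pair is supported by a within-genome hit.  Genes assigned
to no family are kept as singleton rows so that gene gains remain
countable.  The result is a families × genomes copy-number matrix
(0 = absent).

## Ancestral gene content

Two reconstructions share one modelling assumption: a single rate of
change between any two copy-number states.

* **Parsimony** (Sankoff with a uniform unit cost matrix over states
  {0, …, max observed copies}): bottom-up cost vectors give the minimal
  change count; a top-down pass recovers the full most-parsimonious
  (MPR) state set per node.
* **Mk maximum likelihood** (k states, equal rates, uniform stationary
  distribution): likelihood by pruning, marginal ancestral
  probabilities by the up/down (re-rooting) decomposition, and a single
  change rate fitted by bounded one-dimensional ML when not supplied.
  A node is assigned its best state only when its marginal
  log-likelihood beats the runner-up by ≥ 2.0 log units (the common
  support convention; configurable).

Unrooted trees are rooted on the outgroup leaf before reconstruction.
A family ambiguous at the root is kept in the last common ancestor only
if it has out-group evidence (a significant out-group hit), at the
smallest positive state in its MPR set — the smallest-positive choice is
our documented convention for multi-copy ambiguity.  Families ambiguous
at any internal node are excluded from downstream analyses.

Per-branch **flux** is the signed difference of assigned states between
consecutive nodes, copy-number weighted by default (a 2→0 drop counts
two losses; a per-event binary mode exists).  The **ancestor-derived
ortholog universe** contains root-present families found in every
reference (Synechococcus) genome; on each labeled ancestral branch it
splits into a Lost group (state drops to zero on that branch) and a
Retained group (still present in the descendant node), plus a terminal
partition (absent from all vs present in all extant target genomes).

## Codon models

Pairwise rates come in two flavours.  `ng86_pairwise` is the
transparent equal-weight counting method: synonymous/non-synonymous
site fractions per codon position (stop-codon changes excluded from
both numerator and denominator, so S + N = 3 per codon), differences
averaged over all minimal substitution paths avoiding stops, and a
Jukes–Cantor correction d = −¾ ln(1 − 4p/3).  `yn00_hky_pairwise`
weights site classification by the transition/transversion ratio κ,
tallies synonymous and non-synonymous differences split into
transitions and transversions, corrects each with the two-parameter
(transition/transversion-distinguishing) distance, and estimates κ from
fourfold-degenerate and non-degenerate positions, iterating until κ, dN
and dS move by < 1e-8 (flagged unconverged after 100 rounds).  We use
the two-parameter correction rather than a base-frequency-aware one;
at the divergences this package targets the difference is well inside
the counting noise, and at κ = 1 the estimator collapses exactly to the
NG86 correction.  Saturated distances are reported as missing, never
clamped, so family means cannot be silently biased.

The likelihood layer implements the Goldman–Yang codon model over the
61 sense codons of the bacterial genetic code (translation table 11):
q(i→j) is nonzero only for single-nucleotide changes, proportional to
π_j, multiplied by κ for transitions and by ω = dN/dS for
non-synonymous changes.  Each ω-class matrix is scaled to one expected
substitution per codon per unit time, so branch lengths are expected
substitutions per codon.  Equilibrium frequencies default to F3×4
(positional nucleotide frequencies, renormalised over sense codons).
Likelihoods use Felsenstein pruning with site-pattern compression,
per-node rescaling, and eigendecomposition of the reversible rate
matrix for fast matrix exponentials; gap codons are missing data
(partial likelihood one over all states).

`CodonBranchModel.fit` maximises over κ, one ω per branch class, and
all branch lengths by coordinate ascent: bounded scalar optimisation of
κ (bounds 0.1–50) and each ω (1e-6–20) in log space, then all branch
lengths in one sweep using per-edge one-dimensional spectral profiles
(the likelihood along a single branch is Σ_k c_k e^{λ_k t}, with
coefficients from the up/down partials), accepted only when the joint
log-likelihood improves and otherwise damped toward the previous
lengths.  Cycles repeat until the improvement is below 1e-6.  Several
fixed-seed starts (default 3) are warmed for two cycles and the best
continued, guarding against local optima while staying deterministic.
The parameter count NP is 1 (κ) + number of ω classes + number of
branch lengths, excluding the 9 F3×4 frequency parameters by default
(`count_freq_params=True` adds them); published NP conventions for
these models are not uniquely recoverable, so both conventions are
supported and ours is stated explicitly.

`compare_models` performs the likelihood-ratio test
2·(lnL_alt − lnL_null) against χ² with df = ΔNP for nested pairs
(α = 0.05 by default) and always reports AIC = 2k − 2 lnL with
ΔAIC = AIC(first model) − AIC(second); non-nested pairs are decided by
AIC alone.

## Codon usage and CAI

A reference set (ribosomal proteins in the intended use) defines
relative adaptedness w = codon fraction / max fraction among synonyms.
Zero-count sense codons receive a 0.5 pseudocount on the
frequency-per-1000 scale — scale-free, so the table is invariant to
duplicating the reference set; zero handling is poorly documented in
the classic tools, and this convention is configurable.  CAI is the
geometric mean of w over a gene's codons, excluding Met, Trp and stops
(single-codon families carry no information; an option includes them
for strict compatibility with tools that count every sense codon).

## Statistics

Two-sample comparisons default to the Welch t-test because the
Lost/Retained groups have very unequal sizes and variances; the pooled
classical test is available and both are emitted in the reports.  The
one-sided alternative is "Lost mean > Retained mean".  Mann–Whitney U
uses the exact null distribution for n1·n2 ≤ 400 (full enumeration of
group assignments when ties are present and the arrangement count is
manageable), otherwise the tie-corrected normal approximation.  OLS R²
is the squared Pearson correlation.  No multiple-testing correction is
applied, matching the analysis the reports mirror.

## Synthetic data

The generators emulate the study design, not any particular dataset:

* `study_topology()` returns the fixed 15-taxon tree (12
  *Prochlorococcus*, 2 *Synechococcus*, outgroup RCC307) with the nine
  ancestral branches labeled `anc1`–`anc9` and clade tags elsewhere;
  `branch_model_classes()` provides the branch-class maps of the whole
  nested model family (one-ratio through five-ratio and free-ratio).
* Gene content evolves by per-copy exponential loss and Poisson gains;
  gains always found new families, so parsimony reconstruction stays
  identifiable (re-gain of a lost family would be unidentifiable from
  presence/absence data).  Copy numbers above one arise only through an
  explicit duplication rate (default 0), keeping the default matrix
  essentially binary.  The full event ledger is returned as ground
  truth.  The birth–death parameterisation is a stand-in: the original
  analysis only reconstructs content and states no generative model.
* Codon alignments evolve site-independently with exact
  matrix-exponential transition probabilities per branch (not
  Gillespie), removing discretisation error from parameter-recovery
  tests.  The five-ratio simulation truth uses the published ω
  estimates (0.226, 0.001, 0.106, 0.118, 0.076) with κ = 2 and uniform
  codon frequencies.
* Hit tables draw in-group scores from a truncated normal above the
  cutoff (mean 120, sd 15) and out-group scores near 60, with a noise
  parameter that swaps top hits to create inconsistent sets.

What the synthetic data does **not** emulate: genomic islands and
horizontally transferred donor sequences, intergenic DNA, rate
variation among sites, alignment error, and annotation noise.  Passing
recovery tests therefore demonstrates correctness of the algorithms
under their own model assumptions, not robustness to real-data
violations of those assumptions.

## Problem sizes and numerical choices

The acceptance run uses 5000-codon alignments on the 15-taxon topology
for ω recovery (tolerance ±25%, ±0.005 absolute for the 0.001 class),
200-codon three-taxon alignments for the 200-replicate LRT null
calibration, 500 random trees (≤ 6 leaves, ≤ 3 states) for the
parsimony oracle sweep, and a 120-family end-to-end pipeline run; these
sizes give stable recovery statistics at desk scale.  Optimiser
tolerances: 1e-6 on lnL per cycle; 1e-4 (log scale) per scalar
parameter; branch lengths bounded in [1e-8, 50].  Quartile boundaries
in conserved-family selection are inclusive with linear-interpolation
quartiles (the wider, reproducible reading of "in the range"), and the
per-family synonymous-rate filter uses the mean over pairs.  Degenerate
inputs are handled explicitly: zero-variance t-tests return p = 1 for
equal means, saturated distances are missing, an alignment with a
single unique sequence flags ω unidentifiable, and an empty reference
set or a gene with no countable codons is an error.

## Known limitations

* The free-ratio degrees of freedom printed in the original comparison
  (df = 23) cannot be derived from first principles for a 15-taxon
  unrooted tree; the package reports its own NP convention instead of
  matching it.
* No site or branch-site models, no among-site rate variation, no
  codon-frequency ML (F61), no Dollo or asymmetric-cost parsimony, no
  gene-tree/species-tree reconciliation.
* Protein alignment and ML tree inference are external inputs: the
  package maps existing protein alignments to codons and offers a
  Poisson-distance neighbor-joining starting tree, nothing more.
* The YN00-style estimator's distance correction ignores base
  composition; strongly skewed compositions at high divergence would
  bias it relative to a full HKY correction.
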