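# Methods

This note documents the models, numerical choices and benchmark designs
behind `vitephylo`, and what the synthetic validation does and does not
show about real data.

## Synthetic data generator

**Species trees** are pure-birth (Yule) trees conditioned on the taxon
count and rescaled so the root sits at a requested age; node ages decrease
strictly toward the leaves and all root-to-tip path lengths are equal.
Tree shape plays no role in any correctness argument, so the simplest
ultrametric generator suffices.

**Gene families** start as one gene at the species root and evolve by a
linear birth–death process (duplication rate λ_d, loss rate λ_l per
lineage per unit time) inside the species tree, splitting at speciations.
Duplication nodes keep the label `dup`; a family is flagged single-copy
iff every taxon carries exactly one surviving gene. Fully extinct or
single-survivor families are redrawn so the requested family count is
always delivered.

**Codon sequences** evolve on the 61 sense codons of the standard code.
The rate matrix is the nucleotide GTR chain applied independently to the
three codon positions, restricted to sense codons (substitutions into
stops are disallowed). Because the unrestricted chain is reversible with
respect to the product measure over positions, the restriction stays
reversible with stationary distribution equal to the product measure
renormalised over sense codons — which is what the long-branch
stationarity test asserts. The matrix is normalised so one unit of branch
length is one expected nucleotide substitution per site; with no selection
(all changes equally likely) the synonymous divergence per synonymous site
equals the branch length, which calibrates the Ks benchmarks. Defaults:
exchangeabilities (1,2,1,1,2,1) (a mild transition bias), base frequencies
(0.30, 0.20, 0.20, 0.30); per-family lognormal rate jitter is optional.
Transition matrices come from the symmetrised eigendecomposition
S = D Q D⁻¹ with D = diag(√π), so P(t) = D⁻¹ U e^{Λt} Uᵀ D; this is exact
(checked against `scipy.linalg.expm` to 1e-15) and cheap to evaluate per
branch.

**Whole-genome duplication** is modelled by duplicating every gene lineage
alive at the WGD age, each extra copy retained with a stated probability
(non-retention emulates immediate post-WGD loss); truth records (copy
counts, single-copy flags, duplication labels) are updated accordingly.

**Degradation.** Transcripts lose a terminal fraction drawn uniformly on
[0, 2m] for missingness parameter m (or an exact per-gene override, used
to test the missing-data filter); paired-end reads (90 bp by default,
normal insert 250 ± 30) are sampled length-weighted with per-base
low-quality (2%) and N (0.2%) artifacts, plus 2% wholly degraded
"weak-signal" pairs (60% low-quality bases, 10% N) that the read screen is
meant to remove. Qualities are written Phred+33 by default (Phred+64
available). Indels are not simulated; the true alignment of a family is
its sequence set. Coverage is uniform — no expression-level modelling —
so the generator does not reproduce the coverage-driven missingness of
real non-normalised libraries, only its end effect (truncated
transcripts).

What passing tests show, and do not show: truth-recovery results
demonstrate that the pipeline's rules are implemented correctly and behave
as designed under the generative model (no indels, no alignment error, no
contamination, independent families). They do not certify recovery rates
on real transcriptomes, where assembly artifacts, isoforms and alignment
error add failure modes the generator deliberately omits.

## Preprocessing

Reads are discarded iff more than `max_low_quality_bases` (default 40)
bases have quality ≤ `quality_threshold` (default Q7 — the legacy
"ASCII ≤ 71 under Phred+64" rule expressed as a portable Phred value) or
more than 20% of bases are N; both bounds are strict, so exactly 40
low-quality bases or exactly 20% N is kept, and the filter is idempotent.
Contigs shorter than 150 bp are dropped (inclusive bound). Redundant
transcripts (alternative splice forms, duplicate contigs) are collapsed
greedily longest-first: a transcript is dropped when it matches an
already-kept representative at ≥95% identity over ≥80% of its own length
on either strand (edlib infix alignments of the full sequence and its
80% prefix/suffix). CDS extraction translates all six frames, splits
stop-free ORFs (≥20 aa) and locally aligns them to the reference
proteome; the best (ORF, reference) pair at or above `min_score` (default
60, BLOSUM62 units) defines the CDS as the full ORF, guaranteeing a
translation with no internal stop and length divisible by 3. Coordinates
are 0-based half-open internally, 1-based inclusive in written reports.

## Similarity and orthology

The in-house aligner is an exact affine-gap Smith–Waterman (BLOSUM62, gap
open 11, extend 1; a length-L gap costs 11 + L) verified against an
independent brute-force DP on random pairs. Self-scores are diagonal sums
(exact for positive-diagonal matrices). For the ~4,700-protein benchmark,
all-vs-all search runs through the external `blastp`
(`-seg no -comp_based_stats 0`, so raw scores share the plain BLOSUM62
scale), parsed from 13-column tabular output with raw score in the last
column; missing self-hits are supplemented with diagonal self-scores.
Raw cross-scores are symmetrised as the max of the two directions before
H-scores are computed, making the graph independent of query/subject
order.

Edges require aligned length strictly greater than 1/3 of both genes and
H-score strictly greater than 5. Clustering is average-linkage
agglomeration within connected components, with both constraints (merged
density > 1/3, linkage > 5) checked at every merge; pairs have one
theoretical edge and so always satisfy the density rule; ties break on the
lexicographically smallest (cluster-id, cluster-id) pair with a cluster's
id its sorted member tuple. A `density_mode="post"` switch instead merges
on linkage alone and dissolves density-failing families into singletons
afterwards. 1:1 selection keeps families with exactly one gene per
required taxon and none elsewhere.

## Supermatrix

Progressive alignment builds a guide tree from 3-mer distances
(1 − shared/min) by neighbor joining and merges profiles by global affine
DP; column–column scores are expected substitution scores between residue
frequency profiles (gap fractions contribute zero), so for two sequences
the procedure reduces exactly to pairwise global alignment, which the
oracle test checks. Back-translation expands each residue to its source
codon and each gap to `---`, enforcing the 3:1 width invariant and
erroring on any translation mismatch. The missing-data filter drops a
gene as soon as any taxon's row exceeds 50% missing (gaps plus wholly
absent rows; X/N count as present — the filter targets coverage, not
polymorphism); a `quantifier="mean"` variant applies the threshold to the
across-taxa mean instead. Concatenation is in lexicographic family-id
order with absent taxa gap-filled and a partition table for both matrices.

## Tree inference

Parsimony is Fitch counting (bitmask sets, gaps/ambiguities as wildcards),
verified against exhaustive internal-state enumeration on ≤6-taxon trees;
search is random stepwise addition plus NNI or SPR hill climbing, keeping
all equally-best topologies; "TBR" runs the SPR scan (at 15–16 taxa
full TBR adds essentially nothing).

Likelihood is GTR with optional discrete-gamma rates (category rates are
mean-normalised medians of equal-probability bins; rate-category
approximations of other flavours are treated as equivalent stand-ins for
among-site rate variation). Pruning uses pattern compression with
per-pattern scaling. Branch lengths are optimised edge by edge with
bounded Brent on the edge-likelihood function built from "below" and
"rest-of-tree" partials; partials are refreshed once per sweep, and a
sweep that lowers the joint likelihood is reverted, keeping the procedure
monotone. NNI candidates are screened exactly at current branch lengths by
local message substitution around each internal edge (one partial pass for
all 2(n−3) moves — verified to 1e-12 against direct evaluation); if no
move improves at stale lengths, the top three candidates are re-scored
with a branch-length sweep before the search stops. Branch lengths live in
[1e-8, 10]; default branch-optimisation tolerance is 1e-6 log-likelihood
units (relaxed to 1e-3 in jackknife replicate builds, where only the
topology matters). ML searches start from neighbor joining on
Jukes–Cantor distances.

Bootstrap resamples sites with replacement, implemented as multinomial
reweighting of site patterns (equivalent and much faster, since the
pattern set is unchanged); each replicate restarts from the full-data tree
with branch-length re-optimisation and NNI-only refinement — a fast
bootstrap in the rapid-bootstrap spirit. In the jackknife protocol's
support bookkeeping the replicates keep the accepted tree's branch lengths
(NNI-only), trading a little support accuracy for a large constant-factor
saving.

Robinson–Foulds distance is the symmetric difference of internal
bipartitions (canonicalised by the side not containing the first leaf);
topological identity means RF = 0.

## Benchmarks (study conditions)

* **Benchmark tree**: a fixed 15-taxon Yule draw (root age 1) chosen once
  for non-negligible internal edges (minimum ≈ 0.07 time units); sequence
  rate 0.3 substitutions/site per unit time, giving moderately diverged
  proteins.
* **Ortholog recovery**: 300 families, 150 codons each, duplication rate
  0.05 (≈25–30% multi-copy), loss 0 (losses are exercised separately in
  unit tests); scored as exact recovery of true single-copy families and
  absence of chimeric clusters.
* **Topology/bootstrap**: 30 (then 40) genes × 300 codons, concatenated
  GTR ML; 100 bootstrap replicates.
* **Gene jackknife**: an 80-gene pool of 50-codon genes with lognormal
  rate jitter (sd 0.3) on a different fixed Yule draw containing one
  genuinely short internal edge (≈0.004): short genes resolve that edge
  unreliably, so repeats-until-match falls and support rises as N grows —
  the phenomenon the protocol is designed to expose. Grid N = 10..60 step
  10, 30 accepted trees per N, 10 bootstrap replicates per accepted tree
  (replicate count is configurable), per-slot attempt cap 1,000 with
  censoring.
* **Long-branch quartet**: unrooted quartet with two long (0.7) non-sister
  branches and 0.1 elsewhere, Jukes–Cantor, 500 sites × 100 replicates — a
  Felsenstein-zone design where parsimony is inconsistent while likelihood
  has adequate finite-sample power.
* **Dating**: the benchmark topology rescaled to a 90.7 Ma root,
  clock rate 0.005 subst/site/Ma, 800 4D-style sites, 8,000 MCMC steps;
  20 replicates for CI coverage.
* **Ks**: two-sequence simulations at dS ∈ {0.1, 0.5, 1.0} with 3,333
  codons under the uniform-frequency, equal-exchangeability chain (where
  true dS equals branch length); WGD at age 0.75 with rate chosen so
  paralog divergence ≈ 1.0, 60 families × 400 codons, retention 0.8.

## Dating model

The sampler is a deliberate simplification: a strict clock (one rate for
all branches) with Metropolis–Hastings over internal node ages and the
rate. Likelihood is pruning on the 4-fold-degenerate-site matrix with
branch length = rate × duration; per-node partials are cached so an age
move recomputes only the changed node and its ancestors. Priors: normal
calibrations on chosen nodes (crown or stem attachment is explicit), a
diffuse lognormal on the rate (median 0.005 subst/site/Ma, log-sd 2), and
for uncalibrated ages a uniform prior over the order polytope *normalised
per root age* (density ∝ root⁻ᵏ for k free internal nodes) — this makes
the no-data posterior of a root-calibrated tree reproduce the calibration
prior exactly, which the prior-recovery test asserts. Proposals mix
uniform draws on each age's allowed interval with reflected windows
(both symmetric) and a multiplicative rate move with the log-scale
Jacobian; acceptance rates sit in ≈0.25–0.40 on the benchmark.

4-fold-degenerate extraction keeps a codon column's third position only
when every taxon's codon is ungapped, unambiguous and in a 4-fold
degenerate family (first two positions fix the amino acid) — the strict
intersection rule, which guarantees the site is synonymous over the whole
tree at the cost of discarding some usable sites.

## Ks estimation

Nei–Gojobori counting with pathway averaging: synonymous site fractions
per codon and pathway-averaged synonymous/nonsynonymous differences per
codon pair are precomputed as 61×61 tables. By default, mutations to stop
codons are excluded from site denominators and stop-passing pathways are
dropped from the average (the original formulation); a
`stop_mode="nonsynonymous"` switch reproduces the convention of some later
implementations (stops counted as nonsynonymous changes), which is the
mode cross-checked exactly against an independent implementation in the
tests. Unequal-length pairs are aligned at the protein level and
back-translated first. Ks applies the Jukes–Cantor correction and flags
saturation at Sd/S ≥ 3/4. With a gene tree available, the paralog
screen takes one pair per (duplication node, taxon); otherwise all
within-taxon pairs.

## Known limitations

* No indel simulation, so alignment quality is never stressed end to end;
  the aligner is validated against DP oracles instead.
* The clustering agglomerates within connected components with an O(k³)
  scan — fine for family-sized components, not for graphs with giant
  components.
* Strict-clock dating cannot capture rate variation among lineages; it is
  a calibration-propagation tool here, not a substitute for relaxed-clock
  inference.
* The NG86 Ks estimator inherits the Jukes–Cantor correction's bias under
  transition-biased evolution; the consistency benchmark therefore uses
  the unbiased (uniform) regime.
* Bayesian mixture-model tree inference and partitioned/per-gene models
  are out of scope; the amino-acid supermatrix is built but trees default
  to nucleotides.
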