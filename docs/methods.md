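# Methods

`cetevol` implements a codon-model pipeline for studying selection on a gene
family across a fixed mammalian phylogeny, with cetaceans as the focal
clade.  This note records the models, the numerical choices, and the
boundaries of what the packaged synthetic data can and cannot show.

## Codon substitution model

The engine is the Goldman–Yang (GY94) Markov model on the 61 sense codons of
the standard genetic code.  The instantaneous rate from codon *i* to *j* is

    q_ij = 0                    if i and j differ at >1 nucleotide
         = pi_j                 synonymous transversion
         = kappa * pi_j         synonymous transition
         = omega * pi_j         nonsynonymous transversion
         = omega * kappa * pi_j nonsynonymous transition

with equilibrium frequencies `pi` (F3x4 from the analyzed alignment by
default; F61 and equal frequencies selectable), transition/transversion
ratio `kappa` (estimated by ML — the model requires it even when the
scientific question is about `omega` alone), and `omega = dN/dS`.

**Branch-length scale.** The engine writes the generator as
`Q(omega) = A + omega * B`, where `A` (synonymous) and `B` (nonsynonymous)
are jointly scaled so that `A + B` has unit mean rate.  Branch lengths are
therefore expected substitutions per codon *under neutrality*
(`omega = 1`), the convention used by per-site rate methods (alpha/beta
parameterizations).  The practical consequence is that a site class with
`omega > 1` genuinely evolves faster than a purifying class — rescaling
each class to unit mean rate, the main alternative, erases exactly the rate
signal site-model LRTs rely on.  The standalone `build_rate_matrix`
function additionally offers the classic unit-mean-rate normalization
(one expected substitution per unit branch length at the given `omega`)
for single-ratio work.

Transition probabilities use the eigendecomposition of the
reversibility-symmetrized generator (`pi^{1/2} Q pi^{-1/2}` is symmetric
under detailed balance), with an `expm` fallback when `pi` has zero
entries.  Likelihoods use Felsenstein pruning over compressed site
patterns with per-node scaling; gaps and ambiguous codons are missing data
(partial likelihood 1), not deleted columns.  The model is reversible, so
the root is an arbitrary internal node.

## Model families and fitting

* one-ratio (M0): single `omega`;
* two-ratio: one `omega` per branch class (e.g. whale vs background);
* M1: site mixture `{omega0 <= 1, omega = 1}`;
* M2: M1 plus a class `omega2 >= 1` (positive selection);
* branch-site A and its null (`omega2 = 1`): the selected class applies
  only on designated foreground branches.

Parameters are optimized on transformed scales (log kappa in [0.02, 100],
log omega in [1e-4, 999], `omega0` capped at 1, `omega2` floored at 1,
stick-breaking logits in [-15, 15] for proportions) by bounded L-BFGS-B
with 3 restarts (first from a fixed sensible start, others jittered,
seed-controlled).  Per-class conditional likelihood vectors are memoized on
(kappa, omega-map), which makes finite-difference gradients cheap.  Because
numerical gradients bottom out on near-flat boundary ridges (`omega2 -> 1`
with `p2 -> 0`), fits with four or more free parameters get a short
Nelder–Mead polish; this is what keeps nested-model log-likelihood
orderings tight to ~1e-9.  Branch lengths are either supplied or estimated
jointly under the one-ratio model and then held fixed for all other
families, the usual stabilizing practice.

## Tests and corrections

LRT statistics `2 dL` are referred to chi-square (df 2 for M2 vs M1, df 1
for two-ratio vs one-ratio and branch-site).  Negative statistics within
1e-6 are clipped to zero; anything worse raises, since it means the
alternative optimization failed.  The branch-site decision follows the
fixed rule "supported iff `2 dL` strictly exceeds 3.84" (the 5% chi-square
critical value) rather than the mixture null.  FDR correction is
Benjamini–Hochberg, applied separately per test family.  The cross-gene
comparison of whale vs background `omega` uses Spearman's rho with average
ranks for ties.

## Ancestral reconstruction and the whale-lineage analysis

Reconstruction is marginal (per node and site): posterior proportional to
inside x outside partial likelihoods, with `pi` at the root; under a
mixture the per-class posteriors are averaged with NEB class-membership
weights; ties break toward the lowest codon index.  The reconstructed MRCA
of the cetacean clade can be appended to the extant whale alignment as an
extra tip ("extant + ancestral" analysis), after which site models and the
per-site scan run unchanged.  Treating an inferred ancestor as an observed
tip understates uncertainty; the pipeline reproduces this design because it
is the analysis under study, without endorsing it statistically.

Amino-acid replacement events are extracted per edge by translating parent
and child codons; synonymous changes emit nothing.  Third-codon-position
substitution counts per branch class (the near-neutral yardstick for the
damaging/neutral rate contrast) are taken from the same parent/child state
pairs.

## Per-site episodic scan

Each codon gets a synonymous rate `alpha` and a two-point nonsynonymous
mixture: `beta- <= alpha` with weight `p-`, and a free `beta+`.  Branch
assignments are independent, so pruning uses the branch-averaged propagator
`p- P_{beta-}(t) + (1-p-) P_{beta+}(t)` — exact under the model.  The null
constrains `beta+ <= alpha`; p-values use chi-square with 2 df, an upper
bound on significance (the asymptotic null is a mixture), so the scan is
conservative.  Per-branch empirical Bayes factors compare the site
likelihood with one branch clamped to `beta+` versus `beta-`.  The scan
reports every site and leaves significance filtering to the caller.

## Pseudogene scanning

Alignment-relative, against a chosen intact reference ORF: premature
in-frame stops are nonsense events (each carries the fraction of the
reference protein truncated, which is how C-terminal-loss cases are
reported); gap runs of non-triplet length shift the frame and the first
stop read in the shifted frame is attached to the causative indel; an exon
with >= 95% of its reference columns gapped is an exon loss, between 20%
and 95% is flagged ambiguous rather than decided (alignment truncation and
true deletion are not distinguishable from the alignment alone).  Clades in
which every member carries a lesion are "inactivated", annotated "shared"
when one (kind, position) lesion is common to all members and
"independent" otherwise.

## Promoter HRE scanning

The consensus hypoxia response element ACGTG is matched case-insensitively
on gap-stripped rows and mapped back to alignment columns; hits sharing at
least 3 of 5 columns are grouped as homologous; groups seen in >=
`min_species` species (default 3) are conserved.  A conserved group is
clade-specific when every species carrying it belongs to one clade.
Forward strand only by default — the counts mirror how such elements are
tabulated on promoter sequences — with reverse-complement scanning behind a
flag since HIF binding is strand-agnostic.

## Synthetic data

The generator evolves codons by exact transition-matrix sampling per branch
(only node states are observed, so no event-level simulation is needed) and
emits complete truth sets: internal-node states, per-site class
assignments, injected lesion lists, planted promoter-group counts.  The
default phylogeny is 12 taxa — 8 cetaceans (3 baleen, 5 toothed) and 4
outgroups — with branch lengths 0.01–0.1; the whale clade plus its stem is
branch class 1.  Site-class entries may carry an optional per-branch-class
rate multiplier, used to plant episodic bursts: a detectable burst must
carry several substitutions, so the packaged episodic fixture multiplies
two whale branches by 120 at `omega = 10` (roughly 6 expected events).
Promoter backgrounds are rejection-scrubbed of incidental ACGTG so planted
counts are exact.

Parameter-recovery suites use an 8-cetacean topology with all branch
lengths at 0.1, the top of the realistic range: at 500 codons this yields
roughly 150–500 substitutions per alignment, enough for a median
omega-error under 15%; the packaged whale subtree's own lengths (~0.2 total
tree length) would leave any estimator data-limited at desk scale.
Problem sizes elsewhere (300-codon simulations for site models, 100-codon
replicates for null calibration, 40-codon alignments for the episodic
fixture) were chosen as the smallest sizes at which the corresponding
effects are statistically resolvable.

**What passing synthetic tests does not show.** The generator has no indel
evolution (indels are injected), no rate variation beyond the modelled
classes, no alignment error, no base-composition heterogeneity across taxa,
and the fitting model is exactly the generating model.  Recovery results
therefore validate correctness of the machinery, not robustness to the
model violations real alignments carry.

## Known limitations

* NEB only (no Bayes empirical Bayes) for site identification.
* The branch-site 3.84 rule is less conservative than the mixture null at
  the boundary; it is reproduced deliberately.
* Exact reproduction of the published per-gene numbers requires the
  original GenBank/Ensembl alignments, which are not packaged; the
  published log-likelihoods and count tables are used as inputs where the
  arithmetic itself is under test.
* The damaging/neutral rate-contrast denominators for the non-focal branch
  class are only recoverable from published rates to rounding precision, so
  derived ratios are reported from whatever denominators are supplied.
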