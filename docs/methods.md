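# Methods

## Overview

`dracp` classifies peptides as anticancer (ACP) vs non-ACP from sequence
alone. The pipeline is: a 56-dimensional compositional descriptor, an
optional deep-belief-network (DBN) encoder, and a majority-vote ensemble of
101 relevance vector machines (RVMs), evaluated by stratified 10-fold
cross-validation. This note records the model assumptions, the parameters
that matter, the numerical choices, and what the synthetic benchmark does
and does not demonstrate.

## Feature space

The descriptor concatenates two simplex-valued blocks:

* **Composition (20-d).** count(r)/L per residue, residues ordered
  alphabetically by one-letter code. The order is a convention; nothing
  downstream depends on it beyond consistency.
* **Reduced dipeptide frequencies (36-d).** The 20 residues map onto six
  hydropathy groups of sizes 7, 6, 4, 1, 1, 1: strongly hydrophilic
  {R,D,E,N,Q,K,H}, strongly hydrophobic {L,I,A,V,M,F}, weakly hydropathic
  {S,T,Y,W}, proline, glycine, cysteine. S/T/Y/W sit between the strong
  classes on the hydropathy scale and are treated as a single weak group —
  the only reading under which the six groups exhaustively partition the
  alphabet. Every ordered pair of adjacent residues (overlapping windows,
  L−1 of them) is translated to an ordered group pair and counted; counts
  are normalised by L−1. Pair index = 6·(first group) + (second group).
  Overlapping windows are forced by the L−1 normaliser: only then does the
  block sum to exactly 1.

Both blocks sum to 1 for every valid sequence; this conservation is tested
property-style over random sequences. Sequences must be ≥ 2 residues over
the canonical 20-letter alphabet. Ambiguity codes (B,J,O,U,X,Z) are rejected
by default because neither the composition math nor the group mapping is
defined for them; a `drop-record` policy is available for permissive
ingestion.

## DBN encoder

Each restricted Boltzmann machine has energy E(v,h) = −aᵀv − bᵀh − vᵀWh,
giving factorised sigmoid conditionals in both directions. Training is
contrastive divergence (CD-1 by default): hidden states are sampled once,
the visible reconstruction and the subsequent hidden activation use
probabilities. The stack is trained greedily — each layer's hidden
activation probabilities become the next layer's data — and is used at
encode time purely as a deterministic feed-forward recognition network; the
top-level undirected model is never sampled and there is no generative or
supervised fine-tuning.

The 56-d features are frequencies in [0,1] and are fed as soft Bernoulli
probabilities rather than binarised: binarisation would destroy essentially
all compositional information at these magnitudes.

**Defaults and why.** Architecture 56→32→16; mini-batch 10; CD-1; learning
rate 0.5; 200 epochs. The learning rate is deliberately high by RBM
standards: compositional features have small amplitude (individual entries
are mostly < 0.2), so CD gradients are proportionally small, and with a
conventional rate (≈0.05) the weights never grow enough for the hidden
units to discriminate between inputs — the encoder collapses to a
near-constant map (maximum class-mean separation at the second layer
≈ 3·10⁻⁴) and the downstream classifier is at chance. At 0.5/200 epochs the
second-layer separation reaches ≈ 0.1 on the synthetic benchmark and
encodings carry the class signal. All of this is configurable
(`dbn:` block in the YAML config).

Exact quantities (joint probabilities, partition function, log-likelihood)
are available for RBMs with m+n ≤ 20 units by enumeration and refuse larger
models; they exist for testing and diagnostics, not for the pipeline path.

## RVM base learner

Regression formulation: t = Φw + ε over the basis
φ(x) = [1, K(x,x₁), …, K(x,x_N)] with Gaussian kernel
K(x,y) = exp(−‖x−y‖²/width²), width 6 by default. Each weight carries an
independent zero-mean Gaussian prior with precision αᵢ; hyperpriors on α
and the noise precision are taken flat, so evidence maximisation reduces to
the standard type-II maximum-likelihood iteration

    Σ = (σ⁻²ΦᵀΦ + diag(α))⁻¹,  μ = σ⁻²ΣΦᵀt,
    γᵢ = 1 − αᵢΣᵢᵢ,  αᵢ ← γᵢ/μᵢ²,  σ² ← ‖t−Φμ‖²/(N − Σγᵢ).

Binary classification is regression on {0,1} targets with the predictive
mean clipped to [0,1] and thresholded at 0.5 (ties go to the positive
class). This is the simplest self-consistent classification rule for the
regression likelihood; a Laplace-approximated logistic RVM was deliberately
not introduced.

**Numerical choices.** Basis functions with α > 10⁹ are pruned (pruning
only ever removes, so the retained-basis count is non-increasing — a tested
invariant); jitter 10⁻⁸ is added to the posterior precision diagonal before
the Cholesky solve; σ² is floored at 10⁻¹² so noise-free targets cannot
drive the system singular; convergence is max |Δ log α| < 10⁻³ over
surviving basis functions, capped at 100 iterations. α is initialised at
10⁻⁶ and σ² at max(0.1·var(t), 10⁻⁶). If every basis function would be
pruned, the single best-supported one is kept. Degenerate inputs (all
training rows identical) short-circuit to a bias-only model with a warning,
since every kernel column then duplicates the bias. The fit contains no
randomness: identical inputs give identical models.

Prediction follows the posterior predictive: mean μᵀφ(x\*), variance
σ²_MP + φ(x\*)ᵀΣφ(x\*), which is never below the noise floor.

## Ensemble

Each of the 101 rounds draws a feature subset and a sample subset (both
uniform, without replacement within the round; everything is returned to
the pool between rounds — this is not a bootstrap, and is documented as
such), fits one RVM on the slice, and records the feature indices for
prediction-time projection. Two named presets exist for the per-round
draw: `text` (5 features, 100 samples — the default) and `table3`
(10 features, 50 samples); both are shipped because the two are equally
defensible parameterisations of the same construction. A round whose sample
draw contains a single class is redrawn (bounded retries) — a one-class
regression target defines no decision boundary.

The member count must be odd, so a majority vote can never tie. The
continuous score is the fraction of members voting positive; thresholding
it at 0.5 reproduces the majority label exactly (a tested invariant). No
member weighting, out-of-bag estimation, or stacking.

## Evaluation protocol

Stratified k-fold (k = 10) with shuffling; stratification is the default
because realistic ACP benchmarks are imbalanced and small folds otherwise
produce unstable per-fold metrics. For each fold the DBN and the ensemble
are retrained from scratch on the training folds only; per-fold seeds are
derived from (master seed, fold index) and never from data, so trained
models are bitwise independent of held-out rows (tested by replacing test
rows with noise). AUC/AUPR are computed on the pooled held-out scores
rather than averaged per fold — one curve per run — with one ROC threshold
per distinct score (vote fractions tie heavily); AUC then equals the
normalised Mann-Whitney U statistic (tested against an independent
pair-counting oracle) and AUPR is the step-wise integral of precision over
recall. The ablation runs the raw-56-d arm on identical fold assignments.

## Synthetic benchmark

The generator plants the class signal exactly where the feature space
looks: each residue is drawn by sampling a hydropathy group from a
class-conditional 6-vector of group weights, then a residue uniformly
within the group. Defaults: 150 positives / 150 negatives; lengths uniform
on [12, 50] (the typical ACP length band); positives enriched in strongly
hydrophobic residues and cysteine (weights 0.15/0.45/0.15/0.05/0.05/0.15
over the six groups), emulating the amphipathic, often disulfide-stabilised
character of real ACPs; negatives hydrophilic-leaning
(0.40/0.20/0.25/0.05/0.05/0.05), emulating generic soluble peptides. These
weights are well separated by construction.

What passing on this benchmark shows: the pipeline recovers a planted
compositional signal end-to-end — featurisation is faithful, the encoder
preserves class information, the ensemble votes coherently, and the CV
harness leaks nothing. What it does not show: performance on real ACP data.
Real positives and negatives differ in positional motifs, length
distributions, charge clustering and homology structure that an i.i.d.
per-residue group-mixture model cannot express, and real class differences
are far subtler than the planted ones.

## Problem sizes

The shipped test suite and the acceptance script run the full pipeline at
300 synthetic peptides (10 folds, two ablation arms, 101 members per fold),
RBM exactness checks at ≤ 10 units, and RVM recovery at N = 100 (the
classic noise-free sinc experiment, held-out RMSE < 0.05 with < 50
relevance vectors). These sizes exercise every code path at full default
ensemble scale while keeping a complete run in minutes on one core.

## Known limitations

* The DBN is pretrained unsupervised only; no supervised fine-tuning means
  the encoder can discard class-relevant variance if it is not also
  high-variance in the input distribution.
* Classification-by-regression produces scores that are not calibrated
  probabilities; the vote fraction is a ranking score, not a posterior.
* The RVM uses the full O(N³) type-II iteration, appropriate for the
  ≤ a-few-hundred-sample regime this pipeline targets; the fast sequential
  marginal-likelihood algorithm is out of scope.
* Peptides shorter than 2 residues are rejected outright, and ambiguity
  codes are not imputed.
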