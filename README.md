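# dracp

Anticancer peptides (ACPs) are short peptides — mostly 12–50 residues, often
derived from antimicrobial peptides — that selectively kill tumour cells.
Because wet-lab screening is slow and expensive, sequence-based classifiers
are used to rank candidate peptides before synthesis. `dracp` is a complete,
reproducible implementation of one such pipeline for computational peptide
scientists: it classifies peptides as ACP vs non-ACP from the primary
sequence alone.

## The method

Three stages:

1. **Featurisation (56 dimensions).** For a peptide *s* of length *L*:
   the 20 amino-acid composition fractions count(*r*)/*L*, plus 36
   reduced-alphabet dipeptide frequencies *f*ᵢ = *n*ᵢ/(*L*−1), where the 20
   residues are first mapped to six hydropathy groups — strongly hydrophilic
   {R,D,E,N,Q,K,H}, strongly hydrophobic {L,I,A,V,M,F}, weakly hydropathic
   {S,T,Y,W}, and the singletons P, G, C — and *n*ᵢ counts each ordered pair
   of groups over the *L*−1 overlapping residue pairs.
2. **Encoding.** A deep belief network (a stack of restricted Boltzmann
   machines with energy *E*(v,h) = −aᵀv − bᵀh − vᵀWh, trained greedily
   layer-by-layer with contrastive divergence) compresses the 56-d
   descriptor to a low-dimensional representation, 56→32→16 by default.
3. **Classification.** A majority-vote ensemble of 101 relevance vector
   machines (sparse Bayesian kernel regression on {0,1} targets,
   K(x,y) = exp(−‖x−y‖²/width²), type-II maximum-likelihood updates of the
   per-weight precisions α with pruning). Each member is trained on a random
   subset of features and samples, random-forest style; the fraction of
   members voting "ACP" is the continuous score used for ROC/PR analysis.

Evaluation is stratified 10-fold cross-validation with pooled held-out
scores, plus a paired ablation that feeds the raw 56-d features to the
ensemble (no DBN) on identical folds.

A synthetic-data module generates labelled peptide sets with a planted
hydropathy-composition signal, so the entire pipeline can be developed and
tested without any external dataset.

## Worked example

```python
import numpy as np
from dracp import (PipelineConfig, SyntheticSpec, generate_synthetic,
                   cross_validate, derive_seed)

config = PipelineConfig(seed=1)
records = generate_synthetic(SyntheticSpec(seed=derive_seed(1, "synthetic")))
result = cross_validate(records, config)
print(f"mean fold accuracy: {result.mean_fold_accuracy:.4f}")
print(f"pooled AUC: {result.auc:.4f}  AUPR: {result.aupr:.4f}")
```

prints

```
mean fold accuracy: 0.9900
pooled AUC: 0.9998  AUPR: 0.9998
```

meaning that on 300 synthetic peptides (150 ACP-like, 150 background) the
full pipeline recovers the planted compositional signal almost perfectly:
99% of held-out peptides are labelled correctly, and the vote-fraction
score ranks essentially every positive above every negative.

The same pipeline is available from the shell:

```bash
dracp synth --seed 1 --out peptides.fasta --labels-out labels.tsv
dracp train --seed 1 --in peptides.fasta --labels labels.tsv --out model.json
dracp predict --bundle model.json --in peptides.fasta --out scores.tsv
dracp evaluate --seed 1 --in peptides.fasta --labels labels.tsv \
    --out report/ --ablation
```

`evaluate` writes per-fold metrics, ROC/PR point tables, and rendered
figures; `--ablation` adds the no-DBN arm to both plots. Every
hyperparameter can be set in a YAML config (`--config`); see
`docs/methods.md` for the full parameter list and defaults.

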