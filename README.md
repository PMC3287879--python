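# crocpred

Genetic risk prediction on case-control genotype data containing both
common and rare variants, built on the likelihood-ratio ROC framework:

- **FROC** (forward ROC): greedy forward selection of loci that maximize
  the AUC of likelihood-ratio-ordered risk scores, with 10-fold
  cross-validation to pick the model size.
- **CROC** (collapsing ROC): a multistage collapsing step that first merges
  rare variants (MAF < 0.01) into *pseudo-common* carrier-indicator
  variants, then runs the same forward selection over common and
  pseudo-common variants together.

It is aimed at statistical geneticists who want an interpretable,
genotype-group-based risk model from sequencing panels where much of the
signal sits in variants too rare to be selected individually.

## The model

For `K` selected loci, each observed multilocus genotype `G` (the tuple of
minor-allele counts) forms one risk group with likelihood ratio

    LR(G) = P(G | D) / P(G | D̄),

estimated from group frequencies in cases (`D`) and controls (`D̄`) with a
Haldane pseudocount guarding zero cells. Each individual is scored by the
LR of their genotype group; ranking by LR yields the ROC curve with the
largest attainable AUC for those loci. The AUC is the Mann-Whitney
statistic

    AUC = (1 / N_D N_D̄) Σ ψ(s_case, s_ctrl),   ψ = 1, ½, 0  for >, =, <.

Forward selection adds, at each step, the locus whose inclusion raises the
training AUC the most, and stops when no addition improves it; stratified
cross-validation then chooses the prefix of this path with the best mean
held-out AUC. Collapsing grows each pseudo-common variant greedily — seed
with the rare variant whose carrier indicator has the best AUC, keep
absorbing the rare variant that raises the collapsed indicator's AUC most,
stop when it no longer increases — and repeats until every rare variant is
in exactly one group, so risk-increasing and protective variants segregate
into different groups.

A synthetic-data module generates case-control panels shaped like the
GAW17 mini-exome benchmark (697 individuals, 209 cases, 133 common + 400
rare variants) under Hardy-Weinberg genotypes and a logistic liability,
with known causal truth for calibration and recovery experiments.

## Worked example

```python
from crocpred import (SimulationConfig, simulate_dataset, simulate_from_truth,
                      fit_croc, fit_froc, predict, compute_auc)

config = SimulationConfig(
    n_cases=150, n_controls=350, n_common=50, n_rare=150,
    causal_common=4, causal_common_maf_range=(0.25, 0.45), effect_common=1.1,
    causal_rare=100, causal_rare_maf_range=(0.0008, 0.0018), effect_rare=2.6,
    seed=11,
)
train = simulate_dataset(config)
test = simulate_from_truth(train.truth, 150, 350, seed=12)

croc = fit_croc(train, folds=10, seed=1)
froc = fit_froc(train, folds=10, seed=1)

print("CROC selected:", croc.loci)
for name, model in [("CROC", croc), ("FROC", froc)]:
    auc = compute_auc(predict(model, test), test.phenotype).auc
    print(f"{name}: {len(model.loci)} predictors, held-out AUC {auc:.3f}")
```

Output:

```
CROC selected: ['PCV2', 'C018', 'C040']
CROC: 3 predictors, held-out AUC 0.717
FROC: 4 predictors, held-out AUC 0.576
```

CROC's model combines one pseudo-common variant (`PCV2`, a group of
collapsed rare carriers) with two common loci and clearly outperforms
plain forward selection on the same data, whose model cannot exploit the
near-singleton causal rares.

## Command line

```
crocpred simulate --seed 1 --out-prefix data/sim
crocpred fit --genotypes data/sim.genotypes.tsv --phenotype data/sim.phenotype.tsv \
             --seed 1 --out model.json
crocpred predict --genotypes data/sim.genotypes.tsv --phenotype data/sim.phenotype.tsv \
             --model model.json --out scores.tsv
crocpred sweep --seed 1 --common-counts 0,25,50 --repeats 20 --out sweep.csv
```

`fit` accepts genotype TSV (samples × variants, values 0/1/2/NA) or
biallelic VCF plus a two-column phenotype TSV (1 = case, 0 = control);
`--no-collapse` switches to plain FROC. Models are versioned JSON documents
whose round trip is byte-identical and which carry the collapsing plan, so
they can score raw genotype files directly.

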