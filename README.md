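# zinbmm

Model-based clustering of raw scRNA-seq counts with a **penalized
zero-inflated negative binomial mixture model**: simultaneous cell
clustering, batch-effect adjustment, dropout modelling, and cluster-specific
gene selection — no normalization, imputation, or dimension reduction.

It is aimed at analysts who have a cells × genes count matrix with known
batch labels and want cluster assignments *and* an automatically selected
set of cluster-informative genes from a single generative model.

## Model

Counts follow a K-component mixture; in cluster *k*, gene *j* of cell *i* is

```
X_ij ~ pi_jk · δ0 + (1 − pi_jk) · NB(mu_ijk, phi_j),
log mu_ijk = beta_jk + B_i' gamma,
```

where `pi_jk` are cluster-specific dropout probabilities, `phi_j` gene
dispersions (Var = mu + mu²/phi), `B_i` one-hot batch membership, and
`gamma` shared batch coefficients. Parameters maximize the penalized
likelihood

```
l(theta) − lambda · Σ_jk | beta_jk − beta*_j |,
```

with `beta*_j` the gene's pre-estimated global (no-cluster) log-mean. The L1
pull shrinks uninformative genes' cluster means exactly onto `beta*_j`;
genes with at least one unshrunk `beta_jk` are the selected set. A
generalized EM fits the model; `lambda` (and optionally K) are chosen by
`BIC = −2 l + log(n) · d` with `d = (K−1) + J + S + 2KJ − q`, where `q`
counts means shrunk to the global value. See `docs/methods.md` for the full
algorithm and numerical choices.

The package also ships the study's synthetic-data generators (ZINB main
design with batch effects and calibrated dropout levels, cluster-independent
dropout, NB-mixture / zero-inflated-Poisson misspecification variants) and
the evaluation metrics (pair-counting ARI, selection Recall/Precision/F1).

## Worked example

```python
import numpy as np
from zinbmm import (SimulationConfig, simulate_main, select_lambda,
                    ari, selection_prf)

cfg = SimulationConfig(n=300, J=1000, K=3, dropout_level="medium",
                       gamma=(0.1, 0.4), Delta=1.2, seed=7)
truth = simulate_main(cfg)
print("dropout fraction: %.3f" % truth.dropout_indicators.mean())

lam, res, records = select_lambda(truth.X, truth.B, K=3)
sel = np.isin(truth.X.gene_ids, res.selected_genes)
recall, precision, f1 = selection_prf(truth.informative, sel)
print("selected lambda: %.2f" % lam)
print("ARI vs truth: %.3f" % ari(truth.labels, res.labels))
print("selected genes: %d   Recall %.2f  Precision %.2f  F1 %.2f"
      % (sel.sum(), recall, precision, f1))
print("batch contrast gamma_2 - gamma_1: %.3f (truth 0.3)"
      % (res.params.gamma[1] - res.params.gamma[0]))
```

prints

```
dropout fraction: 0.450
selected lambda: 20.00
ARI vs truth: 0.950
selected genes: 68   Recall 0.36  Precision 0.26  F1 0.31
batch contrast gamma_2 - gamma_1: 0.306 (truth 0.3)
```

The medium-dropout design drops 45% of all entries, yet the model recovers
the three clusters almost perfectly (ARI 0.95) and the batch contrast to
within 0.01. BIC lands at the sparse end of the penalty grid, keeping 68 of
1000 genes; under 45% dropout the mean-level evidence for individual
informative genes is weak, so selection recall is modest even when the
clustering itself is excellent — the low-dropout designs select far more
accurately.

The same pipeline from the shell:

```
zinbmm simulate --design main --dropout medium --gamma 0.1 0.4 --seed 7 --out sim/
zinbmm fit --counts sim/counts.csv --k 3 --out fit/        # BIC-selected lambda
zinbmm metrics --truth sim/truth_cells.csv --estimate fit/labels.csv
zinbmm benchmark --design nb-mixture --reps 10 --out bench/
```

`fit` writes `labels.csv`, `selected_genes.tsv`, `params.json`,
`bic_path.csv`, and a run manifest; `select-k` adds BIC-based selection of
the cluster number.

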