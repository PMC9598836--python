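# multipen

Multi-omics, multi-modal prognosis estimation with gene attention, for
survival cohorts such as low-grade glioma (LGG).

Deep models that predict patient prognosis from mRNA expression alone
ignore two informative data streams: miRNA expression (miRNAs repress
their target mRNAs) and clinical covariates. `multipen` implements a
prognosis-estimation network that fuses all three — each stream is
gated by its own squeeze-and-excitation **gene attention layer**, and
the attended features are scored by a **deep ensemble** of residual
sub-models. The attention gates double as an interpretable readout:
after training, each gene's mean gate value in (0, 1) ranks how much
the model relies on it, turning the fitted network into a
prognostic-biomarker screen.

The package is aimed at computational biologists who want to (a) train
and evaluate the network on their own expression + clinical + survival
tables, (b) rank candidate prognostic mRNAs/miRNAs by attention, and
(c) validate the whole pipeline against synthetic cohorts with known
planted signal before touching real data.

## The model in brief

For each data type with feature vector `x ∈ R^p`:

    A = σ(W_A2 · ReLU(W_A1 · x + b₁) + b₂) ∈ (0,1)^p,   x' = A ⊙ x

with bottleneck `q = 10`. The attended streams are concatenated
(mRNA ‖ miRNA ‖ clinical) and fed to `n = 10` sub-models; each is two
residual blocks (widths 16, 8; layer norm before each activation;
dropout; linear skip projection) and a tanh head, so scores lie in
(−1, 1) with higher = longer expected survival. The ensemble prediction
is the mean over sub-models:

    ŷ = (1/n) Σᵢ fᵢ(x')

Training minimizes a pairwise hinge ranking loss on uncensored pairs
(shorter-lived samples must score at least a margin below longer-lived
ones) with Adam. Evaluation uses the concordance index (C-index) under
repeated five-fold cross-validation with every preprocessing statistic
refitted on each training partition (no leakage). Preprocessing
follows the cohort rules: drop genes that are zero in more than half
the training samples or have any missing value, `log2(x+1)` transform,
one-hot clinical encoding with a reserved "unknown" slot.

See `docs/methods.md` for the full model description, the synthetic
cohort generator, and the design decisions.

## Worked example

Generate a synthetic cohort with a strong planted signal, evaluate the
pipeline under the study protocol, and rank genes by attention:

```bash
multipen simulate --seed 1 --out cohort/          # default: 125 samples, 1000 mRNA, 200 miRNA
multipen evaluate --data cohort/ --k 5 --repeats 2 --seed 1 --out results.json
multipen train --data cohort/ --seed 1 --out model.json
multipen rank-genes --model model.json --data cohort/ --top-k 50 --out ranks/
```

The same flow in Python, on the strong-signal preset (20 planted
prognostic mRNAs among 500, 10 planted miRNAs among 100):

```python
import multipen as mp

cohort = mp.generate_cohort(mp.CohortSpec.strong_signal(seed=0))
cfg = mp.ModelConfig.synthetic_cohort()          # lr 1e-3, 100 epochs, dropout 0.2
res = mp.run_experiment(cohort.mrna, cohort.mirna, cohort.clinical,
                        cohort.survival, cfg, k=5, repeats=4, seed=0)
print(f"{len(res.cindices)} experiments: mean C-index {res.mean:.4f} (sd {res.sd:.4f})")
```

which prints

```
20 experiments: mean C-index 0.9580 (sd 0.0193)
```

— each of the 20 cross-validation splits trains a fresh model on 100
samples and scores the 25 held-out samples; a mean C-index of 0.958
against a true-risk ceiling of ≈ 0.97 means the network recovers
nearly all of the planted prognostic ordering. On the matching null
preset (`CohortSpec.null_cohort()`, no signal anywhere) the same
protocol yields a mean C-index of ≈ 0.49 over 100 splits —
indistinguishable from chance, as it must be.

Attention ranking on a trained model:

```python
surv = cohort.survival.uncensored()
prep = mp.fit_preprocessor(cohort.mrna, cohort.mirna, cohort.clinical)
data = mp.transform_cohort(prep, cohort.mrna, cohort.mirna, cohort.clinical, surv.sample_ids)
model = mp.init_model(cfg, data["mrna"].shape[1], data["mirna"].shape[1],
                      data["clinical"].shape[1], seed=10)
model, _ = mp.train(model, data, surv.time, cfg)
report = mp.compute_gene_attention(model, data, data["feature_ids"])[0]
print(mp.rank_genes(report, 5).to_string(index=False))
```

Planted prognostic genes concentrate at the top of the ranking; on this
preset their mean attention exceeds the null genes' at permutation
p < 0.01 (10,000 label permutations).

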