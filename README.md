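# d2nnlm

Classifying cognitive impairment from speech transcripts with deep
n-gram language-space models.

Spontaneous speech changes early in Mild Cognitive Impairment (MCI) and
Alzheimer-type dementia, and picture-description transcripts (e.g. the
Cookie-Theft task) are a cheap, non-invasive window onto those changes.
This package implements, for researchers working with such corpora, a
classification pipeline built from *higher-order n-gram language spaces*:

1. **corpus** — read labeled transcripts (plain text or a minimal CHAT
   dialect), tokenize, and make seeded stratified train/test/validation
   splits;
2. **n-gram features** — build the order-n (n = 4, 5) vocabulary space
   and the sparse document–n-gram matrix X;
3. **SVD reduction** — factor X = U S Vᵀ and use the left-singular
   matrix U as a dense continuous representation (at most one feature
   per transcript in the corpus), projecting held-out transcripts via V;
4. **neural LM classifiers** — a hand-rolled feed-forward tanh/softmax
   network trained by minibatch SGD with L1/L2 regularization, in three
   flavours: **NNLM** (1 hidden layer, sparse input), **DNNLM** (3
   layers, sparse input), and **D2NNLM** (3 layers on the SVD-reduced
   higher-order features);
5. **baseline** — a class-conditional add-one-smoothed 4-gram LM
   classifier;
6. **evaluation** — percent error, base-2 perplexity
   (2^{−(1/N) Σ log₂ q(xᵢ)}), and leave-pair-out cross-validated (LPOCV)
   AUC: every (positive, control) pair is held out once, the model is
   refit on the rest, and pairwise score comparisons give the
   Wilcoxon–Mann–Whitney estimate A = (1/|P||N|) Σ c(p, n), with
   Hanley–McNeil variance, SE, 95% CI, and a z-test against A = 0.5;
7. **synthgen** — a seeded two-group Markov transcript generator with a
   divergence dial δ, emulating the tiny-corpus clinical regime for
   testing and power studies.

Estimators follow scikit-learn conventions (`fit`/`transform`/
`predict`, `get_params`, trailing-underscore attributes) and compose in
sklearn `Pipeline`s.

## Worked example

Generate a divergent synthetic corpus (19 impaired + 19 control
transcripts), train the grid-searched D2NNLM on 4-gram SVD features, and
evaluate:

```sh
d2nnlm simulate --delta 0.8 --seed 1 --out fixture
d2nnlm train --positive-dir fixture/positive --control-dir fixture/control \
    --model d2nnlm --hidden-units 5,11,19 --batch-sizes 9 \
    --seed 1 --out run
```

The run directory gains `manifest.json`, `split.json`, `grid.tsv`,
`model.zip`, and `report.json`; the report prints:

```json
{
 "percent_error": 0.0,
 "perplexity": 1.1414988544214242,
 ...
}
```

i.e. every held-out transcript was classified correctly, and the model
assigned the true class an average probability of 1/1.141 ≈ 0.88 per
transcript (perplexity 1 = perfect, 2 = uninformative for two classes).
The full leave-pair-out protocol:

```sh
d2nnlm lpocv --positive-dir fixture/positive --control-dir fixture/control \
    --model d2nnlm --hidden-units 11 --batch-sizes 9 --seed 1 --out lpocv_run
```

refits the pipeline 361 times (19 × 19 pairs) and reports the AUC with
its Hanley–McNeil standard deviation, SE, confidence interval and
p-value; on this corpus the groups separate perfectly (AUC = 1.0), while
re-running with `--delta 0` yields chance-level AUC ≈ 0.5. A
hidden-layer robustness sweep (`d2nnlm sweep --layers 2,3,4,5 ...`)
writes the percent-error and perplexity curves as TSV.

See `docs/methods.md` for the model, its defaults, and what the
synthetic generator does and does not emulate.

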