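# emdde — distribution-level differential expression for heterogeneous classes

`emdde` identifies genes whose expression **distributions** differ between two
classes of samples.  Conventional differential-expression tests (t-statistics
and their moderated variants) detect differences in *mean* expression and lose
essentially all power when a class is internally heterogeneous — for example
when resistant tumors split into subtypes with high and low expression of the
same gene, so the class mean matches the sensitive class while the shape of
the distribution does not.  `emdde` scores each gene with the Earth mover's
distance (EMD, the 1-D Wasserstein-1 distance) between the two classes'
expression histograms, which responds to *any* difference in distribution:
shifts, bimodality, minority subpopulations, variance changes.

## The statistic and its significance

For gene *g* with class samples *x* (class 1) and *y* (class 2), both classes
are histogrammed on one shared grid of bin centers p₁ < … < p_K with width *w*
(default 0.2 on log₂-scale data), giving unit-mass signatures
P = {(p_i, w_{p_i})} and Q = {(p_i, w_{q_i})}.  The score is the minimum total
mass-times-distance needed to transform P into Q,

    EMD(P, Q) = min_F Σ_ij f_ij |p_i − p_j|  /  Σ_ij f_ij ,

computed by the transportation linear program in `emd_lp` (the exact
reference) and, in the pipeline, by the equivalent closed form for shared
1-D grids,

    EMD(P, Q) = w · Σ_i | CDF_P(i) − CDF_Q(i) | .

Significance is permutation-based.  Class labels are permuted *n*‌_perm times
(default 1000); the per-gene **median** of permuted scores forms the null
vector M = (m₁…m_N).  For a descending threshold grid {T, T−Δ, …, Δ, 0}
(Δ = 0.001, T = round(max score) − 1),

    FDR_ji = Σ_k 1(m_k > t_i) / Σ_k 1(emd_k > t_i)   if emd_j ≥ t_i, else 1,

capped at 1, and q_j = min_i FDR_ji.  Comparator statistics are built in:
Kolmogorov–Smirnov (BH-adjusted asymptotic p-values), a Cramér–von-Mises-style
statistic on the binned CDFs (same permutation q-values), and a SAM-style
moderated t (pooled-permutation q-values).  A mixture-of-Gaussians simulator
with ground-truth flags and a ROC/confusion evaluator round out the package.

## Worked example

Simulate the hardest built-in benchmark — 16,000 genes × 240 samples (90 vs
150), 1,000 truly-DE genes whose class-1 values come from the mean-matched
bimodal mixture ½N(−4,9) + ½N(4,9) while class 2 is N(m,9), m ≈ 0 — then run
the EMD pipeline and score it against the ground truth:

```sh
emdde simulate --case 4 --seed 7 --out-prefix sim
emdde run --matrix sim_matrix.tsv --labels sim_labels.tsv \
          --out results.tsv --method emd --nperm 250 --seed 7
emdde evaluate --results results.tsv --truth sim_truth.tsv --out metrics.tsv
```

`results.tsv` (one row per gene; `#` lines carry the resolved configuration):

```
# emdde 0.1.0
# config {"binwidth": 0.2, "classes": ["class1", "class2"], ... "seed": 7}
gene    score       null_median  q_value  fold_change
g00000  0.10844444  0.14         1        1.014685
...
```

1,000 genes reach q < 0.05 — exactly the truly-DE set.  The three top-scoring
genes show why fold change is blind here: a score near 3 with fold changes on
*both* sides of 1 (0.23×, 0.59×, 2.5×) — the distributions differ massively
while class means barely move:

```
  gene    score  null_median  q_value  fold_change
g07320 2.822222     0.621333      0.0     0.594102
g05592 2.803111     0.612444      0.0     0.233156
g10899 2.803111     0.624444      0.0     2.529164
```

`metrics.tsv` confirms perfect recovery at the 5% FDR operating point, where a
moderated-t analysis of the same data has essentially zero sensitivity (run
`--method sam` to see it):

```
metric          value
tpr_at_0.05     1
fpr_at_0.05     0
auc             1
```

The library API mirrors the CLI: `emdde.run(matrix, labels, method="emd")`
takes a genes × samples `pandas.DataFrame` and a `ClassLabels` mapping and
returns the same table.  Preprocessing helpers for RNA-seq counts
(`filter_low_counts`, `log2_transform`, `quantile_normalize`) live in
`emdde.io`.

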