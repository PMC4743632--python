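# Methods

## Model and procedure

`emdde` treats each gene independently as a two-sample distribution-comparison
problem.  Given expression values x (class 1, n₁ samples) and y (class 2, n₂
samples), both samples are histogrammed on one shared, equally spaced grid and
the test statistic is the Earth mover's distance between the two unit-mass
histograms.  Because both signatures always carry total mass 1, the EMD
normalization denominator (total flow) is 1 and the score is expressed in the
data's own units (log₂ expression): a score of 2 means, loosely, "the average
unit of probability mass must move two log₂ units to turn one class's
distribution into the other's".

Two implementations coexist deliberately:

* `emd_lp` solves the transportation linear program with `scipy.optimize.linprog`
  (HiGHS).  It accepts arbitrary signatures, including unequal masses, and is
  the exact reference.
* `emd_1d` exploits that both signatures share one equally spaced grid:
  EMD = bin_width · Σᵢ |CDF_P(i) − CDF_Q(i)|.  The pipeline only ever uses this
  form; the LP path exists to prove it right (the suite checks agreement to
  1e-9 on 1,000+ random signature pairs).

Significance comes from whole-column label permutations (class sizes
preserved; one permutation shared by all genes per iteration).  The per-gene
median of the permuted scores forms the empirical null vector M, and q-values
are the running minimum of the capped count-ratio FDR over a descending
threshold grid (see README for the formula).  The FDR ratio is defined as 1
wherever its denominator is zero (no gene exceeds the threshold, so the
threshold carries no information).

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| `bin_width` | 0.2 | expression (log₂) | resolves log₂-scale data finely at n ≈ 100–250 samples per class; the EMD score is insensitive to moderate changes because mass that lands one bin over moves the CDF sum by at most one bin width |
| `n_perm` | 1000 | — | permutation count for the null; 250 already gives medians stable to a few percent and is used in the packaged studies |
| `delta` | 0.001 | score units | threshold-grid step; fine enough that the grid, not the step, limits q-value resolution |
| `t_max` | round(max score) − 1 | score units | top of the threshold grid, floored at `delta` so datasets whose maximum score is below 1 still get a grid |
| `pseudocount` | 1 | counts | log₂(v+1) transform for count data |
| count filter | < 20 in > 50% of samples | counts | drops genes too sparse for a meaningful histogram; both comparisons strict, the exactly-50% boundary is retained |

The preprocessing order for count data is filter → log₂ → quantile
normalization (each step optional and configurable); normalizing after the
log transform keeps the target distribution on the same scale as the scores.

## Comparator statistics

*KS*: D = sup |ECDF₁ − ECDF₂| with asymptotic p-values at effective size
round(n₁n₂/(n₁+n₂)) (the same formulation scipy's two-sample test uses), then
Benjamini–Hochberg adjustment across genes.

*CVM*: two forms, with different jobs.  The standalone `cvm_statistic` is the
pooled-observation rank form Σ (ECDF₁−ECDF₂)² over every pooled data point
(each occurrence contributes one term, with full tied counts at duplicated
values).  The *pipeline* form (`BinnedCvmStatistic`) evaluates the same sum
over the bins of the per-gene EMD grid.  The distinction matters: a pure rank
statistic has the identical permutation distribution for every gene of a
continuous dataset, so the per-gene null-median vector degenerates to a
near-constant and the FDR ratio can no longer separate ordinary null genes
from lucky ones — in practice it calls tens of percent of null genes
significant.  The binned form inherits each gene's value-dependent grid, the
null medians track per-gene dispersion, and the false-positive rate lands at
the few-percent level the method family reports.

*SAM-style t*: d = (mean₂ − mean₁)/(s + s₀), with s the pooled two-sample
standard error and the fudge factor s₀ the median of s over genes — a
simplification of SAM's coefficient-of-variation grid search that preserves
its behavior (low-variance genes are damped, everything else is an ordinary
t).  s₀ is frozen at its observed-data value before permutation so null and
observed scores share a denominator offset.  |d| is also (near-)rank-degenerate
under the median null, so SAM q-values use the pooled permutation null
instead: the FDR numerator is the *expected count* of permuted |d| above the
threshold (total count across permutations divided by the permutation
count), which is the procedure the original SAM software family uses.

## The simulator

`simulate.builtin_case(1..5)` emulates a two-class cohort of 16,000 genes ×
240 samples (90 vs 150) with 15,000 null genes i.i.d. N(0,1) in both classes
and 1,000 DE genes: class 2 ~ N(m, 9) with a per-gene mean m ~ N(0, 0.04),
class 1 a case-specific Gaussian mixture with component variance 9, from a
single shifted component N(2,9) (case 1) through mean-matched bimodal and
trimodal mixtures (cases 4–5; see the module docstring for the full table).
Cases 2–5 form a representative heterogeneity ladder chosen by this package;
they are not transcriptions of any published parameter table.  Component
membership is multinomial per sample, so realized proportions fluctuate.

What the simulator does **not** emulate: gene–gene correlation, heavy-tailed
or skewed technical noise, count overdispersion (no negative-binomial RNA-seq
layer), batch structure, or missingness.  Passing the packaged studies
therefore demonstrates correctness of the statistics and calibration
machinery under clean Gaussian mixtures, not end-to-end performance on any
particular real cohort.

## Numerical choices and degenerate inputs

* Histogram bins are half-open [center−w/2, center+w/2) with the final bin
  closed, so every value in the covered range is counted exactly once; bin
  assignment tolerates ~1e-9 relative float error at the edges.
* A constant gene yields a single-bin grid and score 0 in every permutation.
* Quantile normalization resolves within-column ties by assigning the mean
  target value over the tied rank span (deterministic and symmetric).
* The threshold grid steps from T by exact multiples of Δ and appends 0 if T
  is not a multiple of Δ.
* Random streams: one master seed; the simulator, permutation loop and
  bootstrap each draw from independently spawned substreams, so changing
  `n_perm` does not perturb bootstrap resampling.
* Permutation scores are held in one (n_perm × N) array while the exact
  per-gene median is taken; only the medians (and, for the pooled null, the
  sorted flat scores) are kept afterwards.

## Known limitations

* The method needs a moderate number of samples per class (≳ 30) to histogram
  a distribution at all; the sample-size sweep in the test suite shows power
  dropping sharply below that, and `sample_size_sweep` flags such datasets.
* The median-of-permutations null is conservative at strict thresholds (on
  all-null data essentially nothing reaches q < 0.05) but can be
  *anti*-conservative in the mid-range: since an exchangeable null gene
  exceeds its own permutation median half the time, q-values between roughly
  0.05 and 0.2 may admit many more false positives than the nominal level
  when a large fraction of genes is truly DE.  The q < 0.05 operating point
  is the one with published calibration behavior.
* A significant score says the distributions differ, not how; the sign of the
  accompanying fold change (class 2 over class 1) only describes mean shift.
* Only two-class designs are supported, by construction of the statistic.
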