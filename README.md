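# commsize

How many individuals per sample does multivariate community analysis
actually need?

Community ecologists routinely ordinate taxon-by-sample abundance
matrices (NMDS on Bray-Curtis dissimilarities) to read gradients and
groupings out of their data.  Counting and identifying individuals is
often the most expensive part of such a study, so over-sampling wastes
real resources — but under-sampling risks a misleading ordination.
`commsize` quantifies that trade-off directly: it re-collects each
sample *in silico* at a fraction of its original size (drawing
individuals without replacement) and measures how well the reduced
dataset reproduces the complete dataset's multivariate structure,
locating the sample size below which results degrade.

It is aimed at ecologists and palaeoecologists planning collection
effort, and at anyone deciding whether legacy datasets with modest
counts are usable for multivariate re-analysis.

## What it computes

For a complete community matrix **X** and a subsampled copy **X′**:

- **Mantel R** — the Pearson correlation between the off-diagonal
  entries of the Bray-Curtis matrices D(X) and D(X′), with a
  permutation test that jointly relabels rows and columns of one
  matrix; R → 1 as the subsample preserves the pairwise dissimilarity
  structure.
- **PROTEST concordance** — both matrices are ordinated by 2-D
  non-metric multidimensional scaling (Kruskal stress-1, monotone
  regression, multiple starts); the two configurations are aligned by
  Procrustes superimposition (translation, rotation, reflection,
  dilation) and summarised as a concordance in [0, 1] (1 − normalised
  residual sum of squares), with a permutation test over sample
  relabellings.

Repeating this for many replicate subsamples at proportions 50%, 25%,
10%, 5% and 2.5% yields mean ± SD goodness-of-fit curves against median
subsample size (the median across samples of individuals per sample).
A two-segment piecewise-linear fit on log₁₀ size estimates the
**breakpoint**: the sample size where the plateau ends and fidelity
starts dropping.

Two synthetic-data generators supply controlled test beds: Gaussian
response curves along an environmental gradient (random optimum,
tolerance and peak abundance per taxon, sampled at random positions)
and fixed-total "selected abundance" datasets (200 individuals per
sample, geometric rank-abundance series tuned to a target Pielou
evenness, structured into distinct communities).

## Worked example

```python
import commsize as cs

# a 20-sample x 20-taxon community simulated along a 100-unit gradient
spec = cs.random_gradient_spec(n_samples=20, n_taxa=20, gradient_length=100, seed=7)
matrix = cs.simulate_gradient_dataset(spec)
summary = cs.summarize(matrix)
print(f"{matrix.n_samples} samples x {matrix.n_taxa} taxa, "
      f"median sample size {summary.median_sample_size:.0f}, "
      f"mean evenness {summary.mean_evenness:.2f}")

scheme = cs.SubsampleScheme(n_replicates=50, seed=1)
settings = cs.ExperimentSettings(n_permutations=199, seed=2)
records = cs.run_experiment({"demo": matrix}, scheme, settings)
curves = cs.aggregate(cs.records_to_frame(records))
print(curves[["proportion", "median_size_mean", "mantel_mean", "protest_mean"]]
      .round(3).to_string(index=False))
```

prints

```
20 samples x 20 taxa, median sample size 336, mean evenness 0.85
 proportion  median_size_mean  mantel_mean  protest_mean
      0.025               8.5        0.781         0.525
      0.050              17.0        0.888         0.655
      0.100              33.5        0.952         0.775
      0.250              84.0        0.985         0.835
      0.500             168.5        0.995         0.894
```

Read bottom-up: halving the collection effort (median 168 individuals)
leaves both statistics essentially at 1 — the ordination and the
dissimilarity structure are unchanged.  Fidelity stays high down to a
few tens of individuals per sample and only collapses at the 2.5%
proportion (≈ 8 individuals), where the Mantel R of 0.78 and
concordance of 0.53 say the subsample no longer tells the same story.
Across many datasets, `cs.detect_threshold(curves, "mantel")` places
the breakpoint of the pooled curve.

A command-line interface mirrors the library
(`commsize simulate / analyze / threshold / group-test / summary`).

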