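# Methods

## The question

How many individual organisms must one count per sample before a
multivariate, abundance-based community analysis stops improving?  A
"sample" here is one row of a taxon-by-sample count matrix; its "sample
size" is the total number of individuals counted in that row, and the
dataset-level summary used throughout is the **median sample size**
across rows.  The package answers the question experimentally: take a
complete dataset, repeatedly re-collect each sample at a fixed fraction
of its original size by drawing individuals without replacement, and
measure how faithfully each reduced dataset reproduces the complete
dataset's multivariate structure.  Plotting that fidelity against the
median subsample size produces a curve that is flat (a plateau) down to
some size and then falls off; the breakpoint of that curve is the
smallest adequate sample size.

## The comparison statistics

Two complementary statistics compare a subsampled matrix with its
complete parent, both computed on Bray-Curtis dissimilarities
d(x, y) = Σ|xᵢ − yᵢ| / Σ(xᵢ + yᵢ) over raw counts (no standardisation
or transformation is applied anywhere in the pipeline):

**Mantel R** — the Pearson correlation between the vectorised upper
off-diagonal entries of the two dissimilarity matrices.  Its null
distribution comes from jointly relabelling the rows and columns of the
second matrix; because such a relabelling permutes the multiset of
off-diagonal entries, the implementation re-indexes a standardised
condensed vector instead of rebuilding matrices, which is exact and
fast.  The one-tailed p-value uses the observed-included convention
p = (#{r_perm ≥ r_obs} + 1)/(B + 1), so p > 0 always.

**PROTEST concordance** — the two matrices are ordinated by 2-D
non-metric multidimensional scaling (below), the two configurations are
superimposed by symmetric Procrustes analysis (centring, unit-norm
scaling of both, optimal orthogonal map with reflections allowed from
the SVD of the cross-product, optimal dilation), and concordance is
defined as 1 minus the normalised residual sum of squares — equal to
the squared trace correlation, lying in [0, 1] with 1 meaning the
ordinations are identical up to translation, rotation, reflection and
dilation.  Note the classical Procrustes m² is a residual (smaller =
better); this package reports the complementary orientation, which is
the scale on which plateau values like 0.79 are quoted, and also exposes
the raw residual.  The PROTEST null permutes the sample order of the
second configuration and re-runs the superimposition; p-values use the
same +1 convention.  Symmetric scaling makes the statistic symmetric in
its arguments; an asymmetric best-fit mode exists behind a flag.

## NMDS

Kruskal-style non-metric MDS: minimise stress-1,
√(Σ(d − d̂)²/Σd²), where d are configuration distances and d̂ the
least-squares non-decreasing (isotonic) fit of d against the
dissimilarity ranks.  Implementation choices, none of which are
externally prescribed:

- isotonic regression by pool-adjacent-violators; tied dissimilarities
  are block-averaged before fitting, so fitted values are constant
  within a tie block;
- optimisation by iterative majorisation (SMACOF with monotone
  regression): at each sweep the disparities are rescaled to the
  current distance sum of squares and a Guttman transform updates the
  configuration; convergence when the relative stress improvement drops
  below `tol`;
- multiple starts: one deterministic classical-scaling (Torgerson)
  start plus `n_starts` random Gaussian starts (default 20 for
  standalone use; the pipeline uses 1, see below); lowest stress wins;
- exact-zero dissimilarities between distinct samples are jittered by
  1e-12 before ranking; an all-coincident configuration has stress 1 by
  convention;
- the returned configuration is centred, rotated to principal axes, and
  sign-fixed, so runs are bit-reproducible given a seed.

Inside the pipeline, both the complete dataset's ordination and every
subsample ordination use the *same* settings and the same fixed seed
(`NmdsSettings`: 2 dimensions, classical start + 1 random restart,
max 150 sweeps, tol 1e-5).  Using an identical deterministic procedure
on both sides means a proportion-1.0 control subsample reproduces the
complete ordination bit-for-bit and scores concordance exactly 1 — the
natural self-consistency control — and keeps the experiment (tens of
thousands of ordinations) tractable.  On probe datasets the extra
random restarts of the standalone default changed stress only in the
fourth decimal.

## Subsampling

Reducing a sample to k individuals is a multivariate hypergeometric
draw (uniform without replacement from the pooled individuals, labelled
by taxon), delegated to numpy's generator.  The per-row target is
k = max(1, round(p·N)) with round-half-up: the floor of one individual
keeps every row defined for Bray-Curtis at the smallest proportion
(2.5% of a 20-individual sample would otherwise be empty).  Rows are
subsampled independently; taxon columns that end up all-zero are
dropped; rows are never dropped, preserving the pairing between
complete and subsampled matrices.  Default scheme: proportions 50%,
25%, 10%, 5%, 2.5% with 1000 replicates each (5000 matrices per
dataset); the desk-scale experiment below uses 100 replicates.

## Synthetic data

**Gradient-simulated datasets.**  Each taxon's expected abundance along
a one-dimensional environmental gradient of length G is a Gaussian
response curve A·exp(−(g−μ)²/2σ²): μ is the taxon's environmental
optimum, σ its tolerance, A its peak abundance.  Parameters are drawn
per taxon: μ ~ U(1, G), σ ~ U(0.05G, 0.25G), A ~ U(1, 100).  The σ and
A ranges are this package's choice (the original description leaves
them unstated); they were fixed once so that a 20-sample × 20-taxon,
G = 100 design yields median sample sizes in the hundreds of
individuals — the regime the published design table reports — and are
fully exposed in `ParamRanges`.  Samples are taken at distinct random
integer positions in [1, G] (or i.i.d. uniform reals when a design asks
for more samples than integer positions exist, e.g. 200 samples on a
100-unit gradient); each count is the curve height rounded half-up to
an integer, since without-replacement subsampling needs integer units.
A position draw that leaves a sample empty is rejected and redrawn so
every dataset is analysable.  The 22-row design table (n_samples ×
n_taxa × G) is built in; `desk_scale_design` caps G at 100 — a longer
gradient only rescales the position and tolerance units, so the G =
1000/5000 rows are statistically equivalent at G = 100.

**Selected-abundance datasets.**  Every sample holds exactly 200
individuals spread over a fixed richness S as a geometric rank-abundance
series wᵣ ∝ kʳ.  The decay k is found by bisection so that the
*integerised* sample (every taxon ≥ 1 individual, remainder allocated
by largest remainder) hits a target Pielou evenness J = H′/ln S: 0.58
for the low class, 0.79 for the high class, alternating per sample for
mixed datasets.  Samples represent distinct communities in two
dichotomous groups: the second half of the samples shifts the whole
composition by half the taxon pool, and within a group the dominant
rank stays on its taxon while subordinate ranks rotate by
`structure_id` positions per sample.  This gives each dataset clear
between-group and graded within-group compositional differences — the
kind of structure a field study deliberately samples across.  (A naive
all-ranks rotation was tried first and discarded: with steep dominance
it makes every pairwise distance nearly identical, leaving no
multivariate structure for any statistic to recover.)  The standard
suite is a full factorial of evenness class × richness {10, 20, 50} ×
samples {5, 10} × structure {1..4}, 24 datasets per class.

**What the generators do not emulate:** sampling noise around the
response curves (counts are deterministic given positions), species
interactions, skewed or multimodal response shapes, spatial
autocorrelation, and observation error.  Passing tests therefore show
that the analysis pipeline behaves correctly on idealised communities
with known structure; they do not certify any particular field system,
where patchiness or unmodelled noise could raise the required sample
size.

## Threshold detection

The published analyses read the breakpoint off the figures by eye; here
it is formalised: pool the per-dataset-by-proportion mean statistics,
regress them on log₁₀(median size) with a continuous two-segment
piecewise-linear model, grid-searching the breakpoint over the observed
sizes, and report the back-transformed breakpoint plus the mean fitted
value of the right (plateau) segment.  If the right segment's slope
exceeds 0.1 per decade in magnitude the fit is flagged "no plateau"; if
the two-segment fit improves on a single line by less than 5% relative
SSE (or the line already fits exactly) the curve is flagged
breakpoint-free and the plateau is the overall mean.  Both tolerances
are heuristics for flagging, not inference.

## Group tests

Differences in goodness-of-fit between dataset groups (evenness class,
sample count, richness) at a fixed subsample size use Welch's
two-sample t-test for two groups, and one-way ANOVA followed by
Bonferroni-corrected pairwise Welch tests for three or more.  The
"size 50" grouping corresponds to the 25% proportion of the
200-individual selected datasets.

## Experiment scales and reproducibility

The desk-scale experiment regenerated by the tests and the acceptance
script uses one dataset per design row (22 datasets), five proportions,
100 replicates per proportion, and 199 permutations per test — chosen
as the package's standard desk configuration; the full published-scale
protocol (10 replicates per row, 1000 subsample replicates, 999
permutations) is reachable by changing three arguments.  Every source
of randomness derives from explicit seeds via seed sequences keyed by
(dataset, proportion, replicate), so single replicates are reproducible
in isolation and execution order never changes results.  Failed
replicates (e.g. degenerate matrices) are recorded with flags and
excluded from aggregation, with counts reported.

## Known limitations

- The Raup-Crick variant (used only in the distance-measure parity
  check) is the simplest null-model form — fixed per-sample richness,
  equiprobable taxa, Monte-Carlo estimate of P(shared ≥ observed);
  published variants differ and only qualitative parity is asserted.
- Dataset-level "mean evenness" averages per-sample J over samples
  where J is defined (S ≥ 2); computing J on pooled counts is a
  defensible alternative the package does not use.
- NMDS is restricted to two dimensions, matching the analysis the
  package reproduces; no PCoA/CCA alternatives.
- The breakpoint model assumes one plateau and one decline; curves with
  richer shapes will be flagged rather than fit.
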