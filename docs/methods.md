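# Methods

## Problem and approach

Small multivariate biomedical datasets (dozens to a few hundred cases)
often carry clear structure — dense "clouds" of similar cases separated by
"voids" of empty data space — without any tractable parametric model of how
the data arose. `esomgen` augments such datasets model-free: it learns the
cloud/void structure with an emergent self-organizing map (ESOM), derives a
single distance scale that separates within-cloud from between-cloud
distances, and generates new points around each original case at distances
that respect that scale. The generated data should be statistically
indistinguishable from the originals (a tuned discriminator performs at
chance) while the original class structure remains perfectly learnable.

## ESOM training

A rectangular grid of `l x c` neurons (default 50 x 80 = 4000, toroidal)
carries one weight vector per neuron in data space. Weights are
initialized uniformly within the per-variable data ranges. Online
training presents cases in a per-epoch shuffled order; for each case the
best-matching unit (BMU, the nearest weight vector) and its grid
neighbours move toward the case:

    w <- w + alpha(t) * exp(-g^2 / (2 rho(t)^2)) * (x - w)

with `g` the (toroidal) Euclidean grid distance to the BMU. Both the
learning rate `alpha` (0.5 -> 0.05) and the neighbourhood radius `rho`
(half the smaller grid extent -> 1) decay linearly over the epochs
(default 25). Kernel shape and cooling schedule are known to be
second-order concerns for emergent maps, so these conventional choices are
exposed as parameters rather than fixed. BMU ties are broken toward the
lowest neuron index to keep projection deterministic.

The grid default follows the usual emergent-map guidance: thousands of
neurons (so the map projects rather than clusters), an edge ratio around
1.2–1.6, and a floor of roughly 600 neurons.

By default the pipeline z-scores each variable before training. The BMU
assignment is therefore made in standardized space, but the Gabriel-graph
edge lengths below are measured on the *de-standardized* weight vectors,
so the estimated radius — and all generation — lives in the original data
units. With commensurate variables (e.g. the built-in benchmarks) the two
spaces differ only by a near-uniform scale.

## U-matrix, P-matrix, radius diagnostics

* **U-height** of a neuron: mean data-space distance between its weight and
  the weights of its 8 Moore neighbours (wrapping on a toroid). The cell
  itself would contribute a guaranteed zero and is excluded; including it
  would only rescale the field. Ridges of large U-heights mark voids.
* **P-height**: number of data points in the closed hypersphere of radius
  `r` around the neuron's weight — a density field over the map.
* **Diagnostics**: a radius is flagged `too_small` when more than half the
  P-heights are zero (fragmented density estimate), and `too_large` when,
  among the densest quartile of neurons, the Spearman correlation between
  U- and P-heights exceeds 0.5 — high density coinciding with large
  distances means the hyperspheres reach across cloud boundaries
  (crosstalk). The 0.5/0.5 thresholds are configuration, chosen to
  separate the qualitative failure modes sharply on the built-in
  benchmarks, not doctrine.

## Density radius from the Gabriel graph

The distinct BMU weight vectors form a point set whose Gabriel graph
(edge `(a,b)` iff the closed ball on diameter `ab` contains no third
point; a subgraph of the Delaunay triangulation) connects each cloud
internally with short edges and bridges clouds with long ones. The edge
lengths — the "abstract U-matrix heights" — are therefore bimodal for
structured data. Duplicate BMU weights are collapsed first so zero-length
edges cannot corrupt the small-distance mode.

A two-component univariate Gaussian mixture is fitted to the edge lengths
by expectation–maximization: 10 restarts (quartile-based initialization
first, random pairs of sample points after), tolerance 1e-9 on the
log-likelihood, at most 500 iterations, variance floor 1e-12. The Bayes
decision boundary `t_AU` between the small- and large-distance components
solves `w1 N(t; mu1, s1) = w2 N(t; mu2, s2)`; the package brackets the
first sign change of the log-posterior difference on `(mu1, mu2)` and
refines it with Brent's method to relative tolerance 1e-8 (for the
symmetric case this is exactly the midpoint). The density radius is

    r = 0.8 * t_AU,

pulling the working radius safely inside the between-cloud distance. A
sample whose mixture collapses to one mode raises an explicit error
recommending a manually chosen radius — unstructured data admit no
meaningful radius.

## Generation

Around each original case (`seed`) the generator places `k` new points
(default 10): an isotropic unit direction (normalized Gaussian vector)
times a length drawn from a three-band piecewise-uniform law in units of
the neighbourhood scale `c = 0.4 * r`:

| band | length range | share |
|------|--------------|-------|
| A    | (0, 0.72]·c  | 80%   |
| B    | (0.72, 1.22]·c | 15% |
| C    | (1.22, 2.0]·c  | remainder |

Band counts are exact (`round(count * share)`, remainder to band C), and
lengths are assigned to rows in band-block order; the generated block
repeats the seeds in whole copies (all seeds for copy 1, then copy 2, …).
The band limits are the inversion of the neighbourhood-probability
sigmoid

    p(d) = 1 / (1 + exp(10 (d/c - 1))),

which equals 0.5 at `d = c`: band A covers distances with p > ~0.95,
band B the transition 0.10 < p < 0.95, band C the sparse far tail. The
factor 0.4 (rather than 0.5, which would place points exactly halfway
between clouds) keeps generated points from encroaching on neighbouring
clouds while still exploiting most of the allowed variance. Labels are
inherited from the seed; unlabeled input is treated as a single class.

`augment_to_size` fills per-class deficits instead: for each class the
seeds are cycled in original row order, each producing one point by the
same mechanism, until the class reaches its target (typically the largest
group's size). Balancing the printed leukemia transcriptomics group sizes
{108, 266, 163, 15} to 266 therefore adds {158, 0, 103, 251} points.

## Validation battery

On the pooled original + generated table, two tasks are run with a random
forest (500 trees; features-per-split tuned over {sqrt(d), d/3}) and an
SVM (kernel, cost and width tuned over a small grid), each tuned once per
task by 3-fold stratified search on the pool:

1. **Generated-vs-original**: a faithful generator forces chance-level
   balanced accuracy (unweighted mean of per-class recall).
2. **Class assignment**: the original classes must remain learnable,
   ruling out the trivial explanation that the classifiers do not work.

Protocol per task: a class-proportional 20% holdout is selected once as
the best of 1000 candidate splits, scored by the maximum over variables of
the two-sample Kolmogorov–Smirnov statistic between holdout and full data
(the distribution-matched split; 1000 candidates because selection quality
plateaus quickly at these sample sizes). Each of 100 Monte-Carlo
cross-validation runs trains on a fresh class-proportional two-thirds of
the pool and validates on a fresh random 80% subsample of the holdout;
the report gives the median and the 2.5th/97.5th percentiles of the 100
balanced accuracies. Everything is repeated with each predictor column
independently permuted (once per experiment) as an overfitting control,
and every variable is compared between original and generated rows with a
two-sided Wilcoxon–Mann–Whitney test, unadjusted. A variable constant and
identical in both groups gets p = 1 by convention.

## Synthetic benchmarks

`make_hepta` draws seven spherical clouds in 3-D: 32 points uniform in a
ball of radius 0.1 at the origin and 30 points uniform in balls of radius
1 at ±3 on each axis (n = 212, uniform-in-ball via an isotropic direction
and radius `r * U^(1/3)`). The origin cloud is implemented as a uniform
ball of radius 0.1, reading the recipe's angular restriction for class 1
as a typo for the radius; this matches the canonical benchmark geometry.
`make_chainlink` draws two classes of 500 points uniform inside tori
(minor radius 0.1, major radius 1): ring 1 in the xy-plane at the origin,
ring 2 in the xz-plane centred at (1, 0, 0), so the rings interlink.
Torus sampling corrects the major-angle volume bias by rejection.

These benchmarks emulate cleanly separated, isotropic clouds with exactly
known class geometry. Real biomedical data add correlated variables,
unequal scales, heavy tails and label noise; passing the battery here
shows the machinery is sound on unambiguous structure, not that every
omics dataset will augment as cleanly. The discriminator result in
particular depends on the clouds being genuinely indistinguishable after
augmentation — data with strong within-cloud anisotropy would need the
visual U-/P-matrix checks the diagnostics automate only coarsely.

## Problem sizes and determinism

Default experiments run the full protocol: 50 x 80 grid, 25 epochs,
tenfold augmentation of n = 212, 100 cross-validation runs. Unit tests
exercise the same code paths on reduced grids (e.g. 20 x 30, 15 epochs),
which organize the seven Hepta clouds just as reliably. All randomness
flows from explicit integer seeds; the pipeline derives per-stage seeds
from one global seed via `numpy.random.SeedSequence`, and rerunning a
configuration reproduces every artifact bit-identically.

## Known limitations

* A single global radius: clouds of very different internal scale share
  one `r`, which can over- or under-fill individual clouds (the origin
  cloud of the seven-cloud benchmark is deliberately much denser than the
  rest and still augments cleanly, but the limit exists).
* Classes absent from the input cannot be generated — the method
  extrapolates observed structure only.
* Rationally scaled (continuous) variables are assumed; nominal or
  ordinal columns would need encoding upstream.
* The EM fit assumes the edge-length sample is genuinely bimodal;
  borderline structure can yield an unstable boundary, which is why the
  estimate carries its full provenance (sample, fit, boundary) for
  inspection.
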