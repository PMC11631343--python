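# esomgen

Structure-preserving augmentation of small tabular datasets with emergent
self-organizing maps (ESOMs).

Small biomedical studies — rare-disease cohorts, early-stage trials,
expensive omics panels — often end up with group sizes too small for
robust analysis, and with no credible parametric model of the data to
sample from. `esomgen` augments such datasets **model-free**: it detects
the dense-cloud / empty-void structure of the data with a large toroidal
self-organizing map, derives a distance scale separating within-cloud from
between-cloud distances, and generates new cases around each original one
without blurring class boundaries or inventing structure. A built-in
discriminator battery verifies the result: tuned classifiers should be
unable to tell generated rows from original ones, while the original
classes stay perfectly learnable.

## Method in brief

1. **ESOM**: online training of a 50×80 toroidal neuron grid projects the
   data topology-preservingly onto 2-D; the U-matrix (mean
   neighbour-weight distance per neuron) shows voids as ridges, the
   P-matrix (data count within radius *r* of each weight) shows density.
2. **Density radius**: the Gabriel graph over the distinct best-matching
   unit weights yields a bimodal sample of edge lengths (within- vs
   between-cloud). A two-component Gaussian mixture fitted by EM gives
   the Bayes boundary *t*<sub>AU</sub> between the modes, and
   *r* = 0.8·*t*<sub>AU</sub>.
3. **Generation**: each original case seeds *k* new points (default 10)
   at isotropic directions and banded distances: 80% within 0.72·*c*,
   15% in (0.72, 1.22]·*c*, the rest up to 2·*c*, where *c* = 0.4·*r* is
   the scale at which the neighbourhood probability
   *p*(d) = 1/(1+e^{10(d/c−1)}) drops through 0.5. The bands invert
   *p* = 0.95 and *p* = 0.10.
4. **Validation**: class-proportional distribution-matched 20% holdout,
   100 Monte-Carlo cross-validation runs of a tuned random forest and SVM
   on the generated-vs-original and class-assignment tasks, permuted
   controls, and per-variable Wilcoxon–Mann–Whitney tests.

See `docs/methods.md` for the full account.

## Worked example

```python
import esomgen as eg

hepta = eg.make_hepta(seed=1)                      # 212 points, 7 spherical clouds
model = eg.train_esom(hepta, eg.GridSpec(50, 80, True), seed=2)
est = eg.estimate_density_radius(hepta, model, seed=3)
print(f"t_AU {est.t_au:.3f} -> radius {est.radius:.3f}")

gen = eg.generate_data(hepta, est.radius, eg.GenerationConfig(gen_per_data=10, seed=4))
print(gen.generated.n, "generated rows")

disc = eg.discriminator_experiment(gen, classifiers=("rf",), include_permuted=False, seed=5)
cls = eg.class_assignment_experiment(gen, classifiers=("rf",), include_permuted=False, seed=6)
print(f"discriminator RF median {disc['rf'].median:.3f} ({disc['rf'].lo:.3f}-{disc['rf'].hi:.3f})")
print(f"class assignment RF median {cls['rf'].median:.3f}")
```

Output from this exact session:

```
t_AU 1.495 -> radius 1.196
2120 generated rows
discriminator RF median 0.493 (0.487-0.511)
class assignment RF median 1.000
```

Reading: the estimated radius cleanly splits within-cloud (~0.37) from
between-cloud (~2.6) distances; ten generated points per seed yield 2120
new rows; a tuned random forest cannot separate generated from original
rows (median balanced accuracy at the 0.5 guessing level, interval
covering 0.5) yet recovers the seven classes perfectly — the augmentation
preserved the structure without becoming detectable.

The same run is available from the shell:

```sh
esomgen --verbose run --dataset hepta --seed 1 --out run_hepta
```

which writes the trained model, U/P matrices, radius estimate, pooled
CSV (with `Origin` and `SeedIndex` columns) and the evaluation report
into `run_hepta/`. Subcommands `simulate`, `train`, `radius`,
`generate` and `evaluate` expose the individual stages.

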