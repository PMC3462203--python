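# cepel — density estimation by 1d-decomposition

`cepel` estimates multidimensional probability densities by decomposing the
problem into one-dimensional projections.  Data are projected to scalars
(axis coordinates, distances to a centre or a regression line, eigenvector
coordinates, log-curve residuals), each projected sample is fitted with an
adaptive likelihood-tuned kernel density estimator, and the 1-d densities are
combined back into a d-dimensional model

    p̂(x) ∝ combine_j p̂_j(π_j(x)),    combine ∈ {product, mean, max, conditional},

normalised over a bounded support box.  Because every estimation happens in
one dimension, precision does not degrade with dimensionality the way a
multivariate Parzen-window estimate does — provided the chosen projections
match the structure of the data.  Model choice itself is data-driven:
candidate decompositions are ranked by their normalised leave-one-out
log-likelihood, a consistent selection criterion.

The package is aimed at data analysts and methodologists who need
nonparametric density estimates in moderate dimensions, and it ships the
three applications built on the core estimator:

- **Radial-mixture clustering** (`cepel.clustering`) — density estimation of
  clustered, noise-contaminated point sets: per-axis mode finding proposes
  candidate centres, greedy likelihood-driven selection keeps one radial
  component per genuine cluster, and the mean-combined model is normalised
  into a proper density.
- **Automatic data mining** (`cepel.datamining`) — fully automatic discovery
  of relations in a CSV table: every column pair is scored by fitting the
  model zoo (naive Bayes, regression, eigenvectors, radial, logarithmic, or
  class-conditional densities for discrete pairings) and ranking winners by
  their likelihood margin over the independence model.  No parameters to set.
- **Probabilistic region-merging segmentation** (`cepel.segmentation`) —
  grayscale images are segmented by iteratively merging the adjacent region
  pair with the highest Naive Bayes merge posterior, computed from
  brightness, texture and arrangement features whose use is gated by
  per-feature reliability curves P(reliable | region size), until every
  posterior drops below 0.5.

## Worked example

Estimate the density of 500 points forming three Gaussian clusters with 10%
uniform background noise:

```python
import numpy as np
from cepel import (gen_clustered, fit_radial_mixture, estimate_density,
                   integrate_probability, SupportBox, evaluate)

pts, labels = gen_clustered(d=2, n=500, seed=7)
mix = fit_radial_mixture(pts, seed=7)
print("components:", mix.n_components)
for c in mix.centers:
    print("  centre", np.round(c, 3))
print("gains:", [round(s["gain"], 4) for s in mix.trace[1:]])

model = estimate_density(mix)
box = model.support
left = SupportBox(np.column_stack([box.bounds[:, 0], box.bounds.mean(axis=1)]))
print("P(lower-left quadrant):", round(integrate_probability(model, left), 4))
core = pts[labels == 0].mean(axis=0)
print("density at a cluster core:", round(float(evaluate(model, core[None])[0]), 3))
```

Output:

```
components: 3
  centre [0.097 0.133]
  centre [0.481 0.883]
  centre [0.904 0.482]
gains: [0.214, 0.1398]
P(lower-left quadrant): 0.2737
density at a cluster core: 7.288
```

The greedy selection accepted exactly the three planted clusters: the second
and third components each raised the normalised leave-one-out log-likelihood
by far more than the 0.01 nats/dimension acceptance threshold, and a fourth
candidate did not.  The normalised model assigns the lower-left quadrant 27%
of the mass (one cluster plus its share of the noise) and a cluster core a
density of 7.3 — about 26 times the uniform level on the unit box of the 28%
of points that are noise or spread.

The same pipelines are available from the shell:

```bash
cepel synth clustered --seed 7 --n 500 --out points.csv
cepel cluster --input points.csv --seed 7 --out mixture.json
cepel inspect table.csv --json report.json --out report.html --seed 7
cepel segment --train imgs/ labels/ --model m.json
cepel segment --model m.json --input img.png --out labels.png --boundary bnd.png
```

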