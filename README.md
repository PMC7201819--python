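# mieaclust

Fuzzy clustering of tabular clinical data by a modified immune evolutionary
algorithm (MIEA), with Relief feature weighting and external validation.

## The problem

Fuzzy c-means (FCM) partitions n samples x_k ∈ R^p among c prototypes
v_i by minimising

    J(X; U, V) = Σ_k Σ_i u_ik^m · D_ik²,    D_ik² = ‖x_k − v_i‖²,

subject to u_ik ∈ [0, 1] and Σ_i u_ik = 1 for every sample, with fuzzifier
m > 1.  The classic alternating-optimisation solver is a local descent: it
is sensitive to initialisation and can converge to poor local minima, which
matters when clusters feed clinical decision support (e.g. grouping breast
tumour cytology profiles).  This package replaces the single local descent
with a global evolutionary search:

* each **chromosome** is the row-major concatenation of c centers
  (length l = c·p), scored by **fitness f = 1/(J + 1)**;
* a real-coded GA (roulette or rank selection, one/two-point or uniform
  crossover, bounded uniform-reset mutation) explores prototype space;
* **immune operators** accelerate it without degrading it: a *vaccine*
  (a random fraction of the current elite's genes) is injected into
  offspring with probability p_v, and *immune selection* keeps the
  vaccinated individual only if its fitness did not drop; *elitism* carries
  the best individual unchanged, so the elite objective is monotone;
* memberships use the exact FCM update, including the degenerate case: when
  a sample coincides with one or more centers, all membership mass is
  placed on (split uniformly among) the coincident centers.

Around the optimiser the package provides Relief feature weighting with
20-run averaging and threshold / bottom-k pruning, a labelled
Gaussian-mixture generator for fully reproducible experiments, a chunked
(map/reduce-style) objective evaluation, and external validation —
clustering F-measure

    F = Σ_i (n_i / n) · max_j 2 r(i,j) p(i,j) / (r(i,j) + p(i,j)),
    r = n_ij / n_i,  p = n_ij / n_j,

and majority-mapping accuracy Σ_j max_i n_ij / n.

## Worked example

```python
import numpy as np
from mieaclust import (MixtureSpec, generate_mixture, MIEAClustering,
                       contingency, f_measure, majority_accuracy,
                       averaged_weights)

spec = MixtureSpec(means=[[0, 0], [5, 5], [0, 5]], spreads=0.2,
                   noise_features=1, seed=42)
ds = generate_mixture(spec, 300)          # 300 labelled samples, 3 clusters

est = MIEAClustering(n_clusters=3, random_state=42).fit(ds.features[:, :2])
print("final J:", round(est.objective_, 3))
print("centers:\n", np.round(est.cluster_centers_, 3))
cont = contingency(ds.labels, est.labels_)
print("F-measure:", f_measure(cont), " accuracy:", majority_accuracy(cont))

rep = averaged_weights(ds, n_samples=100, repeats=20, base_seed=0)
print("Relief weights (f0, f1, noise0):", np.round(rep.weights, 3))
```

prints

```
final J: 24.541
centers:
 [[ 0.072 -0.082]
 [-0.077  5.079]
 [ 5.017  5.016]]
F-measure: 1.0  accuracy: 1.0
Relief weights (f0, f1, noise0): [0.448 0.319 0.059]
```

The three recovered centers sit within ~0.1 of the generating means
(0,0), (0,5), (5,5); the fuzzy partition, hardened by argmax, reproduces
the generating labels exactly (F = accuracy = 1); and Relief ranks both
informative coordinates far above the appended pure-noise feature.

The same pipeline is scriptable from a shell:

```sh
mieaclust simulate --n 300 --clusters 3 --spread 0.2 --seed 42 \
    --out data.csv --truth truth.json
mieaclust cluster  --data data.csv --label-column label --clusters 3 \
    --seed 42 --out-dir run/
mieaclust evaluate --pred run/labels.csv --truth truth.json
```

UCI-style tables (optional ID column, `?` missing markers, class label
column — e.g. Breast Cancer Wisconsin) load with
`load_table(path, id_column=0, label_column=10)`.

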