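# neuromotif

Meso-scale connectivity statistics from single-neuron axonal
reconstructions.

Single-neuron reconstruction archives describe thalamocortical neurons
as trees of 3-D sample points in a common atlas space (the Allen Common
Coordinate Framework, CCF).  `neuromotif` turns such reconstructions —
for example ventral posteromedial nucleus (VPM) neurons projecting to
the somatosensory cortices — into population-level statistics:

* **Projection profiles and motifs.**  Each axonal terminal branch is
  assigned to the atlas area and layer containing its endpoint, and its
  full path length accrues there.  A neuron's *motif* is the list of
  areas receiving at least 5 of its terminal branches, ordered by
  terminal count; motifs are classed as monofocal, bifurcating,
  trifurcating or quadrifurcating, and multifocal neurons are split
  into *center* vs *border* groups by whether ≥ 4 secondary-area
  terminals lie > 200 μm from the dominant-area border.  Motif
  enrichment is tested with an exact binomial test against the product
  of marginal targeting probabilities, Bonferroni-corrected.
* **Morphological dissimilarity.**  Every neuron pair is compared with
  rotation-only rigid Coherent Point Drift (CPD) on soma-centered
  point clouds of their *topological minors* (soma, branch nodes,
  terminal branches).  With translation and scaling eliminated, the
  converged mean squared registration error isolates differences in
  branching pattern from soma position and orientation.
* **Morphological gradient.**  The all-pairs dissimilarity matrix is
  embedded in 2-D with t-SNE (precomputed-distance mode); each neuron's
  *gradient index* is its geodesic distance from a root neuron (the
  most dorsal barrel-cortex-projecting cell) along a k-nearest-neighbor
  graph, normalized to [0, 1].  Ward clustering of the embedding yields
  three morphotypes ordered along the gradient.
* **Topography.**  The soma→terminal map is quantified by fitting an
  affine least-squares transform from soma positions to the *medoids*
  of each neuron's terminals, polar-decomposing its linear part
  A = R·S, and reporting R as Euler angles plus the fit MSE.

A fully tested synthetic-population generator (`neuromotif.synthetic`)
produces topographically organized populations inside a toy layered
atlas with known ground truth — soma positions, depth parameters, true
motifs and the generator's rotation — so every stage is verifiable
without downloading the archived morphology databases.  Real archives
are supported through standard 7-column SWC and a documented point/line
JSON dialect, with MouseLight-style LIP→PIR orientation normalization.

## Worked example

```python
import numpy as np
from neuromotif import (GeneratorParams, generate_population,
    extract_topological_minor, projection_profile)
from neuromotif.projections import motif_census, order_class_fractions
from neuromotif.topography import terminal_medoid, fit_topography

params = GeneratorParams()                     # default study conditions
neurons, atlas, truth = generate_population(100, params, seed=0)
minors = [extract_topological_minor(m) for m in neurons]
profiles = [projection_profile(t, atlas, params.areas) for t in minors]

print(motif_census(profiles)[["n_neurons", "fraction", "order_class"]].head(6))
print({k: round(v, 3) for k, v in order_class_fractions(profiles).items() if v})

somata = np.array([m.soma_point for m in neurons])
medoids = np.array([terminal_medoid(t.terminal_points) for t in minors])
fit = fit_topography(somata, medoids)
print("euler_deg:", np.round(fit.euler_deg, 2), " mse:", round(fit.mse, 2))
```

prints

```
                 n_neurons  fraction  order_class
SSp-ll - SSp-m          12      0.12  bifurcating
SSs - SSp-n             11      0.11  bifurcating
SSp-ul - SSs             9      0.09  bifurcating
SSp-bfd - SSp-n          7      0.07  bifurcating
SSp-n - SSs              6      0.06  bifurcating
SSs                      6      0.06    monofocal

{'monofocal': 0.24, 'bifurcating': 0.57, 'trifurcating': 0.16, 'quadrifurcating': 0.03}
euler_deg: [ -60.13    0.42 -119.91]  mse: 4.01
```

The census lists each unique motif (areas ordered by terminal count)
with the number and fraction of participating neurons; the order-class
fractions estimate the population's broadcasting mix (here drawn from
26% / 53% / 17% / 1.5% motif-order probabilities).  The topography fit
recovers the generator's soma→terminal rotation — Euler angles
(−60, 0, −120)° — to within a fraction of a degree at the default
20 μm terminal jitter; the MSE is in squared 10-μm voxel units.

The same stages run end-to-end from the command line:

```bash
neuromotif synth --n 60 --seed 0 --out pop/          # SWC + atlas + truth
neuromotif pipeline --config config.yaml --out run/  # all stages, all tables
neuromotif cpd-matrix pop/ --subsample 400 --out D.tsv
```

`pipeline` writes projection profiles, the motif census and
significance table, layer distributions, the dissimilarity matrix, the
embedding with gradient indices and morphotypes, the topography fit,
sparse occupancy maps and coronal/sagittal/horizontal
maximum-projection plots.

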