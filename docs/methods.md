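# Methods

## Model family

All three segmentation models estimate a per-pixel probability vector
p(r) over K classes on the pixel lattice (row-major, 0-based, origin
top-left; 4-connected neighborhoods by default, 8-connected optional,
no padding or wraparound — border sites simply have fewer neighbors).
Each model minimizes an unconstrained convex quadratic:

* **Classic (single source).** Data term (p − v)² against one
  likelihood field v, smoothness term λ Σ (p(r) − p(s))² over lattice
  edges.
* **Lowest-entropy selection.** Per pixel, the source whose likelihood
  distribution has minimal uncertainty is hard-selected (binary
  weights); the classic model then runs on the selected field. Ties go
  to the lowest source index, which makes runs deterministic.
* **Fusion.** Soft data weights ω_f(r) ∝ μ_data/(μ_data + U_f(r))
  normalized over sources; the data term is equivalent (up to a
  constant) to (p − u)² against the mixture u = Σ_f ω_f v^f; the
  smoothness term weights each edge by
  ω_rs = μ_edge/(μ_edge + ‖u(r) − u(s)‖²), so smoothing relaxes across
  likely class boundaries.

The energies are evaluated with each **unordered edge counted once**:
that is the quadratic whose exact coordinate-descent update is the
implemented Gauss–Seidel scheme (counting ordered pairs twice would
put 2λ, not λ, in the update denominators). Because the per-class
update coefficients do not depend on the class, simplex-valued inputs
give simplex-valued iterates and fixed points; no projection step is
needed, and none is applied.

Limit behavior, verified in the test suite: μ_edge → ∞ recovers
unweighted smoothing (and with one source, the classic model);
μ_data → ∞ gives equal source weights 1/N_f; μ_data → 0 gives
**inverse-uncertainty weighting** ω_f → (1/U_f)/Σ_j(1/U_j). The last
coincides with the lowest-entropy hard selection only where the winning
source's uncertainty is close to 0 — a soft rule, not a selection, at
generic uncertainty values. The test suite asserts the correct limit
law; the corresponding acceptance check, which expects hard-selection
equivalence wherever uncertainties merely differ by more than 0.05, is
knowingly left failing with the measured deviation.

## Solver

In-place Gauss–Seidel in fixed row-major order (numba-compiled kernel),
initialized at p⁰ = v (classic) or p⁰ = u (fusion). The data and edge
weights depend only on the likelihoods, so they are computed once
before iterating. Stopping: max-abs update < `tol` (default 1e-6) or
`max_sweeps` (default 200), whichever first; both are logged in the
result, a non-converged run raises a RuntimeWarning and is flagged in
the manifest. The fixed sweep order makes runs bit-reproducible. On
lattices up to 5×5 the converged output matches a dense per-class
linear solve of the same quadratic to well below 1e-6 (worst observed
~1e-12).

Energy traces are recorded per sweep and are non-increasing; the
acceptance suite checks this together with simplex conservation
(|Σ_k p_k − 1| < 1e-8 after every sweep) on the full benchmark.

## Likelihood training

Per source f and class k, a d-dimensional histogram (d ≤ 3 enforced —
avoiding higher-dimensional density estimation is the point of fusing
several low-dimensional sources) over `bins_per_dim` equal-width bins
per dimension. Bin ranges come from the scribbled pixels' min/max per
dimension, shared across classes so bins align; evaluation clamps
out-of-range features to edge bins. `smoothing_eps` (default 1e-6) mass
is added to every cell before normalization, preventing hard zeros
while leaving the declared fallback — a pixel whose bin has zero mass
in every class gets the uniform likelihood 1/K — reachable for
eps = 0 runs. Ties never resolve to an arbitrary class.

**Binning rule.** `bins_per_dim` defaults to 32, suited to dense,
scene-scale training sets on 8-bit imagery. For small training sets the
package provides `bins_for_sample_size(n, d) = clip(floor(n^(1/d)), 2, 256)`
— about one expected training count per cell within a class's support —
and the synthetic-benchmark protocol (`benchmark_config`) applies it to
the smallest class's scribble count. This matters scientifically:
badly undersampled histograms degenerate into single-class deltas whose
zero Gini impurity masquerades as certainty, which defeats
uncertainty-weighted fusion (the weak source looks exactly as confident
as the strong one wherever its sparse bins happen to be occupied).

## Feature spaces

* **Space 1** — green/red/NIR triplet, each band smoothed by an
  edge-preserving bilateral filter (windowed normalized convolution;
  window radius `round(3σ_spatial)`, symmetric padding; defaults
  σ_spatial = 3 px, σ_range = 0.1 × band range; in the σ_range → ∞
  limit it equals a truncated Gaussian blur, which the tests exploit as
  an oracle). Per-band filtering; joint filtering is not implemented.
* **Space 2** — first three principal components of ten vegetation
  indices computed in fixed order (MSR, CI, NDVI, GNDVI, EVI, SARVI,
  RDVI, SAVI, MSAVI, WDRVI) from blue/green/red/NIR reflectances.
  Constants: soil adjustment L = 0.5 (SAVI, SARVI), SARVI γ = 1 in
  ρ_rb = ρ_r − γ(ρ_b − ρ_r), WDRVI α = 0.2 (within the 0.1–0.2 range
  of that index's defining literature; configurable). Some typeset
  sources print MSR and RDVI in a simplified rational form identical to
  NDVI (square roots lost); the standard forms are implemented, with an
  `as_printed=True` switch reproducing the degenerate variants.
  Denominators are guarded by ε = 1e-12 rather than masking, so planes
  stay finite for histogramming.
* **Space 3** — first three principal components of the six reflective
  bands (blue, green, red, NIR, both mid-IR); the thermal band is
  excluded.

PCA is computed on mean-centered (not standardized) features with a
deterministic sign convention (largest-magnitude loading entry
positive). Loadings fitted at training time are carried in the space's
provenance and can be frozen and reused at segmentation time; trained
histograms refuse feature stacks whose provenance does not match.

## Validation

Confusion matrix with rows = actual, columns = predicted; unlabeled (0)
ground-truth sites are excluded. Overall accuracy, per-class precision
(NaN where a class was never predicted), Cohen's kappa
(p_o − p_e)/(1 − p_e) with p_e from the matrix margins (NaN when
p_e = 1). Kappa interpretation bands are half-open on the left
((0.20, 0.40] "Fair", etc.) so every real value lands in exactly one
band; values below 0 are "Poor agreement".

## Synthetic benchmark

The generator emulates the structure of a supervised single-scene
protocol: a piecewise-constant K-class label map (seeded Voronoi cells,
or vertical block strips for layout-exact tests), per-source Gaussian
class emissions of controllable overlap, and scribbles drawn uniformly
from the scene itself (train = test image). The frozen benchmark is
128×128, K = 5, 25 Voronoi regions, two 3-D sources with mean pairwise
Mahalanobis separations 3 (strong) and 1 (weak), isotropic unit
covariance, 5% scribbles, seed 0. Emissions are Gaussian even though
the method is histogram-based — controllable overlap while exercising
the binning — so passing tests demonstrate the models' mathematical
behavior, not performance on real radiometry: no sensor noise model,
no atmosphere, no within-region texture or spatial autocorrelation of
real crops, and no mixed pixels.

Defaults for the solvers: λ = 2.0 (mid-range smoothing on 4-connected
lattices; the underlying method leaves it free, and acceptance checks
hold across λ ∈ {0.1, 1, 10} in the oracle tests), μ_data = μ_edge = 1.0,
Gini impurity as the uncertainty measure (normalized Shannon entropy
ships as the pluggable alternative).

## Known limitations

* No radiometric calibration (digital numbers → reflectance) or
  geometric correction; inputs are assumed already in reflectance-like
  units. Georeferencing payloads are carried through opaquely, and
  TIFF output does not write geo-tags.
* Histogram likelihoods only; no kernel or parametric densities.
* The μ_data → 0 regime approximates hard selection only near zero
  winner uncertainty (see above).
* Sparse scribbles bias bin ranges: features outside the scribbled
  pixels' range are clamped into edge bins.
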