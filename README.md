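# gmmfusion

Probabilistic segmentation of multi-band imagery by **Gauss–Markov
measure field (GMMF) models with multi-source likelihood fusion**, built
for supervised land-cover and crop classification from scribble
annotations.

## The problem and the model

Pixel-wise classifiers for multispectral imagery face two coupled
difficulties: class-conditional densities are only trainable in low
dimension (histograms beyond 3-D are hopelessly sparse), and per-pixel
decisions ignore spatial context. This package addresses both by
training a separate 3-D histogram likelihood per *feature space*
(a band triplet, a PCA of vegetation indices, a PCA of spectral bands)
and fusing the resulting likelihood fields inside a spatially
regularized probabilistic model.

For each source f and class k, normalized histograms h_f(x; k) are fit
from expert scribbles; the per-pixel likelihood is the class-normalized
histogram value

    v_k^f(r) = h_f(x_f(r); k) / Σ_j h_f(x_f(r); j).

The classic single-source GMMF model estimates a probability field p by

    p* = argmin_p Σ_r Σ_k (p_k(r) − v_k(r))² + λ Σ_{s∈N_r} (p_k(r) − p_k(s))²,

solved by the Gauss–Seidel scheme
p_k(r) = (v_k(r) + λ Σ_s p_k(s)) / (1 + λ|N_r|). The fusion model
generalizes both this and its lowest-entropy predecessor (per-pixel hard
selection of the least-uncertain source): each source receives a data
weight from its uncertainty U_f(r) (Gini impurity by default),

    ω_fs(r) = μ / (μ + U_f(r)),   ω_f(r) = ω_fs(r) / Σ_f ω_fs(r),

the sources are mixed into u_k(r) = Σ_f ω_f(r) v_k^f(r), and each
lattice edge is weighted by ω_rs = μ / (μ + ‖u(r) − u(s)‖²) so smoothing
weakens across probable class boundaries. The resulting scheme

    p_k(r) = (u_k(r) + λ Σ_s ω_rs p_k(s)) / (1 + λ Σ_s ω_rs)

is exact coordinate descent on a convex quadratic, preserves the
probability simplex, and decreases the objective every sweep. Labels are
assigned by winner-takes-all, s(r) = argmax_k p_k(r), and validated with
the confusion matrix: overall accuracy, per-class precision, and
Cohen's kappa with its conventional interpretation bands.

## Worked example

`examples/04_model_comparison.py` runs the frozen synthetic benchmark —
a 128×128 five-class scene observed through one well-separated source
and one weak source, with 5% scribbles — through all three models:

```
         model  accuracy    kappa
   gmmf_space1    0.9871   0.9836
   gmmf_space2    0.7383   0.6674
       entropy    0.9860   0.9823
        fusion    0.9864   0.9827
```

Source 1 alone is strong (0.987), source 2 alone weak (0.738); both the
lowest-entropy rule and fusion recover the strong source's accuracy
without being told which source to trust — the fusion weights infer it
from each source's per-pixel uncertainty. `examples/03_train_and_segment.py`
prints the intermediate quantities (mean Gini uncertainty 0.32 for the
strong source vs 0.68 for the weak one, 36 Gauss–Seidel sweeps to a
1e-6 tolerance, final accuracy 0.9864, kappa 0.9827 "Almost perfect
agreement").

The other examples cover scene generation (`01`), the ten vegetation
indices with hand-checkable values (`02`), and feature-space
construction with bilateral filtering and PCA (`05`).

A thin CLI wraps the same API:

```bash
gmmfusion simulate --preset default --seed 0 --out scene/
gmmfusion run --scene scene/ --model fusion --out run/
gmmfusion eval --gt scene/groundtruth.npz --pred run/labels.tif -K 5
```

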