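"""Feature-space construction: vegetation indices, bilateral filtering, PCA.

Three 3-dimensional feature spaces are supported, mirroring common
practice in multispectral crop mapping:

* **Space 1** — bilateral-filtered green/red/NIR band triplet (TM2-TM4);
* **Space 2** — first three principal components of ten vegetation
  indices (MSR, CI, NDVI, GNDVI, EVI, SARVI, RDVI, SAVI, MSAVI, WDRVI);
* **Space 3** — first three principal components of the six reflective
  bands TM1-TM5 and TM7 (the thermal band is excluded).

Each space stays at most 3-dimensional so that class-conditional
densities remain trainable as 3-D histograms; combining spaces is the
job of the fusion segmentation model, not of feature concatenation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.decomposition import PCA

from .errors import ConfigError, DataError
from .raster_io import MultiBandImage

#: Vegetation indices in computation order.
INDEX_NAMES = ("MSR", "CI", "NDVI", "GNDVI", "EVI", "SARVI", "RDVI", "SAVI", "MSAVI", "WDRVI")

#: Band roles entering Space 3 (six reflective TM bands; thermal excluded).
SPACE3_ROLES = ("blue", "green", "red", "nir", "mir1", "mir2")


@dataclass(frozen=True)
class IndexParams:
    """Constants of the vegetation-index formulas.

    ``soil_L`` is the soil-adjustment constant of SAVI/SARVI (0.5, the
    standard recommendation for intermediate vegetation cover);
    ``gamma`` the atmospheric-correction factor inside SARVI's
    ρ_rb = ρ_r − γ(ρ_b − ρ_r) (1.0); ``alpha`` the wide-dynamic-range
    weighting of WDRVI (0.2, within the 0.1-0.2 range of its defining
    literature; unstated in the source method).  ``epsilon_div`` guards
    zero denominators so every plane stays finite for histogramming.
    """

    soil_L: float = 0.5
    gamma: float = 1.0
    alpha: float = 0.2
    epsilon_div: float = 1e-12

    def __post_init__(self) -> None:
        if self.soil_L < 0:
            raise ConfigError("soil_L must be >= 0")
        if not 0 < self.alpha <= 1:
            raise ConfigError("alpha must be in (0, 1]")
        if self.epsilon_div <= 0:
            raise ConfigError("epsilon_div must be > 0")


@dataclass(frozen=True)
class BilateralParams:
    """Bilateral pre-filter settings for Space 1.

    ``sigma_range=None`` resolves per band to 0.1 x (band max − min).
    """

    sigma_spatial: float = 3.0
    sigma_range: float | None = None
    truncate: float = 3.0


@dataclass
class PCAResult:
    """Frozen PCA fit: loadings (n_components x D), mean, variances."""

    loadings: np.ndarray
    mean: np.ndarray
    explained_variance: np.ndarray


@dataclass
class FeatureSpaceStack:
    """Ordered per-source feature planes sharing one lattice.

    ``spaces`` maps a space id to an ``H x W x d`` array (d <= 3);
    ``provenance`` records, per space, how it was built (bands, filter
    settings, PCA loadings) so trained histograms can refuse mismatched
    inputs.
    """

    spaces: dict[int, np.ndarray]
    provenance: dict[int, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.spaces:
            raise DataError("a FeatureSpaceStack needs at least one space")
        shapes = {a.shape[:2] for a in self.spaces.values()}
        if len(shapes) != 1:
            raise DataError(f"feature spaces disagree on lattice shape: {shapes}")
        for sid, arr in self.spaces.items():
            if arr.ndim != 3:
                raise DataError(f"space {sid} must be H x W x d, got shape {arr.shape}")
            if not np.isfinite(arr).all():
                raise DataError(f"space {sid} contains non-finite feature values")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.spaces.values())).shape[:2]

    @property
    def n_sources(self) -> int:
        return len(self.spaces)

    @property
    def space_ids(self) -> tuple[int, ...]:
        return tuple(sorted(self.spaces))

    def arrays(self) -> list[np.ndarray]:
        """Feature arrays in ascending space-id order."""
        return [self.spaces[sid] for sid in self.space_ids]


# ---------------------------------------------------------------------------
# vegetation indices
# ---------------------------------------------------------------------------

def vegetation_indices(
    img: MultiBandImage,
    params: IndexParams | None = None,
    as_printed: bool = False,
) -> np.ndarray:
    """Compute the ten vegetation indices as an ``H x W x 10`` stack.

    Band values are interpreted as reflectance in [0, 1]; values outside
    are accepted (index formulas remain defined) and simply passed
    through the arithmetic.  With ``as_printed=True`` MSR and RDVI fall
    back to the simple rational form (identical to NDVI) that some
    typeset sources show with the square roots lost.

    Order: MSR, CI, NDVI, GNDVI, EVI, SARVI, RDVI, SAVI, MSAVI, WDRVI.
    """
    params = params or IndexParams()
    for role in ("blue", "green", "red", "nir"):
        if role not in img.band_roles:
            raise DataError(f"vegetation indices need band role {role!r}, which is missing")
    b = img.band("blue")
    g = img.band("green")
    r = img.band("red")
    nir = img.band("nir")
    eps = params.epsilon_div
    L = params.soil_L

    def safe_div(num, den):
        return num / np.where(np.abs(den) < eps, np.sign(den) * eps + (den == 0) * eps, den)

    ratio = safe_div(nir, r)
    ndvi = safe_div(nir - r, nir + r)
    if as_printed:
        msr = ndvi
        rdvi = ndvi
    else:
        msr = safe_div(ratio - 1.0, np.sqrt(np.clip(ratio, 0.0, None)) + 1.0)
        rdvi = safe_div(nir - r, np.sqrt(np.clip(nir + r, 0.0, None)) + eps)
    ci = safe_div(nir, g) - 1.0
    gndvi = safe_div(nir - g, nir + g)
    evi = 2.5 * safe_div(nir - r, 1.0 + nir + 6.0 * r - 7.5 * b)
    rb = r - params.gamma * (b - r)
    sarvi = (1.0 + L) * safe_div(nir - rb, nir + rb + L)
    savi = (1.0 + L) * safe_div(nir - r, nir + r + L)
    msavi = 0.5 * (
        2.0 * nir + 1.0 - np.sqrt(np.clip((2.0 * nir + 1.0) ** 2 - 8.0 * (nir - r), 0.0, None))
    )
    wdrvi = safe_div(params.alpha * nir - r, params.alpha * nir + r)

    out = np.stack([msr, ci, ndvi, gndvi, evi, sarvi, rdvi, savi, msavi, wdrvi], axis=-1)
    if not np.isfinite(out).all():  # the guards above should make this unreachable
        raise DataError("vegetation index stack contains non-finite values")
    return out


# ---------------------------------------------------------------------------
# bilateral filter
# ---------------------------------------------------------------------------

def bilateral_filter(
    plane: np.ndarray,
    sigma_spatial: float = 3.0,
    sigma_range: float | None = None,
    truncate: float = 3.0,
) -> np.ndarray:
    """Edge-preserving smoothing by windowed normalized convolution.

    The window radius is ``round(truncate * sigma_spatial)``; spatial
    weights are Gaussian in the pixel offset, range weights Gaussian in
    the intensity difference to the window center.  Borders use
    symmetric padding.  As ``sigma_range`` grows the filter tends to a
    plain (truncated, normalized) Gaussian blur; the output is always a
    convex combination of input values, hence stays inside the input's
    [min, max] range.
    """
    plane = np.asarray(plane, dtype=np.float64)
    if plane.ndim != 2:
        raise DataError(f"bilateral_filter expects a 2-D plane, got shape {plane.shape}")
    if not np.isfinite(plane).all():
        raise DataError("bilateral_filter input contains non-finite values")
    if sigma_spatial <= 0:
        raise ConfigError("sigma_spatial must be > 0")
    if sigma_range is None:
        span = float(plane.max() - plane.min())
        sigma_range = 0.1 * span if span > 0 else 1.0
    if sigma_range <= 0:
        raise ConfigError("sigma_range must be > 0")

    radius = int(truncate * float(sigma_spatial) + 0.5)
    if radius == 0:
        return plane.copy()
    padded = np.pad(plane, radius, mode="symmetric")
    h, w = plane.shape
    num = np.zeros_like(plane)
    den = np.zeros_like(plane)
    inv2ss = 1.0 / (2.0 * sigma_spatial**2)
    inv2sr = 1.0 / (2.0 * sigma_range**2)
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            shifted = padded[radius + dy : radius + dy + h, radius + dx : radius + dx + w]
            wgt = np.exp(-(dy * dy + dx * dx) * inv2ss - (shifted - plane) ** 2 * inv2sr)
            num += wgt * shifted
            den += wgt
    return num / den


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_space(data: np.ndarray, n_components: int = 3) -> tuple[np.ndarray, PCAResult]:
    """Project an ``H x W x D`` stack onto its first principal components.

    Features are mean-centered (not standardized).  The sign of each
    component is fixed so its largest-magnitude loading entry is
    positive, making runs bit-reproducible.  Returns the ``H x W x n``
    score planes and the frozen fit (loadings, mean, variances) for
    reuse on new imagery.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 3:
        raise DataError(f"pca_space expects H x W x D, got shape {data.shape}")
    h, w, d = data.shape
    if d < n_components:
        raise DataError(f"cannot extract {n_components} components from {d} features")
    flat = data.reshape(-1, d)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(flat)
    loadings = pca.components_.copy()
    # deterministic sign: largest-|.| entry of each loading positive
    for c in range(n_components):
        j = int(np.argmax(np.abs(loadings[c])))
        if loadings[c, j] < 0:
            loadings[c] = -loadings[c]
            scores[:, c] = -scores[:, c]
    result = PCAResult(
        loadings=loadings,
        mean=pca.mean_.copy(),
        explained_variance=pca.explained_variance_.copy(),
    )
    return scores.reshape(h, w, n_components), result


def apply_pca(data: np.ndarray, fit: PCAResult) -> np.ndarray:
    """Project new data with a frozen :class:`PCAResult`."""
    data = np.asarray(data, dtype=np.float64)
    h, w, d = data.shape
    if d != fit.loadings.shape[1]:
        raise DataError(
            f"PCA fit expects {fit.loadings.shape[1]} features, data has {d}"
        )
    scores = (data.reshape(-1, d) - fit.mean) @ fit.loadings.T
    return scores.reshape(h, w, -1)


# ---------------------------------------------------------------------------
# space assembly
# ---------------------------------------------------------------------------

def build_spaces(
    img: MultiBandImage,
    combination: Sequence[int],
    params: IndexParams | None = None,
    filter_params: BilateralParams | None = None,
    fitted: Mapping[int, PCAResult] | None = None,
) -> FeatureSpaceStack:
    """Assemble the requested feature spaces from a multi-band image.

    ``combination`` is a subset of {1, 2, 3}; spaces are returned in
    ascending id order.  ``fitted`` optionally supplies frozen PCA fits
    (from training time) for spaces 2 and 3; otherwise PCA is fitted on
    this image and the fit recorded in the provenance.
    """
    combo = sorted(set(int(c) for c in combination))
    if not combo:
        raise ConfigError("feature-space combination must not be empty")
    if any(c not in (1, 2, 3) for c in combo):
        raise ConfigError(f"unknown space ids in combination {combo}; valid ids are 1, 2, 3")
    params = params or IndexParams()
    filter_params = filter_params or BilateralParams()
    fitted = dict(fitted) if fitted else {}

    spaces: dict[int, np.ndarray] = {}
    provenance: dict[int, dict] = {}
    for sid in combo:
        if sid == 1:
            for role in ("green", "red", "nir"):
                if role not in img.band_roles:
                    raise DataError(f"space 1 needs band role {role!r}, which is missing")
            planes = [
                bilateral_filter(
                    img.band(role),
                    filter_params.sigma_spatial,
                    filter_params.sigma_range,
                    filter_params.truncate,
                )
                for role in ("green", "red", "nir")
            ]
            spaces[1] = np.stack(planes, axis=-1)
            provenance[1] = {
                "kind": "filtered_bands",
                "bands": ["green", "red", "nir"],
                "sigma_spatial": filter_params.sigma_spatial,
                "sigma_range": filter_params.sigma_range,
            }
        elif sid == 2:
            idx = vegetation_indices(img, params)
            if 2 in fitted:
                fit = fitted[2]
                spaces[2] = apply_pca(idx, fit)
            else:
                spaces[2], fit = pca_space(idx, 3)
            provenance[2] = {
                "kind": "pca_indices",
                "indices": list(INDEX_NAMES),
                "loadings": fit.loadings.tolist(),
                "explained_variance": fit.explained_variance.tolist(),
                "pca": fit,
            }
        else:
            missing = [r for r in SPACE3_ROLES if r not in img.band_roles]
            if missing:
                raise DataError(f"space 3 needs band roles {missing}, which are missing")
            bands = np.stack([img.band(r) for r in SPACE3_ROLES], axis=-1)
            if 3 in fitted:
                fit = fitted[3]
                spaces[3] = apply_pca(bands, fit)
            else:
                spaces[3], fit = pca_space(bands, 3)
            provenance[3] = {
                "kind": "pca_bands",
                "bands": list(SPACE3_ROLES),
                "loadings": fit.loadings.tolist(),
                "explained_variance": fit.explained_variance.tolist(),
                "pca": fit,
            }
    return FeatureSpaceStack(spaces, provenance)
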