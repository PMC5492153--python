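"""Seeded synthetic scenes with known ground truth.

Generates piecewise-constant K-class label maps (Voronoi cells or block
strips), per-source Gaussian class emissions of controllable overlap,
and scribble masks sampled from the scene itself — the single-scene
supervised protocol in which training pixels come from the image being
segmented.  Emissions are Gaussian even though the segmentation method
is histogram-based: that creates controllable class overlap while still
exercising the binning, but it reproduces neither satellite radiometry
nor the spatial autocorrelation of real crops.

The frozen :func:`benchmark_default` scenario mirrors the structure of
the study this package emulates: five classes observed through one
well-separated source (mean pairwise Mahalanobis distance about 3) and
one weakly separated source (about 1), so single-source, lowest-entropy
and fusion solvers can be ranked on known truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigError, DataError
from .features import FeatureSpaceStack
from .raster_io import LabelRaster


@dataclass(frozen=True)
class SourceSpec:
    """Emission model of one feature space: K class means, shared or
    per-class covariance (scalar = isotropic)."""

    dims: int
    class_means: tuple[tuple[float, ...], ...]   # K x dims
    class_cov: float | tuple = 1.0

    def __post_init__(self) -> None:
        if not 1 <= self.dims <= 3:
            raise ConfigError(f"source dims must be in 1..3, got {self.dims}")
        means = np.asarray(self.class_means, dtype=np.float64)
        if means.ndim != 2 or means.shape[1] != self.dims:
            raise ConfigError(f"class_means must be K x {self.dims}, got {means.shape}")

    def means(self) -> np.ndarray:
        return np.asarray(self.class_means, dtype=np.float64)

    def cov(self, K: int) -> np.ndarray:
        """Per-class covariance matrices, shape (K, dims, dims)."""
        c = np.asarray(self.class_cov, dtype=np.float64)
        if c.ndim == 0:
            return np.broadcast_to(np.eye(self.dims) * float(c), (K, self.dims, self.dims)).copy()
        if c.ndim == 2:
            return np.broadcast_to(c, (K, self.dims, self.dims)).copy()
        if c.ndim == 3:
            return c.copy()
        raise ConfigError(f"class_cov has unsupported shape {c.shape}")


@dataclass(frozen=True)
class ScenarioSpec:
    """Full description of a synthetic scene; deterministic given seed."""

    shape: tuple[int, int]
    K: int
    region_model: str = "voronoi"
    n_regions: int = 25
    sources: tuple[SourceSpec, ...] = ()
    scribble_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region_model not in ("voronoi", "blocks"):
            raise ConfigError(f"unknown region model {self.region_model!r}")
        if self.n_regions < self.K:
            raise ConfigError(
                f"n_regions={self.n_regions} cannot cover K={self.K} classes"
            )
        if not 0 < self.scribble_fraction <= 0.5:
            raise ConfigError("scribble_fraction must be in (0, 0.5]")
        if not self.sources:
            raise ConfigError("scenario needs at least one source")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)


def generate_labels(spec: ScenarioSpec) -> LabelRaster:
    """Piecewise-constant ground-truth label map; every class present.

    Voronoi: ``n_regions`` seeded cell centers, region i pre-assigned
    class (i mod K)+1 and the assignment shuffled, so each class owns at
    least one cell.  Blocks: ``n_regions`` vertical strips cycling
    through the classes (K=2 with 2 strips gives left half class 1,
    right half class 2).
    """
    h, w = spec.shape
    rng = np.random.default_rng(spec.seed)
    region_class = np.array([(i % spec.K) + 1 for i in range(spec.n_regions)])
    if spec.region_model == "voronoi":
        rng.shuffle(region_class)
        centers = rng.uniform(0, 1, size=(spec.n_regions, 2)) * np.array([h, w])
        ii, jj = np.mgrid[0:h, 0:w]
        pts = np.column_stack([ii.ravel() + 0.5, jj.ravel() + 0.5])
        _, nearest = cKDTree(centers).query(pts)
        labels = region_class[nearest].reshape(h, w)
    else:
        edges = np.linspace(0, w, spec.n_regions + 1).astype(int)
        labels = np.zeros((h, w), dtype=np.int32)
        for i in range(spec.n_regions):
            labels[:, edges[i]:edges[i + 1]] = region_class[i]
    raster = LabelRaster(labels, K=spec.K, role="groundtruth")
    present = set(np.unique(labels))
    missing = set(range(1, spec.K + 1)) - present
    if missing:  # a tiny Voronoi cell can be crowded out of the grid
        raise DataError(f"generated scene lost classes {sorted(missing)}; adjust n_regions")
    return raster


def generate_sources(
    labels: LabelRaster, spec: ScenarioSpec
) -> tuple[FeatureSpaceStack, LabelRaster]:
    """Draw per-source Gaussian emissions and sample scribbles.

    Every pixel's feature vector in source f is drawn from that source's
    emission for the pixel's class; scribbles take a deterministic
    ``floor(scribble_fraction * count)`` (at least 1) uniform sample per
    class.  Fully deterministic given ``spec.seed``.
    """
    h, w = labels.shape
    lab = labels.labels
    rng = np.random.default_rng(spec.seed + 1)  # distinct stream from the label map
    spaces: dict[int, np.ndarray] = {}
    provenance: dict[int, dict] = {}
    for f, src in enumerate(spec.sources):
        means = src.means()
        covs = src.cov(spec.K)
        if means.shape[0] != spec.K:
            raise ConfigError(f"source {f}: class_means rows != K={spec.K}")
        out = np.empty((h, w, src.dims))
        for k in range(1, spec.K + 1):
            mask = lab == k
            n = int(mask.sum())
            if n == 0:
                continue
            if np.allclose(covs[k - 1], 0.0):  # noiseless: features are the means
                out[mask] = means[k - 1]
                continue
            try:
                chol = np.linalg.cholesky(covs[k - 1] + 0.0)
            except np.linalg.LinAlgError as exc:
                raise DataError(f"source {f}, class {k}: singular covariance") from exc
            z = rng.standard_normal((n, src.dims))
            out[mask] = means[k - 1] + z @ chol.T
        sid = f + 1
        spaces[sid] = out
        provenance[sid] = {"kind": "synthetic_gaussian", "source_index": f}
    stack = FeatureSpaceStack(spaces, provenance)

    scrib = np.zeros((h, w), dtype=np.int32)
    flat = lab.ravel()
    for k in range(1, spec.K + 1):
        idx = np.flatnonzero(flat == k)
        n_take = max(1, int(np.floor(spec.scribble_fraction * idx.size)))
        take = rng.choice(idx, size=n_take, replace=False)
        scrib.ravel()[take] = k
    return stack, LabelRaster(scrib, K=spec.K, role="scribble")


def generate_scene(spec: ScenarioSpec) -> tuple[LabelRaster, FeatureSpaceStack, LabelRaster]:
    """Convenience: ground truth, feature stack and scribbles in one call."""
    gt = generate_labels(spec)
    stack, scribbles = generate_sources(gt, spec)
    return gt, stack, scribbles


def mean_pairwise_separation(means: np.ndarray, cov: np.ndarray | float = 1.0) -> float:
    """Mean pairwise Mahalanobis distance between class means."""
    means = np.asarray(means, dtype=np.float64)
    d = means.shape[1]
    cov = np.eye(d) * cov if np.ndim(cov) == 0 else np.asarray(cov)
    inv = np.linalg.inv(cov)
    dists = []
    for i in range(len(means)):
        for j in range(i + 1, len(means)):
            diff = means[i] - means[j]
            dists.append(float(np.sqrt(diff @ inv @ diff)))
    return float(np.mean(dists))


# five well-spread base points in R^3 (vertices of the unit cube's
# corner tetrahedron plus its far corner); scaled to a target mean
# pairwise distance for each source
_BASE_MEANS = np.array(
    [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [1.0, 1.0, 1.0]]
)


def _scaled_means(target: float) -> tuple[tuple[float, ...], ...]:
    base = mean_pairwise_separation(_BASE_MEANS, 1.0)
    scaled = _BASE_MEANS * (target / base)
    return tuple(tuple(float(x) for x in row) for row in scaled)


def benchmark_default() -> ScenarioSpec:
    """The frozen benchmark: 128 x 128, K=5, one strong + one weak source.

    Source A has mean pairwise Mahalanobis separation 3 (well separated),
    source B separation 1 (weak); both isotropic unit covariance.  Seed 0,
    5% scribbles, 25 Voronoi regions.  Byte-identical across calls.
    """
    return ScenarioSpec(
        shape=(128, 128),
        K=5,
        region_model="voronoi",
        n_regions=25,
        sources=(
            SourceSpec(dims=3, class_means=_scaled_means(3.0), class_cov=1.0),
            SourceSpec(dims=3, class_means=_scaled_means(1.0), class_cov=1.0),
        ),
        scribble_fraction=0.05,
        seed=0,
    )


def write_scene(spec: ScenarioSpec, out_dir: str | Path) -> dict:
    """Materialize a scene on disk (NPZ rasters + spec JSON); returns paths."""
    from .raster_io import write_label_raster

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gt, stack, scribbles = generate_scene(spec)
    paths = {
        "groundtruth": str(write_label_raster(gt, out_dir / "groundtruth.npz")),
        "scribbles": str(write_label_raster(scribbles, out_dir / "scribbles.npz")),
        "spec": str(out_dir / "scenario.json"),
    }
    np.savez_compressed(
        out_dir / "features.npz",
        **{f"space_{sid}": stack.spaces[sid] for sid in stack.space_ids},
    )
    paths["features"] = str(out_dir / "features.npz")
    (out_dir / "scenario.json").write_text(spec.to_json())
    return paths


def read_scene_features(path: str | Path) -> FeatureSpaceStack:
    """Re-read a feature stack written by :func:`write_scene`."""
    with np.load(path) as z:
        spaces = {
            int(name.split("_")[1]): np.asarray(z[name])
            for name in z.files
            if name.startswith("space_")
        }
    return FeatureSpaceStack(
        spaces,
        {sid: {"kind": "synthetic_gaussian", "source_index": sid - 1} for sid in spaces},
    )
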