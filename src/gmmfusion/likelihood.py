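"""Histogram likelihoods trained from expert scribbles.

For every source (feature space) f and class k a normalized d-dim
histogram h_f(x; k) is built from the scribbled pixels of class k,
Σ_x h_f(x; k) = 1.  At segmentation time the per-pixel likelihood over
classes is obtained by normalizing the histogram values across classes,

    v_k^f(r) = h_f(x_f(r); k) / Σ_j h_f(x_f(r); j),

so each pixel carries one probability vector per source.  Histograms
are deliberately capped at d <= 3: avoiding higher-dimensional density
estimation is the point of fusing several low-dimensional sources.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DataError
from .features import FeatureSpaceStack
from .raster_io import LabelRaster, RunConfig


@dataclass
class SourceHistogram:
    """Trained histogram for one source: edges plus per-class masses."""

    space_id: int
    bin_edges: list[np.ndarray]          # one strictly increasing array per dim
    mass: np.ndarray                     # (K,) + (bins,)*d, sums to 1 per class

    @property
    def ndim(self) -> int:
        return len(self.bin_edges)


@dataclass
class ClassHistogramSet:
    """Per-source, per-class normalized histograms with their provenance."""

    sources: dict[int, SourceHistogram]
    K: int
    smoothing_eps: float
    provenance: dict = field(default_factory=dict)

    @property
    def space_ids(self) -> tuple[int, ...]:
        return tuple(sorted(self.sources))


def bins_for_sample_size(n: int, d: int) -> int:
    """Bins per dimension so a class's n training points give about one
    expected count per occupied cell: floor(n**(1/d)), clipped to [2, 256]
    (256 matching the dynamic range of 8-bit imagery).

    The package default of 32 bins/dim suits dense scene-scale training
    sets (8-bit imagery, thousands of scribbles per class); for small
    synthetic scenes this rule keeps histograms honest — badly
    undersampled histograms turn into single-class deltas whose zero
    uncertainty defeats uncertainty-based fusion.
    """
    if n < 1 or d < 1:
        raise DataError(f"need n >= 1 and d >= 1, got n={n}, d={d}")
    return int(np.clip(np.floor(n ** (1.0 / d)), 2, 256))


def _bin_index(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Map values to bin indices 0..nbins-1, clamping out-of-range values."""
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


def fit_histograms(
    stack: FeatureSpaceStack,
    scribbles: LabelRaster,
    cfg: RunConfig | None = None,
) -> ClassHistogramSet:
    """Train per-source, per-class histograms from scribbled pixels.

    Bin ranges come from the scribbled pixels' min/max per dimension
    (shared across classes so bins align); ``cfg.smoothing_eps`` mass is
    added to every cell before normalization.  Every class 1..K must
    have at least one scribbled pixel.
    """
    cfg = cfg or RunConfig()
    if stack.shape != scribbles.shape:
        raise DataError(
            f"feature stack shape {stack.shape} != scribble shape {scribbles.shape}"
        )
    K = scribbles.K
    lab = scribbles.labels
    for k in range(1, K + 1):
        if not (lab == k).any():
            raise DataError(f"class {k} has no scribbled pixels; cannot train its histogram")

    nbins = cfg.bins_per_dim
    sources: dict[int, SourceHistogram] = {}
    mask = lab > 0
    for sid in stack.space_ids:
        feats = stack.spaces[sid]
        d = feats.shape[2]
        if d > 3:
            raise DataError(
                f"space {sid} is {d}-dimensional; histograms are limited to d <= 3"
            )
        train = feats[mask]                      # (n, d)
        edges = []
        for dim in range(d):
            lo = float(train[:, dim].min())
            hi = float(train[:, dim].max())
            if hi <= lo:                          # constant feature: widen minimally
                lo, hi = lo - 0.5, hi + 0.5
            edges.append(np.linspace(lo, hi, nbins + 1))
        mass = np.empty((K,) + (nbins,) * d)
        for k in range(1, K + 1):
            pts = feats[lab == k]
            idx = tuple(_bin_index(pts[:, dim], edges[dim]) for dim in range(d))
            counts = np.zeros((nbins,) * d)
            np.add.at(counts, idx, 1.0)
            counts += cfg.smoothing_eps
            total = counts.sum()
            mass[k - 1] = counts / total if total > 0 else counts
        sources[sid] = SourceHistogram(sid, edges, mass)

    prov = {sid: _space_signature(stack, sid) for sid in stack.space_ids}
    return ClassHistogramSet(sources, K=K, smoothing_eps=cfg.smoothing_eps, provenance=prov)


def _space_signature(stack: FeatureSpaceStack, sid: int) -> dict:
    info = dict(stack.provenance.get(sid, {}))
    info.pop("pca", None)  # frozen fit object, not JSON-comparable
    return {"space_id": sid, "dims": int(stack.spaces[sid].shape[2]), **info}


def evaluate_likelihood(
    hists: ClassHistogramSet,
    stack: FeatureSpaceStack,
    check_provenance: bool = True,
) -> list[np.ndarray]:
    """Per-pixel class likelihood fields, one ``H x W x K`` array per source.

    Features outside the trained range are clamped to edge bins.  Where
    all classes have zero mass (possible only with smoothing_eps = 0)
    the likelihood falls back to the uniform distribution 1/K.
    """
    if set(stack.space_ids) != set(hists.space_ids):
        raise DataError(
            f"stack spaces {stack.space_ids} do not match trained spaces {hists.space_ids}"
        )
    fields: list[np.ndarray] = []
    for sid in hists.space_ids:
        sh = hists.sources[sid]
        feats = stack.spaces[sid]
        if feats.shape[2] != sh.ndim:
            raise DataError(
                f"space {sid}: stack has {feats.shape[2]} dims, histogram trained on {sh.ndim}"
            )
        if check_provenance:
            got = json.dumps(_space_signature(stack, sid), sort_keys=True)
            want = json.dumps(hists.provenance.get(sid, {}), sort_keys=True)
            if hists.provenance.get(sid) and got != want:
                raise DataError(
                    f"space {sid} provenance mismatch between stack and trained histograms"
                )
        h, w, d = feats.shape
        idx = tuple(
            _bin_index(feats[:, :, dim].ravel(), sh.bin_edges[dim]) for dim in range(d)
        )
        per_class = sh.mass[(slice(None),) + idx]        # (K, H*W)
        total = per_class.sum(axis=0)
        v = np.where(total > 0, per_class / np.where(total > 0, total, 1.0), 1.0 / hists.K)
        fields.append(np.moveaxis(v, 0, -1).reshape(h, w, hists.K))
    return fields


# ---------------------------------------------------------------------------
# model serialization
# ---------------------------------------------------------------------------

def save_model(hists: ClassHistogramSet, path: str | Path) -> Path:
    """Serialize a trained model (edges, masses, provenance) to one NPZ."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload: dict[str, np.ndarray] = {
        "meta": np.array(
            json.dumps(
                {
                    "K": hists.K,
                    "smoothing_eps": hists.smoothing_eps,
                    "space_ids": list(hists.space_ids),
                    "provenance": hists.provenance,
                }
            )
        )
    }
    for sid, sh in hists.sources.items():
        payload[f"mass_{sid}"] = sh.mass
        for dim, e in enumerate(sh.bin_edges):
            payload[f"edges_{sid}_{dim}"] = e
    np.savez_compressed(path, **payload)
    return path


def load_model(path: str | Path) -> ClassHistogramSet:
    path = Path(path)
    if not path.exists():
        raise DataError(f"model file not found: {path}")
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        sources = {}
        for sid in meta["space_ids"]:
            mass = np.asarray(z[f"mass_{sid}"])
            d = mass.ndim - 1
            edges = [np.asarray(z[f"edges_{sid}_{dim}"]) for dim in range(d)]
            sources[int(sid)] = SourceHistogram(int(sid), edges, mass)
    prov = {int(k): v for k, v in meta["provenance"].items()}
    return ClassHistogramSet(
        sources, K=int(meta["K"]), smoothing_eps=float(meta["smoothing_eps"]), provenance=prov
    )
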