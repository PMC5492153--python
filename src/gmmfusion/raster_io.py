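"""Raster I/O, lattice conventions and run configuration.

All modules share the conventions fixed here: arrays are indexed
``(row, col)`` with 0-based row-major order and pixel ``(0, 0)`` at the
top-left; multi-band imagery is an ``H x W x B`` float array with a role
map naming which band is blue/green/red/nir/..., mirroring the Landsat-5
TM band set (TM1..TM5, TM7 plus the thermal TM6).

Two container formats are supported.  TIFF (via :mod:`tifffile`) is the
interchange format for imagery, label maps and probability fields; the
NPZ array container is the documented fallback that additionally carries
the band-role map and an opaque georeferencing payload in one file, so
tests and synthetic runs need no GIS stack.  Georeferencing is carried
through unchanged and never interpreted: the segmentation models are
georeferencing-agnostic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigError, DataError

#: Recognised band roles (Landsat-5 TM order: TM1..TM7).
BAND_ROLES = ("blue", "green", "red", "nir", "mir1", "tir", "mir2")

LABEL_ROLES = ("scribble", "groundtruth", "prediction")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class MultiBandImage:
    """``H x W x B`` image with named band roles.

    Parameters
    ----------
    data
        Band values, cast to float64; every value must be finite.
    band_roles
        Map from role name (subset of :data:`BAND_ROLES`) to band index.
    crs_and_transform
        Opaque georeferencing payload, carried through unchanged.
    """

    data: np.ndarray
    band_roles: dict[str, int] = field(default_factory=dict)
    crs_and_transform: object | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise DataError(f"image data must be H x W x B, got shape {self.data.shape}")
        h, w, b = self.data.shape
        if h < 1 or w < 1 or b < 1:
            raise DataError(f"degenerate image shape {self.data.shape}")
        _reject_nonfinite(self.data, "image")
        seen: dict[int, str] = {}
        for role, idx in self.band_roles.items():
            if role not in BAND_ROLES:
                raise DataError(f"unknown band role {role!r}; expected one of {BAND_ROLES}")
            if not 0 <= int(idx) < b:
                raise DataError(
                    f"band role {role!r} maps to band {idx} but image has only {b} bands"
                )
            if int(idx) in seen:
                raise DataError(
                    f"band roles {seen[int(idx)]!r} and {role!r} both map to band {idx}"
                )
            seen[int(idx)] = role

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band(self, role: str) -> np.ndarray:
        """Return the ``H x W`` plane for a named role."""
        if role not in self.band_roles:
            raise DataError(f"band role {role!r} not declared for this image")
        return self.data[:, :, self.band_roles[role]]


@dataclass
class LabelRaster:
    """``H x W`` integer label map.

    ``0`` means "unlabeled" and is legal only for scribbles and ground
    truth; predictions must label every site with a class in ``1..K``.
    """

    labels: np.ndarray
    K: int
    role: str = "scribble"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.all(self.labels == np.round(self.labels)):
                raise DataError("label raster contains non-integer values")
            self.labels = self.labels.astype(np.int32)
        self.labels = self.labels.astype(np.int32)
        if self.labels.ndim != 2:
            raise DataError(f"label raster must be 2-D, got shape {self.labels.shape}")
        if self.role not in LABEL_ROLES:
            raise DataError(f"unknown label role {self.role!r}")
        if self.K < 1:
            raise DataError("K must be >= 1")
        lo, hi = int(self.labels.min()), int(self.labels.max())
        if hi > self.K:
            raise DataError(f"label value {hi} exceeds K={self.K}")
        if lo < 0:
            raise DataError(f"negative label value {lo}")
        if self.role == "prediction" and lo == 0:
            raise DataError("prediction rasters may not contain unlabeled (0) sites")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def class_counts(self) -> dict[int, int]:
        """Pixel count per label value actually present (including 0)."""
        vals, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}


@dataclass(frozen=True)
class Lattice:
    """Pixel lattice with 4- or 8-connectivity, no padding or wraparound."""

    shape: tuple[int, int]
    connectivity: int = 4

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise ConfigError(f"connectivity must be 4 or 8, got {self.connectivity}")
        if self.shape[0] < 1 or self.shape[1] < 1:
            raise ConfigError(f"degenerate lattice shape {self.shape}")

    def neighbors(self, i: int, j: int) -> Iterator[tuple[int, int]]:
        """Yield the neighbors of site ``(i, j)``; border sites have fewer."""
        h, w = self.shape
        offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        if self.connectivity == 8:
            offs += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
        for di, dj in offs:
            ni, nj = i + di, j + dj
            if 0 <= ni < h and 0 <= nj < w:
                yield ni, nj


@dataclass
class RunConfig:
    """Parameters shared by training and the three solvers.

    ``lambda_reg`` is the smoothing strength λ of the quadratic coupling
    between neighboring probability vectors; ``mu_data`` controls how
    sharply per-source uncertainty translates into data weights
    (ω_fs = μ/(μ+U_f)); ``mu_edge`` plays the same role for the edge
    weights ω_rs = μ/(μ+‖u(r)−u(s)‖²).  Both μ default to 1, λ to 2.
    """

    lambda_reg: float = 2.0
    mu_data: float = 1.0
    mu_edge: float = 1.0
    tol: float = 1e-6
    max_sweeps: int = 200
    bins_per_dim: int = 32
    smoothing_eps: float = 1e-6
    connectivity: int = 4
    seed: int = 0
    space_combination: tuple[int, ...] = (1, 3)

    def __post_init__(self) -> None:
        if self.lambda_reg <= 0:
            raise ConfigError(f"lambda_reg must be > 0, got {self.lambda_reg}")
        if self.mu_data <= 0:
            raise ConfigError(f"mu_data must be > 0, got {self.mu_data}")
        if self.mu_edge <= 0:
            raise ConfigError(f"mu_edge must be > 0, got {self.mu_edge}")
        if self.tol <= 0:
            raise ConfigError("tol must be > 0")
        if self.max_sweeps < 1:
            raise ConfigError("max_sweeps must be >= 1")
        if self.bins_per_dim < 1:
            raise ConfigError("bins_per_dim must be >= 1")
        if self.smoothing_eps < 0:
            raise ConfigError("smoothing_eps must be >= 0")
        if self.connectivity not in (4, 8):
            raise ConfigError(f"connectivity must be 4 or 8, got {self.connectivity}")
        self.space_combination = tuple(int(s) for s in self.space_combination)
        if any(s not in (1, 2, 3) for s in self.space_combination):
            raise ConfigError(
                f"space_combination must be a subset of {{1,2,3}}, got {self.space_combination}"
            )

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ConfigError(f"unknown config keys: {sorted(extra)}")
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, Mapping):
            raise ConfigError(f"config file {path} does not hold a mapping")
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["space_combination"] = list(self.space_combination)
        return d

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _reject_nonfinite(arr: np.ndarray, what: str) -> None:
    bad = ~np.isfinite(arr)
    if bad.any():
        n = int(bad.sum())
        first = tuple(int(x) for x in np.argwhere(bad)[0])
        raise DataError(f"{what} contains {n} non-finite values; first at index {first}")


def _require(path: str | Path) -> Path:
    path = Path(path)
    if not path.exists():
        raise DataError(f"file not found: {path}")
    return path


def read_image(path: str | Path, band_roles: Mapping[str, int] | None = None) -> MultiBandImage:
    """Read a multi-band raster as a :class:`MultiBandImage`.

    ``.npz`` containers carry their own role map and georeferencing
    payload; for TIFF the roles come from ``band_roles`` or from a
    ``<name>.roles.json`` sidecar written by :func:`write_image`.
    """
    path = _require(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            data = np.asarray(z["data"], dtype=np.float64)
            roles = json.loads(str(z["band_roles"])) if "band_roles" in z else {}
            transform = json.loads(str(z["transform"])) if "transform" in z else None
        if band_roles is not None:
            roles = dict(band_roles)
    else:
        import tifffile

        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None, :, :]
        data = np.moveaxis(np.asarray(arr, dtype=np.float64), 0, -1)  # pages are bands
        roles = dict(band_roles) if band_roles is not None else {}
        sidecar = path.with_suffix(path.suffix + ".roles.json")
        if band_roles is None and sidecar.exists():
            roles = json.loads(sidecar.read_text())
        transform = None
    return MultiBandImage(data, {k: int(v) for k, v in roles.items()}, transform)


def write_image(img: MultiBandImage, path: str | Path) -> Path:
    """Write a :class:`MultiBandImage`; format chosen by extension."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".npz":
        np.savez_compressed(
            path,
            data=img.data,
            band_roles=np.array(json.dumps(img.band_roles)),
            transform=np.array(json.dumps(img.crs_and_transform)),
        )
    else:
        import tifffile

        tifffile.imwrite(path, np.moveaxis(img.data, -1, 0).astype(np.float32), photometric="minisblack")
        path.with_suffix(path.suffix + ".roles.json").write_text(json.dumps(img.band_roles))
    return path


def read_label_raster(path: str | Path, K: int, role: str = "scribble") -> LabelRaster:
    """Read a single-band integer raster and validate labels against 0..K."""
    path = _require(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            labels = np.asarray(z["labels"])
    elif path.suffix == ".png":
        import imageio.v3 as iio

        labels = np.asarray(iio.imread(path))
    else:
        import tifffile

        labels = np.asarray(tifffile.imread(path))
    if labels.ndim != 2:
        raise DataError(f"label raster must be single-band 2-D, got shape {labels.shape}")
    return LabelRaster(labels, K=K, role=role)


def write_label_raster(raster: LabelRaster, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".npz":
        np.savez_compressed(path, labels=raster.labels)
    elif path.suffix == ".png":
        import imageio.v3 as iio

        if raster.K > 255:
            raise DataError("PNG label rasters support K <= 255 only")
        iio.imwrite(path, raster.labels.astype(np.uint8))
    else:
        import tifffile

        tifffile.imwrite(path, raster.labels.astype(np.int32), photometric="minisblack")
    return path


def read_probability_raster(path: str | Path) -> np.ndarray:
    """Read an ``H x W x K`` probability field written by :func:`write_outputs`."""
    path = _require(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            return np.asarray(z["p"], dtype=np.float64)
    import tifffile

    arr = np.asarray(tifffile.imread(path), dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None]
    return np.moveaxis(arr, 0, -1)


def write_outputs(
    p: np.ndarray,
    s: LabelRaster,
    out_dir: str | Path,
    cfg: RunConfig | None = None,
    fmt: str = "tif",
    extra: Mapping | None = None,
) -> dict:
    """Write a segmentation result: label map, probability field, manifest.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    p = np.asarray(p, dtype=np.float64)
    if p.shape[:2] != s.shape:
        raise DataError(f"probability field shape {p.shape[:2]} != label shape {s.shape}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    label_path = out_dir / f"labels.{fmt}"
    write_label_raster(s, label_path)
    prob_path = out_dir / f"probabilities.{fmt}"
    if fmt == "npz":
        np.savez_compressed(prob_path, p=p)
    else:
        import tifffile

        tifffile.imwrite(prob_path, np.moveaxis(p, -1, 0).astype(np.float32), photometric="minisblack")

    manifest = {
        "files": {"labels": label_path.name, "probabilities": prob_path.name},
        "K": s.K,
        "shape": list(s.shape),
        "config": cfg.to_dict() if cfg is not None else None,
        "config_hash": cfg.digest() if cfg is not None else None,
        "seed": cfg.seed if cfg is not None else None,
    }
    if extra:
        manifest.update(dict(extra))
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
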