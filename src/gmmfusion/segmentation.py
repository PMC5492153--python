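"""Probabilistic segmentation solvers on the pixel lattice.

Three models of increasing generality, all quadratic in the per-pixel
probability vectors p(r) and all solved by in-place Gauss-Seidel:

* the classic Gauss-Markov measure-field model, whose data term ties
  p(r) to a single likelihood field v(r) and whose smoothness term
  couples neighbors with strength λ;
* the lowest-entropy predecessor, which per pixel hard-selects the
  source whose likelihood distribution has minimal uncertainty and then
  runs the classic model on the selected field;
* the fusion model, which soft-weights every source by its uncertainty
  (ω_fs = μ/(μ + U_f), normalized over sources), smooths against the
  resulting mixture field u(r) = Σ_f ω_f(r) v^f(r), and modulates each
  lattice edge by ω_rs = μ/(μ + ‖u(r) − u(s)‖²) so smoothing weakens
  across probable class boundaries.

Because the per-class Gauss-Seidel update is a convex combination with
class-independent coefficients, simplex-valued inputs yield
simplex-valued iterates and fixed points: no projection is needed.
Energies are evaluated with each unordered lattice edge counted once,
the quadratic for which the update is exact coordinate minimization,
hence monotonically non-increasing sweep by sweep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from ._sweeps import gs_sweep
from .errors import ConfigError, DataError
from .raster_io import LabelRaster, Lattice, RunConfig

UncertaintyFn = Callable[[np.ndarray], np.ndarray]


# ---------------------------------------------------------------------------
# uncertainty measures
# ---------------------------------------------------------------------------

def gini_impurity(dist: np.ndarray) -> np.ndarray:
    """Gini impurity 1 − fᵀf of simplex vectors along the last axis.

    0 for a delta distribution, 1 − 1/K for the uniform one.  Inputs are
    renormalized internally; entries below −1e-6 are rejected.
    """
    dist = np.asarray(dist, dtype=np.float64)
    if dist.min() < -1e-6:
        raise DataError(f"distribution has negative entries (min {dist.min():.3g})")
    dist = np.clip(dist, 0.0, None)
    total = dist.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise DataError("distribution sums to zero")
    f = dist / total
    return 1.0 - np.einsum("...k,...k->...", f, f)


def shannon_uncertainty(dist: np.ndarray) -> np.ndarray:
    """Shannon entropy normalized by log K, so the range is [0, 1]."""
    dist = np.asarray(dist, dtype=np.float64)
    dist = np.clip(dist, 0.0, None)
    total = dist.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise DataError("distribution sums to zero")
    f = dist / total
    K = f.shape[-1]
    if K == 1:
        return np.zeros(f.shape[:-1])
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(f > 0, np.log(f), 0.0)
    return -(f * logs).sum(axis=-1) / np.log(K)


UNCERTAINTY_MEASURES: dict[str, UncertaintyFn] = {
    "gini": gini_impurity,
    "shannon": shannon_uncertainty,
}


def _resolve_measure(measure: str | UncertaintyFn) -> UncertaintyFn:
    if callable(measure):
        return measure
    try:
        return UNCERTAINTY_MEASURES[measure]
    except KeyError:
        raise ConfigError(
            f"unknown uncertainty measure {measure!r}; known: {sorted(UNCERTAINTY_MEASURES)}"
        ) from None


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ProbabilityField:
    """Converged probability field plus solver diagnostics."""

    p: np.ndarray
    iterations_run: int
    final_delta: float
    energy_trace: list[float] = field(default_factory=list)
    converged: bool = True

    @property
    def shape(self) -> tuple[int, int]:
        return self.p.shape[:2]

    @property
    def K(self) -> int:
        return self.p.shape[2]


@dataclass
class FusionState:
    """Inspectable intermediates of the fusion model.

    ``U`` stacks the per-source uncertainty maps (F x H x W);
    ``w_data_raw`` the unnormalized ω_fs, ``w_data`` the per-pixel
    normalized ω_f (summing to 1 over sources); ``u`` the mixture
    field; ``w_edge`` the per-direction edge-weight arrays as used by
    the sweep kernel.
    """

    U: np.ndarray
    w_data_raw: np.ndarray
    w_data: np.ndarray
    u: np.ndarray
    w_edge: dict[str, np.ndarray] | None = None


def _check_simplex(v: np.ndarray, what: str, tol: float = 1e-6) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    if v.ndim != 3:
        raise DataError(f"{what} must be H x W x K, got shape {v.shape}")
    if v.min() < -tol:
        raise DataError(f"{what} has negative entries (min {v.min():.3g})")
    err = np.abs(v.sum(axis=-1) - 1.0).max()
    if err > 1e-4:
        raise DataError(f"{what} rows deviate from the simplex by {err:.3g}")
    return v


def _stack_list(v_list: Sequence[np.ndarray], what: str) -> list[np.ndarray]:
    if len(v_list) < 1:
        raise DataError(f"{what}: need at least one likelihood field")
    out = [_check_simplex(v, f"{what} source {i}") for i, v in enumerate(v_list)]
    shapes = {v.shape for v in out}
    if len(shapes) != 1:
        raise DataError(f"{what}: sources disagree on shape: {shapes}")
    return out


# ---------------------------------------------------------------------------
# energies (each unordered edge counted once)
# ---------------------------------------------------------------------------

def _unit_edge_weights(shape: tuple[int, int]) -> dict[str, np.ndarray]:
    h, w = shape
    return {
        "v": np.ones((max(h - 1, 0), w)),
        "h": np.ones((h, max(w - 1, 0))),
        "d1": np.ones((max(h - 1, 0), max(w - 1, 0))),
        "d2": np.ones((max(h - 1, 0), max(w - 1, 0))),
    }


def _smoothness_energy(p: np.ndarray, w_edge: dict[str, np.ndarray], connectivity: int) -> float:
    e = 0.0
    dv = ((p[1:] - p[:-1]) ** 2).sum(-1)
    e += float((w_edge["v"] * dv).sum())
    dh = ((p[:, 1:] - p[:, :-1]) ** 2).sum(-1)
    e += float((w_edge["h"] * dh).sum())
    if connectivity == 8:
        d1 = ((p[1:, 1:] - p[:-1, :-1]) ** 2).sum(-1)
        e += float((w_edge["d1"] * d1).sum())
        d2 = ((p[1:, :-1] - p[:-1, 1:]) ** 2).sum(-1)
        e += float((w_edge["d2"] * d2).sum())
    return e


def gmmf_energy(p: np.ndarray, v: np.ndarray, lam: float, connectivity: int = 4) -> float:
    """Quadratic objective of the classic model (edges counted once)."""
    data = float(((p - v) ** 2).sum())
    return data + lam * _smoothness_energy(p, _unit_edge_weights(p.shape[:2]), connectivity)


def fusion_energy(
    p: np.ndarray,
    v_list: Sequence[np.ndarray],
    w_data: np.ndarray,
    w_edge: dict[str, np.ndarray],
    lam: float,
    connectivity: int = 4,
) -> float:
    """Objective of the fusion model: Σ_f ω_f(p−v^f)² + λ Σ_edges ω_rs(p(r)−p(s))²."""
    data = 0.0
    for f, v in enumerate(v_list):
        data += float((w_data[f] * ((p - v) ** 2).sum(-1)).sum())
    return data + lam * _smoothness_energy(p, w_edge, connectivity)


# ---------------------------------------------------------------------------
# fusion intermediates
# ---------------------------------------------------------------------------

def fusion_weights(
    v_list: Sequence[np.ndarray],
    mu_data: float,
    measure: str | UncertaintyFn = "gini",
) -> FusionState:
    """Uncertainty maps and normalized per-source data weights.

    ω_fs(r) = μ/(μ + U_f(r)); ω_f(r) = ω_fs(r)/Σ_f ω_fs(r).  Large μ
    drives all weights to 1/N_f; small μ weights sources by inverse
    uncertainty, approaching hard selection where the best source's
    uncertainty is near zero.
    """
    if mu_data <= 0:
        raise ConfigError("mu_data must be > 0")
    fn = _resolve_measure(measure)
    v_list = _stack_list(v_list, "fusion_weights")
    U = np.stack([fn(v) for v in v_list])            # (F, H, W)
    if U.min() < -1e-9 or U.max() > 1.0 + 1e-9:
        raise DataError(f"uncertainty measure left [0,1]: range [{U.min()}, {U.max()}]")
    raw = mu_data / (mu_data + U)
    w = raw / raw.sum(axis=0, keepdims=True)
    state = FusionState(U=U, w_data_raw=raw, w_data=w, u=mixture_field(v_list, w))
    return state


def mixture_field(v_list: Sequence[np.ndarray], w_data: np.ndarray) -> np.ndarray:
    """Convex combination u_k(r) = Σ_f ω_f(r) v_k^f(r)."""
    v = np.stack(list(v_list))                        # (F, H, W, K)
    return np.einsum("fhw,fhwk->hwk", w_data, v)


def edge_weights(
    u: np.ndarray,
    mu_edge: float,
    lattice: Lattice | None = None,
    connectivity: int | None = None,
) -> dict[str, np.ndarray]:
    """Per-edge smoothing weights ω_rs = μ/(μ + ‖u(r) − u(s)‖²).

    ω_rs ∈ (0, 1], equal to 1 exactly when u(r) = u(s), and symmetric by
    construction (one value per unordered edge, stored in direction
    arrays: see :mod:`gmmfusion._sweeps`).
    """
    if mu_edge <= 0:
        raise ConfigError("mu_edge must be > 0")
    u = np.asarray(u, dtype=np.float64)
    conn = connectivity or (lattice.connectivity if lattice is not None else 4)
    w: dict[str, np.ndarray] = {}
    w["v"] = mu_edge / (mu_edge + ((u[1:] - u[:-1]) ** 2).sum(-1))
    w["h"] = mu_edge / (mu_edge + ((u[:, 1:] - u[:, :-1]) ** 2).sum(-1))
    if conn == 8:
        w["d1"] = mu_edge / (mu_edge + ((u[1:, 1:] - u[:-1, :-1]) ** 2).sum(-1))
        w["d2"] = mu_edge / (mu_edge + ((u[1:, :-1] - u[:-1, 1:]) ** 2).sum(-1))
    else:
        h_, w_ = u.shape[:2]
        w["d1"] = np.ones((max(h_ - 1, 0), max(w_ - 1, 0)))
        w["d2"] = np.ones((max(h_ - 1, 0), max(w_ - 1, 0)))
    return w


# ---------------------------------------------------------------------------
# solvers
# ---------------------------------------------------------------------------

def _iterate(
    u: np.ndarray,
    w_edge: dict[str, np.ndarray],
    cfg: RunConfig,
    energy_fn: Callable[[np.ndarray], float],
    p0: np.ndarray | None = None,
) -> ProbabilityField:
    p = np.ascontiguousarray((u if p0 is None else p0).copy())
    eight = cfg.connectivity == 8
    lam = float(cfg.lambda_reg)
    trace: list[float] = []
    delta = np.inf
    sweeps = 0
    for sweeps in range(1, cfg.max_sweeps + 1):
        delta = gs_sweep(
            p, u, lam,
            np.ascontiguousarray(w_edge["v"]), np.ascontiguousarray(w_edge["h"]),
            np.ascontiguousarray(w_edge["d1"]), np.ascontiguousarray(w_edge["d2"]),
            eight,
        )
        trace.append(energy_fn(p))
        if delta < cfg.tol:
            break
    converged = delta < cfg.tol
    if not converged:
        warnings.warn(
            f"Gauss-Seidel stopped at max_sweeps={cfg.max_sweeps} with delta={delta:.3g}",
            RuntimeWarning,
            stacklevel=3,
        )
    return ProbabilityField(
        p=p, iterations_run=sweeps, final_delta=float(delta),
        energy_trace=trace, converged=converged,
    )


def gmmf_solve(v: np.ndarray, cfg: RunConfig | None = None) -> ProbabilityField:
    """Classic single-source measure-field solve.

    Fixed point of p_k(r) = (v_k(r) + λ Σ_{s∈N_r} p_k(s)) / (1 + λ|N_r|),
    initialized at p⁰ = v, stopped at max-abs update < tol.
    """
    cfg = cfg or RunConfig()
    v = _check_simplex(v, "gmmf_solve likelihood")
    w_edge = _unit_edge_weights(v.shape[:2])
    return _iterate(
        v, w_edge, cfg, lambda p: gmmf_energy(p, v, cfg.lambda_reg, cfg.connectivity)
    )


def entropy_select(
    v_list: Sequence[np.ndarray],
    measure: str | UncertaintyFn = "gini",
    return_index: bool = False,
):
    """Per pixel, keep the likelihood of the least-uncertain source.

    Generalizes the two-source binary-weight rule to an argmin over all
    sources; ties go to the lowest source index (deterministic).
    """
    v_list = _stack_list(v_list, "entropy_select")
    if len(v_list) < 2:
        raise DataError("entropy_select needs at least two sources")
    fn = _resolve_measure(measure)
    U = np.stack([fn(v) for v in v_list])             # (F, H, W)
    pick = np.argmin(U, axis=0)                       # first minimum wins ties
    stacked = np.stack(v_list)                        # (F, H, W, K)
    sel = np.take_along_axis(stacked, pick[None, :, :, None], axis=0)[0]
    if return_index:
        return sel, pick
    return sel


def entropy_gmmf_solve(
    v_list: Sequence[np.ndarray],
    cfg: RunConfig | None = None,
    measure: str | UncertaintyFn = "gini",
) -> ProbabilityField:
    """Lowest-entropy predecessor model: select, then classic solve.

    With binary data weights the multi-source data term collapses to
    the selected likelihood, so this is exactly the classic solve on
    :func:`entropy_select`'s output.
    """
    return gmmf_solve(entropy_select(v_list, measure), cfg)


def fusion_solve(
    v_list: Sequence[np.ndarray],
    cfg: RunConfig | None = None,
    measure: str | UncertaintyFn = "gini",
) -> tuple[ProbabilityField, FusionState]:
    """Multi-source fusion solve.

    The uncertainty maps, data weights, mixture field and edge weights
    depend only on the likelihoods, so they are computed once; the
    Gauss-Seidel scheme
    p_k(r) = (u_k(r) + λ Σ_s ω_rs p_k(s)) / (1 + λ Σ_s ω_rs)
    then iterates from p⁰ = u until max-abs update < tol.
    """
    cfg = cfg or RunConfig()
    v_list = _stack_list(v_list, "fusion_solve")
    state = fusion_weights(v_list, cfg.mu_data, measure)
    state.w_edge = edge_weights(state.u, cfg.mu_edge, connectivity=cfg.connectivity)
    pf = _iterate(
        state.u,
        state.w_edge,
        cfg,
        lambda p: fusion_energy(
            p, v_list, state.w_data, state.w_edge, cfg.lambda_reg, cfg.connectivity
        ),
    )
    return pf, state


def winner_takes_all(p: ProbabilityField | np.ndarray) -> LabelRaster:
    """Label map s(r) = argmax_k p_k(r); ties go to the smallest class."""
    arr = p.p if isinstance(p, ProbabilityField) else np.asarray(p)
    arr = _check_simplex(arr, "winner_takes_all input")
    labels = np.argmax(arr, axis=-1).astype(np.int32) + 1
    return LabelRaster(labels, K=arr.shape[-1], role="prediction")
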