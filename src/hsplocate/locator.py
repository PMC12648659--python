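"""Locate a material in Hansen space from an absorbance-weighted solvent panel.

The estimator treats the HSPs of an unknown material M as the centroid of a
single cluster of test solvents, where each solvent i (at δS_i, with UV/vis
maximum absorbance w_i acting as a solubility score) pulls the centroid with
strength w_i. Formally it minimizes the total weighted Hansen distance

    f(δM) = Σ_i w_i · R_i(δM),        R_i = Hansen distance to solvent i,

i.e. computes a weighted geometric median (Fermat–Weber point) in the
anisotropic Hansen metric. Minimization is plain fixed-step gradient
descent,

    δM ← δM − α · ∇f(δM),

stopped when the Euclidean norm of the update drops below ``tol``
(default 0.005 MPa^1/2, α default 0.01), capped at ``max_iter`` steps.
The starting point comes from the squared-distance surrogate
Σ w_i² R_i²(δM), whose minimizer is available in closed form:

    δM_init = Σ w_i² δS_i / Σ w_i²     (component-wise).

Squaring removes the non-smoothness, and because the squared problem is a
weighted least-squares centroid its solution always lies inside the
component-wise bounding box of the panel — the optimization therefore starts
(and, for a convex objective, stays) in chemically plausible territory.
After each step the iterate is clamped to the non-negative orthant, the
minimal projection keeping predictions physically meaningful.

Note f is convex (a non-negatively weighted sum of norms of affine maps), so
every local minimum is global; :func:`multistart_validate` and
:func:`grid_oracle` provide independent confirmation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .core import HANSEN_SCALE, HspVector, as_hsp
from .database import SolventDatabase
from .errors import (
    DegenerateWeightsError,
    GridTooLargeError,
    InvalidInputError,
    SchemaError,
)

__all__ = [
    "AbsorbanceMeasurement",
    "MeasurementSet",
    "LocatorConfig",
    "LocateResult",
    "MultistartReport",
    "DEFAULT_BOUNDS",
    "build_weights",
    "analytic_init",
    "objective",
    "gradient",
    "locate",
    "grid_oracle",
    "multistart_validate",
    "load_measurements",
]

logger = logging.getLogger(__name__)

#: Default Hansen-space box for random starts and synthetic materials:
#: spans the recommended candidate-solvent ranges (δD 14–19, δP 0–18,
#: δH 0–42 MPa^1/2) with a little headroom.
DEFAULT_BOUNDS: Tuple[Tuple[float, float], ...] = ((14.0, 20.0), (0.0, 19.0), (0.0, 43.0))

Bounds = Sequence[Tuple[float, float]]


@dataclass(frozen=True)
class AbsorbanceMeasurement:
    """One panel entry: a solvent, its HSPs and the measured max absorbance (AU).

    ``lambda_max`` (nm) is carried as metadata only; it never enters the
    estimate. Absorbances must be read consistently from the same
    absorption band across the panel — that is the user's responsibility.
    """

    solvent: str
    absorbance: float
    hsp: HspVector
    lambda_max: Optional[float] = None

    def __post_init__(self) -> None:
        a = float(self.absorbance)
        if not math.isfinite(a) or a < 0:
            raise InvalidInputError(
                f"absorbance for {self.solvent!r} must be finite and >= 0, got {self.absorbance!r}"
            )
        object.__setattr__(self, "absorbance", a)


@dataclass(frozen=True)
class MeasurementSet:
    """The user's solvent panel with resolved HSPs."""

    measurements: Tuple[AbsorbanceMeasurement, ...]

    def __post_init__(self) -> None:
        ms = tuple(self.measurements)
        object.__setattr__(self, "measurements", ms)
        if len(ms) < 1:
            raise InvalidInputError("a measurement set needs at least one measurement")
        seen = {}
        for m in ms:
            k = m.solvent.strip().lower()
            if k in seen:
                raise InvalidInputError(f"duplicate solvent {m.solvent!r} in measurement set")
            seen[k] = m

    @property
    def n(self) -> int:
        return len(self.measurements)

    @property
    def solvents(self) -> Tuple[str, ...]:
        return tuple(m.solvent for m in self.measurements)

    def weight_vector(self) -> np.ndarray:
        return np.array([m.absorbance for m in self.measurements])

    def hsp_matrix(self) -> np.ndarray:
        return np.array([[m.hsp.dD, m.hsp.dP, m.hsp.dH] for m in self.measurements])


@dataclass(frozen=True)
class LocatorConfig:
    """Optimizer settings.

    alpha
        learning rate of the fixed-step descent (default 0.01).
    tol
        convergence threshold on ‖Δ‖₂, MPa^1/2 (default 0.005).
    max_iter
        iteration cap (default 10,000).
    eps_guard
        distance floor: a panel term with R_i below this contributes a zero
        (sub)gradient, the valid subgradient choice at the kink.
    init
        ``"analytic"`` (closed-form squared-cost start, default),
        ``"random"`` (uniform in ``bounds``, driven by ``seed``), or an
        explicit :class:`HspVector` / 3-sequence.
    """

    alpha: float = 0.01
    tol: float = 0.005
    max_iter: int = 10_000
    eps_guard: float = 1e-9
    init: Union[str, HspVector, Sequence[float]] = "analytic"
    bounds: Bounds = DEFAULT_BOUNDS
    seed: Optional[int] = None
    record_trajectory: bool = False

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise InvalidInputError(f"alpha must be > 0, got {self.alpha}")
        if not self.tol > 0:
            raise InvalidInputError(f"tol must be > 0, got {self.tol}")
        if self.max_iter < 1:
            raise InvalidInputError(f"max_iter must be >= 1, got {self.max_iter}")
        if not self.eps_guard > 0:
            raise InvalidInputError(f"eps_guard must be > 0, got {self.eps_guard}")
        if isinstance(self.init, str):
            if self.init not in ("analytic", "random"):
                raise InvalidInputError(f"unknown init mode {self.init!r}")
        else:
            object.__setattr__(self, "init", as_hsp(self.init))


@dataclass(frozen=True)
class LocateResult:
    """Outcome of :func:`locate`."""

    estimate: HspVector
    init: HspVector
    iterations: int
    converged: bool
    objective_value: float  # Σ w_i R_i at the estimate, MPa^1/2 (unnormalized)
    config: LocatorConfig
    trajectory: Optional[Tuple[Tuple[np.ndarray, float], ...]] = None

    @property
    def global_error(self) -> float:
        """The convergence threshold rounded to report precision (2 dp)."""
        return round(self.config.tol, 2)


# ---------------------------------------------------------------------------
# building blocks

def build_weights(ms: MeasurementSet) -> np.ndarray:
    """Raw absorbances in panel order.

    No normalization: the argmin of a weighted sum of distances is invariant
    under uniform positive scaling of the weights, so the raw values are
    canonical. All-zero weights carry no information and are rejected.
    """
    w = ms.weight_vector()
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise InvalidInputError("absorbance weights must be finite and >= 0")
    if not np.any(w > 0):
        raise DegenerateWeightsError("all absorbances are zero; panel carries no signal")
    return w


def _coerce_hsps(solvent_hsps) -> np.ndarray:
    arr = np.asarray(
        [[h.dD, h.dP, h.dH] if isinstance(h, HspVector) else list(h) for h in solvent_hsps],
        dtype=float,
    )
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise InvalidInputError(f"expected an (n, 3) HSP array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("solvent HSPs must be finite")
    return arr


def _check_lengths(weights: np.ndarray, hsps: np.ndarray) -> None:
    if len(weights) != len(hsps):
        raise InvalidInputError(
            f"{len(weights)} weights vs {len(hsps)} solvent HSP rows"
        )


def analytic_init(weights, solvent_hsps) -> HspVector:
    """Closed-form start: component-wise Σ w_i² δS_i / Σ w_i².

    Minimizer of the squared surrogate Σ w_i² R_i²; always inside the
    component-wise min/max box of the panel solvents.
    """
    w = np.asarray(weights, dtype=float)
    S = _coerce_hsps(solvent_hsps)
    _check_lengths(w, S)
    w2 = w**2
    tot = w2.sum()
    if tot <= 0:
        raise DegenerateWeightsError("all weights zero: analytic init undefined")
    return HspVector.from_array((w2[:, None] * S).sum(axis=0) / tot)


def _distances(point: np.ndarray, S: np.ndarray) -> np.ndarray:
    d = (point - S) * HANSEN_SCALE
    return np.sqrt((d * d).sum(axis=1))


def objective(point, weights, solvent_hsps) -> float:
    """Total weighted Hansen distance Σ w_i R_i(point), MPa^1/2 (convex)."""
    p = as_hsp(point).as_array() if not isinstance(point, np.ndarray) else np.asarray(point, float)
    w = np.asarray(weights, dtype=float)
    S = _coerce_hsps(solvent_hsps)
    _check_lengths(w, S)
    return float(w @ _distances(p, S))


def gradient(point, weights, solvent_hsps, eps_guard: float = 1e-9) -> np.ndarray:
    """∇ of the weighted-distance objective w.r.t. the material HSPs.

    Per solvent: w_i · (4(δD−δD_i), (δP−δP_i), (δH−δH_i)) / R_i. Terms with
    R_i < ``eps_guard`` contribute the zero vector — a valid subgradient at
    the kink, and the choice that makes a dominant-weight solvent an exact
    fixed point.
    """
    p = as_hsp(point).as_array() if not isinstance(point, np.ndarray) else np.asarray(point, float)
    if not np.all(np.isfinite(p)):
        raise InvalidInputError(f"non-finite iterate {p}")
    w = np.asarray(weights, dtype=float)
    S = _coerce_hsps(solvent_hsps)
    _check_lengths(w, S)
    d = p - S
    r = _distances(p, S)
    mask = r >= eps_guard
    g = np.zeros(3)
    if np.any(mask):
        coef = (w[mask] / r[mask])[:, None]
        terms = np.column_stack([4.0 * d[mask, 0], d[mask, 1], d[mask, 2]])
        g = (coef * terms).sum(axis=0)
    return g


# ---------------------------------------------------------------------------
# the estimator

def _resolve_init(cfg: LocatorConfig, w: np.ndarray, S: np.ndarray) -> np.ndarray:
    if isinstance(cfg.init, HspVector):
        return cfg.init.as_array()
    if cfg.init == "analytic":
        return analytic_init(w, S).as_array()
    # random
    rng = np.random.default_rng(cfg.seed)
    lo = np.array([b[0] for b in cfg.bounds], dtype=float)
    hi = np.array([b[1] for b in cfg.bounds], dtype=float)
    if np.any(hi < lo):
        raise InvalidInputError(f"empty bounds box {cfg.bounds}")
    return rng.uniform(lo, hi)


def locate(ms: MeasurementSet, cfg: Optional[LocatorConfig] = None) -> LocateResult:
    """Estimate the material's HSPs from an absorbance panel.

    Fixed-step gradient descent on the weighted-distance objective; each
    iterate is clamped to the non-negative orthant. Converged means the
    update norm ‖Δ‖₂ fell below ``cfg.tol`` within ``cfg.max_iter`` steps.
    Deterministic for analytic or explicit initialization.
    """
    cfg = cfg or LocatorConfig()
    w = build_weights(ms)
    S = ms.hsp_matrix()
    x0 = _resolve_init(cfg, w, S)
    x = np.maximum(x0, 0.0)
    traj: Optional[List[Tuple[np.ndarray, float]]] = [] if cfg.record_trajectory else None
    converged = False
    iterations = 0
    logger.debug("locate: init=%s alpha=%s tol=%s", x0, cfg.alpha, cfg.tol)
    for iterations in range(1, cfg.max_iter + 1):
        delta = -cfg.alpha * gradient(x, w, S, cfg.eps_guard)
        x = np.maximum(x + delta, 0.0)
        step = float(np.linalg.norm(delta))
        if traj is not None:
            traj.append((x.copy(), step))
        if iterations % 100 == 0:
            logger.debug(
                "locate: iter=%d objective=%.6f step=%.6g", iterations, objective(x, w, S), step
            )
        if step < cfg.tol:
            converged = True
            break
    result = LocateResult(
        estimate=HspVector.from_array(x),
        init=HspVector.from_array(x0),
        iterations=iterations,
        converged=converged,
        objective_value=objective(x, w, S),
        config=cfg,
        trajectory=tuple(traj) if traj is not None else None,
    )
    logger.info(
        "locate: %s after %d iterations, estimate=(%.4f, %.4f, %.4f), objective=%.4f",
        "converged" if converged else "hit max_iter",
        iterations, *x, result.objective_value,
    )
    return result


# ---------------------------------------------------------------------------
# validation oracles

def grid_oracle(
    weights,
    solvent_hsps,
    bounds: Bounds = DEFAULT_BOUNDS,
    step: float = 0.05,
    cell_cap: int = 60_000_000,
) -> HspVector:
    """Brute-force minimizer of the weighted-distance objective on a grid.

    Independent of the gradient path: evaluates the objective at every node
    of a regular grid over ``bounds`` and returns the best node, breaking
    exact ties by lexicographic (δD, δP, δH) order. Intended as a testing
    oracle, not production use. Grids above ``cell_cap`` nodes raise
    :class:`GridTooLargeError`.
    """
    if not step > 0:
        raise InvalidInputError(f"grid step must be > 0, got {step}")
    w = np.asarray(weights, dtype=float)
    S = _coerce_hsps(solvent_hsps)
    _check_lengths(w, S)
    axes = []
    for lo, hi in bounds:
        if hi < lo:
            raise InvalidInputError(f"empty bounds box {bounds}")
        axes.append(np.arange(lo, hi + step / 2, step))
    n_cells = axes[0].size * axes[1].size * axes[2].size
    if n_cells > cell_cap:
        raise GridTooLargeError(
            f"grid of {n_cells} cells exceeds cap {cell_cap}; shrink bounds or coarsen step"
        )
    dP_grid, dH_grid = np.meshgrid(axes[1], axes[2], indexing="ij")  # lexicographic (dP, dH)
    best_val = np.inf
    best_point: Optional[np.ndarray] = None
    for dD in axes[0]:  # ascending dD keeps the overall scan lexicographic
        obj = np.zeros_like(dP_grid)
        for wi, (sD, sP, sH) in zip(w, S):
            obj += wi * np.sqrt(
                4.0 * (dD - sD) ** 2 + (dP_grid - sP) ** 2 + (dH_grid - sH) ** 2
            )
        idx = int(np.argmin(obj))  # first occurrence = lexicographically smallest
        val = float(obj.flat[idx])
        if val < best_val:  # strict: earlier (smaller) points win ties
            i, j = divmod(idx, dH_grid.shape[1])
            best_val = val
            best_point = np.array([dD, axes[1][i], axes[2][j]])
    assert best_point is not None
    return HspVector.from_array(best_point)


@dataclass(frozen=True)
class MultistartReport:
    """Per-start outcomes of repeated random-init runs plus their dispersion."""

    starts: Tuple[LocateResult, ...]
    dispersion: float  # max pairwise Hansen distance among converged estimates
    all_converged: bool

    def agree(self, tol: float) -> bool:
        """True when every converged estimate lies within ``2·tol`` of the others."""
        return self.all_converged and self.dispersion <= 2.0 * tol


def multistart_validate(
    ms: MeasurementSet,
    cfg: Optional[LocatorConfig] = None,
    n_starts: int = 100,
    bounds: Bounds = DEFAULT_BOUNDS,
    seed: Optional[int] = None,
) -> MultistartReport:
    """Re-run :func:`locate` from ``n_starts`` uniform random points.

    Because the objective is convex, all converged runs must agree (up to
    the stopping tolerance); disagreement signals an implementation bug or
    a pathological panel. Reproducible for a fixed ``seed``.
    """
    if n_starts < 1:
        raise InvalidInputError(f"n_starts must be >= 1, got {n_starts}")
    cfg = cfg or LocatorConfig()
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if np.any(hi < lo):
        raise InvalidInputError(f"empty bounds box {bounds}")
    results = []
    for _ in range(n_starts):
        start = HspVector.from_array(rng.uniform(lo, hi))
        results.append(locate(ms, replace(cfg, init=start)))
    conv = [r for r in results if r.converged]
    dispersion = 0.0
    from .core import hansen_distance

    for i in range(len(conv)):
        for j in range(i + 1, len(conv)):
            dispersion = max(dispersion, hansen_distance(conv[i].estimate, conv[j].estimate))
    return MultistartReport(
        starts=tuple(results),
        dispersion=dispersion,
        all_converged=len(conv) == len(results),
    )


# ---------------------------------------------------------------------------
# measurement I/O

def load_measurements(path, db: Optional[SolventDatabase] = None) -> MeasurementSet:
    """Read a panel CSV: ``solvent,absorbance[,lambda_max][,dD,dP,dH]``.

    Rows with all three of dD/dP/dH present use those inline HSPs;
    otherwise the solvent key is resolved through ``db``.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    df.columns = [c.strip() for c in df.columns]
    for col in ("solvent", "absorbance"):
        if col not in df.columns:
            raise SchemaError(f"measurements file {path} is missing required column {col!r}")
    inline = all(c in df.columns for c in ("dD", "dP", "dH"))
    measurements = []
    for _, row in df.iterrows():
        key = str(row["solvent"]).strip()
        lam = row.get("lambda_max")
        lam = float(lam) if lam is not None and pd.notna(lam) else None
        if inline and pd.notna(row["dD"]) and pd.notna(row["dP"]) and pd.notna(row["dH"]):
            hsp = HspVector(float(row["dD"]), float(row["dP"]), float(row["dH"]))
        else:
            if db is None:
                raise InvalidInputError(
                    f"solvent {key!r} has no inline HSPs and no database was provided"
                )
            hsp = db.get(key).hsp
        measurements.append(
            AbsorbanceMeasurement(
                solvent=key, absorbance=float(row["absorbance"]), hsp=hsp, lambda_max=lam
            )
        )
    return MeasurementSet(tuple(measurements))


def write_measurements(ms: MeasurementSet, path) -> None:
    """Emit a panel CSV (inline HSPs included) consumable by :func:`load_measurements`."""
    rows = [
        {
            "solvent": m.solvent,
            "absorbance": m.absorbance,
            "lambda_max": m.lambda_max if m.lambda_max is not None else "",
            "dD": m.hsp.dD,
            "dP": m.hsp.dP,
            "dH": m.hsp.dH,
        }
        for m in ms.measurements
    ]
    pd.DataFrame(rows, columns=["solvent", "absorbance", "lambda_max", "dD", "dP", "dH"]).to_csv(
        path, index=False
    )
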