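"""Seeded synthetic materials and absorbance panels for recovery testing.

The estimator rests on two hypotheses about real measurements: a better
solvent (i) sits closer to the material in Hansen space and (ii) yields a
stronger UV/vis absorbance for the same aliquot of suspended material. The
generator here embodies exactly that structure with the simplest monotone
link — an exponential decay of absorbance in Hansen distance,

    A_i = max(floor, amplitude · exp(−R_i / τ) + ε_i),   ε_i ~ N(0, noise_sd²),

truncated below at ``floor`` (absorbance cannot be negative). It makes no
claim about real suspension photometrics (no Beer–Lambert pathlength or
concentration model, no band shapes, no scattering); it exists so that
parameter-recovery experiments have a known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .core import HspVector, as_hsp, hansen_distance
from .database import SolventDatabase, SolventRecord
from .errors import InvalidInputError
from .locator import (
    DEFAULT_BOUNDS,
    AbsorbanceMeasurement,
    Bounds,
    LocateResult,
    LocatorConfig,
    MeasurementSet,
    locate,
)

__all__ = [
    "AbsorbanceModel",
    "make_material",
    "simulate_absorbance",
    "recovery_experiment",
    "RecoverySummary",
]

SeedLike = Union[int, np.random.Generator, None]


@dataclass(frozen=True)
class AbsorbanceModel:
    """Parameters of the synthetic absorbance–distance link.

    amplitude
        absorbance of a hypothetical solvent at zero Hansen distance, AU.
        Default 1.0, the order of a strong band maximum in a 1 cm cell.
    tau
        decay scale in MPa^1/2. Default 5.0: absorbance falls by ~e over a
        distance comparable to typical good-solvent radii, so a panel
        spanning R ≈ 0–35 shows realistic dynamic range.
    noise_sd
        additive Gaussian noise, AU. Default 0.02, typical bench
        spectrometer repeatability.
    floor
        lower truncation, AU (default 0).
    """

    amplitude: float = 1.0
    tau: float = 5.0
    noise_sd: float = 0.02
    floor: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.amplitude, self.tau, self.noise_sd, self.floor)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidInputError(f"absorbance model parameters must be finite: {vals}")
        if not self.amplitude > 0 or not self.tau > 0:
            raise InvalidInputError("amplitude and tau must be > 0")
        if self.noise_sd < 0 or self.floor < 0:
            raise InvalidInputError("noise_sd and floor must be >= 0")
        if not self.amplitude > self.floor:
            raise InvalidInputError("amplitude must exceed floor")


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def make_material(seed: SeedLike = None, bounds: Bounds = DEFAULT_BOUNDS) -> HspVector:
    """Draw a synthetic material uniformly from a Hansen-space box."""
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if np.any(hi < lo):
        raise InvalidInputError(f"empty bounds box {bounds}")
    return HspVector.from_array(_rng(seed).uniform(lo, hi))


Candidate = Union[SolventRecord, Tuple[str, HspVector], Tuple[str, Sequence[float]]]


def simulate_absorbance(
    truth,
    solvents: Iterable[Candidate],
    model: AbsorbanceModel = AbsorbanceModel(),
    seed: SeedLike = None,
) -> MeasurementSet:
    """Simulate a measurement panel for a material at ``truth``.

    Absorbance decays exponentially in the Hansen distance and is truncated
    below at ``model.floor``; with ``noise_sd == 0`` it is strictly
    decreasing in R. Reproducible for a fixed seed.
    """
    truth = as_hsp(truth)
    rng = _rng(seed)
    items: List[Tuple[str, HspVector]] = []
    for c in solvents:
        if isinstance(c, SolventRecord):
            items.append((c.name, c.hsp))
        else:
            items.append((c[0], as_hsp(c[1])))
    if not items:
        raise InvalidInputError("need at least one solvent to simulate")
    noise = rng.normal(0.0, model.noise_sd, size=len(items)) if model.noise_sd > 0 else np.zeros(len(items))
    measurements = []
    for (name, hsp), eps in zip(items, noise):
        r = hansen_distance(truth, hsp)
        a = max(model.floor, model.amplitude * math.exp(-r / model.tau) + float(eps))
        measurements.append(AbsorbanceMeasurement(solvent=name, absorbance=a, hsp=hsp))
    return MeasurementSet(tuple(measurements))


@dataclass(frozen=True)
class TrialResult:
    truth: HspVector
    panel: MeasurementSet
    result: LocateResult

    @property
    def error(self) -> np.ndarray:
        return self.result.estimate.as_array() - self.truth.as_array()


@dataclass(frozen=True)
class RecoverySummary:
    """Aggregate recovery statistics over seeded trials (all in MPa^1/2)."""

    trials: Tuple[TrialResult, ...]
    bias: Tuple[float, float, float] = field(init=False)
    rmse: Tuple[float, float, float] = field(init=False)
    max_abs_error: float = field(init=False)

    def __post_init__(self) -> None:
        errs = np.array([t.error for t in self.trials])
        object.__setattr__(self, "bias", tuple(errs.mean(axis=0)))
        object.__setattr__(self, "rmse", tuple(np.sqrt((errs**2).mean(axis=0))))
        object.__setattr__(self, "max_abs_error", float(np.abs(errs).max()))


def recovery_experiment(
    n_trials: int,
    panel_size: int = 8,
    model: AbsorbanceModel = AbsorbanceModel(),
    cfg: Optional[LocatorConfig] = None,
    seed: SeedLike = None,
    db: Optional[SolventDatabase] = None,
    bounds: Bounds = DEFAULT_BOUNDS,
) -> RecoverySummary:
    """Repeated truth → simulate → locate round trips.

    Each trial draws a material uniformly from ``bounds``, samples
    ``panel_size − 1`` distinct solvents from the database (bundled panel by
    default) plus one probe solvent placed at the truth itself, simulates
    absorbances under ``model`` and runs the estimator. The probe mirrors
    the favourable regime where the panel actually brackets the material;
    see the recovery notes in the docs for what this does and does not show.
    """
    if n_trials < 1:
        raise InvalidInputError(f"n_trials must be >= 1, got {n_trials}")
    if db is None:
        from .datasets import bundled_database

        db = bundled_database()
    records = list(db)
    if panel_size < 2 or panel_size - 1 > len(records):
        raise InvalidInputError(
            f"panel_size must be in [2, {len(records) + 1}], got {panel_size}"
        )
    rng = _rng(seed)
    trials = []
    cfg = cfg or LocatorConfig()
    for _ in range(n_trials):
        truth = make_material(rng, bounds)
        chosen_idx = rng.choice(len(records), size=panel_size - 1, replace=False)
        panel: List[Candidate] = [records[i] for i in chosen_idx]
        panel.append(("synthetic-probe", truth))
        ms = simulate_absorbance(truth, panel, model, rng)
        trials.append(TrialResult(truth=truth, panel=ms, result=locate(ms, cfg)))
    return RecoverySummary(trials=tuple(trials))
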