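"""Closed-form one-compartment biokinetic models of contaminant body burden.

Two first-order models of whole-organism concentration ``C_org(t)`` during an
exposure experiment with an uptake phase (organism in contaminated medium,
``0 <= t <= t_e``) followed by an elimination/depuration phase (organism moved
to clean medium, ``t > t_e``):

* **OC** — the plain one-compartment model.  Uptake is proportional to the
  exposure-medium concentration (rate constant ``k1``) and elimination is
  first-order in the accumulated burden (rate constant ``k2``)::

      uptake:       C(t) = C0 + Cexp * (k1/k2) * (1 - exp(-k2 t))
      elimination:  C(t) = C0 + Cexp * (k1/k2) * (exp(-k2 (t - t_e)) - exp(-k2 t))

* **OC-SF** — the one-compartment model with a *stored fraction* ``SF`` in
  [0, 1]: a fraction of the absorbed material is sequestered in tissue (for
  example the hepatopancreas of isopods or the chloragogenous tissue of
  earthworms) and is not subject to first-order elimination.  The stored pool
  accrues linearly during uptake and is retained thereafter::

      uptake:       C(t) = C0 + SF*Cexp*k1*t  + (1-SF) * [OC uptake term]
      elimination:  C(t) = C0 + SF*Cexp*k1*t_e + (1-SF) * [OC elimination term]

Setting ``SF = 0`` recovers the OC model exactly; the OC model is the
two-parameter slice of the three-parameter OC-SF family.

All functions are pure and unit-agnostic: ``k1`` is in medium-mass (or volume)
per organism-mass per time, ``k2`` in inverse time, and no unit conversion is
ever performed — the time/medium unit labels on :class:`ExposureScenario` are
metadata only.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ModelKind",
    "KineticParameters",
    "ExposureScenario",
    "ConcentrationSeries",
    "predict_concentration",
    "simulate_series",
    "steady_state_burden",
]


class ModelKind(str, enum.Enum):
    """The two candidate biokinetic models."""

    OC = "oc"
    OC_SF = "ocsf"

    @property
    def n_params(self) -> int:
        """Number of fitted kinetic parameters (2 for OC, 3 for OC-SF)."""
        return 2 if self is ModelKind.OC else 3

    @classmethod
    def coerce(cls, value: "ModelKind | str") -> "ModelKind":
        if isinstance(value, cls):
            return value
        key = str(value).strip().lower().replace("-", "").replace("_", "")
        if key == "oc":
            return cls.OC
        if key in ("ocsf", "ocstoredfraction"):
            return cls.OC_SF
        raise ValueError(f"unknown model kind {value!r}; expected 'oc' or 'ocsf'")


@dataclass(frozen=True)
class KineticParameters:
    """Kinetic rate constants and stored fraction.

    Parameters
    ----------
    k1 : float
        Uptake rate constant (medium mass/volume per organism mass per time).
    k2 : float
        Elimination rate constant (per time).  Must be strictly positive.
    sf : float, default 0.0
        Dimensionless stored fraction in [0, 1]; 0 for the OC model.
    """

    k1: float
    k2: float
    sf: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.k1) or self.k1 < 0:
            raise ValueError(f"k1 must be finite and >= 0, got {self.k1}")
        if not math.isfinite(self.k2) or self.k2 <= 0:
            raise ValueError(f"k2 must be finite and > 0, got {self.k2}")
        if not math.isfinite(self.sf) or not 0.0 <= self.sf <= 1.0:
            raise ValueError(f"sf must lie in [0, 1], got {self.sf}")

    def validate_for(self, model: ModelKind) -> None:
        """Check compatibility with a model kind (OC requires sf == 0)."""
        if ModelKind.coerce(model) is ModelKind.OC and self.sf != 0.0:
            raise ValueError("OC model requires sf == 0; use OC_SF for sf > 0")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.k1, self.k2, self.sf)


@dataclass(frozen=True)
class ExposureScenario:
    """Exposure-experiment design: medium concentration, timings, grid step.

    ``t_e`` is the time at which organisms are transferred from the
    contaminated to a clean medium; ``t_total`` the end of the simulation.
    Unit labels are free text carried along for reporting, never converted.
    """

    c_exposure: float
    t_e: float
    t_total: float
    c_org0: float = 0.0
    dt: float = 1.0
    time_unit: str = "hour"
    medium_unit: str = "mg/L"

    def __post_init__(self) -> None:
        if self.c_org0 < 0:
            raise ValueError(f"c_org0 must be >= 0, got {self.c_org0}")
        if self.c_exposure < 0:
            raise ValueError(f"c_exposure must be >= 0, got {self.c_exposure}")
        if not 0 < self.t_e <= self.t_total:
            raise ValueError(
                f"need 0 < t_e <= t_total, got t_e={self.t_e}, t_total={self.t_total}"
            )
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")

    def with_(self, **kwargs) -> "ExposureScenario":
        return replace(self, **kwargs)


@dataclass(eq=False)
class ConcentrationSeries:
    """Aligned (time, concentration) observations or predictions.

    Times must be non-decreasing; duplicate times represent replicates.
    """

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if self.times.size != self.values.size:
            raise ValueError(
                f"times ({self.times.size}) and values ({self.values.size}) differ in length"
            )
        if self.times.size < 1:
            raise ValueError("a series needs at least one point")
        if np.any(self.times < 0):
            raise ValueError("times must be non-negative")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")

    def __len__(self) -> int:
        return int(self.times.size)

    def __eq__(self, other) -> bool:  # value equality, used in round-trip tests
        if not isinstance(other, ConcentrationSeries):
            return NotImplemented
        return (
            np.array_equal(self.times, other.times)
            and np.array_equal(self.values, other.values)
            and self.label == other.label
        )


def _evaluate(
    t: np.ndarray,
    k1: np.ndarray,
    k2: np.ndarray,
    sf: np.ndarray,
    c_org0: float,
    c_exposure: float,
    t_e: float,
) -> np.ndarray:
    """Broadcasting core for both models over arrays of times and parameters.

    ``t = t_e`` is assigned to the uptake branch; both branches agree there so
    the choice is a convention only.
    """
    t = np.asarray(t, dtype=float)
    k1 = np.asarray(k1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    sf = np.asarray(sf, dtype=float)
    uptake = t <= t_e
    with np.errstate(over="ignore", invalid="ignore"):
        ratio = c_exposure * k1 / k2
        exch_up = ratio * (1.0 - np.exp(-k2 * t))
        exch_el = ratio * (np.exp(-k2 * (t - t_e)) - np.exp(-k2 * t))
        stored = sf * c_exposure * k1 * np.where(uptake, t, t_e)
        out = c_org0 + stored + (1.0 - sf) * np.where(uptake, exch_up, exch_el)
    return out


def predict_concentration(
    model: ModelKind | str,
    params: KineticParameters,
    scenario: ExposureScenario,
    t: float | Sequence[float] | np.ndarray,
) -> float | np.ndarray:
    """Evaluate the analytical body-burden solution at time(s) ``t``.

    Returns a scalar for scalar ``t``, else an ndarray.  Raises for negative
    times and for parameters invalid under ``model``.
    """
    model = ModelKind.coerce(model)
    params.validate_for(model)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    out = _evaluate(
        t_arr, params.k1, params.k2, params.sf,
        scenario.c_org0, scenario.c_exposure, scenario.t_e,
    )
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def time_grid(scenario: ExposureScenario) -> np.ndarray:
    """Evaluation grid {0, dt, 2dt, ...} up to t_total, with t_e inserted.

    ``t_e`` is appended when it is not (within a small relative tolerance) a
    multiple of ``dt`` so the kink at the phase boundary is always on the grid.
    """
    if scenario.dt > scenario.t_total:
        raise ValueError(
            f"dt ({scenario.dt}) must not exceed t_total ({scenario.t_total})"
        )
    n = int(np.floor(scenario.t_total / scenario.dt + 1e-9))
    grid = np.arange(n + 1, dtype=float) * scenario.dt
    if not np.any(np.isclose(grid, scenario.t_e, rtol=1e-12, atol=1e-12)):
        grid = np.sort(np.append(grid, scenario.t_e))
    return grid


def simulate_series(
    model: ModelKind | str,
    params: KineticParameters,
    scenario: ExposureScenario,
    label: str = "",
) -> ConcentrationSeries:
    """Analytical solution on the scenario's time grid (see :func:`time_grid`)."""
    grid = time_grid(scenario)
    values = predict_concentration(model, params, scenario, grid)
    return ConcentrationSeries(times=grid, values=np.asarray(values), label=label)


def steady_state_burden(
    params: KineticParameters, scenario: ExposureScenario
) -> float:
    """Plateau body burden ``c_org0 + c_exposure * k1 / k2`` of the OC uptake phase.

    With a nonzero stored fraction the uptake phase grows without bound
    (linear stored accrual), so a finite steady state exists only for sf == 0.
    """
    if params.sf != 0.0:
        raise ValueError("no finite steady state exists for sf > 0")
    return scenario.c_org0 + scenario.c_exposure * params.k1 / params.k2
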