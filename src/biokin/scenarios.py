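"""Registry of pre-defined bioaccumulation-kinetics scenarios.

Bundles fitted OC / OC-SF parameters for a set of published organism /
nanomaterial exposure datasets (green algae, water flea, zebrafish and
earthworm exposed to C60, TiO2, SiO2, graphene, graphene oxide, Au, Ag-NP and
AgNO3) so that simulations can be launched without re-entering constants.
Each dataset appears twice, once per model.  The registry is read-only at
runtime; user-defined scenarios belong in separate files loaded with
:func:`load_user_scenarios`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Mapping

from .models import ExposureScenario, KineticParameters, ModelKind

__all__ = ["ScenarioRecord", "list_scenarios", "get_scenario", "load_user_scenarios"]


@dataclass(frozen=True)
class ScenarioRecord:
    """One registry entry: a fitted model for an organism/material dataset."""

    id: str
    organism: str
    material: str
    exposure_type: str
    model: ModelKind
    params: KineticParameters
    c_exposure: float | None
    c_exposure_unit: str
    adj_r2_reported: float | None
    k1_unit: str
    time_unit: str
    t_e: float | None
    t_total: float | None
    literature: Mapping[str, object]
    reported_akaike_weight: float | None
    source: str
    notes: str | None
    unit_caveat: bool

    @classmethod
    def from_dict(cls, raw: Mapping[str, object]) -> "ScenarioRecord":
        params = raw["params"]
        return cls(
            id=raw["id"],
            organism=raw["organism"],
            material=raw["material"],
            exposure_type=raw["exposure_type"],
            model=ModelKind.coerce(raw["model"]),
            params=KineticParameters(
                k1=float(params["k1"]), k2=float(params["k2"]),
                sf=float(params.get("sf", 0.0)),
            ),
            c_exposure=raw.get("c_exposure"),
            c_exposure_unit=raw.get("c_exposure_unit", ""),
            adj_r2_reported=raw.get("adj_r2_reported"),
            k1_unit=raw.get("k1_unit", ""),
            time_unit=raw.get("time_unit", ""),
            t_e=raw.get("t_e"),
            t_total=raw.get("t_total"),
            literature=dict(raw.get("literature", {})),
            reported_akaike_weight=raw.get("reported_akaike_weight"),
            source=raw.get("source", ""),
            notes=raw.get("notes"),
            unit_caveat=bool(raw.get("unit_caveat", False)),
        )

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "organism": self.organism,
            "material": self.material,
            "exposure_type": self.exposure_type,
            "model": self.model.value,
            "c_exposure": self.c_exposure,
            "c_exposure_unit": self.c_exposure_unit,
            "params": {"k1": self.params.k1, "k2": self.params.k2, "sf": self.params.sf},
            "adj_r2_reported": self.adj_r2_reported,
            "k1_unit": self.k1_unit,
            "time_unit": self.time_unit,
            "t_e": self.t_e,
            "t_total": self.t_total,
            "literature": dict(self.literature),
            "reported_akaike_weight": self.reported_akaike_weight,
            "source": self.source,
            "notes": self.notes,
            "unit_caveat": self.unit_caveat,
        }

    def to_exposure_scenario(
        self,
        t_total: float | None = None,
        dt: float = 1.0,
        t_e: float | None = None,
        c_exposure: float | None = None,
        c_org0: float = 0.0,
    ) -> ExposureScenario:
        """Build an :class:`ExposureScenario`, filling gaps from arguments.

        Records lacking ``c_exposure`` or ``t_e`` (not reported alongside the
        original fit) require those values to be supplied here.
        """
        c_exp = c_exposure if c_exposure is not None else self.c_exposure
        if c_exp is None:
            raise ValueError(
                f"scenario {self.id!r} has no recorded exposure concentration; pass c_exposure"
            )
        te = t_e if t_e is not None else self.t_e
        if te is None:
            raise ValueError(f"scenario {self.id!r} has no recorded t_e; pass t_e")
        total = t_total if t_total is not None else (self.t_total or 2 * te)
        return ExposureScenario(
            c_exposure=float(c_exp), t_e=float(te), t_total=float(total),
            c_org0=c_org0, dt=dt, time_unit=self.time_unit,
            medium_unit=self.c_exposure_unit,
        )


@lru_cache(maxsize=1)
def _registry() -> tuple[ScenarioRecord, ...]:
    text = resources.files("biokin.data").joinpath("scenarios.json").read_text()
    raw = json.loads(text)
    records = tuple(ScenarioRecord.from_dict(r) for r in raw["records"])
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise RuntimeError("bundled scenario registry contains duplicate ids")
    return records


def list_scenarios() -> tuple[ScenarioRecord, ...]:
    """All bundled scenario records (immutable tuple)."""
    return _registry()


def get_scenario(scenario_id: str) -> ScenarioRecord:
    """Look up one record by slug; raises ``KeyError`` listing valid ids."""
    for record in _registry():
        if record.id == scenario_id:
            return record
    valid = ", ".join(r.id for r in _registry())
    raise KeyError(f"unknown scenario {scenario_id!r}; valid ids: {valid}")


def load_user_scenarios(path: str | Path) -> tuple[ScenarioRecord, ...]:
    """Read additional records from a user JSON file with the bundled schema."""
    raw = json.loads(Path(path).read_text())
    records = raw["records"] if isinstance(raw, Mapping) else raw
    return tuple(ScenarioRecord.from_dict(r) for r in records)
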