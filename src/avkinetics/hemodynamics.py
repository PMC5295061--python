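"""Indicator-dilution plasma flow and bicarbonate-phase CO2 kinetics.

p-Aminohippurate (PAH) is infused at a constant, known rate into the femoral
artery, upstream of the hindlimb; downstream (femoral-vein) dilution of the
indicator yields limb plasma flow:

    PF = PAH infusion (mg/h) / (C_vein - C_artery) (mg/L) / BW (kg)
       [L * kg^-1 * h^-1]

The bicarbonate tracer phase gives whole-body CO2 production by classic
tracer dilution (infusion rate / arterial 13CO2 enrichment) and, with the
flow, the net labelled-CO2 release across the limb.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigError, DivisionGuardError, NoDilutionError

ROUTES = ("jugular_vein", "femoral_artery")
INFUSATES = ("bicarbonate", "leucine", "pah")


@dataclass(frozen=True)
class InfusionProtocol:
    """One infusate of the primed-continuous protocol.

    Units: tracer primes in umol/kg and rates in umol * kg^-1 * h^-1; the PAH
    indicator prime in mL and rate in mL/min of a solution whose
    concentration (mg/mL) must be given to convert to a mass infusion rate.
    ``window`` is (start_h, end_h) relative to the first feeding.
    """

    infusate: str
    prime: float
    rate: float
    route: str
    window: tuple
    prime_unit: str = "umol/kg"
    rate_unit: str = "umol/kg/h"
    solution_mg_per_ml: Optional[float] = None

    def __post_init__(self):
        if self.infusate not in INFUSATES:
            raise ConfigError(f"unknown infusate {self.infusate!r}")
        if self.route not in ROUTES:
            raise ConfigError(f"unknown route {self.route!r}")
        if self.rate <= 0:
            raise ConfigError("infusion rate must be > 0")
        if not (len(self.window) == 2 and self.window[0] < self.window[1]):
            raise ConfigError("window must be (start_h, end_h) with start < end")
        if self.infusate == "pah" and self.rate_unit == "mL/min" \
                and self.solution_mg_per_ml is None:
            raise ConfigError("PAH in mL/min requires solution_mg_per_ml")


def default_protocols() -> dict:
    """The study's infusion protocol.

    NaH13CO3: 7.5 umol/kg prime + 10 umol kg-1 h-1 for hours 0-2 (jugular);
    [1-13C]leucine: 10 umol/kg prime + 10 umol kg-1 h-1 for hours 2-8
    (jugular); PAH: 19.1 mL prime + 0.788 mL/min intra-arterial throughout.
    The PAH solution concentration is a site-specific preparation; the
    default 20 mg/mL yields limb flows of the magnitude this protocol
    produces (~1.3 L kg-1 h-1 at 20 kg).
    """
    return {
        "bicarbonate": InfusionProtocol("bicarbonate", prime=7.5, rate=10.0,
                                        route="jugular_vein", window=(0.0, 2.0)),
        "leucine": InfusionProtocol("leucine", prime=10.0, rate=10.0,
                                    route="jugular_vein", window=(2.0, 8.0)),
        "pah": InfusionProtocol("pah", prime=19.1, rate=0.788,
                                route="femoral_artery", window=(-1.0, 8.0),
                                prime_unit="mL", rate_unit="mL/min",
                                solution_mg_per_ml=20.0),
    }


def load_protocols(path) -> dict:
    """Load an infusion-protocol file (YAML or JSON mapping of infusates)."""
    text = Path(path).read_text()
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(raw, dict) or "infusates" not in raw:
        raise ConfigError("protocol file must contain an 'infusates' mapping")
    protocols = {}
    for name, spec in raw["infusates"].items():
        if name not in INFUSATES:
            raise ConfigError(f"unknown infusate {name!r} in protocol file")
        spec = dict(spec)
        spec["window"] = tuple(spec.get("window", ()))
        protocols[name] = InfusionProtocol(infusate=name, **spec)
    missing = set(INFUSATES) - set(protocols)
    if missing:
        raise ConfigError(f"protocol file missing infusate(s): {sorted(missing)}")
    return protocols


def save_protocols(protocols: dict, path) -> None:
    payload = {"infusates": {}}
    for name, p in protocols.items():
        d = asdict(p)
        d.pop("infusate")
        d["window"] = list(d["window"])
        if d["solution_mg_per_ml"] is None:
            d.pop("solution_mg_per_ml")
        payload["infusates"][name] = d
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def pah_infusion_mg_per_h(protocol: InfusionProtocol) -> float:
    """Mass infusion rate of the PAH indicator in mg/h."""
    if protocol.infusate != "pah":
        raise ConfigError("expected the PAH infusate")
    if protocol.rate_unit == "mg/h":
        return protocol.rate
    if protocol.rate_unit == "mL/min":
        return protocol.rate * 60.0 * protocol.solution_mg_per_ml
    raise ConfigError(f"unsupported PAH rate unit {protocol.rate_unit!r}")


@dataclass(frozen=True)
class PlasmaFlow:
    """Limb plasma flow, L * kg^-1 * h^-1, normalised per kg body weight."""

    value: float
    body_weight: float

    def __post_init__(self):
        if self.value <= 0:
            raise ConfigError("plasma flow must be > 0")
        if self.body_weight <= 0:
            raise ConfigError("body weight must be > 0")


def plasma_flow_pah(pah_infusion: float, c_art: float, c_ven: float,
                    body_weight: float) -> PlasmaFlow:
    """Plasma flow by indicator dilution.

    Parameters
    ----------
    pah_infusion
        PAH mass infusion rate, mg/h.
    c_art, c_ven
        Steady-state PAH concentration in the carotid artery and femoral
        vein, mg/L.  The indicator enters the femoral artery, so the venous
        concentration must exceed the arterial one.
    body_weight
        kg.
    """
    if body_weight <= 0:
        raise ConfigError("body weight must be > 0")
    if c_ven <= c_art:
        raise NoDilutionError(
            f"venous PAH ({c_ven}) must exceed arterial ({c_art}); "
            "no indicator dilution measurable")
    return PlasmaFlow(pah_infusion / (c_ven - c_art) / body_weight, body_weight)


def whole_body_co2_production(bicarb_rate: float, e_co2_art: float) -> float:
    """Whole-body CO2 production rate by bicarbonate tracer dilution.

    Ra_CO2 = bicarbonate infusion rate / arterial 13CO2 enrichment
    (umol * kg^-1 * h^-1; enrichment as a fraction).
    """
    if e_co2_art <= 0:
        raise DivisionGuardError("arterial CO2 enrichment must be > 0")
    return bicarb_rate / e_co2_art


def limb_13co2_release(pf: PlasmaFlow, c_co2_art: float, e_art: float,
                       c_co2_ven: float, e_ven: float) -> float:
    """Net labelled-CO2 release across the limb, umol * kg^-1 * h^-1.

    F13CO2 = PF * (C_v * E_v - C_a * E_a).  A negative value (venous
    labelled content below arterial) is returned as-is; callers flag it.
    """
    if min(c_co2_art, c_co2_ven, e_art, e_ven) < 0:
        raise ConfigError("concentrations and enrichments must be >= 0")
    return pf.value * (c_co2_ven * e_ven - c_co2_art * e_art)


def limb_bicarbonate_recovery(f13co2: float, bicarb_rate: float) -> float:
    """Fraction of the infused labelled bicarbonate recovered across the limb.

    A diagnostic; it is NOT applied as an oxidation correction unless the
    analysis options explicitly enable a recovery divisor.
    """
    if bicarb_rate <= 0:
        raise ConfigError("bicarbonate infusion rate must be > 0")
    return f13co2 / bicarb_rate
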