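"""Two-pool arteriovenous tracer-balance model of limb leucine kinetics.

With plasma flow PF (L kg-1 h-1), arterial/venous leucine concentrations
C_a, C_v (umol/L) and [1-13C]leucine enrichments E_a, E_v (fractions), KIC
concentrations/enrichments K_a, K_v / Ek_a, Ek_v, and the net labelled-CO2
release F13CO2, the limb fluxes (all umol kg-1 h-1) are

    arterial input        Ra_in  = PF * C_a
    net uptake            NB     = PF * (C_a - C_v)
    tracer uptake         U13    = PF * (C_a*E_a - C_v*E_v)
    utilization           Rd     = U13 / E_a
    protein degradation   PD     = Rd - NB
    net transamination    T_net  = PF * (K_v - K_a)
    13C-KIC production    P13    = PF * (K_v*Ek_v - K_a*Ek_a)
    oxidation             Ox     = F13CO2 / (E_precursor * recovery)
    protein synthesis     PS     = Rd - Ox - T_net
    protein deposition    PDep   = PS - PD  =  NB - Ox - T_net

Utilization (total leucine disposal) follows from labelled-leucine
extraction diluted by the arterial enrichment; the unlabelled release it
exceeds net balance by is proteolysis.  The oxidation precursor pool
defaults to the venous [1-13C]KIC enrichment (the reciprocal-pool surrogate
for intracellular leucine enrichment); arterial leucine enrichment is
selectable.  Four identities hold exactly by construction and anchor the
model:  PDep = PS - PD,  PD = Rd - NB,  Rd = PS + Ox + T_net,  and
PDep = NB - Ox - T_net.

All functions accept scalars or NumPy arrays and are pure arithmetic, so the
same code path serves per-animal analysis and vectorised Monte-Carlo work.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .errors import DivisionGuardError, IncompleteInputError
from .hemodynamics import PlasmaFlow, limb_13co2_release
from .plateau import SteadyStateSummary

PRECURSOR_POOLS = ("venous-kic", "arterial-leucine")

#: the per-animal flux panel, in computation order
FLUX_FIELDS = ("arterial_input", "net_uptake", "utilization",
               "net_transamination", "oxidation", "protein_synthesis",
               "protein_degradation", "protein_deposition")
TRACER_FLUX_FIELDS = ("leu13_uptake", "kic13_production", "co2_13_release")


@dataclass(frozen=True)
class LeucineKinetics:
    """Per-animal limb leucine flux panel (umol kg-1 h-1; fractions in %)."""

    animal_id: Optional[str]
    group: Optional[str]
    plasma_flow: float
    arterial_input: float
    net_uptake: float
    utilization: float
    net_transamination: float
    oxidation: float
    protein_synthesis: float
    protein_degradation: float
    protein_deposition: float
    leu13_uptake: float
    kic13_production: float
    co2_13_release: float
    fractions: Mapping[str, float]
    precursor: str = "venous-kic"
    recovery: float = 1.0
    flags: tuple = field(default=())


def _value(x):
    a = np.asarray(x, dtype=float)
    return float(a) if a.ndim == 0 else a


def _pf(pf):
    return pf.value if isinstance(pf, PlasmaFlow) else pf


def arterial_input(c_art_leu, pf):
    """Arterial leucine delivery to the limb: Ra_in = C_a * PF."""
    return _value(c_art_leu * _pf(pf))


def net_uptake(c_art, c_ven, pf):
    """Net leucine balance NB = PF * (C_a - C_v); negative = net release."""
    return _value(_pf(pf) * (np.asarray(c_art, float) - c_ven))


def tracer_leucine_uptake(c_art, e_art, c_ven, e_ven, pf):
    """Net [1-13C]leucine uptake U13 = PF * (C_a E_a - C_v E_v)."""
    return _value(_pf(pf) * (np.asarray(c_art, float) * e_art - np.asarray(c_ven, float) * e_ven))


def utilization(c_art, e_art, c_ven, e_ven, pf):
    """Total leucine disposal Rd = U13 / E_a (tracer-balance dilution)."""
    if np.any(np.asarray(e_art, float) <= 0):
        raise DivisionGuardError("arterial leucine enrichment must be > 0")
    return _value(tracer_leucine_uptake(c_art, e_art, c_ven, e_ven, pf)
                  / np.asarray(e_art, float))


def protein_degradation(utilization, net_uptake):
    """Unlabelled leucine appearance from limb proteolysis: PD = Rd - NB."""
    return _value(np.asarray(utilization, float) - net_uptake)


def net_transamination(c_art_kic, c_ven_kic, pf):
    """Net KIC release by the limb: T_net = PF * (K_v - K_a)."""
    return _value(_pf(pf) * (np.asarray(c_ven_kic, float) - c_art_kic))


def kic13_production(c_art_kic, e_art_kic, c_ven_kic, e_ven_kic, pf):
    """Net [1-13C]KIC production P13 = PF * (K_v Ek_v - K_a Ek_a)."""
    return _value(_pf(pf) * (np.asarray(c_ven_kic, float) * e_ven_kic
                             - np.asarray(c_art_kic, float) * e_art_kic))


def oxidation(f13co2, e_precursor, recovery: float = 1.0):
    """Leucine oxidation Ox = F13CO2 / (E_precursor * recovery).

    ``recovery`` (0 < r <= 1) optionally divides out incomplete labelled-CO2
    recovery; the default 1.0 applies no correction.
    """
    if np.any(np.asarray(e_precursor, float) <= 0):
        raise DivisionGuardError("precursor enrichment must be > 0")
    if not 0 < recovery <= 1:
        raise ValueError("recovery must lie in (0, 1]")
    return _value(np.asarray(f13co2, float) / (np.asarray(e_precursor, float) * recovery))


def protein_synthesis(utilization, oxidation, net_transamination):
    """Leucine incorporated into limb protein: PS = Rd - Ox - T_net."""
    return _value(np.asarray(utilization, float) - oxidation - net_transamination)


def protein_deposition(protein_synthesis, protein_degradation):
    """Net protein accretion PDep = PS - PD (= NB - Ox - T_net)."""
    return _value(np.asarray(protein_synthesis, float) - protein_degradation)


def partition_fractions(k) -> dict:
    """Partition of the leucine stream, as percentages.

    ``utilization_of_input`` is Rd as % of arterial input; the synthesis,
    transamination and oxidation fractions are percentages of utilization
    and sum to exactly 100.  Accepts a :class:`LeucineKinetics` or any
    object with the flux attributes.
    """
    ra, rd = k.arterial_input, k.utilization
    if np.any(np.asarray(ra, float) <= 0) or np.any(np.asarray(rd, float) <= 0):
        raise DivisionGuardError("arterial input and utilization must be > 0")
    return {
        "utilization_of_input": _value(100.0 * np.asarray(rd, float) / ra),
        "synthesis_of_utilization": _value(100.0 * np.asarray(k.protein_synthesis, float) / rd),
        "transamination_of_utilization": _value(100.0 * np.asarray(k.net_transamination, float) / rd),
        "oxidation_of_utilization": _value(100.0 * np.asarray(k.oxidation, float) / rd),
    }


def compute_fluxes(c_art_leu, e_art_leu, c_ven_leu, e_ven_leu,
                   c_art_kic, e_art_kic, c_ven_kic, e_ven_kic,
                   c_art_co2, e_art_co2, c_ven_co2, e_ven_co2,
                   pf, precursor: str = "venous-kic",
                   recovery: float = 1.0) -> dict:
    """The full flux panel from plateau values; scalar or vectorised.

    Returns a dict keyed by :data:`FLUX_FIELDS` + :data:`TRACER_FLUX_FIELDS`.
    """
    if precursor not in PRECURSOR_POOLS:
        raise ValueError(f"unknown precursor pool {precursor!r}")
    pfv = _pf(pf)
    ra_in = arterial_input(c_art_leu, pfv)
    nb = net_uptake(c_art_leu, c_ven_leu, pfv)
    u13 = tracer_leucine_uptake(c_art_leu, e_art_leu, c_ven_leu, e_ven_leu, pfv)
    rd = utilization(c_art_leu, e_art_leu, c_ven_leu, e_ven_leu, pfv)
    pd_ = protein_degradation(rd, nb)
    t_net = net_transamination(c_art_kic, c_ven_kic, pfv)
    p13 = kic13_production(c_art_kic, e_art_kic, c_ven_kic, e_ven_kic, pfv)
    f13 = _value(pfv * (np.asarray(c_ven_co2, float) * e_ven_co2
                        - np.asarray(c_art_co2, float) * e_art_co2))
    e_prec = e_ven_kic if precursor == "venous-kic" else e_art_leu
    ox = oxidation(f13, e_prec, recovery)
    ps = protein_synthesis(rd, ox, t_net)
    pdep = protein_deposition(ps, pd_)
    return {
        "arterial_input": ra_in, "net_uptake": nb, "utilization": rd,
        "net_transamination": t_net, "oxidation": ox,
        "protein_synthesis": ps, "protein_degradation": pd_,
        "protein_deposition": pdep,
        "leu13_uptake": u13, "kic13_production": p13, "co2_13_release": f13,
    }


REQUIRED_STEADY_STATES = tuple((a, s) for a in ("leucine", "kic", "co2")
                               for s in ("artery", "vein"))


def analyze_animal(steady_states: Mapping, pf: PlasmaFlow,
                   precursor: str = "venous-kic", recovery: float = 1.0,
                   animal_id: Optional[str] = None,
                   group: Optional[str] = None) -> LeucineKinetics:
    """Compute the per-animal flux panel from steady-state summaries.

    Parameters
    ----------
    steady_states
        ``{(analyte, site): SteadyStateSummary}`` covering leucine, KIC and
        CO2 at both sites (a PAH entry may be present and is ignored here —
        the flow has already been folded into ``pf``).
    pf
        Limb plasma flow from indicator dilution.
    precursor
        Oxidation precursor pool: ``"venous-kic"`` (default, reciprocal-pool
        surrogate) or ``"arterial-leucine"``.
    recovery
        Labelled-CO2 recovery divisor applied inside the oxidation term;
        1.0 = no correction.

    Raises
    ------
    IncompleteInputError
        Naming every missing ``analyte@site`` combination.
    """
    missing = [f"{a}@{s}" for (a, s) in REQUIRED_STEADY_STATES
               if (a, s) not in steady_states
               or steady_states[(a, s)].mean_enrichment is None]
    if missing:
        raise IncompleteInputError(missing)

    def cs(analyte, site):
        s: SteadyStateSummary = steady_states[(analyte, site)]
        return s.mean_concentration, s.mean_enrichment

    ca_leu, ea_leu = cs("leucine", "artery")
    cv_leu, ev_leu = cs("leucine", "vein")
    ca_kic, ea_kic = cs("kic", "artery")
    cv_kic, ev_kic = cs("kic", "vein")
    ca_co2, ea_co2 = cs("co2", "artery")
    cv_co2, ev_co2 = cs("co2", "vein")

    fluxes = compute_fluxes(ca_leu, ea_leu, cv_leu, ev_leu,
                            ca_kic, ea_kic, cv_kic, ev_kic,
                            ca_co2, ea_co2, cv_co2, ev_co2,
                            pf, precursor=precursor, recovery=recovery)
    flags = []
    if fluxes["net_uptake"] < 0:
        flags.append("net-release")
    if fluxes["co2_13_release"] < 0:
        flags.append("negative-13co2-gradient")
    if fluxes["protein_degradation"] < 0:
        flags.append("negative-degradation")
    for (a, s), summ in steady_states.items():
        flags.extend(summ.flags)

    k = LeucineKinetics(
        animal_id=animal_id, group=group, plasma_flow=pf.value,
        fractions={}, precursor=precursor, recovery=recovery,
        flags=tuple(flags), **fluxes)
    fractions = partition_fractions(k) if k.arterial_input > 0 and k.utilization > 0 else {}
    return LeucineKinetics(
        animal_id=animal_id, group=group, plasma_flow=pf.value,
        fractions=fractions, precursor=precursor, recovery=recovery,
        flags=tuple(flags), **fluxes)
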