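"""End-to-end analysis: sample table -> per-animal kinetics -> group reports.

Stage order mirrors the measurement chain: unit normalisation and (if raw
ion ratios were supplied) enrichment computation; per-animal steady-state
summaries; indicator-dilution plasma flow; the two-pool flux panel; then the
group statistics.  Animals with incomplete inputs are excluded with a
warning naming the gaps, and every intermediate is persisted so any reported
flux can be audited.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import kinetics as kin
from .enrichment import enrichment_from_ion_ratios
from .errors import ConfigError, IncompleteInputError, AVKineticsError
from .hemodynamics import (default_protocols, load_protocols,
                           limb_bicarbonate_recovery, pah_infusion_mg_per_h,
                           plasma_flow_pah, whole_body_co2_production)
from .plateau import animal_steady_states, steady_state_frame
from .samples import body_weights, normalize_units, read_samples, validate_samples
from .stats import group_table, pearson_matrix

#: Correlated per-animal variables of the study's correlation table
CORRELATION_VARIABLES = ("leu13_uptake", "kic13_production",
                         "protein_synthesis", "protein_degradation",
                         "protein_deposition")

FRACTION_FIELDS = ("utilization_of_input", "synthesis_of_utilization",
                   "transamination_of_utilization", "oxidation_of_utilization")


@dataclass(frozen=True)
class AnalysisOptions:
    """Tunable choices of the analysis, recorded in the output metadata."""

    plateau_rule: str = "last3"        # or "detect"
    plateau_k: int = 3
    co2_time_h: float = 2.0
    detect_alpha: float = 0.05
    cv_threshold: float = 15.0
    precursor: str = "venous-kic"      # or "arterial-leucine"
    recovery_correction: bool = False
    recovery_fraction: float = 0.8     # used only when correction is on
    ttest_variant: str = "pooled"
    default_body_weight: float = 20.0

    def effective_recovery(self) -> float:
        return self.recovery_fraction if self.recovery_correction else 1.0


@dataclass(frozen=True)
class CohortResult:
    kinetics: pd.DataFrame       # one row per analysed animal
    steady_states: pd.DataFrame
    per_animal: dict             # animal_id -> LeucineKinetics
    excluded: dict               # animal_id -> reason
    flags: tuple


def analyze_cohort(samples: pd.DataFrame, protocols: Optional[dict] = None,
                   options: AnalysisOptions = AnalysisOptions()) -> CohortResult:
    """Per-animal flux panels for a whole (validated, raw-dialect) table."""
    protocols = protocols or default_protocols()
    samples = validate_samples(samples)
    samples = enrichment_from_ion_ratios(samples)
    norm = normalize_units(samples)
    weights = body_weights(norm, default=options.default_body_weight)
    pah_mg_h = pah_infusion_mg_per_h(protocols["pah"])
    bicarb_rate = protocols["bicarbonate"].rate

    rows, per_animal, excluded, summaries_all = [], {}, {}, {}
    cohort_flags = []
    for animal, sub in norm.groupby("animal_id", sort=True):
        group = sub["group"].iloc[0]
        try:
            summaries = animal_steady_states(
                sub, rule=options.plateau_rule, k=options.plateau_k,
                co2_time_h=options.co2_time_h, alpha=options.detect_alpha,
                cv_threshold=options.cv_threshold)
            missing_pah = [f"pah@{s}" for s in ("artery", "vein")
                           if ("pah", s) not in summaries]
            if missing_pah:
                raise IncompleteInputError(missing_pah)
            pf = plasma_flow_pah(
                pah_mg_h,
                summaries[("pah", "artery")].mean_concentration,
                summaries[("pah", "vein")].mean_concentration,
                weights[animal])
            panel = kin.analyze_animal(
                summaries, pf, precursor=options.precursor,
                recovery=options.effective_recovery(),
                animal_id=animal, group=group)
        except AVKineticsError as exc:
            warnings.warn(f"animal {animal!r} excluded: {exc}")
            excluded[animal] = str(exc)
            continue
        summaries_all[animal] = summaries
        per_animal[animal] = panel
        e_a_co2 = summaries[("co2", "artery")].mean_enrichment
        row = {"animal_id": animal, "group": group,
               "body_weight_kg": weights[animal],
               "plasma_flow": panel.plasma_flow}
        row.update({f: getattr(panel, f) for f in kin.FLUX_FIELDS})
        row.update({f: getattr(panel, f) for f in kin.TRACER_FLUX_FIELDS})
        row.update({f: panel.fractions.get(f) for f in FRACTION_FIELDS})
        row["whole_body_co2_production"] = whole_body_co2_production(
            bicarb_rate, e_a_co2)
        row["limb_bicarbonate_recovery"] = limb_bicarbonate_recovery(
            panel.co2_13_release, bicarb_rate)
        row["flags"] = ";".join(panel.flags)
        rows.append(row)

    kinetics_df = pd.DataFrame(rows)
    if len(kinetics_df):
        sizes = kinetics_df.groupby("group").size()
        if (sizes < 2).any():
            msg = ("single-animal group(s) detected: results equal plugging "
                   "group means into the flux formulas, which is NOT the "
                   "per-animal-then-average convention of this analysis")
            warnings.warn(msg)
            cohort_flags.append("group-means-input")
    return CohortResult(kinetics=kinetics_df,
                        steady_states=steady_state_frame(summaries_all),
                        per_animal=per_animal, excluded=excluded,
                        flags=tuple(cohort_flags))


def fractions_of_group_means(kinetics_df: pd.DataFrame) -> pd.DataFrame:
    """Partition fractions recomputed from group-mean fluxes.

    The headline fractions are per-animal-then-averaged; this companion view
    (fraction of the mean fluxes) is also reported because the two differ
    whenever fluxes vary between animals.
    """
    rows = []
    for group, sub in kinetics_df.groupby("group"):
        means = sub[list(kin.FLUX_FIELDS)].mean()

        class _K:  # minimal flux-attribute view
            arterial_input = means["arterial_input"]
            utilization = means["utilization"]
            protein_synthesis = means["protein_synthesis"]
            net_transamination = means["net_transamination"]
            oxidation = means["oxidation"]

        rows.append({"group": group, **kin.partition_fractions(_K)})
    return pd.DataFrame(rows)


def cohort_statistics(kinetics_df: pd.DataFrame,
                      options: AnalysisOptions = AnalysisOptions()):
    """Group comparison table and the per-animal correlation matrix."""
    variables = [c for c in
                 list(kin.FLUX_FIELDS) + list(kin.TRACER_FLUX_FIELDS)
                 + ["plasma_flow"] + list(FRACTION_FIELDS)
                 if c in kinetics_df.columns
                 and kinetics_df[c].notna().all()]
    comparisons = group_table(kinetics_df, variables,
                              variant=options.ttest_variant)
    corr = pearson_matrix(kinetics_df, variables=list(CORRELATION_VARIABLES))
    return comparisons, corr


@dataclass(frozen=True)
class RunConfig:
    """File-level run configuration (CLI ``run`` subcommand)."""

    samples: str
    out_dir: str
    protocol: Optional[str] = None
    options: AnalysisOptions = field(default_factory=AnalysisOptions)
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict) or "samples" not in raw or "out_dir" not in raw:
            raise ConfigError("run config must define 'samples' and 'out_dir'")
        opts = AnalysisOptions(**raw.get("options", {}))
        return cls(samples=raw["samples"], out_dir=raw["out_dir"],
                   protocol=raw.get("protocol"), options=opts,
                   seed=int(raw.get("seed", 0)))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and persist every intermediate.

    Writes ``kinetics.csv``, ``steady_state.csv``, ``statistics.csv``,
    ``correlations_r.csv`` / ``correlations_p.csv`` /
    ``correlations_annotated.csv``, ``fractions_of_group_means.csv`` and a
    ``metadata.json`` recording the analysis options, exclusions and flags.
    Returns the output paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples = read_samples(config.samples)
    protocols = load_protocols(config.protocol) if config.protocol else None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        result = analyze_cohort(samples, protocols, config.options)
    if result.kinetics.empty:
        raise ConfigError("no analysable animals in the sample table")

    paths = {"kinetics": out / "kinetics.csv",
             "steady_state": out / "steady_state.csv",
             "metadata": out / "metadata.json"}
    result.kinetics.to_csv(paths["kinetics"], index=False)
    result.steady_states.to_csv(paths["steady_state"], index=False)

    n_groups_ok = result.kinetics.groupby("group").size().ge(2).sum() == 2 \
        and result.kinetics["group"].nunique() == 2
    if n_groups_ok:
        comparisons, corr = cohort_statistics(result.kinetics, config.options)
        paths["statistics"] = out / "statistics.csv"
        comparisons.to_csv(paths["statistics"], index=False)
        for name, frame in (("correlations_r", corr.r),
                            ("correlations_p", corr.p),
                            ("correlations_annotated", corr.annotated())):
            paths[name] = out / f"{name}.csv"
            frame.to_csv(paths[name])
        paths["fractions_of_group_means"] = out / "fractions_of_group_means.csv"
        fractions_of_group_means(result.kinetics).to_csv(
            paths["fractions_of_group_means"], index=False)

    metadata = {
        "options": asdict(config.options),
        "effective_recovery": config.options.effective_recovery(),
        "seed": config.seed,
        "n_animals": int(len(result.kinetics)),
        "excluded": result.excluded,
        "flags": list(result.flags),
        "warnings": sorted({str(w.message) for w in caught}),
    }
    paths["metadata"].write_text(json.dumps(metadata, indent=2))
    return {k: str(v) for k, v in paths.items()}
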