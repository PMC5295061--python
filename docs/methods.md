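# Methods

## The measurement problem

A limb tracer-balance study estimates how much of the leucine delivered to a
muscle bed is deposited as protein, recycled through proteolysis, shunted
into transamination (to α-ketoisocaproate, KIC) or oxidised to CO₂. Three
infusions run concurrently: an inert indicator (p-aminohippurate, PAH) into
the femoral artery whose venous dilution gives plasma flow; a
primed-continuous NaH¹³CO₃ infusion (hours 0–2) that labels the bicarbonate
pool and yields whole-body CO₂ production; and a primed-continuous
[1-¹³C]leucine infusion (hours 2–8) that labels the leucine and, via
transamination, the KIC and CO₂ pools. Arterial and venous plasma is drawn
hourly; the analysis uses only the isotopic/concentration plateaus.

## Enrichment

Single-label LC-MS work reports the M+1/M ion-intensity ratio; subtracting
the pre-infusion (baseline) ratio of the same animal/site/analyte gives the
tracer-to-tracee ratio and `MPE = 100·TTR/(1+TTR)`. No isotopomer-matrix
correction is applied beyond this single-ratio background subtraction, and
MPE is computed without correcting the tracee pool for tracer mass — the
standard single-label convention. Corrected ratios that come out slightly
negative (noise around natural abundance) are clamped to zero and flagged
rather than rejected; a `raise` policy is available.

## Plateau rules

The default mirrors the study design: the arithmetic mean of the **last
three** hourly samples for leucine, KIC and PAH (the infusions are primed,
so the plateau spans the tail of each phase), and the **single 2-h sample**
for CO₂ (the end of the bicarbonate phase). Which samples constitute "the
last three" is configurable (`plateau_k`, and the sampling times belong to
the caller). A stricter detector (`plateau_rule="detect"`) returns the
longest trailing window whose least-squares slope is not significantly
different from zero (default α = 0.05) and whose CV stays ≤ 15 %, falling
back to the last-k rule with a warning; it is off by default because the
reproduction target is the fixed rule. Missing samples inside a window are
dropped with a warning rather than failing the animal.

## Flux model and conventions

The two-pool arteriovenous balance equations are given in the README. Points
where a convention had to be chosen:

* **Oxidation precursor.** `Ox = F13CO2 / (E_precursor · recovery)`. The
  default precursor is venous [1-¹³C]KIC enrichment — the reciprocal-pool
  surrogate for intracellular leucine enrichment — with arterial leucine
  enrichment selectable. The choice is recorded in the output metadata
  because published group-level tables in this field are frequently not
  reproducible from their steady-state means under either convention (see
  "Limitations").
* **Recovery correction.** Incomplete recovery of labelled CO₂ (bicarbonate
  fixation, slow pool exchange) can be divided out of the oxidation term.
  With CO₂ sampled only during the bicarbonate phase, estimating the
  recovery from the same summary that feeds the oxidation numerator would
  be circular, so the correction takes a *configured* scalar
  (`recovery_fraction`, default 0.8 when enabled) and is **off** by default
  (divisor 1.0). The limb bicarbonate recovery
  `F13CO2(bicarbonate phase) / infusion rate` is always reported as a
  diagnostic column.
* **Per-animal averaging.** All fluxes are computed per animal and averaged
  afterwards. Plugging group-mean concentrations and enrichments into the
  formulas yields ratio-of-means values that can differ from the mean of
  per-animal ratios by several percent (the package's acceptance checks
  demonstrate the discrepancy on published group means). The cohort report
  therefore warns, and flags `group-means-input`, whenever a diet group
  contains a single "animal" — the signature of aggregated input.
* **Signs.** Negative intermediate fluxes (net release, a negative labelled
  CO₂ gradient, negative apparent degradation) are propagated unchanged and
  flagged, never truncated.
* **Units.** Internal canonical units are µmol/L (PAH mg/L), fractional
  enrichment, hours, kg, and L·kg⁻¹·h⁻¹ for flow, so the flux panel lands
  directly in µmol·kg⁻¹·h⁻¹. Flow is normalised per kg body weight (not per
  kg limb), consistent with a flux panel reported per kg body weight.
* **PAH mass rate.** The protocol expresses PAH as mL/min of a solution;
  the mass rate is `mL/min · 60 · mg/mL` and the solution concentration is
  a required protocol field (default 20 mg/mL, which places limb flows at
  the ~1.3 L·kg⁻¹·h⁻¹ this preparation produces in ~20-kg animals).

## Statistics

Two-tailed pooled-variance Student's t-tests per variable (Welch
selectable), no multiple-testing correction, matching per-variable reporting
practice in animal science. Two "pooled SEM" conventions circulate; both are
reported. The headline `pooled_sem` is the pooled standard error of the
group **difference**, `sqrt(sp²·(1/n_a+1/n_b))` — the convention that
reproduces printed p-values from published means-plus-pooled-SEM tables —
with the per-group variant alongside. `t_from_summary` audits published
comparisons from means and SEMs alone
(`t = Δmean/√(SEM_a²+SEM_b²)`, df = n_a+n_b−2; identical to the raw-data
pooled test when group sizes are equal). The correlation report is the
pairwise Pearson matrix over per-animal fluxes with two-tailed p-values and
the conventional significance stars.

## The simulator

`simulate_cohort` forward-simulates the full design: 2 groups × 6 animals
(configurable), hourly sampling 0–8 h, each analyte/site series following
`X(t) = X_ss − (X_ss − X₀)·exp(−k·(t − t₀))` after its phase start.
Ground truth per animal is the arterial plateaus plus the five independent
fluxes (NB, Rd, T_net, Ox, P13); venous plateaus come from algebraically
inverting the balance equations, so the pipeline applied to a noise-free
simulated animal returns the truth exactly — the forward–inverse identity
that anchors the whole implementation. Group base truths default to the
magnitudes of the study's printed steady-state and flux tables, so a default
cohort resembles the experiment out of the box.

### Rise constants

Primed infusions are designed to hit plateau quickly; the defaults model
well-chosen primes: k = 8 h⁻¹ (leucine, KIC), 12 h⁻¹ (CO₂), 30 h⁻¹ (PAH).
With these, every analysis window sits ≥ 24 time constants past its phase
start and the plateau shortfall (≤ e⁻²⁴ ≈ 4·10⁻¹¹ relative) is far below
the 10⁻⁹ recovery tolerance the validation demands. Slower, visibly rising
curves are available by setting `k_rise` per analyte; the plateau rules are
unchanged.

### Variability model

Two layers, both truncated at physical bounds:

* **Between-animal** — mean-one lognormal multipliers on every truth
  parameter: CV 0.20 for concentrations and flow (0.10 for total CO₂, which
  is tightly regulated), 0.30 for enrichments, 0.35 for the uptake fluxes
  (NB, Rd) and 0.50 for the catabolic fluxes (T_net, Ox, P13). These were
  desk-calibrated so simulated group SEMs land within a factor of two of
  the published steady-state table's pooled SEMs at n = 6.
* **Measurement** — multiplicative Gaussian on concentrations and additive
  Gaussian on MPE per sample: CV 8 % and SD = 10 % of the plateau MPE for
  the LC-MS analytes (leucine, KIC) and the colorimetric PAH assay, but
  0.5 % for both total-CO₂ concentration and ¹³CO₂ MPE. The CO₂ figures
  reflect the instruments (an automated total-CO₂ analyser and
  isotope-ratio mass spectrometry, whose δ¹³C precision of a few tenths of
  a per mil is ~0.5–1 % of a bicarbonate-infusion plateau): the labelled-CO₂
  arteriovenous gradient is only a few percent of the labelled content, so
  an 8 %-CV CO₂ assay would make oxidation unmeasurable — and incompatible
  with the oxidation SEMs such studies report.

Infeasible jittered truths (negative venous concentration, enrichment
outside [0, 1)) are redrawn. Identical config + seed gives byte-identical
sample tables.

### Monte-Carlo engine

Replicate-study validation (recovery bias, RMSE, t-test calibration) uses a
vectorised plateau-level engine that draws each plateau-window mean from its
exact sampling distribution (a 3-sample window mean of i.i.d. noise is
itself Gaussian with SD/√3) and pushes the arrays through the same flux
algebra the file pipeline uses; only the exponential-rise transient
(≤ 4·10⁻¹¹) and the CSV plumbing are skipped, and a test pins the two
engines to identical output at zero noise. Bias estimation optionally uses
**antithetic noise pairing** (sign-flipped noise within replicate pairs):
the estimand is untouched — the noise distribution is symmetric — but the
linear noise terms cancel within each pair, so bias estimates converge
orders of magnitude faster at the same replicate count. Validation problem
sizes: 1 000 property-sampled truths for the forward–inverse identity, 500
replicate cohorts for recovery bias, 10 000 for t-test calibration.

### What passing simulations do and do not show

The generator reproduces the design's structure (plateau kinetics, AV
coupling, two variability layers) but not everything real data can do:
no within-animal temporal autocorrelation or drift in the plateau, no
correlated assay batch effects, no catheter failures or missing-sample
patterns beyond what the user injects, lognormal (hence unimodal,
positive) biology, and a self-consistent truth — whereas published group
means need not be self-consistent (see below). Recovery and calibration
results therefore validate the estimator algebra and its noise robustness,
not the assay chemistry or physiological model adequacy.

## Numerical choices

Plateau CV uses the sample SD (ddof = 1); an exactly constant window is
treated as slope-zero without a regression (the slope test is 0/0 there).
Tracer-dilution denominators (arterial leucine enrichment, precursor
enrichment) raise a division-guard error at ≤ 0; indicator dilution requires
venous > arterial PAH. Degenerate t-tests: two zero-variance samples with
equal means give p = 1; with unequal means the comparison is flagged
`degenerate-sample` (p = 0). Constant columns make Pearson correlations
undefined and raise, naming the column.

## Limitations

* Published group-level flux tables in this literature are not generally
  recoverable from their own steady-state group means — per-animal
  averaging, unprinted per-animal flows and possibly unstated recovery
  corrections intervene. In particular, an oxidation group mean can sit
  several-fold below what the printed CO₂ plateaus imply under either
  precursor convention; this package reports the convention used and leaves
  reconciliation to the analyst rather than guessing.
* The two-pool model has no intracellular compartment: utilization from
  venous-dilution of the tracer, with KIC as precursor surrogate, is the
  classic organ-balance approximation, not a three-pool biopsy model.
* Whole-body CO₂ production and the limb bicarbonate recovery come from a
  single fixed-time sample, inheriting its noise undamped.
* The t-test calibration result (empirical size ≈ 0.046–0.049 at α = 0.05
  under the null) reflects mildly skewed lognormal per-animal fluxes at
  n = 6 with equal group sizes; heavier-tailed real data may deviate more.
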