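# Methods

This note documents the models behind each analysis stage, the defaults that
matter, what the synthetic generators do and do not emulate, and the design
choices made where the procedure was genuinely open.

## Units and conventions

Time in seconds, concentrations in mM, chamber volume in ml, protein in mg,
temperature in °C; alamethicin is dosed by mass (µg). Trace time stamps must
be strictly increasing; exactly repeated stamps (an instrument-export
artifact) are collapsed by averaging, decreasing stamps are an error — they
are never silently reordered, because the flux and rate stages differentiate
or regress against time. Every operation that drops, clamps or interpolates
data logs a structured record with counts; pure math operations are silent.

## Mg²⁺ speciation and the ADP-ATP exchange rate

The speciation system holds conserved totals (Mg_T; adenine A_T = ATP_T +
ADP_T, conservation enforced in practice by the adenylate-kinase inhibitor
Ap5A in the assay buffer; indicator dye D_T) and three dissociation
constants, default K_ATP = 0.04 mM, K_ADP = 0.35 mM, K_MgG = 1.0 mM. The
conservation law

    Mg_T = Mg_f·[1 + ATP_T/(K_ATP+Mg_f) + ADP_T/(K_ADP+Mg_f) + D_T/(K_MgG+Mg_f)]

is strictly increasing in Mg_f, so the forward problem (Mg_f given ATP_T)
has a unique root in (0, Mg_T]; `free_mg_given_atp` solves it by plain
bisection to < 1e-12 mM and is kept deliberately primitive so it can serve
as the oracle for the closed-form inverse

    ATP_T = [Mg_T − Mg_f − D_T·β_MgG − A_T·β_ADP] / (β_ATP − β_ADP),
    β_X = Mg_f/(K_X + Mg_f),

which requires K_ATP < K_ADP (enforced at configuration time: with equal
affinities the ATP/ADP split is unidentifiable). ATP_T within 1e-6 mM
outside [0, A_T] is clamped (numeric noise at the endpoints); larger
excursions are an inconsistent-input error. A_T is taken from the ADP
addition amount in the event log; contaminating basal nucleotides are
assumed zero. EGTA (0.1 mM in the assay buffer) is ignored in the
speciation — its Mg²⁺ affinity near pH 7.25 is orders of magnitude weaker
than the nucleotides' — but an optional extra ligand (L_total, Kd_L) is
supported for sensitivity checks.

The exchange rate is the OLS slope of the reconstructed [ATP](t), reported
in mM/min with its standard error and the window used. The default "auto"
window runs from 5 s after the ADP addition to whichever comes first of
60 s later or 25% of A_T consumed: the early phase is quasi-linear, and the
window is always reported because the choice is a convention, not a
measurement. Mass-specific rates (nmol·min⁻¹·mg⁻¹ = mM/min × chamber ml ×
1000 / protein mg) are reported alongside, since the field uses both scales.

## Indicator calibrations

* **Endpoint (MgG):** F_min = plateau median after 5 mM EDTA, F_max after
  25 mM MgCl₂. Settling convention everywhere: 10 s after an addition is
  excluded (mixing artifact), the plateau is the median of the following
  20 s, truncated at the next event. Signals within 2% of (F_max − F_min) of
  an endpoint are clamped with a warning (noise should not hard-fail a run);
  beyond that band they are saturation/below-floor errors, and in whole-trace
  reconstruction such samples are flagged NaN rather than aborting the run
  (with a quality warning above 5% flagged).
* **Safranine O (ΔΨm):** percentage scale with the pre-ADP plateau as 100%
  polarization and the post-SF 6847 plateau as 0%. At 495/585 nm with 5 µM
  dye the fluorescence is taken to **rise** on depolarization (quench-mode
  convention); only the two endpoints enter the formula, so the percentage
  is invariant to gain/offset changes. The ADP-induced depolarization depth
  is 100 minus the minimum of a 2 s rolling median of polarization over the
  post-ADP window — the median guard keeps single-sample noise from
  inflating depths.
* **BCECF (matrix pH):** pH = a·exp[b/(x + c)] fitted to ≥ 4 buffer points
  spanning ≥ 0.5 pH units. The ratio orientation is F(490)/F(450)
  (pH-sensitive over quasi-isosbestic), overridable upstream. The model's
  convergence basin is narrow, so the fit seeds a grid search over c (with
  ln a and b solved linearly in log space) and refines with 5 multi-start
  Levenberg–Marquardt runs perturbed ±50%; r² is computed on pH values and
  per-parameter standard errors come from the covariance. Ratios beyond the
  calibrated range ± 10% of its width get a range warning; x + c ≤ 0 is a
  domain error.
* **Scatter (swelling):** S(t) = 100·(A − A_alm)/(A_0 − A_alm) with A_0 the
  pre-first-addition plateau and A_alm the post-alamethicin plateau.
  Swelling = a sustained (≥ 30 s) drop of the pre-alamethicin signal below
  85% (threshold configurable); the alamethicin calibration drop itself can
  therefore never classify as swelling.

## Ca²⁺ capacity counting

Per bolus: baseline = median of the 5 s before the addition; peak = median
of 2 s around the maximum within 15 s after it (never reaching back before
the addition); the residual fraction of the step is read at the decision
time (next event, 120 s, or trace end). "No further decrease" is
operationalized as residual ≥ 0.5 at decision time — the threshold is a
package convention (no numeric criterion exists for it), is configurable,
and is echoed in every report. Counting is of *consecutive* sequestered
boluses from the start; the first failure terminates the count and the
failing addition is excluded. Steps at or below 3× the normal-scaled MAD of
the baseline are kept as unsequestered with a warning. Bolus amounts come
from the event log only — Calcium Green 5N is used qualitatively and never
converted to concentration. Capacity is reported per mg of loaded protein,
uncorrected for non-mitochondrial contamination (a correction factor exists
in the config and defaults to 1).

## Respiration

Flux = −dC/dt·1000/(protein/volume), pmol O₂·s⁻¹·mg⁻¹. The derivative is a
centered moving OLS slope (Savitzky–Golay, polynomial order 1, derivative 1)
over a 10 s window by default; half a window is trimmed at each end, and an
integral-consistency property test guards that smoothing preserves mass
balance to < 1%. Segments are delimited by addition events and labelled by
the preceding compound (basal, state3, post_cATR, uncoupled, post_KCN); each
segment excludes 10 s of settling after the addition and 6 s before the next
(so the smoothing window never straddles a boundary), and segments shorter
than 15 s after exclusions are skipped with a warning. Dithionite segments
are always excluded (non-biological oxygen removal). The RCR numerator is
state 3; the denominator defaults to post-cATR (ANT blocked, state-4-like)
with basal as fallback — the choice is recorded in the output and both
ratios are reported, since either convention exists in practice. The
post-KCN segment is the chemical-background check: post-KCN flux < 2% of
state 3 sets the cyanide-sensitivity flag.

## Synthetic generators

The generators are phenomenological forward models of the *measured
signals*, not mechanistic ODE models of bioenergetics. Species presets carry
the generative truth: capacity 1.2 (crangon), 0.6 (palaemon), 2.0 (artemia),
0.4 (mouse-liver) µmol/mg; exchange rates 0.10 / 0.08 / 0.40 / 0.30 mM/min
(the brine-shrimp preset is 4× the brown-shrimp one); state fluxes
(basal, state3, post_cATR, uncoupled, post_KCN) = (150, 200, 100, 320, 1)
pmol·s⁻¹·mg⁻¹, i.e. RCR 2.0 with uncoupled 1.6× state 3; ADP-depolarization
depths 25 / 25 / 50 / 60% of full scale; swelling on Ca²⁺ load only in the
mouse-liver preset (and not under cyclosporin A). ANT-ligand pre-treatments
inhibit exchange by a fixed 0.9 (BKA, cATR) on sensitive species and 0 on
artemia; the BKA vehicle (NH₄OH) by 0.05.

* **Exchange runs:** ADP (2 mM) at 60 s; ATP_T(t) = min(r·Δt, 1.0 mM)·(1−inh);
  free Mg²⁺ from the bisection oracle; fluorescence through the isotherm
  (F_min 100, F_max 600 afu); EDTA at 240 s and MgCl₂ at 270 s close the run.
  5 Hz sampling throughout, as in the assay protocol.
* **Ca runs:** boluses (default 100 µM in-chamber) every 120 s; each step
  decays first-order (k = 0.05 s⁻¹; the final sequestered bolus 10% slower,
  emulating the small end-of-capacity variability) while cumulative uptake is
  below capacity, then not at all; one unsequestered bolus precedes the
  alamethicin scatter calibration. The scatter channel is flat for
  no-swelling presets and drops sigmoidally (40% deep, 20 s time constant)
  after capacity for swelling presets.
* **Safranine runs:** depolarization depth = d_max·(1 − inh(dose, pH_in));
  the inhibition is a Hill curve (h = 2, IC50 2.5 µM at reference pH_in
  7.33) whose effective concentration scales with the protonated-BKA
  fraction (Henderson–Hasselbalch, pKa 5.5 — the protonation requirement is
  established pharmacology, the pKa a modeling choice). pH_in is an affine
  map of pH_o per species (mouse: +0.03; artemia: 7.05 + 0.5·(pH_o − 6.7);
  crangon/palaemon: +0.10), anchored to the two reported pH_o→pH_in pairs
  and otherwise a labelled modeling convenience.
* **Oxygraph runs:** piecewise-linear O₂ decline whose slopes encode the
  truth fluxes; additions ADP 0.2 mM / cATR 2 µM / SF 6847 1 µM / KCN 1 mM
  at 180 s intervals, then dithionite driving the chamber anoxic.

**Noise model.** Additive Gaussian, per-channel sd expressed as a fraction
(default 1%) of the channel's biologically driven signal excursion for the
phase being analysed: the exchange-phase excursion for MgG, one bolus step
for Calcium Green, the full normalization span for scatter and safranine.
The O₂ channel uses an absolute default of 0.2 µM, typical of polarographic
sensors. Tying the MgG noise to the biological excursion (rather than the
calibration span) reflects that the informative signal change in a slow
exchange run is small and the analysis operates on that scale; it also makes
the relative precision of the rate estimate approximately rate-independent.
Identical (preset, seed) pairs produce bit-identical CSV output.

**What passing tests do and do not show.** The generators use white Gaussian
noise, instantaneous mixing, perfectly conserved totals, ideal single-site
indicator response, and step-like additions. Real traces add drift,
photobleaching, correlated (1/f) noise, mixing transients longer than 10 s,
basal contaminating nucleotides, and indicator non-ideality near saturation
— so round-trip recovery here validates the *algebra and estimators*, not
robustness to every instrumental artifact. Where a real run violates the
assumptions, the pipelines are designed to say so (clamp warnings, flagged
samples, window provenance) rather than fail silently.

## Problem sizes and runtimes

Test and acceptance runs use 5-minute exchange traces (1 500 samples),
capacity runs of 4–11 boluses (4 000–7 000 samples), 15.5-minute oxygraph
runs (4 650 samples), 11-point pH calibrations, and 1 000-system speciation
sweeps — sizes chosen to match the simulated protocols while keeping the
full suite in the seconds range on one CPU.

## Known limitations

* Calcium Green 5N is never calibrated to absolute [Ca²⁺]; capacity relies
  on bolus counting only, so the granularity is one bolus.
* Safranine is not converted to millivolts; all ΔΨm statements are on the
  percentage scale, and the sign convention (fluorescence rises on
  depolarization) is a configurable default.
* The exchange model ignores membrane-potential dependence of ANT flux and
  any basal nucleotide pool; rates are operational slopes over a stated
  window, not kinetic constants.
* Whether reported exchange rates should be normalized per mg protein is
  left to the caller: both mM/min and nmol·min⁻¹·mg⁻¹ are computed.
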