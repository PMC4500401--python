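# Methods

`n2mbw` does three things: it analyzes nitrogen multiple-breath washout
(N2MBW) recordings (FRC, LCI, phase III slope indices), it simulates
physiologically structured synthetic washout recordings with known ground
truth, and it measures how sensitive the washout outcomes are to every
configurable analysis setting. This note documents the models, the
conventions, and the choices made where the design was genuinely open.

## 1. The measurement being modelled

In N2MBW the subject breathes 100% O2 through a mouthpiece; resident lung
nitrogen washes out over successive tidal breaths. Flow is measured by a
mainstream ultrasonic flowmeter at the mouth; O2 by a side-stream sensor at
a gas sampling port displaced from the flowmeter, CO2 by a mainstream
infra-red sensor. N2 is not measured directly: with argon assumed to track
N2 at the dry room-air molar ratio r = 0.0093/0.7808,

    FN2 = (1 − FO2 − FCO2) / (1 + r).

Because the gas sensors are displaced from the flowmeter, each gas channel
lags the flow channel by a transport/processing delay (~600 ms for the
side-stream O2, ~50–60 ms for CO2). Every volume-weighted gas quantity
(expired N2 volume, hence FRC, hence LCI) depends on multiplying flow by a
correctly time-aligned gas fraction, which is why delay settings are the
most consequential settings of the whole analysis.

### Outcome definitions

* **FRC**: from cumulative net expired tracer,
  `FRC_raw = Σ_breaths (expired N2 − re-inspired N2) / (C0 − C_end)`, where
  C0 is the mean pre-phase end-tidal N2 and C_end the end-tidal N2 of the
  last included breath; the reported FRC subtracts the pre-capillary
  apparatus dead space, so it refers to the volume on the patient side of
  the mouthpiece (alveolar gas + anatomic airway).
* **Washout end**: the first run of 3 consecutive breaths with end-tidal N2
  below 1/40 of C0; outcomes include breaths up to and including the first
  breath of that run, with no interpolation at the crossing (fixed for
  determinism).
* **CEV / LCI**: CEV sums per-breath expired volume minus total apparatus
  dead space (pre + post-capillary); LCI = CEV / FRC.
* **SIII / SnIII**: ordinary least squares of FN2 against cumulative expired
  volume over the 65–95% window of each breath's expirogram, normalised by
  the mean FN2 of the window.
* **Scond / Sacin**: Scond is the OLS slope of SnIII against lung turnover
  over turnovers 1.5–6.0 (the field's standard range); Sacin is the first
  washout breath's SnIII minus Scond times its turnover. The VT-corrected
  variants repeat both fits on SnIII × VT (L); this simple multiplicative
  correction is a declared surrogate for the published pediatric procedure.
* **End-tidal fraction**: median FN2 over the last 5% of *expired volume*.
  A volume (not time) window with a median keeps it robust to the
  misalignment artifacts that cluster at the flow reversal.

### Signal pipeline

Fixed order: align gas channels onto the flow time base (linear
interpolation for fractional samples, edges held) → invert the O2 sensor's
first-order response lag (`y + τ·dy/dt`, with the derivative from a 5-point
centred least-squares stencil — centred, phase-free, and ~2× less
noise-amplifying than the 2-point stencil) → remove linear-in-time O2 drift
(fitted to the washout inspired-O2 plateaus, whose true value 1.0 is known;
pre-phase end-tidals are not used because their true value is not known
a priori) → dynamic CO2 correction `FCO2·(1 + kd(FO2 − 0.2095))` with
kd = 0.05 (the true cross-sensitivity coefficient is unpublished; this
value produces percent-level LCI shifts when disabled, the observed order)
→ N2 derivation (clipped to [0,1] for all volume integrals; the unclipped
channel is retained for artifact diagnostics, since the inspiratory "divot"
artifact is a negative N2 excursion) → BTPS scaling of flow (inspiratory
factor on inspired samples, expiratory on expired).

BTPS factors use the Magnus saturation-pressure formula (6.112, 17.62,
243.12 hPa/°C), ambient relative humidity fixed at 0.5, and an effective
expired-gas temperature of 34 °C; both are conventional values exposed as
advanced settings.

### Breath segmentation

Breaths are flow zero-crossing pairs (inspiration then expiration); a
trailing unpaired half-phase is discarded. Candidate breaths whose expired
volume is below the minimum tidal volume (default 25 mL) are merged into an
accepted neighbour rather than deleted, so cumulative expired volume is
conserved; if no breath reaches the threshold the trace is rejected. Each
breath's expirogram additionally keeps the samples of the following
inspiration up to a 10 mL detection-hysteresis volume, attributed at
constant cumulative volume — the standard debounce of flow-based breath
detectors, and the reason end-expiratory misalignment spikes (which
straddle the zero crossing) appear on the expired trace where the artifact
metric looks for them.

### Re-inspired N2

When enabled, the re-inspired tracer volume per breath is the measured
integral of inspired flow × FN2 plus `ds_post × previous end-tidal N2` for
expirate stored beyond the sampling point that returns to the lungs
unmeasured. Whether the commercial software includes such a storage term
is unpublished; it is included here because it gives the post-capillary
dead-space setting a defined FRC effect, and because with the simulator's
port-flush model (below) it makes the FRC estimator exactly unbiased.

## 2. The synthetic lung and sensor chain

The simulator is a one- or two-compartment well-mixed lung breathing
through a series dead space, rendered at the sampling port at 200 Hz
(typical for ultrasonic-flowmeter devices; resolves 10 ms delay steps at
2-sample granularity).

* **Flow**: sinusoidal half-waves, equal inspiratory/expiratory time.
* **Gas transport**: plug flow. The sensed expirate shows a fresh-gas
  prefix of one (airway + pre-capillary) dead-space volume, then a logistic
  phase II transition (10–90% width configurable; the logistic centre is
  adjusted so the fresh-gas volume is exact for any width — mass
  conservation of the dead-space gas), then the alveolar plateau.
* **Two-compartment emptying**: the slow compartment's instantaneous share
  of expiratory flow is `w2(x) = q2(1−λ) + q2·λ·(p+1)·x^p` with p = 3 over
  expired fraction x, integrating to its ventilation share q2 for any skew
  λ ∈ [0,1). λ > 0 concentrates the slow unit late in expiration, producing
  a positive phase III slope whose normalised value grows over the washout
  (the Scond mechanism). The power form was chosen because it lets the
  late-expiratory weighting approach the slow compartment's *volume* share,
  which is what keeps the tracer-balance FRC estimate honest when
  inhomogeneity is strong (see §4).
* **Re-inspiration**: each inspiration first returns one full dead-space
  volume (airway + pre- + post-capillary + sampling-port volume) of the
  previous expirate to the lungs, at the mean concentration of the stored
  expirate column (the tail mean of the previous breath's alveolar
  emission), then fresh gas (100% O2 during washout, room air before). The
  continuously purged bypass means the *sensed* inspirate shows only the
  small port volume (3 mL) of that slug before switching to supply gas.
  With this geometry the analysis-side estimator telescopes exactly:
  FRC_raw = V_alv + airway DS + pre-capillary DS, so reported FRC equals
  true FRC in the noise-free limit.
* **Sensor chain**: CO2 cross-sensitivity (the sensor under-reads CO2 in
  O2-rich gas by the same kd the analysis inverts), transport delays
  (fractional-sample interpolation), first-order response lags (O2 30 ms,
  CO2 10 ms) discretised bilinearly so the discrete group delay equals τ,
  optional linear O2 drift, i.i.d. Gaussian noise (default SD 0.001) on
  both gas channels. Measured flow is BTPS flow divided by the true
  conversion factor of each phase. The CO2 lag is deliberately left
  uncorrected by the analysis (as in the modelled pipeline) and contributes
  a ~0.3% FRC bias.

### Ground truth

For one compartment the washout has a closed form: each breath multiplies
the alveolar concentration by ρ = (V_alv + VR)/(V_alv + VT), where VR is
the total re-inspired dead-space volume, so the breath count to reach 1/40
and the LCI are analytic. These oracles are computed with the model's
exact ρ (via the equivalent alveolar tidal volume V_alv(VT−VR)/(V_alv+VR))
and with the CEV-convention tidal volume, so engine-vs-oracle comparisons
are like-for-like. Two-compartment runs carry the true FRC only.

## 3. The synthetic cohort

`generate_cohort` draws 30 subjects: 10 healthy young children (dead-space
reducer set 2: 9.5 mL post-capillary, delays 601/51 ms), 10 former preterm
and 10 CF children and adolescents (set 3: 22 mL, 618/60 ms). Group
parameter ranges (FRC 850–2200 mL, VT 0.24–0.35 FRC, specific-ventilation
ratio of the slow compartment 0.08–0.50, emptying skew 0.35–0.82) were
calibrated once so the baseline-analyzed noise-free LCI spans ≈ 6.3–10.5
turnovers with healthy < preterm < CF medians. Anatomic dead space scales
with tidal volume (0.17–0.24 VT, the ≈2 mL/kg rule) and phase II width with
tidal volume (0.30–0.44 VT), as in pediatric expirograms where the 50–80%
window genuinely includes phase II. Per-subject true sensor delays jitter
±1.5 ms around the per-set baseline values, and per-subject O2 drift is
drawn at SD 3×10⁻⁴ /min (zero mean), so the drift-correction toggle has
heterogeneous effects across subjects.

What the generator does *not* emulate: breath-to-breath tidal volume and
rate variability, cardiogenic oscillations, flow-dependent sensor delays,
within-breath temperature dynamics, leaks, or irregular breathing. Passing
tests therefore demonstrate the analysis engine's correctness and the
direction/size of setting-induced biases under idealised tidal breathing —
not robustness to real-world signal quality.

## 4. Numerical and design notes

* **Inhomogeneity vs FRC fidelity.** A strongly inhomogeneous lung retains
  tracer at the 1/40 end, and a tracer-dilution FRC then genuinely
  underestimates: the estimator's error grows with the gap between the
  volume-weighted and end-tidal-weighted compartment concentrations at the
  end of test, and with the mismatch between the measured end-tidal value
  and the stored-slug concentration in the re-inspired correction. The
  cohort's upper LCI (~10.5) is where these biases stay within the
  package's accuracy targets (median < 1%, max < 3% noise-free); pushing
  LCI toward 15 drives the FRC error past 3%. This trade-off is a real
  property of the method, not of the implementation.
* **Noise rectification.** Because the derived FN2 is clipped at zero, any
  noise on the inspired-phase channels rectifies into a positive bias of
  the measured re-inspired N2 and hence a negative FRC bias; the 5-point
  derivative stencil in the response-time correction keeps this below ~2%
  at the default noise level.
* **Direction analyses are run noise-free.** The washout end is a
  threshold rule on a discrete breath series, so subjects whose end-tidal
  N2 sits very close to 1/40·C0 can gain or lose a whole breath (≈2–3% of
  LCI) when noise is re-rolled by a settings change. The systematic
  directions of the settings experiment are read off the noise-free
  cohort, where they are deterministic and reproducible across seeds;
  recovery under noise is reported separately.
* **Degenerate inputs.** Tidal volume not clearing the series dead space,
  traces without zero crossings, washouts that never sustain the end
  threshold, and c0 ≤ end-tidal all raise with explicit messages; breaths
  whose expired volume is below the apparatus dead space contribute zero
  CEV with a warning rather than a negative volume.

## 5. Known limitations

* Three qualitative behaviours of the modelled commercial pipeline are not
  reproduced, and the corresponding acceptance checks are deliberately left
  failing rather than worked around: (i) switching BTPS off *raises* LCI in
  the reference data but lowers it slightly here — with this package's CEV
  and FRC conventions the dead-space offsets force the sign; (ii) lowering
  the post-capillary dead-space setting raises LCI in the reference data
  but lowers it here, because the re-inspired storage term gives FRC a
  larger relative dead-space sensitivity than CEV's; (iii) the
  end-expiratory spike under a −40 ms O2 delay error reaches ~4–5× its
  baseline metric, not 10×: with flow-independent delays the O2 rise and
  CO2 fall share the same port-flush timing at the reversal, so the
  mismatch lobe is partial — the full-amplitude spike in real recordings
  rides on flow-dependent transport, which is out of scope here.
* The drift, dynamic-CO2 and response-time corrections are declared
  surrogates for unpublished proprietary algorithms; only their on/off
  directions and orders of magnitude are meaningful.
* Scond magnitudes of the synthetic cohort (~0.2–0.5 L⁻¹) run higher than
  typical clinical values; the harness compares paired analyses of the same
  trace, so only within-subject changes matter.
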