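# n2mbw

Nitrogen multiple-breath washout (N2MBW) analysis engine with a synthetic
tidal-breathing simulator and a settings-sensitivity harness.

N2MBW measures ventilation inhomogeneity — an early marker of peripheral
lung disease in cystic fibrosis and other pediatric conditions — by washing
resident lung nitrogen out with 100% O2 over many tidal breaths. Its
outcomes are FRC (lung volume at end-expiration, from the tracer balance
FRC = ΣN2,net / (C0 − Cend)), LCI (cumulative expired volume needed to
reach 1/40 of the starting N2, divided by FRC) and the phase III slope
indices Scond and Sacin. Because N2 is computed indirectly as
FN2 = (1 − FO2 − FCO2)/(1 + r) from sensors that are physically displaced
from the flowmeter, every outcome depends on software settings: flow–gas
delay times, sensor corrections, apparatus dead spaces, environmental
(BTPS) conversion. This package quantifies how much each setting matters
by re-analyzing the same raw signals under systematically perturbed
settings — a measurement-bias sensitivity analysis, with paired Wilcoxon
signed-rank tests, Bland–Altman limits of agreement and 5–10% / >10%
relevance counts over a 30-subject cohort.

Raw clinical signal files for this kind of study are not publicly
deposited, so the package includes a first-class forward model: a one- or
two-compartment tidal-breathing lung with series dead space, plug-flow gas
transport, sequential compartment emptying (positive phase III slopes), and
a sensor chain with transport delays, first-order response lags, CO2
cross-sensitivity, drift and noise. Every simulated trace carries its
ground truth, and the one-compartment case has closed-form breath-count
and LCI oracles.

## Layout

    src/n2mbw/        library: domain types & settings (domain.py),
                      simulator (simulate.py), signal pipeline (signals.py),
                      breath segmentation (breaths.py), outcomes
                      (outcomes.py), sensitivity harness (sensitivity.py),
                      paired statistics (stats.py), text-format IO (io.py),
                      CLI (cli.py)
    analysis/         numbered drivers: 01 simulate cohort, 02 baseline
                      outcomes, 03 sensitivity grid, 04 summary figures
    scripts/          acceptance.py (see "Reproducing the results")
    tests/            pytest suite
    docs/methods.md   models, conventions, calibration and limitations

## Worked example

```python
from n2mbw import (LungParams, SensorChainParams, default_profile,
                   simulate_subject, analyze_trace)

profile = default_profile(2)          # dead-space set 2: 601/51 ms delays
lung = LungParams(frc_mL=1000, vt_mL=300, airway_ds_mL=50, n_compartments=1)
sensors = SensorChainParams(noise_sd_fraction=0.0, seed=1)
trace, truth = simulate_subject(lung, sensors, profile)

out = analyze_trace(trace, profile)
print(f"FRC {out.frc_mL:.0f} mL  LCI {out.lci:.2f}  "
      f"breaths {out.n_washout_breaths} (analytic {truth.analytic_breath_count})")

bad = analyze_trace(trace, profile.replace(o2_delay_ms=561))  # -40 ms error
print(f"misaligned: FRC {bad.frc_mL:.0f} mL  LCI {bad.lci:.2f}")
```

prints

    FRC 1004 mL  LCI 5.31  breaths 20 (analytic 20)
    misaligned: FRC 917 mL  LCI 5.81

The aligned analysis recovers the true 1000 mL FRC within 0.5% and ends the
washout on exactly the breath the single-compartment dilution formula
predicts. Setting the flow–O2 delay 40 ms too low pushes the N2 waveform
late relative to flow: measured expired N2 drops (FRC −8.7%) and LCI rises
by 9.5% — the misalignment bias this kind of sensitivity analysis is
designed to expose.

The same from a shell:

    n2mbw simulate --cohort-seed 1 --out cohort/
    n2mbw analyze --trace cohort/healthy00.tsv \
                  --settings cohort/healthy00.settings.yaml --out out.csv
    n2mbw sensitivity --cohort cohort/ --grid full --out sens/
    n2mbw report --results sens/ --out report/

The full experiment over the default cohort (`analysis/01` … `04`)
re-analyzes 30 subjects under 32 perturbations in four groups —
environmental conditions, apparatus dead space, signal-processing toggles
and detection limits, and delay times — and writes per-subject changes,
per-group effect tables, an arrow-style direction summary and Bland–Altman
data under `results/`.

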