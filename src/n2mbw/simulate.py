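"""Synthetic tidal-breathing N2 washout simulator with known ground truth.

The forward model is a one- or two-compartment well-mixed lung breathing
through a series dead space (anatomic airway + pre-capillary apparatus +
post-capillary apparatus), sampled at the gas port of the apparatus:

* Flow is sinusoidal half-waves (equal inspiration/expiration time).
* Gas transport is plug flow: the expirate sensed at the port shows a
  fresh-gas prefix of one (pre-capillary + airway) dead-space volume,
  then a logistic phase II transition into the alveolar plateau.
* Two compartments empty in parallel with flow shares that drift linearly
  toward the slow compartment over the expiration (``emptying_skew``),
  which generates a positive phase III slope that steepens, relative to
  the mean concentration, as the washout proceeds.
* On inspiration the lungs re-inspire one full dead-space volume of the
  previous expirate (airway + pre- + post-capillary + sampling-port
  volumes) before fresh gas; the continuously purged bypass means the
  sensed inspirate shows only the small port volume of that slug before
  switching to supply gas.
* The sensed O2/CO2 channels are then distorted the way the real sensor
  chain distorts them: CO2 cross-sensitivity to O2, transport delays,
  first-order response lags, optional linear O2 drift, Gaussian noise.
  Measured flow is the body-conditions (BTPS) flow divided by the true
  inspiratory/expiratory conversion factors.

Every simulated trace carries a GroundTruth record; for the
one-compartment case the washout breath count and LCI have closed forms
used as oracles.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
from scipy.signal import lfilter
from scipy.special import expit

from .domain import ROOM_AIR, ARGON_N2_RATIO, SettingsProfile, SignalTrace, default_profile
from .signals import btps_factors

#: True CO2-sensor cross-sensitivity to O2 (the analysis default inverts it).
KD_CO2_TRUE = 0.05


@dataclass
class LungParams:
    """Physiological parameters of one simulated subject.

    ``frc_mL`` is the total lung volume at end-expiration (alveolar gas plus
    anatomic airway dead space) — the quantity a tracer washout reports.
    ``emptying_skew`` (lambda >= 0) weights late expiration toward the slow
    compartment, producing a positive phase III slope.
    """

    frc_mL: float
    vt_mL: float
    rr_per_min: float = 20.0
    airway_ds_mL: float = 50.0
    n_compartments: int = 1
    compartment_volume_fractions: tuple[float, ...] = (1.0,)
    compartment_ventilation_fractions: tuple[float, ...] = (1.0,)
    emptying_skew: float = 0.0
    prephase_breaths: int = 4
    etco2_fraction: float = 0.05
    phase2_width_mL: float = 30.0  # 10-90% width of the logistic transition

    def __post_init__(self) -> None:
        if self.frc_mL <= 0:
            raise ValueError("frc_mL must be positive")
        if self.frc_mL <= self.airway_ds_mL:
            raise ValueError("frc_mL must exceed the airway dead space")
        if self.n_compartments not in (1, 2):
            raise ValueError("n_compartments must be 1 or 2")
        for name in ("compartment_volume_fractions",
                     "compartment_ventilation_fractions"):
            fr = getattr(self, name)
            if len(fr) != self.n_compartments or abs(sum(fr) - 1.0) > 1e-9:
                raise ValueError(f"{name} must have {self.n_compartments} "
                                 "entries summing to 1")
        if self.emptying_skew < 0:
            raise ValueError("emptying_skew must be >= 0")


@dataclass
class SensorChainParams:
    """True (to-be-inverted) properties of the sensor chain."""

    true_o2_delay_ms: float = 601.0
    true_co2_delay_ms: float = 51.0
    o2_response_tau_ms: float = 30.0
    co2_response_tau_ms: float = 10.0
    o2_drift_per_min: float = 0.0  # additive fraction per minute
    noise_sd_fraction: float = 0.001
    port_volume_mL: float = 3.0  # sampling-port volume sensed of the slug
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("true_o2_delay_ms", "true_co2_delay_ms",
                     "o2_response_tau_ms", "co2_response_tau_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """What the simulator knows that the analysis must recover."""

    frc_mL: float
    analytic_lci: float | None = None  # one-compartment only
    analytic_breath_count: int | None = None
    n_washout_breaths: int | None = None  # breaths simulated to the stop rule
    c0: float = ROOM_AIR["fn2"]
    params: dict[str, Any] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Closed-form oracles (single-compartment dilution)
# ---------------------------------------------------------------------------

def analytic_breath_count(frc_mL: float, alveolar_vt_mL: float,
                          end_fraction: float) -> int:
    """Breaths for a single well-mixed compartment to dilute below a fraction.

    Each breath multiplies the tracer concentration by
    ``frc/(frc + alveolar_vt)``; returns the smallest n >= 1 with
    ``ratio**n <= end_fraction``.
    """
    if alveolar_vt_mL <= 0:
        raise ValueError("alveolar_vt_mL must be positive")
    if frc_mL <= 0:
        raise ValueError("frc_mL must be positive")
    ratio = frc_mL / (frc_mL + alveolar_vt_mL)
    if end_fraction >= 1.0:
        return 1
    n = math.ceil(math.log(end_fraction) / math.log(ratio) - 1e-12)
    return max(1, n)


def analytic_lci(frc_mL: float, vt_mL: float, alveolar_vt_mL: float,
                 end_fraction: float) -> float:
    """LCI of the single-compartment washout: breaths x VT / FRC."""
    n = analytic_breath_count(frc_mL, alveolar_vt_mL, end_fraction)
    return n * vt_mL / frc_mL


def effective_alveolar_vt(v_alv_mL: float, vt_mL: float,
                          reinspired_mL: float) -> float:
    """Alveolar tidal volume equivalent to dilution with re-inspiration.

    With a re-inspired dead-space volume VR of own expirate, the per-breath
    dilution ratio is (V+VR)/(V+VT); this returns the alveolar VT whose
    plain ratio V/(V+VA) equals it.
    """
    return v_alv_mL * (vt_mL - reinspired_mL) / (v_alv_mL + reinspired_mL)


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------

_EMPTYING_POWER = 3


def _emptying_weights(x: np.ndarray, q: np.ndarray, lam: float) -> np.ndarray:
    """Flow share of the slow compartment at expired fraction x (2-comp).

    ``w2(x) = q2*(1 - lam) + q2*lam*(p+1)*x**p`` with p = 3: integrates to
    the slow compartment's ventilation share q2 for any skew lam in [0, 1),
    is flat at lam = 0, and concentrates the slow unit's contribution in
    late expiration as lam grows (sequential emptying).
    """
    p = _EMPTYING_POWER
    w2 = q[1] * (1.0 - lam) + q[1] * lam * (p + 1) * x ** p
    return np.clip(w2, 0.0, 1.0)


def simulate_subject(lung: LungParams, sensors: SensorChainParams,
                     settings: SettingsProfile | None = None,
                     sample_rate: float = 200.0,
                     ) -> tuple[SignalTrace, GroundTruth]:
    """Simulate one subject's full washout recording.

    The trace contains ``prephase_breaths`` room-air breaths followed by
    100%-O2 washout breaths until the alveolar end-expirate has stayed below
    ``washout_end_fraction`` of the starting N2 for
    ``washout_end_consecutive_breaths`` breaths, plus two extra breaths.
    """
    if settings is None:
        settings = default_profile(2)
    r = ARGON_N2_RATIO
    vt = lung.vt_mL
    v_alv = lung.frc_mL - lung.airway_ds_mL
    vr = (lung.airway_ds_mL + settings.ds_pre_mL + settings.ds_post_mL
          + sensors.port_volume_mL)
    if vt <= vr:
        raise ValueError("no alveolar ventilation: tidal volume does not "
                         "clear the series dead space")
    vols = np.array(lung.compartment_volume_fractions) * v_alv
    q = np.array(lung.compartment_ventilation_fractions)
    lam = lung.emptying_skew if lung.n_compartments == 2 else 0.0
    if lung.n_compartments == 2:
        if lam >= 1.0:
            raise ValueError("emptying_skew must be < 1")
        w_edges = _emptying_weights(np.array([0.0, 1.0]), q, lam)
        if w_edges[0] < 0.0 or w_edges[1] >= 1.0:
            raise ValueError("emptying_skew too large for the ventilation split")

    dt = 1.0 / sample_rate
    n_half = max(2, round(sample_rate * 30.0 / lung.rr_per_min))
    t_half = n_half * dt
    flow_amp = math.pi * vt / (2.0 * t_half)
    # within-phase sample times (phase-local, first sample at t=dt)
    tk = (np.arange(n_half) + 1) * dt
    vol_of_t = vt * (1.0 - np.cos(math.pi * tk / t_half)) / 2.0
    flow_half = flow_amp * np.sin(math.pi * tk / t_half)

    f_insp_true, f_exp_true = btps_factors(
        settings.ambient_temp_C, settings.ambient_pressure_hPa, enabled=True,
        rh=settings.ambient_rh, expired_temp_C=settings.expired_temp_C)

    w_sig = lung.phase2_width_mL / 4.0  # logistic scale from 10-90% width
    v0 = settings.ds_pre_mL + lung.airway_ds_mL  # fresh prefix of expirate
    # centre the phase II logistic so the fresh-gas (dead-space) volume of
    # the expirate equals v0 exactly for any transition width
    v0_c = v0
    for _ in range(3):
        v0_c = v0 - w_sig * math.log1p(math.exp(-v0_c / w_sig))
    m_port = sensors.port_volume_mL
    w_port = max(m_port / 3.0, 0.25)
    m_port_c = m_port
    for _ in range(3):
        m_port_c = m_port - w_port * math.log1p(math.exp(-m_port_c / w_port))

    c = np.full(lung.n_compartments, ROOM_AIR["fn2"], dtype=float)
    c0 = ROOM_AIR["fn2"]
    threshold = settings.washout_end_fraction * c0
    etco2 = lung.etco2_fraction

    def end_mix(conc: np.ndarray) -> float:
        if lung.n_compartments == 1:
            return float(conc[0])
        w2 = float(_emptying_weights(np.array([1.0]), q, lam)[0])
        return (1.0 - w2) * conc[0] + w2 * conc[1]

    # stored-gas (re-inspired slug) concentration: mean of the alveolar mix
    # over the last `vr` millilitres of the expirate column (the gas sitting
    # in airway + apparatus dead space at end-expiration)
    x_lo = max(0.0, 1.0 - vr / vt)

    def slug_mix(conc: np.ndarray) -> float:
        if lung.n_compartments == 1:
            return float(conc[0])
        p = _EMPTYING_POWER
        mean_xp = (1.0 - x_lo ** (p + 1)) / ((p + 1) * (1.0 - x_lo))
        w2 = q[1] * (1.0 - lam) + q[1] * lam * (p + 1) * mean_xp
        w2 = min(max(w2, 0.0), 1.0)
        return (1.0 - w2) * conc[0] + w2 * conc[1]

    flow_parts: list[np.ndarray] = []
    fn2_parts: list[np.ndarray] = []
    fco2_parts: list[np.ndarray] = []

    c_slug_prev = slug_mix(c)
    below = 0
    extra = 0
    n_washout = 0
    max_breaths = lung.prephase_breaths + 400
    breath = 0
    while True:
        washout = breath >= lung.prephase_breaths
        if washout:
            src_fn2, src_fco2 = 0.0, 0.0
        else:
            src_fn2, src_fco2 = ROOM_AIR["fn2"], ROOM_AIR["fco2"]
        # --- alveolar dilution by this inspiration ---
        c = (c * vols + c_slug_prev * q * vr + src_fn2 * q * (vt - vr)) \
            / (vols + q * vt)
        # --- sensed inspirate: port slug then supply gas ---
        si = expit((vol_of_t - m_port_c) / w_port)
        fn2_in = (1.0 - si) * c_slug_prev + si * src_fn2
        fco2_in = (1.0 - si) * etco2 + si * src_fco2
        # --- sensed expirate: fresh prefix, phase II, alveolar plateau ---
        s = expit((vol_of_t - v0_c) / w_sig)
        a = np.clip(vol_of_t - v0, 0.0, vt)
        if lung.n_compartments == 2:
            w2 = _emptying_weights(a / vt, q, lam)
            c_alv = (1.0 - w2) * c[0] + w2 * c[1]
        else:
            c_alv = np.full_like(a, c[0])
        fn2_ex = (1.0 - s) * src_fn2 + s * c_alv
        fco2_ex = (1.0 - s) * src_fco2 + s * etco2
        c_slug_prev = slug_mix(c)
        c_end = end_mix(c)

        flow_parts.append(flow_half / f_insp_true)
        flow_parts.append(-flow_half / f_exp_true)
        fn2_parts.extend([fn2_in, fn2_ex])
        fco2_parts.extend([fco2_in, fco2_ex])

        breath += 1
        if washout:
            n_washout += 1
            if below >= settings.washout_end_consecutive_breaths:
                extra += 1
                if extra >= 2:
                    break
            elif c_end < threshold:
                below += 1
            else:
                below = 0
        if breath >= max_breaths:
            raise RuntimeError("washout did not complete within the breath cap")

    flow = np.concatenate(flow_parts)
    fn2_sp = np.concatenate(fn2_parts)
    fco2_sp = np.concatenate(fco2_parts)
    fo2_sp = 1.0 - (1.0 + r) * fn2_sp - fco2_sp
    n = len(flow)
    time = np.arange(n) * dt

    # --- sensor chain distortions ---
    rng = np.random.default_rng(sensors.seed)
    fco2_m = fco2_sp / (1.0 + KD_CO2_TRUE * (fo2_sp - ROOM_AIR["fo2"]))

    def delay(x: np.ndarray, d_ms: float) -> np.ndarray:
        idx = np.arange(n, dtype=float) - d_ms / 1000.0 * sample_rate
        return np.interp(idx, np.arange(n, dtype=float), x)

    def lag(x: np.ndarray, tau_ms: float) -> np.ndarray:
        if tau_ms <= 0:
            return x
        # bilinear discretization of y' = (x-y)/tau: preserves the
        # low-frequency group delay (= tau) of the continuous sensor
        tau = tau_ms / 1000.0
        b0 = dt / (2.0 * tau + dt)
        a1 = (2.0 * tau - dt) / (2.0 * tau + dt)
        y = lfilter([b0, b0], [1.0, -a1], x - x[0])
        return y + x[0]

    fo2_m = lag(delay(fo2_sp, sensors.true_o2_delay_ms), sensors.o2_response_tau_ms)
    fco2_m = lag(delay(fco2_m, sensors.true_co2_delay_ms), sensors.co2_response_tau_ms)
    fo2_m = fo2_m + sensors.o2_drift_per_min * time / 60.0
    if sensors.noise_sd_fraction > 0:
        fo2_m = fo2_m + rng.normal(0.0, sensors.noise_sd_fraction, n)
        fco2_m = fco2_m + rng.normal(0.0, sensors.noise_sd_fraction, n)

    trace = SignalTrace(sample_rate=sample_rate, time=time, flow=flow,
                        fo2=fo2_m, fco2=fco2_m,
                        meta={"ds_set": settings.ds_set})

    gt = GroundTruth(frc_mL=lung.frc_mL, c0=c0, n_washout_breaths=n_washout,
                     params={"lung": asdict(lung), "sensors": asdict(sensors)})
    if lung.n_compartments == 1:
        va_eff = effective_alveolar_vt(v_alv, vt, vr)
        count = analytic_breath_count(v_alv, va_eff,
                                      settings.washout_end_fraction)
        vt_cev = vt - settings.ds_pre_mL - settings.ds_post_mL
        gt.analytic_breath_count = count
        gt.analytic_lci = count * vt_cev / lung.frc_mL
    return trace, gt


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

#: Per-group simulation condition ranges.  Chosen so the baseline-analyzed
#: noise-free LCI distribution spans roughly 6.3-15 turnovers with healthy
#: lowest and CF highest/widest, mirroring a mixed pediatric cohort
#: (10 healthy ~6 y on dead-space set 2; 10 former preterm ~8 y and
#: 10 CF 5-18 y on set 3).
COHORT_DESIGN: dict[str, dict[str, Any]] = {
    "healthy": dict(ds_set=2, frc=(850.0, 1150.0), vt_frac=(0.30, 0.35),
                    rr=(18.0, 24.0), airway_frac=(0.17, 0.22),
                    slow_vol=(0.38, 0.44), svr=(0.35, 0.50),
                    skew=(0.35, 0.55), width_frac=(0.30, 0.38),
                    o2_delay=(601.0, 1.5), co2_delay=(51.0, 1.5)),
    "preterm": dict(ds_set=3, frc=(950.0, 1400.0), vt_frac=(0.27, 0.33),
                    rr=(16.0, 22.0), airway_frac=(0.18, 0.23),
                    slow_vol=(0.40, 0.46), svr=(0.22, 0.35),
                    skew=(0.50, 0.70), width_frac=(0.33, 0.42),
                    o2_delay=(618.0, 1.5), co2_delay=(60.0, 1.5)),
    "cf": dict(ds_set=3, frc=(1100.0, 2200.0), vt_frac=(0.25, 0.31),
               rr=(14.0, 20.0), airway_frac=(0.18, 0.24),
               slow_vol=(0.42, 0.48), svr=(0.145, 0.22),
               skew=(0.60, 0.82), width_frac=(0.34, 0.44),
               o2_delay=(618.0, 1.5), co2_delay=(60.0, 1.5)),
}

#: Per-subject O2 sensor drift (fraction/min): zero-mean so the drift
#: correction's benefit is heterogeneous across subjects.
DRIFT_SD_PER_MIN = 3e-4


def draw_subject(group: str, rng: np.random.Generator,
                 noise_sd: float = 0.001,
                 ) -> tuple[LungParams, SensorChainParams, SettingsProfile]:
    """Draw one subject's simulation parameters for a cohort group."""
    d = COHORT_DESIGN[group]
    frc = rng.uniform(*d["frc"])
    vt = frc * rng.uniform(*d["vt_frac"])
    slow_vol = rng.uniform(*d["slow_vol"])
    svr = rng.uniform(*d["svr"])  # slow/fast specific-ventilation ratio
    vol_ratio = slow_vol / (1.0 - slow_vol)
    q1 = 1.0 / (1.0 + svr * vol_ratio)
    lung = LungParams(
        frc_mL=frc, vt_mL=vt, rr_per_min=rng.uniform(*d["rr"]),
        airway_ds_mL=vt * rng.uniform(*d["airway_frac"]), n_compartments=2,
        compartment_volume_fractions=(1.0 - slow_vol, slow_vol),
        compartment_ventilation_fractions=(q1, 1.0 - q1),
        emptying_skew=rng.uniform(*d["skew"]),
        phase2_width_mL=vt * rng.uniform(*d["width_frac"]))
    mu_o2, sd_o2 = d["o2_delay"]
    mu_co2, sd_co2 = d["co2_delay"]
    sensors = SensorChainParams(
        true_o2_delay_ms=rng.normal(mu_o2, sd_o2),
        true_co2_delay_ms=rng.normal(mu_co2, sd_co2),
        o2_drift_per_min=rng.normal(0.0, DRIFT_SD_PER_MIN),
        noise_sd_fraction=noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)))
    return lung, sensors, default_profile(d["ds_set"])


def generate_cohort(n_per_group: int = 10, seed: int = 0,
                    noise_sd: float = 0.001,
                    ) -> list[tuple[SignalTrace, GroundTruth, str]]:
    """Simulate the 30-subject study cohort (3 groups, seeded)."""
    rng = np.random.default_rng(seed)
    out = []
    for group in ("healthy", "preterm", "cf"):
        for i in range(n_per_group):
            lung, sensors, settings = draw_subject(group, rng, noise_sd)
            trace, gt = simulate_subject(lung, sensors, settings)
            trace.meta.update({"subject": f"{group}{i:02d}", "group": group})
            out.append((trace, gt, group))
    return out
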