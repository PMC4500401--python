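"""Signal alignment and gas-channel corrections.

Converts a raw trace (flow + delayed, lagged, possibly drifting O2/CO2
channels) into an aligned, corrected trace with a derived N2 channel.
Pipeline order is fixed: align -> O2 response-time -> O2 drift ->
dynamic CO2 -> N2 derivation -> BTPS flow scaling.  Every delay and
correction perturbation of the sensitivity harness acts on this stage.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .domain import ARGON_N2_RATIO, ROOM_AIR, SettingsProfile, SignalTrace

log = logging.getLogger(__name__)

# Magnus saturation-vapour-pressure constants (hPa over liquid water).
_MAGNUS_A = 6.112
_MAGNUS_B = 17.62
_MAGNUS_C = 243.12
BODY_TEMP_K = 310.15  # 37 °C


def saturation_pressure_hPa(temp_C: float) -> float:
    """Water saturation vapour pressure by the Magnus formula (hPa)."""
    return _MAGNUS_A * np.exp(_MAGNUS_B * temp_C / (_MAGNUS_C + temp_C))


@dataclass
class AlignedTrace:
    """A SignalTrace after alignment/correction, with the derived N2 channel.

    ``fn2`` is clipped to [0, 1] and feeds every volume integral; the
    unclipped channel ``fn2_raw`` is kept because the misalignment "divot"
    artifact is a negative N2 excursion that clipping would hide from the
    artifact metrics.
    """

    trace: SignalTrace
    fn2_raw: np.ndarray
    applied_settings: SettingsProfile
    btps_factors: tuple[float, float]
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def fn2(self) -> np.ndarray:
        assert self.trace.fn2 is not None
        return self.trace.fn2


def _shift_channel(x: np.ndarray, shift_samples: float) -> np.ndarray:
    """Advance a channel by ``shift_samples`` (may be fractional).

    ``y[i] = x[i + shift]`` via linear interpolation; edges are extended by
    holding the terminal values.
    """
    if shift_samples == 0:
        return x.copy()
    n = len(x)
    idx = np.arange(n, dtype=float) + shift_samples
    return np.interp(idx, np.arange(n, dtype=float), x)


def align_signals(trace: SignalTrace, o2_delay_ms: float,
                  co2_delay_ms: float) -> SignalTrace:
    """Advance the gas channels onto the flow time base.

    The side-stream O2 and mainstream CO2 sensors lag the flowmeter by their
    transport/processing delays; alignment advances each gas channel by its
    configured delay (fractional samples by linear interpolation).  Flow is
    untouched.
    """
    if o2_delay_ms < 0 or co2_delay_ms < 0:
        raise ValueError("delays must be non-negative")
    duration_ms = (trace.n_samples - 1) / trace.sample_rate * 1000.0
    if max(o2_delay_ms, co2_delay_ms) > duration_ms:
        raise ValueError("delay exceeds trace duration")
    out = trace.copy()
    out.fo2 = _shift_channel(trace.fo2, o2_delay_ms / 1000.0 * trace.sample_rate)
    out.fco2 = _shift_channel(trace.fco2, co2_delay_ms / 1000.0 * trace.sample_rate)
    return out


def correct_o2_response_time(fo2: np.ndarray, tau_ms: float,
                             sample_rate: float) -> np.ndarray:
    """Invert a first-order sensor lag of time constant ``tau_ms``.

    For y' = (x - y)/tau the original signal is x = y + tau*dy/dt; the
    derivative is taken by centred differences (one-sided at the edges).
    tau = 0 is the identity.
    """
    if tau_ms < 0:
        raise ValueError("tau_ms must be non-negative")
    if tau_ms == 0:
        return fo2.copy()
    tau_s = tau_ms / 1000.0
    dydt = _centered_derivative(fo2, 1.0 / sample_rate)
    return fo2 + tau_s * dydt


def _centered_derivative(x: np.ndarray, dt: float) -> np.ndarray:
    """Centered 5-point least-squares derivative (3-point at the edges).

    Equivalent to fitting a line through each sample's +/-2 neighbourhood;
    noise-robust while keeping the estimate centred (no phase shift).
    """
    n = len(x)
    if n < 5:
        return np.gradient(x, dt)
    kernel = np.array([2.0, 1.0, 0.0, -1.0, -2.0]) / (10.0 * dt)
    d = np.convolve(x, kernel, mode="same")
    d[:2] = np.gradient(x[:5], dt)[:2]
    d[-2:] = np.gradient(x[-5:], dt)[-2:]
    return d


def _phase_spans(flow: np.ndarray) -> list[tuple[int, int, int]]:
    """Raw (insp_start, insp_end, exp_end) spans from flow sign changes.

    Used internally where breath boundaries are needed before the full
    segmentation stage (drift correction).  No minimum-volume merging.
    """
    sign = np.where(flow > 0, 1, -1)
    edges = np.flatnonzero(np.diff(sign) != 0) + 1
    bounds = np.concatenate(([0], edges, [len(flow)]))
    spans = []
    i = 0
    while i + 2 < len(bounds):
        a, b, c = bounds[i], bounds[i + 1], bounds[i + 2]
        if sign[a] > 0 and sign[b] < 0:
            spans.append((int(a), int(b), int(c)))
            i += 2
        else:
            i += 1
    return spans


def correct_o2_drift(fo2: np.ndarray, flow: np.ndarray, time: np.ndarray,
                     enabled: bool = True) -> np.ndarray:
    """Remove a linear-in-time additive drift from the O2 channel.

    During the washout the inspired gas is pure O2, so the mid-inspiration
    plateau of every washout breath has a known value of 1.0.  A straight
    line is fitted to the plateau deviations against time and subtracted
    from the whole channel.  Disabled -> identity.
    """
    if not enabled:
        return fo2.copy()
    refs_t, refs_dev = [], []
    for a, b, _ in _phase_spans(flow):
        lo = a + (b - a) // 4
        hi = a + (3 * (b - a)) // 4
        if hi <= lo:
            continue
        med = float(np.median(fo2[lo:hi]))
        if med > 0.6:  # washout inspiration (pure O2)
            refs_t.append(float(np.median(time[lo:hi])))
            refs_dev.append(med - 1.0)
    if len(refs_t) < 2:
        warnings.warn("O2 drift correction skipped: no inspired-O2 plateaus found")
        return fo2.copy()
    coef = np.polyfit(np.asarray(refs_t), np.asarray(refs_dev), 1)
    return fo2 - np.polyval(coef, time)


def correct_co2_dynamic(fco2: np.ndarray, fo2: np.ndarray,
                        enabled: bool = True, kd: float = 0.05) -> np.ndarray:
    """Adjust the CO2 signal for its cross-sensitivity to high O2 fractions.

    The infra-red CO2 sensor under-reads when the background gas is O2-rich;
    the correction scales the reading by ``1 + kd*(fo2 - 0.2095)`` (no-op at
    room-air O2).  Disabled or kd = 0 -> identity.
    """
    if not enabled or kd == 0:
        return fco2.copy()
    if len(fco2) != len(fo2):
        raise ValueError("channels must have equal length")
    return fco2 * (1.0 + kd * (fo2 - ROOM_AIR["fo2"]))


def derive_n2(fo2: np.ndarray, fco2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Derive the N2 fraction from the measured O2 and CO2 fractions.

    Argon is inert and is assumed to track N2 at the room-air molar ratio
    r = 0.0093/0.7808, hence fn2 = (1 - fo2 - fco2)/(1 + r).  Returns
    ``(clipped, raw)``: the clipped channel (within [0, 1]) is used for all
    gas-volume integrals, the raw one for artifact diagnostics.
    """
    raw = (1.0 - fo2 - fco2) / (1.0 + ARGON_N2_RATIO)
    return np.clip(raw, 0.0, 1.0), raw


def btps_factors(temp_C: float, pressure_hPa: float, enabled: bool = True,
                 rh: float = 0.5, expired_temp_C: float = 34.0,
                 ) -> tuple[float, float]:
    """BTPS conversion factors (inspiratory, expiratory) for measured flow.

    Inspired gas at ambient temperature/humidity and expired gas at an
    effective temperature of 34 °C (saturated) are both converted to body
    conditions (37 °C, saturated, ambient pressure):

        f = (310.15/(273.15+T)) * ((P - RH*Psat(T)) / (P - Psat(37)))

    The inspiratory factor multiplies inspired-flow samples, the expiratory
    factor expired-flow samples.  Disabled -> (1, 1).
    """
    if not enabled:
        return (1.0, 1.0)
    p_body = saturation_pressure_hPa(37.0)
    if pressure_hPa <= p_body:
        raise ValueError("ambient pressure must exceed Psat at body temperature")
    def factor(t: float, humidity: float) -> float:
        return (BODY_TEMP_K / (273.15 + t)) * (
            (pressure_hPa - humidity * saturation_pressure_hPa(t))
            / (pressure_hPa - p_body))
    return (factor(temp_C, rh), factor(expired_temp_C, 1.0))


def preprocess(trace: SignalTrace, settings: SettingsProfile) -> AlignedTrace:
    """Run the full correction pipeline on a raw trace.

    Order: align -> O2 response-time -> O2 drift -> dynamic CO2 -> N2
    derivation -> BTPS factors.  Re-running on the output with null settings
    (zero delays, corrections off) is the identity.
    """
    aligned = align_signals(trace, settings.o2_delay_ms, settings.co2_delay_ms)
    aligned.fo2 = correct_o2_response_time(
        aligned.fo2, settings.o2_response_time_ms, trace.sample_rate)
    aligned.fo2 = correct_o2_drift(
        aligned.fo2, aligned.flow, aligned.time,
        enabled=settings.o2_drift_correction)
    aligned.fco2 = correct_co2_dynamic(
        aligned.fco2, aligned.fo2,
        enabled=settings.dynamic_co2_correction, kd=settings.kd_co2)
    fn2, fn2_raw = derive_n2(aligned.fo2, aligned.fco2)
    aligned.fn2 = fn2
    factors = btps_factors(
        settings.ambient_temp_C, settings.ambient_pressure_hPa,
        enabled=settings.btps_enabled, rh=settings.ambient_rh,
        expired_temp_C=settings.expired_temp_C)
    return AlignedTrace(trace=aligned, fn2_raw=fn2_raw,
                        applied_settings=settings, btps_factors=factors)
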