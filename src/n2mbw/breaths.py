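"""Breath segmentation and per-breath gas bookkeeping.

Breaths are delimited by flow zero-crossings (an inspiration followed by an
expiration); candidate breaths whose expired volume falls below the
configured minimum tidal volume are merged into their neighbour rather than
dropped, so no expired volume is lost from the cumulative bookkeeping.
"""
from __future__ import annotations

import logging

import numpy as np

from .domain import ROOM_AIR, BreathRecord, SettingsProfile
from .signals import AlignedTrace

log = logging.getLogger(__name__)


def _phase_bounds(flow: np.ndarray) -> list[tuple[int, int, int]]:
    """(insp_start, insp_end, exp_end) spans; trailing unpaired phase dropped."""
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


def _exp_volume(flow: np.ndarray, dt: float, a: int, c: int) -> float:
    """Expired volume (mL) in [a, c) by trapezoidal integration of -flow."""
    seg = np.clip(-flow[a:c], 0.0, None)
    return float(np.trapezoid(seg, dx=dt))


def detect_breaths(trace_or_flow, sample_rate: float | None = None,
                   min_tidal_volume_mL: float = 25.0,
                   ) -> list[tuple[int, int, int]]:
    """Segment flow into breath boundaries, merging sub-threshold breaths.

    Accepts an AlignedTrace, a SignalTrace or a bare flow array (then
    ``sample_rate`` is required).  Returns chronological, non-overlapping
    (insp_start, insp_end, exp_end) triples where ``insp_end`` marks the
    start of the breath's final expiratory phase.  Raises when no breath
    satisfies the minimum expired volume.
    """
    if isinstance(trace_or_flow, AlignedTrace):
        flow, sr = trace_or_flow.trace.flow, trace_or_flow.trace.sample_rate
    elif hasattr(trace_or_flow, "flow"):
        flow, sr = trace_or_flow.flow, trace_or_flow.sample_rate
    else:
        flow = np.asarray(trace_or_flow, dtype=float)
        if sample_rate is None:
            raise ValueError("sample_rate required with a bare flow array")
        sr = sample_rate
    dt = 1.0 / sr
    spans = _phase_bounds(flow)
    if not spans:
        raise ValueError("no breaths: flow has no inspiration/expiration cycle")
    vols = [_exp_volume(flow, dt, a, c) for a, _, c in spans]
    accepted = [i for i, v in enumerate(vols) if v >= min_tidal_volume_mL]
    if not accepted:
        raise ValueError("no breaths reach the minimum tidal volume")
    # each sub-threshold candidate merges into its accepted neighbour
    # (preceding if one exists, else following), never silently dropped
    merged: list[tuple[int, int, int]] = []
    prev_acc = -1
    for k, i in enumerate(accepted):
        a, b, c = spans[i]
        if i > prev_acc + 1:  # preceding sub-threshold run
            if merged:
                pa, pb, _ = merged[-1]
                merged[-1] = (pa, pb, spans[i - 1][2])
                # the run's phases extend the previous accepted breath
                a = spans[i][0]
            else:
                a = spans[prev_acc + 1][0]  # prepend to the first breath
        merged.append((a, b, c))
        prev_acc = i
    if prev_acc < len(spans) - 1:  # trailing sub-threshold run
        pa, pb, _ = merged[-1]
        merged[-1] = (pa, pb, spans[-1][2])
    return merged


def _last_exp(span: tuple[int, int, int]) -> tuple[int, int]:
    return span[0], span[2]


#: Breath-detection hysteresis: inspired volume after a reversal that is
#: still attributed to the preceding expiration's signal trace.
DETECTION_HYSTERESIS_ML = 10.0


def _reversal_tail(tr, fn2: np.ndarray, c: int, f_insp: float,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """fn2 samples of the next inspiration's first few millilitres."""
    n = len(fn2)
    if c >= n:
        return np.empty(0), np.empty(0)
    j, vol = c, 0.0
    while j < n and vol < DETECTION_HYSTERESIS_ML and tr.flow[j] >= 0:
        vol += max(tr.flow[j], 0.0) * f_insp * tr.dt
        j += 1
    return np.empty(j - c), fn2[c:j]


def breath_quantities(aligned: AlignedTrace, span: tuple[int, int, int],
                      index: int) -> BreathRecord:
    """Volumes, gas-volume integrals and end-tidal fractions for one breath.

    Flow and flow*gas products are integrated trapezoidally; inspiratory
    samples are scaled by the inspiratory BTPS factor and expiratory samples
    by the expiratory factor.  The end-tidal fraction is the median fn2 over
    the last 5% of expired volume (a volume, not time, window: robust to
    end-expiratory misalignment spikes while keeping them detectable by the
    artifact metrics).
    """
    a, b, c = span
    tr = aligned.trace
    dt = tr.dt
    f_insp, f_exp = aligned.btps_factors
    fn2 = aligned.fn2
    flow_in = np.clip(tr.flow[a:c], 0.0, None) * f_insp
    flow_ex = np.clip(-tr.flow[a:c], 0.0, None) * f_exp
    vt_insp = float(np.trapezoid(flow_in, dx=dt))
    vt_exp = float(np.trapezoid(flow_ex, dx=dt))
    if vt_exp <= 0:
        raise ValueError(f"breath {index}: zero expired volume")
    exp_n2 = float(np.trapezoid(flow_ex * fn2[a:c], dx=dt))
    # cumulative expired volume within the breath, for the expirogram
    cum = np.concatenate(([0.0], np.cumsum((flow_ex[1:] + flow_ex[:-1]) * 0.5 * dt)))
    ex_mask = flow_ex > 0
    # the expirogram keeps the reversal region: samples of the following
    # inspiration up to a small detection-hysteresis volume are appended at
    # constant cumulative volume, so end-expiratory misalignment spikes
    # (which straddle the zero crossing) stay on the expired trace
    ext_v, ext_f = _reversal_tail(tr, fn2, c, f_insp)
    expirogram = (np.concatenate([cum[ex_mask], np.full(len(ext_f), cum[ex_mask][-1] if np.any(ex_mask) else 0.0)]),
                  np.concatenate([fn2[a:c][ex_mask], ext_f]))
    # end-tidal: median over the last 5% of expired volume
    tail = cum >= 0.95 * vt_exp
    tail &= ex_mask
    if not np.any(tail):
        tail = ex_mask
    et_n2 = float(np.median(fn2[a:c][tail]))
    et_co2 = float(np.median(tr.fco2[a:c][tail]))
    # mid-inspiration O2 (washout-start detection)
    lo, hi = a + (b - a) // 4, a + (3 * (b - a)) // 4
    insp_o2 = float(np.median(tr.fo2[lo:hi])) if hi > lo else float(tr.fo2[a])
    return BreathRecord(index=index, insp_start=a, insp_end=b, exp_end=c,
                        vt_insp_mL=vt_insp, vt_exp_mL=vt_exp,
                        exp_n2_volume_mL=exp_n2, et_n2=et_n2, et_co2=et_co2,
                        insp_o2=insp_o2, expirogram=expirogram)


def reinspired_n2(aligned: AlignedTrace, breath: BreathRecord,
                  settings: SettingsProfile,
                  prev_et_n2: float | None = None) -> float:
    """Re-inspired N2 volume (mL) for one breath.

    When the correction is enabled: the N2 measured flowing back past the
    sampling point (integral of inspired flow x fn2) plus an estimate
    ``ds_post * previous end-tidal N2`` for expirate stored beyond the
    sampling point that returns to the lungs unmeasured.  For the first
    breath the starting alveolar fraction (room-air N2) stands in for the
    previous end-tidal.  Disabled -> 0.
    """
    if not settings.reinspired_n2_correction:
        return 0.0
    a, b = breath.insp_start, breath.insp_end
    tr = aligned.trace
    f_insp, _ = aligned.btps_factors
    flow_in = np.clip(tr.flow[a:b], 0.0, None) * f_insp
    measured = float(np.trapezoid(flow_in * aligned.fn2[a:b], dx=tr.dt))
    if prev_et_n2 is None:
        prev_et_n2 = ROOM_AIR["fn2"]
    return measured + settings.ds_post_mL * prev_et_n2


def segment(aligned: AlignedTrace, settings: SettingsProfile | None = None,
            ) -> list[BreathRecord]:
    """Full per-breath table for an aligned trace."""
    if settings is None:
        settings = aligned.applied_settings
    spans = detect_breaths(aligned, min_tidal_volume_mL=settings.min_tidal_volume_mL)
    records: list[BreathRecord] = []
    prev_et: float | None = None
    for i, span in enumerate(spans):
        rec = breath_quantities(aligned, span, i)
        rec.reinsp_n2_volume_mL = reinspired_n2(aligned, rec, settings, prev_et)
        records.append(rec)
        prev_et = rec.et_n2
    return records
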