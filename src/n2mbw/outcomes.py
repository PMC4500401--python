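"""Washout outcomes: FRC, LCI, phase III slope indices, artifact metrics.

Conventions (fixed for determinism):

* FRC is the tracer-derived volume at the sampling point minus the
  pre-capillary dead space — the volume on the patient side of the gas
  sampling port down to the mouth, i.e. the lung volume at end-expiration.
* CEV sums per-breath expired volume minus total apparatus dead space
  (pre + post), with no interpolation at the 1/40 threshold crossing: the
  washout ends at the first breath of the first qualifying run.
* Scond is fitted over lung turnovers 1.5–6.0; Sacin is the first breath's
  SnIII minus Scond's contribution at that turnover.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np

from .domain import BreathRecord, OutcomeSet, SettingsProfile, SIIIRecord
from .breaths import segment
from .signals import AlignedTrace, preprocess

log = logging.getLogger(__name__)

#: Turnover range of the Scond fit (field convention).
SCOND_TO_RANGE = (1.5, 6.0)
#: Inspired-O2 threshold that marks the start of the washout.
WASHOUT_O2_THRESHOLD = 0.6


def find_washout_window(breaths: list[BreathRecord], end_fraction: float,
                        consecutive: int, c0: float | None = None,
                        ) -> tuple[int, int, float]:
    """Locate the washout among the breaths and its 1/40th end point.

    The washout starts at the first breath whose inspirate is O2-rich
    (median inspired O2 > 0.6); the starting concentration c0 is the mean
    end-tidal N2 of the pre-phase breaths (unless supplied).  The washout
    ends at the first breath of the first run of ``consecutive`` breaths
    with end-tidal N2 below ``end_fraction * c0``; outcomes use breaths up
    to and including that breath.  Returns (start, end, c0) breath indices,
    end inclusive.
    """
    start = next((b.index for b in breaths if b.insp_o2 > WASHOUT_O2_THRESHOLD),
                 None)
    if start is None:
        raise ValueError("no washout: inspired O2 never exceeds threshold")
    if c0 is None:
        pre = [b.et_n2 for b in breaths if b.index < start]
        if not pre:
            raise ValueError("no pre-phase breaths to define c0")
        c0 = float(np.mean(pre))
    threshold = end_fraction * c0
    run = 0
    for b in breaths[start:]:
        if b.et_n2 < threshold:
            run += 1
            if run == consecutive:
                return start, b.index - (consecutive - 1), c0
        else:
            run = 0
    if run > 0 and start + run <= len(breaths):
        # trace ends inside a qualifying run shorter than `consecutive`
        pass
    raise ValueError("incomplete washout: end threshold never sustained")


def compute_frc(window_breaths: list[BreathRecord], c0: float,
                settings: SettingsProfile) -> float:
    """FRC (mL) from the cumulative net expired tracer volume.

    FRC_raw = sum(expired N2 - re-inspired N2) / (c0 - end-tidal N2 at the
    end); the reported FRC subtracts the pre-capillary dead space so that
    the volume refers to the patient side of the mouthpiece.
    """
    et_end = window_breaths[-1].et_n2
    if c0 <= et_end:
        raise ValueError("c0 must exceed the end-tidal N2 at washout end")
    net = sum(b.exp_n2_volume_mL - b.reinsp_n2_volume_mL for b in window_breaths)
    return net / (c0 - et_end) - settings.ds_pre_mL


def breath_cev_contribution(b: BreathRecord, settings: SettingsProfile) -> float:
    """One breath's CEV contribution: expired volume minus apparatus DS."""
    ds = settings.ds_pre_mL + settings.ds_post_mL
    contrib = b.vt_exp_mL - ds
    if contrib <= 0:
        warnings.warn(f"breath {b.index}: expired volume below apparatus "
                      "dead space; CEV contribution clamped at 0")
        return 0.0
    return contrib


def compute_lci(window_breaths: list[BreathRecord], frc: float,
                settings: SettingsProfile) -> tuple[float, float]:
    """(CEV in mL, LCI in turnovers) over the washout window."""
    if frc <= 0:
        raise ValueError("frc must be positive")
    cev = sum(breath_cev_contribution(b, settings) for b in window_breaths)
    return cev, cev / frc


def phase3_slope(expirogram: tuple[np.ndarray, np.ndarray],
                 window_fractions: tuple[float, float],
                 vt_exp_mL: float | None = None) -> tuple[float, float, bool]:
    """Phase III slope of one breath by OLS on the expirogram.

    Fits fn2 against cumulative expired volume over
    ``[lo, hi] * vt_exp``.  Returns (siii, sniii, ok) with the slope in
    fraction per litre and SnIII = slope / mean fn2 over the window.
    ``ok`` is False when the window holds fewer than 5 samples.
    """
    vol, fn2 = expirogram
    if vt_exp_mL is None:
        vt_exp_mL = float(vol[-1])
    lo, hi = window_fractions
    mask = (vol >= lo * vt_exp_mL) & (vol <= hi * vt_exp_mL)
    if int(mask.sum()) < 5:
        return np.nan, np.nan, False
    v, y = vol[mask], fn2[mask]
    slope_per_mL = float(np.polyfit(v, y, 1)[0])
    siii = slope_per_mL * 1000.0  # per L
    mean_fn2 = float(np.mean(y))
    sniii = siii / mean_fn2 if mean_fn2 > 0 else np.nan
    return siii, sniii, bool(np.isfinite(sniii))


def scond_sacin(records: list[SIIIRecord],
                to_range: tuple[float, float] = SCOND_TO_RANGE,
                ) -> tuple[float | None, float | None, float | None, float | None]:
    """(Scond, Sacin, Scond*VT, Sacin*VT) from the per-breath SnIII series.

    Scond is the OLS slope of SnIII against turnover over ``to_range``;
    Sacin is the first washout breath's SnIII minus Scond's contribution at
    its turnover.  The VT-corrected variants repeat both fits on
    SnIII * VT (L).  Returns Nones when fewer than 3 usable records fall in
    the turnover range or the first breath is unusable.
    """
    usable = [r for r in records if r.ok and np.isfinite(r.sniii)]
    lo, hi = to_range
    in_range = [r for r in usable if lo <= r.to <= hi]
    if len(in_range) < 3 or not records or not records[0].ok:
        return None, None, None, None
    first = records[0]

    def fit(yvals: np.ndarray, tos: np.ndarray, y_first: float) -> tuple[float, float]:
        slope = float(np.polyfit(tos, yvals, 1)[0])
        return slope, y_first - slope * first.to

    tos = np.array([r.to for r in in_range])
    y_raw = np.array([r.sniii for r in in_range])
    y_vt = np.array([r.sniii * r.vt_mL / 1000.0 for r in in_range])
    scond, sacin = fit(y_raw, tos, first.sniii)
    scond_vt, sacin_vt = fit(y_vt, tos, first.sniii * first.vt_mL / 1000.0)
    return scond, sacin, scond_vt, sacin_vt


def n2_artifact_metric(aligned: AlignedTrace, breaths: list[BreathRecord],
                       window: tuple[int, int]) -> tuple[float, float]:
    """Misalignment-artifact metrics over the last 5 washout breaths.

    spike_metric: mean over those breaths of (max fn2 in the last 10% of
    expired volume - median fn2 over the 65-95% window), floored at 0 —
    the end-expiratory "spike" that appears when the O2 signal is advanced
    too little.  divot_metric: mean of (median inspired fn2 over
    mid-inspiration - min fn2 in the first 10% of inspired volume), floored
    at 0, computed on the unclipped N2 channel — the early-inspiratory
    "divot" (a negative N2 excursion) of an over-advanced O2 signal.
    """
    start, end = window
    wb = [b for b in breaths if start <= b.index <= end]
    last = wb[-5:] if len(wb) >= 5 else wb
    tr = aligned.trace
    spikes, divots = [], []
    for b in last:
        vol, fn2 = b.expirogram
        vt = b.vt_exp_mL
        tail = vol >= 0.9 * vt
        mid = (vol >= 0.65 * vt) & (vol <= 0.95 * vt)
        if np.any(tail) and np.any(mid):
            spikes.append(max(0.0, float(np.max(fn2[tail]) - np.median(fn2[mid]))))
        a, bnd = b.insp_start, b.insp_end
        flow_in = np.clip(tr.flow[a:bnd], 0.0, None)
        cum = np.concatenate(([0.0],
                              np.cumsum((flow_in[1:] + flow_in[:-1]) * 0.5 * tr.dt)))
        vti = cum[-1]
        raw = aligned.fn2_raw[a:bnd]
        head = cum <= 0.10 * vti
        midin = (cum >= 0.25 * vti) & (cum <= 0.75 * vti)
        if np.any(head) and np.any(midin):
            divots.append(max(0.0, float(np.median(raw[midin]) - np.min(raw[head]))))
    spike = float(np.mean(spikes)) if spikes else np.nan
    divot = float(np.mean(divots)) if divots else np.nan
    return spike, divot


def analyze_trace(trace, settings: SettingsProfile) -> OutcomeSet:
    """Full analysis of one raw trace under one settings profile."""
    aligned = trace if isinstance(trace, AlignedTrace) else preprocess(trace, settings)
    breaths = segment(aligned, settings)
    start, end, c0 = find_washout_window(
        breaths, settings.washout_end_fraction,
        settings.washout_end_consecutive_breaths)
    window_breaths = breaths[start:end + 1]
    frc = compute_frc(window_breaths, c0, settings)
    if frc <= 0:
        raise ValueError("non-positive FRC")
    cev, lci = compute_lci(window_breaths, frc, settings)
    records: list[SIIIRecord] = []
    cum_cev = 0.0
    for b in window_breaths:
        cum_cev += breath_cev_contribution(b, settings)
        siii, sniii, ok = phase3_slope(b.expirogram, settings.siii_window,
                                       b.vt_exp_mL)
        records.append(SIIIRecord(breath_index=b.index, siii=siii, sniii=sniii,
                                  to=cum_cev / frc, vt_mL=b.vt_exp_mL, ok=ok))
    scond, sacin, scond_vt, sacin_vt = scond_sacin(records)
    spike, divot = n2_artifact_metric(aligned, breaths, (start, end))
    return OutcomeSet(frc_mL=frc, lci=lci, cev_mL=cev,
                      n_washout_breaths=end - start + 1,
                      scond=scond, sacin=sacin,
                      scond_vt=scond_vt, sacin_vt=sacin_vt,
                      c0=c0, et_n2_end=window_breaths[-1].et_n2,
                      spike_metric=spike, divot_metric=divot,
                      per_breath=breaths, siii_records=records)
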