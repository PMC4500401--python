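"""The settings-sensitivity experiment: perturbation grid, paired re-analysis
and report tables.

Each raw trace is analyzed once with its baseline profile and re-analyzed
under every perturbation of the grid; per-subject percent changes feed
Wilcoxon signed-rank tests, Bland-Altman limits of agreement, and the
5-10% / >10% relevance counts.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .domain import (Edit, OutcomeSet, Perturbation, SettingsProfile,
                     SignalTrace, apply_perturbation)
from .outcomes import analyze_trace
from .stats import bland_altman, wilcoxon_signed_rank

log = logging.getLogger(__name__)

OUTCOME_NAMES = ("lci", "frc_mL", "scond", "sacin", "scond_vt", "sacin_vt")


def build_grid() -> list[Perturbation]:
    """The full 32-perturbation experiment grid.

    Four groups: environmental conditions (temperature +/-5 °C, pressure
    +/-20 hPa, BTPS off), apparatus dead space (pre +/-5 mL, post +/-2 mL on
    set 2 / +/-5 mL on set 3, both together), signal processing and
    detection limits (four corrections off, minimum tidal volume 100 mL,
    SIII window 50-80%), and signal delay times (O2 +/-20/40/60 ms, CO2
    +/-10 ms, simultaneous different and identical shifts).
    """
    g: list[Perturbation] = []

    def add(pid: str, group: str, *edits: Edit) -> None:
        g.append(Perturbation(id=pid, group=group, edits=tuple(edits)))

    # 1. environmental conditions
    add("temp_-5", "environment", Edit("ambient_temp_C", "add", -5.0))
    add("temp_+5", "environment", Edit("ambient_temp_C", "add", 5.0))
    add("pressure_-20", "environment", Edit("ambient_pressure_hPa", "add", -20.0))
    add("pressure_+20", "environment", Edit("ambient_pressure_hPa", "add", 20.0))
    add("btps_off", "environment", Edit("btps_enabled", "set", False))
    # 2. apparatus dead space
    post_step = {2: 2.0, 3: 5.0}
    add("ds_pre_-5", "dead_space", Edit("ds_pre_mL", "add", -5.0))
    add("ds_pre_+5", "dead_space", Edit("ds_pre_mL", "add", 5.0))
    add("ds_post_lower", "dead_space",
        Edit("ds_post_mL", "add_by_set", {k: -v for k, v in post_step.items()}))
    add("ds_post_higher", "dead_space",
        Edit("ds_post_mL", "add_by_set", dict(post_step)))
    add("ds_both_lower", "dead_space", Edit("ds_pre_mL", "add", -5.0),
        Edit("ds_post_mL", "add_by_set", {k: -v for k, v in post_step.items()}))
    add("ds_both_higher", "dead_space", Edit("ds_pre_mL", "add", 5.0),
        Edit("ds_post_mL", "add_by_set", dict(post_step)))
    # 3. signal processing and detection limits
    add("o2_drift_off", "processing", Edit("o2_drift_correction", "set", False))
    add("dynamic_co2_off", "processing",
        Edit("dynamic_co2_correction", "set", False))
    add("o2_response_off", "processing", Edit("o2_response_time_ms", "set", 0.0))
    add("reinspired_n2_off", "processing",
        Edit("reinspired_n2_correction", "set", False))
    add("min_vt_100", "processing", Edit("min_tidal_volume_mL", "set", 100.0))
    add("siii_window_50_80", "processing",
        Edit("siii_window", "set", (0.50, 0.80)))
    # 4. signal delay times
    for step in (-20.0, -40.0, -60.0, 20.0, 40.0, 60.0):
        add(f"o2_delay_{step:+.0f}", "delay", Edit("o2_delay_ms", "add", step))
    for step in (-10.0, 10.0):
        add(f"co2_delay_{step:+.0f}", "delay", Edit("co2_delay_ms", "add", step))
    for o2, co2 in ((-100.0, -10.0), (100.0, 10.0), (-100.0, 10.0),
                    (100.0, -10.0)):
        add(f"o2_{o2:+.0f}_co2_{co2:+.0f}", "delay",
            Edit("o2_delay_ms", "add", o2), Edit("co2_delay_ms", "add", co2))
    for both in (-40.0, 40.0, 80.0):
        add(f"both_delays_{both:+.0f}", "delay",
            Edit("o2_delay_ms", "add", both), Edit("co2_delay_ms", "add", both))
    assert len(g) == 32
    return g


@dataclass
class PerturbationResult:
    """Paired baseline-vs-perturbed comparison for one grid entry."""

    perturbation_id: str
    group: str
    subjects: list[str]
    baseline: dict[str, np.ndarray]  # outcome name -> per-subject values
    perturbed: dict[str, np.ndarray]
    pct_change: dict[str, np.ndarray]
    mean_lci_pct: float
    sd_lci_pct: float
    n_5_10: int
    n_gt10: int
    wilcoxon_p: dict[str, float]
    bland_altman_lci: tuple[float, float, float]
    failed: list[str] = field(default_factory=list)


def _collect(outcomes: Sequence[OutcomeSet], name: str) -> np.ndarray:
    key = "frc_mL" if name == "frc_mL" else name
    vals = [getattr(o, key) for o in outcomes]
    return np.array([np.nan if v is None else v for v in vals], dtype=float)


def summarize_pair(pid: str, group: str, subjects: list[str],
                   base: Sequence[OutcomeSet], pert: Sequence[OutcomeSet],
                   failed: list[str] | None = None) -> PerturbationResult:
    """Build a PerturbationResult from paired outcome lists."""
    baseline = {k: _collect(base, k) for k in OUTCOME_NAMES}
    perturbed = {k: _collect(pert, k) for k in OUTCOME_NAMES}
    pct = {}
    for k in OUTCOME_NAMES:
        with np.errstate(divide="ignore", invalid="ignore"):
            pct[k] = 100.0 * (perturbed[k] - baseline[k]) / baseline[k]
    abs_lci = np.abs(pct["lci"])
    ok = np.isfinite(abs_lci)
    n_5_10 = int(np.sum((abs_lci[ok] >= 5.0) & (abs_lci[ok] <= 10.0)))
    n_gt10 = int(np.sum(abs_lci[ok] > 10.0))
    pvals = {}
    for k in OUTCOME_NAMES:
        mask = np.isfinite(baseline[k]) & np.isfinite(perturbed[k])
        pvals[k] = (wilcoxon_signed_rank(baseline[k][mask],
                                         perturbed[k][mask])[1]
                    if mask.sum() >= 1 else np.nan)
    mask = np.isfinite(baseline["lci"]) & np.isfinite(perturbed["lci"])
    ba = bland_altman(baseline["lci"][mask], perturbed["lci"][mask]) \
        if mask.sum() >= 2 else (np.nan, np.nan, np.nan)
    return PerturbationResult(
        perturbation_id=pid, group=group, subjects=list(subjects),
        baseline=baseline, perturbed=perturbed, pct_change=pct,
        mean_lci_pct=float(np.nanmean(pct["lci"])),
        sd_lci_pct=float(np.nanstd(pct["lci"], ddof=1)),
        n_5_10=n_5_10, n_gt10=n_gt10, wilcoxon_p=pvals,
        bland_altman_lci=tuple(ba), failed=failed or [])


def run_sensitivity(traces: Sequence[SignalTrace],
                    profiles: Sequence[SettingsProfile],
                    grid: Sequence[Perturbation],
                    subjects: Sequence[str] | None = None,
                    ) -> tuple[list[OutcomeSet], list[PerturbationResult]]:
    """Analyze every trace at baseline and under every grid perturbation.

    Subjects whose baseline analysis fails are excluded from all results;
    per-perturbation failures are excluded pairwise and logged.  Returns
    (baseline outcomes, one PerturbationResult per grid entry).
    """
    if subjects is None:
        subjects = [t.meta.get("subject", f"s{i:02d}")
                    for i, t in enumerate(traces)]
    base_out, keep, kept_subjects, kept_profiles = [], [], [], []
    for trace, prof, sid in zip(traces, profiles, subjects):
        try:
            base_out.append(analyze_trace(trace, prof))
        except Exception as exc:  # noqa: BLE001 - record and move on
            log.warning("baseline analysis failed for %s: %s", sid, exc)
            continue
        keep.append(trace)
        kept_subjects.append(sid)
        kept_profiles.append(prof)
    results = []
    for p in grid:
        pert_out, ok_idx, failed = [], [], []
        for i, (trace, prof) in enumerate(zip(keep, kept_profiles)):
            try:
                pert_out.append(analyze_trace(trace, apply_perturbation(prof, p)))
                ok_idx.append(i)
            except Exception as exc:  # noqa: BLE001
                log.warning("%s failed for %s: %s", p.id, kept_subjects[i], exc)
                failed.append(kept_subjects[i])
        results.append(summarize_pair(
            p.id, p.group, [kept_subjects[i] for i in ok_idx],
            [base_out[i] for i in ok_idx], pert_out, failed))
    return base_out, results


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def _arrow(mean_change: float, p: float) -> str:
    """Direction arrow with significance tier (p<0.001, <0.01, <0.05, ns)."""
    if not np.isfinite(p) or p >= 0.05 or mean_change == 0.0:
        return "<->"
    up = mean_change > 0
    if p < 0.001:
        return "^^" if up else "vv"
    if p < 0.01:
        return "^" if up else "v"
    return "(^)" if up else "(v)"


def effect_table(results: Sequence[PerturbationResult]) -> pd.DataFrame:
    """Effect-size table: changed LCI, % change, relevance counts, p-values."""
    rows = []
    for r in results:
        lci = r.perturbed["lci"]
        rows.append({
            "setting": r.perturbation_id, "group": r.group,
            "mean_lci": float(np.nanmean(lci)),
            "sd_lci": float(np.nanstd(lci, ddof=1)),
            "mean_pct_change": r.mean_lci_pct, "sd_pct_change": r.sd_lci_pct,
            "n_5_10pct": r.n_5_10, "n_gt10pct": r.n_gt10,
            "p_lci": r.wilcoxon_p["lci"], "p_frc": r.wilcoxon_p["frc_mL"],
            "p_scond": r.wilcoxon_p["scond"], "p_sacin": r.wilcoxon_p["sacin"],
            "ba_mean_diff": r.bland_altman_lci[0],
            "ba_loa_lower": r.bland_altman_lci[1],
            "ba_loa_upper": r.bland_altman_lci[2]})
    return pd.DataFrame(rows)


def arrow_table(results: Sequence[PerturbationResult]) -> pd.DataFrame:
    """Direction-of-change summary mirroring the arrow-style tables."""
    rows = []
    for r in results:
        row: dict[str, Any] = {"setting": r.perturbation_id, "group": r.group}
        for k in OUTCOME_NAMES:
            mean_pct = float(np.nanmean(r.pct_change[k])) \
                if np.any(np.isfinite(r.pct_change[k])) else np.nan
            row[k] = _arrow(mean_pct, r.wilcoxon_p[k])
        rows.append(row)
    return pd.DataFrame(rows)


def render_report(results: Sequence[PerturbationResult],
                  out_dir: str | Path) -> list[Path]:
    """Write per-group effect tables, the arrow summary and Bland-Altman data.

    Deterministic: regenerating from the same results is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    eff = effect_table(results)
    for group in sorted(eff["group"].unique()):
        path = out_dir / f"effect_{group}.csv"
        eff[eff["group"] == group].to_csv(path, index=False,
                                          float_format="%.6g")
        written.append(path)
    arrows = arrow_table(results)
    path = out_dir / "arrows.csv"
    arrows.to_csv(path, index=False)
    written.append(path)
    for r in results:
        mask = np.isfinite(r.baseline["lci"]) & np.isfinite(r.perturbed["lci"])
        ba = pd.DataFrame({
            "subject": [s for s, m in zip(r.subjects, mask) if m],
            "mean_lci": (r.baseline["lci"][mask] + r.perturbed["lci"][mask]) / 2,
            "diff_lci": r.perturbed["lci"][mask] - r.baseline["lci"][mask]})
        path = out_dir / f"bland_altman_{r.perturbation_id}.csv"
        ba.to_csv(path, index=False, float_format="%.6g")
        written.append(path)
    return written
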