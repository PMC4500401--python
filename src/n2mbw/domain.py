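"""Shared domain types for N2 multiple-breath washout analysis.

Units are fixed repo-wide: volumes in mL, flow in mL/s, delays in ms,
temperature in °C, pressure in hPa, gas concentrations as molar fractions
in [0, 1].
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np

#: Argon-to-nitrogen molar ratio of dry room air.  Argon is inert and washes
#: out together with N2, so the estimated argon channel tracks N2 at this
#: fixed ratio throughout the washout.
ARGON_N2_RATIO = 0.0093 / 0.7808

#: Dry room-air composition (O2, CO2, Ar, N2 molar fractions).
ROOM_AIR = {"fo2": 0.2095, "fco2": 0.0004, "far": 0.0093, "fn2": 0.7808}


@dataclass
class SignalTrace:
    """Uniformly sampled flow/O2/CO2 time series — the raw input to everything.

    Flow is measured at the mouth by a mainstream ultrasonic flowmeter
    (positive = inspiration); O2 comes from a side-stream laser sensor and
    CO2 from a mainstream infra-red sensor, both physically displaced from
    the flow measurement and therefore delayed relative to it.
    """

    sample_rate: float  # samples per second
    time: np.ndarray  # s, uniformly spaced
    flow: np.ndarray  # mL/s, positive = inspiration
    fo2: np.ndarray  # O2 molar fraction
    fco2: np.ndarray  # CO2 molar fraction
    fn2: np.ndarray | None = None  # derived N2 channel, absent until derived
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        self.fo2 = np.asarray(self.fo2, dtype=float)
        self.fco2 = np.asarray(self.fco2, dtype=float)
        n = len(self.time)
        if n < 2:
            raise ValueError("trace needs at least 2 samples")
        for name in ("flow", "fo2", "fco2"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name!r} length mismatch")
        step = np.diff(self.time)
        if not np.all(step > 0):
            raise ValueError("time must be strictly increasing")
        if not np.allclose(step, 1.0 / self.sample_rate, rtol=1e-6, atol=1e-9):
            raise ValueError("time step must equal 1/sample_rate")

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    def copy(self) -> "SignalTrace":
        out = dataclasses.replace(self)
        out.time = self.time.copy()
        out.flow = self.flow.copy()
        out.fo2 = self.fo2.copy()
        out.fco2 = self.fco2.copy()
        if self.fn2 is not None:
            out.fn2 = self.fn2.copy()
        out.meta = dict(self.meta)
        return out


# ---------------------------------------------------------------------------
# Settings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SettingsProfile:
    """Every configurable analysis setting the sensitivity harness perturbs.

    Defaults follow the manufacturer-recommended baseline: ambient 21 °C /
    980 hPa, pre-capillary dead space 24 mL, and per-set post-capillary dead
    space and flow-gas delays (set 2: 9.5 mL, 601/51 ms; set 3: 22 mL,
    618/60 ms).  ``o2_response_time_ms = 0`` means the response-time
    correction is off; the other corrections are explicit flags.
    """

    ambient_temp_C: float = 21.0
    ambient_pressure_hPa: float = 980.0
    btps_enabled: bool = True
    ds_pre_mL: float = 24.0
    ds_post_mL: float = 9.5
    ds_set: int = 2
    o2_delay_ms: float = 601.0
    co2_delay_ms: float = 51.0
    o2_drift_correction: bool = True
    dynamic_co2_correction: bool = True
    o2_response_time_ms: float = 30.0
    reinspired_n2_correction: bool = True
    min_tidal_volume_mL: float = 25.0
    siii_window: tuple[float, float] = (0.65, 0.95)
    washout_end_fraction: float = 1.0 / 40.0
    washout_end_consecutive_breaths: int = 3
    # advanced constants (fixed conventions, exposed for completeness)
    kd_co2: float = 0.05  # dynamic CO2 cross-sensitivity coefficient
    ambient_rh: float = 0.5  # ambient relative humidity for BTPS
    expired_temp_C: float = 34.0  # effective expired-gas temperature

    def replace(self, **edits: Any) -> "SettingsProfile":
        return dataclasses.replace(self, **edits)

    def as_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["siii_window"] = list(self.siii_window)
        return d


def default_profile(ds_set: int = 2) -> SettingsProfile:
    """Baseline profile for a dead-space reducer set (2 or 3)."""
    if ds_set == 2:
        return SettingsProfile()
    if ds_set == 3:
        return SettingsProfile(ds_post_mL=22.0, ds_set=3,
                               o2_delay_ms=618.0, co2_delay_ms=60.0)
    raise ValueError(f"unknown dead-space set {ds_set!r}")


def validate_settings(profile: SettingsProfile) -> list[str]:
    """Return a list of invariant violations (empty iff the profile is valid)."""
    v: list[str] = []
    lo, hi = profile.siii_window
    if not (0.0 < lo < hi <= 1.0):
        v.append("siii_window: requires 0 < lo < hi <= 1")
    for name in ("ds_pre_mL", "ds_post_mL", "o2_delay_ms", "co2_delay_ms",
                 "o2_response_time_ms", "min_tidal_volume_mL"):
        if getattr(profile, name) < 0:
            v.append(f"{name}: must be non-negative")
    if not (0.0 < profile.washout_end_fraction < 1.0):
        v.append("washout_end_fraction: must lie in (0, 1)")
    if profile.washout_end_consecutive_breaths < 1:
        v.append("washout_end_consecutive_breaths: must be >= 1")
    if profile.ds_set not in (2, 3):
        v.append("ds_set: must be 2 or 3")
    if profile.ambient_pressure_hPa <= 62.66:
        v.append("ambient_pressure_hPa: must exceed water vapour pressure at 37 °C")
    if not (0.0 <= profile.ambient_rh <= 1.0):
        v.append("ambient_rh: must lie in [0, 1]")
    return v


# ---------------------------------------------------------------------------
# Perturbations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Edit:
    """One settings edit: set a field, add a delta, or add a per-set delta."""

    field: str
    op: str  # 'set' | 'add' | 'add_by_set'
    value: Any

    def as_dict(self) -> dict[str, Any]:
        return {"field": self.field, "op": self.op, "value": self.value}


@dataclass(frozen=True)
class Perturbation:
    """A named settings change belonging to one of the four study groups."""

    id: str
    group: str  # 'environment' | 'dead_space' | 'processing' | 'delay'
    edits: tuple[Edit, ...]

    def as_dict(self) -> dict[str, Any]:
        return {"id": self.id, "group": self.group,
                "edits": [e.as_dict() for e in self.edits]}


_GROUPS = ("environment", "dead_space", "processing", "delay")


def apply_perturbation(profile: SettingsProfile, p: Perturbation) -> SettingsProfile:
    """Return a new profile with only the perturbation's edits applied.

    The input profile is unmodified; an edit naming an unknown field raises.
    """
    valid = {f.name for f in dataclasses.fields(SettingsProfile)}
    changes: dict[str, Any] = {}
    for e in p.edits:
        if e.field not in valid:
            raise KeyError(f"perturbation {p.id!r}: unknown settings field {e.field!r}")
        cur = changes.get(e.field, getattr(profile, e.field))
        if e.op == "set":
            new = tuple(e.value) if isinstance(e.value, (list, tuple)) else e.value
        elif e.op == "add":
            new = cur + e.value
        elif e.op == "add_by_set":
            delta = e.value[profile.ds_set] if profile.ds_set in e.value \
                else e.value[str(profile.ds_set)]
            new = cur + delta
        else:
            raise ValueError(f"unknown edit op {e.op!r}")
        changes[e.field] = new
    return profile.replace(**changes)


def inverse_edits(profile: SettingsProfile, p: Perturbation) -> Perturbation:
    """Perturbation that undoes ``p`` relative to the given baseline profile."""
    inv = tuple(Edit(e.field, "set", getattr(profile, e.field)) for e in p.edits)
    return Perturbation(id=p.id + "_inverse", group=p.group, edits=inv)


# ---------------------------------------------------------------------------
# Per-breath and outcome records
# ---------------------------------------------------------------------------

@dataclass
class BreathRecord:
    """One segmented breath: volumes, gas integrals, end-tidal fractions."""

    index: int
    insp_start: int  # sample index, inclusive
    insp_end: int  # first expiratory sample
    exp_end: int  # one past last expiratory sample
    vt_insp_mL: float = np.nan
    vt_exp_mL: float = np.nan
    exp_n2_volume_mL: float = np.nan
    reinsp_n2_volume_mL: float = np.nan
    et_n2: float = np.nan
    et_co2: float = np.nan
    insp_o2: float = np.nan  # median inspired O2 (washout-start detection)
    expirogram: tuple[np.ndarray, np.ndarray] | None = None  # (cum exp vol, fn2)


@dataclass
class SIIIRecord:
    """Phase III slope of one washout breath on the expirogram."""

    breath_index: int
    siii: float  # fn2 per L expired
    sniii: float  # siii / mean fn2 over the fit window, per L
    to: float  # lung turnover (CEV so far / FRC)
    vt_mL: float
    ok: bool = True  # False when the fit window held too few samples


@dataclass
class OutcomeSet:
    """FRC, LCI and phase-III-slope indices for one analyzed trace."""

    frc_mL: float
    lci: float
    cev_mL: float
    n_washout_breaths: int
    scond: float | None = None  # SnIII per turnover (L^-1 per TO)
    sacin: float | None = None  # L^-1
    scond_vt: float | None = None
    sacin_vt: float | None = None
    c0: float = np.nan  # starting end-tidal N2
    et_n2_end: float = np.nan
    spike_metric: float = np.nan
    divot_metric: float = np.nan
    per_breath: list[BreathRecord] = field(default_factory=list)
    siii_records: list[SIIIRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frc_mL <= 0:
            raise ValueError("frc_mL must be positive")
        if self.n_washout_breaths < 1:
            raise ValueError("n_washout_breaths must be >= 1")
        if abs(self.lci - self.cev_mL / self.frc_mL) > 1e-9:
            raise ValueError("lci must equal cev_mL / frc_mL")
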