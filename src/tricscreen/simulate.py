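"""Synthetic TRIC experiment generator with known ground truth.

The trace model is a two-state mixture: bound and free tracer each have a
cold-state fluorescence and, after IR-laser onset at ``t = 0``, relax
mono-exponentially toward ``1 + amp`` of their cold level.  A well at bound
fraction ``fb`` emits the ``fb``-weighted mixture of the two state curves,
with multiplicative i.i.d. Gaussian noise per sample.  This is the simplest
model that reproduces the observed phenomenology (fast post-onset intensity
change reaching a quasi-plateau whose amplitude depends on binding state);
no claim is made about the underlying photophysics.

Ground truth (per-well bound fractions, per-peptide affinities, injected
artifacts) is returned alongside every simulated data set so downstream
analysis can be validated without instrument data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import trapezoid

from .binding import BinarySystem, solve_binary, solve_competitive
from .traces import DEFAULT_F0_WINDOW, DEFAULT_F1_WINDOW, TricTrace

__all__ = [
    "TricPhotophysics",
    "TraceSchedule",
    "ArtifactSpec",
    "simulate_trace",
    "noiseless_curve",
    "infer_bound_fraction",
    "calibrated_area_scale",
    "simulate_screen_plate",
    "simulate_dose_response",
    "inject_artifact",
    "well_name",
    "PLATE_CAPACITY",
]

PLATE_CAPACITY = 384  # 16 rows x 24 columns


@dataclass(frozen=True)
class TricPhotophysics:
    """Two-state TRIC response parameters.

    Amplitudes are fractional fluorescence changes on heating (negative =
    quenching on heating, the common case for red dyes); taus are relaxation
    time constants in seconds.  Defaults place the hot plateau well within a
    1.5 s heating window and give a fully displacing competitor an area
    statistic of ~2 after calibration, comfortably above the 0.5 binder
    threshold.
    """

    f_init_bound: float = 1.0
    f_init_free: float = 1.0
    amp_bound: float = -0.12
    amp_free: float = -0.06
    tau_bound: float = 0.15
    tau_free: float = 0.12
    noise_cv: float = 0.005

    def __post_init__(self) -> None:
        if not (self.tau_bound > 0 and self.tau_free > 0):
            raise ValueError("relaxation time constants must be positive")
        for a in (self.amp_bound, self.amp_free):
            if not (-1.0 < a < 1.0):
                raise ValueError("amplitudes must lie in (-1, 1)")
        if self.amp_bound == self.amp_free and self.f_init_bound == self.f_init_free:
            raise ValueError("bound and free responses are identical: zero assay window")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.f_init_bound <= 0 or self.f_init_free <= 0:
            raise ValueError("cold-state fluorescence must be positive")


@dataclass(frozen=True)
class TraceSchedule:
    """Sampling schedule around laser onset at t = 0."""

    t_start: float = -1.0
    t_end: float = 1.5
    sampling_rate: float = 100.0

    def __post_init__(self) -> None:
        if not (self.t_start < 0.0 < self.t_end):
            raise ValueError("schedule must span t_start < 0 < t_end")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    def times(self) -> np.ndarray:
        n = int(round((self.t_end - self.t_start) * self.sampling_rate)) + 1
        return self.t_start + np.arange(n) / self.sampling_rate


@dataclass(frozen=True)
class ArtifactSpec:
    """A well artifact to inject: kind and dimensionless magnitude."""

    kind: str
    magnitude: float

    KINDS = ("autofluorescent", "quenched", "aggregated", "bubble")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        if not self.magnitude > 0:
            raise ValueError("artifact magnitude must be > 0")


def _state_curves(photo: TricPhotophysics, t: np.ndarray) -> tuple:
    heat = t >= 0.0
    sb = photo.f_init_bound * (
        1.0 + photo.amp_bound * (1.0 - np.exp(-np.maximum(t, 0.0) / photo.tau_bound)) * heat
    )
    sf = photo.f_init_free * (
        1.0 + photo.amp_free * (1.0 - np.exp(-np.maximum(t, 0.0) / photo.tau_free)) * heat
    )
    return sb, sf


def noiseless_curve(
    bound_fraction: float, photo: TricPhotophysics, t: np.ndarray
) -> np.ndarray:
    """Noise-free mixture trace at the given bound fraction."""
    sb, sf = _state_curves(photo, np.asarray(t, dtype=float))
    return bound_fraction * sb + (1.0 - bound_fraction) * sf


def simulate_trace(
    bound_fraction: float,
    photo: TricPhotophysics = TricPhotophysics(),
    schedule: TraceSchedule = TraceSchedule(),
    seed: int = 0,
    *,
    well_id: str = "A01",
    plate_id: str = "plate1",
    rng: "np.random.Generator | None" = None,
) -> TricTrace:
    """Simulate one well's TRIC trace; deterministic given the seed."""
    if not (0.0 <= bound_fraction <= 1.0):
        raise ValueError(f"bound_fraction must be in [0, 1], got {bound_fraction!r}")
    t = schedule.times()
    f = noiseless_curve(bound_fraction, photo, t)
    if photo.noise_cv > 0:
        rng = rng if rng is not None else np.random.default_rng(seed)
        f = f * (1.0 + photo.noise_cv * rng.standard_normal(t.size))
    return TricTrace(well_id=well_id, time=t, fluorescence=f, plate_id=plate_id)


def infer_bound_fraction(
    trace: TricTrace,
    photo: TricPhotophysics,
    f0_window: tuple = DEFAULT_F0_WINDOW,
    f1_window: tuple = DEFAULT_F1_WINDOW,
) -> float:
    """Invert the two-state mixture from a trace's F_0/F_1 window means.

    Exact on noiseless traces (round-trip with :func:`simulate_trace`);
    a consistency check, not an estimator for noisy data.
    """
    sb, sf = _state_curves(photo, trace.time)

    def wmean(x: np.ndarray, win: tuple) -> float:
        m = (trace.time >= win[0]) & (trace.time <= win[1])
        return float(x[m].mean())

    f0m, f1m = trace.window_mean(f0_window), trace.window_mean(f1_window)
    ratio = f1m / f0m
    # f1(fb) - ratio * f0(fb) = 0 is linear in fb
    a = (wmean(sb, f1_window) - ratio * wmean(sb, f0_window)) - (
        wmean(sf, f1_window) - ratio * wmean(sf, f0_window)
    )
    b = wmean(sf, f1_window) - ratio * wmean(sf, f0_window)
    return -b / a


def calibrated_area_scale(
    assay: BinarySystem,
    photo: TricPhotophysics = TricPhotophysics(),
    schedule: TraceSchedule = TraceSchedule(),
    window: "tuple | None" = None,
    f0_window: tuple = DEFAULT_F0_WINDOW,
) -> float:
    """Area-statistic calibration constant for an assay configuration.

    The raw area between the no-competitor control curve (binary bound
    fraction) and the fully displaced curve (bound fraction 0), both
    baseline-normalized and noise-free, divided by 2 — so a fully displacing
    competitor scores exactly 2 under these defaults and the fixed 0.5
    binder threshold retains its meaning across configurations.
    """
    t = schedule.times()
    fb0 = solve_binary(assay).tracer_bound_fraction
    ctrl = noiseless_curve(fb0, photo, t)
    disp = noiseless_curve(0.0, photo, t)

    def norm(f: np.ndarray) -> np.ndarray:
        m = (t >= f0_window[0]) & (t <= f0_window[1])
        return f / f[m].mean()

    if window is None:
        window = (0.0, float(t[-1]))
    m = (t >= window[0]) & (t <= window[1])
    raw = float(trapezoid(np.abs(norm(disp) - norm(ctrl))[m], t[m]))
    return raw / 2.0


def well_name(index: int) -> str:
    """384-well name (A01..P24) for a running 0-based index."""
    if not 0 <= index < PLATE_CAPACITY:
        raise ValueError(f"well index {index} outside 384-well plate")
    return f"{chr(ord('A') + index // 24)}{index % 24 + 1:02d}"


def _normalize_library(library) -> "list[tuple[str, float]]":
    """Accept a mapping, sequence of pairs, or DataFrame(peptide_id, ki_m)."""
    if isinstance(library, pd.DataFrame):
        items = list(zip(library["peptide_id"], library["ki_m"]))
    elif isinstance(library, dict):
        items = list(library.items())
    else:
        items = [tuple(x) for x in library]
    out = []
    for pid, ki in items:
        ki = float("nan") if ki is None else float(ki)
        out.append((str(pid), ki))
    if not out:
        raise ValueError("library must not be empty")
    return out


def simulate_screen_plate(
    library,
    assay: BinarySystem,
    screen_concentration: float,
    photo: TricPhotophysics = TricPhotophysics(),
    schedule: TraceSchedule = TraceSchedule(),
    *,
    n_replicates: int = 2,
    controls_per_plate: int = 8,
    artifacts: "dict | None" = None,
    seed: int = 0,
) -> tuple:
    """Simulate a single-dose 384-well screen with duplicate wells.

    ``library`` maps peptide ids to true K_i in molar (NaN/None marks a
    non-binder, which leaves the control equilibrium untouched).  Each
    peptide occupies ``n_replicates`` wells at the single screen
    concentration; every plate carries its own no-competitor control wells.
    Libraries exceeding one plate spill onto additional plates.  ``artifacts``
    maps peptide id -> :class:`ArtifactSpec`, applied to that peptide's first
    well.  Returns ``(traces, layout, truth)``.
    """
    peptides = _normalize_library(library)
    if n_replicates < 2:
        raise ValueError("peptides are screened in at least duplicate")
    if controls_per_plate < 2:
        raise ValueError("need >= 2 control wells per plate")
    rng = np.random.default_rng(seed)
    fb_control = solve_binary(assay).tracer_bound_fraction

    fb = {}
    for pid, ki in peptides:
        if np.isfinite(ki):
            st = solve_competitive(assay.with_competitor(screen_concentration, ki))
            fb[pid] = st.tracer_bound_fraction
        else:
            fb[pid] = fb_control

    per_plate_tests = PLATE_CAPACITY - controls_per_plate
    if per_plate_tests < n_replicates:
        raise ValueError("controls_per_plate leaves no room for test wells")

    traces: list[TricTrace] = []
    layout_rows = []
    truth_wells = {}
    artifacts = artifacts or {}
    artifact_log = {}

    plate_no, slot = 0, None
    ctrl_count = 0

    def new_plate():
        nonlocal plate_no, slot, ctrl_count
        plate_no += 1
        slot = 0
        ctrl_count = 0

    new_plate()

    def emit(pid: str, role: str, frac: float, rep: int, spec: "ArtifactSpec | None"):
        nonlocal slot
        plate_id = f"plate{plate_no}"
        wid = well_name(slot)
        slot += 1
        tr = simulate_trace(
            frac, photo, schedule, well_id=wid, plate_id=plate_id, rng=rng
        )
        if spec is not None:
            tr = inject_artifact(tr, spec, rng=rng)
            artifact_log[f"{plate_id}:{wid}"] = spec.kind
        traces.append(tr)
        layout_rows.append(
            {
                "plate_id": plate_id,
                "well_id": wid,
                "peptide_id": pid,
                "role": role,
                "concentration_m": 0.0 if role == "control" else screen_concentration,
                "replicate": rep,
            }
        )
        truth_wells[f"{plate_id}:{wid}"] = frac

    for pid, ki in peptides:
        if slot + n_replicates > PLATE_CAPACITY:
            new_plate()
        if ctrl_count == 0:
            for r in range(controls_per_plate):
                emit("CONTROL", "control", fb_control, r, None)
                ctrl_count += 1
        spec = artifacts.get(pid)
        for r in range(n_replicates):
            emit(pid, "test", fb[pid], r, spec if r == 0 else None)

    layout = pd.DataFrame(layout_rows)
    truth = {
        "screen_concentration_m": screen_concentration,
        "control_bound_fraction": fb_control,
        "peptide_ki_m": {pid: (ki if np.isfinite(ki) else None) for pid, ki in peptides},
        "peptide_bound_fraction": fb,
        "well_bound_fraction": truth_wells,
        "artifacts": artifact_log,
        "n_plates": plate_no,
    }
    return traces, layout, truth


def simulate_dose_response(
    ki: float,
    assay: BinarySystem,
    top_concentration: float,
    photo: TricPhotophysics = TricPhotophysics(),
    schedule: TraceSchedule = TraceSchedule(),
    *,
    n_points: int = 12,
    factor: float = 2.0,
    n_replicates: int = 1,
    n_controls: int = 2,
    seed: int = 0,
    peptide_id: str = "PEP1",
) -> tuple:
    """Simulate a dilution-series displacement titration.

    Twelve two-fold dilutions from the top concentration by default, plus
    ``n_controls`` no-competitor control wells; the true bound fraction at
    every point comes from the exact competitive equilibrium.  ``ki =
    inf``/NaN simulates a non-binder (flat series).  Returns
    ``(traces, layout, truth)``.
    """
    if top_concentration <= 0:
        raise ValueError("top concentration must be positive")
    rng = np.random.default_rng(seed)
    conc = top_concentration / factor ** np.arange(n_points)
    fb0 = solve_binary(assay).tracer_bound_fraction
    if np.isfinite(ki):
        fracs = [
            solve_competitive(assay.with_competitor(c, ki)).tracer_bound_fraction
            for c in conc
        ]
    else:
        fracs = [fb0] * n_points

    traces, rows = [], []
    slot = 0

    def emit(pid, role, c, frac, rep):
        nonlocal slot
        wid = well_name(slot)
        slot += 1
        traces.append(simulate_trace(frac, photo, schedule, well_id=wid, rng=rng))
        rows.append(
            {
                "plate_id": "plate1",
                "well_id": wid,
                "peptide_id": pid,
                "role": role,
                "concentration_m": c,
                "replicate": rep,
            }
        )

    for r in range(n_controls):
        emit("CONTROL", "control", 0.0, fb0, r)
    for rep in range(n_replicates):
        for c, frac in zip(conc, fracs):
            emit(peptide_id, "test", c, frac, rep)
    layout = pd.DataFrame(rows)
    truth = {
        "peptide_id": peptide_id,
        "ki_m": ki if np.isfinite(ki) else None,
        "concentrations_m": conc.tolist(),
        "bound_fractions": list(map(float, fracs)),
    }
    return traces, layout, truth


def inject_artifact(
    trace: TricTrace,
    spec: ArtifactSpec,
    seed: int = 0,
    *,
    rng: "np.random.Generator | None" = None,
) -> TricTrace:
    """Return a copy of the trace with one artifact injected.

    autofluorescent / quenched scale the whole trace (steady-state
    brightness change); aggregated adds 1–3 smooth Gaussian bumps in the
    heating window; bubble applies a step discontinuity.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    t, f = trace.time, trace.fluorescence.copy()
    m = spec.magnitude
    if spec.kind == "autofluorescent":
        f = f * (1.0 + m)
    elif spec.kind == "quenched":
        if m >= 1.0:
            raise ValueError("quench magnitude >= 1 would make fluorescence non-positive")
        f = f * (1.0 - m)
    elif spec.kind == "aggregated":
        # aggregate particles drifting through the detection volume give
        # transient positive intensity excursions during heating
        n_bumps = int(rng.integers(1, 4))
        t_hi = float(t[-1])
        for _ in range(n_bumps):
            center = float(rng.uniform(0.1 * t_hi, 0.9 * t_hi))
            width = float(rng.uniform(0.05, 0.3))
            f = f + m * f * np.exp(-0.5 * ((t - center) / width) ** 2)
        if np.any(f <= 0):
            raise ValueError("aggregation magnitude drove fluorescence non-positive")
    elif spec.kind == "bubble":
        t_hi = float(t[-1])
        t_step = float(rng.uniform(0.1 * t_hi, 0.9 * t_hi))
        sign = float(rng.choice([-1.0, 1.0]))
        fac = 1.0 + sign * m
        if fac <= 0:
            raise ValueError("bubble magnitude drove fluorescence non-positive")
        f = np.where(t >= t_step, f * fac, f)
    return TricTrace(
        well_id=trace.well_id, time=t, fluorescence=f, plate_id=trace.plate_id
    )
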