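"""TRIC trace processing: F_norm, per-well QC, and the screening area statistic.

A TRIC trace is a well's fluorescence versus time around the IR-laser onset
at ``t = 0``: a cold baseline for ``t < 0`` and a heating phase relaxing to a
quasi-plateau for ``t > 0``.  Binding state changes the relaxation amplitude,
so displacement of a bound tracer is visible either as an F_norm shift
(hot/cold window ratio) or, in single-dose screening mode, as the area
between the mean test trace and the mean no-competitor control trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import trapezoid
from scipy.ndimage import median_filter
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "TricTrace",
    "FnormResult",
    "QCThresholds",
    "QCVerdict",
    "ScreenRecord",
    "AnalysisError",
    "DEFAULT_F0_WINDOW",
    "DEFAULT_F1_WINDOW",
    "compute_fnorm",
    "qc_well",
    "qc_plate",
    "area_statistic",
    "screen_records",
    "classify_screen",
]

#: Default cold (pre-laser) and hot (quasi-plateau) averaging windows, seconds.
DEFAULT_F0_WINDOW = (-0.8, 0.0)
DEFAULT_F1_WINDOW = (1.0, 1.4)

DISQUALIFYING_FLAGS = frozenset(
    {"autofluorescent", "quenched", "aggregated", "bubble_or_precipitate"}
)


class AnalysisError(ValueError):
    """Raised when a trace cannot be analyzed (bad windows, no usable wells)."""


@dataclass(frozen=True)
class TricTrace:
    """One well's time-resolved fluorescence."""

    well_id: str
    time: np.ndarray
    fluorescence: np.ndarray
    plate_id: str = "plate1"

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.ndim != 1 or t.shape != f.shape or t.size < 4:
            raise AnalysisError(f"well {self.well_id}: malformed trace arrays")
        if not np.all(np.diff(t) > 0):
            raise AnalysisError(f"well {self.well_id}: time must be strictly increasing")
        if not np.all(np.isfinite(f)) or np.any(f <= 0):
            raise AnalysisError(f"well {self.well_id}: fluorescence must be finite and positive")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "fluorescence", f)

    def window_mean(self, window: tuple) -> float:
        lo, hi = window
        mask = (self.time >= lo) & (self.time <= hi)
        if not mask.any():
            raise AnalysisError(
                f"well {self.well_id}: window [{lo}, {hi}] s contains no samples"
            )
        return float(self.fluorescence[mask].mean())


@dataclass(frozen=True)
class FnormResult:
    """Cold mean F_0, hot mean F_1 and F_norm = 1000 * F_1/F_0 (per-mille)."""

    f0: float
    f1: float
    fnorm: float


def compute_fnorm(
    trace: TricTrace,
    f0_window: tuple = DEFAULT_F0_WINDOW,
    f1_window: tuple = DEFAULT_F1_WINDOW,
) -> FnormResult:
    """F_norm of one trace: per-mille ratio of hot to cold window means."""
    if f0_window[1] > 0 or f1_window[0] < 0:
        raise AnalysisError("f0 window must end at/before laser-on, f1 window after")
    f0 = trace.window_mean(f0_window)
    f1 = trace.window_mean(f1_window)
    if f0 <= 0:
        raise AnalysisError(f"well {trace.well_id}: non-positive F_0")
    return FnormResult(f0=f0, f1=f1, fnorm=1000.0 * f1 / f0)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QCThresholds:
    """Thresholds for the per-well artifact heuristics.

    Baseline thresholds are relative deviations from the plate-median cold
    fluorescence.  The aggregation and step detectors compare residual
    magnitudes (on baseline-normalized traces) against the larger of an
    absolute floor and a multiple of the per-trace robust noise scale
    (1.4826 x MAD of high-pass residuals).
    """

    auto_baseline: float = 0.25   # flag if baseline > median * (1 + this)
    quench_baseline: float = 0.20  # flag if baseline < median * (1 - this)
    agg_abs: float = 0.015
    agg_rel: float = 3.0
    shape_abs: float = 0.03
    shape_rel: float = 6.0
    step_abs: float = 0.03
    step_rel: float = 10.0
    smooth_window: int = 5


@dataclass(frozen=True)
class QCVerdict:
    flags: frozenset
    metrics: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not (self.flags & DISQUALIFYING_FLAGS)


def _robust_noise_scale(x: np.ndarray) -> float:
    d = np.diff(x)
    mad = np.median(np.abs(d - np.median(d)))
    return 1.4826 * mad / np.sqrt(2.0)


def qc_well(
    trace: TricTrace,
    plate_baselines: np.ndarray,
    thresholds: QCThresholds = QCThresholds(),
    f0_window: tuple = DEFAULT_F0_WINDOW,
    heat_window: "tuple | None" = None,
    external_flags: "frozenset | None" = None,
    reference_shape: "np.ndarray | None" = None,
) -> QCVerdict:
    """Classify one well's artifacts from its trace and plate context.

    Autofluorescence and quenching are steady-state effects detected on the
    cold baseline relative to the plate-median baseline.  Aggregation is
    flagged by either of two complementary residuals: a non-monotone
    deviation of the smoothed heating curve from an isotonic reference, or
    — when a plate-median ``reference_shape`` is available — the residual of
    the well's heating curve after affine regression onto that shape, which
    also catches bumps that happen to reshape the decay monotonically.
    Bubbles/precipitates produce single-sample steps.  Hardware axial-scan
    verdicts, when available, enter as ``external_flags``.
    """
    plate_baselines = np.asarray(plate_baselines, dtype=float)
    if plate_baselines.size < 8:
        raise AnalysisError("need >= 8 wells on the plate for robust baseline statistics")
    f0 = trace.window_mean(f0_window)
    ratio = f0 / float(np.median(plate_baselines))

    flags = set(external_flags or ())
    if ratio > 1.0 + thresholds.auto_baseline:
        flags.add("autofluorescent")
    if ratio < 1.0 - thresholds.quench_baseline:
        flags.add("quenched")

    g = trace.fluorescence / f0
    base = g[(trace.time >= f0_window[0]) & (trace.time <= f0_window[1])]
    nscale = _robust_noise_scale(base)

    if heat_window is None:
        heat_window = (0.0, float(trace.time[-1]))
    hmask = (trace.time >= heat_window[0]) & (trace.time <= heat_window[1])
    heat = g[hmask]
    w = thresholds.smooth_window
    ref = median_filter(heat, size=w, mode="nearest")
    xs = np.arange(ref.size, dtype=float)
    # direction chosen by fit quality, so verdicts stay deterministic
    candidates = [
        IsotonicRegression(increasing=inc).fit(xs, ref).predict(xs)
        for inc in (True, False)
    ]
    iso = min(candidates, key=lambda c: float(((c - ref) ** 2).sum()))
    agg_score = float(np.max(np.abs(ref - iso)))
    if agg_score > max(thresholds.agg_abs, thresholds.agg_rel * nscale):
        flags.add("aggregated")

    shape_score = float("nan")
    if reference_shape is not None and reference_shape.size == heat.size:
        a_mat = np.column_stack([np.ones_like(reference_shape), reference_shape])
        coef, *_ = np.linalg.lstsq(a_mat, heat, rcond=None)
        resid = median_filter(heat - a_mat @ coef, size=w, mode="nearest")
        shape_score = float(np.max(np.abs(resid)))
        if shape_score > max(thresholds.shape_abs, thresholds.shape_rel * nscale):
            flags.add("aggregated")

    d = np.diff(heat)
    hp = d - median_filter(d, size=9, mode="nearest")
    step_score = float(np.max(np.abs(hp))) if hp.size else 0.0
    if step_score > max(thresholds.step_abs, thresholds.step_rel * nscale * np.sqrt(2.0)):
        flags.add("bubble_or_precipitate")

    return QCVerdict(
        flags=frozenset(flags),
        metrics={
            "baseline_ratio": ratio,
            "noise_scale": nscale,
            "smoothness_score": agg_score,
            "shape_score": shape_score,
            "step_score": step_score,
        },
    )


def qc_plate(
    traces: "list[TricTrace]",
    thresholds: QCThresholds = QCThresholds(),
    f0_window: tuple = DEFAULT_F0_WINDOW,
    heat_window: "tuple | None" = None,
    external_flags: "dict | None" = None,
) -> dict:
    """QC verdicts for every well on one plate, keyed by well id.

    When all wells share a time grid, the plate-median normalized heating
    curve serves as the reference shape for the aggregation detector.
    """
    baselines = np.array([t.window_mean(f0_window) for t in traces])
    external_flags = external_flags or {}
    reference = None
    t0 = traces[0].time
    if all(t.time.shape == t0.shape and np.array_equal(t.time, t0) for t in traces[1:]):
        if heat_window is None:
            hw = (0.0, float(t0[-1]))
        else:
            hw = heat_window
        hmask = (t0 >= hw[0]) & (t0 <= hw[1])
        curves = np.stack([
            (t.fluorescence / b)[hmask] for t, b in zip(traces, baselines)
        ])
        reference = median_filter(
            np.median(curves, axis=0), size=thresholds.smooth_window, mode="nearest"
        )
    return {
        t.well_id: qc_well(
            t,
            baselines,
            thresholds,
            f0_window,
            heat_window,
            external_flags=frozenset(external_flags.get(t.well_id, ())),
            reference_shape=reference,
        )
        for t in traces
    }


# ---------------------------------------------------------------------------
# single-dose screening statistic
# ---------------------------------------------------------------------------

def _normalized_matrix(traces: "list[TricTrace]", f0_window: tuple) -> tuple:
    t0 = traces[0].time
    for t in traces[1:]:
        if t.time.shape != t0.shape or not np.allclose(t.time, t0):
            raise AnalysisError("traces must share a common time grid for the area statistic")
    mat = np.stack([t.fluorescence / t.window_mean(f0_window) for t in traces])
    return t0, mat


def area_statistic(
    test_traces: "list[TricTrace]",
    control_traces: "list[TricTrace]",
    window: "tuple | None" = None,
    *,
    scale: float = 1.0,
    f0_window: tuple = DEFAULT_F0_WINDOW,
) -> tuple:
    """Area between mean test and mean control trace, baseline-normalized.

    Each trace is normalized to its own cold-window mean, the absolute
    difference of the mean test and mean control curves is integrated
    (trapezoid) over the heating window, and the integral is divided by a
    calibration ``scale`` so that a fully displacing competitor under the
    simulator's default photophysics scores ~2 (see
    :func:`tricscreen.simulate.calibrated_area_scale`).

    Returns ``(area, area_sd, n_test_used)``; the SD is the spread of
    per-well areas against the mean control curve (NaN for a single well).
    """
    if len(test_traces) < 1 or len(control_traces) < 2:
        raise AnalysisError("need >= 1 test and >= 2 control traces")
    time, tmat = _normalized_matrix(list(test_traces) + list(control_traces), f0_window)
    n_test = len(test_traces)
    ctrl_mean = tmat[n_test:].mean(axis=0)
    if window is None:
        window = (0.0, float(time[-1]))
    m = (time >= window[0]) & (time <= window[1])
    tw, cw = time[m], ctrl_mean[m]

    def one_area(curve: np.ndarray) -> float:
        return float(trapezoid(np.abs(curve - cw), tw)) / scale

    area = one_area(tmat[:n_test].mean(axis=0)[m])
    per_well = np.array([one_area(tmat[i][m]) for i in range(n_test)])
    sd = float(per_well.std(ddof=1)) if n_test >= 2 else float("nan")
    return area, sd, n_test


@dataclass(frozen=True)
class ScreenRecord:
    """Per-peptide single-dose screening outcome."""

    peptide_id: str
    area: float
    area_sd: float
    n_wells: int
    flags: frozenset
    evaluable: bool
    is_binder: bool = False


def screen_records(
    traces: "list[TricTrace]",
    layout: pd.DataFrame,
    *,
    scale: float,
    thresholds: QCThresholds = QCThresholds(),
    f0_window: tuple = DEFAULT_F0_WINDOW,
    window: "tuple | None" = None,
    external_flags: "dict | None" = None,
) -> "list[ScreenRecord]":
    """Compute QC verdicts and area statistics for a single-dose screen.

    ``layout`` needs columns plate_id, well_id, peptide_id, role
    (test/control).  QC-flagged wells are excluded from the area computation;
    peptides whose test wells are all flagged are marked unevaluable rather
    than silently scored zero.
    """
    by_plate: dict = {}
    for tr in traces:
        by_plate.setdefault(tr.plate_id, {})[tr.well_id] = tr

    records: list[ScreenRecord] = []
    for plate_id, plate_traces in by_plate.items():
        sub = layout[layout["plate_id"] == plate_id]
        verdicts = qc_plate(
            list(plate_traces.values()), thresholds, f0_window, window,
            external_flags=(external_flags or {}).get(plate_id),
        )
        ctrl_ids = sub.loc[sub["role"] == "control", "well_id"]
        controls = [
            plate_traces[w] for w in ctrl_ids
            if w in plate_traces and verdicts[w].ok
        ]
        if len(controls) < 2:
            raise AnalysisError(
                f"plate {plate_id}: fewer than 2 QC-passing control wells"
            )
        tests = sub[sub["role"] == "test"]
        for pep, grp in tests.groupby("peptide_id", sort=False):
            wells = [w for w in grp["well_id"] if w in plate_traces]
            flags: set = set()
            for w in wells:
                flags |= set(verdicts[w].flags)
            usable = [plate_traces[w] for w in wells if verdicts[w].ok]
            if not usable:
                records.append(
                    ScreenRecord(pep, float("nan"), float("nan"), 0,
                                 frozenset(flags), evaluable=False)
                )
                continue
            area, sd, n = area_statistic(
                usable, controls, window, scale=scale, f0_window=f0_window
            )
            records.append(
                ScreenRecord(pep, area, sd, n, frozenset(flags), evaluable=True)
            )
    return records


def classify_screen(
    records: "list[ScreenRecord]", threshold: float = 0.5
) -> "list[ScreenRecord]":
    """Apply the binder threshold (strict ``area > threshold``) and sort.

    Unevaluable peptides (all wells QC-failed) are never binders; flagged
    wells were already excluded upstream.  Returns records sorted by area,
    highest first, unevaluable records last.
    """
    out = [
        ScreenRecord(
            r.peptide_id, r.area, r.area_sd, r.n_wells, r.flags, r.evaluable,
            is_binder=bool(r.evaluable and r.area > threshold),
        )
        for r in records
    ]
    return sorted(
        out,
        key=lambda r: (not r.evaluable, -(r.area if np.isfinite(r.area) else -np.inf)),
    )


def records_to_frame(records: "list[ScreenRecord]") -> pd.DataFrame:
    """Tabular view of screen records (for TSV export)."""
    return pd.DataFrame(
        {
            "peptide_id": [r.peptide_id for r in records],
            "area": [r.area for r in records],
            "area_sd": [r.area_sd for r in records],
            "n_wells": [r.n_wells for r in records],
            "flags": [";".join(sorted(r.flags)) for r in records],
            "evaluable": [r.evaluable for r in records],
            "is_binder": [r.is_binder for r in records],
        }
    )
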