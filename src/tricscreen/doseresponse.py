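"""Displacement titration fitting: EC50, K_i, S/N, outliers, replicates.

Twelve-point, two-fold dilution series of an unlabeled competitor against a
constant receptor–tracer complex are fit either with a four-parameter
logistic on log10 concentration (``logistic4``) or with the exact
competitive-equilibrium forward model (``competitive_exact``), which is the
default because the high-affinity tracer operates in a receptor-depleted
regime where the Cheng–Prusoff assumption fails badly.

S/N is defined as the fitted response amplitude divided by the residual
standard deviation; non-displacing series are reported as censored
(``K_i`` greater than the top assayed concentration) rather than fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .binding import (
    BinarySystem,
    TightBindingError,
    displacement_curve,
    ec50_to_ki,
    ki_to_ec50,
    solve_binary,
)
from .traces import DEFAULT_F0_WINDOW, DEFAULT_F1_WINDOW, QCThresholds, compute_fnorm, qc_plate

__all__ = [
    "DoseSeries",
    "DoseResponseFit",
    "ReplicateSummary",
    "build_dilution_series",
    "dose_series_from_traces",
    "fit_dose_response",
    "detect_outliers",
    "summarize_replicates",
]


def build_dilution_series(top: float, n: int = 12, factor: float = 2.0) -> np.ndarray:
    """Geometric dilution series ``[top / factor**k for k in 0..n-1]``."""
    if not (top > 0 and np.isfinite(top)):
        raise ValueError(f"top concentration must be positive, got {top!r}")
    if n < 2 or factor <= 1.0:
        raise ValueError("need n >= 2 points and dilution factor > 1")
    return top / factor ** np.arange(n)


@dataclass(frozen=True)
class DoseSeries:
    """F_norm responses of one peptide across a dilution series."""

    peptide_id: str
    concentrations: np.ndarray  # molar
    fnorm: np.ndarray  # per-mille
    replicate: "np.ndarray | None" = None
    qc_ok: "np.ndarray | None" = None

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        y = np.asarray(self.fnorm, dtype=float)
        if c.shape != y.shape or c.ndim != 1:
            raise ValueError("concentrations and fnorm must be equal-length vectors")
        if np.any(~np.isfinite(c)) or np.any(c <= 0):
            raise ValueError("concentrations must be strictly positive and finite")
        if np.any(~np.isfinite(y)):
            raise ValueError("fnorm values must be finite")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "fnorm", y)
        if self.qc_ok is None:
            object.__setattr__(self, "qc_ok", np.ones(c.size, dtype=bool))
        else:
            object.__setattr__(self, "qc_ok", np.asarray(self.qc_ok, dtype=bool))


def dose_series_from_traces(
    traces,
    layout,
    peptide_id: "str | None" = None,
    *,
    f0_window: tuple = DEFAULT_F0_WINDOW,
    f1_window: tuple = DEFAULT_F1_WINDOW,
    qc_thresholds: "QCThresholds | None" = None,
) -> DoseSeries:
    """Build a :class:`DoseSeries` from raw traces plus a layout table.

    Wells failing QC (when thresholds are given and the plate carries at
    least 8 wells) are kept in the series but masked out via ``qc_ok``.
    """
    by_well = {(t.plate_id, t.well_id): t for t in traces}
    sub = layout[layout["role"] == "test"]
    if peptide_id is not None:
        sub = sub[sub["peptide_id"] == peptide_id]
    else:
        ids = sub["peptide_id"].unique()
        if len(ids) != 1:
            raise ValueError(f"layout contains several peptides {list(ids)}; pass peptide_id")
        peptide_id = ids[0]
    qc_ok = {}
    if qc_thresholds is not None and len(traces) >= 8:
        for v_well, verdict in qc_plate(list(traces), qc_thresholds, f0_window).items():
            qc_ok[v_well] = verdict.ok
    conc, fn, rep, ok = [], [], [], []
    for _, row in sub.iterrows():
        tr = by_well[(row["plate_id"], row["well_id"])]
        conc.append(row["concentration_m"])
        fn.append(compute_fnorm(tr, f0_window, f1_window).fnorm)
        rep.append(row.get("replicate", 0))
        ok.append(qc_ok.get(row["well_id"], True))
    return DoseSeries(
        peptide_id=peptide_id,
        concentrations=np.array(conc),
        fnorm=np.array(fn),
        replicate=np.array(rep),
        qc_ok=np.array(ok),
    )


@dataclass(frozen=True)
class DoseResponseFit:
    """Result of fitting one displacement titration."""

    peptide_id: str
    model: str
    verdict: str  # ok | no_displacement | unfittable
    ec50: float = float("nan")
    hill: float = float("nan")
    top: float = float("nan")
    bottom: float = float("nan")
    ki: float = float("nan")
    ki_lower_bound: "float | None" = None  # censored: true ki exceeds this
    s_n: float = float("nan")
    residual_sd: float = float("nan")
    n_points: int = 0
    excluded_points: list = field(default_factory=list)
    converged: bool = False
    notes: str = ""

    @property
    def censored(self) -> bool:
        return self.ki_lower_bound is not None


def _logistic4(x, top, bottom, log_ec50, hill):
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((x - log_ec50) * hill))


def _fit_logistic4(conc: np.ndarray, y: np.ndarray):
    x = np.log10(conc)
    top0 = y[np.argsort(conc)[:2]].mean()
    bot0 = y[np.argsort(conc)[-2:]].mean()
    mid = 0.5 * (top0 + bot0)
    ec0 = x[np.argmin(np.abs(y - mid))]
    p, _ = curve_fit(
        _logistic4, x, y, p0=[top0, bot0, ec0, 1.0], maxfev=20_000
    )
    pred = _logistic4(x, *p)
    eps = np.sqrt(np.finfo(float).eps)
    jac = np.empty((x.size, 4))
    for j in range(4):
        dp = np.array(p, dtype=float)
        h = eps * max(abs(dp[j]), 1.0)
        dp[j] += h
        jac[:, j] = (_logistic4(x, *dp) - pred) / h
    params = {"top": p[0], "bottom": p[1], "log_ec50": p[2], "hill": p[3]}
    return params, pred, jac


def _fit_competitive(conc: np.ndarray, y: np.ndarray, assay: BinarySystem):
    lo = np.log10(conc.min()) - 3.0
    hi = np.log10(conc.max()) + 3.0
    best = None
    for lki in np.linspace(lo, hi, 31):
        fb = displacement_curve(assay, conc, 10.0**lki)
        a_mat = np.column_stack([np.ones_like(fb), fb])
        coef, *_ = np.linalg.lstsq(a_mat, y, rcond=None)
        sse = float(((a_mat @ coef - y) ** 2).sum())
        if best is None or sse < best[0]:
            best = (sse, coef, lki)
    _, (base0, amp0), lki0 = best

    def resid(p):
        base, amp, lki = p
        return y - (base + amp * displacement_curve(assay, conc, 10.0**lki))

    sol = least_squares(resid, x0=[base0, amp0, lki0], method="lm", max_nfev=5_000)
    base, amp, lki = sol.x
    pred = y - sol.fun
    params = {"base": base, "amp": amp, "log_ki": lki}
    return params, pred, -sol.jac


def _external_studentized(resid: np.ndarray, jac: np.ndarray) -> np.ndarray:
    """Externally studentized residuals via the linearized-leverage formula."""
    n, p = jac.shape
    if n <= p + 1:
        return np.zeros(n)
    jtj = jac.T @ jac
    h = np.einsum("ij,jk,ik->i", jac, np.linalg.pinv(jtj), jac)
    h = np.clip(h, 0.0, 1.0 - 1e-9)
    sse = float((resid**2).sum())
    out = np.empty(n)
    for i in range(n):
        s2 = (sse - resid[i] ** 2 / (1.0 - h[i])) / (n - p - 1)
        if s2 <= 0:
            out[i] = np.inf if resid[i] != 0 else 0.0
        else:
            out[i] = resid[i] / np.sqrt(s2 * (1.0 - h[i]))
    return out


def _fit_once(conc, y, model, assay):
    if model == "logistic4":
        return _fit_logistic4(conc, y)
    if model == "competitive_exact":
        if assay is None:
            raise ValueError("competitive_exact requires the assay BinarySystem")
        return _fit_competitive(conc, y, assay)
    raise ValueError(f"unknown model {model!r}")


def detect_outliers(
    series: DoseSeries,
    model: str = "competitive_exact",
    assay: "BinarySystem | None" = None,
    *,
    threshold: float = 3.0,
    max_exclusions: int = 2,
    min_residual: float = 0.05,
) -> list:
    """Iteratively flag at most ``max_exclusions`` outlier points.

    After a provisional fit, the single worst point whose externally
    studentized residual exceeds the threshold is excluded and the curve is
    refit, up to the cap.  Studentization is scale-free, so a point is only
    excludable if its raw residual also exceeds ``min_residual`` per-mille —
    otherwise optimizer-tolerance noise on an essentially perfect fit would
    be studentized into spurious outliers.  Returns
    ``[(index, studentized_residual), ...]`` in exclusion order, indices
    into the series arrays.
    """
    idx = np.where(series.qc_ok)[0]
    excluded = []
    for _ in range(max_exclusions):
        conc, y = series.concentrations[idx], series.fnorm[idx]
        _, pred, jac = _fit_once(conc, y, model, assay)
        resid = y - pred
        t = np.where(np.abs(resid) > min_residual, _external_studentized(resid, jac), 0.0)
        worst = int(np.argmax(np.abs(t)))
        if np.abs(t[worst]) <= threshold:
            break
        excluded.append((int(idx[worst]), float(t[worst])))
        idx = np.delete(idx, worst)
    return excluded


def fit_dose_response(
    series: DoseSeries,
    model: str = "competitive_exact",
    assay: "BinarySystem | None" = None,
    *,
    min_points: int = 8,
    min_span_log10: float = 2.0,
    outlier_threshold: float = 3.0,
    max_exclusions: int = 2,
    no_displacement_k: float = 5.0,
    min_amplitude: float = 2.0,
    ki_mode: str = "exact",
) -> DoseResponseFit:
    """Fit one titration and attach EC50, K_i and S/N.

    ``competitive_exact`` fits (baseline, amplitude, K_i) with the exact
    displacement equilibrium as forward model; ``logistic4`` fits a 4PL on
    log10 concentration and converts its EC50 to K_i via
    :func:`tricscreen.binding.ec50_to_ki` (mode ``ki_mode``).  Outliers are
    excluded iteratively (externally studentized residual > threshold, at
    most ``max_exclusions``).  A predicted response span over the titrated
    range below ``max(no_displacement_k * residual SD, min_amplitude)``
    per-mille yields a censored non-binder verdict with
    ``ki > top concentration``.
    """
    usable = np.where(series.qc_ok)[0]
    if usable.size < min_points:
        return DoseResponseFit(
            series.peptide_id, model, "unfittable",
            n_points=int(usable.size),
            notes=f"only {usable.size} QC-passing points (need {min_points})",
        )
    span = np.log10(series.concentrations[usable].max() / series.concentrations[usable].min())
    if span < min_span_log10:
        return DoseResponseFit(
            series.peptide_id, model, "unfittable",
            n_points=int(usable.size),
            notes=f"concentration span {span:.2f} log10 units (need {min_span_log10})",
        )

    excluded = detect_outliers(
        series, model, assay, threshold=outlier_threshold, max_exclusions=max_exclusions
    )
    keep = np.setdiff1d(usable, [i for i, _ in excluded])
    conc, y = series.concentrations[keep], series.fnorm[keep]
    params, pred, jac = _fit_once(conc, y, model, assay)
    resid = y - pred
    dof = max(conc.size - jac.shape[1], 1)
    resid_sd = float(np.sqrt((resid**2).sum() / dof))
    top_conc = float(series.concentrations.max())
    excluded_records = [
        {
            "index": i,
            "concentration_m": float(series.concentrations[i]),
            "fnorm": float(series.fnorm[i]),
            "studentized_residual": t,
        }
        for i, t in excluded
    ]

    # detectability is judged on the predicted response span across the
    # concentrations actually titrated, not on extrapolated asymptotes (a
    # noise-chasing fit can report a huge asymptotic amplitude on a flat
    # series while predicting an essentially flat curve in-range)
    amplitude = float(np.ptp(pred))
    if model == "competitive_exact":
        fb0 = solve_binary(assay).tracer_bound_fraction
        top_resp = params["base"] + params["amp"] * fb0  # zero-dose asymptote
        bottom_resp = params["base"]  # full displacement
        ki = 10.0 ** params["log_ki"]
        hill = float("nan")
    else:
        top_resp, bottom_resp = params["top"], params["bottom"]
        ki = float("nan")
        hill = params["hill"]

    if amplitude < max(no_displacement_k * resid_sd, min_amplitude):
        return DoseResponseFit(
            series.peptide_id, model, "no_displacement",
            ki_lower_bound=top_conc,
            residual_sd=resid_sd,
            n_points=int(conc.size),
            excluded_points=excluded_records,
            notes="response amplitude below detection; K_i exceeds top concentration",
        )

    notes = ""
    if model == "competitive_exact":
        ec50 = ki_to_ec50(ki, assay)
    else:
        ec50 = 10.0 ** params["log_ec50"]
        try:
            ki = ec50_to_ki(ec50, assay, mode=ki_mode)
        except TightBindingError as err:
            ki = float("nan")
            notes = str(err)

    return DoseResponseFit(
        peptide_id=series.peptide_id,
        model=model,
        verdict="ok",
        ec50=float(ec50),
        hill=float(hill),
        top=float(top_resp),
        bottom=float(bottom_resp),
        ki=float(ki),
        s_n=float(amplitude / resid_sd) if resid_sd > 0 else float("inf"),
        residual_sd=resid_sd,
        n_points=int(conc.size),
        excluded_points=excluded_records,
        converged=True,
        notes=notes,
    )


@dataclass(frozen=True)
class ReplicateSummary:
    """Replicate spread of fitted K_i (or EC50) values, linear scale.

    Mirrors the violin-plot convention: mean, median, 25–75% quantiles
    (linear interpolation) and the whisker range within 1.5 x IQR; a
    geometric mean accompanies the linear one since affinities tend to be
    log-normally distributed.
    """

    n: int
    mean: float
    sd: float
    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float
    outliers: list
    geometric_mean: float


def summarize_replicates(values) -> ReplicateSummary:
    """Summarize replicate affinity values (floats or fits with finite ki)."""
    vals = []
    for v in values:
        if isinstance(v, DoseResponseFit):
            v = v.ki
        if np.isfinite(v):
            vals.append(float(v))
    if not vals:
        raise ValueError("no finite replicate values to summarize")
    x = np.array(sorted(vals))
    if x.size == 1:
        v = float(x[0])
        return ReplicateSummary(1, v, float("nan"), v, v, v, v, v, [], v)
    q25, med, q75 = np.quantile(x, [0.25, 0.5, 0.75])  # linear interpolation
    iqr = q75 - q25
    in_whisker = x[(x >= q25 - 1.5 * iqr) & (x <= q75 + 1.5 * iqr)]
    outliers = x[(x < q25 - 1.5 * iqr) | (x > q75 + 1.5 * iqr)].tolist()
    return ReplicateSummary(
        n=int(x.size),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)),
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        whisker_low=float(in_whisker.min()),
        whisker_high=float(in_whisker.max()),
        outliers=outliers,
        geometric_mean=float(np.exp(np.log(x).mean())),
    )
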