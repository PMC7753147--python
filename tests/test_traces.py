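"""F_norm computation, per-well QC heuristics, and the area statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import trapezoid

from tricscreen import (
    QCThresholds,
    TricTrace,
    area_statistic,
    classify_screen,
    compute_fnorm,
    solve_binary,
)
from tricscreen.simulate import (
    ArtifactSpec,
    calibrated_area_scale,
    inject_artifact,
    noiseless_curve,
    simulate_screen_plate,
    simulate_trace,
)
from tricscreen.traces import AnalysisError, ScreenRecord, qc_plate, screen_records


def _flat_trace(value: float = 2.0, well: str = "A01") -> TricTrace:
    t = np.linspace(-1.0, 1.5, 251)
    return TricTrace(well, t, np.full_like(t, value))


class TestFnorm:
    def test_constant_trace_is_1000_permille(self):
        assert compute_fnorm(_flat_trace()).fnorm == pytest.approx(1000.0)

    def test_hot_plateau_ratio(self):
        t = np.linspace(-1.0, 1.5, 251)
        f = np.where(t <= 0, 1.0, 0.9)
        res = compute_fnorm(TricTrace("A01", t, f))
        assert res.fnorm == pytest.approx(900.0)
        assert res.f0 == pytest.approx(1.0)

    def test_window_means_match_closed_form(self, photo_noiseless, schedule):
        # pure-state traces: window mean of the mono-exponential, analytically
        t = schedule.times()
        f1_lo, f1_hi = 1.0, 1.4
        for amp, tau, fb in ((photo_noiseless.amp_free, photo_noiseless.tau_free, 0.0),
                             (photo_noiseless.amp_bound, photo_noiseless.tau_bound, 1.0)):
            tr = simulate_trace(fb, photo_noiseless, schedule)
            m = (t >= f1_lo) & (t <= f1_hi)
            # discrete mean of the analytic curve over the window samples
            expect = np.mean(1.0 + amp * (1.0 - np.exp(-t[m] / tau)))
            assert compute_fnorm(tr).fnorm == pytest.approx(1000.0 * expect, rel=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(scale=st.floats(1e-6, 1e6))
    def test_scale_invariance(self, scale):
        t = np.linspace(-1.0, 1.5, 251)
        f = 1.0 + 0.05 * np.sin(t)  # arbitrary positive trace
        base = compute_fnorm(TricTrace("A01", t, f)).fnorm
        scaled = compute_fnorm(TricTrace("A01", t, f * scale)).fnorm
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_empty_window_names_well(self):
        tr = _flat_trace(well="B07")
        with pytest.raises(AnalysisError, match="B07"):
            tr.window_mean((5.0, 6.0))


class TestQC:
    def _plate(self, photo, schedule, fb, n=16, seed=0):
        rng = np.random.default_rng(seed)
        return [
            simulate_trace(fb, photo, schedule, well_id=f"A{i + 1:02d}", rng=rng)
            for i in range(n)
        ]

    def test_clean_plate_has_no_flags(self, assay, photo, schedule):
        fb = solve_binary(assay).tracer_bound_fraction
        verdicts = qc_plate(self._plate(photo, schedule, fb))
        assert all(not v.flags for v in verdicts.values())

    @pytest.mark.parametrize(
        "kind,mag,flag",
        [
            ("autofluorescent", 0.5, "autofluorescent"),
            ("quenched", 0.3, "quenched"),
            ("aggregated", 0.1, "aggregated"),
            ("bubble", 0.2, "bubble_or_precipitate"),
        ],
    )
    def test_injected_artifact_detected(self, assay, photo, schedule, kind, mag, flag):
        fb = solve_binary(assay).tracer_bound_fraction
        traces = self._plate(photo, schedule, fb, seed=5)
        traces[3] = inject_artifact(traces[3], ArtifactSpec(kind, mag), seed=11)
        verdicts = qc_plate(traces)
        assert flag in verdicts["A04"].flags
        others = [w for w in verdicts if w != "A04"]
        assert all(not verdicts[w].flags for w in others)

    def test_verdicts_are_deterministic(self, assay, photo, schedule):
        fb = solve_binary(assay).tracer_bound_fraction
        traces = self._plate(photo, schedule, fb, seed=9)
        a = qc_plate(traces)
        b = qc_plate(traces)
        assert {w: v.flags for w, v in a.items()} == {w: v.flags for w, v in b.items()}

    def test_external_hardware_flags_pass_through(self, assay, photo, schedule):
        fb = solve_binary(assay).tracer_bound_fraction
        traces = self._plate(photo, schedule, fb)
        verdicts = qc_plate(
            traces, external_flags={"A02": {"bubble_or_precipitate"}}
        )
        assert "bubble_or_precipitate" in verdicts["A02"].flags

    def test_small_plate_rejected(self, assay, photo, schedule):
        fb = solve_binary(assay).tracer_bound_fraction
        with pytest.raises(AnalysisError):
            qc_plate(self._plate(photo, schedule, fb, n=4))


class TestAreaStatistic:
    def test_identical_test_and_control_area_zero(self, photo_noiseless, schedule):
        tr = [simulate_trace(0.5, photo_noiseless, schedule, well_id=w)
              for w in ("A01", "A02", "A03", "A04")]
        area, sd, n = area_statistic(tr[:2], tr[2:], scale=0.03)
        assert area == 0.0
        assert n == 2

    def test_full_displacement_matches_analytic_integral(
        self, assay, photo_noiseless, schedule
    ):
        fb0 = solve_binary(assay).tracer_bound_fraction
        ctrl = [simulate_trace(fb0, photo_noiseless, schedule, well_id=w)
                for w in ("A01", "A02")]
        disp = [simulate_trace(0.0, photo_noiseless, schedule, well_id="A03")]
        scale = calibrated_area_scale(assay, photo_noiseless, schedule)
        area, _, _ = area_statistic(disp, ctrl, scale=scale)
        # analytic: integral of the exponential-difference mixture over heating
        t = schedule.times()
        m = t >= 0
        diff = np.abs(noiseless_curve(0.0, photo_noiseless, t)
                      - noiseless_curve(fb0, photo_noiseless, t))
        expect = trapezoid(diff[m], t[m]) / scale
        assert area == pytest.approx(expect, rel=1e-10)
        assert area == pytest.approx(2.0, rel=1e-10)  # calibration convention

    def test_area_monotone_in_displacement(self, assay, photo_noiseless, schedule):
        fb0 = solve_binary(assay).tracer_bound_fraction
        ctrl = [simulate_trace(fb0, photo_noiseless, schedule, well_id=w)
                for w in ("A01", "A02")]
        scale = calibrated_area_scale(assay, photo_noiseless, schedule)
        areas = [
            area_statistic(
                [simulate_trace(fb, photo_noiseless, schedule, well_id="B01")],
                ctrl, scale=scale,
            )[0]
            for fb in np.linspace(fb0, 0.0, 9)
        ]
        assert areas[0] == 0.0
        assert np.all(np.diff(areas) > 0)

    def test_requires_two_controls(self, photo, schedule):
        a = simulate_trace(0.5, photo, schedule, well_id="A01")
        b = simulate_trace(0.5, photo, schedule, well_id="A02")
        with pytest.raises(AnalysisError):
            area_statistic([a], [b], scale=1.0)


class TestClassifyScreen:
    @staticmethod
    def _rec(pid, area, flags=frozenset(), evaluable=True):
        return ScreenRecord(pid, area, 0.01, 2, flags, evaluable)

    def test_strict_threshold_semantics(self):
        recs = classify_screen([self._rec("lo", 0.49), self._rec("hi", 0.51)])
        verdict = {r.peptide_id: r.is_binder for r in recs}
        assert verdict == {"hi": True, "lo": False}
        assert [r.peptide_id for r in recs] == ["hi", "lo"]  # sorted by area

    def test_unevaluable_never_binder(self):
        recs = classify_screen(
            [self._rec("bad", float("nan"), frozenset({"aggregated"}), evaluable=False)]
        )
        assert not recs[0].is_binder

    def test_flagged_wells_excluded_from_area(self, assay, photo, schedule):
        # binder whose first well is aggregated: area comes from the clean well
        conc = 100e-6
        traces, layout, truth = simulate_screen_plate(
            [("hit", 5e-6), ("dud", None)], assay, conc, photo, schedule,
            artifacts={"hit": ArtifactSpec("aggregated", 0.15)}, seed=21,
        )
        scale = calibrated_area_scale(assay, photo, schedule)
        recs = classify_screen(screen_records(traces, layout, scale=scale))
        by_id = {r.peptide_id: r for r in recs}
        assert "aggregated" in by_id["hit"].flags
        assert by_id["hit"].n_wells == 1  # one well excluded, one used
        assert by_id["hit"].is_binder
        assert not by_id["dud"].is_binder

    def test_all_wells_flagged_is_unevaluable(self, assay, photo, schedule):
        conc = 100e-6
        traces, layout, _ = simulate_screen_plate(
            [("hit", 5e-6)], assay, conc, photo, schedule, n_replicates=2, seed=3,
        )
        # flag both replicate wells
        flagged = []
        rng = np.random.default_rng(0)
        for tr in traces:
            if layout.set_index("well_id").loc[tr.well_id, "role"] == "test":
                tr = inject_artifact(tr, ArtifactSpec("aggregated", 0.2), rng=rng)
            flagged.append(tr)
        scale = calibrated_area_scale(assay, photo, schedule)
        recs = classify_screen(screen_records(flagged, layout, scale=scale))
        assert len(recs) == 1
        assert not recs[0].evaluable
        assert not recs[0].is_binder
        assert np.isnan(recs[0].area)
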