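"""Run configuration with schema validation.

Every tunable of the pipeline lives here with its default; YAML or JSON
files are validated strictly (unknown keys rejected) before any
computation.  Concentrations accept unit-tagged strings (``"1.54 nM"``) or
raw molar floats.  The default assay parameters describe the benchmark
tracer system (K_D 1.54 nM) at typical working concentrations; working
receptor/tracer concentrations are deliberately configuration, not
constants, since they vary per experiment.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from .binding import BinarySystem
from .simulate import TraceSchedule, TricPhotophysics
from .traces import QCThresholds
from .units import to_molar

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


Conc = "float | str"


class AssayConfig(_Strict):
    kd_tracer: float | str = "1.54 nM"
    tracer_total: float | str = "2 nM"
    receptor_total: float | str = "5 nM"

    def system(self) -> BinarySystem:
        return BinarySystem(
            receptor_total=to_molar(self.receptor_total),
            tracer_total=to_molar(self.tracer_total),
            kd_tracer=to_molar(self.kd_tracer),
        )


class PhotophysicsConfig(_Strict):
    f_init_bound: float = 1.0
    f_init_free: float = 1.0
    amp_bound: float = -0.12
    amp_free: float = -0.06
    tau_bound: float = 0.15
    tau_free: float = 0.12
    noise_cv: float = 0.005

    def photophysics(self) -> TricPhotophysics:
        return TricPhotophysics(**self.model_dump())


class ScheduleConfig(_Strict):
    t_start: float = -1.0
    t_end: float = 1.5
    sampling_rate: float = 100.0

    def schedule(self) -> TraceSchedule:
        return TraceSchedule(**self.model_dump())


class WindowsConfig(_Strict):
    f0: tuple[float, float] = (-0.8, 0.0)
    f1: tuple[float, float] = (1.0, 1.4)


class QCConfig(_Strict):
    auto_baseline: float = 0.25
    quench_baseline: float = 0.20
    agg_abs: float = 0.015
    agg_rel: float = 3.0
    shape_abs: float = 0.03
    shape_rel: float = 6.0
    step_abs: float = 0.03
    step_rel: float = 10.0
    smooth_window: int = 5

    def thresholds(self) -> QCThresholds:
        return QCThresholds(**self.model_dump())


class ScreenConfig(_Strict):
    concentration: float | str = "100 uM"
    n_replicates: int = 2
    controls_per_plate: int = 8
    area_threshold: float = 0.5
    area_scale: float | None = None  # None: calibrate from assay + photophysics


class SeriesConfig(_Strict):
    top: float | str = "400 uM"
    n_points: int = 12
    factor: float = 2.0
    n_replicates: int = 1


class FitConfig(_Strict):
    model: str = "competitive_exact"
    ki_mode: str = "exact"
    min_points: int = 8
    min_span_log10: float = 2.0
    outlier_threshold: float = 3.0
    max_exclusions: int = 2
    no_displacement_k: float = 5.0
    min_amplitude: float = 2.0


class ScanConfig(_Strict):
    probe_concentration: float | str = "50 nM"
    n_arrays: int = 3
    array_noise_cv: float = 0.05


class RunConfig(_Strict):
    assay: AssayConfig = AssayConfig()
    photophysics: PhotophysicsConfig = PhotophysicsConfig()
    schedule: ScheduleConfig = ScheduleConfig()
    windows: WindowsConfig = WindowsConfig()
    qc: QCConfig = QCConfig()
    screen: ScreenConfig = ScreenConfig()
    series: SeriesConfig = SeriesConfig()
    fit: FitConfig = FitConfig()
    scan: ScanConfig = ScanConfig()
    seed: int = 0


def load_config(path: "str | Path | None") -> RunConfig:
    """Load and validate a YAML/JSON run config; defaults if path is None."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return RunConfig.model_validate(data or {})
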