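import numpy as np
import pytest

from tricscreen import BinarySystem
from tricscreen.simulate import TraceSchedule, TricPhotophysics

#: Benchmark tracer system: receptor 5 nM, tracer 2 nM, tracer K_D 1.54 nM.
BENCH_RECEPTOR = 5e-9
BENCH_TRACER = 2e-9
BENCH_KD = 1.54e-9
BENCH_KI = 12.1e-6


@pytest.fixture(scope="session")
def assay() -> BinarySystem:
    return BinarySystem(BENCH_RECEPTOR, BENCH_TRACER, BENCH_KD)


@pytest.fixture(scope="session")
def photo() -> TricPhotophysics:
    return TricPhotophysics()


@pytest.fixture(scope="session")
def photo_noiseless() -> TricPhotophysics:
    return TricPhotophysics(noise_cv=0.0)


@pytest.fixture(scope="session")
def schedule() -> TraceSchedule:
    return TraceSchedule()


def random_system(rng: np.random.Generator):
    """One log-uniform random competitive system spanning 1 pM - 1 mM."""
    r0, a0, b0, ka, kb = 10.0 ** rng.uniform(-12, -3, 5)
    return BinarySystem(r0, a0, ka).with_competitor(b0, kb)
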