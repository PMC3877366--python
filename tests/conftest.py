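import pytest
from hypothesis import HealthCheck, settings

import tsokit as tk

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def arch_g3() -> tk.TSOArchitecture:
    """Fixed-window TSO: 10-base UMI, rGGG."""
    return tk.TSOArchitecture(umi_len=10, ribo_spec="GGG")


@pytest.fixture
def arch_n3() -> tk.TSOArchitecture:
    """Degenerate-window TSO: 10-base UMI, rNNN."""
    return tk.TSOArchitecture(umi_len=10, ribo_spec="NNN")


@pytest.fixture
def spike_config_n3(arch_n3) -> tk.SimulationConfig:
    """Error-free, duplication-free spike simulation with the rNNN TSO."""
    return tk.SimulationConfig(
        transcripts=tk.ercc_spike_transcripts(),
        architecture=arch_n3,
        seed=7,
        error_rate=0.0,
        duplication_mean=1.0,
    )


def delta(k: int) -> dict[int, float]:
    """Degenerate addition-length law concentrated at one k."""
    return {k: 1.0}


ALL_C = tuple({"A": 0.0, "C": 1.0, "G": 0.0, "T": 0.0} for _ in range(8))


@pytest.fixture
def allc_g3_config(arch_g3):
    """δ(k=3), all-C additions, fixed rGGG: every molecule switches with
    a junction G run of exactly 3."""
    return tk.SimulationConfig(
        transcripts=tk.ercc_spike_transcripts(),
        architecture=arch_g3,
        seed=11,
        addition_len_probs=delta(3),
        addition_base_probs=ALL_C,
        error_rate=0.0,
        duplication_mean=1.0,
    )
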