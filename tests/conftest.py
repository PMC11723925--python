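import numpy as np
import pytest

import morphodist as md


@pytest.fixture(scope="session")
def schema():
    return md.Schema.sibhudu()


@pytest.fixture(scope="session")
def small_assemblage():
    """Complete 4-phase synthetic assemblage, 25 flakes per phase."""
    cfg = md.SimulationConfig(n_per_group=25, seed=42)
    table, truth = md.simulate_assemblage(cfg)
    return table, truth


@pytest.fixture(scope="session")
def null_assemblage():
    """Two exchangeable groups, no phase signal, complete."""
    cfg = md.SimulationConfig.null(n_per_group=40, n_groups=2, seed=7)
    table, _ = md.simulate_assemblage(cfg)
    return table


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def write_csv(tmp_path, text, name="flakes.csv"):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return p
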