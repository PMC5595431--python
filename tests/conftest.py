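import numpy as np
import pytest

from istex import (
    AnchorSpec,
    DivergenceParams,
    SimConfig,
    TelomereClone,
    process_experiment,
    simulate_experiment,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_917)


def clones_of(exp):
    cfg = exp.config
    return [
        TelomereClone(c.clone_id, cfg.locus_id, cfg.genotype, c.seq)
        for c in exp.clones
    ]


def run_calls(cfg: SimConfig, params: DivergenceParams | None = None,
              mode: str = "consensus"):
    """Simulate and call one experiment; returns (calls df, experiment)."""
    exp = simulate_experiment(cfg)
    anchor = AnchorSpec(cfg.locus_id, cfg.anchor_seq)
    calls, _ = process_experiment(
        clones_of(exp), anchor, params, mode=mode,
        reference=exp.master if mode == "reference" else None,
    )
    return calls, exp
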