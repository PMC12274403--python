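import numpy as np
import pandas as pd
import pytest

from newrna import simulate

PC, PE = 0.02, 0.001


@pytest.fixture(scope="session")
def standard_reads():
    """Mixed-depth read fixture: one gene per (read count, true pi)."""
    specs = [
        (50, 0.05), (50, 0.4), (80, 0.9), (120, 0.2), (200, 0.6),
        (500, 0.1), (1000, 0.3), (2000, 0.75),
    ]
    frames = []
    for i, (reads, pi) in enumerate(specs):
        cfg = simulate.SimulationConfig(
            n_genes=1,
            reads_per_gene=reads,
            p_c=PC,
            p_e=PE,
            pi_per_gene=pi,
            n_length_dist=(20, 200),
            sample_id="fix",
            seed=1000 + i,
        )
        df = simulate.simulate_reads(cfg)
        df["gene_id"] = f"gene{i}"
        df["true_pi"] = pi
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
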