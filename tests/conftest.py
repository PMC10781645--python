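import numpy as np
import pytest

from ultraseq.oscillation import oscillation_score
from ultraseq.sequences import identify_sequences
from ultraseq.simulate import SimConfig, generate_session
from ultraseq.sorting import oscillation_phase


@pytest.fixture(scope="session")
def clean_run():
    """A clean mid-size oscillatory session analyzed once, shared broadly.

    150 cells, 20 min, 120-s period, moderate gaps; the fixture carries
    the session, its ground truth, the oscillation estimate, the
    identified sequences and the T_osc-smoothed phase trace.
    """
    cfg = SimConfig(n_cells=150, duration=1200.0, period=120.0,
                    gap_prob=0.25, rng_seed=3)
    session, truth = generate_session(cfg)
    est = oscillation_score(session.events)
    seqs = identify_sequences(session.events, est.t_osc)
    phase = oscillation_phase(session.events, smoothing_width=est.t_osc)
    return {"cfg": cfg, "session": session, "truth": truth,
            "estimate": est, "seqs": seqs, "phase": phase}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
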