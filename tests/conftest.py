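import numpy as np
import pandas as pd
import pytest

from sexsplice.io import JunctionCounts


def make_events(n, event_type="SE", genes=None):
    """Minimal valid event table for n events."""
    idx = pd.Index([f"e{i}" for i in range(n)], name="event_id")
    if genes is None:
        genes = [f"g{i // 2}" for i in range(n)]
    types = [event_type] * n if isinstance(event_type, str) else list(event_type)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "event_type": types,
            "chrom": "chr1",
            "strand": "+",
            "coords": [f"{100 + 10 * i}-{105 + 10 * i}" for i in range(n)],
        },
        index=idx,
    )


def make_counts(ijc, sjc, samples):
    """JunctionCounts from 2-D arrays (events × samples)."""
    ijc = np.atleast_2d(np.asarray(ijc))
    sjc = np.atleast_2d(np.asarray(sjc))
    idx = pd.Index([f"e{i}" for i in range(ijc.shape[0])], name="event_id")
    return JunctionCounts(
        pd.DataFrame(ijc, index=idx, columns=samples),
        pd.DataFrame(sjc, index=idx, columns=samples),
    )


@pytest.fixture
def splicing_panel():
    """A small turkey-like simulated panel with a planted effect."""
    from sexsplice.simulate import simulate_splicing

    events, counts, meta, truth = simulate_splicing(
        n_events=400, coverage_mean=150.0, frac_biased=0.2, delta=0.4,
        lambda_mix=0.5, rho=0.02, seed=101)
    return events, counts, meta, truth


@pytest.fixture
def sexes_5v5():
    males = [f"dom{i}" for i in range(1, 6)]
    females = [f"fem{i}" for i in range(1, 6)]
    return males, females
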