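import numpy as np
import pandas as pd
import pytest

from mirsplice import presets, simulate


@pytest.fixture(scope="session")
def study_bundle():
    """One study-scale synthetic bundle, shared across read-only tests."""
    return simulate.simulate_bundle(presets.study_config(seed=11))


@pytest.fixture(scope="session")
def study_config():
    return presets.study_config(seed=11)


def random_event_table(rng: np.random.Generator, genes, n_events: int) -> pd.DataFrame:
    """Small random event table used by overlap/matching oracle tests."""
    from mirsplice.simulate import EVENT_TYPES

    rows = []
    for _ in range(n_events):
        start = int(rng.integers(1_000, 1_000_000))
        n = int(rng.integers(2, 5))
        ijc = rng.integers(0, 50, size=n)
        sjc = rng.integers(0, 50, size=n)
        rows.append(
            dict(
                gene=str(rng.choice(genes)),
                event_type=str(rng.choice(EVENT_TYPES)),
                chrom=f"chr{int(rng.integers(1, 5))}",
                strand=str(rng.choice(["+", "-"])),
                c1=start, c2=start + 100, c3=start + 200, c4=start + 300,
                ijc=",".join(map(str, ijc)), sjc=",".join(map(str, sjc)),
                inc_len=200, skip_len=100,
                psi_g1=float(rng.uniform(0, 1)), psi_g2=float(rng.uniform(0, 1)),
                delta_psi=float(rng.uniform(-1, 1)),
                pvalue=float(rng.uniform(0, 1)),
            )
        )
    return pd.DataFrame(rows)
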