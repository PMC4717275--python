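import numpy as np
import pandas as pd
import pytest

from cnvsurv.core import MarkerMap
from cnvsurv.synthetic_data import simulate_marker_map


def make_map(positions, chrom="1", pfb=0.5, gc=0.5):
    """Hand-built marker map with explicit positions (single chromosome)."""
    positions = list(positions)
    n = len(positions)
    return MarkerMap.from_arrays(
        marker_id=[f"m{chrom}_{i}" for i in range(n)],
        chrom=[chrom] * n,
        pos=positions,
        pfb=np.full(n, pfb) if np.isscalar(pfb) else np.asarray(pfb),
        gc=np.full(n, gc) if np.isscalar(gc) else np.asarray(gc),
    )


@pytest.fixture(scope="session")
def small_map():
    return simulate_marker_map(400, {"1": 4_000_000}, 2100, seed=11)


@pytest.fixture(scope="session")
def two_chrom_map():
    return simulate_marker_map(400, {"1": 2_000_000, "2": 2_000_000}, 2100, seed=12)


def exponential_cohort(rng, n, beta_x=0.0, censor_scale=3.0, binary=True):
    """Tie-free right-censored exponential survival data, no truncation."""
    x = rng.integers(0, 2, n).astype(float) if binary else rng.normal(size=n)
    dur = rng.exponential(1.0 / np.exp(beta_x * x))
    cens = rng.exponential(censor_scale, n)
    return pd.DataFrame({
        "entry_age": -1e-9,  # entry strictly below every exit
        "exit_age": np.minimum(dur, cens),
        "event": (dur <= cens).astype(int),
        "x": x,
    })
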