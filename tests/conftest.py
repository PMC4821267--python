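import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sharksize.measurements import collapse_repeats, filter_by_precision
from sharksize.simulate import SyntheticConfig, make_dataset

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def paired_table(seed: int = 1, **overrides) -> pd.DataFrame:
    """Run the generator + QC preprocessing into a paired analysis table."""
    cfg = SyntheticConfig(seed=seed, **overrides)
    records, _ = make_dataset(cfg)
    kept, _ = filter_by_precision(records)
    pairs, _ = collapse_repeats([r for r in kept if r.stereo_m is not None])
    return pairs


@pytest.fixture(scope="session")
def default_pairs() -> pd.DataFrame:
    """Survey-scale paired table (95 individuals / 123 sightings, seed 1)."""
    return paired_table(seed=1)


def small_lmm_dataset(seed: int, n_ind: int, reps: int) -> pd.DataFrame:
    """A small grouped dataset (n_ind*reps rows) for mixed-model oracles."""
    rng = np.random.default_rng(seed)
    ind = np.repeat(np.arange(n_ind), reps)
    tln = rng.uniform(3.5, 11.0, size=n_ind)[ind]
    b = rng.normal(0.0, 0.55, size=n_ind)[ind]
    y = -1.6 + 0.45 * tln + b + rng.normal(0.0, 0.6, size=ind.size)
    return pd.DataFrame(
        {
            "diff_m": y,
            "tln_m": tln,
            "time_of_day": rng.uniform(10, 16, size=ind.size),
            "individual_id": [f"I{i}" for i in ind],
        }
    )


@pytest.fixture(scope="session")
def small_lmm_datasets() -> list[pd.DataFrame]:
    """The bundled <= 30-row datasets used for oracle-equivalence checks."""
    return [
        small_lmm_dataset(11, 4, 3),   # 12 rows, 4 individuals
        small_lmm_dataset(12, 6, 4),   # 24 rows, balanced
        small_lmm_dataset(13, 10, 3),  # 30 rows
        small_lmm_dataset(14, 5, 2),   # 10 rows, minimal replication
    ]


@pytest.fixture()
def fixture_dir(tmp_path):
    from sharksize.simulate import make_fixture

    make_fixture(tmp_path, seed=2024)
    return tmp_path
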