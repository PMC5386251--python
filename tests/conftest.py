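import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from varzea.core import build_community_table, SiteMetadata
from varzea.simulate import MetacommunityConfig, generate_dataset

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_table():
    """Three sites, two biomes, hand-enumerable species sets."""
    rows = [
        ("s1", "Aa bb", 4), ("s1", "Aa cc", 1), ("s1", "Dd ee", 2),
        ("s2", "Aa bb", 3), ("s2", "Ff gg", 5),
        ("s3", "Dd ee", 1), ("s3", "Ff gg", 2), ("s3", "Hh ii", 7),
    ]
    return build_community_table(pd.DataFrame(rows))


@pytest.fixture
def toy_metadata():
    return SiteMetadata(
        df=pd.DataFrame(
            {
                "site_id": ["s1", "s2", "s3"],
                "biome": ["Amazon", "Amazon", "Cerrado"],
                "mat": [26.0, 27.0, 23.0],
                "map_mm": [2400.0, 2600.0, 1300.0],
            }
        )
    )


def small_config(seed: int, **overrides) -> MetacommunityConfig:
    """A scaled-down metacommunity: 3 biomes, modest pools and site sizes."""
    defaults = dict(
        biomes=("Amazon", "Cerrado", "Pampas"),
        pool_sizes={"Amazon": 400, "Cerrado": 300, "Pampas": 150},
        pairwise_overlap={
            ("Amazon", "Cerrado"): 0.15,
            ("Amazon", "Pampas"): 0.05,
            ("Cerrado", "Pampas"): 0.10,
        },
        site_counts={"Amazon": 12, "Cerrado": 10, "Pampas": 8},
        stems_per_site={
            "Amazon": (600.0, 200.0), "Cerrado": (500.0, 150.0), "Pampas": (400.0, 120.0),
        },
    )
    defaults.update(overrides)
    return MetacommunityConfig(**defaults, seed=seed)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_config(seed=42))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)
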