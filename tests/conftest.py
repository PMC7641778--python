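import datetime as dt
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from searchsurge.data_model import AnalysisWindow, CovariateTable, QuerySeries
from searchsurge.synthetic import SyntheticConfig, generate_panel

REPO_ROOT = Path(__file__).resolve().parents[1]


def make_series(geography="US", topic="reform", start=dt.date(2020, 1, 1), values=(1.0, 2.0, 3.0)):
    dates = [start + dt.timedelta(days=i) for i in range(len(values))]
    return QuerySeries(geography, topic, dates, np.asarray(values, float))


@pytest.fixture
def simple_series():
    return make_series()


@pytest.fixture
def paper_window():
    return AnalysisWindow(dt.date(2010, 1, 1), dt.date(2020, 5, 25), dt.date(2020, 7, 5))


@pytest.fixture(scope="session")
def small_config():
    """Small synthetic panel config used across modules (fast to generate)."""
    return SyntheticConfig(
        n_geographies=10,
        start=dt.date(2019, 6, 1),
        end=dt.date(2020, 7, 5),
        event_date=dt.date(2020, 5, 25),
        ar_coeffs=(0.5,),
        innovation_sd=0.4,
        mean_level=8.0,
        geo_level_sigma=0.3,
        effect_multiplier=37.7,
        decay_halflife=10.0,
        floor_multiplier=5.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return generate_panel(small_config)


@pytest.fixture
def covariates():
    return CovariateTable(
        pd.DataFrame(
            {
                "geography": ["AA", "BB", "CC", "DD"],
                "vote_share_trump": [0.3, 0.45, 0.55, 0.7],
                "winner": ["Clinton", "Clinton", "Trump", "Trump"],
            }
        )
    )


@pytest.fixture
def demo_config_path():
    return REPO_ROOT / "examples" / "demo.yaml"
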