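import warnings

import numpy as np
import pandas as pd
import pytest

from finsong import AnalysisConfig, NoteEvent
from finsong.synthetic_data import BehaviorParams, generate_cohort

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture
def cfg() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture
def regular_notes():
    """Three notes at 12 s spacing: the minimal qualifying song."""
    return [NoteEvent("a", 0.0, 1.0), NoteEvent("a", 12.0, 1.0), NoteEvent("a", 24.0, 1.0)]


def make_notes(starts, duration=1.0, singer="a"):
    return [NoteEvent(singer, float(s), duration) for s in starts]


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-track synthetic cohort shared across tests (generation is cheap,
    the pipeline GAMs are not — keep one instance per session)."""
    return generate_cohort(n_tracks=30, seed=11)


@pytest.fixture(scope="session")
def cohort_result(small_cohort):
    from finsong import run_pipeline

    return run_pipeline(
        small_cohort.notes, small_cohort.locations, AnalysisConfig(), fit_models=False
    )


@pytest.fixture
def notes_csv(tmp_path):
    path = tmp_path / "notes.csv"
    pd.DataFrame(
        {
            "singer_id": ["a", "a", "b"],
            "start_epoch_s": [0.0, 12.0, 5.0],
            "duration_s": [1.0, 1.0, 1.0],
        }
    ).to_csv(path, index=False)
    return path


@pytest.fixture
def locations_csv(tmp_path):
    path = tmp_path / "locations.csv"
    pd.DataFrame(
        {
            "singer_id": ["a", "a", "a"],
            "time_epoch_s": [0.0, 3600.0, 7200.0],
            "lat": [55.0, 55.1, 55.2],
            "lon": [-30.0, -30.0, -30.0],
        }
    ).to_csv(path, index=False)
    return path
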