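import pandas as pd
import pytest

from actispoof import features, oracle, simulate


def make_recording(user_id: str, counts_by_day: dict, minute_step: int = 1):
    """Build a UserRecording from {date_str: {minute_of_day: count}} dicts."""
    rows = []
    for date, minutes in counts_by_day.items():
        base = pd.Timestamp(date)
        for minute, count in sorted(minutes.items()):
            ts = base + pd.Timedelta(minutes=minute)
            rows.append((ts, ts.date(), count))
    df = pd.DataFrame(rows, columns=["timestamp", "date", "activity"])
    return features.UserRecording(user_id=user_id, samples=df)


def constant_day(value: int) -> dict:
    return {m: value for m in range(0, 1440)}


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-user, 8-day synthetic cohort with its ground-truth templates."""
    config = simulate.CohortConfig(n_users=6, days_per_user=8, seed=11)
    recordings, templates = simulate.generate_cohort(config)
    return config, recordings, templates


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    """Normalized labeled feature rows from the small cohort."""
    _, recordings, _ = small_cohort
    profiles = []
    for rec in recordings:
        profiles.extend(features.extract_daily_profiles(rec))
    matrix = features.normalize(profiles)
    return oracle.LabeledDataset.from_feature_matrix(matrix)


@pytest.fixture(scope="session")
def small_rf(small_dataset):
    """A 500-tree random forest fitted on a split of the small cohort."""
    train, test = oracle.split_per_user(small_dataset, 0.5, seed=5)
    model = oracle.train_model(oracle.ModelSpec("random_forest"), train, seed=5)
    return model, train, test
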