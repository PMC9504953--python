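import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from bedposture import (
    DEFAULT_GEOMETRY, OccupantProfile, PostureSchedule,
    extract_features, random_schedule, sample_cohort, simulate_recording,
)
from bedposture.evaluation import PostureExperiment

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def geometry():
    return DEFAULT_GEOMETRY


def build_cohort_data(profiles, duration_s, master_seed):
    """Simulate a cohort and assemble the combined labelled feature table."""
    ss = np.random.SeedSequence(master_seed).generate_state(len(profiles)) % (2 ** 31)
    tables, labels = {}, {}
    for i, profile in enumerate(profiles):
        rng = np.random.default_rng(int(ss[i]))
        schedule = random_schedule(duration_s, rng)
        rec, truth = simulate_recording(profile, schedule, seed=int(ss[i]))
        tables[f"P{i + 1}"] = extract_features(rec)
        labels[f"P{i + 1}"] = truth["posture"].to_numpy()
    exp = PostureExperiment.from_tables(tables, labels, models=("LGB",))
    return exp.data


@pytest.fixture(scope="session")
def cohort_data():
    """Nine simulated subjects, 30 min each, with genuine between-subject shift."""
    return build_cohort_data(sample_cohort(9, seed=7), duration_s=1800.0, master_seed=7)


def _jittered_profile(rng):
    base = OccupantProfile()
    off = {p: (x + rng.uniform(-0.01, 0.01), y + rng.uniform(-0.01, 0.01))
           for p, (x, y) in base.static_com_offset.items()}
    ang = {p: float(np.clip(a + rng.uniform(-3, 3), 0, 90))
           for p, a in base.resp_axis_angle.items()}
    return OccupantProfile(body_weight=rng.uniform(600, 800),
                           static_com_offset=off, resp_axis_angle=ang,
                           noise_sd=0.4)


@pytest.fixture(scope="session")
def separable_data():
    """Four subjects with nearly identical, well-separated posture signatures."""
    rng = np.random.default_rng(21)
    profiles = [_jittered_profile(rng) for _ in range(4)]
    return build_cohort_data(profiles, duration_s=600.0, master_seed=21)


@pytest.fixture()
def short_recording(geometry):
    """A noiseless 2-minute supine recording for deterministic feature checks."""
    profile = OccupantProfile(noise_sd=0.0, cardiac_amp=0.0)
    schedule = PostureSchedule((("SUPINE", 120.0),))
    rec, truth = simulate_recording(profile, schedule, geometry, seed=3)
    return rec, truth
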