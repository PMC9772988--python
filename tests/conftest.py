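import numpy as np
import pandas as pd
import pytest

from cgmrisk import (
    GeneratorConfig,
    CGMRecord,
    annotate_cohort,
    generate_cohort,
    generate_traces,
    range_metrics_table,
)


def make_record(values, subject_id="T001", start="2024-01-06", step_min=5):
    """Record with evenly spaced timestamps from local midnight of `start`."""
    values = np.asarray(values, dtype=float)
    t0 = np.datetime64(start, "ns")
    step = np.timedelta64(step_min * 60 * 1_000_000_000, "ns")
    times = t0 + np.arange(values.size) * step
    return CGMRecord(subject_id=subject_id, times=times, glucose=values)


@pytest.fixture(scope="session")
def small_config():
    # desk-scale fixture cohort: 60 subjects, 6 progressors, fixed seed
    return GeneratorConfig(n_subjects=60, n_progressors=6, seed=0)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_records(small_config, small_cohort):
    return generate_traces(small_cohort, small_config, seed=1)


@pytest.fixture(scope="session")
def small_merged(small_cohort, small_records):
    metrics = range_metrics_table(small_records)
    merged = small_cohort.merge(metrics[metrics["eligible"]], on="subject_id")
    return annotate_cohort(merged)
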