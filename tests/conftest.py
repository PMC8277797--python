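"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from phenospace import (
    CohortConfig,
    ExpressionMatrix,
    SpatialConfig,
    arcsinh_transform,
    filter_events,
    generate_cytof_cohort,
    generate_spatial_cohort,
    two_round_phenotype,
)


def make_expression(values: np.ndarray, markers: list[str],
                    sample_id=None, length=None, scale="arcsinh") -> ExpressionMatrix:
    """Hand-build a small ExpressionMatrix for unit tests."""
    n = len(values)
    return ExpressionMatrix(
        values=pd.DataFrame(values, columns=markers),
        sample_id=pd.Series(sample_id if sample_id is not None else ["s1"] * n),
        event_length=pd.Series(length if length is not None else [30.0] * n),
        scale_state=scale,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default two-group cohort (raw scale) with its ground truth."""
    return generate_cytof_cohort(CohortConfig(seed=11, n_events_per_sample=2000))


@pytest.fixture(scope="session")
def phenotyped_cohort(default_cohort):
    """QC'd, transformed, two-round-phenotyped version of the default cohort,
    plus the truth restricted to the retained events."""
    data, truth = default_cohort
    filtered, _ = filter_events(data)
    transformed = arcsinh_transform(filtered)
    result = two_round_phenotype(transformed, seed=11)
    keep = (
        (data.values["HistoneH3"] >= 10).to_numpy()
        & data.event_length.between(10, 70).to_numpy()
    )
    truth_kept = truth.events.loc[keep].reset_index(drop=True)
    return transformed, result, truth_kept, truth


@pytest.fixture(scope="session")
def spatial_cohort():
    """One default spatial cohort with per-sample truth."""
    return generate_spatial_cohort(SpatialConfig(seed=7))
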