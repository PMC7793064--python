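"""Shared fixtures: small synthetic cohorts reused across module tests."""

import numpy as np
import pytest

from cytorelapse import pipeline, synthetic
from cytorelapse.profiles import PercentileMatrix


@pytest.fixture(scope="session")
def small_cohort():
    """A 16-patient planted-effect cohort at reduced event counts."""
    return synthetic.generate_cohort(n_patients=16, prevalence=0.25,
                                     events_per_tube=800, seed=42)


@pytest.fixture(scope="session")
def small_pms(small_cohort):
    """Percentile matrices for the small cohort via the direct path."""
    return pipeline.direct_percentiles(small_cohort, subsample_n=500)


@pytest.fixture(scope="session")
def planted_pms_full():
    """Percentile matrices of a study-sized planted-effect cohort."""
    cohort = synthetic.generate_cohort(n_patients=56, prevalence=13 / 56,
                                       events_per_tube=5000, seed=1)
    return pipeline.direct_percentiles(cohort, subsample_n=3000)


def make_pms(rng, n_r=5, n_n=9, markers=("CD38", "CD19", "CD10"), p=5,
             mu_r=0.4, mu_n=0.6, spread=0.05):
    """Hand-built percentile matrices: class-shifted, sorted rows."""
    grid = tuple(np.linspace(10, 90, p))
    out = []
    for i in range(n_r + n_n):
        label = "R" if i < n_r else "N"
        mu = mu_r if label == "R" else mu_n
        vals = np.sort(np.clip(mu + spread * rng.standard_normal((len(markers), p)),
                               0, 1), axis=1)
        out.append(PercentileMatrix(values=vals, markers=list(markers), grid=grid,
                                    patient_id=f"X{i:02d}", label=label))
    return out
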