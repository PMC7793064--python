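"""Clinical/genetic association stage: correlations and group contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, ttest_ind

from cytorelapse import pipeline, synthetic
from cytorelapse.associate import (CorrelationReport, correlate,
                                   encode_covariates, group_difference,
                                   read_clinical)
from cytorelapse.profiles import PercentileMatrix


def toy_clinical(n=6):
    return pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(n)],
        "label": ["R", "R", "N", "N", "N", "N"][:n],
        "age_years": [2.0, 4.0, 3.0, 6.0, 1.5, 8.0][:n],
        "sex": ["F", "M", "F", "M", "M", "F"][:n],
        "blast_pct": [80.0, 90.0, 70.0, 85.0, 60.0, 95.0][:n],
        "karyotype": ["hyperdiploid", "normal", None, "normal",
                      "hyperdiploid", "hypodiploid"][:n],
        "t_12_21": [1, 0, 0, 1, 0, 0][:n],
        "t_1_19": [0] * n,
        "t_4_11": [0] * n,
        "mll_rearrangement": [0, 1, 0, 0, 0, 0][:n],
        "t_9_22": [0] * n,
        "time_to_relapse_months": [12.0, 30.0, np.nan, np.nan, np.nan, np.nan][:n],
    })


def toy_pms(values_by_patient, marker="CD38"):
    grid = (15.0, 50.0, 85.0)
    return [PercentileMatrix(values=np.array([v]), markers=[marker], grid=grid,
                             patient_id=pid, label=None)
            for pid, v in values_by_patient.items()]


def test_pearson_matches_brute_force_on_toy_table():
    clin = toy_clinical()
    vals = {f"P{i}": [0.1 * i, 0.2 + 0.1 * i, 0.4 + 0.1 * i] for i in range(6)}
    report = correlate(clin, toy_pms(vals), levels=(15, 50, 85))
    a = clin["age_years"].to_numpy()
    b = np.array([vals[f"P{i}"][1] for i in range(6)])
    r_manual = (np.sum((a - a.mean()) * (b - b.mean()))
                / np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2)))
    assert report.r.loc["age_years", "CD38_P50"] == pytest.approx(r_manual)
    t = r_manual * np.sqrt(4 / (1 - r_manual**2))
    from scipy.stats import t as tdist
    p_manual = 2 * tdist.sf(abs(t), 4)
    assert report.p.loc["age_years", "CD38_P50"] == pytest.approx(p_manual)


def test_duplicated_covariate_has_unit_correlation():
    clin = toy_clinical()
    vals = {f"P{i}": sorted(np.random.default_rng(i).uniform(size=3))
            for i in range(6)}
    clin["blast_pct"] = clin["age_years"] * 10      # exact duplicate up to scale
    report = correlate(clin, toy_pms(vals))
    assert report.r.loc["age_years", "blast_pct"] == pytest.approx(1.0)
    assert report.p.loc["age_years", "blast_pct"] < 1e-6


def test_constant_variable_marked_missing():
    clin = toy_clinical()
    vals = {f"P{i}": sorted(np.random.default_rng(i).uniform(size=3))
            for i in range(6)}
    report = correlate(clin, toy_pms(vals))
    assert np.isnan(report.r.loc["t_9_22", "CD38_P50"])     # all zeros


def test_display_matrix_mixes_r_and_p():
    clin = toy_clinical()
    vals = {f"P{i}": sorted(np.random.default_rng(i).uniform(size=3))
            for i in range(6)}
    report = correlate(clin, toy_pms(vals))
    disp = report.display_matrix()
    iu, il = np.triu_indices(len(report.variables), 1), np.tril_indices(len(report.variables), -1)
    np.testing.assert_array_equal(np.nan_to_num(disp.values[iu], nan=-9),
                                  np.nan_to_num(report.p.values[iu], nan=-9))
    np.testing.assert_array_equal(np.nan_to_num(disp.values[il], nan=-9),
                                  np.nan_to_num(report.r.values[il], nan=-9))


def test_complete_case_deletion_is_local():
    """Blanking one patient's karyotype changes only karyotype correlations."""
    clin = toy_clinical()
    vals = {f"P{i}": sorted(np.random.default_rng(i).uniform(size=3))
            for i in range(6)}
    full = correlate(clin, toy_pms(vals))
    clin2 = clin.copy()
    clin2.loc[0, "karyotype"] = None
    partial = correlate(clin2, toy_pms(vals))
    kary_cols = {"hyperdiploid", "normal", "hypodiploid"}
    for a in full.variables:
        for b in full.variables:
            if {a, b} & kary_cols:
                continue
            va, vb = full.r.loc[a, b], partial.r.loc[a, b]
            assert (np.isnan(va) and np.isnan(vb)) or va == vb


def test_report_file_round_trip(tmp_path):
    clin = toy_clinical()
    vals = {f"P{i}": sorted(np.random.default_rng(i).uniform(size=3))
            for i in range(6)}
    report = correlate(clin, toy_pms(vals))
    report.to_files(tmp_path / "assoc")
    back = CorrelationReport.from_json(tmp_path / "assoc.json")
    pd.testing.assert_frame_equal(back.r, report.r)
    pd.testing.assert_frame_equal(back.p, report.p)


def test_planted_inverse_cd38_hyperdiploidy_link_recovered():
    """The generator's hyperdiploid indicator is negatively coupled to CD38
    expression; the sign of r(P85, hyperdiploid) recovers it in most seeds."""
    negative = 0
    n_seeds = 10
    for seed in range(n_seeds):
        cohort = synthetic.generate_cohort(n_patients=40, events_per_tube=1500,
                                           seed=300 + seed)
        pms = pipeline.direct_percentiles(cohort, subsample_n=900)
        report = correlate(cohort.clinical, pms, marker="CD38", levels=(15, 50, 85))
        negative += report.r.loc["CD38_P85", "hyperdiploid"] < 0
    assert negative >= 9


def test_group_difference_null_p_values_uniform():
    rng = np.random.default_rng(0)
    pvals = []
    for _ in range(1000):
        values = rng.standard_normal(30)
        groups = np.array(["F"] * 15 + ["M"] * 15)
        pvals.append(group_difference(values, groups)["p"])
    assert kstest(pvals, "uniform").statistic < 0.05


def test_group_difference_power_for_one_sd_effect():
    rng = np.random.default_rng(1)
    detected = 0
    for _ in range(200):
        female = rng.standard_normal(24) + 1.0
        male = rng.standard_normal(32)
        out = group_difference(np.concatenate([female, male]),
                               np.array(["F"] * 24 + ["M"] * 32))
        detected += out["p"] < 0.05
    assert detected / 200 > 0.8


def test_single_patient_group_errors_without_fallback():
    values = np.array([0.1, 0.5, 0.6, 0.7])
    groups = np.array(["F", "M", "M", "M"])
    with pytest.raises(ValueError, match="single-patient"):
        group_difference(values, groups)


def test_encode_covariates_binary_codes():
    enc = encode_covariates(toy_clinical())
    assert enc.loc["P0", "relapse"] == 1.0 and enc.loc["P2", "relapse"] == 0.0
    assert enc.loc["P1", "male"] == 1.0 and enc.loc["P0", "male"] == 0.0
    assert enc.loc["P0", "hyperdiploid"] == 1.0
    assert np.isnan(enc.loc["P2", "hyperdiploid"])   # missing karyotype
    assert np.isnan(enc.loc["P2", "time_to_relapse_months"])


def test_read_clinical_validates_schema(tmp_path):
    toy_clinical().to_csv(tmp_path / "clin.csv", index=False)
    df = read_clinical(tmp_path / "clin.csv")
    assert df.shape[0] == 6
    bad = toy_clinical()
    bad["karyotype"] = "tetraploid"
    bad.to_csv(tmp_path / "bad.csv", index=False)
    with pytest.raises(ValueError, match="karyotype"):
        read_clinical(tmp_path / "bad.csv")
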