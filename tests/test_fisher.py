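"""Fisher's-Ratio matrix, control points and the probability classifier."""

import numpy as np
import pytest

from conftest import make_pms
from cytorelapse.fisher import (FisherModel, classify, control_points,
                                fisher_matrix, patient_point)
from cytorelapse.profiles import PercentileMatrix


def brute_force_fr(train, location="median"):
    """Element-wise re-derivation of the FR matrix with explicit loops."""
    m, p = train[0].values.shape
    r = [pm.values for pm in train if pm.label == "R"]
    n = [pm.values for pm in train if pm.label == "N"]
    fr = np.empty((m, p))
    stats = {}
    for j in range(m):
        for k in range(p):
            rv = [x[j, k] for x in r]
            nv = [x[j, k] for x in n]
            loc = np.median if location == "median" else np.mean
            mu_r, mu_n = loc(rv), loc(nv)
            s_r = np.sqrt(sum((v - np.mean(rv)) ** 2 for v in rv) / (len(rv) - 1))
            s_n = np.sqrt(sum((v - np.mean(nv)) ** 2 for v in nv) / (len(nv) - 1))
            fr[j, k] = (mu_r - mu_n) ** 2 / (s_r**2 + s_n**2)
            stats[(j, k)] = (mu_r, mu_n, s_r, s_n)
    return fr, stats


def test_direct_substitution_examples():
    # mu_R=1, mu_N=0, sigma_R=sigma_N=1 -> FR = 0.5
    assert (1 - 0) ** 2 / (1 + 1) == 0.5
    model = _toy_model(mu_r=2.0, sigma_r=2.0, mu_n=0.0, sigma_n=5.0)
    (rbar, nbar), = control_points(model).values()
    assert rbar == 1.0                # mu_R/sigma_R = 2/2
    assert nbar == 0.0                # mu_N = 0 regardless of sigma_N
    assert patient_point(0.7, _toy_model(sigma_r=1, sigma_n=1), (0, 0)) == 0.7
    assert patient_point(2.0, _toy_model(sigma_r=1, sigma_n=3), (0, 0)) == 1.0


def _toy_model(mu_r=1.0, mu_n=0.0, sigma_r=1.0, sigma_n=1.0):
    shape = (1, 1)
    return FisherModel(fr=np.full(shape, 1.0), markers=["m"], grid=(50.0,),
                       mu_r=np.full(shape, float(mu_r)),
                       mu_n=np.full(shape, float(mu_n)),
                       sigma_r=np.full(shape, float(sigma_r)),
                       sigma_n=np.full(shape, float(sigma_n)),
                       selected=[(0, 0)], threshold=0.5)


def test_identical_classes_give_zero_fr():
    # dyadic values keep the within-class std at exactly zero in float
    base = np.tile(np.array([0.125, 0.25, 0.375, 0.5, 0.625]), (3, 1))
    pms = [PercentileMatrix(values=base.copy(), markers=["a", "b", "c"],
                            grid=(10., 30., 50., 70., 90.),
                            patient_id=f"P{i}", label=("R" if i % 2 else "N"))
           for i in range(6)]
    # identical values in both classes: numerator 0 but denominator 0 too
    with pytest.raises(ValueError, match="zero within-class variance"):
        fisher_matrix(pms)
    # distinct patients, same class distributions -> FR exactly 0 where medians agree
    for i, pm in enumerate(pms):
        pm.values = base + (i // 2) * 0.01
    model = fisher_matrix(pms, threshold=1e9)
    np.testing.assert_allclose(model.fr, 0.0, atol=1e-20)


def test_fisher_matrix_matches_brute_force():
    rng = np.random.default_rng(1)
    for _ in range(20):
        pms = make_pms(rng, n_r=3, n_n=3)
        model = fisher_matrix(pms, threshold=0.5)
        fr, stats = brute_force_fr(pms)
        np.testing.assert_allclose(model.fr, fr, rtol=1e-12)
        for (j, k), (mu_r, mu_n, s_r, s_n) in stats.items():
            assert model.mu_r[j, k] == pytest.approx(mu_r)
            assert model.sigma_n[j, k] == pytest.approx(s_n)


def test_selection_threshold_and_fallback():
    rng = np.random.default_rng(2)
    pms = make_pms(rng, mu_r=0.2, mu_n=0.8, spread=0.02)   # huge separation
    model = fisher_matrix(pms)
    assert model.selected == [tuple(jk) for jk in
                              np.argwhere(np.nan_to_num(model.fr, nan=-1) > 0.5)]
    # impossible threshold: single top-1 fallback feature
    model2 = fisher_matrix(pms, threshold=1e12)
    assert len(model2.selected) == 1
    j, k = model2.selected[0]
    assert model2.fr[j, k] == np.nanmax(model2.fr)


def test_single_class_rejected():
    rng = np.random.default_rng(3)
    pms = make_pms(rng, n_r=0, n_n=6)
    with pytest.raises(ValueError, match="per class"):
        fisher_matrix(pms)


def test_fr_translation_and_scale_invariance():
    rng = np.random.default_rng(4)
    pms = make_pms(rng)
    base = fisher_matrix(pms, threshold=1e9).fr
    shifted = [PercentileMatrix(values=pm.values + 3.0, markers=pm.markers,
                                grid=pm.grid, patient_id=pm.patient_id,
                                label=pm.label) for pm in pms]
    scaled = [PercentileMatrix(values=pm.values * 2.5, markers=pm.markers,
                               grid=pm.grid, patient_id=pm.patient_id,
                               label=pm.label) for pm in pms]
    np.testing.assert_allclose(fisher_matrix(shifted, threshold=1e9).fr, base,
                               rtol=1e-9)
    np.testing.assert_allclose(fisher_matrix(scaled, threshold=1e9).fr, base,
                               rtol=1e-9)


def test_probabilities_sum_to_one_exactly():
    rng = np.random.default_rng(5)
    pms = make_pms(rng)
    model = fisher_matrix(pms, threshold=0.0)
    for distance in ("feature", "curve", "scaled"):
        pred = classify(pms[0], model, distance=distance)
        for f, p in pred.per_feature.items():
            assert p + pred.per_feature_non_relapse[f] == 1.0


def test_zero_distance_cases():
    model = _toy_model(mu_r=2.0, mu_n=0.0, sigma_r=1.0, sigma_n=1.0)
    at_r = PercentileMatrix(values=np.array([[2.0]]), markers=["m"], grid=(50.0,),
                            patient_id="p", label=None)
    # sitting exactly on the relapse control point / median curve
    assert classify(at_r, model, distance="scaled").p_relapse == 1.0
    assert classify(at_r, model, distance="feature").p_relapse == 1.0
    assert classify(at_r, model, convention="as-printed",
                    distance="scaled").p_relapse == 0.0
    # equidistant from both control points -> exactly 0.5, tie -> N
    mid = PercentileMatrix(values=np.array([[1.0]]), markers=["m"], grid=(50.0,),
                           patient_id="p", label=None)
    pred = classify(mid, model, distance="feature")
    assert pred.p_relapse == 0.5
    assert pred.label == "N"


def test_conventions_are_complementary_for_single_feature():
    rng = np.random.default_rng(6)
    pms = make_pms(rng)
    model = fisher_matrix(pms, threshold=1e12)      # single selected feature
    patient = pms[0]
    a = classify(patient, model, convention="proximity", distance="scaled")
    b = classify(patient, model, convention="as-printed", distance="scaled")
    assert a.p_relapse == pytest.approx(1.0 - b.p_relapse)
    if a.p_relapse != 0.5:
        assert {a.label, b.label} == {"R", "N"}


def test_missing_selected_feature_rejected():
    rng = np.random.default_rng(7)
    pms = make_pms(rng)
    model = fisher_matrix(pms)
    other = PercentileMatrix(values=np.zeros((2, 5)), markers=["x", "y"],
                             grid=pms[0].grid, patient_id="q", label=None)
    with pytest.raises(ValueError, match="does not match"):
        classify(other, model)


def test_model_json_round_trip(tmp_path):
    rng = np.random.default_rng(8)
    model = fisher_matrix(make_pms(rng))
    path = tmp_path / "model.json"
    model.to_json(path)
    back = FisherModel.from_json(path)
    np.testing.assert_allclose(back.fr, model.fr)
    assert back.selected == model.selected
    assert back.threshold == model.threshold
    np.testing.assert_allclose(back.sigma_r, model.sigma_r)


def test_location_mean_option_matches_brute_force():
    rng = np.random.default_rng(9)
    pms = make_pms(rng)
    model = fisher_matrix(pms, location="mean")
    fr, _ = brute_force_fr(pms, location="mean")
    np.testing.assert_allclose(model.fr, fr, rtol=1e-12)
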