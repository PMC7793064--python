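"""Preprocessing chain: compensation, merging, normalisation, gating."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from cytorelapse import synthetic
from cytorelapse.preprocess import (PatientSample, TubeFrame, cd19_threshold,
                                    common_panel, compensate, gate_cd19,
                                    merge_tubes, normalise, quantile_scale,
                                    read_tube, subsample)


def make_tube(events, markers, spillover=None, tube_id="T1"):
    return TubeFrame(events=np.asarray(events, dtype=float),
                     channels=list(markers), markers=list(markers),
                     spillover=spillover, tube_id=tube_id)


# -- reading ---------------------------------------------------------------

def test_read_tube_round_trips_written_cohort(tmp_path):
    cohort = synthetic.generate_cohort(n_patients=4, events_per_tube=200, seed=3)
    raw = synthetic.to_raw_scale(cohort)
    synthetic.write_cohort(raw, tmp_path)
    tube = read_tube(tmp_path / "P001_T1.fcs")
    src = raw.tube_frames[("P001", "T1")]
    np.testing.assert_allclose(tube.events, src.events.astype(np.float32), rtol=0)
    assert tube.markers == src.markers
    np.testing.assert_allclose(tube.spillover, src.spillover, rtol=1e-12)
    assert tube.patient_id == "P001" and tube.tube_id == "T1"


# -- compensation ----------------------------------------------------------

def test_compensate_identity_spillover_is_noop():
    tube = make_tube([[1.0, 2.0], [3.0, 4.0]], ["a", "b"], spillover=np.eye(2))
    np.testing.assert_array_equal(compensate(tube).events, tube.events)


def test_compensate_matches_two_by_two_closed_form():
    # observed = true @ S with S = [[1, .1], [0, 1]]; the closed-form inverse
    # is [[1, -.1], [0, 1]], so true = [obs1, obs2 - .1 obs1]
    s = np.array([[1.0, 0.1], [0.0, 1.0]])
    observed = np.array([[1.1, 1.0], [2.0, 0.5]])
    comp = compensate(make_tube(observed, ["a", "b"], spillover=s))
    expected = np.column_stack([observed[:, 0],
                                observed[:, 1] - 0.1 * observed[:, 0]])
    np.testing.assert_allclose(comp.events, expected, rtol=1e-12)


def test_compensate_singular_spillover_errors():
    s = np.array([[1.0, 1.0], [1.0, 1.0]])
    tube = TubeFrame(events=np.ones((2, 2)), channels=["a", "b"],
                     markers=["a", "b"])
    tube.spillover = s   # bypass unit-diagonal validation to hit the inverse
    with pytest.raises(ValueError, match="singular"):
        compensate(tube)


def test_compensate_twice_rejected():
    tube = make_tube(np.ones((3, 2)), ["a", "b"])
    with pytest.raises(ValueError, match="already compensated"):
        compensate(compensate(tube))


# -- merging ---------------------------------------------------------------

def test_merge_identical_backbone_recovers_held_out_values():
    rng = np.random.default_rng(0)
    bb = rng.normal(2, 0.5, size=(50, 2))
    extra1 = rng.normal(1, 0.2, size=50)
    extra2 = rng.normal(3, 0.2, size=50)
    t1 = make_tube(np.column_stack([bb, extra1]), ["CD19", "CD45", "CD10"], tube_id="T1")
    t2 = make_tube(np.column_stack([bb, extra2]), ["CD19", "CD45", "CD38"], tube_id="T2")
    merged = merge_tubes([t1, t2], ["CD19", "CD45"])
    assert merged.markers == ["CD19", "CD45", "CD10", "CD38"]
    np.testing.assert_array_equal(merged.marker_column("CD38"), extra2)


def test_merge_tie_break_lowest_index():
    # all donor cells identical on the single backbone marker: every
    # reference cell must take donor index 0
    t1 = make_tube(np.column_stack([np.ones(4), np.arange(4.0)]),
                   ["CD19", "CD10"], tube_id="T1")
    t2 = make_tube(np.column_stack([np.ones(3), np.array([7.0, 8.0, 9.0])]),
                   ["CD19", "CD38"], tube_id="T2")
    merged = merge_tubes([t1, t2], ["CD19"])
    np.testing.assert_array_equal(merged.marker_column("CD38"), np.full(4, 7.0))


def test_merge_preserves_marker_distributions(small_cohort):
    from cytorelapse.preprocess import logicle_transform
    pid = small_cohort.patient_ids[0]
    tubes = [small_cohort.tube_frames[(pid, t)] for t, _ in small_cohort.design.tubes]
    merged = merge_tubes(tubes, list(small_cohort.design.backbone))
    for marker in small_cohort.design.markers:
        donor_tube = next(t for t, s in small_cohort.design.tubes if marker in s)
        direct = small_cohort.tube_frames[(pid, donor_tube)].marker_column(marker)
        ks = ks_2samp(merged.marker_column(marker), direct).statistic
        assert ks < 0.15, marker   # 800 events; 0.1 at 5,000 events


def test_merge_requires_backbone_and_two_tubes():
    t1 = make_tube(np.ones((3, 1)), ["CD19"])
    with pytest.raises(ValueError, match="two tubes"):
        merge_tubes([t1], ["CD19"])
    t2 = make_tube(np.ones((3, 1)), ["CD10"], tube_id="T2")
    with pytest.raises(ValueError, match="backbone"):
        merge_tubes([t1, t2], [])
    with pytest.raises(ValueError, match="lacks backbone"):
        merge_tubes([t1, t2], ["CD19"])


# -- normalisation ---------------------------------------------------------

def test_quantile_scale_defining_points():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(1000, 1))
    q05, q95 = np.percentile(x, [5, 95])
    scaled = quantile_scale(x, clip=False)
    np.testing.assert_allclose(
        scaled[np.isclose(x, q05)].ravel(), 0.0, atol=1e-12)
    np.testing.assert_allclose(
        scaled[np.isclose(x, q95)].ravel(), 1.0, atol=1e-12)


def test_quantile_scale_uniform_median_near_half():
    rng = np.random.default_rng(2)
    x = rng.uniform(0, 1, size=(10000, 1))
    assert abs(np.median(quantile_scale(x)) - 0.5) < 0.02


def test_quantile_scale_constant_marker_errors():
    x = np.column_stack([np.ones(100), np.arange(100.0)])
    with pytest.raises(ValueError, match="CD19"):
        quantile_scale(x, markers=["CD19", "CD10"])


def test_normalise_twice_rejected():
    sample = PatientSample(events=np.random.default_rng(0).normal(size=(100, 2)),
                           markers=["a", "b"], patient_id="P1")
    with pytest.raises(ValueError, match="already normalised"):
        normalise(normalise(sample))


# -- gating ----------------------------------------------------------------

def test_gate_threshold_splits_well_separated_modes():
    rng = np.random.default_rng(3)
    neg = rng.normal(0.2, 0.05, 2000)
    pos = rng.normal(0.8, 0.05, 3000)
    thr = cd19_threshold(np.concatenate([neg, pos]))
    assert abs(thr - 0.5) < 0.1
    assert (pos > thr).mean() > 0.99


def test_gate_fallback_retains_all_positive_cells():
    rng = np.random.default_rng(4)
    sample = PatientSample(events=rng.normal(0.8, 0.05, size=(500, 1)),
                           markers=["CD19"], patient_id="P1")
    gated = gate_cd19(sample, fallback=0.0)
    assert gated.events.shape[0] == 500


def test_gate_unimodal_without_fallback_errors():
    rng = np.random.default_rng(5)
    values = rng.normal(0.5, 0.05, 500)
    with pytest.raises(ValueError, match="unimodal"):
        cd19_threshold(values)


def test_gate_threshold_deterministic():
    rng = np.random.default_rng(6)
    values = np.concatenate([rng.normal(0.2, 0.05, 500),
                             rng.normal(0.8, 0.05, 500)])
    assert cd19_threshold(values) == cd19_threshold(values)


def test_raising_threshold_never_increases_retained_count():
    rng = np.random.default_rng(7)
    values = rng.uniform(0, 1, 1000)
    counts = [(values > thr).sum() for thr in np.linspace(0, 1, 20)]
    assert all(np.diff(counts) <= 0)


# -- subsampling -----------------------------------------------------------

def test_subsample_all_cells_is_permutation():
    sample = PatientSample(events=np.arange(20.0).reshape(10, 2),
                           markers=["a", "b"], patient_id="P1")
    out = subsample(sample, 10, seed=0)
    np.testing.assert_array_equal(np.sort(out.events[:, 0]),
                                  np.sort(sample.events[:, 0]))


def test_subsample_seeded_and_bounded():
    sample = PatientSample(events=np.arange(40.0).reshape(20, 2),
                           markers=["a", "b"], patient_id="P7")
    a = subsample(sample, 5, seed=11)
    b = subsample(sample, 5, seed=11)
    np.testing.assert_array_equal(a.events, b.events)
    with pytest.raises(ValueError, match="P7"):
        subsample(sample, 21, seed=0)


def test_subsample_is_uniform():
    """Each cell's inclusion frequency over repeated draws matches n/N
    within three standard errors."""
    sample = PatientSample(events=np.arange(40.0).reshape(20, 2),
                           markers=["a", "b"], patient_id="P1")
    reps = 10000
    counts = np.zeros(20)
    for s in range(reps):
        out = subsample(sample, 5, seed=s)
        counts[(out.events[:, 0] / 2).astype(int)] += 1
    freq = counts / reps
    se = np.sqrt(0.25 * 0.75 / reps)
    assert np.all(np.abs(freq - 0.25) < 3.5 * se)


def test_common_panel_threshold():
    sets = [["CD19", "CD10", "CD38"], ["CD19", "CD38", "CD20"]]
    assert common_panel(sets, min_markers=2) == ["CD19", "CD38"]
    with pytest.raises(ValueError, match="minimum"):
        common_panel(sets, min_markers=3)
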