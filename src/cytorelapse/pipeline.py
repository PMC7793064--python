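"""End-to-end relapse-prediction workflow driven by a single config.

Two ways of producing per-patient percentile matrices are provided:

* the *full* path — write the synthetic cohort to raw-scale FCS 3.0 files,
  read them back, and run the complete preprocessing chain (compensation,
  logicle, tube merging, normalisation, CD19 gating, subsampling) exactly as
  one would on exported cytometer files;
* the *direct* path — draw each patient's complete event matrix on the
  transformed scale and apply only normalisation, gating and subsampling.
  This skips the raw-scale round trip (whose fidelity is validated
  separately) and is the fast route for simulation studies.

``run_pipeline`` executes the full path plus classification, validation and
the clinical-association stage, writing delimited reports and a provenance
record.  All randomness flows from the single ``seed`` in the config, so two
runs with the same config are bit-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import associate, preprocess, profiles, synthetic, validate
from .fisher import fisher_matrix
from .logicle import LogicleParams
from .preprocess import PatientSample
from .profiles import PercentileMatrix

__all__ = ["default_config", "load_config", "run_pipeline",
           "direct_percentiles", "direct_samples", "preprocess_cohort_files"]


def default_config() -> dict:
    return {
        "seed": 1,
        "cohort": {
            "n_patients": 56,
            "prevalence": 13 / 56,
            "events_per_tube": 5000,
            "effects": "default",       # "default", "null", or {marker: {delta, fraction}}
        },
        "preprocess": {
            "logicle": {"w": 0.75, "t": 262144.0, "m": 4.5, "a": 0.0},
            "subsample_n": 3000,
            "clip": True,
            "min_common_markers": 15,
        },
        "profiles": {"grid_step": 5},
        "fisher": {"threshold": 0.5, "location": "median",
                   "convention": "proximity", "distance": "feature"},
        "validate": {
            "schemes": [{"scheme": "loocv"}, {"scheme": "kfold", "k": 4}],
            "repeats": 5,
            "n_splits": 100,
            "rf": {"n_runs": 20, "n_trees": 50},
        },
        "associate": {"marker": "CD38", "levels": [15, 50, 85]},
    }


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    if overrides:
        cfg.update(overrides)
    return cfg


def _effects_from_config(spec) -> synthetic.EffectSpec:
    if spec == "default" or spec is None:
        return synthetic.EffectSpec.default()
    if spec == "null":
        return synthetic.EffectSpec.null()
    base = synthetic.EffectSpec.default()
    shifts = {m: synthetic.MarkerShift(delta=float(d["delta"]),
                                       fraction=float(d.get("fraction", 1.0)))
              for m, d in spec.items()}
    return synthetic.EffectSpec(shifts=shifts, covariate_links=base.covariate_links)


def _grid(cfg: dict) -> tuple[float, ...]:
    step = int(cfg.get("profiles", {}).get("grid_step", 5))
    return tuple(range(5, 100, step))


def _patient_seed(master: int, index: int) -> int:
    return int(np.random.SeedSequence(master, spawn_key=(9, index)).generate_state(1)[0]
               % (2**31 - 1))


def generate_from_config(cfg: dict) -> synthetic.SyntheticCohort:
    c = cfg["cohort"]
    return synthetic.generate_cohort(
        effects=_effects_from_config(c.get("effects", "default")),
        n_patients=int(c["n_patients"]), prevalence=float(c["prevalence"]),
        events_per_tube=int(c["events_per_tube"]), seed=int(cfg["seed"]))


# ---------------------------------------------------------------------------
# direct path (no file round trip)
# ---------------------------------------------------------------------------

def direct_samples(cohort: synthetic.SyntheticCohort, subsample_n: int | None = 3000,
                   clip: bool = True, n_events: int | None = None) -> list[PatientSample]:
    """Complete event matrices -> normalise -> CD19 gate -> subsample."""
    n_events = n_events or cohort.events_per_tube
    labels = cohort.labels()
    out = []
    for i, pid in enumerate(cohort.patient_ids):
        events = synthetic.complete_events(cohort, pid, n_events)
        sample = PatientSample(events=events, markers=list(cohort.design.markers),
                               patient_id=pid, label=labels[pid])
        sample = preprocess.normalise(sample, clip=clip)
        sample = preprocess.gate_cd19(sample)
        if subsample_n is not None:
            sample = preprocess.subsample(sample, subsample_n,
                                          _patient_seed(cohort.seed, i))
        out.append(sample)
    return out


def direct_percentiles(cohort: synthetic.SyntheticCohort, subsample_n: int | None = 3000,
                       grid=profiles.DEFAULT_GRID, clip: bool = True,
                       n_events: int | None = None) -> list[PercentileMatrix]:
    return [profiles.percentile_matrix(s.events, s.markers, grid,
                                       patient_id=s.patient_id, label=s.label)
            for s in direct_samples(cohort, subsample_n, clip, n_events)]


# ---------------------------------------------------------------------------
# full path (FCS round trip)
# ---------------------------------------------------------------------------

def preprocess_cohort_files(fcs_dir: str | Path, cfg: dict) -> list[PatientSample]:
    """Read every patient's tubes from ``fcs_dir`` and preprocess them."""
    fcs_dir = Path(fcs_dir)
    clinical = associate.read_clinical(fcs_dir / "clinical.csv")
    labels = dict(zip(clinical["patient_id"], clinical["label"]))
    pp = cfg["preprocess"]
    params = LogicleParams(**pp["logicle"])

    by_patient: dict[str, list[Path]] = {}
    for path in sorted(fcs_dir.glob("*.fcs")):
        pid = path.stem.split("_")[0]
        by_patient.setdefault(pid, []).append(path)

    tubes_by_patient = {pid: [preprocess.read_tube(p) for p in paths]
                        for pid, paths in by_patient.items()}
    panel = preprocess.common_panel(
        [sorted({m for t in tubes for m in t.markers})
         for tubes in tubes_by_patient.values()],
        min_markers=int(pp.get("min_common_markers", 15)))

    backbone = [m for m in ("CD19", "CD45", "CD34") if m in panel]
    samples = []
    for i, (pid, tubes) in enumerate(sorted(tubes_by_patient.items())):
        sample = preprocess.preprocess_patient(
            tubes, backbone=backbone, logicle_params=params,
            subsample_n=pp.get("subsample_n"), seed=_patient_seed(cfg["seed"], i),
            clip=bool(pp.get("clip", True)), label=labels.get(pid))
        keep = [sample.markers.index(m) for m in panel if m in sample.markers]
        sample.events = sample.events[:, keep]
        sample.markers = [sample.markers[j] for j in keep]
        samples.append(sample)
    return samples


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(cfg: dict, out_dir: str | Path) -> dict:
    """Simulate, preprocess, fit, validate and associate; write all reports."""
    out = Path(out_dir)
    (out / "fcs").mkdir(parents=True, exist_ok=True)
    (out / "reports").mkdir(parents=True, exist_ok=True)

    cohort = generate_from_config(cfg)
    raw = synthetic.to_raw_scale(
        cohort, logicle_params=LogicleParams(**cfg["preprocess"]["logicle"]))
    synthetic.write_cohort(raw, out / "fcs")

    samples = preprocess_cohort_files(out / "fcs", cfg)
    grid = _grid(cfg)
    pms = [profiles.percentile_matrix(s.events, s.markers, grid,
                                      patient_id=s.patient_id, label=s.label)
           for s in samples]
    pd.concat([pm.to_frame() for pm in pms]).to_csv(
        out / "reports" / "percentiles.csv", index=False)

    fcfg = cfg["fisher"]
    model = fisher_matrix(pms, threshold=float(fcfg["threshold"]),
                          location=fcfg["location"])
    model.to_json(out / "reports" / "fisher_model.json")
    fr_frame = pd.DataFrame(model.fr, index=model.markers, columns=list(model.grid))
    fr_frame.to_csv(out / "reports" / "fisher_matrix.csv")

    vcfg = cfg["validate"]
    perf_rows, perf_raw = [], {}
    for scheme_cfg in vcfg["schemes"]:
        report = validate.cross_validate(
            pms, scheme=scheme_cfg["scheme"], k=scheme_cfg.get("k"),
            repeats=int(vcfg.get("repeats", 20)), seed=int(cfg["seed"]),
            threshold=float(fcfg["threshold"]), location=fcfg["location"],
            convention=fcfg["convention"], distance=fcfg["distance"])
        perf_rows.append(report.summary_row())
        key = report.scheme if report.k is None else f"{report.scheme}{report.k}"
        perf_raw[key] = {m: [report.mean[m], report.sd[m]] for m in validate.METRICS}
    pd.DataFrame(perf_rows).to_csv(out / "reports" / "performance.csv", index=False)

    ff = validate.feature_frequency(
        pms, n_splits=int(vcfg.get("n_splits", 100)), seed=int(cfg["seed"]),
        threshold=float(fcfg["threshold"]), location=fcfg["location"],
        convention=fcfg["convention"], distance=fcfg["distance"])
    pd.DataFrame(ff.tables).rename_axis("marker").to_csv(
        out / "reports" / "feature_frequency.csv")

    rf_cfg = vcfg.get("rf", {})
    rf = validate.random_forest_comparison(
        pms, n_runs=int(rf_cfg.get("n_runs", 100)),
        n_trees=int(rf_cfg.get("n_trees", 50)), seed=int(cfg["seed"]))
    rf.importance.to_csv(out / "reports" / "random_forest_importance.csv")

    stats_table = profiles.summary_table(samples)
    tests = validate.compare_summaries(stats_table)
    tests.to_csv(out / "reports" / "summary_tests.csv", index=False)

    acfg = cfg["associate"]
    clinical = associate.read_clinical(out / "fcs" / "clinical.csv")
    corr = associate.correlate(clinical, pms, marker=acfg["marker"],
                               levels=tuple(acfg["levels"]))
    corr.to_files(out / "reports" / "associations")
    corr.display_matrix().to_csv(out / "reports" / "associations_matrix.csv")

    provenance = {
        "config": cfg,
        "n_patients": len(samples),
        "markers": pms[0].markers,
        "grid": list(grid),
        "selected_features": model.selected_features,
        "oob_error_mean": rf.mean_oob_error,
        "cv": perf_raw,
    }
    (out / "reports" / "provenance.json").write_text(
        json.dumps(provenance, indent=1, sort_keys=True, default=str))
    return provenance
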