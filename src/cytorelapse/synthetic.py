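"""Synthetic multi-tube flow-cytometry cohorts for childhood B-ALL analyses.

The generator emulates the statistical structure the downstream analysis
relies on, without claiming to reproduce any real patient's data:

* an ~20-marker panel acquired in several tubes that share *backbone*
  markers (here CD19 / CD45 / CD34), so tubes can be merged by
  nearest-neighbour imputation;
* per-cell fluorescence that, on the logicle display scale, follows a
  two-component (negative / positive) Gaussian location-scale mixture per
  marker, with a strongly bimodal CD19 so the B-cell gate has something to
  find;
* patient-level random effects (component locations and mixing weights
  jitter between patients), which create the within-class variance the
  Fisher's-Ratio statistic divides by;
* a plantable, class-dependent shift: in relapse-class patients the
  *positive* component of chosen markers moves by ``delta`` decades for a
  fraction ``f`` of positive cells.  The default effect is CD38 shifted
  down by one decade, the relapse signature the analysis is built to
  detect.  (A shift of *all* cells would be removed exactly by the
  per-patient quantile normalisation, so effects act on the positive
  component relative to the negative one.)
* clinical/genetic covariates (age, sex, blast %, karyotype category,
  translocation flags, time to relapse) with configurable correlations to a
  marker's patient-level expression score, induced by thresholding shared
  latent Gaussians;
* class imbalance matching the study setting (about 23% relapse).

Everything is driven by a single integer seed; per-patient substreams are
split by counter so regeneration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit, ndtri

from .fcs import write_fcs
from .logicle import Logicle, LogicleParams
from .preprocess import TubeFrame

__all__ = [
    "PanelDesign", "MarkerShift", "CovariateLink", "EffectSpec",
    "SyntheticCohort", "generate_cohort", "to_raw_scale", "write_cohort",
    "default_spillover", "complete_events",
]

# ---------------------------------------------------------------------------
# panel design
# ---------------------------------------------------------------------------

_DETECTORS = ["FITC-A", "PE-A", "PerCP-Cy5-5-A", "PE-Cy7-A",
              "APC-A", "APC-H7-A", "V450-A", "V500-A"]


@dataclass(frozen=True)
class PanelDesign:
    """Markers, their tube layout and their detector assignment."""

    markers: tuple[str, ...]
    tubes: tuple[tuple[str, tuple[str, ...]], ...]   # (tube id, marker subset)
    backbone: tuple[str, ...]
    channel_map: dict[str, str] = field(default_factory=dict)  # marker -> detector

    def __post_init__(self) -> None:
        if len(self.backbone) < 2:
            raise ValueError("at least two backbone markers are required for merging")
        union: set[str] = set()
        for tube_id, subset in self.tubes:
            missing = [m for m in self.backbone if m not in subset]
            if missing:
                raise ValueError(f"tube {tube_id!r} lacks backbone markers {missing}")
            dets = [self.channel_map.get(m, m) for m in subset]
            if len(set(dets)) != len(dets):
                raise ValueError(f"tube {tube_id!r} maps two markers to the same detector")
            union.update(subset)
        if union != set(self.markers):
            raise ValueError("union of tube marker subsets must equal the panel marker list")

    def tube_markers(self, tube_id: str) -> tuple[str, ...]:
        for tid, subset in self.tubes:
            if tid == tube_id:
                return subset
        raise KeyError(tube_id)

    @classmethod
    def default(cls) -> "PanelDesign":
        backbone = ("CD19", "CD45", "CD34")
        bb_det = {"CD19": "APC-A", "CD45": "V500-A", "CD34": "PerCP-Cy5-5-A"}
        tube_specific = {
            "T1": ("CD10", "CD20", "CD38", "CD58", "CD123"),
            "T2": ("CD22", "CD24", "IgM", "CD66c", "CD13"),
            "T3": ("CD33", "CD15", "CD71", "HLA-DR", "CD9"),
        }
        free_det = ["FITC-A", "PE-A", "PE-Cy7-A", "APC-H7-A", "V450-A"]
        channel_map = dict(bb_det)
        tubes = []
        for tid, extra in tube_specific.items():
            for m, det in zip(extra, free_det):
                channel_map[m] = det
            tubes.append((tid, backbone + extra))
        markers = backbone + sum(tube_specific.values(), ())
        return cls(markers=markers, tubes=tuple(tubes), backbone=backbone,
                   channel_map=channel_map)


# ---------------------------------------------------------------------------
# effects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerShift:
    """Class-dependent shift of a marker's positive component.

    ``delta`` is in display decades and applies to relapse-class patients;
    ``fraction`` is the share of positive-component cells affected.
    """

    delta: float
    fraction: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta):
            raise ValueError("shift delta must be finite")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"affected fraction must lie in [0, 1], got {self.fraction}")


@dataclass(frozen=True)
class CovariateLink:
    """Correlation between a binary covariate and a marker's expression score.

    The covariate indicator is obtained by thresholding a latent Gaussian
    that correlates (coefficient ``rho``) with the patient's standardised
    positive-component location of ``marker`` — a simple way to plant a
    Pearson correlation of controllable sign and size.  ``region`` records
    which part of the percentile curve the link is expected to show up in.
    """

    marker: str
    rho: float
    rate: float            # marginal probability of the indicator
    region: str = "high"

    def __post_init__(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie strictly inside (-1, 1)")
        if not 0.0 < self.rate < 1.0:
            raise ValueError("rate must lie strictly inside (0, 1)")


@dataclass(frozen=True)
class EffectSpec:
    """Planted class effects and covariate correlations."""

    shifts: dict[str, MarkerShift] = field(default_factory=dict)
    covariate_links: dict[str, CovariateLink] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "EffectSpec":
        # relapse signature: CD38 positive component down one decade;
        # hyperdiploid karyotype inversely, female sex and t(12;21) directly
        # linked to CD38 expression.
        return cls(
            shifts={"CD38": MarkerShift(delta=-1.0, fraction=1.0)},
            covariate_links={
                "hyperdiploid": CovariateLink("CD38", rho=-0.5, rate=0.25),
                "female": CovariateLink("CD38", rho=0.4, rate=0.43),
                "t_12_21": CovariateLink("CD38", rho=0.4, rate=0.14),
            },
        )

    @classmethod
    def null(cls) -> "EffectSpec":
        return cls(shifts={}, covariate_links={})

    def validate(self, design: PanelDesign) -> None:
        for m in self.shifts:
            if m not in design.markers:
                raise ValueError(f"effect on unknown marker {m!r}")
        for cov, link in self.covariate_links.items():
            if link.marker not in design.markers:
                raise ValueError(f"covariate {cov!r} linked to unknown marker {link.marker!r}")


# ---------------------------------------------------------------------------
# marker base profiles (display-decade scale)
# ---------------------------------------------------------------------------

# (mu_neg, mu_pos, sd_neg, sd_pos, w_pos in B cells, w_pos in non-B cells)
_BASE_PROFILES: dict[str, tuple[float, float, float, float, float, float]] = {
    "CD19":   (0.80, 3.00, 0.25, 0.30, 0.985, 0.02),
    "CD45":   (1.20, 2.60, 0.30, 0.35, 0.95, 0.98),
    "CD34":   (0.90, 2.50, 0.30, 0.35, 0.70, 0.10),
    "CD10":   (0.85, 2.60, 0.30, 0.35, 0.85, 0.05),
    "CD20":   (0.90, 2.40, 0.30, 0.40, 0.40, 0.15),
    "CD38":   (0.90, 2.70, 0.30, 0.35, 0.75, 0.50),
    "CD58":   (1.00, 2.60, 0.30, 0.35, 0.90, 0.40),
    "CD123":  (0.90, 2.30, 0.30, 0.40, 0.50, 0.10),
    "CD22":   (0.90, 2.40, 0.30, 0.35, 0.80, 0.10),
    "CD24":   (0.90, 2.60, 0.30, 0.35, 0.90, 0.10),
    "IgM":    (0.90, 2.20, 0.30, 0.40, 0.30, 0.10),
    "CD66c":  (0.90, 2.30, 0.30, 0.40, 0.35, 0.05),
    "CD13":   (0.90, 2.30, 0.30, 0.40, 0.30, 0.15),
    "CD33":   (0.90, 2.30, 0.30, 0.40, 0.35, 0.20),
    "CD15":   (0.90, 2.20, 0.30, 0.40, 0.20, 0.15),
    "CD71":   (0.90, 2.40, 0.30, 0.40, 0.45, 0.15),
    "HLA-DR": (1.00, 2.70, 0.30, 0.35, 0.85, 0.50),
    "CD9":    (0.90, 2.40, 0.30, 0.40, 0.60, 0.20),
}
_FALLBACK_PROFILE = (0.90, 2.40, 0.30, 0.38, 0.50, 0.15)

# patient-level random-effect scales (decades / logit units)
_MU_POS_JITTER = 0.15
_MU_NEG_JITTER = 0.10
_LOGIT_W_JITTER = 0.35
_B_FRACTION = 0.85
_LOGIT_BFRAC_JITTER = 0.30


@dataclass
class PatientModel:
    """Realised per-patient mixture parameters for every marker."""

    patient_id: str
    label: str                              # "R" or "N"
    b_fraction: float
    mu_neg: dict[str, float]
    mu_pos: dict[str, float]
    sd_neg: dict[str, float]
    sd_pos: dict[str, float]
    w_pos_b: dict[str, float]
    w_pos_nonb: dict[str, float]
    shift: dict[str, MarkerShift]           # effects active for this patient
    z_mu_pos: dict[str, float]              # standard-normal jitter draws


@dataclass
class SyntheticCohort:
    """A generated cohort: tube frames, clinical table and its ground truth."""

    design: PanelDesign
    effects: EffectSpec
    patients: list[PatientModel]
    tube_frames: dict[tuple[str, str], TubeFrame]   # (patient id, tube id) -> frame
    clinical: pd.DataFrame
    seed: int
    events_per_tube: int
    scale: str = "transformed"              # "transformed" (decades) or "raw"
    logicle_params: LogicleParams | None = None
    spillover: np.ndarray | None = None

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def labels(self) -> dict[str, str]:
        return {p.patient_id: p.label for p in self.patients}


def _profile(marker: str) -> tuple[float, float, float, float, float, float]:
    return _BASE_PROFILES.get(marker, _FALLBACK_PROFILE)


def _patient_model(pid: str, label: str, design: PanelDesign, effects: EffectSpec,
                   rng: np.random.Generator) -> PatientModel:
    mu_neg, mu_pos, sd_neg, sd_pos, w_b, w_nb, z_mu = {}, {}, {}, {}, {}, {}, {}
    for m in design.markers:
        base = _profile(m)
        z = rng.standard_normal()
        z_mu[m] = z
        mu_pos[m] = base[1] + _MU_POS_JITTER * z
        mu_neg[m] = base[0] + _MU_NEG_JITTER * rng.standard_normal()
        sd_neg[m] = base[2]
        sd_pos[m] = base[3]
        w_b[m] = float(expit(logit(np.clip(base[4], 1e-3, 1 - 1e-3))
                             + _LOGIT_W_JITTER * rng.standard_normal()))
        w_nb[m] = float(expit(logit(np.clip(base[5], 1e-3, 1 - 1e-3))
                              + _LOGIT_W_JITTER * rng.standard_normal()))
    b_frac = float(expit(logit(_B_FRACTION) + _LOGIT_BFRAC_JITTER * rng.standard_normal()))
    shift = dict(effects.shifts) if label == "R" else {}
    return PatientModel(pid, label, b_frac, mu_neg, mu_pos, sd_neg, sd_pos,
                        w_b, w_nb, shift, z_mu)


def _draw_events(model: PatientModel, markers: tuple[str, ...], n: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Draw n cells for the given markers from one patient's mixture model."""
    is_b = rng.random(n) < model.b_fraction
    out = np.empty((n, len(markers)))
    for j, m in enumerate(markers):
        w = np.where(is_b, model.w_pos_b[m], model.w_pos_nonb[m])
        positive = rng.random(n) < w
        mu = np.where(positive, model.mu_pos[m], model.mu_neg[m])
        sd = np.where(positive, model.sd_pos[m], model.sd_neg[m])
        if m in model.shift:
            eff = model.shift[m]
            affected = positive & is_b & (rng.random(n) < eff.fraction)
            mu = np.where(affected, mu + eff.delta, mu)
        out[:, j] = mu + sd * rng.standard_normal(n)
    return out


def _covariates(patients: list[PatientModel], effects: EffectSpec,
                rng: np.random.Generator) -> pd.DataFrame:
    """Draw the clinical table, with covariate-marker correlations planted."""
    n = len(patients)
    labels = np.array([p.label for p in patients])
    relapse = (labels == "R").astype(int)

    # standardised patient-level expression score per marker used by links:
    # positive-component location offset including any class effect
    def score(marker: str) -> np.ndarray:
        base_mu = _profile(marker)[1]
        raw = np.array([
            p.mu_pos[marker]
            + (p.shift[marker].delta * p.shift[marker].fraction if marker in p.shift else 0.0)
            - base_mu
            for p in patients
        ])
        sd = raw.std()
        return (raw - raw.mean()) / (sd if sd > 0 else 1.0)

    def linked_indicator(link: CovariateLink) -> np.ndarray:
        z = link.rho * score(link.marker) + np.sqrt(1 - link.rho**2) * rng.standard_normal(n)
        return (z > ndtri(1 - link.rate)).astype(int)

    links = effects.covariate_links
    female = (linked_indicator(links["female"]) if "female" in links
              else (rng.random(n) < 0.43).astype(int))
    hyper = (linked_indicator(links["hyperdiploid"]) if "hyperdiploid" in links
             else (rng.random(n) < 0.25).astype(int))
    t1221 = (linked_indicator(links["t_12_21"]) if "t_12_21" in links
             else (rng.random(n) < 0.14).astype(int))

    age = np.clip(np.exp(np.log(3.75) + 0.8 * rng.standard_normal(n)), 0.2, 18.0)
    blast = np.clip(100 * rng.beta(5.0, 1.2, size=n), 10.0, 96.0)

    karyotype = np.where(hyper == 1, "hyperdiploid",
                         np.where(rng.random(n) < 0.03, "hypodiploid", "normal"))
    karyotype = karyotype.astype(object)
    karyotype[rng.random(n) < 0.2] = None      # some patients lack karyotype data

    t0119 = (rng.random(n) < 0.04).astype(int)
    t0411 = (rng.random(n) < 0.02).astype(int)
    mll = (rng.random(n) < 0.05).astype(int)
    t0922 = np.zeros(n, dtype=int)

    ttr = np.where(relapse == 1,
                   np.round(np.exp(np.log(24.0) + 0.5 * rng.standard_normal(n)), 1),
                   np.nan)

    return pd.DataFrame({
        "patient_id": [p.patient_id for p in patients],
        "label": labels,
        "age_years": np.round(age, 2),
        "sex": np.where(female == 1, "F", "M"),
        "blast_pct": np.round(blast, 1),
        "karyotype": karyotype,
        "t_12_21": t1221,
        "t_1_19": t0119,
        "t_4_11": t0411,
        "mll_rearrangement": mll,
        "t_9_22": t0922,
        "time_to_relapse_months": ttr,
    })


def generate_cohort(design: PanelDesign | None = None,
                    effects: EffectSpec | None = None,
                    n_patients: int = 56,
                    prevalence: float = 13 / 56,
                    events_per_tube: int = 5000,
                    seed: int = 0) -> SyntheticCohort:
    """Generate a multi-tube cohort with planted class effects.

    Relapse labels are assigned to ``round(prevalence * n_patients)`` patients
    chosen at random; each tube's events are independent draws from the same
    patient-level mixture model, so merging tubes is statistically consistent.
    """
    design = design or PanelDesign.default()
    effects = effects if effects is not None else EffectSpec.default()
    effects.validate(design)
    if n_patients < 4:
        raise ValueError("at least 4 patients are required")
    if events_per_tube < 100:
        raise ValueError("at least 100 events per tube are required")
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie strictly inside (0, 1)")
    n_relapse = int(round(prevalence * n_patients))
    if n_relapse < 1:
        raise ValueError(
            f"prevalence {prevalence} over {n_patients} patients yields no relapse patient"
        )

    cohort_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    order = cohort_rng.permutation(n_patients)
    labels = np.array(["N"] * n_patients, dtype=object)
    labels[order[:n_relapse]] = "R"

    patients, frames = [], {}
    for i in range(n_patients):
        pid = f"P{i + 1:03d}"
        prng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1, i)))
        model = _patient_model(pid, str(labels[i]), design, effects, prng)
        patients.append(model)
        for t_idx, (tube_id, subset) in enumerate(design.tubes):
            erng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2, i, t_idx)))
            events = _draw_events(model, subset, events_per_tube, erng)
            frames[(pid, tube_id)] = TubeFrame(
                events=events,
                channels=[design.channel_map.get(m, m) for m in subset],
                markers=list(subset),
                spillover=np.eye(len(subset)),
                tube_id=tube_id, patient_id=pid,
                compensated=True, transformed=True,
            )

    crng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    clinical = _covariates(patients, effects, crng)
    return SyntheticCohort(design=design, effects=effects, patients=patients,
                           tube_frames=frames, clinical=clinical, seed=seed,
                           events_per_tube=events_per_tube)


def complete_events(cohort: SyntheticCohort, patient_id: str, n_events: int,
                    stream: int = 0) -> np.ndarray:
    """Fresh draw of a complete (all-marker) event matrix for one patient.

    Used as the direct-generation reference when measuring how faithfully the
    raw-scale round trip and tube merging recover a patient's distributions.
    """
    i = cohort.patient_ids.index(patient_id)
    rng = np.random.default_rng(np.random.SeedSequence(cohort.seed, spawn_key=(4, i, stream)))
    return _draw_events(cohort.patients[i], cohort.design.markers, n_events, rng)


def default_spillover(n: int, strength: float = 0.08) -> np.ndarray:
    """Deterministic spillover matrix: unit diagonal, off-diagonal decaying
    with detector distance (max ``strength``), always invertible."""
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    s = strength * 0.5 ** (dist - 1.0)
    np.fill_diagonal(s, 1.0)
    return s


def to_raw_scale(cohort: SyntheticCohort, spillover: np.ndarray | None = None,
                 logicle_params: LogicleParams | None = None) -> SyntheticCohort:
    """Map a transformed-scale cohort to raw fluorescence with spillover.

    Display decades go through the inverse logicle to the raw scale, then the
    channels are mixed as ``observed = true @ S``.  Running the preprocessing
    chain (compensation + logicle) recovers the originals within the root
    finder's tolerance.
    """
    if cohort.scale != "transformed":
        raise ValueError("cohort is already on the raw scale")
    params = logicle_params or LogicleParams()
    n_det = len(cohort.design.tubes[0][1])
    s = default_spillover(n_det) if spillover is None else np.asarray(spillover, dtype=float)
    if s.shape[0] != s.shape[1]:
        raise ValueError("spillover matrix must be square")
    if not np.allclose(np.diag(s), 1.0):
        raise ValueError("spillover matrix must have unit diagonal")
    if np.any(s < 0):
        raise ValueError("spillover matrix must be non-negative")
    if abs(np.linalg.det(s)) < 1e-12:
        raise ValueError("singular spillover matrix")
    lg = Logicle(params)

    frames = {}
    for key, tf in cohort.tube_frames.items():
        if s.shape[0] != tf.events.shape[1]:
            raise ValueError("spillover size does not match the tube's channel count")
        raw = lg.inverse(tf.events) @ s
        frames[key] = TubeFrame(events=raw, channels=list(tf.channels),
                                markers=list(tf.markers), spillover=s,
                                tube_id=tf.tube_id, patient_id=tf.patient_id,
                                compensated=False, transformed=False)
    return SyntheticCohort(design=cohort.design, effects=cohort.effects,
                           patients=cohort.patients, tube_frames=frames,
                           clinical=cohort.clinical, seed=cohort.seed,
                           events_per_tube=cohort.events_per_tube,
                           scale="raw", logicle_params=params, spillover=s)


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> list[Path]:
    """Write one FCS 3.0 file per tube per patient plus ``clinical.csv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for (pid, tube_id), tf in sorted(cohort.tube_frames.items()):
        path = directory / f"{pid}_{tube_id}.fcs"
        spill = ((tf.spillover, list(tf.channels)) if tf.spillover is not None else None)
        write_fcs(path, tf.events, tf.channels, markers=tf.markers, spillover=spill,
                  extra_keywords={"PATIENT": pid, "TUBE": tube_id})
        written.append(path)
    clin_path = directory / "clinical.csv"
    cohort.clinical.to_csv(clin_path, index=False)
    written.append(clin_path)
    return written
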