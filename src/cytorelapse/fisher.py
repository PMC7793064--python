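"""Fisher's-Ratio feature selection and the control-point classifier.

Features are (marker j, percentile k) entries of per-patient percentile
matrices.  For classes R (relapse) and N (non-relapse) the Fisher's Ratio of
a feature is

    FR_jk = (mu_Rjk - mu_Njk)^2 / (sigma_Rjk^2 + sigma_Njk^2),

where mu is the across-patient class *median* of the feature (a class mean is
available by configuration) and sigma the within-class sample (n-1) standard
deviation.  Features with FR above a threshold (default 0.5) are selected; if
none passes, the single highest-FR feature is used so a classifier can always
be built inside a cross-validation fold.

Each selected feature defines two class control points and a scale-free
patient point,

    Rbar = mu_R / sigma_R,   Nbar = mu_N / sigma_N,
    Pbar = v / ((sigma_R + sigma_N) / 2),

and per-feature class-membership probabilities are formed from the distances
of Pbar to the control points with a shared denominator,

    P(in R) + P(in N) = 1  exactly.

Two orientation conventions are implemented.  The default, ``proximity``,
makes membership probability *decrease* with distance to that class's control
point (a patient whose value sits on the relapse control point gets relapse
probability 1), which is the behaviour the method's illustration implies.
The ``as-printed`` convention uses the opposite orientation, in which the
distance *to* a class's control point appears in that class's numerator; it
is provided for literal reproduction.  A patient's relapse probability is the
mean of the per-feature probabilities; the hard label uses threshold 0.5 with
ties assigned to N.

Three distance geometries are available.  The default, ``feature``, measures
per selected feature the absolute difference between the patient's percentile
value and each class's *median curve* value — the distances the method's
illustration draws between a patient's cumulative curve and the two class
median curves.  ``curve`` is its per-marker form (Euclidean over the marker's
selected percentiles, probabilities averaged per marker).  ``scaled`` uses
the sigma-scaled control points Rbar/Nbar against Pbar.  The scaled geometry
is only well-behaved when the two class sigmas of a feature are comparable:
because Pbar is scaled by the *mean* of the class sigmas while each control
point is scaled by its *own* sigma, a feature with strongly unequal class
sigmas (e.g. one class saturated by clipping) places both classes' patients
near the same control point and the hard labels degrade, which is why the
unscaled curve geometry is the default.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .profiles import PercentileMatrix

__all__ = ["FisherModel", "Prediction", "fisher_matrix", "control_points",
           "patient_point", "classify"]


@dataclass
class FisherModel:
    """FR matrix with class statistics and the selected feature set."""

    fr: np.ndarray                      # (M, P), NaN where dropped
    markers: list[str]
    grid: tuple[float, ...]
    mu_r: np.ndarray
    mu_n: np.ndarray
    sigma_r: np.ndarray
    sigma_n: np.ndarray
    selected: list[tuple[int, int]]     # (marker index, level index)
    threshold: float
    location: str = "median"
    n_r: int = 0
    n_n: int = 0

    @property
    def selected_features(self) -> list[tuple[str, float]]:
        return [(self.markers[j], self.grid[k]) for j, k in self.selected]

    @property
    def selected_markers(self) -> list[str]:
        seen: dict[str, None] = {}
        for j, _ in self.selected:
            seen.setdefault(self.markers[j], None)
        return list(seen)

    def marker_level_fr(self) -> dict[str, float]:
        """Mean FR over each marker's percentile levels (NaN-aware)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(self.fr, axis=1)
        return dict(zip(self.markers, means))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "markers": self.markers,
            "grid": list(self.grid),
            "fr": np.where(np.isnan(self.fr), None, self.fr).tolist(),
            "mu_r": self.mu_r.tolist(), "mu_n": self.mu_n.tolist(),
            "sigma_r": self.sigma_r.tolist(), "sigma_n": self.sigma_n.tolist(),
            "selected": [list(s) for s in self.selected],
            "threshold": self.threshold, "location": self.location,
            "n_r": self.n_r, "n_n": self.n_n,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FisherModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        fr = np.array([[np.nan if v is None else v for v in row] for row in d["fr"]])
        return cls(fr=fr, markers=d["markers"], grid=tuple(d["grid"]),
                   mu_r=np.array(d["mu_r"]), mu_n=np.array(d["mu_n"]),
                   sigma_r=np.array(d["sigma_r"]), sigma_n=np.array(d["sigma_n"]),
                   selected=[tuple(s) for s in d["selected"]],
                   threshold=d["threshold"], location=d["location"],
                   n_r=d["n_r"], n_n=d["n_n"])


def _stack(train: list[PercentileMatrix]) -> tuple[np.ndarray, np.ndarray, list[str], tuple]:
    markers, grid = train[0].markers, train[0].grid
    for pm in train[1:]:
        if pm.markers != markers or pm.grid != grid:
            raise ValueError("all percentile matrices must share markers and grid")
    x = np.stack([pm.values for pm in train])          # (patients, M, P)
    labels = np.array([pm.label for pm in train])
    return x, labels, markers, grid


def fisher_matrix(train: list[PercentileMatrix], threshold: float = 0.5,
                  location: str = "median") -> FisherModel:
    """Fit the FR matrix and select discriminant features on training data.

    Zero-variance features (both class sigmas zero) cannot be scored and are
    dropped with a warning (their FR is NaN).
    """
    if location not in ("median", "mean"):
        raise ValueError("location must be 'median' or 'mean'")
    x, labels, markers, grid = _stack(train)
    r, n = x[labels == "R"], x[labels == "N"]
    if len(r) < 2 or len(n) < 2:
        raise ValueError(
            f"need at least 2 patients per class to estimate sigma "
            f"(got R={len(r)}, N={len(n)})"
        )
    loc = np.median if location == "median" else np.mean
    mu_r, mu_n = loc(r, axis=0), loc(n, axis=0)
    sigma_r = np.std(r, axis=0, ddof=1)
    sigma_n = np.std(n, axis=0, ddof=1)

    denom = sigma_r**2 + sigma_n**2
    dead = denom == 0
    if dead.all():
        raise ValueError("all features have zero within-class variance")
    if dead.any():
        warnings.warn(f"dropping {int(dead.sum())} zero-variance feature(s)")
    with np.errstate(divide="ignore", invalid="ignore"):
        fr = np.where(dead, np.nan, (mu_r - mu_n) ** 2 / np.where(dead, 1.0, denom))

    passing = np.argwhere(np.nan_to_num(fr, nan=-1.0) > threshold)
    if len(passing) == 0:
        flat = np.nanargmax(np.where(dead, -np.inf, fr))
        passing = np.array([np.unravel_index(flat, fr.shape)])
    selected = [tuple(int(v) for v in jk) for jk in passing]
    return FisherModel(fr=fr, markers=markers, grid=grid, mu_r=mu_r, mu_n=mu_n,
                       sigma_r=sigma_r, sigma_n=sigma_n, selected=selected,
                       threshold=threshold, location=location,
                       n_r=len(r), n_n=len(n))


def control_points(model: FisherModel) -> dict[tuple[int, int], tuple[float, float]]:
    """Per selected feature: (Rbar, Nbar) = (mu_R/sigma_R, mu_N/sigma_N)."""
    out = {}
    for j, k in model.selected:
        if model.sigma_r[j, k] == 0 or model.sigma_n[j, k] == 0:
            raise ValueError(
                f"feature ({model.markers[j]}, {model.grid[k]}) has a zero class sigma"
            )
        out[(j, k)] = (model.mu_r[j, k] / model.sigma_r[j, k],
                       model.mu_n[j, k] / model.sigma_n[j, k])
    return out


def patient_point(value: float, model: FisherModel, feature: tuple[int, int]) -> float:
    """Scale a patient's feature value by the mean of the two class sigmas."""
    j, k = feature
    if feature not in model.selected:
        raise ValueError(f"feature ({j}, {k}) is not selected in this model")
    return float(value / ((model.sigma_r[j, k] + model.sigma_n[j, k]) / 2.0))


@dataclass
class Prediction:
    """Per-feature and aggregated relapse probabilities for one patient."""

    patient_id: str
    p_relapse: float
    label: str
    per_feature: dict[tuple[int, int], float] = field(default_factory=dict)
    decision_threshold: float = 0.5

    @property
    def per_feature_non_relapse(self) -> dict[tuple[int, int], float]:
        return {f: 1.0 - p for f, p in self.per_feature.items()}


def classify(patient: PercentileMatrix, model: FisherModel,
             convention: str = "proximity", distance: str = "feature",
             decision_threshold: float = 0.5) -> Prediction:
    """Classify one patient against a fitted model.

    ``distance='feature'`` (default) uses, per selected feature, the absolute
    difference between the patient's percentile value and each class's median
    value, averaging per-feature probabilities; ``distance='curve'`` uses the
    Euclidean distance over each marker's selected percentile levels (the
    curve-to-curve reading), averaging per-marker probabilities;
    ``distance='scaled'`` uses the sigma-scaled control points (Pbar against
    Rbar/Nbar).
    """
    if convention not in ("proximity", "as-printed"):
        raise ValueError("convention must be 'proximity' or 'as-printed'")
    if distance not in ("feature", "curve", "scaled"):
        raise ValueError("distance must be 'feature', 'curve' or 'scaled'")
    if patient.markers != model.markers or patient.grid != model.grid:
        raise ValueError("patient percentile matrix does not match the model layout")

    def prob_r(d_r: float, d_n: float) -> float:
        if d_r + d_n == 0:
            return 0.5
        if convention == "proximity":
            return d_n / (d_r + d_n)
        return d_r / (d_r + d_n)

    per_feature = {}
    if distance == "feature":
        for j, k in model.selected:
            v = patient.values[j, k]
            per_feature[(j, k)] = prob_r(abs(v - model.mu_r[j, k]),
                                         abs(v - model.mu_n[j, k]))
        probs = list(per_feature.values())
    elif distance == "scaled":
        cps = control_points(model)
        for (j, k), (rbar, nbar) in cps.items():
            pbar = patient_point(patient.values[j, k], model, (j, k))
            per_feature[(j, k)] = prob_r(abs(pbar - rbar), abs(pbar - nbar))
        probs = list(per_feature.values())
    else:
        by_marker: dict[int, list[tuple[int, int]]] = {}
        for j, k in model.selected:
            by_marker.setdefault(j, []).append((j, k))
        probs = []
        for j, feats in by_marker.items():
            v = np.array([patient.values[jj, kk] for jj, kk in feats])
            mu_r = np.array([model.mu_r[jj, kk] for jj, kk in feats])
            mu_n = np.array([model.mu_n[jj, kk] for jj, kk in feats])
            p = prob_r(float(np.linalg.norm(v - mu_r)), float(np.linalg.norm(v - mu_n)))
            probs.append(p)
            for f in feats:
                per_feature[f] = p

    p_relapse = float(np.mean(probs))
    label = "R" if p_relapse > decision_threshold else "N"   # ties -> N
    return Prediction(patient_id=patient.patient_id, p_relapse=p_relapse,
                      label=label, per_feature=per_feature,
                      decision_threshold=decision_threshold)
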