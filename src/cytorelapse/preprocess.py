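"""Per-patient preprocessing of multi-tube cytometry data.

A patient is acquired as several *tubes* (aliquots), each staining a partly
overlapping marker panel that shares a set of *backbone* markers.  This module
turns the per-tube raw matrices into one complete, normalised, CD19-gated,
fixed-size event x marker matrix per patient:

1. spillover compensation (``observed @ S^-1``),
2. logicle transformation to display decades,
3. nearest-neighbour merging of tubes on the backbone markers,
4. per-marker quantile scaling ``x' = (x - q05) / (q95 - q05)`` (clipped to
   [0, 1] by default),
5. density-based CD19+ gating,
6. seeded uniform subsampling to a fixed event count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import gaussian_kde

from .fcs import read_fcs
from .logicle import Logicle, LogicleParams

__all__ = [
    "TubeFrame", "PatientSample", "LogicleParams",
    "read_tube", "compensate", "logicle_transform", "merge_tubes",
    "quantile_scale", "normalise", "gate_cd19", "cd19_threshold", "subsample",
    "common_panel", "preprocess_patient",
]


@dataclass
class TubeFrame:
    """Event x channel matrix of one tube with its acquisition metadata."""

    events: np.ndarray              # (cells, channels)
    channels: list[str]             # detector names
    markers: list[str]              # stain names, aligned with channels
    spillover: np.ndarray | None = None
    tube_id: str = ""
    patient_id: str = ""
    compensated: bool = False
    transformed: bool = False

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=float)
        if self.events.ndim != 2:
            raise ValueError("events must be a 2-D (cells x channels) matrix")
        n_ch = self.events.shape[1]
        if len(self.channels) != n_ch or len(self.markers) != n_ch:
            raise ValueError("channel/marker name count must match event-matrix width")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError(f"duplicate marker names in tube {self.tube_id!r}")
        if self.spillover is not None:
            s = np.asarray(self.spillover, dtype=float)
            if s.shape != (n_ch, n_ch):
                raise ValueError("spillover matrix must be square and match channel count")
            if not np.allclose(np.diag(s), 1.0):
                raise ValueError("spillover matrix must have unit diagonal")
            self.spillover = s

    def marker_column(self, marker: str) -> np.ndarray:
        return self.events[:, self.markers.index(marker)]


@dataclass
class PatientSample:
    """Merged, transformed event x marker matrix for one patient."""

    events: np.ndarray
    markers: list[str]
    patient_id: str = ""
    label: str | None = None        # "R" (relapse) or "N"
    normalised: bool = False
    gated: bool = False
    provenance: dict = field(default_factory=dict)

    def marker_column(self, marker: str) -> np.ndarray:
        return self.events[:, self.markers.index(marker)]


def read_tube(path) -> TubeFrame:
    """Load an FCS 3.0 file into a :class:`TubeFrame`.

    Marker names come from ``$PnS``, falling back to ``$PnN``; a file without
    a spillover keyword gets the identity matrix (with a warning from the
    reader).
    """
    data = read_fcs(path)
    spill = data.spillover
    if spill is None:
        matrix = np.eye(len(data.channels))
    else:
        matrix, det_names = spill
        if det_names != data.channels:
            order = [det_names.index(c) for c in data.channels]
            matrix = matrix[np.ix_(order, order)]
    return TubeFrame(
        events=data.events,
        channels=list(data.channels),
        markers=list(data.markers),
        spillover=matrix,
        tube_id=data.keywords.get("TUBE", data.keywords.get("$SMNO", "")),
        patient_id=data.keywords.get("PATIENT", data.keywords.get("$SRC", "")),
    )


def compensate(tube: TubeFrame) -> TubeFrame:
    """Undo spectral spillover: ``true = observed @ inverse(spillover)``."""
    if tube.compensated:
        raise ValueError(f"tube {tube.tube_id!r} is already compensated")
    s = tube.spillover if tube.spillover is not None else np.eye(tube.events.shape[1])
    try:
        inv = np.linalg.inv(s)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular spillover matrix in tube {tube.tube_id!r}") from exc
    return replace(tube, events=tube.events @ inv, compensated=True)


def logicle_transform(tube: TubeFrame, params: LogicleParams | None = None) -> TubeFrame:
    """Apply the logicle transform channel-wise; output in display decades."""
    if tube.transformed:
        raise ValueError(f"tube {tube.tube_id!r} is already logicle-transformed")
    lg = Logicle(params)
    return replace(tube, events=lg.transform(tube.events), transformed=True)


def _nearest_lowest_index(tree: cKDTree, points: np.ndarray, data: np.ndarray) -> np.ndarray:
    """k=1 nearest neighbour with exact ties broken toward the lowest index."""
    if data.shape[0] == 1:
        return np.zeros(points.shape[0], dtype=int)
    dist, idx = tree.query(points, k=2)
    nearest = idx[:, 0].copy()
    # exact distance ties are resolved by scanning the full tie set
    for i in np.flatnonzero(dist[:, 0] == dist[:, 1]):
        cand = tree.query_ball_point(points[i], r=dist[i, 0] + 1e-300)
        nearest[i] = min(cand)
    return nearest


def merge_tubes(tubes: list[TubeFrame], backbone: list[str]) -> TubeFrame:
    """Merge tubes into one frame by backbone nearest-neighbour imputation.

    The tube with the most markers is the *reference* (ties broken by list
    order); its cells are retained.  Every other tube independently donates
    its tube-specific marker values: each reference cell receives the values
    of its nearest neighbour in backbone-marker space (Euclidean, k=1, ties
    to the lowest donor index).  The output carries the union of all markers
    for every retained cell.
    """
    if len(tubes) < 2:
        raise ValueError("merging requires at least two tubes")
    if not backbone:
        raise ValueError("backbone marker set is empty")
    for t in tubes:
        missing = [m for m in backbone if m not in t.markers]
        if missing:
            raise ValueError(f"tube {t.tube_id!r} lacks backbone markers {missing}")
        if t.events.shape[0] < 1:
            raise ValueError(f"tube {t.tube_id!r} has no events to match against")

    ref = max(tubes, key=lambda t: len(t.markers))  # max is stable: first of ties
    ref_bb = np.column_stack([ref.marker_column(m) for m in backbone])

    merged_markers = list(ref.markers)
    merged_cols = [ref.events[:, i] for i in range(len(ref.markers))]
    for t in tubes:
        if t is ref:
            continue
        donor_bb = np.column_stack([t.marker_column(m) for m in backbone])
        idx = _nearest_lowest_index(cKDTree(donor_bb), ref_bb, donor_bb)
        for m in t.markers:
            if m in merged_markers:
                continue
            merged_markers.append(m)
            merged_cols.append(t.marker_column(m)[idx])
    return TubeFrame(
        events=np.column_stack(merged_cols),
        channels=list(merged_markers),
        markers=merged_markers,
        spillover=None,
        tube_id="merged",
        patient_id=ref.patient_id,
        compensated=ref.compensated,
        transformed=ref.transformed,
    )


def quantile_scale(events: np.ndarray, markers: list[str] | None = None,
                   clip: bool = True) -> np.ndarray:
    """Per-marker robust min-max scaling anchored at the 5th/95th percentiles.

    ``x' = (x - q05) / (q95 - q05)``; by default values are clipped to [0, 1]
    so that downstream percentile curves live on a fixed domain.
    """
    events = np.asarray(events, dtype=float)
    q05 = np.percentile(events, 5, axis=0)
    q95 = np.percentile(events, 95, axis=0)
    span = q95 - q05
    degenerate = np.flatnonzero(span == 0)
    if degenerate.size:
        names = ([markers[i] for i in degenerate] if markers is not None
                 else degenerate.tolist())
        raise ValueError(f"degenerate marker(s) with q05 == q95: {names}")
    scaled = (events - q05) / span
    if clip:
        scaled = np.clip(scaled, 0.0, 1.0)
    return scaled


def normalise(sample: PatientSample, clip: bool = True) -> PatientSample:
    """Quantile-scale a patient sample once; a second application raises."""
    if sample.normalised:
        raise ValueError(
            f"patient {sample.patient_id!r} is already normalised; "
            "re-normalising would recompute quantiles on scaled data"
        )
    events = quantile_scale(sample.events, sample.markers, clip=clip)
    return replace(sample, events=events, normalised=True)


def cd19_threshold(values: np.ndarray, fallback: float | None = None,
                   grid_size: int = 512) -> float:
    """Density-based positivity threshold for a (CD19) marker.

    A Gaussian KDE with Silverman bandwidth is evaluated on a regular grid;
    the threshold is the deepest density minimum between the two largest
    modes.  A unimodal density falls back to ``fallback`` or raises.
    """
    values = np.asarray(values, dtype=float)
    kde = gaussian_kde(values, bw_method="silverman")
    lo, hi = values.min(), values.max()
    pad = 0.05 * (hi - lo + 1e-12)
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.flatnonzero(interior) + 1
    if peaks.size < 2:
        if fallback is not None:
            return float(fallback)
        raise ValueError(
            "marker density is unimodal; supply a manual fallback threshold"
        )
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    left, right = int(top2.min()), int(top2.max())
    valley = left + int(np.argmin(dens[left : right + 1]))
    return float(grid[valley])


def gate_cd19(sample: PatientSample, marker: str = "CD19",
              fallback: float | None = None) -> PatientSample:
    """Retain cells above the density threshold on the CD19 marker."""
    if marker not in sample.markers:
        raise ValueError(f"gating marker {marker!r} not present for patient {sample.patient_id!r}")
    thr = cd19_threshold(sample.marker_column(marker), fallback=fallback)
    keep = sample.marker_column(marker) > thr
    out = replace(sample, events=sample.events[keep], gated=True)
    out.provenance = dict(sample.provenance, cd19_threshold=thr,
                          cells_before_gate=int(sample.events.shape[0]),
                          cells_after_gate=int(keep.sum()))
    return out


def subsample(sample: PatientSample, n: int, seed: int) -> PatientSample:
    """Draw ``n`` cells uniformly without replacement (seeded)."""
    n_cells = sample.events.shape[0]
    if n > n_cells:
        raise ValueError(
            f"patient {sample.patient_id!r} has {n_cells} gated cells, "
            f"fewer than the requested subsample of {n}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(n_cells, size=n, replace=False)
    return replace(sample, events=sample.events[idx])


def common_panel(marker_sets: list[list[str]], min_markers: int = 15) -> list[str]:
    """Intersect per-patient marker sets into the cohort's common panel.

    Mirrors the inclusion rule that every patient must share a minimum number
    of markers with the rest of the cohort.
    """
    if not marker_sets:
        raise ValueError("no marker sets given")
    common = [m for m in marker_sets[0] if all(m in ms for ms in marker_sets)]
    if len(common) < min_markers:
        raise ValueError(
            f"only {len(common)} markers are common to all patients "
            f"(minimum required: {min_markers})"
        )
    return common


def preprocess_patient(tubes: list[TubeFrame], backbone: list[str],
                       logicle_params: LogicleParams | None = None,
                       subsample_n: int | None = 3000, seed: int = 0,
                       clip: bool = True, gate_marker: str = "CD19",
                       gate_fallback: float | None = None,
                       label: str | None = None) -> PatientSample:
    """Full chain: compensate, logicle, merge, normalise, gate, subsample."""
    staged = [logicle_transform(compensate(t), logicle_params) for t in tubes]
    merged = merge_tubes(staged, backbone)
    sample = PatientSample(events=merged.events, markers=merged.markers,
                           patient_id=merged.patient_id, label=label)
    sample = normalise(sample, clip=clip)
    sample = gate_cd19(sample, marker=gate_marker, fallback=gate_fallback)
    if subsample_n is not None:
        sample = subsample(sample, subsample_n, seed)
    sample.provenance["subsample_n"] = subsample_n
    return sample
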