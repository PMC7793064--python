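"""Associations between marker expression and clinical/genetic covariates.

Selected percentiles of a marker (by default CD38 at the 15th, 50th and 85th
levels, standing for low, typical and high expression) are correlated with
the clinical table by the Pearson coefficient, with p-values from the exact
t-transform of r and pairwise complete-case deletion (missing clinical fields
are never imputed).  Binary covariates are encoded 0/1 (relapse = 1,
male = 1, alteration present = 1, one-hot karyotype block), so their Pearson
correlation with a continuous variable is the point-biserial coefficient.
Group contrasts (e.g. CD38 expression by sex) use two-sample t-tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import PercentileMatrix

__all__ = ["read_clinical", "encode_covariates", "CorrelationReport",
           "correlate", "group_difference"]

_KARYOTYPES = ("hyperdiploid", "normal", "hypodiploid")
_FLAG_COLUMNS = ("t_12_21", "t_1_19", "t_4_11", "mll_rearrangement", "t_9_22")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read the per-patient clinical table (CSV, empty fields = missing)."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "label", "age_years", "sex", "karyotype"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table lacks required columns: {sorted(missing)}")
    bad = set(df["karyotype"].dropna()) - set(_KARYOTYPES)
    if bad:
        raise ValueError(f"unknown karyotype categories: {sorted(bad)}")
    return df


def encode_covariates(clinical: pd.DataFrame) -> pd.DataFrame:
    """Numeric 0/1 encoding of the clinical table, indexed by patient.

    Missing fields become NaN and survive into pairwise-complete
    correlations; time to relapse stays missing for non-relapsing patients.
    """
    enc = pd.DataFrame(index=clinical["patient_id"])
    enc["relapse"] = (clinical["label"].to_numpy() == "R").astype(float)
    enc["age_years"] = clinical["age_years"].to_numpy(dtype=float)
    sex = clinical["sex"].astype(object)
    enc["male"] = np.where(sex.isna(), np.nan, (sex == "M").astype(float))
    if "blast_pct" in clinical:
        enc["blast_pct"] = clinical["blast_pct"].to_numpy(dtype=float)
    kary = clinical["karyotype"].astype(object)
    for cat in _KARYOTYPES:
        enc[cat] = np.where(kary.isna(), np.nan, (kary == cat).astype(float))
    for col in _FLAG_COLUMNS:
        if col in clinical:
            enc[col] = clinical[col].to_numpy(dtype=float)
    if "time_to_relapse_months" in clinical:
        enc["time_to_relapse_months"] = clinical["time_to_relapse_months"].to_numpy(dtype=float)
    return enc


def _pearson_with_p(a: np.ndarray, b: np.ndarray, min_pairs: int = 4):
    mask = ~(np.isnan(a) | np.isnan(b))
    if mask.sum() < min_pairs:
        return np.nan, np.nan, int(mask.sum())
    x, y = a[mask], b[mask]
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan, int(mask.sum())
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(mask.sum())


@dataclass
class CorrelationReport:
    """Pairwise Pearson matrix with p-values and complete-case counts."""

    variables: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    alpha_level: float = 0.05

    @property
    def significant(self) -> pd.DataFrame:
        return (self.p < self.alpha_level) & self.p.notna()

    def display_matrix(self) -> pd.DataFrame:
        """Lower triangle: r; upper triangle: p-values; diagonal: 1."""
        out = self.r.copy()
        iu = np.triu_indices(len(self.variables), k=1)
        out.values[iu] = self.p.values[iu]
        np.fill_diagonal(out.values, 1.0)
        return out

    def to_files(self, prefix: str | Path) -> list[Path]:
        prefix = Path(prefix)
        paths = [Path(f"{prefix}_r.csv"), Path(f"{prefix}_p.csv"),
                 Path(f"{prefix}.json")]
        self.r.to_csv(paths[0])
        self.p.to_csv(paths[1])
        payload = {"variables": self.variables, "alpha_level": self.alpha_level,
                   "r": self.r.where(self.r.notna(), None).values.tolist(),
                   "p": self.p.where(self.p.notna(), None).values.tolist(),
                   "n": self.n.values.tolist()}
        paths[2].write_text(json.dumps(payload, indent=1, sort_keys=True))
        return paths

    @classmethod
    def from_json(cls, path: str | Path) -> "CorrelationReport":
        d = json.loads(Path(path).read_text())
        variables = d["variables"]

        def mk(values):
            arr = np.array([[np.nan if v is None else v for v in row] for row in values])
            return pd.DataFrame(arr, index=variables, columns=variables)

        return cls(variables=variables, r=mk(d["r"]), p=mk(d["p"]),
                   n=pd.DataFrame(np.array(d["n"]), index=variables, columns=variables),
                   alpha_level=d["alpha_level"])


def correlate(clinical: pd.DataFrame, percentiles: list[PercentileMatrix],
              marker: str = "CD38", levels=(15, 50, 85),
              alpha_level: float = 0.05) -> CorrelationReport:
    """Pearson correlations of marker percentiles with the clinical table."""
    enc = encode_covariates(clinical)
    for pm in percentiles:
        if marker not in pm.markers:
            raise ValueError(f"patient {pm.patient_id!r} lacks marker {marker!r}")
    by_id = {pm.patient_id: pm for pm in percentiles}
    missing = [pid for pid in enc.index if pid not in by_id]
    if missing:
        raise ValueError(f"no percentile data for patients {missing}")

    table = enc.copy()
    for lev in levels:
        col = []
        for pid in enc.index:
            pm = by_id[pid]
            if float(lev) not in [float(g) for g in pm.grid]:
                raise ValueError(f"percentile level {lev} is not on the grid {pm.grid}")
            k = [float(g) for g in pm.grid].index(float(lev))
            col.append(pm.row(marker)[k])
        table[f"{marker}_P{lev}"] = col

    variables = list(table.columns)
    nv = len(variables)
    r = np.full((nv, nv), np.nan)
    p = np.full((nv, nv), np.nan)
    n = np.zeros((nv, nv), dtype=int)
    arr = table.to_numpy(dtype=float)
    for i in range(nv):
        r[i, i], p[i, i] = 1.0, 0.0
        n[i, i] = int(np.sum(~np.isnan(arr[:, i])))
        for j in range(i + 1, nv):
            rij, pij, nij = _pearson_with_p(arr[:, i], arr[:, j])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
            n[i, j] = n[j, i] = nij
    idx = pd.Index(variables)
    return CorrelationReport(variables=variables,
                             r=pd.DataFrame(r, index=idx, columns=idx),
                             p=pd.DataFrame(p, index=idx, columns=idx),
                             n=pd.DataFrame(n, index=idx, columns=idx),
                             alpha_level=alpha_level)


def group_difference(values: np.ndarray, groups: np.ndarray,
                     welch_fallback: bool = False) -> dict[str, float]:
    """Two-sample t-test of a percentile level between two covariate groups.

    ``groups`` holds exactly two distinct group codes (e.g. "F"/"M").  A
    group of a single patient has no variance estimate; by default this is an
    error, with ``welch_fallback`` the test degrades to Welch's form (which
    still requires two values per group to be defined).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    mask = ~np.isnan(values)
    values, groups = values[mask], groups[mask]
    names = sorted(set(groups.tolist()))
    if len(names) != 2:
        raise ValueError(f"need exactly two groups, got {names}")
    a = values[groups == names[0]]
    b = values[groups == names[1]]
    if min(len(a), len(b)) < 2:
        if not welch_fallback:
            raise ValueError(
                f"group sizes {len(a)}/{len(b)}: a single-patient group has no "
                "variance estimate (set welch_fallback=True to attempt Welch)"
            )
    t, p = stats.ttest_ind(a, b, equal_var=not welch_fallback)
    return {"group_a": names[0], "group_b": names[1],
            "mean_a": float(a.mean()), "mean_b": float(b.mean()),
            "n_a": int(len(a)), "n_b": int(len(b)),
            "t": float(t), "p": float(p)}
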