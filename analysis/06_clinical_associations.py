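"""Correlate CD38 expression percentiles with clinical/genetic covariates.

Reads results/percentiles.csv and the cohort's clinical table, computes the
pairwise Pearson matrix over CD38 P15/P50/P85 and the encoded covariates
(pairwise complete cases), and contrasts CD38 P50 between the sexes.
Writes results/associations_{r,p}.csv and results/associations_matrix.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from cytorelapse import associate, pipeline
from cytorelapse.profiles import PercentileMatrix

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    pct_path = ROOT / "results" / "percentiles.csv"
    clin_path = ROOT / "scratch" / "cohort" / "clinical.csv"
    if not pct_path.exists() or not clin_path.exists():
        raise SystemExit("run analysis/01 and analysis/02 first")
    cfg = pipeline.load_config(ROOT / "analysis" / "config.yaml")
    pms = PercentileMatrix.from_frame(pd.read_csv(pct_path))
    clinical = associate.read_clinical(clin_path)

    acfg = cfg["associate"]
    report = associate.correlate(clinical, pms, marker=acfg["marker"],
                                 levels=tuple(acfg["levels"]))
    report.to_files(ROOT / "results" / "associations")
    report.display_matrix().to_csv(ROOT / "results" / "associations_matrix.csv")

    marker = acfg["marker"]
    print(f"significant correlations (p<0.05) involving {marker} percentiles:")
    for var in report.variables:
        for lev in acfg["levels"]:
            col = f"{marker}_P{lev}"
            if var.startswith(marker) or col == var:
                continue
            if report.significant.loc[col, var]:
                print(f"  {col} vs {var}: r={report.r.loc[col, var]:+.2f} "
                      f"(p={report.p.loc[col, var]:.3f}, "
                      f"n={report.n.loc[col, var]})")

    p50 = {pm.patient_id: pm.row(marker)[list(pm.grid).index(50.0)] for pm in pms}
    values = np.array([p50[pid] for pid in clinical["patient_id"]])
    out = associate.group_difference(values, clinical["sex"].to_numpy())
    print(f"{marker} P50 by sex: F mean {out['mean_a']:.3f} vs "
          f"M mean {out['mean_b']:.3f} (t={out['t']:+.2f}, p={out['p']:.3f})")


if __name__ == "__main__":
    main()
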