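"""Cross-validated performance, feature frequency and the RF comparison.

Reads results/percentiles.csv and writes:
  results/performance.csv            scheme x metric (mean +/- sd)
  results/feature_frequency.csv      marker usage over 100 random 75:25 splits
  results/random_forest.csv          OOB error and marker-level importance
"""

from pathlib import Path

import pandas as pd

from cytorelapse import pipeline, validate
from cytorelapse.profiles import PercentileMatrix

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    pct_path = ROOT / "results" / "percentiles.csv"
    if not pct_path.exists():
        raise SystemExit("no percentile table; run analysis/02_preprocess.py first")
    cfg = pipeline.load_config(ROOT / "analysis" / "config.yaml")
    pms = PercentileMatrix.from_frame(pd.read_csv(pct_path))
    fcfg, vcfg = cfg["fisher"], cfg["validate"]

    rows = []
    for scheme_cfg in vcfg["schemes"]:
        report = validate.cross_validate(
            pms, scheme=scheme_cfg["scheme"], k=scheme_cfg.get("k"),
            repeats=int(vcfg["repeats"]), seed=int(cfg["seed"]),
            threshold=float(fcfg["threshold"]), location=fcfg["location"],
            convention=fcfg["convention"], distance=fcfg["distance"])
        rows.append(report.summary_row())
        print(f"{rows[-1]['method']:>7}: accuracy {rows[-1]['accuracy']}, "
              f"AUC {rows[-1]['auc']}")
    pd.DataFrame(rows).to_csv(ROOT / "results" / "performance.csv", index=False)

    ff = validate.feature_frequency(pms, n_splits=int(vcfg["n_splits"]),
                                    seed=int(cfg["seed"]))
    freq = pd.DataFrame(ff.tables).rename_axis("marker")
    freq.to_csv(ROOT / "results" / "feature_frequency.csv")
    always = freq[freq[0.0] >= 0.99].index.tolist()
    print(f"markers used in (almost) every split classifier: {always}")

    rf = validate.random_forest_comparison(
        pms, n_runs=int(vcfg["rf"]["n_runs"]), n_trees=int(vcfg["rf"]["n_trees"]),
        seed=int(cfg["seed"]))
    rf.importance.to_csv(ROOT / "results" / "random_forest.csv")
    print(f"random forest: mean OOB error {rf.mean_oob_error:.3f} "
          f"± {rf.sd_oob_error:.3f}; top marker by permutation importance: "
          f"{rf.importance['importance_mean'].idxmax()}")


if __name__ == "__main__":
    main()
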