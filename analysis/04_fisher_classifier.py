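"""Fisher's-Ratio feature selection and the full-cohort classifier model.

Reads results/percentiles.csv (run 02_preprocess.py first), computes the
M x P Fisher's-Ratio matrix, selects discriminant (marker, percentile)
features at FR > 0.5, and writes the FR matrix and the serialised model.
"""

from pathlib import Path

import pandas as pd

from cytorelapse import pipeline
from cytorelapse.fisher import fisher_matrix
from cytorelapse.profiles import PercentileMatrix

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    pct_path = ROOT / "results" / "percentiles.csv"
    if not pct_path.exists():
        raise SystemExit("no percentile table; run analysis/02_preprocess.py first")
    cfg = pipeline.load_config(ROOT / "analysis" / "config.yaml")
    pms = PercentileMatrix.from_frame(pd.read_csv(pct_path))

    model = fisher_matrix(pms, threshold=float(cfg["fisher"]["threshold"]),
                          location=cfg["fisher"]["location"])
    pd.DataFrame(model.fr, index=model.markers,
                 columns=list(model.grid)).to_csv(ROOT / "results" / "fisher_matrix.csv")
    model.to_json(ROOT / "results" / "fisher_model.json")

    mfr = model.marker_level_fr()
    top = sorted(mfr.items(), key=lambda kv: -(kv[1] if kv[1] == kv[1] else -1))[:5]
    print("marker-level FR (mean over percentiles), top five:")
    for marker, value in top:
        print(f"  {marker:>7}: {value:.3f}")
    print(f"{len(model.selected)} features selected at FR > {model.threshold}: "
          f"markers {model.selected_markers}")


if __name__ == "__main__":
    main()
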