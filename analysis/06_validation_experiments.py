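"""Statistical validation: null calibration, recovery, promoter-vs-CpG.

Runs the three study-scale experiments (the same entry points the
acceptance checks use) and writes their summary to
results/validation_summary.json.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS

from promclock.experiments import (
    null_calibration,
    promoter_vs_cpg_benchmark,
    recovery_experiment,
)


def main() -> None:
    null = null_calibration(list(range(1, 21)))
    rec = recovery_experiment(seed=1)
    bench = promoter_vs_cpg_benchmark(list(range(1, 21)))
    summary = {
        "null_screen": {
            "mean_kept_fraction": round(null["mean_kept_fraction"], 4),
            "alpha": null["alpha"],
        },
        "recovery": {
            "causal_retention": rec.causal_retention,
            "test_r2_pearson_sq": round(rec.test_r2_pearson_sq, 3),
            "test_mae_years": round(rec.test_mae_years, 2),
            "causal_in_top10_importance": rec.causal_in_top10_shap,
        },
        "promoter_vs_cpg": {
            "promoter_wins": bench["promoter_wins"],
            "replicates": bench["n_replicates"],
            "mean_promoter_r2": round(bench["mean_promoter_r2"], 3),
            "mean_cpg_r2": round(bench["mean_site_r2"], 3),
        },
    }
    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "validation_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    print(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
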