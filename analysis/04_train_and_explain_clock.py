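"""Train, evaluate and explain the elastic-net age clock per cohort.

Uses a seeded 70/30 train/test split, fits the clock on cascade-selected
promoters plus sex and PMI, reports withheld-set accuracy (squared Pearson
R^2, coefficient of determination, MAE), exports the re-importable
coefficient table, ranks features by mean |Shapley attribution| and extracts
the deduplicated age-gene list.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import COHORTS, RESULTS, load_cohort

import promclock as pc
from promclock.selection import CascadeConfig

SEED = 42


def main() -> None:
    rows = []
    for name in COHORTS:
        _, _, pm, cov = load_cohort(name)
        selected, report = pc.run_cascade(pm, cov, CascadeConfig())
        train_ids, test_ids = pc.split_samples(pm.sample_ids, 0.7, SEED)
        model = pc.fit_clock(
            selected.subset_samples(train_ids), cov.subset(train_ids), seed=SEED
        )
        preds = pc.predict(model, selected.subset_samples(test_ids), cov.subset(test_ids))
        ev = pc.evaluate(preds, cov.data.loc[test_ids, "age"])
        imp = pc.attribute(model, selected.subset_samples(test_ids), cov.subset(test_ids))
        gene_map = dict(zip(selected.promoter_ids, selected.genes))
        genes = pc.extract_age_genes(model, report, gene_map, p_max=0.05)
        pc.export_coefficients(model, RESULTS / f"clock_coefficients_{name}.tsv")
        imp.mean_abs.head(20).rename("mean_abs_attribution_years").to_csv(
            RESULTS / f"top_importance_{name}.tsv", sep="\t"
        )
        ev.predictions.to_csv(RESULTS / f"predictions_{name}.tsv", sep="\t")
        rows.append(
            {
                "cohort": name,
                "n_train": len(train_ids),
                "n_test": len(test_ids),
                "features_in": selected.n_promoters + 2,
                "contributing": len(model.contributing_features()),
                "r2_pearson_sq": round(ev.r2_pearson_sq, 3),
                "r2_cod": round(ev.r2_cod, 3),
                "mae_years": round(ev.mae, 2),
                "age_genes": len(genes),
            }
        )
        print(f"{name}: test R^2 = {ev.r2_pearson_sq:.3f}, MAE = {ev.mae:.2f} y, "
              f"{len(genes)} age genes")
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "clock_metrics.tsv", sep="\t", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
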