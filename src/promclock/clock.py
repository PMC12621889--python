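"""Elastic-net age clock: training, tuning, evaluation, attribution, export.

The clock is an elastic-net linear regression of chronological age on
standardized promoter mean-methylation features plus sex and PMI. The
objective is

    (1/2n) * ||y - X beta||^2 + lam * (a_mix * ||beta||_1 + (1 - a_mix)/2 * ||beta||_2^2)

with the mixing parameter ``a_mix`` in [0, 1] (1 = lasso, 0 = ridge) and
penalty ``lam`` chosen by k-fold cross-validation over a log-spaced penalty
path, ties broken toward the larger penalty (the sparser model).

Feature attributions follow the Shapley convention for linear models with
independent features: attribution(i, j) = beta_j * (x_ij - mean_j) / sd_j
with the training-set feature means as background, so attributions sum to
the prediction minus the intercept (local accuracy).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet, enet_path
from sklearn.model_selection import KFold

from promclock.features import PromoterMatrix
from promclock.io import CovariateTable
from promclock.selection import SelectionReport


@dataclass
class TuningConfig:
    """Hyperparameter search grid for the elastic net."""

    l1_ratios: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)
    n_lambdas: int = 50
    lambda_min_ratio: float = 1e-3
    cv_folds: int = 5


@dataclass
class ClockModel:
    """A fitted elastic-net age clock.

    Prediction is affine: ``intercept + sum_j beta_j * (x_j - mean_j) / sd_j``
    where betas are on the standardized-feature scale (years per SD) and
    (mean, sd) are the training-set scaling statistics.
    """

    intercept: float
    betas: dict[str, float]
    scaling: dict[str, tuple[float, float]]  # feature -> (mean, sd)
    l1_ratio: float = 1.0
    lam: float = 0.0
    metadata: dict = field(default_factory=dict)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.betas)

    def contributing_features(self) -> list[str]:
        """Features with |beta| > 0 — the set that defines the clock."""
        return [f for f, b in self.betas.items() if abs(b) > 0]

    def validate(self) -> None:
        missing = set(self.betas) - set(self.scaling)
        if missing:
            raise ValueError(f"betas without scaling entries: {sorted(missing)}")


@dataclass
class EvaluationReport:
    """Test-set accuracy of a clock.

    ``r2_pearson_sq`` (the headline R^2) is the squared Pearson correlation
    of predicted vs reported age; ``r2_cod`` is the coefficient of
    determination 1 - SSres/SStot; ``mae`` is in years.
    """

    r2_pearson_sq: float
    r2_cod: float
    mae: float
    predictions: pd.DataFrame  # index sample_id; columns predicted, reported


@dataclass
class ImportanceTable:
    """Per-sample, per-feature Shapley attributions (years) for a linear clock."""

    attributions: pd.DataFrame  # samples x features, signed, in years
    base_value: float  # prediction at the training-mean background
    mean_abs: pd.Series  # per-feature mean |attribution|, descending


def split_samples(
    sample_ids: Sequence[str], train_frac: float = 0.7, seed: int = 42
) -> tuple[list[str], list[str]]:
    """Reproducible disjoint, exhaustive train/test split.

    ``floor(n * train_frac)`` samples go to training. Requires n >= 10.
    """
    ids = list(sample_ids)
    n = len(ids)
    if n < 10:
        raise ValueError(f"need >= 10 samples to split, got {n}")
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(n * train_frac))
    train = sorted(ids[i] for i in perm[:n_train])
    test = sorted(ids[i] for i in perm[n_train:])
    return train, test


def design_frame(pm: PromoterMatrix, cov: CovariateTable) -> pd.DataFrame:
    """Feature frame for the clock: promoter columns plus sex and PMI."""
    df = pm.to_frame()
    covd = cov.data.loc[pm.sample_ids]
    df["sex"] = covd["sex"].to_numpy(dtype=float)
    df["pmi"] = covd["pmi"].to_numpy(dtype=float)
    return df


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)  # constant columns standardize to 0
    return (x - mean) / sd_safe, mean, sd_safe


def fit_clock(
    features: PromoterMatrix | pd.DataFrame,
    cov: CovariateTable | None = None,
    tuning: TuningConfig | None = None,
    seed: int = 42,
    train_frac: float | None = None,
) -> ClockModel:
    """Fit an elastic-net age clock on training samples.

    ``features`` is either a PromoterMatrix (sex and PMI are appended from
    ``cov``) or a ready feature DataFrame indexed by sample id; ``cov`` must
    then still provide ages. Columns are standardized by training statistics
    (the munge step); the penalty and mixing parameter are tuned by k-fold
    CV minimizing MSE, ties broken toward larger penalty then larger L1 share.
    """
    tuning = tuning or TuningConfig()
    if isinstance(features, PromoterMatrix):
        if cov is None:
            raise ValueError("cov required with a PromoterMatrix")
        df = design_frame(features, cov)
    else:
        df = features.copy()
    if cov is None:
        raise ValueError("cov required (provides ages)")
    y = cov.data.loc[df.index, "age"].to_numpy(dtype=float)
    n = len(df)
    if n < tuning.cv_folds:
        raise ValueError(
            f"{n} training samples < {tuning.cv_folds} CV folds"
        )
    x_raw = df.to_numpy(dtype=float)
    z, mean, sd = _standardize(x_raw)
    y_mean = y.mean()
    yc = y - y_mean

    # penalty path: from the smallest penalty that zeroes all coefficients
    # down three decades, shared logic per l1_ratio
    best = None  # (mse, -lam, -l1_ratio) minimized lexicographically
    kf = KFold(n_splits=tuning.cv_folds, shuffle=True, random_state=seed)
    folds = list(kf.split(z))
    for l1_ratio in tuning.l1_ratios:
        alpha_max = np.max(np.abs(z.T @ yc)) / (n * max(l1_ratio, 1e-3))
        alphas = np.logspace(
            np.log10(alpha_max),
            np.log10(alpha_max * tuning.lambda_min_ratio),
            tuning.n_lambdas,
        )
        sse = np.zeros(len(alphas))
        for tr, va in folds:
            ytr = yc[tr] - yc[tr].mean()
            _, coefs, _ = enet_path(
                z[tr], ytr, l1_ratio=l1_ratio, alphas=alphas, max_iter=5000
            )
            pred = z[va] @ coefs + (yc[tr].mean() + y_mean)
            sse += ((pred - (yc[va] + y_mean)[:, None]) ** 2).sum(axis=0)
        mse = sse / n
        for ai, lam in enumerate(alphas):
            key = (round(float(mse[ai]), 12), -lam, -l1_ratio)
            if best is None or key < best[0]:
                best = (key, l1_ratio, float(lam))
    _, l1_ratio, lam = best
    model = ElasticNet(alpha=lam, l1_ratio=l1_ratio, max_iter=50000, tol=1e-8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(z, y)
    clock = ClockModel(
        intercept=float(model.intercept_),
        betas={f: float(b) for f, b in zip(df.columns, model.coef_)},
        scaling={f: (float(m), float(s)) for f, m, s in zip(df.columns, mean, sd)},
        l1_ratio=l1_ratio,
        lam=lam,
        metadata={
            "seed": int(seed),
            "n_train": int(n),
            "cv_folds": tuning.cv_folds,
            "train_frac": train_frac,
        },
    )
    clock.validate()
    return clock


def predict(
    model: ClockModel,
    features: PromoterMatrix | pd.DataFrame,
    cov: CovariateTable | None = None,
) -> pd.Series:
    """Predicted ages for new samples (affine in the standardized features)."""
    if isinstance(features, PromoterMatrix):
        if cov is None:
            raise ValueError("cov required with a PromoterMatrix")
        df = design_frame(features, cov)
    else:
        df = features
    missing = [f for f in model.betas if f not in df.columns]
    if missing:
        raise ValueError(f"features missing from input: {missing}")
    extra = [c for c in df.columns if c not in model.betas]
    if extra:
        warnings.warn(f"ignoring {len(extra)} feature(s) unseen at training", stacklevel=2)
    feats = list(model.betas)
    x = df[feats].to_numpy(dtype=float)
    mean = np.array([model.scaling[f][0] for f in feats])
    sd = np.array([model.scaling[f][1] for f in feats])
    beta = np.array([model.betas[f] for f in feats])
    pred = model.intercept + ((x - mean) / sd) @ beta
    return pd.Series(pred, index=df.index, name="predicted_age")


def evaluate(predictions: pd.Series, reported: pd.Series) -> EvaluationReport:
    """Accuracy of predicted vs reported age on withheld samples."""
    reported = reported.loc[predictions.index]
    if len(predictions) < 3:
        raise ValueError("need >= 3 samples to evaluate")
    y = reported.to_numpy(dtype=float)
    p = predictions.to_numpy(dtype=float)
    if np.var(y) == 0:
        raise ValueError("zero variance in reported ages")
    if np.var(p) == 0:
        r = 0.0
    else:
        r = float(stats.pearsonr(p, y).statistic)
    ss_res = float(((y - p) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return EvaluationReport(
        r2_pearson_sq=r**2,
        r2_cod=1.0 - ss_res / ss_tot,
        mae=float(np.abs(y - p).mean()),
        predictions=pd.DataFrame(
            {"predicted": p, "reported": y}, index=predictions.index
        ),
    )


def attribute(
    model: ClockModel,
    features: PromoterMatrix | pd.DataFrame,
    cov: CovariateTable | None = None,
) -> ImportanceTable:
    """Shapley attributions of each prediction to each feature, in years.

    For a linear model with the independent-features convention the exact
    Shapley value of feature j for sample i is
    ``beta_j * (x_ij - mean_j) / sd_j`` against the training-mean background;
    the base value is the intercept and attributions satisfy local accuracy.
    Features are ranked by mean absolute attribution.
    """
    if isinstance(features, PromoterMatrix):
        if cov is None:
            raise ValueError("cov required with a PromoterMatrix")
        df = design_frame(features, cov)
    else:
        df = features
    feats = list(model.betas)
    x = df[feats].to_numpy(dtype=float)
    mean = np.array([model.scaling[f][0] for f in feats])
    sd = np.array([model.scaling[f][1] for f in feats])
    beta = np.array([model.betas[f] for f in feats])
    attr = ((x - mean) / sd) * beta
    table = pd.DataFrame(attr, index=df.index, columns=feats)
    mean_abs = table.abs().mean(axis=0).sort_values(ascending=False)
    return ImportanceTable(
        attributions=table, base_value=model.intercept, mean_abs=mean_abs
    )


def extract_age_genes(
    model: ClockModel,
    report: SelectionReport,
    gene_map: dict[str, str],
    p_max: float = 0.05,
) -> list[str]:
    """Genes that both contribute to the clock and associate with age.

    A promoter qualifies when its clock coefficient is nonzero (|beta| > 0)
    and its screen p-value is below ``p_max``. Genes hit by several
    qualifying promoters are included only once, ordered by their most
    significant promoter.
    """
    screen = report.table[report.table["stage"] == "screen"].set_index("promoter_id")
    genes: list[str] = []
    seen: set[str] = set()
    qualifying = []
    for pid, beta in model.betas.items():
        if pid not in screen.index or abs(beta) == 0:
            continue
        p = screen.loc[pid, "p"]
        if pd.notna(p) and p < p_max:
            qualifying.append((float(p), pid))
    for _, pid in sorted(qualifying):
        gene = gene_map.get(pid)
        if gene and gene not in seen:
            seen.add(gene)
            genes.append(gene)
    return genes


def export_coefficients(model: ClockModel, path: str | Path) -> None:
    """Write the clock as a TSV of per-feature coefficients plus an intercept row.

    Columns: feature_id, beta_std (years per SD), beta_raw (years per raw
    unit = beta_std / sd), mean, sd. Re-importable to an identical predictor.
    """
    if not model.betas:
        raise ValueError("model has no fitted coefficients")
    rows = [
        {
            "feature_id": f,
            "beta_std": repr(model.betas[f]),
            "beta_raw": repr(model.betas[f] / model.scaling[f][1]),
            "mean": repr(model.scaling[f][0]),
            "sd": repr(model.scaling[f][1]),
        }
        for f in model.betas
    ]
    rows.append(
        {
            "feature_id": "(intercept)",
            "beta_std": repr(model.intercept),
            "beta_raw": repr(model.intercept),
            "mean": "0",
            "sd": "1",
        }
    )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def import_coefficients(path: str | Path) -> ClockModel:
    """Rebuild a predictor from an exported coefficient table."""
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str})
    inter = df[df["feature_id"] == "(intercept)"]
    if len(inter) != 1:
        raise ValueError("coefficient table must contain exactly one intercept row")
    feats = df[df["feature_id"] != "(intercept)"]
    model = ClockModel(
        intercept=float(inter["beta_std"].iloc[0]),
        betas={r.feature_id: float(r.beta_std) for r in feats.itertuples()},
        scaling={r.feature_id: (float(r.mean), float(r.sd)) for r in feats.itertuples()},
    )
    model.validate()
    return model


def save_model(model: ClockModel, path: str | Path) -> None:
    """Persist the full model (coefficients, scaling, tuning, metadata) as JSON."""
    payload = {
        "intercept": model.intercept,
        "betas": model.betas,
        "scaling": {f: list(v) for f, v in model.scaling.items()},
        "l1_ratio": model.l1_ratio,
        "lam": model.lam,
        "metadata": model.metadata,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path: str | Path) -> ClockModel:
    with open(path) as fh:
        payload = json.load(fh)
    model = ClockModel(
        intercept=payload["intercept"],
        betas=payload["betas"],
        scaling={f: tuple(v) for f, v in payload["scaling"].items()},
        l1_ratio=payload["l1_ratio"],
        lam=payload["lam"],
        metadata=payload.get("metadata", {}),
    )
    model.validate()
    return model
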