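"""Three-stage promoter selection cascade.

1. Methylation principal components are computed from the column-standardized
   promoter matrix (they later adjust the association screen).
2. Redundant promoters are pruned greedily within batches of consecutive
   promoters: a promoter is dropped when an earlier still-kept promoter in
   the same batch correlates with it at Pearson r above the threshold.
3. Age is regressed on each surviving promoter individually, adjusted for
   sex, PMI and the first k methylation PCs (OLS); promoters with a two-sided
   p-value below alpha on the promoter coefficient are kept.

The cascade is deterministic given the input ordering and configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from promclock.features import PromoterMatrix
from promclock.io import CovariateTable


@dataclass
class PCScores:
    """Principal-component scores of the promoter methylation matrix."""

    sample_ids: list[str]
    scores: np.ndarray  # samples x k, centered
    explained_variance: np.ndarray  # length k, non-increasing


@dataclass
class CascadeConfig:
    r_max: float = 0.9
    batch_size: int = 1000
    alpha: float = 0.05
    k_pcs: int = 20


@dataclass
class SelectionReport:
    """Per-promoter fate through the cascade.

    ``table`` has one row per input promoter with columns: promoter_id,
    batch, stage (prune | screen), kept, reason, beta, p.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def kept_ids(self) -> list[str]:
        return self.table.loc[self.table["kept"], "promoter_id"].tolist()


def compute_pcs(pm: PromoterMatrix, k: int = 20) -> PCScores:
    """PCA of the column-standardized promoter matrix.

    Constant columns are dropped from the PCA with a warning; if the sample
    count cannot support k components, k is reduced with a warning.
    """
    x = pm.values
    sd = x.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant promoter column(s) dropped from PCA",
            stacklevel=2,
        )
        x = x[:, ~constant]
        sd = sd[~constant]
    z = (x - x.mean(axis=0)) / sd
    max_k = min(pm.n_samples - 1, z.shape[1])
    if k > max_k:
        warnings.warn(f"k_pcs reduced from {k} to {max_k} (rank bound)", stacklevel=2)
        k = max_k
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(z)
    return PCScores(
        sample_ids=list(pm.sample_ids),
        scores=scores,
        explained_variance=pca.explained_variance_,
    )


def _batch_correlation(x: np.ndarray) -> np.ndarray:
    """Pearson correlation between columns; NaN-aware, zero-variance -> r = 0.

    Columns with fewer than 3 pairwise-complete observations against a
    partner get r = 0 for that pair (never pruned on that evidence).
    """
    if np.isnan(x).any():
        c = pd.DataFrame(x).corr(min_periods=3).to_numpy()
        c[np.isnan(c)] = 0.0
        return c
    sd = x.std(axis=0)
    z = np.zeros_like(x)
    ok = sd > 0
    z[:, ok] = (x[:, ok] - x[:, ok].mean(axis=0)) / sd[ok]
    c = z.T @ z / x.shape[0]
    c[~ok, :] = 0.0
    c[:, ~ok] = 0.0
    return c


def prune_correlated(
    pm: PromoterMatrix, r_max: float = 0.9, batch_size: int = 1000
) -> tuple[list[str], pd.DataFrame]:
    """Greedy keep-first pruning of correlated promoters within batches.

    Promoters are scanned in their (genomic) order, split into batches of
    ``batch_size`` consecutive promoters; promoter j is dropped iff some
    earlier still-kept promoter i in the same batch has r(i, j) > ``r_max``
    (strict). Cross-batch pairs are never compared. Correlations use
    pairwise-complete non-imputed values; zero-variance promoters are treated
    as r = 0 everywhere (never pruned for correlation).
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    values = pm.values.astype(float).copy()
    if pm.imputed is not None and pm.imputed.any():
        values[pm.imputed] = np.nan
    n_p = pm.n_promoters
    kept_ids: list[str] = []
    rows = []
    for b0 in range(0, n_p, batch_size):
        idx = np.arange(b0, min(b0 + batch_size, n_p))
        corr = _batch_correlation(values[:, idx])
        kept_local: list[int] = []
        for jj, j in enumerate(idx):
            culprit = None
            for ii in kept_local:
                if corr[ii, jj] > r_max:
                    culprit = pm.promoter_ids[idx[ii]]
                    break
            if culprit is None:
                kept_local.append(jj)
                kept_ids.append(pm.promoter_ids[j])
                rows.append((pm.promoter_ids[j], b0 // batch_size, True, ""))
            else:
                rows.append(
                    (pm.promoter_ids[j], b0 // batch_size, False, f"correlated-with:{culprit}")
                )
    report = pd.DataFrame(rows, columns=["promoter_id", "batch", "kept", "reason"])
    report["stage"] = "prune"
    return kept_ids, report


def age_screen(
    pm: PromoterMatrix,
    cov: CovariateTable,
    pcs: PCScores,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Covariate-adjusted OLS association screen of age on each promoter.

    For each promoter the model is
    ``age ~ intercept + promoter + sex + pmi + PC1..PCk``; the two-sided
    t-test p-value on the promoter coefficient decides retention (p < alpha).
    Implemented by residualizing age and every promoter on the adjustment
    design (Frisch–Waugh–Lovell), which gives coefficients, standard errors
    and p-values identical to the full per-promoter OLS fits.

    Returns a table with promoter_id, kept, reason, beta, p.
    """
    covd = cov.data.loc[pm.sample_ids]
    y = covd["age"].to_numpy(dtype=float)
    z = np.column_stack(
        [
            np.ones(pm.n_samples),
            covd["sex"].to_numpy(dtype=float),
            covd["pmi"].to_numpy(dtype=float),
            pcs.scores,
        ]
    )
    q = np.linalg.matrix_rank(z)
    # residualize via least squares (handles collinear adjustment columns)
    zt_pinv = np.linalg.pinv(z)
    y_r = y - z @ (zt_pinv @ y)
    x = pm.values
    x_r = x - z @ (zt_pinv @ x)
    sxx = np.einsum("ij,ij->j", x_r, x_r)
    sxy = x_r.T @ y_r
    dof = pm.n_samples - q - 1
    if dof < 1:
        raise ValueError("not enough samples for the adjusted screen")
    # promoters numerically inside the span of the adjustment design are
    # rank-deficient: flagged and excluded
    scale = np.einsum("ij,ij->j", x, x)
    degenerate = sxx <= 1e-10 * np.maximum(scale, 1.0)
    beta = np.full(pm.n_promoters, np.nan)
    pval = np.full(pm.n_promoters, np.nan)
    ok = ~degenerate
    beta[ok] = sxy[ok] / sxx[ok]
    rss = np.maximum(y_r @ y_r - beta[ok] ** 2 * sxx[ok], 0.0)
    se = np.sqrt(rss / dof / sxx[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[ok] / se, np.inf * np.sign(beta[ok]))
    pval[ok] = 2.0 * stats.t.sf(np.abs(t), dof)
    kept = ok & (pval < alpha)
    reason = np.where(
        degenerate, "rank-deficient", np.where(kept, "", "p>=alpha")
    )
    out = pd.DataFrame(
        {
            "promoter_id": pm.promoter_ids,
            "kept": kept,
            "reason": reason,
            "beta": beta,
            "p": pval,
        }
    )
    out["stage"] = "screen"
    return out


def run_cascade(
    pm: PromoterMatrix,
    cov: CovariateTable,
    config: CascadeConfig | None = None,
    fit_sample_ids: list[str] | None = None,
) -> tuple[PromoterMatrix, SelectionReport]:
    """Run PCs -> correlation pruning -> age screen and assemble the report.

    ``fit_sample_ids`` restricts the statistics driving selection (PCs,
    correlations, screen) to a subset of samples — the leakage-safe mode;
    by default the whole cohort is used, matching the published procedure.
    The returned matrix always covers all samples, restricted to surviving
    promoters.
    """
    config = config or CascadeConfig()
    fit_pm = pm
    fit_cov = cov
    if fit_sample_ids is not None:
        idx = [pm.sample_ids.index(s) for s in fit_sample_ids]
        fit_pm = PromoterMatrix(
            promoter_ids=list(pm.promoter_ids),
            sample_ids=list(fit_sample_ids),
            values=pm.values[idx],
            n_cpgs=pm.n_cpgs,
            genes=list(pm.genes),
            imputed=pm.imputed[idx] if pm.imputed is not None else None,
            order=pm.order,
        )
        fit_cov = cov.subset(fit_sample_ids)
    # the screen design is intercept + promoter + sex + pmi + k PCs; keep at
    # least ~6 residual degrees of freedom on small cohorts
    k = min(config.k_pcs, max(1, fit_pm.n_samples - 10))
    if k < config.k_pcs:
        warnings.warn(
            f"k_pcs reduced from {config.k_pcs} to {k} to preserve screen "
            "degrees of freedom",
            stacklevel=2,
        )
    pcs = compute_pcs(fit_pm, k)
    kept_ids, prune_rows = prune_correlated(fit_pm, config.r_max, config.batch_size)
    pruned_pm = fit_pm.subset_promoters(kept_ids)
    screen_rows = age_screen(pruned_pm, fit_cov, pcs, config.alpha)
    batch_of = dict(zip(prune_rows["promoter_id"], prune_rows["batch"]))
    screen_rows["batch"] = screen_rows["promoter_id"].map(batch_of)
    dropped = prune_rows[~prune_rows["kept"]].assign(beta=np.nan, p=np.nan)
    table = pd.concat([dropped, screen_rows], ignore_index=True)[
        ["promoter_id", "batch", "stage", "kept", "reason", "beta", "p"]
    ]
    order = {p: i for i, p in enumerate(pm.promoter_ids)}
    table = table.sort_values("promoter_id", key=lambda s: s.map(order)).reset_index(
        drop=True
    )
    survivors = screen_rows.loc[screen_rows["kept"], "promoter_id"].tolist()
    if not survivors:
        raise ValueError("no promoter survives the cascade")
    return pm.subset_promoters(survivors), SelectionReport(table=table)
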