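"""Tumor-vs-normal Z scoring, outlier-gene filtering, hierarchical clustering
with clinical association, and disease-free-survival screening.

The Z transform standardizes each tumor's expression against the mean and SD
of the normal samples, gene by gene. Genes "altered by more than +/-z in
more than f of tumors" (both strict) form the outlier panel that feeds
clustering and the survival screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import chi2_contingency

from .stats import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class ZMatrix:
    """Gene x tumor Z scores relative to the normal reference.

    Genes whose normal-sample SD is zero are excluded from ``z`` and listed
    in ``flagged_genes``.
    """

    z: pd.DataFrame
    flagged_genes: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class OutlierFilterParams:
    z_abs_min: float = 2.0
    tumor_fraction_min: float = 0.35

    def __post_init__(self) -> None:
        if self.z_abs_min <= 0 or self.tumor_fraction_min <= 0:
            raise ValueError("thresholds must be > 0")


def tumor_normal_z(expr: pd.DataFrame, clinical: pd.DataFrame) -> ZMatrix:
    """Z[g, s] = (expr[g, s] - mean_normals(g)) / sd_normals(g), tumors only."""
    tumors = clinical.loc[clinical["role"] == "tumor", "sample"].tolist()
    normals = clinical.loc[clinical["role"] == "normal", "sample"].tolist()
    if len(normals) < 2:
        raise ValueError("at least 2 normal samples are required for the Z reference")
    nx = expr[normals].to_numpy(dtype=float)
    mu = nx.mean(axis=1)
    sd = nx.std(axis=1, ddof=1)
    flagged = expr.index[sd == 0].tolist()
    if flagged:
        logger.warning("%d genes with zero normal SD flagged and excluded", len(flagged))
    keep = sd > 0
    tx = expr.loc[keep, tumors].to_numpy(dtype=float)
    z = (tx - mu[keep][:, None]) / sd[keep][:, None]
    return ZMatrix(z=pd.DataFrame(z, index=expr.index[keep], columns=tumors),
                   flagged_genes=flagged)


def filter_outlier_genes(
    z: ZMatrix | pd.DataFrame, params: OutlierFilterParams = OutlierFilterParams()
) -> list[str]:
    """Genes with |Z| > z_abs_min in strictly more than tumor_fraction_min of
    tumors."""
    zdf = z.z if isinstance(z, ZMatrix) else z
    frac = (zdf.abs() > params.z_abs_min).mean(axis=1)
    return zdf.index[frac > params.tumor_fraction_min].tolist()


def cluster_and_associate(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    n_clusters: int,
    covariates: tuple[str, ...] = ("age",),
    linkage_method: str = "ward",
    metric: str = "euclidean",
    standardize: bool = True,
    gleason_cut: int = 7,
) -> tuple[pd.Series, dict]:
    """Hierarchical clustering of samples plus cluster-grade association.

    Samples (columns of ``expr``) are clustered on the given genes with
    agglomerative clustering (Ward/Euclidean by default, genes standardized).
    Cluster membership is tested against high Gleason grade (> gleason_cut)
    two ways: an unadjusted chi-squared contingency test, and a logistic
    regression likelihood-ratio test of cluster terms on top of the listed
    covariates.
    """
    if n_clusters < 2:
        raise ValueError("at least 2 clusters must be requested")
    if n_clusters > expr.shape[1]:
        raise ValueError("n_clusters exceeds the number of samples")
    x = expr.to_numpy(dtype=float)
    if standardize:
        sd = x.std(axis=1, ddof=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=1)[:, None]) / sd[:, None]
    link = hierarchy.linkage(pdist(x.T, metric=metric), method=linkage_method)
    labels = pd.Series(
        hierarchy.fcluster(link, t=n_clusters, criterion="maxclust"),
        index=expr.columns,
        name="cluster",
    )

    clin = clinical.set_index("sample").loc[labels.index]
    high = (clin["gleason_sum"] > gleason_cut).astype(int)
    tests: dict = {}
    table = pd.crosstab(labels, high)
    if table.shape == (n_clusters, 2) or table.size > 1:
        chi2, p, dof, _ = chi2_contingency(table)
        tests["chi2"] = dict(statistic=float(chi2), p=float(p), dof=int(dof))
    else:
        tests["chi2"] = dict(statistic=np.nan, p=np.nan, dof=0)

    import statsmodels.api as sm

    X_full = pd.get_dummies(labels.astype("category"), prefix="cluster", drop_first=True)
    X_full = X_full.astype(float)
    for cov in covariates:
        X_full[cov] = clin[cov].astype(float)
    X_null = X_full[list(covariates)] if covariates else pd.DataFrame(index=X_full.index)
    try:
        full = sm.Logit(high, sm.add_constant(X_full)).fit(disp=0)
        null = sm.Logit(high, sm.add_constant(X_null) if len(X_null.columns) else
                        np.ones((len(high), 1))).fit(disp=0)
        from scipy.stats import chi2 as chi2_dist

        lr = 2.0 * (full.llf - null.llf)
        df = full.df_model - null.df_model
        tests["logistic_lr"] = dict(
            statistic=float(lr), p=float(chi2_dist.sf(lr, df)), df=int(df)
        )
    except Exception as exc:  # separation or singular fits on degenerate inputs
        logger.warning("logistic association inestimable: %s", exc)
        tests["logistic_lr"] = dict(statistic=np.nan, p=np.nan, df=0)
    return labels, tests


def _cox_fit(df: pd.DataFrame, covariate: str, adjust_age: bool):
    cols = ["dfs_time", "dfs_event", covariate] + (["age"] if adjust_age else [])
    cph = CoxPHFitter()
    cph.fit(df[cols], duration_col="dfs_time", event_col="dfs_event")
    hr = float(np.exp(cph.params_[covariate]))
    ci = cph.confidence_intervals_.loc[covariate]
    return hr, float(np.exp(ci.iloc[0])), float(np.exp(ci.iloc[1])), float(
        cph.summary.loc[covariate, "p"]
    )


def survival_screen(
    data,
    clinical: pd.DataFrame,
    mode: str = "per_gene_median_split",
    padj_max: float = 0.1,
    adjust_age: bool = False,
    horizon: float | None = None,
    fit_cox: bool = True,
) -> pd.DataFrame:
    """Screen genes (median split) or clusters for disease-free survival.

    ``data`` is a genes x tumors expression frame in per_gene_median_split
    mode (each gene split at its cohort median) or a sample->cluster label
    Series in per_cluster mode (each cluster vs the rest). Per unit: log-rank
    p, and (optionally) a Cox hazard ratio with 95% CI, optionally age
    adjusted. BH adjustment across units; ``significant`` marks padj <
    padj_max. Units where a test cannot be estimated (no events, or an arm
    with fewer than 2 samples) are flagged inestimable rather than raising.

    ``horizon`` truncates follow-up (e.g. 60 months for 5-year recurrence).
    """
    if mode not in ("per_gene_median_split", "per_cluster"):
        raise ValueError("mode must be per_gene_median_split or per_cluster")
    clin = clinical[clinical["role"] == "tumor"].set_index("sample")
    clin = clin.dropna(subset=["dfs_time", "dfs_event"])
    if horizon is not None:
        over = clin["dfs_time"] > horizon
        clin = clin.assign(
            dfs_event=np.where(over, 0, clin["dfs_event"]).astype(int),
            dfs_time=np.minimum(clin["dfs_time"], horizon),
        )
    if int(clin["dfs_event"].sum()) < 1:
        logger.warning("no events in the cohort: all units flagged inestimable")

    if mode == "per_gene_median_split":
        samples = [s for s in data.columns if s in clin.index]
        units = [
            (g, pd.Series((data.loc[g, samples] > data.loc[g, samples].median()).astype(int).to_numpy(),
                          index=samples))
            for g in data.index
        ]
    else:
        samples = [s for s in data.index if s in clin.index]
        labels = data.loc[samples]
        units = [
            (f"cluster_{c}", (labels == c).astype(int))
            for c in sorted(labels.unique())
        ]

    rows = []
    for unit, grp in units:
        sub = clin.loc[grp.index]
        mask = grp.to_numpy().astype(bool)
        n_hi, n_lo = int(mask.sum()), int((~mask).sum())
        ev_hi = int(sub.loc[mask, "dfs_event"].sum())
        ev_lo = int(sub.loc[~mask, "dfs_event"].sum())
        inestimable = n_hi < 2 or n_lo < 2 or (ev_hi + ev_lo) < 1
        lr_p = hr = ci_lo = ci_hi = cox_p = np.nan
        if not inestimable:
            res = logrank_test(
                sub.loc[mask, "dfs_time"], sub.loc[~mask, "dfs_time"],
                event_observed_A=sub.loc[mask, "dfs_event"],
                event_observed_B=sub.loc[~mask, "dfs_event"],
            )
            lr_p = float(res.p_value)
            if fit_cox:
                df = sub[["dfs_time", "dfs_event"]].copy()
                df["group"] = grp.to_numpy().astype(float)
                if adjust_age:
                    df["age"] = sub["age"].astype(float)
                try:
                    hr, ci_lo, ci_hi, cox_p = _cox_fit(df, "group", adjust_age)
                except (ConvergenceError, ValueError, np.linalg.LinAlgError) as exc:
                    logger.warning("Cox fit inestimable for %s: %s", unit, exc)
                    inestimable = True
        rows.append(
            dict(unit=unit, n_high=n_hi, n_low=n_lo, events_high=ev_hi, events_low=ev_lo,
                 logrank_p=lr_p, hr=hr, hr_ci_low=ci_lo, hr_ci_high=ci_hi, cox_p=cox_p,
                 inestimable=inestimable)
        )
    out = pd.DataFrame(rows)
    est = ~out["inestimable"] & out["logrank_p"].notna()
    out["padj"] = np.nan
    if est.any():
        out.loc[est, "padj"] = bh_adjust(out.loc[est, "logrank_p"].to_numpy())
    out["significant"] = out["padj"] < padj_max
    return out


def km_curves(group: pd.Series, clinical: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier survival-curve coordinates for each arm of a grouping.

    ``group`` maps tumor sample ids to arm labels. Returns long-format
    (arm, time, survival) suitable for CSV export or plotting.
    """
    clin = clinical[clinical["role"] == "tumor"].set_index("sample")
    clin = clin.dropna(subset=["dfs_time", "dfs_event"])
    frames = []
    for arm in sorted(group.unique()):
        idx = group.index[group == arm]
        idx = [s for s in idx if s in clin.index]
        if not idx:
            continue
        km = KaplanMeierFitter()
        km.fit(clin.loc[idx, "dfs_time"], clin.loc[idx, "dfs_event"], label=str(arm))
        sf = km.survival_function_
        frames.append(
            pd.DataFrame(dict(arm=str(arm), time=sf.index.to_numpy(),
                              survival=sf.iloc[:, 0].to_numpy()))
        )
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["arm", "time", "survival"]
    )
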