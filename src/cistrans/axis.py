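"""miRNA-side statistics: consensus target voting, biotin-pulldown targetome
calling, candidate-set elevation bootstrap, quartile stratification, the
quartile-stratified correlation-shift procedure with its Welch test, and the
axis differential-expression contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import EmpiricalTestResult, bh_adjust, bootstrap_set_statistic, pearson_columns

logger = logging.getLogger(__name__)

SHIFT_CLASSES = ("strengthened", "weakened", "switched", "unchanged")


@dataclass(frozen=True)
class StratifiedCohort:
    """Lower- and upper-quartile sample strata of a stratifying variable."""

    low: tuple[str, ...]
    high: tuple[str, ...]
    variable: str = ""

    def __post_init__(self) -> None:
        if set(self.low) & set(self.high):
            raise ValueError("strata must be disjoint")


def consensus_targets(votes: pd.DataFrame, min_votes: int = 5) -> dict[str, list[str]]:
    """Per-miRNA target lists from a prediction-algorithm vote matrix.

    ``votes`` has columns (mirna, gene, votes); an interaction is kept when
    at least ``min_votes`` algorithms predicted it.
    """
    missing = [c for c in ("mirna", "gene", "votes") if c not in votes.columns]
    if missing:
        raise ValueError(f"vote matrix missing columns: {missing}")
    kept = votes[votes["votes"] >= min_votes]
    return {m: sorted(g["gene"]) for m, g in kept.groupby("mirna", sort=True)}


def mirna_set_elevation_test(
    mirna_de: pd.DataFrame,
    candidate_set,
    n_resamples: int = 100_000,
    seed: int = 0,
    statistic_col: str = "log2FC",
) -> EmpiricalTestResult:
    """Bootstrap test: is a candidate miRNA set more elevated than chance?

    The observed statistic is the mean tumor-vs-normal elevation (the
    ``statistic_col`` column, fold change by default; pass a rank column to
    use significance ranks instead) over the candidate set; the null is the
    same statistic for equal-size sets sampled with replacement from the
    full miRNA universe.
    """
    candidates = list(candidate_set)
    if not candidates:
        raise ValueError("candidate set is empty")
    if n_resamples < 1000:
        raise ValueError("n_resamples must be >= 1000 for a stable empirical p")
    universe = mirna_de["mirna"] if "mirna" in mirna_de.columns else mirna_de["gene"]
    values = mirna_de[statistic_col].to_numpy(dtype=float)
    mask = universe.isin(candidates).to_numpy()
    n_set = int(mask.sum())
    if n_set == 0:
        raise ValueError("candidate set does not intersect the miRNA universe")
    observed = float(values[mask].mean())
    res = bootstrap_set_statistic(values, n_set, observed, n_resamples, seed)
    res.extra["n_set"] = n_set
    return res


def call_pulldown_targets(
    pd_table: pd.DataFrame, fc_min: float = 1.2, padj_max: float = 0.05
) -> list[str]:
    """Targetome calling from biotin-pulldown enrichment over input.

    A gene is a direct target when it is enriched (linear FC > fc_min,
    strict, and padj < padj_max) in the targeting-mimic pulldown but NOT
    enriched by the same rule in the non-targeting control pulldown.
    Columns: gene, log2FC_mir, padj_mir, log2FC_ctl, padj_ctl.
    """
    required = ["gene", "log2FC_mir", "padj_mir", "log2FC_ctl", "padj_ctl"]
    missing = [c for c in required if c not in pd_table.columns]
    if missing:
        raise ValueError(f"pulldown table missing columns (control contrast required): {missing}")
    lfc_min = np.log2(fc_min)
    in_mir = (pd_table["log2FC_mir"] > lfc_min) & (pd_table["padj_mir"] < padj_max)
    in_ctl = (pd_table["log2FC_ctl"] > lfc_min) & (pd_table["padj_ctl"] < padj_max)
    return pd_table.loc[in_mir & ~in_ctl, "gene"].tolist()


def quartile_stratify(values: pd.Series, variable: str = "") -> StratifiedCohort:
    """Lower/upper quartile strata of floor(n/4) samples each.

    Ties are broken by stable sample order, so the split is deterministic
    for any input ordering of equal values.
    """
    n = len(values)
    if n < 8:
        raise ValueError("need at least 8 samples to stratify by quartile")
    v = values.to_numpy(dtype=float)
    if np.all(v == v[0]):
        raise ValueError("all values equal: quartile strata are undefined")
    order = np.argsort(v, kind="stable")
    k = n // 4
    low = tuple(values.index[order[:k]])
    high = tuple(values.index[order[-k:]])
    return StratifiedCohort(low=low, high=high, variable=variable or str(values.name))


def _stratum_correlations(
    network: np.ndarray, dep: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    r, p = pearson_columns(network, dep)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = bh_adjust(p[ok])
    return r, q


def correlation_shift(
    network_gene: str,
    dependent_genes,
    expr: pd.DataFrame,
    strata: StratifiedCohort,
    q_max: float = 0.1,
    welch_on: str = "r_low",
) -> tuple[pd.DataFrame, dict]:
    """Per-gene correlation change between the low and high strata.

    Within each stratum the Pearson r of every dependent gene against the
    network gene is computed with a t-distribution p, BH-adjusted within the
    stratum. Genes significant (q < q_max) in at least one stratum are kept
    and classified by how the correlation shifts from the high to the low
    stratum: ``switched`` (sign flip, both strata significant),
    ``strengthened`` (|r_low| > |r_high|), ``weakened`` (|r_low| < |r_high|),
    else ``unchanged``. delta = r_low - r_high.

    The Welch two-sample t-test compares the correlation strengths of the
    positive-strengthened group against the negative-weakened group
    (``welch_on``: "r_low" for raw r in the low stratum, "fisher_z" for the
    Fisher transform). Fewer than 2 genes in either group flags the test
    inestimable instead of raising.
    """
    dependents = [g for g in dependent_genes if g != network_gene]
    missing = set(dependents) - set(expr.index)
    if missing:
        raise ValueError(f"dependent genes absent from expression: {sorted(missing)[:5]}")
    if len(strata.low) < 10 or len(strata.high) < 10:
        raise ValueError("each stratum must have at least 10 samples")

    out = {}
    for name, samples in (("low", strata.low), ("high", strata.high)):
        sub = expr.loc[:, list(samples)]
        net = sub.loc[network_gene].to_numpy(dtype=float)
        dep = sub.loc[dependents].to_numpy(dtype=float).T
        out[name] = _stratum_correlations(net, dep)

    r_low, q_low = out["low"]
    r_high, q_high = out["high"]
    sig_low = q_low < q_max
    sig_high = q_high < q_max
    keep = sig_low | sig_high

    delta = r_low - r_high
    cls = np.full(len(dependents), "unchanged", dtype=object)
    switched = sig_low & sig_high & (np.sign(r_low) != np.sign(r_high))
    stronger = np.abs(r_low) > np.abs(r_high)
    weaker = np.abs(r_low) < np.abs(r_high)
    cls[stronger] = "strengthened"
    cls[weaker] = "weakened"
    cls[switched] = "switched"

    table = pd.DataFrame(
        dict(gene=dependents, r_low=r_low, q_low=q_low, r_high=r_high, q_high=q_high,
             delta=delta, shift_class=cls)
    )[keep]
    table = table.reset_index(drop=True)

    pos_strength = table[(table["r_low"] > 0) & (table["shift_class"] == "strengthened")]
    neg_weak = table[(table["r_low"] < 0) & (table["shift_class"] == "weakened")]

    def _vals(df):
        v = df["r_low"].to_numpy()
        return np.arctanh(np.clip(v, -0.999999, 0.999999)) if welch_on == "fisher_z" else v

    welch: dict = dict(n_pos_strengthened=len(pos_strength), n_neg_weakened=len(neg_weak))
    if len(pos_strength) < 2 or len(neg_weak) < 2:
        welch.update(inestimable=True, statistic=np.nan, p=np.nan, effect=np.nan)
    else:
        a, b = _vals(pos_strength), _vals(neg_weak)
        t = sps.ttest_ind(a, b, equal_var=False)
        welch.update(
            inestimable=False,
            statistic=float(t.statistic),
            p=float(t.pvalue),
            effect=float(a.mean() - b.mean()),
        )
    summary = dict(
        n_dependents=len(dependents),
        n_kept=int(len(table)),
        mean_delta=float(table["delta"].mean()) if len(table) else np.nan,
        class_counts={c: int((table["shift_class"] == c).sum()) for c in SHIFT_CLASSES},
        welch=welch,
    )
    return table, summary


def axis_differential_expression(
    expr: pd.DataFrame,
    group_a,
    group_b,
    contrast: str = "a_vs_b",
) -> pd.DataFrame:
    """Per-gene Welch t contrast of two disjoint sample groups.

    log2FC = mean(a) - mean(b) on the log2-scale matrix; SE is the Welch
    standard error; p is the Welch t p-value, BH adjusted. The output schema
    (gene, log2FC, SE, p, padj, contrast) matches the DE tables consumed by
    the response-modulation operations.
    """
    a, b = list(group_a), list(group_b)
    if set(a) & set(b):
        raise ValueError("groups must be disjoint")
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 samples")
    xa = expr[a].to_numpy(dtype=float)
    xb = expr[b].to_numpy(dtype=float)
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    va, vb = xa.var(axis=1, ddof=1), xb.var(axis=1, ddof=1)
    se = np.sqrt(va / len(a) + vb / len(b))
    _, p = sps.ttest_ind_from_stats(
        ma, np.sqrt(va), len(a), mb, np.sqrt(vb), len(b), equal_var=False
    )
    return pd.DataFrame(
        dict(gene=expr.index, log2FC=ma - mb, SE=se, p=p, padj=bh_adjust(p),
             contrast=contrast)
    ).reset_index(drop=True)


def correlation_matrix(expr: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r matrix with BH q-values for the off-diagonal.

    ``expr`` is features x samples (genes and miRNAs may be concatenated on
    shared samples). Zero-variance features yield NaN entries (flagged).
    Returns (r matrix, q matrix); the diagonal of r is 1 and of q is NaN.
    """
    x = expr.to_numpy(dtype=float)
    n_feat, n_samp = x.shape
    if n_samp < 3:
        raise ValueError("need at least 3 shared samples")
    sd = x.std(axis=1)
    if (sd == 0).any():
        logger.warning("%d zero-variance features flagged (NaN entries)", int((sd == 0).sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    np.fill_diagonal(r, np.where(sd == 0, np.nan, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n_samp - 2) / (1 - r**2))
    p = 2.0 * sps.t.sf(np.abs(t), df=n_samp - 2)
    iu = np.triu_indices(n_feat, k=1)
    q = np.full_like(p, np.nan)
    flat = p[iu]
    ok = ~np.isnan(flat)
    adj = np.full_like(flat, np.nan)
    if ok.any():
        adj[ok] = bh_adjust(flat[ok])
    q[iu] = adj
    q[(iu[1], iu[0])] = adj
    rdf = pd.DataFrame(r, index=expr.index, columns=expr.index)
    qdf = pd.DataFrame(q, index=expr.index, columns=expr.index)
    return rdf, qdf
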