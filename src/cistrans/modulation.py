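"""DEG calling and knockdown response-modulation (dampening) classification.

A hormone-responsive transcriptome measured in control and in regulator-
knockdown cells is compared gene by gene. For each control DEG an
interaction z-test on the difference of log2 fold changes (pooled SEs)
decides whether the knockdown significantly reshaped the response; genes
with a same-sign but significantly smaller knockdown effect are "dampened",
sign flips or collapses below the fold threshold are "lost", and knockdown-
only DEGs are "gained".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust, hypergeom_upper

CATEGORIES = ("dampened_induction", "dampened_repression", "lost", "gained", "unchanged")


@dataclass(frozen=True)
class DegThresholds:
    """Linear fold-change and adjusted-p cutoffs for DEG calling.

    The fold-change boundary is inclusive (|log2FC| >= log2(fold_change_linear));
    the adjusted-p boundary is exclusive (padj < padj_max).
    """

    fold_change_linear: float = 1.2
    padj_max: float = 0.05

    def __post_init__(self) -> None:
        if self.fold_change_linear < 1:
            raise ValueError("fold_change_linear must be >= 1")
        if self.padj_max <= 0:
            raise ValueError("padj_max must be > 0")

    @property
    def lfc_min(self) -> float:
        return float(np.log2(self.fold_change_linear))


def _check_schema(de: pd.DataFrame, need_se: bool = False) -> None:
    required = ["gene", "log2FC", "padj"] + (["SE"] if need_se else [])
    missing = [c for c in required if c not in de.columns]
    if missing:
        raise ValueError(f"DE table missing columns: {missing}")


def call_degs(de: pd.DataFrame, thr: DegThresholds = DegThresholds()) -> tuple[set, set]:
    """Return (up, down) DEG gene sets at the given thresholds."""
    _check_schema(de)
    sig = de["padj"] < thr.padj_max
    up = set(de.loc[sig & (de["log2FC"] >= thr.lfc_min), "gene"])
    down = set(de.loc[sig & (de["log2FC"] <= -thr.lfc_min), "gene"])
    return up, down


def response_venn(ctl_degs: set, kd_degs: set) -> dict[str, int]:
    """Counts of the shared / control-only / knockdown-only DEG partition."""
    return {
        "shared": len(ctl_degs & kd_degs),
        "ctl_only": len(ctl_degs - kd_degs),
        "kd_only": len(kd_degs - ctl_degs),
    }


def classify_modulation(
    ctl: pd.DataFrame,
    kd: pd.DataFrame,
    thr: DegThresholds = DegThresholds(),
    alpha_interaction: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Classify how knockdown reshapes each hormone response.

    The DEG universe is the control DEGs; per gene the interaction statistic
    z = (lfc_ctl - lfc_kd) / sqrt(SE_ctl^2 + SE_kd^2) is tested two-sided and
    BH-adjusted across that universe. Categories: dampened (significant,
    same sign, smaller knockdown magnitude), lost (significant with a sign
    flip or the knockdown effect below the fold threshold), gained (DEG in
    knockdown only, appended rows), else unchanged.

    Returns (calls table, summary). The summary reports counts per category,
    the dampened fraction of the control DEG universe, a hypergeometric
    enrichment p for modulated (dampened or lost) genes among control DEGs,
    and a directional-consistency sign test (are significant interactions
    predominantly magnitude reductions?).
    """
    _check_schema(ctl, need_se=True)
    _check_schema(kd, need_se=True)
    if ctl["SE"].isna().any() or kd["SE"].isna().any():
        raise ValueError(
            "SE values are required in both tables; regenerate them from replicate-level "
            "data (the synthetic generator provides SEs)"
        )
    merged = ctl.merge(kd, on="gene", suffixes=("_ctl", "_kd"))
    up_c, down_c = call_degs(ctl, thr)
    up_k, down_k = call_degs(kd, thr)
    ctl_degs = up_c | down_c
    kd_degs = up_k | down_k

    uni = merged[merged["gene"].isin(ctl_degs)].reset_index(drop=True)
    se = np.sqrt(uni["SE_ctl"] ** 2 + uni["SE_kd"] ** 2)
    delta = uni["log2FC_ctl"] - uni["log2FC_kd"]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, delta / se, np.inf * np.sign(delta))
    p_int = 2.0 * sps.norm.sf(np.abs(z))
    padj_int = bh_adjust(p_int)

    lfc_c = uni["log2FC_ctl"].to_numpy()
    lfc_k = uni["log2FC_kd"].to_numpy()
    sig = padj_int < alpha_interaction
    same_sign = np.sign(lfc_c) == np.sign(lfc_k)
    smaller = np.abs(lfc_k) < np.abs(lfc_c)
    below_thr = np.abs(lfc_k) < thr.lfc_min

    category = np.full(len(uni), "unchanged", dtype=object)
    lost = sig & (~same_sign | below_thr) & ~(same_sign & smaller & ~below_thr)
    dampened = sig & same_sign & smaller & ~below_thr
    # a significant same-sign reduction that drops below the DEG fold
    # threshold is still a dampening event if the gene remains a kd DEG
    damp_rescue = sig & same_sign & smaller & below_thr & uni["gene"].isin(kd_degs).to_numpy()
    lost = lost & ~damp_rescue
    dampened = dampened | damp_rescue
    category[lost] = "lost"
    category[dampened & (lfc_c > 0)] = "dampened_induction"
    category[dampened & (lfc_c < 0)] = "dampened_repression"

    calls = pd.DataFrame(
        dict(
            gene=uni["gene"],
            category=category,
            lfc_control=lfc_c,
            lfc_knockdown=lfc_k,
            delta=delta,
            p_interaction=p_int,
            padj_interaction=padj_int,
        )
    )

    gained_genes = sorted(kd_degs - ctl_degs)
    if gained_genes:
        g = merged[merged["gene"].isin(gained_genes)]
        gained_rows = pd.DataFrame(
            dict(
                gene=g["gene"],
                category="gained",
                lfc_control=g["log2FC_ctl"],
                lfc_knockdown=g["log2FC_kd"],
                delta=g["log2FC_ctl"] - g["log2FC_kd"],
                p_interaction=np.nan,
                padj_interaction=np.nan,
            )
        )
        calls = pd.concat([calls, gained_rows], ignore_index=True)

    n_uni = len(uni)
    counts = {c: int((calls["category"] == c).sum()) for c in CATEGORIES}
    n_modulated = counts["dampened_induction"] + counts["dampened_repression"] + counts["lost"]
    n_dampened = counts["dampened_induction"] + counts["dampened_repression"]
    # enrichment of modulated genes among control DEGs vs all genes tested
    n_all = len(merged)
    p_hyper = (
        hypergeom_upper(n_modulated, n_all, n_uni, max(n_uni, 1)) if n_uni else 1.0
    )
    n_sig = int(sig.sum())
    n_reduced = int((sig & smaller).sum())
    sign_test_p = float(sps.binomtest(n_reduced, n_sig, 0.5, alternative="greater").pvalue) if n_sig else 1.0
    summary = dict(
        n_universe=n_uni,
        counts=counts,
        dampened_fraction=(n_dampened / n_uni) if n_uni else 0.0,
        modulated_fraction=(n_modulated / n_uni) if n_uni else 0.0,
        hypergeometric_p=p_hyper,
        sign_test_p=sign_test_p,
        n_significant_interactions=n_sig,
        n_magnitude_reduced=n_reduced,
    )
    return calls, summary


def ddct_fold_change(
    ct_target_exp: float, ct_ref_exp: float, ct_target_ctl: float, ct_ref_ctl: float
) -> float:
    """Relative qPCR fold change by the 2^-ddCt method.

    dCt = Ct(target) - Ct(reference) per condition; ddCt = dCt(experimental)
    - dCt(control); FC = 2^-ddCt.
    """
    for v in (ct_target_exp, ct_ref_exp, ct_target_ctl, ct_ref_ctl):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_exp - ct_ref_exp) - (ct_target_ctl - ct_ref_ctl)
    return float(2.0 ** (-ddct))
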