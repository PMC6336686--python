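"""Peak-to-TSS annotation, cistrome overlap significance, and the bootstrap
cistrome-transcriptome association test.

Coordinates are BED-style 0-based half-open internally; TSS tables carry
1-based positions and are converted on use. Distances between a peak and a
TSS are interval gaps: 0 when the TSS base falls inside the peak, otherwise
the number of bases separating the TSS base from the nearest peak edge.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import EmpiricalTestResult, bootstrap_set_statistic, hypergeom_upper

logger = logging.getLogger(__name__)

STATISTICS = ("mean_abs_lfc", "mean_lfc")


def annotate_peaks_to_tss(
    peaks: pd.DataFrame, tss: pd.DataFrame, window: int = 7500
) -> pd.DataFrame:
    """Map peaks to genes whose TSS lies within ``window`` bp.

    Returns one row per (peak, gene) pair with the absolute gap distance and
    a strand-aware signed distance (positive = peak downstream of the TSS on
    the gene's strand). Genes may map to several peaks and vice versa.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if len(tss) == 0:
        logger.warning("empty TSS table: returning an empty peak-gene map")
        return pd.DataFrame(columns=["peak", "gene", "distance", "signed_distance"])
    rows = []
    peak_names = peaks["name"] if "name" in peaks.columns else pd.Series(
        [f"peak_{i}" for i in range(len(peaks))]
    )
    for chrom, tgrp in tss.groupby("chrom", sort=False):
        pgrp = peaks[peaks["chrom"] == chrom]
        if pgrp.empty:
            continue
        s = pgrp["start"].to_numpy()[:, None]
        e = pgrp["end"].to_numpy()[:, None]
        names = peak_names.loc[pgrp.index].to_numpy()
        t1 = tgrp["tss"].to_numpy()[None, :]  # 1-based
        t0 = t1 - 1  # 0-based base [t0, t0+1)
        gap_right = t0 - e  # TSS downstream of peak end
        gap_left = s - (t0 + 1)  # TSS upstream of peak start
        dist = np.maximum(np.maximum(gap_left, gap_right), 0)
        # direction on the genome: +1 if the peak lies right of the TSS base
        genome_sign = np.where(gap_left > 0, 1, np.where(gap_right > 0, -1, 0))
        strand_sign = np.where(tgrp["strand"].to_numpy()[None, :] == "-", -1, 1)
        signed = dist * genome_sign * strand_sign
        pi, gi = np.nonzero(dist <= window)
        gnames = tgrp["gene"].to_numpy()
        for a, b in zip(pi, gi):
            rows.append((names[a], gnames[b], int(dist[a, b]), int(signed[a, b])))
    out = pd.DataFrame(rows, columns=["peak", "gene", "distance", "signed_distance"])
    return out


def count_overlaps(a: pd.DataFrame, b: pd.DataFrame, max_gap: int = 500) -> int:
    """Number of intervals in ``a`` lying within ``max_gap`` bp of any
    interval in ``b`` (each ``a`` interval counted once)."""
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    n = 0
    for chrom, agrp in a.groupby("chrom", sort=False):
        bgrp = b[b["chrom"] == chrom]
        if bgrp.empty:
            continue
        s1 = agrp["start"].to_numpy()[:, None]
        e1 = agrp["end"].to_numpy()[:, None]
        s2 = bgrp["start"].to_numpy()[None, :]
        e2 = bgrp["end"].to_numpy()[None, :]
        gap = np.maximum(s2 - e1, s1 - e2)  # negative => overlap
        n += int(np.any(gap <= max_gap, axis=1).sum())
    return n


def overlap_significance(
    a: pd.DataFrame, b: pd.DataFrame, max_gap: int = 500, universe: int = 0
) -> tuple[int, float]:
    """Overlap count and upper-tail hypergeometric p for two peak sets.

    The genome is modeled as ``universe`` bins; ``|a|`` bins are drawn and
    ``|b|`` bins carry successes, so p = P(X >= n_overlap) under the
    hypergeometric law. The universe (bin count) is the caller's choice; a
    common default is genome length divided by the median peak width.
    """
    n_a, n_b = len(a), len(b)
    if universe < max(n_a, n_b):
        raise ValueError("universe must be at least as large as each peak set")
    k = count_overlaps(a, b, max_gap=max_gap)
    if universe < n_a + n_b - k:
        raise ValueError("universe smaller than the combined occupancy of the two sets")
    p = hypergeom_upper(k, universe, n_b, n_a)
    return k, p


def bootstrap_expression_association(
    bound_genes,
    de: pd.DataFrame,
    n_resamples: int = 100_000,
    seed: int = 0,
    statistic: str = "mean_abs_lfc",
) -> EmpiricalTestResult:
    """Bootstrap test: is the fold change of a gene set extreme vs chance?

    The observed statistic (mean |log2FC| by default, or mean log2FC) of the
    bound genes is compared with a null built by repeatedly sampling, with
    replacement, gene sets of the same size from the full DE universe. The
    empirical p uses add-one smoothing and is never 0.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}")
    if n_resamples < 1000:
        raise ValueError("n_resamples must be >= 1000 for a stable empirical p")
    universe = de["gene"].to_numpy()
    lfc = de["log2FC"].to_numpy(dtype=float)
    values = np.abs(lfc) if statistic == "mean_abs_lfc" else lfc
    mask = np.isin(universe, np.asarray(list(bound_genes), dtype=object))
    n_set = int(mask.sum())
    if n_set == 0:
        raise ValueError("bound gene set does not intersect the DE universe")
    logger.info("bootstrap association: %d of %d set genes in universe", n_set, len(bound_genes))
    observed = float(values[mask].mean())
    result = bootstrap_set_statistic(values, n_set, observed, n_resamples, seed)
    result.extra["n_set"] = n_set
    result.extra["statistic"] = statistic
    return result


def correlation_distribution_test(
    focal, target_genes, expr: pd.DataFrame
) -> tuple[pd.Series, float, float]:
    """Compare correlation distributions of a target set vs the background.

    Pearson r is computed between the focal expression vector and every gene
    in ``expr`` (genes x samples); a two-sample Kolmogorov-Smirnov test then
    compares the r values of ``target_genes`` with those of all genes.
    Returns (per-gene r, KS statistic D, p).
    """
    focal = np.asarray(focal, dtype=float)
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if focal.shape[0] != expr.shape[1]:
        raise ValueError("focal vector length must equal the number of samples")
    if np.std(focal) == 0:
        raise ValueError("focal vector has zero variance")
    target_genes = list(target_genes)
    missing = set(target_genes) - set(expr.index)
    if missing:
        raise ValueError(f"target genes absent from the expression matrix: {sorted(missing)[:5]}")
    from .stats import pearson_columns

    r, _ = pearson_columns(focal, expr.to_numpy(dtype=float).T)
    r = pd.Series(r, index=expr.index, name="r").dropna()
    background = r.to_numpy()
    target = r.loc[[g for g in target_genes if g in r.index]].to_numpy()
    if set(target_genes) >= set(r.index):
        return r, 0.0, 1.0
    ks = sps.ks_2samp(target, background)
    return r, float(ks.statistic), float(ks.pvalue)
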