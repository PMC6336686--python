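"""Synthetic cohort, knockdown-experiment, cistrome and gene-set generators.

Every generator is deterministic given its spec's seed and emits the same
plain-text-serializable tables the rest of the pipeline consumes, with
planted ground truth recorded alongside:

* ``generate_cohort`` – log2-scale gene and miRNA expression for tumors and
  normals with (i) miRNA-target correlations planted separately in the low
  and high miRNA-expression quartile strata, (ii) outlier genes shifted by a
  stated number of normal-reference SDs in a stated fraction of tumors, and
  (iii) exponential disease-free survival with a planted hazard ratio for a
  marker-defined tumor subgroup.
* ``generate_de_experiment`` – a two-factor (knockdown x hormone) replicate
  experiment summarized to per-contrast DE tables (log2FC, SE, Welch p, BH
  adjusted p), with a stated subset of hormone-responsive genes dampened by
  a multiplicative factor in the knockdown conditions only.
* ``generate_cistrome`` – peaks (BED-style), a TSS table and a DE table in
  which bound genes' |log2FC| is elevated on average.
* ``generate_gene_sets`` – keyword-named gene sets plus an enrichment table
  with one keyword over-represented among the enriched sets.

Expression is generated on the log2 scale from a Gaussian latent model;
correlations are planted by mixing a shared standardized latent factor, so
the planted Pearson r is the population correlation within each stratum.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .specs import (
    CohortSpec,
    CistromeSpec,
    DEExperimentSpec,
    GeneSetSpec,
)
from .stats import bh_adjust

CONTRAST_CTL = "ctl_hormone_vs_vehicle"
CONTRAST_KD = "kd_hormone_vs_vehicle"


def _standardize(v: np.ndarray) -> np.ndarray:
    s = v.std()
    if s == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / s


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (gene expression, miRNA expression, clinical table).

    Columns are samples (``T0000..`` tumors then ``N0000..`` normals); rows
    are genes / miRNAs. The clinical table has one row per sample with role,
    age, Gleason sum and disease-free survival fields (tumors only).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_ids()
    mirnas = spec.mirna_ids()
    tumors = [f"T{i:04d}" for i in range(spec.n_tumors)]
    normals = [f"N{i:04d}" for i in range(spec.n_normals)]
    samples = tumors + normals
    n_samp = len(samples)

    gene_mu = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_genes)
    mirna_mu = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_mirnas)
    gene_x = gene_mu[:, None] + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n_samp))
    mirna_x = mirna_mu[:, None] + rng.normal(0.0, spec.noise_sd, size=(spec.n_mirnas, n_samp))

    gene_index = {g: i for i, g in enumerate(genes)}
    n_t = spec.n_tumors

    for ax in spec.axes():
        if n_t < 8:
            break
        mi = mirnas.index(ax.mirna_id)
        m_tumor = mirna_x[mi, :n_t]
        order = np.argsort(m_tumor, kind="stable")
        k = n_t // 4
        low_idx = order[:k]
        high_idx = order[-k:]
        mid_idx = order[k : n_t - k]
        r_mid = 0.5 * (ax.r_low + ax.r_high)
        for gid in ax.target_gene_ids:
            gi = gene_index[gid]
            for idx, r in ((low_idx, ax.r_low), (high_idx, ax.r_high), (mid_idx, r_mid)):
                if len(idx) < 2:
                    continue
                z = _standardize(m_tumor[idx])
                eps = rng.normal(size=len(idx))
                gene_x[gi, idx] = gene_mu[gi] + spec.noise_sd * (
                    r * z + np.sqrt(max(0.0, 1.0 - r**2)) * eps
                )

    if spec.planted_outliers is not None and n_t > 0:
        po = spec.planted_outliers
        n_aff = int(round(po.tumor_fraction * n_t))
        affected = rng.permutation(n_t)[:n_aff]
        for gid in po.gene_ids:
            gene_x[gene_index[gid], affected] += po.z_effect * spec.noise_sd

    subgroup_mask = np.zeros(n_t, dtype=bool)
    if spec.planted_survival is not None and n_t > 0:
        ps = spec.planted_survival
        n_sub = int(round(ps.subgroup_fraction * n_t))
        subgroup_mask[rng.permutation(n_t)[:n_sub]] = True
        for gid in ps.subgroup_gene_ids:
            gene_x[gene_index[gid], :n_t][subgroup_mask] += ps.marker_shift * spec.noise_sd

    clinical = _clinical_table(spec, rng, tumors, normals, subgroup_mask)

    genes_df = pd.DataFrame(gene_x, index=pd.Index(genes, name="feature"), columns=samples)
    mirnas_df = pd.DataFrame(mirna_x, index=pd.Index(mirnas, name="feature"), columns=samples)
    return genes_df, mirnas_df, clinical


def _clinical_table(spec, rng, tumors, normals, subgroup_mask) -> pd.DataFrame:
    n_t = len(tumors)
    age = np.round(rng.normal(62.0, 8.0, size=n_t + len(normals))).astype(int)
    rows = []
    ps = spec.planted_survival
    base_rate = 1.0 / 24.0  # per month; median untreated time-to-event ~16.6 months
    if ps is not None and n_t > 0:
        rates = np.where(subgroup_mask, base_rate * ps.hazard_ratio, base_rate)
        horizon = _censoring_horizon(rates, ps.event_fraction)
        t_event = rng.exponential(1.0 / rates)
        dfs_time = np.minimum(t_event, horizon)
        dfs_event = (t_event <= horizon).astype(int)
        p_high = np.where(
            subgroup_mask, ps.gleason_high_prob_subgroup, ps.gleason_high_prob_other
        )
    else:
        t_event = rng.exponential(1.0 / base_rate, size=n_t)
        horizon = _censoring_horizon(np.full(max(n_t, 1), base_rate), 0.5)
        dfs_time = np.minimum(t_event, horizon)
        dfs_event = (t_event <= horizon).astype(int)
        p_high = np.full(n_t, 0.3)
    high = rng.random(n_t) < p_high
    gleason = np.where(high, rng.integers(8, 10, size=n_t), rng.integers(6, 8, size=n_t))
    for i, s in enumerate(tumors):
        rows.append(
            dict(
                sample=s,
                role="tumor",
                age=age[i],
                gleason_sum=int(gleason[i]),
                dfs_time=float(dfs_time[i]),
                dfs_event=int(dfs_event[i]),
                subgroup=bool(subgroup_mask[i]) if ps is not None else False,
            )
        )
    for j, s in enumerate(normals):
        rows.append(
            dict(
                sample=s,
                role="normal",
                age=age[n_t + j],
                gleason_sum=np.nan,
                dfs_time=np.nan,
                dfs_event=np.nan,
                subgroup=False,
            )
        )
    return pd.DataFrame(rows)


def _censoring_horizon(rates: np.ndarray, event_fraction: float) -> float:
    """Administrative censoring horizon giving the requested event fraction."""
    if event_fraction >= 1.0:
        return np.inf
    if event_fraction <= 0.0:
        return 0.0

    def frac(c):
        return np.mean(1.0 - np.exp(-rates * c)) - event_fraction

    hi = 1.0
    while frac(hi) < 0:
        hi *= 2.0
        if hi > 1e9:
            return hi
    return float(optimize.brentq(frac, 1e-9, hi))


# -- knockdown x hormone experiment -----------------------------------------


def generate_de_experiment(
    spec: DEExperimentSpec,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Generate per-contrast DE tables and ground-truth labels.

    Returns ``({contrast_name: DETable}, labels)``; the two contrasts are
    hormone-vs-vehicle in control and in knockdown cells. Labels record the
    planted hormone log2FC and which genes were responsive / dampened.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = np.array(spec.gene_ids())
    n = spec.n_genes

    if n == 0:
        empty = pd.DataFrame(columns=["gene", "log2FC", "SE", "p", "padj", "contrast"])
        labels = pd.DataFrame(columns=["gene", "responsive", "dampened", "true_lfc"])
        return {CONTRAST_CTL: empty.copy(), CONTRAST_KD: empty.copy()}, labels

    responsive = np.zeros(n, dtype=bool)
    resp_idx = rng.permutation(n)[: spec.n_responsive]
    responsive[resp_idx] = True
    n_damp = int(round(spec.dampened_fraction * spec.n_responsive))
    dampened = np.zeros(n, dtype=bool)
    dampened[resp_idx[:n_damp]] = True

    magnitude = np.maximum(spec.lfc_min, rng.normal(spec.lfc_mean, spec.lfc_sd, size=n))
    sign = rng.choice([-1.0, 1.0], size=n)
    true_lfc = np.where(responsive, sign * magnitude, 0.0)
    kd_lfc = np.where(dampened, true_lfc * spec.dampening_factor, true_lfc)

    baseline = spec.baseline_mean + rng.normal(0.0, 1.0, size=n)
    reps = spec.n_replicates

    def contrast(effect: np.ndarray, name: str) -> pd.DataFrame:
        veh = baseline[:, None] + rng.normal(0.0, spec.residual_sd, size=(n, reps))
        horm = (
            baseline[:, None]
            + effect[:, None]
            + rng.normal(0.0, spec.residual_sd, size=(n, reps))
        )
        m1, m0 = horm.mean(axis=1), veh.mean(axis=1)
        v1, v0 = horm.var(axis=1, ddof=1), veh.var(axis=1, ddof=1)
        se = np.sqrt(v1 / reps + v0 / reps)
        t, p = sps.ttest_ind_from_stats(
            m1, np.sqrt(v1), reps, m0, np.sqrt(v0), reps, equal_var=False
        )
        return pd.DataFrame(
            dict(gene=genes, log2FC=m1 - m0, SE=se, p=p, padj=bh_adjust(p), contrast=name)
        )

    tables = {
        CONTRAST_CTL: contrast(true_lfc, CONTRAST_CTL),
        CONTRAST_KD: contrast(kd_lfc, CONTRAST_KD),
    }
    labels = pd.DataFrame(
        dict(gene=genes, responsive=responsive, dampened=dampened, true_lfc=true_lfc)
    )
    return tables, labels


# -- cistrome ----------------------------------------------------------------


def generate_cistrome(
    spec: CistromeSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (peaks, TSS table, DE table) with planted bound-gene effect.

    Every planted bound gene is guaranteed at least one peak whose interval
    lies within ``spec.window`` bp of its TSS; remaining peaks fall uniformly
    on the genome.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_ids()
    chroms = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    margin = spec.window + spec.peak_width_mean + 1

    gene_chrom = rng.integers(0, spec.n_chroms, size=spec.n_genes)
    tss_pos = rng.integers(margin, spec.chrom_length - margin, size=spec.n_genes)
    strand = rng.choice(["+", "-"], size=spec.n_genes)
    tss = pd.DataFrame(
        dict(
            gene=genes,
            chrom=[chroms[c] for c in gene_chrom],
            strand=strand,
            tss=tss_pos,  # 1-based
        )
    )

    w = spec.peak_width_mean
    rows = []
    bound = list(spec.planted_bound_gene_ids)
    gene_row = {g: i for i, g in enumerate(genes)}
    for gid in bound:
        gi = gene_row[gid]
        tss0 = tss_pos[gi] - 1  # to 0-based
        max_off = spec.window - 1
        center = tss0 + rng.integers(-max_off, max_off + 1)
        start = max(0, center - w // 2)
        rows.append((chroms[gene_chrom[gi]], start, start + w))
    n_rest = max(0, spec.n_peaks - len(bound))
    rest_chrom = rng.integers(0, spec.n_chroms, size=n_rest)
    rest_start = rng.integers(0, spec.chrom_length - w, size=n_rest)
    rows.extend((chroms[c], s, s + w) for c, s in zip(rest_chrom, rest_start))
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    peaks["name"] = [f"peak_{i}" for i in range(len(peaks))]
    peaks["score"] = np.round(rng.uniform(1, 1000, size=len(peaks))).astype(int)
    peaks["strand"] = "."

    lfc = rng.normal(0.0, spec.de_lfc_sd, size=spec.n_genes)
    is_bound = np.isin(np.array(genes), np.array(bound, dtype=object))
    uplift = rng.choice([-1.0, 1.0], size=spec.n_genes) * spec.bound_effect
    lfc = np.where(is_bound, lfc + uplift, lfc)
    se = np.full(spec.n_genes, spec.de_lfc_sd / np.sqrt(3.0))
    z = lfc / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    de = pd.DataFrame(
        dict(
            gene=genes,
            log2FC=lfc,
            SE=se,
            p=p,
            padj=bh_adjust(p),
            contrast="knockdown_vs_control",
        )
    )
    return peaks, tss, de


# -- gene sets ---------------------------------------------------------------


def generate_gene_sets(spec: GeneSetSpec) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Generate (gene-set memberships, enrichment table).

    Set names are underscore-joined keyword tokens; the planted keyword
    appears in enriched-set names at ``enrichment_rate`` and in the rest at
    ``background_rate``. The enrichment table carries NES and FDR q values
    such that exactly ``n_enriched`` sets pass NES > 1.8, q < 0.05.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    vocab = [t.upper() for t in spec.keyword_vocab if spec.planted_keyword is None
             or t.upper() != spec.planted_keyword.upper()]
    if not vocab:
        raise ValueError("keyword_vocab must contain tokens besides the planted keyword")
    genes = np.array([f"G{i:05d}" for i in range(spec.n_genes)])

    enriched_flags = np.zeros(spec.n_sets, dtype=bool)
    enriched_flags[rng.permutation(spec.n_sets)[: spec.n_enriched]] = True

    names, members = [], {}
    for i in range(spec.n_sets):
        k = min(spec.tokens_per_name, len(vocab))
        toks = list(rng.choice(vocab, size=k, replace=False))
        if spec.planted_keyword is not None:
            rate = spec.enrichment_rate if enriched_flags[i] else spec.background_rate
            if rng.random() < rate:
                toks[int(rng.integers(0, len(toks)))] = spec.planted_keyword.upper()
        name = "_".join(toks + [f"S{i}"])
        names.append(name)
        members[name] = list(rng.choice(genes, size=min(spec.genes_per_set, spec.n_genes),
                                        replace=False))

    nes = np.where(
        enriched_flags,
        rng.uniform(1.9, 3.0, size=spec.n_sets),
        rng.uniform(0.4, 1.7, size=spec.n_sets),
    )
    q = np.where(
        enriched_flags,
        rng.uniform(1e-4, 0.04, size=spec.n_sets),
        rng.uniform(0.06, 1.0, size=spec.n_sets),
    )
    enrichment = pd.DataFrame(
        dict(
            set_name=names,
            NES=nes,
            fdr_q=q,
            direction=rng.choice(["up", "down"], size=spec.n_sets),
        )
    )
    return members, enrichment
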