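"""Keyword meta-group mining over enriched gene-set names, and the generic
hypergeometric gene-set overlap test.

Gene-set names are underscore-delimited keyword tokens (the MSigDB
convention). Mining asks, keyword by keyword, whether sets whose names carry
the keyword are over-represented among the enriched sets relative to the
full collection, by an upper-tail hypergeometric test with BH adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import bh_adjust, hypergeom_upper

logger = logging.getLogger(__name__)

#: name-component tokens ignored by the keyword tokenizer: collection
#: prefixes and connectives that carry no biology. Direction suffixes
#: (UP/DN) are deliberately kept as tokens.
DEFAULT_STOP_TOKENS = frozenset(
    {
        "HALLMARK", "KEGG", "REACTOME", "BIOCARTA", "PID", "WP", "GOBP", "GOCC",
        "GOMF", "GSE", "MODULE", "OF", "THE", "AND", "IN", "TO", "VS", "WITH",
        "BY", "FROM", "FOR",
    }
)


@dataclass(frozen=True)
class EnrichmentThresholds:
    """Strict cutoffs for selecting enriched sets (NES > nes_min, q < q_max)."""

    nes_min: float = 1.8
    q_max: float = 0.05

    def __post_init__(self) -> None:
        if self.nes_min <= 0:
            raise ValueError("nes_min must be > 0")


def select_enriched(
    tbl: pd.DataFrame, thr: EnrichmentThresholds = EnrichmentThresholds()
) -> list[str]:
    """Set names passing NES > nes_min and FDR q < q_max (both strict)."""
    missing = [c for c in ("set_name", "NES", "fdr_q") if c not in tbl.columns]
    if missing:
        raise ValueError(f"enrichment table missing columns: {missing}")
    keep = (tbl["NES"] > thr.nes_min) & (tbl["fdr_q"] < thr.q_max)
    return list(tbl.loc[keep, "set_name"])


def tokenize(name: str, stop_tokens: frozenset[str] = DEFAULT_STOP_TOKENS) -> set[str]:
    """Unique upper-cased underscore-split tokens of a set name, minus stops."""
    return {t for t in name.upper().split("_") if t and t not in stop_tokens}


def mine_keywords(
    all_names,
    enriched_names,
    min_count: int = 2,
    stop_tokens: frozenset[str] = DEFAULT_STOP_TOKENS,
) -> pd.DataFrame:
    """Hypergeometric over-representation of name keywords among enriched sets.

    For each keyword: N = number of sets in the collection, K = sets whose
    name carries the keyword, n = enriched sets, k = enriched sets carrying
    it; p = P(X >= k) with BH adjustment across keywords. Keywords seen in
    fewer than ``min_count`` set names are dropped before adjustment.
    Duplicate names are dropped with a warning; results are invariant to
    name order.
    """
    all_list = list(dict.fromkeys(all_names))
    if len(all_list) < len(list(all_names)):
        logger.warning("duplicate set names dropped from the collection")
    enr_list = list(dict.fromkeys(enriched_names))
    if not set(enr_list) <= set(all_list):
        raise ValueError("enriched names must be a subset of the collection names")
    if not enr_list:
        logger.warning("no enriched sets: returning an empty keyword table")
        return pd.DataFrame(columns=["keyword", "n_background", "n_enriched", "p", "padj"])

    bg_counts: dict[str, int] = {}
    for name in all_list:
        for tok in tokenize(name, stop_tokens):
            bg_counts[tok] = bg_counts.get(tok, 0) + 1
    enr_counts: dict[str, int] = {}
    for name in enr_list:
        for tok in tokenize(name, stop_tokens):
            enr_counts[tok] = enr_counts.get(tok, 0) + 1

    keywords = sorted(t for t, c in bg_counts.items() if c >= min_count)
    N, n = len(all_list), len(enr_list)
    rows = []
    for tok in keywords:
        K = bg_counts[tok]
        k = enr_counts.get(tok, 0)
        rows.append((tok, K, k, hypergeom_upper(k, N, K, n)))
    out = pd.DataFrame(rows, columns=["keyword", "n_background", "n_enriched", "p"])
    out["padj"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def gene_set_overlap_test(set_a, set_b, universe_size: int) -> tuple[int, float]:
    """Upper-tail hypergeometric test of the overlap between two gene sets."""
    a, b = set(set_a), set(set_b)
    if universe_size < len(a | b):
        raise ValueError("universe_size must be at least |a union b|")
    k = len(a & b)
    p = hypergeom_upper(k, universe_size, len(b), len(a))
    return k, p
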