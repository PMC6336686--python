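"""Readers and writers for the plain-text formats the pipeline consumes.

Conventions: expression matrices are TSV with genes (or miRNAs) as rows and
samples as columns, values on the log2 scale; peaks are 6-column BED
(0-based, half-open); TSS tables are TSV with 1-based positions; DE and
clinical tables are TSV with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from . import specs

DE_COLUMNS = ["gene", "log2FC", "SE", "p", "padj", "contrast"]
TSS_COLUMNS = ["gene", "chrom", "strand", "tss"]
BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="feature")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DE_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"DE table missing columns: {missing}")
    return df


def write_bed(peaks: pd.DataFrame, path) -> None:
    """Write peaks as 6-column BED. Expects chrom/start/end (+ optional name,
    score, strand)."""
    df = peaks.copy()
    if "name" not in df.columns:
        df["name"] = [f"peak_{i}" for i in range(len(df))]
    if "score" not in df.columns:
        df["score"] = 0
    if "strand" not in df.columns:
        df["strand"] = "."
    df[BED_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : min(6, df.shape[1])]
    df.columns = BED_COLUMNS[: df.shape[1]]
    if df.shape[1] < 3:
        raise ValueError("BED file must have at least 3 columns")
    if ((df["end"] <= df["start"]) | (df["start"] < 0)).any():
        raise ValueError("BED intervals must satisfy 0 <= start < end")
    return df


def write_tss(tss: pd.DataFrame, path) -> None:
    tss[TSS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_tss(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TSS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"TSS table missing columns: {missing}")
    if (df["tss"] < 1).any():
        raise ValueError("TSS positions are 1-based and must be >= 1")
    return df


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene-set memberships from GMT (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    lines = ["\t".join([name, "na", *members]) for name, members in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


# -- config ----------------------------------------------------------------

_SPEC_KINDS = {
    "cohort": specs.CohortSpec,
    "de": specs.DEExperimentSpec,
    "cistrome": specs.CistromeSpec,
    "genesets": specs.GeneSetSpec,
}

_NESTED = {
    "planted_axis": specs.PlantedAxis,
    "planted_outliers": specs.PlantedOutliers,
    "planted_survival": specs.PlantedSurvival,
}


def load_config(path, kind: str, seed: int | None = None):
    """Build a generator spec from a YAML (or JSON) config file.

    ``kind`` selects the spec type (cohort/de/cistrome/genesets); a top-level
    key of that name may hold the fields, or they may sit at the root.
    ``seed`` overrides the config's seed when given.
    """
    if kind not in _SPEC_KINDS:
        raise ValueError(f"unknown config kind: {kind!r}")
    raw = yaml.safe_load(Path(path).read_text())
    if isinstance(raw, dict) and kind in raw:
        raw = raw[kind]
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping of spec fields")
    fields = dict(raw)

    def _build(cls, mapping):
        sub = dict(mapping)
        for tup_key in ("target_gene_ids", "gene_ids", "subgroup_gene_ids"):
            if tup_key in sub:
                sub[tup_key] = tuple(sub[tup_key])
        return cls(**sub)

    for key, cls in _NESTED.items():
        if key in fields and fields[key] is not None:
            val = fields[key]
            if key == "planted_axis" and isinstance(val, list):
                fields[key] = tuple(_build(cls, v) for v in val)
            else:
                fields[key] = _build(cls, val)
    if "planted_bound_gene_ids" in fields:
        fields["planted_bound_gene_ids"] = tuple(fields["planted_bound_gene_ids"])
    if "keyword_vocab" in fields:
        fields["keyword_vocab"] = tuple(fields["keyword_vocab"])
    if seed is not None:
        fields["seed"] = seed
    spec = _SPEC_KINDS[kind](**fields)
    spec.validate()
    return spec
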