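"""Specification types for the synthetic-data generators.

Each spec is a frozen dataclass whose ``validate`` method raises
``SpecValidationError`` naming the offending field. Specs can be loaded from
a single YAML/JSON config file mirroring these fields (see ``io.load_config``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence


class SpecValidationError(ValueError):
    """Raised when a generator spec field is invalid; names the field."""

    def __init__(self, spec_field: str, message: str):
        self.field = spec_field
        super().__init__(f"{spec_field}: {message}")


@dataclass(frozen=True)
class PlantedAxis:
    """A miRNA whose expression stratifies the cohort, and its target genes.

    Within the lower-quartile stratum of the miRNA the target genes are
    generated with Pearson correlation ``r_low`` against the miRNA; within
    the upper quartile, ``r_high``. Middle samples receive the mean of both.
    """

    mirna_id: str
    target_gene_ids: tuple[str, ...]
    r_low: float
    r_high: float

    def validate(self) -> None:
        for name, r in (("r_low", self.r_low), ("r_high", self.r_high)):
            if not -1.0 <= r <= 1.0:
                raise SpecValidationError(f"planted_axis.{name}", "must be in [-1, 1]")


@dataclass(frozen=True)
class PlantedOutliers:
    """Genes shifted by ``z_effect`` normal-reference SDs in a tumor subset."""

    gene_ids: tuple[str, ...]
    z_effect: float
    tumor_fraction: float

    def validate(self) -> None:
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise SpecValidationError("planted_outliers.tumor_fraction", "must be in [0, 1]")


@dataclass(frozen=True)
class PlantedSurvival:
    """A tumor subgroup (marked by elevated subgroup genes) with planted hazard.

    Disease-free survival times are exponential; subgroup tumors have hazard
    ``hazard_ratio`` times the baseline. ``event_fraction`` sets the overall
    event rate via an administrative censoring horizon.
    """

    subgroup_gene_ids: tuple[str, ...]
    hazard_ratio: float
    event_fraction: float
    subgroup_fraction: float = 0.5
    marker_shift: float = 3.0
    gleason_high_prob_subgroup: float = 0.8
    gleason_high_prob_other: float = 0.2

    def validate(self) -> None:
        if self.hazard_ratio <= 0:
            raise SpecValidationError("planted_survival.hazard_ratio", "must be > 0")
        if not 0.0 <= self.event_fraction <= 1.0:
            raise SpecValidationError("planted_survival.event_fraction", "must be in [0, 1]")
        if not 0.0 < self.subgroup_fraction < 1.0:
            raise SpecValidationError("planted_survival.subgroup_fraction", "must be in (0, 1)")


@dataclass(frozen=True)
class CohortSpec:
    """Tumor/normal expression cohort with planted axis, outliers and survival."""

    n_tumors: int
    n_normals: int
    n_genes: int
    n_mirnas: int
    planted_axis: PlantedAxis | tuple[PlantedAxis, ...] | None = None
    planted_outliers: PlantedOutliers | None = None
    planted_survival: PlantedSurvival | None = None
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    seed: int = 0

    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    def mirna_ids(self) -> list[str]:
        return [f"miR-{i:04d}" for i in range(self.n_mirnas)]

    def axes(self) -> tuple[PlantedAxis, ...]:
        """Planted axis groups, normalized to a tuple (possibly empty).

        Several groups may share a stratifying miRNA to plant different
        correlation signs (e.g. a positively coupled target group and a
        mirror negatively coupled one) in the same cohort.
        """
        if self.planted_axis is None:
            return ()
        if isinstance(self.planted_axis, PlantedAxis):
            return (self.planted_axis,)
        return tuple(self.planted_axis)

    def validate(self) -> None:
        for name in ("n_tumors", "n_normals", "n_genes", "n_mirnas"):
            if getattr(self, name) < 0:
                raise SpecValidationError(name, "must be >= 0")
        if self.noise_sd <= 0:
            raise SpecValidationError("noise_sd", "must be > 0")
        genes = set(self.gene_ids())
        mirnas = set(self.mirna_ids())
        seen: set[str] = set()
        for ax in self.axes():
            ax.validate()
            if ax.mirna_id not in mirnas:
                raise SpecValidationError("planted_axis.mirna_id", "not in the miRNA universe")
            targets = set(ax.target_gene_ids)
            if not targets <= genes:
                raise SpecValidationError(
                    "planted_axis.target_gene_ids", "not a subset of the gene universe"
                )
            if targets & seen:
                raise SpecValidationError(
                    "planted_axis.target_gene_ids", "target sets of axis groups must be disjoint"
                )
            seen |= targets
        if self.planted_outliers is not None:
            self.planted_outliers.validate()
            if not set(self.planted_outliers.gene_ids) <= genes:
                raise SpecValidationError(
                    "planted_outliers.gene_ids", "not a subset of the gene universe"
                )
        if self.planted_survival is not None:
            self.planted_survival.validate()
            if not set(self.planted_survival.subgroup_gene_ids) <= genes:
                raise SpecValidationError(
                    "planted_survival.subgroup_gene_ids", "not a subset of the gene universe"
                )


@dataclass(frozen=True)
class DEExperimentSpec:
    """Two-factor (knockdown x hormone) expression experiment.

    ``planted_responsive`` genes get a hormone log2 fold change drawn from
    N(lfc_mean, lfc_sd) with random sign; a stated subset of them has that
    effect multiplied by ``dampening_factor`` in the knockdown conditions
    only. ``dampening_factor = 1`` is the no-dampening null.
    """

    n_genes: int
    n_replicates: int = 3
    n_responsive: int = 0
    dampened_fraction: float = 0.0
    dampening_factor: float = 1.0
    lfc_mean: float = 1.5
    lfc_sd: float = 0.3
    lfc_min: float = 0.5
    residual_sd: float = 0.1
    baseline_mean: float = 8.0
    seed: int = 0

    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    def validate(self) -> None:
        if self.n_genes < 0:
            raise SpecValidationError("n_genes", "must be >= 0")
        if self.n_replicates < 2:
            raise SpecValidationError("n_replicates", "must be >= 2 (SE undefined otherwise)")
        if not 0 <= self.n_responsive <= self.n_genes:
            raise SpecValidationError("n_responsive", "must be in [0, n_genes]")
        if not 0.0 <= self.dampened_fraction <= 1.0:
            raise SpecValidationError("dampened_fraction", "must be in [0, 1]")
        if not 0.0 <= self.dampening_factor <= 1.0:
            raise SpecValidationError("dampening_factor", "must be in [0, 1]")
        if self.residual_sd <= 0:
            raise SpecValidationError("residual_sd", "must be > 0")


@dataclass(frozen=True)
class CistromeSpec:
    """Peak set + TSS table + DE table with planted bound-gene effect.

    Every planted bound gene receives at least one peak within ``window`` bp
    of its TSS; bound genes' |log2FC| is elevated by ``bound_effect`` on
    average in the accompanying DE table.
    """

    n_chroms: int = 4
    chrom_length: int = 50_000_000
    n_peaks: int = 500
    n_genes: int = 1000
    planted_bound_gene_ids: tuple[str, ...] = ()
    bound_effect: float = 0.0
    window: int = 7500
    peak_width_mean: int = 300
    de_lfc_sd: float = 0.3
    seed: int = 0

    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    def validate(self) -> None:
        if self.window <= 0:
            raise SpecValidationError("window", "must be > 0")
        if self.n_chroms < 1:
            raise SpecValidationError("n_chroms", "must be >= 1")
        if self.chrom_length < 2 * self.window:
            raise SpecValidationError("chrom_length", "too short for the TSS window")
        if not set(self.planted_bound_gene_ids) <= set(self.gene_ids()):
            raise SpecValidationError(
                "planted_bound_gene_ids", "not a subset of the gene universe"
            )
        if self.bound_effect < 0:
            raise SpecValidationError("bound_effect", "must be >= 0")


@dataclass(frozen=True)
class GeneSetSpec:
    """Collection of keyword-named gene sets with a planted enriched keyword."""

    n_sets: int = 300
    n_enriched: int = 30
    keyword_vocab: tuple[str, ...] = ()
    planted_keyword: str | None = None
    enrichment_rate: float = 0.8
    background_rate: float = 0.1
    tokens_per_name: int = 4
    genes_per_set: int = 25
    n_genes: int = 2000
    seed: int = 0

    def validate(self) -> None:
        if len(self.keyword_vocab) == 0:
            raise SpecValidationError("keyword_vocab", "must be non-empty")
        for name in ("enrichment_rate", "background_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise SpecValidationError(name, "must be in [0, 1]")
        if self.n_enriched > self.n_sets:
            raise SpecValidationError("n_enriched", "must be <= n_sets")


def spec_to_dict(spec) -> dict:
    return asdict(spec)
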