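import numpy as np
import pandas as pd
import pytest

from cistrans.specs import (
    CohortSpec,
    DEExperimentSpec,
    PlantedAxis,
    PlantedOutliers,
    PlantedSurvival,
)
from cistrans import synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-tumor cohort with one planted axis, outliers and survival."""
    spec = CohortSpec(
        n_tumors=120,
        n_normals=30,
        n_genes=100,
        n_mirnas=3,
        planted_axis=PlantedAxis("miR-0000", ("G00000", "G00001", "G00002"), 0.8, 0.1),
        planted_outliers=PlantedOutliers(("G00010", "G00011"), 5.0, 0.45),
        planted_survival=PlantedSurvival(("G00020",), 2.0, 0.4),
        seed=123,
    )
    genes, mirnas, clinical = synthetic.generate_cohort(spec)
    return spec, genes, mirnas, clinical


@pytest.fixture(scope="session")
def dampened_experiment():
    spec = DEExperimentSpec(
        n_genes=600,
        n_responsive=400,
        dampened_fraction=0.6,
        dampening_factor=0.4,
        residual_sd=0.1,
        seed=321,
    )
    tables, labels = synthetic.generate_de_experiment(spec)
    return spec, tables, labels


def random_intervals(rng: np.random.Generator, n: int, chroms=("chr1", "chr2"),
                     length: int = 100_000) -> pd.DataFrame:
    start = rng.integers(0, length - 500, size=n)
    width = rng.integers(1, 500, size=n)
    return pd.DataFrame(
        dict(
            chrom=rng.choice(chroms, size=n),
            start=start,
            end=start + width,
            name=[f"p{i}" for i in range(n)],
        )
    )
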