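"""Consensus voting, pulldown targetome calling, quartile stratification,
correlation shift with Welch test, axis DE, and the correlation matrix."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cistrans import synthetic
from cistrans.axis import (
    axis_differential_expression,
    call_pulldown_targets,
    consensus_targets,
    correlation_matrix,
    correlation_shift,
    mirna_set_elevation_test,
    quartile_stratify,
    StratifiedCohort,
)
from cistrans.modulation import call_degs
from cistrans.specs import CohortSpec, PlantedAxis


def test_consensus_votes_boundary_and_scan():
    votes = pd.DataFrame(
        dict(mirna=["m1"] * 4, gene=["a", "b", "c", "d"], votes=[9, 5, 4, 0])
    )
    targets = consensus_targets(votes)
    assert targets == {"m1": ["a", "b"]}  # >= 5 kept, 4 dropped
    rng = np.random.default_rng(6)
    big = pd.DataFrame(
        dict(
            mirna=rng.choice(["m1", "m2"], 200),
            gene=[f"g{i}" for i in range(200)],
            votes=rng.integers(0, 10, 200),
        )
    )
    got = consensus_targets(big, min_votes=5)
    for m, genes in got.items():
        expected = sorted(
            r.gene for r in big.itertuples() if r.mirna == m and r.votes >= 5
        )
        assert genes == expected


def test_pulldown_control_subtraction_and_boundary():
    lfc_in = np.log2(1.5)
    tbl = pd.DataFrame(
        dict(
            gene=["kept", "in_both", "at_fc", "weak"],
            log2FC_mir=[lfc_in, lfc_in, np.log2(1.2), lfc_in],
            padj_mir=[0.01, 0.01, 0.01, 0.2],
            log2FC_ctl=[0.0, lfc_in, 0.0, 0.0],
            padj_ctl=[0.9, 0.01, 0.9, 0.9],
        )
    )
    assert call_pulldown_targets(tbl) == ["kept"]  # FC boundary strict, control subtracted
    with pytest.raises(ValueError, match="control"):
        call_pulldown_targets(tbl.drop(columns=["log2FC_ctl", "padj_ctl"]))


def test_pulldown_equals_row_scan():
    rng = np.random.default_rng(9)
    tbl = pd.DataFrame(
        dict(
            gene=[f"g{i}" for i in range(50)],
            log2FC_mir=rng.normal(0.2, 0.4, 50),
            padj_mir=rng.uniform(0, 0.2, 50),
            log2FC_ctl=rng.normal(0, 0.4, 50),
            padj_ctl=rng.uniform(0, 0.5, 50),
        )
    )
    got = call_pulldown_targets(tbl)
    lfc_min = np.log2(1.2)
    expected = [
        r.gene for r in tbl.itertuples()
        if (r.log2FC_mir > lfc_min and r.padj_mir < 0.05)
        and not (r.log2FC_ctl > lfc_min and r.padj_ctl < 0.05)
    ]
    assert got == expected


def test_elevation_test_enumeration_oracle():
    """8-miRNA universe, 3-miRNA set: compare to 8^3 exact enumeration."""
    rng = np.random.default_rng(13)
    vals = rng.normal(0, 1, 8)
    de = pd.DataFrame(dict(mirna=[f"m{i}" for i in range(8)], log2FC=vals))
    cand = ["m0", "m3", "m5"]
    obs = vals[[0, 3, 5]].mean()
    exact = np.mean(
        [vals[list(c)].mean() >= obs for c in itertools.product(range(8), repeat=3)]
    )
    res = mirna_set_elevation_test(de, cand, n_resamples=100_000, seed=2)
    assert abs(res.p_empirical - exact) < 0.02
    with pytest.raises(ValueError, match="empty"):
        mirna_set_elevation_test(de, [], n_resamples=1000, seed=0)


def test_elevation_test_extreme_set():
    de = pd.DataFrame(
        dict(mirna=[f"m{i}" for i in range(40)],
             log2FC=np.r_[np.full(5, 10.0), np.zeros(35)])
    )
    res = mirna_set_elevation_test(de, [f"m{i}" for i in range(5)],
                                   n_resamples=10_000, seed=1)
    assert res.p_empirical < 0.001


def test_quartile_stratify_forced_and_sizes():
    v = pd.Series(range(1, 9), index=[f"s{i}" for i in range(1, 9)])
    strata = quartile_stratify(v)
    assert strata.low == ("s1", "s2") and strata.high == ("s7", "s8")
    big = pd.Series(np.arange(498.0), index=[f"s{i}" for i in range(498)])
    st = quartile_stratify(big)
    assert len(st.low) == len(st.high) == 124  # floor(498/4)


def test_quartile_stratify_tie_determinism_and_errors():
    vals = [1.0, 1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 3.0]
    v = pd.Series(vals, index=[f"s{i}" for i in range(8)])
    a = quartile_stratify(v)
    b = quartile_stratify(v)
    assert a.low == b.low == ("s0", "s1") and a.high == ("s6", "s7")
    with pytest.raises(ValueError, match="8 samples"):
        quartile_stratify(v.iloc[:5])
    with pytest.raises(ValueError, match="all values equal"):
        quartile_stratify(pd.Series([1.0] * 8))
    with pytest.raises(ValueError, match="disjoint"):
        StratifiedCohort(low=("a",), high=("a",))


def _axis_cohort(r_low_pos=0.7, r_high_pos=0.1, seed=0, n_tumors=480, n_genes=400):
    pos = tuple(f"G{i:05d}" for i in range(100))
    neg = tuple(f"G{i:05d}" for i in range(100, 150))
    spec = CohortSpec(
        n_tumors=n_tumors, n_normals=10, n_genes=n_genes, n_mirnas=2,
        planted_axis=(
            PlantedAxis("miR-0000", pos, r_low_pos, r_high_pos),
            PlantedAxis("miR-0000", neg, -r_high_pos, -r_low_pos),
        ),
        seed=seed,
    )
    genes, mirnas, clinical = synthetic.generate_cohort(spec)
    tumors = clinical.loc[clinical["role"] == "tumor", "sample"].tolist()
    expr = genes[tumors].copy()
    expr.loc["miR-0000"] = mirnas.loc["miR-0000", tumors]
    strata = quartile_stratify(mirnas.loc["miR-0000", tumors])
    return pos, neg, expr, strata


def test_correlation_shift_identity_all_unchanged():
    rng = np.random.default_rng(21)
    samples = [f"T{i}" for i in range(60)]
    expr = pd.DataFrame(rng.normal(size=(20, 60)),
                        index=[f"G{i}" for i in range(20)], columns=samples)
    # high stratum duplicates the low stratum expression exactly
    expr[[f"T{i}" for i in range(30, 60)]] = expr[[f"T{i}" for i in range(30)]].to_numpy()
    strata = StratifiedCohort(low=tuple(samples[:30]), high=tuple(samples[30:]))
    table, summary = correlation_shift("G0", [f"G{i}" for i in range(1, 20)], expr, strata)
    assert np.allclose(table["delta"], 0, atol=1e-12)
    assert (table["shift_class"] == "unchanged").all() or table.empty


def test_correlation_shift_recovers_planted_delta():
    pos, neg, expr, strata = _axis_cohort(seed=3)
    table, summary = correlation_shift("miR-0000", [g for g in expr.index if g != "miR-0000"],
                                       expr, strata)
    planted = table[table["gene"].isin(pos)]
    assert abs(planted["delta"].mean() - 0.6) < 0.1
    assert (planted["shift_class"] == "strengthened").mean() > 0.8
    w = summary["welch"]
    assert not w["inestimable"] and w["p"] < 0.05 and w["effect"] > 0


def test_correlation_shift_stratum_exchange_antisymmetry():
    pos, neg, expr, strata = _axis_cohort(seed=4)
    deps = [g for g in expr.index if g != "miR-0000"]
    t1, s1 = correlation_shift("miR-0000", deps, expr, strata)
    swapped = StratifiedCohort(low=strata.high, high=strata.low)
    t2, s2 = correlation_shift("miR-0000", deps, expr, swapped)
    m = t1.merge(t2, on="gene", suffixes=("_a", "_b"))
    assert np.allclose(m["delta_a"], -m["delta_b"], atol=1e-12)
    c1, c2 = s1["class_counts"], s2["class_counts"]
    assert c1["strengthened"] == c2["weakened"]
    assert c1["weakened"] == c2["strengthened"]


def test_correlation_shift_validation():
    _, _, expr, strata = _axis_cohort(seed=5, n_genes=200)
    with pytest.raises(ValueError, match="absent"):
        correlation_shift("miR-0000", ["NOPE"], expr, strata)
    tiny = StratifiedCohort(low=strata.low[:5], high=strata.high)
    with pytest.raises(ValueError, match="at least 10"):
        correlation_shift("miR-0000", list(expr.index[:5]), expr, tiny)


def test_axis_de_planted_shift_recovered():
    rng = np.random.default_rng(30)
    n_a, n_b = 60, 66
    genes = [f"g{i}" for i in range(300)]
    a_cols = [f"A{i}" for i in range(n_a)]
    b_cols = [f"B{i}" for i in range(n_b)]
    x = rng.normal(8, 0.5, size=(300, n_a + n_b))
    x[:50, :n_a] += 1.0  # 2-fold shift in the first 50 genes
    expr = pd.DataFrame(x, index=genes, columns=a_cols + b_cols)
    de = axis_differential_expression(expr, a_cols, b_cols)
    up, down = call_degs(de)  # schema composes with DEG calling
    assert len(set(genes[:50]) & up) >= 45
    assert len(up - set(genes[:50])) <= 5


def test_axis_de_null_calibration_and_errors():
    rng = np.random.default_rng(31)
    expr = pd.DataFrame(rng.normal(size=(200, 20)),
                        index=[f"g{i}" for i in range(200)],
                        columns=[f"S{i}" for i in range(20)])
    de = axis_differential_expression(expr, [f"S{i}" for i in range(10)],
                                      [f"S{i}" for i in range(10, 20)])
    assert (de["p"] < 0.05).mean() < 0.12  # ~ alpha under the null
    with pytest.raises(ValueError, match="disjoint"):
        axis_differential_expression(expr, ["S0", "S1", "S2"], ["S2", "S3", "S4"])
    with pytest.raises(ValueError, match="at least 3"):
        axis_differential_expression(expr, ["S0", "S1"], ["S2", "S3", "S4"])


def test_correlation_matrix_diagonal_planted_and_flags(caplog):
    rng = np.random.default_rng(33)
    n = 300
    base = rng.normal(size=n)
    x = np.vstack([
        base,
        -0.9 * base + np.sqrt(1 - 0.81) * rng.normal(size=n),
        rng.normal(size=n),
        np.zeros(n),
    ])
    expr = pd.DataFrame(x, index=["a", "b", "c", "flat"])
    with caplog.at_level("WARNING"):
        r, q = correlation_matrix(expr)
    assert r.loc["a", "a"] == 1.0
    assert -0.95 <= r.loc["a", "b"] <= -0.8
    assert np.isnan(r.loc["flat", "a"])
    assert q.loc["a", "b"] == q.loc["b", "a"] < 0.05
    # sample-order permutation invariance
    perm = rng.permutation(n)
    r2, _ = correlation_matrix(expr.iloc[:, perm])
    pd.testing.assert_frame_equal(r, r2)


from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(min_value=-100, max_value=100), min_size=8, max_size=60,
                unique=True))
def test_quartile_stratify_properties(values):
    """Strata have floor(n/4) samples each, are disjoint, and every low-stratum
    value is <= every high-stratum value."""
    v = pd.Series(values, index=[f"s{i}" for i in range(len(values))])
    st_ = quartile_stratify(v)
    k = len(values) // 4
    assert len(st_.low) == len(st_.high) == k
    assert not set(st_.low) & set(st_.high)
    assert max(v[list(st_.low)]) <= min(v[list(st_.high)])
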