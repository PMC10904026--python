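"""Repeated-measures ANOVA against a sums-of-squares oracle; Bonferroni."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import braincat.stats as bstats


def _table(values):
    """values[subject][i][j] -> long table with factors f1 (levels Ai), f2 (Bj)."""
    rows = []
    for s, mat in enumerate(values):
        for i, row in enumerate(mat):
            for j, v in enumerate(row):
                rows.append({"subj": s, "f1": f"A{i}", "f2": f"B{j}", "y": v})
    return pd.DataFrame(rows)


def _ss_oracle(values):
    """Textbook two-way within-subject decomposition (independent oracle)."""
    y = np.asarray(values, dtype=float)      # (n, a, b)
    n, a, b = y.shape
    grand = y.mean()
    A = y.mean(axis=(0, 2))
    B = y.mean(axis=(0, 1))
    S = y.mean(axis=(1, 2))
    AB = y.mean(axis=0)
    AS = y.mean(axis=2)
    BS = y.mean(axis=1)
    ss_a = n * b * ((A - grand) ** 2).sum()
    ss_b = n * a * ((B - grand) ** 2).sum()
    ss_ab = n * ((AB - A[:, None] - B[None, :] + grand) ** 2).sum()
    ss_as = b * ((AS - A[None, :] - S[:, None] + grand) ** 2).sum()
    ss_bs = a * ((BS - B[None, :] - S[:, None] + grand) ** 2).sum()
    ss_abs = ((y - AB[None] - AS[:, :, None] - BS[:, None, :]
               + A[None, :, None] + B[None, None, :] + S[:, None, None]
               - grand) ** 2).sum()
    f_a = (ss_a / (a - 1)) / (ss_as / ((a - 1) * (n - 1)))
    f_b = (ss_b / (b - 1)) / (ss_bs / ((b - 1) * (n - 1)))
    f_ab = (ss_ab / ((a - 1) * (b - 1))) / (ss_abs / ((a - 1) * (b - 1) * (n - 1)))
    return {"f1": (f_a, a - 1, (a - 1) * (n - 1)),
            "f2": (f_b, b - 1, (b - 1) * (n - 1)),
            "f1:f2": (f_ab, (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1))}


def test_rm_anova_matches_manual_ss_oracle():
    rng = np.random.default_rng(0)
    values = rng.normal(size=(4, 2, 2)) + np.array([[0.0, 0.5], [1.0, 1.2]])
    res = bstats.rm_anova(_table(values), "y", ["f1", "f2"], "subj")
    oracle = _ss_oracle(values)
    for _, row in res.iterrows():
        f, df1, df2 = oracle[row["effect"]]
        assert row["F"] == pytest.approx(f, rel=1e-8)
        assert row["df1"] == df1 and row["df2"] == df2


def test_rm_anova_three_level_factor_against_oracle():
    rng = np.random.default_rng(1)
    values = rng.normal(size=(5, 3, 2)) + np.arange(3)[None, :, None] * 0.8
    res = bstats.rm_anova(_table(values), "y", ["f1", "f2"], "subj")
    oracle = _ss_oracle(values)
    got = {r["effect"]: r for _, r in res.iterrows()}
    assert got["f1"]["F"] == pytest.approx(oracle["f1"][0], rel=1e-8)
    # the three-level factor carries a sphericity assessment
    assert np.isfinite(got["f1"]["mauchly_p"])
    assert 0 < got["f1"]["eps"] <= 1.0
    assert got["f1"]["p_gg"] >= got["f1"]["p"] - 1e-12


def test_rm_anova_null_design_not_significant():
    rng = np.random.default_rng(2)
    values = rng.normal(0, 1, size=(12, 3, 2)) * 0.1 + 5.0
    res = bstats.rm_anova(_table(values), "y", ["f1", "f2"], "subj")
    assert (res["p"] > 0.05).all()


def test_rm_anova_additive_design_has_no_interaction():
    rng = np.random.default_rng(3)
    n, a, b = 8, 3, 2
    subj = rng.normal(0, 0.3, n)
    eff_a = np.array([0.0, 1.0, 2.0])
    eff_b = np.array([0.0, 0.7])
    values = (subj[:, None, None] + eff_a[None, :, None] + eff_b[None, None, :]
              + rng.normal(0, 0.01, (n, a, b)))
    res = bstats.rm_anova(_table(values), "y", ["f1", "f2"], "subj")
    got = {r["effect"]: r for _, r in res.iterrows()}
    assert got["f1"]["p"] < 0.001 and got["f2"]["p"] < 0.001
    assert got["f1:f2"]["p"] > 0.05


def test_rm_anova_rejects_unbalanced():
    df = _table(np.zeros((3, 2, 2)))
    with pytest.raises(ValueError):
        bstats.rm_anova(df.iloc[:-1], "y", ["f1", "f2"], "subj")


def test_bonferroni_arithmetic():
    a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.1, 7.2, 8.0, 9.1, 10.0, 11.0, 12.0])
    b = a + np.array([0.3, -0.1, 0.4, 0.2, 0.3, 0.1, 0.2, 0.4, 0.1, 0.3, 0.2, 0.3])
    res = bstats.bonferroni_pairwise([("c", a, b)], family_size=10)
    row = res.iloc[0]
    assert row["p_bonferroni"] == pytest.approx(min(1.0, 10 * row["p"]))
    # p = 0.01 with m = 10 would not survive the 0.005 threshold
    assert not (0.01 * 10 < bstats.ALPHA)


def test_bonferroni_identical_samples():
    x = np.arange(12.0)
    res = bstats.bonferroni_pairwise([("same", x, x.copy())])
    assert res.iloc[0]["t"] == 0.0
    assert res.iloc[0]["p"] == 1.0
    assert not res.iloc[0]["significant"]


def test_bonferroni_unequal_pairing_rejected():
    with pytest.raises(ValueError):
        bstats.bonferroni_pairwise([("bad", np.zeros(3), np.zeros(4))])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(p=st.floats(1e-12, 1.0), m=st.integers(1, 50))
def test_bonferroni_adjustment_monotone_and_idempotent(p, m):
    adj = min(1.0, m * p)
    assert p <= adj <= 1.0
    assert min(1.0, 1 * adj) == adj     # idempotent at family size 1


def test_paired_cells_extraction():
    df = pd.DataFrame({
        "subj": [0, 1, 0, 1], "cond": ["x", "x", "y", "y"],
        "v": [1.0, 2.0, 3.0, 4.0]})
    a, b = bstats.paired_cells(df, "v", "subj", "cond", "x", "y")
    assert list(a) == [1.0, 2.0] and list(b) == [3.0, 4.0]
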