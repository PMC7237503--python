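"""Differential table, BH correction, consistency selection, intersection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ariomics.diffsig import (
    DesignError,
    differential_table,
    intersect_contexts,
    score_selection,
    select_consistent,
)

from conftest import make_matrix


def bh_bruteforce(p):
    """Independent BH recomputation from sorted p-values."""
    p = np.asarray(p)
    m = p.size
    order = np.argsort(p)
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def test_identical_groups_give_zero_fc_and_p_one(tiny_matrix):
    vals = tiny_matrix.values.copy()
    vals.iloc[:, 3:] = vals.iloc[:, :3].to_numpy()
    mat = make_matrix(
        {f: vals.loc[f].to_numpy() for f in vals.index},
        dict(zip(vals.columns, tiny_matrix.design["group"])),
    )
    res = differential_table(mat)
    assert np.allclose(res["log2fc"], 0.0)
    assert np.all(res["p"] > 0.99)


def test_noiseless_planted_fc_is_exact():
    mat = make_matrix(
        {"f1": [10.0, 10.0, 20.0, 20.0]},
        {"s1": "WT", "s2": "WT", "s3": "KO", "s4": "KO"},
    )
    res = differential_table(mat)
    assert res.loc[0, "log2fc"] == pytest.approx(1.0, abs=1e-12)


def test_q_matches_bruteforce_bh(small_proteome):
    mats, _, _ = small_proteome
    res = differential_table(mats["2D"])
    for _, grp in res.groupby(["group", "format"]):
        assert np.allclose(grp["q"], bh_bruteforce(grp["p"].to_numpy()), atol=1e-12)


def test_q_dominates_p_and_monotone_in_sorted_order(small_proteome):
    mats, _, _ = small_proteome
    res = differential_table(mats["3D"])
    assert (res["q"] >= res["p"] - 1e-12).all()
    for _, grp in res.groupby(["group", "format"]):
        s = grp.sort_values("p")
        assert (np.diff(s["q"]) >= -1e-12).all()


def test_requires_two_replicates():
    with pytest.raises(DesignError, match="2 replicates"):
        differential_table(
            make_matrix({"f": [1.0, 2.0, 3.0]}, {"a": "WT", "b": "WT", "c": "KO"})
        )


def test_unknown_group_raises(tiny_matrix):
    with pytest.raises(DesignError):
        differential_table(tiny_matrix, comparisons=[("nonesuch", "2D")])


def test_permutation_mode_flags_real_effects(small_proteome):
    mats, truth, _ = small_proteome
    res = differential_table(mats["2D"], permutation=True, n_permutations=199, seed=1)
    sig = truth.index[truth["is_signature"]]
    null = truth.index[~truth["is_signature"]]
    med_sig = res[res["feature"].isin(sig)].groupby("feature")["p"].max().median()
    med_null = res[res["feature"].isin(null)].groupby("feature")["p"].max().median()
    # permutation p-values are floored near 3/n_perm by near-identity label
    # splits of a 4v4 design, so planted effects sit low but not at 1/n_perm
    assert med_sig < 0.1
    assert med_null > 0.4


def test_select_consistent_empty_and_threshold_validation():
    assert select_consistent(pd.DataFrame()) == []
    res = pd.DataFrame(
        {"feature": ["f"], "group": ["g"], "format": ["x"],
         "log2fc": [2.0], "p": [0.001], "q": [0.01], "sign": [1]}
    )
    with pytest.raises(ValueError, match="fc_threshold"):
        select_consistent(res, fc_threshold=1.0)
    with pytest.raises(ValueError, match="k_of_n"):
        select_consistent(res, k_of_n=5)


def test_select_consistent_sign_rule():
    rows = []
    for i, (fcs, feat) in enumerate(
        [((1.0, 1.2), "same_sign"), ((1.0, -1.2), "flip"), ((0.3, 1.2), "one_weak")]
    ):
        for j, fc in enumerate(fcs):
            rows.append({"feature": feat, "group": f"g{j}", "format": "x",
                         "log2fc": fc, "p": 0.01, "q": 0.02, "sign": int(np.sign(fc))})
    res = pd.DataFrame(rows)
    assert select_consistent(res, 1.5, 0.05, k_of_n=2) == ["same_sign"]
    assert set(select_consistent(res, 1.5, 0.05, k_of_n=2, require_sign=False)) == {
        "same_sign", "flip"}
    # the sign veto applies to all qualifying comparisons even at k_of_n=1
    assert select_consistent(res, 1.5, 0.05, k_of_n=1) == ["same_sign", "one_weak"]


@settings(max_examples=30, deadline=None)
@given(
    seed=st.integers(0, 10_000),
    fc1=st.floats(1.1, 2.0),
    fc2=st.floats(0.0, 1.5),
    p1=st.floats(0.001, 0.2),
)
def test_select_consistent_monotone_in_thresholds(seed, fc1, fc2, p1):
    """Tightening any threshold never adds features (without the sign veto).

    The sign-consistency veto can re-admit a feature when a contrary-sign
    comparison stops qualifying, so monotonicity is asserted with
    require_sign=False.
    """
    rng = np.random.default_rng(seed)
    n = 40
    res = pd.DataFrame(
        {
            "feature": np.repeat([f"f{i}" for i in range(n)], 3),
            "group": np.tile(["a", "b", "c"], n),
            "format": "x",
            "log2fc": rng.normal(0, 1.5, 3 * n),
            "p": rng.uniform(0, 0.3, 3 * n),
        }
    )
    res["q"] = res["p"]
    res["sign"] = np.sign(res["log2fc"]).astype(int)
    loose = set(select_consistent(res, fc_threshold=fc1, p_threshold=p1 * 2, k_of_n=2,
                                  require_sign=False))
    tight = set(select_consistent(res, fc_threshold=fc1 + fc2, p_threshold=p1, k_of_n=2,
                                  require_sign=False))
    tighter_k = set(select_consistent(res, fc_threshold=fc1 + fc2, p_threshold=p1, k_of_n=3,
                                     require_sign=False))
    assert tight <= loose
    assert tighter_k <= tight


def test_intersect_contexts_subset_and_disjoint(small_proteome):
    mats, _, _ = small_proteome
    results = {f: differential_table(m) for f, m in mats.items()}
    sels = {
        f: select_consistent(r, 1.5, 0.05, k_of_n=3) for f, r in results.items()
    }
    res_all = pd.concat(results.values(), ignore_index=True)
    panel = intersect_contexts(sels, res=res_all)
    for sel in sels.values():
        assert set(panel.features) <= set(sel)
    # ordering by mean |log2fc| descending
    mean_abs = res_all[res_all["feature"].isin(panel.features)].groupby("feature")[
        "log2fc"].apply(lambda s: s.abs().mean())
    assert list(panel.features) == list(mean_abs.loc[panel.features].sort_values(
        ascending=False).index)
    assert len(intersect_contexts({"2D": ["a"], "3D": ["b"]})) == 0
    with pytest.raises(ValueError, match="two formats"):
        intersect_contexts({"2D": ["a"]})


def test_score_selection_edges(small_proteome):
    _, truth, _ = small_proteome
    signature = list(truth.index[truth["is_signature"]])
    assert score_selection(signature, truth) == {"sensitivity": 1.0, "observed_fdr": 0.0}
    assert score_selection([], truth) == {"sensitivity": 0.0, "observed_fdr": 0.0}
    with pytest.raises(KeyError):
        score_selection(["nope"], truth)


def test_score_selection_random_expectation(small_proteome):
    """Random selections hit the signature in proportion to its prevalence."""
    _, truth, design = small_proteome
    rng = np.random.default_rng(0)
    n_sig = int(truth["is_signature"].sum())
    s = 50
    sens = [
        score_selection(rng.choice(truth.index, s, replace=False), truth)["sensitivity"]
        for _ in range(1000)
    ]
    expected = s / len(truth)  # each signature member sampled w.p. s/n
    assert np.mean(sens) == pytest.approx(expected, rel=0.05)
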