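"""Stratification, Kaplan-Meier, logrank and signed-rank oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ariomics.survival import (
    CohortTable,
    km_curve,
    kmeans_1d_dp,
    logrank_test,
    stratify_kmeans,
    wilcoxon_signed_rank,
)
from ariomics.synthetic import gen_cohort


def cohort_from(expr, time=None, event=None):
    n = len(expr)
    return CohortTable(
        pd.DataFrame(
            {
                "expression": expr,
                "time": np.ones(n) if time is None else time,
                "event": np.ones(n, dtype=int) if event is None else event,
            },
            index=[f"p{i}" for i in range(n)],
        )
    )


def test_cohort_validation():
    with pytest.raises(ValueError, match="negative"):
        cohort_from([1, 2, 3], time=[-1, 1, 1])
    with pytest.raises(ValueError, match="event"):
        cohort_from([1, 2, 3], event=[0, 1, 2])


def test_kmeans_recovers_point_masses():
    expr = np.concatenate([np.full(5, -3.0), np.full(7, 0.0), np.full(4, 3.0)])
    strata = stratify_kmeans(cohort_from(expr), seed=0)
    labels = strata.labels
    assert set(labels[:5]) == {"low"}
    assert set(labels[5:12]) == {"mid"}
    assert set(labels[12:]) == {"high"}
    assert np.all(np.diff(strata.centroids) > 0)


def test_kmeans_order_invariance():
    rng = np.random.default_rng(4)
    expr = rng.normal(size=60)
    base = stratify_kmeans(cohort_from(expr), seed=5).labels
    perm = rng.permutation(60)
    shuffled = stratify_kmeans(cohort_from(expr[perm]), seed=5).labels
    assert list(shuffled) == list(base.iloc[perm])


def test_kmeans_matches_dp_optimum():
    """Multi-restart heuristic attains the DP-exact optimum for n <= 50."""
    for seed in range(10):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(9, 51))
        expr = rng.normal(size=n) * rng.uniform(0.5, 3)
        strata = stratify_kmeans(cohort_from(expr), k=3, restarts=20, seed=seed)
        centred = expr - expr.mean()
        wcss = sum(
            ((centred[(strata.labels == lab).to_numpy()] -
              centred[(strata.labels == lab).to_numpy()].mean()) ** 2).sum()
            for lab in set(strata.labels)
        )
        _, opt = kmeans_1d_dp(expr, 3)
        assert wcss == pytest.approx(opt, rel=1e-9, abs=1e-9)


def test_kmeans_degenerate_data_error():
    with pytest.raises(ValueError, match="distinct"):
        stratify_kmeans(cohort_from([1.0, 1.0, 1.0, 2.0]), k=3)


def test_km_closed_form_no_censoring():
    ct = cohort_from([0, 0, 0, 0], time=[1, 2, 3, 4])
    curve = km_curve(ct).set_index("time")["survival"]
    assert np.allclose(curve.loc[[1.0, 2.0, 3.0, 4.0]], [0.75, 0.5, 0.25, 0.0], atol=1e-12)
    assert curve.loc[0.0] == 1.0


def test_km_all_censored_stays_at_one():
    ct = cohort_from([0, 0, 0], time=[1, 2, 3], event=[0, 0, 0])
    assert (km_curve(ct)["survival"] == 1.0).all()


def test_km_matches_product_formula_on_random_cohorts():
    rng = np.random.default_rng(8)
    for _ in range(10):
        n = int(rng.integers(5, 25))
        time = np.round(rng.exponential(5, n), 1)
        event = rng.integers(0, 2, n)
        if event.sum() == 0:
            event[0] = 1
        ct = cohort_from(np.zeros(n), time=time, event=event)
        curve = km_curve(ct).set_index("time")["survival"]
        # brute-force product-limit estimator
        s = 1.0
        for t in sorted(set(time[event == 1])):
            d = int(((time == t) & (event == 1)).sum())
            at_risk = int((time >= t).sum())
            s *= 1 - d / at_risk
            assert curve.loc[t] == pytest.approx(s, abs=1e-12)


def test_km_monotone_and_bounded():
    cohort, _ = gen_cohort(n=100, seed=2)
    curve = km_curve(cohort)
    surv = curve["survival"].to_numpy()
    assert surv[0] == 1.0
    assert (np.diff(surv) <= 1e-12).all()
    assert ((surv >= 0) & (surv <= 1)).all()


def test_logrank_hand_computed_two_sample():
    """Two-stratum statistic equals the hand-computed (O-E)^2/V on 6 patients."""
    time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    event = np.ones(6, dtype=int)
    groups = np.array(["a", "a", "a", "b", "b", "b"])
    o_minus_e, var = 0.0, 0.0
    for t in time:
        at_risk = time >= t
        n = at_risk.sum()
        n_a = (at_risk & (groups == "a")).sum()
        d = 1
        e_a = d * n_a / n
        o_a = 1.0 if groups[time == t][0] == "a" else 0.0
        o_minus_e += o_a - e_a
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    chi2_hand = o_minus_e**2 / var
    ct = cohort_from(np.zeros(6), time=time, event=event)
    strata = pd.Series(groups, index=ct.data.index, name="stratum")
    from ariomics.survival import StrataAssignment

    res = logrank_test(StrataAssignment(strata, np.array([0.0, 1.0])), ct)
    assert res["chi2"] == pytest.approx(chi2_hand, rel=1e-9)
    assert res["df"] == 1


def test_logrank_extreme_separation():
    time = np.concatenate([np.arange(1, 21), np.arange(100, 120)])
    ct = cohort_from(np.zeros(40), time=time)
    labels = pd.Series(["early"] * 20 + ["late"] * 20, index=ct.data.index)
    from ariomics.survival import StrataAssignment

    res = logrank_test(StrataAssignment(labels, np.array([0.0, 1.0])), ct)
    assert res["p"] < 1e-4


def test_logrank_invariant_under_monotone_time_transform():
    cohort, _ = gen_cohort(n=120, seed=3)
    strata = stratify_kmeans(cohort, seed=0)
    base = logrank_test(strata, cohort)
    warped = CohortTable(cohort.data.assign(time=np.log1p(cohort.data["time"]) ** 2))
    res = logrank_test(strata, warped)
    assert res["chi2"] == pytest.approx(base["chi2"], rel=1e-9)


def test_logrank_single_stratum_error():
    cohort, _ = gen_cohort(n=30, seed=0)
    labels = pd.Series("only", index=cohort.data.index)
    from ariomics.survival import StrataAssignment

    with pytest.raises(ValueError, match="two non-empty"):
        logrank_test(StrataAssignment(labels, np.array([0.0])), cohort)


def test_wilcoxon_all_positive_exact():
    res = wilcoxon_signed_rank(np.arange(1, 15, dtype=float))
    assert res["method"] == "exact"
    assert res["p"] == pytest.approx(2 * (1 / 2**14), rel=1e-12)


def test_wilcoxon_symmetric_differences_near_one():
    diffs = np.array([-3.0, 3.0, -2.0, 2.0, -1.0, 1.0, -4.0, 4.0])
    assert wilcoxon_signed_rank(diffs)["p"] > 0.9


def test_wilcoxon_matches_enumeration():
    """Exact p equals brute-force enumeration over all 2^n sign patterns."""
    rng = np.random.default_rng(6)
    for trial in range(6):
        n = int(rng.integers(5, 13))
        diffs = np.round(rng.normal(0.4, 1.0, n), 1)
        diffs = diffs[diffs != 0]
        if diffs.size < 5:
            continue
        res = wilcoxon_signed_rank(diffs)
        ranks = stats.rankdata(np.abs(diffs))
        w_obs = ranks[diffs > 0].sum()
        total = 0
        m = diffs.size
        lo = hi = 0
        for signs in itertools.product([0, 1], repeat=m):
            w = sum(r for s, r in zip(signs, ranks) if s)
            lo += w <= w_obs + 1e-9
            hi += w >= w_obs - 1e-9
        p_brute = min(1.0, 2 * min(lo, hi) / 2**m)
        assert res["p"] == pytest.approx(p_brute, rel=1e-12)


def test_wilcoxon_matches_scipy_without_ties():
    rng = np.random.default_rng(9)
    diffs = rng.normal(0.5, 1, 15)
    ours = wilcoxon_signed_rank(diffs)
    ref = stats.wilcoxon(diffs, alternative="two-sided", mode="exact")
    assert ours["p"] == pytest.approx(ref.pvalue, rel=1e-9)


def test_wilcoxon_degenerate_inputs():
    with pytest.raises(ValueError, match="at least 5"):
        wilcoxon_signed_rank(np.array([1.0, 2.0]))
    with pytest.raises(ValueError, match="zero"):
        wilcoxon_signed_rank(np.zeros(8))


def test_cohort_generator_censoring_and_power():
    cohort, _ = gen_cohort(n=60, censor_rate=0.0, seed=1)
    assert (cohort.data["event"] == 1).all()
    # planted HR 2 between extreme strata at n=300: stratification + logrank
    # rejects at 0.05 in a clear majority of seeds
    rejections = 0
    for seed in range(50):
        cohort, _ = gen_cohort(n=300, hazard_ratio_per_group=(1.0, 1.4, 2.0), seed=seed)
        strata = stratify_kmeans(cohort, seed=0)
        rejections += logrank_test(strata, cohort)["p"] < 0.05
    assert rejections > 25
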