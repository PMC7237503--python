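"""Expression-based patient stratification and survival statistics.

A cohort table carries one expression value per patient (a single gene of
interest), a right-censored survival time and an event flag, plus optional
paired pre/post immunohistochemistry histoscores.  Patients are stratified
into low/mid/high expression groups by 1-D k-means on mean-centred
expression, survival per stratum is estimated by Kaplan-Meier and compared
with a k-sample logrank test; paired histoscores are compared with an exact
Wilcoxon matched-pair signed-rank test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sklearn.cluster import KMeans

__all__ = [
    "CohortTable",
    "StrataAssignment",
    "stratify_kmeans",
    "kmeans_1d_dp",
    "km_curve",
    "logrank_test",
    "wilcoxon_signed_rank",
]


@dataclass
class CohortTable:
    """Per-patient expression, survival time and event flag."""

    data: pd.DataFrame  # index patient id; columns expression, time, event

    def __post_init__(self):
        required = {"expression", "time", "event"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        if (self.data["time"] < 0).any():
            raise ValueError("negative survival times")
        if not self.data["event"].isin([0, 1]).all():
            raise ValueError("event flags must be 0/1")

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class StrataAssignment:
    labels: pd.Series  # patient id -> stratum label
    centroids: np.ndarray  # ascending

    @property
    def strata(self) -> list[str]:
        return list(pd.unique(self.labels))


_K3_NAMES = ("low", "mid", "high")


def _stratum_names(k: int) -> list[str]:
    return list(_K3_NAMES) if k == 3 else [f"s{i + 1}" for i in range(k)]


def stratify_kmeans(
    cohort: CohortTable,
    k: int = 3,
    restarts: int = 10,
    seed: int = 0,
) -> StrataAssignment:
    """1-D k-means stratification on mean-centred expression.

    Best of ``restarts`` k-means++ initialisations by within-cluster sum of
    squares; clusters are relabelled by ascending centroid (low/mid/high for
    k = 3).  Deterministic under a fixed seed and invariant to patient
    order.
    """
    expr = cohort.data["expression"].to_numpy(dtype=float)
    if np.unique(expr).size < k:
        raise ValueError(
            f"need at least {k} distinct expression values, "
            f"got {np.unique(expr).size}"
        )
    centred = expr - expr.mean()
    # sort for order invariance; map assignments back afterwards
    order = np.argsort(centred, kind="stable")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed % (2**32))
    raw = km.fit_predict(centred[order].reshape(-1, 1))
    centroids = km.cluster_centers_.ravel()
    rank = {old: new for new, old in enumerate(np.argsort(centroids))}
    names = _stratum_names(k)
    labels_sorted = np.array([names[rank[c]] for c in raw])
    labels = np.empty(len(expr), dtype=object)
    labels[order] = labels_sorted
    return StrataAssignment(
        labels=pd.Series(labels, index=cohort.data.index, name="stratum"),
        centroids=np.sort(centroids) + expr.mean(),
    )


def kmeans_1d_dp(values: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Exact optimal 1-D k-means by dynamic programming (O(k n^2)).

    Returns (cluster index per input value, optimal within-cluster SS).
    The optimal 1-D clustering is a partition of the sorted values into
    contiguous blocks, so DP over split points is exhaustive.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < k:
        raise ValueError("fewer points than clusters")
    order = np.argsort(values, kind="stable")
    x = values[order]
    pref = np.concatenate([[0.0], np.cumsum(x)])
    pref2 = np.concatenate([[0.0], np.cumsum(x**2)])

    def cost(i: int, j: int) -> float:  # SS of x[i:j]
        s = pref[j] - pref[i]
        s2 = pref2[j] - pref2[i]
        return s2 - s * s / (j - i)

    INF = math.inf
    dp = np.full((k + 1, n + 1), INF)
    arg = np.zeros((k + 1, n + 1), dtype=int)
    dp[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, best_i = INF, c - 1
            for i in range(c - 1, j):
                v = dp[c - 1, i] + cost(i, j)
                if v < best - 1e-15:
                    best, best_i = v, i
            dp[c, j], arg[c, j] = best, best_i
    assign_sorted = np.zeros(n, dtype=int)
    j = n
    for c in range(k, 0, -1):
        i = arg[c, j]
        assign_sorted[i:j] = c - 1
        j = i
    assign = np.zeros(n, dtype=int)
    assign[order] = assign_sorted
    return assign, float(dp[k, n])


def km_curve(cohort: CohortTable) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate with right censoring.

    Returns a step function as a DataFrame with columns ``time`` and
    ``survival`` (starting at S(0) = 1, dropping only at event times).
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    kmf = KaplanMeierFitter()
    kmf.fit(cohort.data["time"], cohort.data["event"])
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
    )


def logrank_test(strata: StrataAssignment, cohort: CohortTable) -> dict:
    """k-sample logrank test for equality of the stratum survival curves.

    Observed minus expected events per stratum over the pooled risk sets,
    hypergeometric variance for ties; the statistic is chi-square with
    (number of strata - 1) degrees of freedom.
    """
    labels = strata.labels.reindex(cohort.data.index)
    present = pd.unique(labels.dropna())
    if len(present) < 2:
        raise ValueError("logrank needs at least two non-empty strata")
    res = multivariate_logrank_test(
        cohort.data["time"], labels, cohort.data["event"]
    )
    return {
        "chi2": float(res.test_statistic),
        "df": int(len(present) - 1),
        "p": float(res.p_value),
    }


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p over all sign assignments of tie-averaged ranks.

    Ranks may be half-integers under ties; doubling makes them integers so
    the null distribution of 2*W+ is built by polynomial convolution over
    the 2^n equally likely assignments.
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = doubled.sum()
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: pmf.size - r]
        pmf = 0.5 * (pmf + shifted)
    w2 = int(round(2 * w_plus))
    lower = pmf[: w2 + 1].sum()
    upper = pmf[w2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(
    pre, post=None, exact_max_n: int = 25
) -> dict:
    """Wilcoxon matched-pair signed-rank test (two-sided).

    Pass paired ``pre``/``post`` scores, or the differences alone.  Zero
    differences are dropped; ties get averaged ranks.  The p-value is exact
    (full sign-assignment distribution) for n <= ``exact_max_n`` retained
    pairs, otherwise a normal approximation with tie correction is used.
    """
    pre = np.asarray(pre, dtype=float)
    diffs = pre if post is None else np.asarray(post, dtype=float) - pre
    if diffs.size < 5:
        raise ValueError("need at least 5 pairs")
    diffs = diffs[diffs != 0]
    if diffs.size == 0:
        raise ValueError("all paired differences are zero")
    n = diffs.size
    ranks = stats.rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    if n <= exact_max_n:
        p = _exact_signed_rank_p(ranks, w_plus)
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, counts = np.unique(ranks, return_counts=True)
        var -= (counts**3 - counts).sum() / 48.0
        z = (w_plus - mu) / math.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
        method = "normal"
    return {"W": w_plus, "p": float(min(p, 1.0)), "n": n, "method": method}
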