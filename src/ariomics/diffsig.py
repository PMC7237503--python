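"""Per-comparison differential statistics and consistency selection.

The resistance panel is built from feature-by-sample abundance matrices
(label-free proteomics, metabolomics, lipidomics) with a group/format design:
Welch t-tests on log2 abundances per group-vs-reference comparison,
Benjamini-Hochberg q-values within each comparison, then a consistency rule
(|log2FC| above threshold with one sign in at least k of n comparisons) and
an intersection across culture formats (2D / 3D).

A seeded label-permutation mode is available as an alternative significance
engine, and a Monte Carlo Dunnett many-to-one test covers the ANOVA-style
group comparisons used for metabolite and lipid panels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OmicsMatrix",
    "SignaturePanel",
    "differential_table",
    "dunnett_test",
    "dunnett_table",
    "select_consistent",
    "intersect_contexts",
    "score_selection",
]


class DesignError(ValueError):
    """Sample design missing, inconsistent, or referencing unknown groups."""


@dataclass
class OmicsMatrix:
    """Features x samples abundance matrix with a sample design.

    ``values``: DataFrame indexed by feature id, columns = sample ids,
    non-negative abundances in arbitrary units.
    ``design``: DataFrame indexed by sample id with columns ``group``,
    ``format`` (optional, defaults to a single format) and ``replicate``.
    ``reference``: name of the reference group (e.g. parental/WT line).
    """

    values: pd.DataFrame
    design: pd.DataFrame
    reference: str

    def __post_init__(self):
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise DesignError(f"duplicate feature ids: {list(dups)[:5]}")
        missing = self.values.columns.difference(self.design.index)
        if len(missing):
            raise DesignError(f"samples without design entry: {list(missing)[:5]}")
        if "group" not in self.design.columns:
            raise DesignError("design table needs a 'group' column")
        if "format" not in self.design.columns:
            self.design = self.design.assign(format="default")
        if self.reference not in set(self.design["group"]):
            raise DesignError(f"reference group {self.reference!r} absent from design")

    @property
    def groups(self) -> list[str]:
        seen: dict = {}
        for g in self.design.loc[self.values.columns, "group"]:
            seen.setdefault(g, None)
        return list(seen)

    @property
    def formats(self) -> list[str]:
        seen: dict = {}
        for f in self.design.loc[self.values.columns, "format"]:
            seen.setdefault(f, None)
        return list(seen)

    def samples_of(self, group: str, fmt: str | None = None) -> list[str]:
        d = self.design.loc[self.values.columns]
        sel = d["group"] == group
        if fmt is not None:
            sel &= d["format"] == fmt
        return list(d.index[sel])


def _log2_block(mat: OmicsMatrix, samples: list[str]) -> np.ndarray:
    """Log2 abundances for the given samples; non-positive values become NaN."""
    block = mat.values[samples].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(block > 0, np.log2(np.where(block > 0, block, 1.0)), np.nan)
    return out


def differential_table(
    mat: OmicsMatrix,
    comparisons: list[tuple[str, str]] | None = None,
    permutation: bool = False,
    n_permutations: int = 250,
    seed: int = 0,
) -> pd.DataFrame:
    """Welch t-test per feature per (group-vs-reference, format) comparison.

    ``comparisons``: list of (group, format) pairs; default is every
    non-reference group crossed with every format present.  Returns a tidy
    frame with columns feature, group, format, log2fc, p, q, sign, n_group,
    n_ref.  Features with fewer than two finite log values in either side of
    a comparison are dropped from that comparison (no imputation).  q is the
    Benjamini-Hochberg adjusted p within each comparison, so q >= p holds
    per feature.  With ``permutation=True`` p-values come from seeded label
    shuffling (two-sided, on the Welch t statistic) instead of the t
    distribution.
    """
    if comparisons is None:
        comparisons = [
            (g, f)
            for f in mat.formats
            for g in mat.groups
            if g != mat.reference
        ]
    rng = np.random.default_rng(seed)
    pieces = []
    for group, fmt in comparisons:
        g_samples = mat.samples_of(group, fmt)
        r_samples = mat.samples_of(mat.reference, fmt)
        if not g_samples:
            raise DesignError(f"no samples for group {group!r} in format {fmt!r}")
        if len(g_samples) < 2 or len(r_samples) < 2:
            raise DesignError(
                f"comparison {group} vs {mat.reference} ({fmt}): "
                "need >=2 replicates per group"
            )
        a = _log2_block(mat, g_samples)
        b = _log2_block(mat, r_samples)
        ok = (np.isfinite(a).sum(axis=1) >= 2) & (np.isfinite(b).sum(axis=1) >= 2)
        a, b = a[ok], b[ok]
        feats = mat.values.index[ok]
        log2fc = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)
        with warnings.catch_warnings():
            # noiseless/identical groups trip a precision warning; the NaN
            # results they produce are resolved explicitly below
            warnings.simplefilter("ignore", RuntimeWarning)
            tstat, p = stats.ttest_ind(a, b, axis=1, equal_var=False, nan_policy="omit")
        p = np.asarray(p, dtype=float)
        # zero-variance identical groups yield NaN t; identical means => no evidence
        degenerate = ~np.isfinite(p)
        p[degenerate & (log2fc == 0)] = 1.0
        p[degenerate & (log2fc != 0)] = 0.0
        if permutation:
            p = _permutation_p(a, b, np.asarray(tstat), rng, n_permutations)
        q = np.full_like(p, np.nan)
        finite = np.isfinite(p)
        if finite.any():
            q[finite] = multipletests(p[finite], method="fdr_bh")[1]
        pieces.append(
            pd.DataFrame(
                {
                    "feature": feats,
                    "group": group,
                    "format": fmt,
                    "log2fc": log2fc,
                    "p": p,
                    "q": q,
                    "sign": np.sign(log2fc).astype(int),
                    "n_group": np.isfinite(a).sum(axis=1),
                    "n_ref": np.isfinite(b).sum(axis=1),
                }
            )
        )
    return pd.concat(pieces, ignore_index=True)


def _permutation_p(a, b, t_obs, rng, n_permutations):
    """Two-sided label-permutation p per feature on the Welch t statistic."""
    pooled = np.concatenate([a, b], axis=1)
    n_a = a.shape[1]
    count = np.zeros(a.shape[0])
    t_obs = np.where(np.isfinite(t_obs), t_obs, 0.0)
    for _ in range(n_permutations):
        perm = rng.permutation(pooled.shape[1])
        pa, pb = pooled[:, perm[:n_a]], pooled[:, perm[n_a:]]
        t_perm, _ = stats.ttest_ind(pa, pb, axis=1, equal_var=False, nan_policy="omit")
        t_perm = np.where(np.isfinite(t_perm), t_perm, 0.0)
        count += np.abs(t_perm) >= np.abs(t_obs) - 1e-12
    return (count + 1.0) / (n_permutations + 1.0)


# Cache of Monte Carlo null max-|t| samples keyed by the sampling layout.
_DUNNETT_NULL_CACHE: dict = {}


def _dunnett_null(sizes: tuple[int, ...], n_ref: int, df: int, n_draws: int, seed: int) -> np.ndarray:
    key = (sizes, n_ref, df, n_draws, seed)
    if key not in _DUNNETT_NULL_CACHE:
        rng = np.random.default_rng(seed)
        k = len(sizes)
        m_ref = rng.normal(0.0, 1.0 / math.sqrt(n_ref), size=n_draws)
        s = np.sqrt(rng.chisquare(df, size=n_draws) / df)
        t_all = np.empty((k, n_draws))
        for i, n_i in enumerate(sizes):
            m_i = rng.normal(0.0, 1.0 / math.sqrt(n_i), size=n_draws)
            t_all[i] = (m_i - m_ref) / (s * math.sqrt(1.0 / n_i + 1.0 / n_ref))
        maxabs = np.abs(t_all).max(axis=0)
        _DUNNETT_NULL_CACHE[key] = np.sort(maxabs)
    return _DUNNETT_NULL_CACHE[key]


def dunnett_table(
    mat: OmicsMatrix,
    features: list | None = None,
    fmt: str | None = None,
    n_draws: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte Carlo Dunnett many-to-one test for every requested feature.

    Equal-variance model: the variance is pooled across all groups (ANOVA
    residual), and family-wise adjusted p-values come from the seeded Monte
    Carlo null distribution of max |t| over the group-vs-reference contrasts
    (shared across features with the same replication layout).  Adjusted
    p-values are floored at the unadjusted two-sided t p-value so that
    adjustment can never appear anti-conservative.  With a single
    non-reference group the test degrades to a plain two-sided pooled t-test
    and the ``flag`` column says so.
    """
    fmts = mat.formats if fmt is None else [fmt]
    if len(fmts) > 1:
        raise DesignError("dunnett_table operates within one format; pass fmt=")
    fmt = fmts[0]
    groups = [g for g in mat.groups if g != mat.reference]
    if not groups:
        raise DesignError("no non-reference group")
    if features is None:
        features = list(mat.values.index)
    ref_samples = mat.samples_of(mat.reference, fmt)
    grp_samples = {g: mat.samples_of(g, fmt) for g in groups}
    sizes = tuple(len(grp_samples[g]) for g in groups)
    n_ref = len(ref_samples)
    if n_ref < 2 or min(sizes) < 2:
        raise DesignError("need >=2 replicates per group for the pooled variance")
    n_total = n_ref + sum(sizes)
    df = n_total - (len(groups) + 1)

    single = len(groups) == 1
    null = None if single else _dunnett_null(sizes, n_ref, df, n_draws, seed)

    vals = mat.values.loc[features]
    if (vals.to_numpy(dtype=float) <= 0).any():
        bad = vals.index[(vals <= 0).any(axis=1)]
        raise ValueError(f"non-positive abundance for feature(s) {list(bad)[:5]}")
    logv = np.log2(vals)
    ref_arr = logv[ref_samples].to_numpy()
    grp_arr = {g: logv[grp_samples[g]].to_numpy() for g in groups}
    resid_all = ((ref_arr - ref_arr.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    for g in groups:
        v = grp_arr[g]
        resid_all = resid_all + ((v - v.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2_all = resid_all / df
    rows = []
    for fi, feat in enumerate(features):
        y_ref = ref_arr[fi]
        ys = {g: grp_arr[g][fi] for g in groups}
        s2 = s2_all[fi]
        for g in groups:
            n_i = len(ys[g])
            se = math.sqrt(s2 * (1.0 / n_i + 1.0 / n_ref)) if s2 > 0 else 0.0
            diff = ys[g].mean() - y_ref.mean()
            t = diff / se if se > 0 else (0.0 if diff == 0 else math.inf)
            p_unadj = 2.0 * stats.t.sf(abs(t), df) if math.isfinite(t) else 0.0
            if single:
                p_adj, flag = p_unadj, "fallback-two-sided-t"
            else:
                idx = np.searchsorted(null, abs(t), side="left")
                p_mc = (len(null) - idx + 1.0) / (len(null) + 1.0)
                p_adj, flag = max(p_mc, p_unadj), "dunnett-mc"
            rows.append(
                {
                    "feature": feat,
                    "group": g,
                    "log2fc": diff,
                    "t": t,
                    "p_unadjusted": p_unadj,
                    "p_adjusted": min(p_adj, 1.0),
                    "flag": flag,
                }
            )
    return pd.DataFrame(rows)


def dunnett_test(
    mat: OmicsMatrix,
    feature,
    fmt: str | None = None,
    n_draws: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Dunnett many-to-one comparisons for a single feature (see dunnett_table)."""
    return dunnett_table(mat, features=[feature], fmt=fmt, n_draws=n_draws, seed=seed)


def select_consistent(
    res: pd.DataFrame,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    k_of_n: int | None = None,
    require_sign: bool = True,
    p_column: str = "p",
) -> list:
    """Consistency filter over a tidy comparison table.

    A feature is retained iff (|log2fc| >= log2(fc_threshold) and
    p < p_threshold) in at least ``k_of_n`` comparisons and, when
    ``require_sign``, all qualifying comparisons share one sign.
    ``p_column`` may be set to ``"q"`` to filter on BH-adjusted values.

    Retention is monotone in the thresholds (tightening never adds a
    feature) except through the sign veto: tightening can remove a
    qualifying contrary-sign comparison and thereby admit a feature, so the
    monotonicity guarantee holds only with ``require_sign=False``.
    """
    if fc_threshold <= 1.0:
        raise ValueError(f"fc_threshold must exceed 1 (got {fc_threshold})")
    if res.empty:
        return []
    n_comparisons = res.groupby("feature").size().max()
    if k_of_n is None:
        k_of_n = int(n_comparisons)
    if k_of_n > n_comparisons:
        raise ValueError(
            f"k_of_n={k_of_n} exceeds the {n_comparisons} comparisons present"
        )
    log_thr = math.log2(fc_threshold)
    hit = (res["log2fc"].abs() >= log_thr) & (res[p_column] < p_threshold)
    sub = res[hit]
    retained = []
    for feat, grp in sub.groupby("feature", sort=False):
        if len(grp) < k_of_n:
            continue
        if require_sign and grp["sign"].nunique() > 1:
            continue
        retained.append(feat)
    order = {f: i for i, f in enumerate(res["feature"].unique())}
    return sorted(retained, key=lambda f: order.get(f, 0))


@dataclass
class SignaturePanel:
    """Ordered consistent-feature panel with direction and supporting log2FCs."""

    table: pd.DataFrame  # index feature; columns: direction, then log2fc per comparison

    @property
    def features(self) -> list:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


def intersect_contexts(
    panel_by_format: dict,
    res: pd.DataFrame | None = None,
    require_sign: bool = True,
) -> SignaturePanel:
    """Intersect per-format selections into one signature panel.

    ``panel_by_format`` maps format -> iterable of retained features.  When
    the tidy comparison table ``res`` is supplied, members are annotated with
    their per-comparison log2FCs, sign consistency across formats is enforced
    (if ``require_sign``) and the panel is ordered by mean |log2fc|
    descending; otherwise the bare intersection is returned in input order.
    """
    if len(panel_by_format) < 2:
        raise ValueError("need selections for at least two formats")
    sets = [set(v) for v in panel_by_format.values()]
    common = set.intersection(*sets)
    if res is None:
        first = next(iter(panel_by_format.values()))
        table = pd.DataFrame(index=[f for f in first if f in common])
        table["direction"] = "?"
        return SignaturePanel(table)
    missing = set(panel_by_format) - set(res["format"])
    if missing:
        raise KeyError(f"formats absent from comparison table: {sorted(missing)}")
    sub = res[res["feature"].isin(common)]
    rows = []
    for feat, grp in sub.groupby("feature", sort=False):
        signs = set(np.sign(grp["log2fc"]).astype(int)) - {0}
        if require_sign and len(signs) > 1:
            continue
        direction = "+" if grp["log2fc"].mean() > 0 else "-"
        entry = {"feature": feat, "direction": direction,
                 "mean_abs_log2fc": grp["log2fc"].abs().mean()}
        for _, r in grp.iterrows():
            entry[f"log2fc_{r['format']}_{r['group']}"] = r["log2fc"]
        rows.append(entry)
    if not rows:
        return SignaturePanel(pd.DataFrame(columns=["direction"]))
    table = (
        pd.DataFrame(rows)
        .sort_values("mean_abs_log2fc", ascending=False)
        .set_index("feature")
        .drop(columns="mean_abs_log2fc")
    )
    return SignaturePanel(table)


def score_selection(selected, truth: pd.DataFrame) -> dict:
    """Sensitivity and observed FDR of a selection against a planted truth table."""
    selected = list(selected)
    unknown = set(selected) - set(truth.index)
    if unknown:
        raise KeyError(f"selected features missing from truth: {sorted(unknown)[:5]}")
    signature = set(truth.index[truth["is_signature"]])
    hits = signature.intersection(selected)
    sensitivity = len(hits) / len(signature) if signature else 0.0
    observed_fdr = (len(selected) - len(hits)) / max(1, len(selected))
    return {"sensitivity": sensitivity, "observed_fdr": observed_fdr}
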