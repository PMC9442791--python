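"""Group-wise differential abundance: one-way ANOVA, Tukey HSD, BH and the
signed -log10(p) ranking metric."""

from __future__ import annotations

import itertools
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def _check_groups(groups: pd.Series) -> list[str]:
    labels = sorted(set(groups.dropna()))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    return labels


def anova_feature(values_by_group: Sequence[np.ndarray]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA F and p from per-group value arrays.

    Returns (nan, nan) for degenerate input (zero total variance, or fewer
    than two groups with >= 2 observations each).
    """
    gs = [np.asarray(g, float) for g in values_by_group if len(g) >= 2]
    if len(gs) < 2:
        return np.nan, np.nan
    allv = np.concatenate(gs)
    grand = allv.mean()
    if np.allclose(allv, grand):
        return np.nan, np.nan
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b = len(gs) - 1
    df_w = len(allv) - len(gs)
    if df_w <= 0:
        return np.nan, np.nan
    if ss_within == 0:
        return np.inf, 0.0
    F = (ss_between / df_b) / (ss_within / df_w)
    return float(F), float(stats.f.sf(F, df_b, df_w))


def anova_tukey(values: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-feature one-way ANOVA with Tukey HSD post-hoc tests.

    ``values`` is a features x samples DataFrame of log2 abundances;
    ``groups`` maps sample id to group label. Features with fewer than two
    groups carrying >= 2 non-missing values are reported untested (NaN)
    rather than erroring the run.
    """
    labels = _check_groups(groups)
    pairs = list(itertools.combinations(labels, 2))
    cols_by_group = {g: [s for s in values.columns if groups.get(s) == g] for g in labels}

    records = []
    for feat, row in values.iterrows():
        per_group = {g: row[cols_by_group[g]].dropna().to_numpy(float) for g in labels}
        tested = [g for g in labels if len(per_group[g]) >= 2]
        rec: dict = {"feature_id": feat}
        for g in labels:
            rec[f"mean_{g}"] = per_group[g].mean() if len(per_group[g]) else np.nan
        F, p = anova_feature([per_group[g] for g in tested])
        rec["F"], rec["p"] = F, p
        tukey_p: dict[tuple[str, str], float] = {}
        if np.isfinite(F) and len(tested) >= 2:
            res = stats.tukey_hsd(*[per_group[g] for g in tested])
            for i, gi in enumerate(tested):
                for j, gj in enumerate(tested):
                    if i < j:
                        tukey_p[(gi, gj)] = float(res.pvalue[i, j])
        for g1, g2 in pairs:
            rec[f"tukey_p_{g1}_vs_{g2}"] = tukey_p.get((g1, g2), np.nan)
            rec[f"log2fc_{g1}_vs_{g2}"] = rec[f"mean_{g1}"] - rec[f"mean_{g2}"]
        records.append(rec)
    out = pd.DataFrame.from_records(records).set_index("feature_id")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def anova_pvalues(values: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """Vectorized one-way ANOVA p-values (complete data, no Tukey)."""
    labels = _check_groups(groups)
    arrays = [
        values[[s for s in values.columns if groups.get(s) == g]].to_numpy(float)
        for g in labels
    ]
    res = stats.f_oneway(*arrays, axis=1)
    return pd.Series(res.pvalue, index=values.index, name="p")


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvalues, float)
    finite = ~np.isnan(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    pv = p[finite]
    n = pv.size
    if n:
        order = np.argsort(pv, kind="mergesort")
        ranked = pv[order] * n / np.arange(1, n + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty(n)
        adj[order] = np.minimum(ranked, 1.0)
        q[finite] = adj
    return q


def rank_metric(p, log2fc):
    """Signed ranking value: -log10(p) times the sign of the fold-change.

    p = 0 is clamped to the smallest positive normal float (logged).
    """
    p = np.asarray(p, float)
    fc = np.asarray(log2fc, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n_zero = int(np.sum(p == 0))
    if n_zero:
        logger.warning("rank_metric: clamping %d zero p-value(s)", n_zero)
        p = np.where(p == 0, np.finfo(float).tiny, p)
    out = -np.log10(p) * np.sign(fc)
    return float(out) if out.ndim == 0 else out
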