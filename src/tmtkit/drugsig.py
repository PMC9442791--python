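"""Drug-sensitivity correlation signatures.

Basal abundance is correlated with screen viability per feature (Spearman on
matched pairs); correlations are oriented so proteins elevated in sensitive
(low-viability) lines score positive. Duplicate screen entries for a drug
are reduced by the per-feature median. The top-k features form a signature
scored per sample by single-sample enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from tmtkit.enrichment import nes_by_permutation
from tmtkit.matrix import AbundanceMatrix

SCREEN_META_COLUMNS = ("drug_id", "entry_id")


@dataclass
class SignatureResult:
    correlations: pd.Series  # per-feature correlation to sensitivity
    members: tuple[str, ...]  # ordered top-k list
    sample_scores: pd.Series | None = None  # per-sample NES


def _screen_samples(screen: pd.DataFrame) -> list[str]:
    return [c for c in screen.columns if c not in SCREEN_META_COLUMNS]


def correlate_response(
    matrix: AbundanceMatrix | pd.DataFrame,
    screen: pd.DataFrame,
    excluded_samples: Iterable[str] = (),
    min_pairs: int = 4,
) -> pd.DataFrame:
    """Spearman correlation-to-sensitivity per feature per screen entry.

    Correlations are computed on matched (abundance, viability) pairs after
    pairwise deletion of missing values and the exclusion list, then negated
    so that features high in sensitive (low-viability) samples score
    positive. Constant features (or fewer than ``min_pairs`` pairs) are NaN.
    """
    values = matrix.values if isinstance(matrix, AbundanceMatrix) else matrix
    excluded = set(excluded_samples)
    common = [s for s in values.columns if s in _screen_samples(screen) and s not in excluded]
    if not common:
        raise ValueError("no sample overlap between abundance matrix and drug screen")

    X = values[common].to_numpy(float)
    out = {}
    for row in screen.itertuples(index=False):
        entry = getattr(row, "entry_id")
        resp = np.array([getattr(row, s) for s in common], float)
        rho = np.full(X.shape[0], np.nan)
        resp_ok = ~np.isnan(resp)
        for i in range(X.shape[0]):
            ok = resp_ok & ~np.isnan(X[i])
            if ok.sum() < min_pairs:
                continue
            x = X[i, ok]
            if np.all(x == x[0]) or np.all(resp[ok] == resp[ok][0]):
                continue
            rho[i] = stats.spearmanr(x, resp[ok]).statistic
        out[entry] = -rho  # sensitivity orientation
    return pd.DataFrame(out, index=values.index)


def median_over_entries(
    correlations: pd.DataFrame, screen: pd.DataFrame, drug_id: str
) -> pd.Series:
    """Per-feature median correlation across a drug's screen entries."""
    entries = list(screen.loc[screen["drug_id"] == drug_id, "entry_id"])
    if not entries:
        raise ValueError(f"no screen entries for drug {drug_id!r}")
    return correlations[entries].median(axis=1, skipna=True)


def extract_signature(correlations: pd.Series, k: int = 100) -> SignatureResult:
    """Top-k features by correlation-to-sensitivity (ties broken by id)."""
    defined = correlations.dropna()
    if len(defined) < k:
        warnings.warn(
            f"only {len(defined)} features with defined correlation; returning all"
        )
    order = sorted(defined.index, key=lambda i: (-defined[i], str(i)))
    members = tuple(order[:k])
    return SignatureResult(correlations=correlations, members=members)


def score_signature(
    matrix: AbundanceMatrix | pd.DataFrame,
    signature: SignatureResult | Sequence[str],
    alpha: float = 0.75,
    n_perm: int = 200,
    seed: int | None = None,
) -> pd.Series:
    """Per-sample NES of the signature by single-sample enrichment."""
    values = matrix.values if isinstance(matrix, AbundanceMatrix) else matrix
    members = signature.members if isinstance(signature, SignatureResult) else tuple(signature)
    scores = {}
    for j, col in enumerate(values.columns):
        profile = values[col].dropna()
        scores[col] = nes_by_permutation(
            profile, members, alpha=alpha, n_perm=n_perm,
            seed=None if seed is None else seed + j,
        )
    return pd.Series(scores, name="NES")


def compare_extremes(
    scores: pd.Series,
    response: pd.Series,
    n_extreme: int = 50,
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-sided t-test of response between top-n and bottom-n scored lines.

    Lines are ranked by ``scores`` (signature NES or single-protein
    abundance); Welch's unequal-variance form is the default.
    """
    common = scores.dropna().index.intersection(response.dropna().index)
    if len(common) < 2 * n_extreme:
        raise ValueError(
            f"cohort of {len(common)} lines cannot form two groups of {n_extreme}"
        )
    ranked = scores[common].sort_values(ascending=False, kind="mergesort")
    top = ranked.index[:n_extreme]
    bottom = ranked.index[-n_extreme:]
    res = stats.ttest_ind(response[top], response[bottom], equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)
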