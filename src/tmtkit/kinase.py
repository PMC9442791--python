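"""Kinase-substrate network assembly and bounded kinase-activity inference.

Curated links are matched exactly on (accession, residue, position);
predicted links enter the network only above a score cutoff chosen by
maximizing the Matthews correlation coefficient against the curated truth
set. Activities are estimated per sample by bounded least squares under the
site model: predicted site abundance = mean of its kinases' activities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from tmtkit.matrix import AbundanceMatrix

logger = logging.getLogger(__name__)


class PhosphositeKey(NamedTuple):
    accession: str
    residue: str  # S, T or Y
    position: int  # 1-based

    @property
    def key(self) -> str:
        return f"{self.accession}_{self.residue}{self.position}"

    @classmethod
    def parse(cls, key: str) -> "PhosphositeKey":
        acc, _, rp = key.rpartition("_")
        if not acc or rp[0] not in "STY" or not rp[1:].isdigit() or int(rp[1:]) < 1:
            raise ValueError(f"malformed phosphosite key {key!r}")
        return cls(acc, rp[0], int(rp[1:]))


@dataclass(frozen=True)
class KinaseSubstrateLink:
    kinase: str
    site: str  # phosphosite key, ACCESSION_RESPOS
    source: str  # 'curated' | 'predicted'
    score: float | None = None

    def __post_init__(self) -> None:
        if self.source not in ("curated", "predicted"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.source == "predicted" and self.score is None:
            raise ValueError("predicted links require a score")


@dataclass
class CutoffResult:
    grid: pd.DataFrame  # threshold, TP, FN, TN, FP, MCC
    chosen: float


@dataclass
class KinaseActivityProfile:
    activities: pd.DataFrame  # kinase x sample
    residuals: pd.Series  # per-sample best objective value
    lower: float = 0.0
    upper: float = 24.0

    def __post_init__(self) -> None:
        a = self.activities.to_numpy()
        if a.size and (a.min() < self.lower - 1e-9 or a.max() > self.upper + 1e-9):
            raise ValueError("activities violate bounds")


# -- input tables -------------------------------------------------------

def read_curated_tsv(path: str | Path) -> pd.DataFrame:
    """PhosphoSitePlus-dialect table: KINASE, SUB_ACC_ID, SUB_MOD_RSD."""
    return pd.read_csv(path, sep="\t")


def read_predictions_tsv(path: str | Path) -> list[KinaseSubstrateLink]:
    """Prediction table: kinase, accession, residue, position, score."""
    t = pd.read_csv(path, sep="\t")
    return [
        KinaseSubstrateLink(
            kinase=str(r.kinase),
            site=PhosphositeKey(str(r.accession), str(r.residue), int(r.position)).key,
            source="predicted",
            score=float(r.score),
        )
        for r in t.itertuples()
    ]


def match_curated(
    sites: Iterable[str], curated: pd.DataFrame
) -> list[KinaseSubstrateLink]:
    """Link observed phosphosite keys to curated kinase annotations.

    Matching is exact on (accession, residue, 1-based position); malformed
    curated rows are skipped with a logged count. Unobserved curated rows
    and unmatched sites simply produce no link.
    """
    site_set = {str(s) for s in sites}
    links = []
    skipped = 0
    for row in curated.itertuples():
        rsd = str(row.SUB_MOD_RSD).strip()
        if not rsd or rsd[0].upper() not in "STY" or not rsd[1:].isdigit() or int(rsd[1:]) < 1:
            skipped += 1
            continue
        key = f"{row.SUB_ACC_ID}_{rsd[0].upper()}{int(rsd[1:])}"
        if key in site_set:
            links.append(KinaseSubstrateLink(str(row.KINASE), key, "curated"))
    if skipped:
        logger.info("match_curated: skipped %d malformed rows", skipped)
    # de-duplicate (kinase, site) pairs
    return list(dict.fromkeys(links))


# -- MCC cutoff ---------------------------------------------------------

def mcc(tp: int, fn: int, tn: int, fp: int) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def default_grid(scores: Sequence[float]) -> np.ndarray:
    """Unique observed scores plus midpoints between consecutive values."""
    u = np.unique(np.asarray(scores, float))
    mids = (u[:-1] + u[1:]) / 2 if u.size > 1 else np.array([])
    return np.unique(np.concatenate([u, mids]))


def optimize_cutoff(
    predictions: Sequence[KinaseSubstrateLink],
    curated: Sequence[KinaseSubstrateLink],
    grid: Sequence[float] | None = None,
) -> CutoffResult:
    """Choose the prediction-score threshold maximizing the MCC.

    Curated-pair predictions above a threshold count as TP and below as FN;
    non-curated predictions count as FP above and TN below. The chosen
    threshold is the smallest grid value attaining the maximum MCC.
    """
    curated_pairs = {(l.kinase, l.site) for l in curated}
    if not curated_pairs:
        raise ValueError("no curated pairs: a truth set is required")
    scores = np.array([l.score for l in predictions], float)
    is_pos = np.array([(l.kinase, l.site) in curated_pairs for l in predictions], bool)
    if grid is None:
        grid = default_grid(scores)
    grid = np.asarray(sorted(grid), float)

    rows = []
    for t in grid:
        above = scores > t
        tp = int(np.sum(above & is_pos))
        fn = int(np.sum(~above & is_pos))
        fp = int(np.sum(above & ~is_pos))
        tn = int(np.sum(~above & ~is_pos))
        rows.append({"threshold": float(t), "TP": tp, "FN": fn, "TN": tn, "FP": fp,
                     "MCC": mcc(tp, fn, tn, fp)})
    table = pd.DataFrame(rows)
    best = table["MCC"].max()
    chosen = float(table.loc[table["MCC"] == best, "threshold"].iloc[0])
    return CutoffResult(grid=table, chosen=chosen)


def build_network(
    curated: Sequence[KinaseSubstrateLink],
    predicted: Sequence[KinaseSubstrateLink],
    cutoff: float,
    detected_kinases: Iterable[str] | None = None,
) -> list[KinaseSubstrateLink]:
    """Union of curated links and predictions scoring strictly above the cutoff.

    Curated links take precedence on duplicate (kinase, site) pairs; links
    whose kinase is absent from ``detected_kinases`` (when given) are removed.
    """
    by_pair: dict[tuple[str, str], KinaseSubstrateLink] = {}
    for l in predicted:
        if l.score is not None and l.score > cutoff:
            by_pair[(l.kinase, l.site)] = l
    for l in curated:
        by_pair[(l.kinase, l.site)] = l
    links = list(by_pair.values())
    if detected_kinases is not None:
        det = {str(k) for k in detected_kinases}
        links = [l for l in links if l.kinase in det]
    return links


# -- activity scoring ---------------------------------------------------

def score_activities(
    sites: AbundanceMatrix | pd.DataFrame,
    network: Sequence[KinaseSubstrateLink],
    n_starts: int = 100,
    lower: float = 0.0,
    upper: float = 24.0,
    seed: int | None = None,
) -> KinaseActivityProfile:
    """Bounded multi-start least-squares estimation of kinase activities.

    Per sample, activities minimize sum over observed sites of
    (observed - mean of linked kinases' activities)^2 subject to
    lower <= a <= upper, via L-BFGS-B from ``n_starts`` uniform-random
    initializations; the best objective is kept (ties: first found).
    Site values must be on the log2 scale.
    """
    values = sites.values if isinstance(sites, AbundanceMatrix) else sites
    site_kinases: dict[str, list[str]] = {}
    for l in network:
        if l.site in values.index:
            site_kinases.setdefault(l.site, []).append(l.kinase)
    kinases = sorted({k for ks in site_kinases.values() for k in ks})
    dropped = sorted({l.kinase for l in network} - set(kinases))
    if dropped:
        warnings.warn(
            f"excluding {len(dropped)} kinase(s) with no linked observed site: "
            + ", ".join(dropped[:5])
        )
    if not kinases:
        raise ValueError("no kinase has a linked observed site")
    kin_idx = {k: i for i, k in enumerate(kinases)}
    model_sites = sorted(site_kinases)
    C = np.zeros((len(model_sites), len(kinases)))
    for i, s in enumerate(model_sites):
        ks = sorted(set(site_kinases[s]))
        for k in ks:
            C[i, kin_idx[k]] = 1.0 / len(ks)

    rng = np.random.default_rng(seed)
    starts = rng.uniform(lower, upper, size=(max(1, n_starts), len(kinases)))
    bounds = [(lower, upper)] * len(kinases)
    Y = values.loc[model_sites]

    act = np.full((len(kinases), values.shape[1]), np.nan)
    resid = np.full(values.shape[1], np.nan)
    for j, col in enumerate(values.columns):
        y = Y[col].to_numpy(float)
        ok = ~np.isnan(y)
        if not ok.any():
            continue
        Cs, ys = C[ok], y[ok]
        CtC = Cs.T @ Cs
        Cty = Cs.T @ ys
        yty = float(ys @ ys)

        def objective(a: np.ndarray) -> tuple[float, np.ndarray]:
            r = CtC @ a
            f = float(a @ r) - 2.0 * float(Cty @ a) + yty
            return f, 2.0 * (r - Cty)

        best_f, best_a = np.inf, None
        for a0 in starts:
            res = optimize.minimize(
                objective, a0, jac=True, method="L-BFGS-B", bounds=bounds
            )
            if res.fun < best_f - 1e-12:
                best_f, best_a = res.fun, res.x
        act[:, j] = np.clip(best_a, lower, upper)
        resid[j] = max(best_f, 0.0)

    return KinaseActivityProfile(
        activities=pd.DataFrame(act, index=kinases, columns=values.columns),
        residuals=pd.Series(resid, index=values.columns, name="residual"),
        lower=lower,
        upper=upper,
    )


def differential_activity(
    profile: KinaseActivityProfile, groups: pd.Series
) -> pd.DataFrame:
    """One-way ANOVA + Tukey + BH across subgroups, per kinase."""
    from tmtkit.differential import anova_tukey

    return anova_tukey(profile.activities, groups)
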