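"""Gene-set enrichment: single-sample (area) scores, ranked-list GSEA with
gene-label permutation, and hypergeometric over-representation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from tmtkit.differential import bh_adjust


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
        upper = tuple(dict.fromkeys(m.upper() for m in self.members))
        object.__setattr__(self, "members", upper)


def read_gmt(path: str | Path) -> list[GeneSet]:
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets.append(GeneSet(name=parts[0], description=parts[1], members=tuple(parts[2:])))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    lines = ["\t".join([s.name, s.description or "na", *s.members]) for s in sets]
    Path(path).write_text("\n".join(lines) + "\n")


def _ordered(profile: pd.Series) -> pd.Series:
    """Sort by descending value; ties broken by feature id for determinism."""
    df = profile.dropna()
    order = sorted(df.index, key=lambda i: (-df[i], str(i)))
    return df[order]


def ssgsea_es(profile: pd.Series, members: Iterable[str], alpha: float = 0.75) -> float:
    """Single-sample enrichment score (area statistic).

    Features are walked in descending-value order; set members add
    |value|^alpha normalized to the set's total weight, non-members subtract
    1/(N - n_set). The score is the sum of the running-sum values. When the
    set covers every feature the decrement pool is empty and only the
    increments contribute.
    """
    ordered = _ordered(profile)
    ids = [str(i).upper() for i in ordered.index]
    member_set = {m.upper() for m in members}
    hits = np.array([i in member_set for i in ids])
    n_set = int(hits.sum())
    if n_set == 0:
        raise ValueError("no gene-set member present in the profile")
    N = len(ordered)
    v = np.abs(ordered.to_numpy(float)) ** alpha
    steps = np.zeros(N)
    wsum = v[hits].sum()
    steps[hits] = v[hits] / wsum if wsum > 0 else 1.0 / n_set
    if N > n_set:
        steps[~hits] = -1.0 / (N - n_set)
    return float(np.cumsum(steps).sum())


def ssgsea_collection(
    profile: pd.Series,
    sets: Sequence[GeneSet],
    alpha: float = 0.75,
    norm: str = "range",
    n_perm: int = 200,
    seed: int | None = None,
) -> pd.DataFrame:
    """Score a profile against a collection; NES by range- or permutation-scaling.

    ``norm='range'`` divides each ES by the range of ES across the evaluated
    collection; ``norm='permutation'`` divides by the mean |ES| of ``n_perm``
    random same-size sets drawn from the profile's features.
    """
    rows = []
    for s in sets:
        overlap = len(set(m.upper() for m in s.members) & {str(i).upper() for i in profile.dropna().index})
        es = ssgsea_es(profile, s.members, alpha=alpha) if overlap else np.nan
        rows.append({"set": s.name, "ES": es, "overlap": overlap})
    out = pd.DataFrame(rows).set_index("set")
    if norm == "range":
        rng_width = out["ES"].max() - out["ES"].min()
        out["NES"] = out["ES"] / rng_width if rng_width > 0 else np.nan
    elif norm == "permutation":
        rng = np.random.default_rng(seed)
        feats = list(profile.dropna().index)
        nes = []
        for s in sets:
            size = min(len(s.members), len(feats))
            null = [
                abs(ssgsea_es(profile, rng.choice(feats, size=size, replace=False), alpha=alpha))
                for _ in range(n_perm)
            ]
            denom = float(np.mean(null))
            nes.append(out.loc[s.name, "ES"] / denom if denom > 0 else np.nan)
        out["NES"] = nes
    else:
        raise ValueError(f"unknown norm {norm!r}")
    return out


def nes_by_permutation(
    profile: pd.Series,
    members: Iterable[str],
    alpha: float = 0.75,
    n_perm: int = 200,
    seed: int | None = None,
) -> float:
    """ES of one set divided by the mean |ES| of random same-size sets."""
    rng = np.random.default_rng(seed)
    es = ssgsea_es(profile, members, alpha=alpha)
    feats = list(profile.dropna().index)
    size = min(len(set(members)), len(feats))
    null = [
        abs(ssgsea_es(profile, rng.choice(feats, size=size, replace=False), alpha=alpha))
        for _ in range(n_perm)
    ]
    denom = float(np.mean(null))
    return es / denom if denom > 0 else np.nan


def _ranked_es_from_positions(
    positions: np.ndarray, weights: np.ndarray, N: int
) -> float:
    """Classic (max-deviation) GSEA ES from sorted 0-based hit positions."""
    m = positions.size
    if m == 0:
        return np.nan
    if N == m:
        return 1.0
    order = np.argsort(positions)
    pos = positions[order]
    w = weights[order]
    wsum = w.sum()
    if wsum <= 0:
        w = np.ones(m)
        wsum = float(m)
    cw = np.cumsum(w) / wsum
    d = 1.0 / (N - m)
    after = cw - d * (pos + 1 - np.arange(1, m + 1))  # just after each hit
    before = np.concatenate([[0.0], cw[:-1]]) - d * (pos - np.arange(m))  # just before
    hi = after.max()
    lo = min(before.min(), after[-1] - d * (N - 1 - pos[-1]))
    return float(hi if hi >= -lo else lo)


def gsea_ranked(
    ranks: pd.Series,
    sets: Sequence[GeneSet],
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 1.0,
) -> pd.DataFrame:
    """Ranked-list GSEA with gene-label permutation significance.

    ES is the maximum deviation of the weighted running sum; p-values come
    from permuting gene labels (equivalently, drawing random same-size
    member sets) and honor the (b+1)/(n_perm+1) bound; q is BH across sets.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives coarse permutation p-values")
    rng = np.random.default_rng(seed)
    ordered = _ordered(ranks)
    ids = np.array([str(i).upper() for i in ordered.index])
    vals = np.abs(ordered.to_numpy(float)) ** alpha
    N = len(ids)
    pos_of = {g: i for i, g in enumerate(ids)}

    rows = []
    for s in sets:
        positions = np.array(sorted(pos_of[m] for m in set(s.members) if m in pos_of))
        if positions.size == 0:
            rows.append({"set": s.name, "ES": np.nan, "NES": np.nan, "p": np.nan, "overlap": 0})
            continue
        m = positions.size
        es = _ranked_es_from_positions(positions, vals[positions], N)
        perm_es = np.empty(n_perm)
        for b in range(n_perm):
            perm_pos = rng.choice(N, size=m, replace=False)
            perm_es[b] = _ranked_es_from_positions(np.sort(perm_pos), vals[np.sort(perm_pos)], N)
        # magnitude-based permutation p: uniform under the null and attains
        # the (b+1)/(n_perm+1) lower bound
        p = (1 + int(np.sum(np.abs(perm_es) >= abs(es)))) / (n_perm + 1)
        same_sign = perm_es[perm_es >= 0] if es >= 0 else perm_es[perm_es < 0]
        denom = float(np.mean(np.abs(same_sign))) if same_sign.size else float(
            np.mean(np.abs(perm_es))
        )
        nes = es / denom if denom > 0 else np.nan
        rows.append({"set": s.name, "ES": es, "NES": nes, "p": p, "overlap": m})
    out = pd.DataFrame(rows).set_index("set")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def hypergeom_ora(
    signature: Iterable[str], gene_set: GeneSet | Iterable[str], background: Iterable[str]
) -> float:
    """Upper-tail hypergeometric p for the signature/set overlap."""
    sig = {str(g).upper() for g in signature}
    bg = {str(g).upper() for g in background}
    members = gene_set.members if isinstance(gene_set, GeneSet) else tuple(gene_set)
    st = {str(g).upper() for g in members} & bg
    if not sig <= bg:
        raise ValueError("signature must be a subset of the background")
    k = len(sig & st)
    return float(stats.hypergeom.sf(k - 1, len(bg), len(st), len(sig)))
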