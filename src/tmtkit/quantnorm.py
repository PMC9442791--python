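"""Peptide filtering, protein/phosphosite rollup and cross-plex normalization.

The normalization sequence is sample-loading (SL) scaling within each plex,
internal-reference-standard (IRS) scaling across plexes, then trimmed mean
of M-values (TMM) on the combined matrix. All three act on linear reporter
intensities and preserve the missingness mask.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from tmtkit.matrix import AbundanceMatrix

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    pass


def _sample_columns(table: pd.DataFrame) -> list[str]:
    from tmtkit.simulate import QUANT_META_COLUMNS

    return [c for c in table.columns if c not in QUANT_META_COLUMNS]


def _masters(cell: str) -> list[str]:
    return [m for m in str(cell).split(";") if m]


# -- filters ------------------------------------------------------------

def filter_human_unique(table: pd.DataFrame) -> pd.DataFrame:
    """Retain only human-specific peptides, preserving row order."""
    if "species" not in table.columns:
        raise SchemaError("quant table lacks a 'species' column")
    return table[table["species"] == "human"].copy()


def filter_phosphopeptides(table: pd.DataFrame, min_score: float = 200.0) -> pd.DataFrame:
    """Keep unambiguous, single-protein phosphopeptides confidently identified
    (score strictly above ``min_score``) in at least one plex.

    ``table`` may hold rows from several plexes; the score criterion is
    evaluated on the best per-plex score of each peptide.
    """
    t = table
    has_site = t["phospho_positions"].fillna("").astype(str) != ""
    unambiguous = ~t["localization_ambiguous"].astype(bool)
    single_master = t["master_proteins"].map(lambda c: len(_masters(c)) == 1)
    t = t[has_site & unambiguous & single_master]
    if t.empty:
        return t.copy()

    key_cols = ["peptide_sequence", "master_proteins", "phospho_positions"]
    best = t.groupby(key_cols + ["plex_id"])["id_score"].max().reset_index()
    passing = best[best["id_score"] > min_score][key_cols].drop_duplicates()
    merged = t.merge(passing.assign(_keep=True), on=key_cols, how="left")
    merged.index = t.index
    return t[merged["_keep"].notna().to_numpy()].copy()


# -- rollup -------------------------------------------------------------

def _infer_samples(columns: Sequence[str], plex_id: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "plex_id": plex_id,
            "channel_id": [f"ch{i + 1:02d}" for i in range(len(columns))],
            "is_reference": [str(c).startswith("ref_") for c in columns],
        },
        index=pd.Index(columns, name="sample_id"),
    )


def rollup_proteins(table: pd.DataFrame, samples: pd.DataFrame | None = None) -> AbundanceMatrix:
    """Sum peptide abundances per protein per channel.

    Peptides mapping to more than one master protein are excluded. Missing
    values are ignored in sums; a protein with no observed peptide in a
    channel stays missing.
    """
    cols = _sample_columns(table)
    single = table[table["master_proteins"].map(lambda c: len(_masters(c)) == 1)]
    acc = single["master_proteins"].map(lambda c: _masters(c)[0])
    values = single[cols].groupby(acc).sum(min_count=1)
    values.index.name = "feature_id"
    if samples is None:
        plex = str(single["plex_id"].iloc[0]) if len(single) else "plex1"
        samples = _infer_samples(cols, plex)
    return AbundanceMatrix(values, samples)


def rollup_peptides(table: pd.DataFrame, samples: pd.DataFrame | None = None) -> AbundanceMatrix:
    """One feature per (modified) peptide; rows with the same key are summed."""
    cols = _sample_columns(table)
    key = (
        table["master_proteins"].astype(str)
        + "|"
        + table["peptide_sequence"].astype(str)
        + "|"
        + table["phospho_positions"].fillna("").astype(str)
    )
    values = table[cols].groupby(key).sum(min_count=1)
    values.index.name = "feature_id"
    if samples is None:
        plex = str(table["plex_id"].iloc[0]) if len(table) else "plex1"
        samples = _infer_samples(cols, plex)
    return AbundanceMatrix(values, samples)


def peptide_site_map(table: pd.DataFrame) -> dict[str, list[str]]:
    """Map each peptide feature key to the phosphosite keys it carries."""
    out: dict[str, list[str]] = {}
    for _, row in table.iterrows():
        key = f"{row['master_proteins']}|{row['peptide_sequence']}|{row['phospho_positions']}"
        sites = []
        for token in str(row["phospho_positions"]).split(";"):
            token = token.strip()
            if not token:
                continue
            res, pos = token[0], token[1:]
            if res not in "STY" or not pos.isdigit() or int(pos) < 1:
                raise SchemaError(f"malformed phospho position {token!r}")
            sites.append(f"{_masters(row['master_proteins'])[0]}_{res}{pos}")
        if sites:
            out.setdefault(key, sites)
    return out


def condense_phosphosites(
    matrix: AbundanceMatrix, sites_by_feature: Mapping[str, Iterable[str]]
) -> AbundanceMatrix:
    """Average peptide-level abundances into phosphosite rows.

    A multiply-phosphorylated peptide contributes to every site it carries;
    missing values are ignored per site per sample.
    """
    records: dict[str, list[str]] = {}
    for feat, sites in sites_by_feature.items():
        if feat not in matrix.values.index:
            continue
        for s in sites:
            records.setdefault(s, []).append(feat)
    if not records:
        raise ValueError("no matrix feature carries a phosphosite")
    rows = {}
    for site in sorted(records):
        rows[site] = matrix.values.loc[records[site]].mean(axis=0, skipna=True)
    values = pd.DataFrame.from_dict(rows, orient="index")
    values.index.name = "feature_id"
    values = values[matrix.values.columns]
    return AbundanceMatrix(values, matrix.samples.copy(), dict(matrix.provenance))


# -- missingness --------------------------------------------------------

def filter_missing(matrix: AbundanceMatrix, max_missing_frac: float = 0.5) -> AbundanceMatrix:
    """Drop features missing in at least ``max_missing_frac`` of analytic samples."""
    if not 0 < max_missing_frac <= 1:
        raise ValueError("max_missing_frac must be in (0, 1]")
    cols = matrix.analytic_columns() or list(matrix.sample_ids)
    frac = matrix.values[cols].isna().mean(axis=1)
    keep = frac < max_missing_frac
    out = matrix.select_features(matrix.feature_ids[keep])
    out.provenance["missing_filtered"] = int((~keep).sum())
    return out


# -- normalizations -----------------------------------------------------

def normalize_sl(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Sample-loading scaling: equalize observed column sums within each plex."""
    out = matrix.copy()
    factors: dict[str, float] = {}
    for plex in out.plexes():
        cols = out.plex_columns(plex)
        sums = out.values[cols].sum(axis=0, skipna=True)
        zero = sums[sums <= 0]
        if len(zero):
            raise ValueError(f"zero total intensity in column(s): {list(zero.index)}")
        target = sums.mean()
        for c in cols:
            f = target / sums[c]
            out.values[c] = out.values[c] * f
            factors[c] = float(f)
    out.provenance.setdefault("sl_factors", {}).update(factors)
    return out


def normalize_irs(
    matrices: Sequence[AbundanceMatrix], drop_reference: bool = True
) -> AbundanceMatrix:
    """Internal-reference-standard scaling across plexes.

    Per feature, each plex's columns are multiplied by
    (geometric mean of the feature's reference values across plexes) /
    (its reference value in that plex), equalizing the reference channel.
    Features absent from (or zero in) any plex's reference are dropped.
    """
    mats = [m for m in matrices]
    if not mats:
        raise ValueError("no matrices given")
    refs = {}
    for m in mats:
        plexes = m.plexes()
        if len(plexes) != 1:
            raise ValueError("normalize_irs expects one matrix per plex")
        refs[plexes[0]] = m.values[m.reference_column(plexes[0])]

    ref_df = pd.DataFrame(refs)
    usable = ref_df.notna().all(axis=1) & (ref_df > 0).all(axis=1)
    common = ref_df.index[usable]
    # keep only features present in every plex's value matrix
    for m in mats:
        common = common.intersection(m.values.index)
    dropped = len(ref_df) - len(common)
    if dropped:
        logger.info("IRS: dropped %d features absent/zero in a reference", dropped)
    ref_df = ref_df.loc[common]
    geo = np.exp(np.log(ref_df).mean(axis=1))

    scaled = []
    samples = []
    for m in mats:
        plex = m.plexes()[0]
        factor = geo / ref_df[plex]
        vals = m.values.loc[common].mul(factor, axis=0)
        scaled.append(vals)
        samples.append(m.samples)
    values = pd.concat(scaled, axis=1)
    samples = pd.concat(samples, axis=0)
    out = AbundanceMatrix(values, samples)
    for m in mats:  # carry upstream provenance (e.g. SL factors) forward
        for k, v in m.provenance.items():
            if isinstance(v, dict):
                out.provenance.setdefault(k, {}).update(v)
            else:
                out.provenance[k] = v
    out.provenance["irs_dropped"] = int(dropped)
    out.provenance["irs_factors"] = {
        plex: (geo / ref_df[plex]).to_dict() for plex in ref_df.columns
    }
    if drop_reference:
        out = AbundanceMatrix(
            out.values[out.analytic_columns()],
            out.samples.loc[out.analytic_columns()],
            out.provenance,
        )
    return out


def tmm_factors(
    values: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05
) -> pd.Series:
    """TMM scale factors for the columns of a linear-intensity matrix.

    The reference column is the one whose upper quartile (of observed
    positive values) is closest to the mean upper quartile. Per column, the
    factor is 2^(weighted trimmed mean of per-feature log2 ratios to the
    reference), with the stated fractions of extreme M and A values trimmed
    and precision weights from the delta method. Factors are scaled to have
    geometric mean 1.
    """
    if values.shape[0] == 0:
        raise ValueError("TMM: empty matrix (no shared features across plexes?)")
    cols = list(values.columns)
    uq = values.where(values > 0).quantile(0.75)
    ref_col = (uq - uq.mean()).abs().idxmin()
    totals = values.sum(axis=0, skipna=True)

    factors = {}
    r = values[ref_col]
    for c in cols:
        if c == ref_col:
            factors[c] = 1.0
            continue
        x = values[c]
        ok = (x > 0) & (r > 0)
        xs, rs = x[ok].to_numpy(), r[ok].to_numpy()
        if xs.size == 0:
            factors[c] = 1.0
            continue
        m = np.log2(xs / rs)
        a = 0.5 * (np.log2(xs) + np.log2(rs))
        n = m.size
        m_rank = stats.rankdata(m)
        a_rank = stats.rankdata(a)
        keep = (
            (m_rank > n * trim_m)
            & (m_rank <= n * (1 - trim_m))
            & (a_rank > n * trim_a)
            & (a_rank <= n * (1 - trim_a))
        )
        if not keep.any():
            keep = np.ones(n, bool)
        w = 1.0 / (
            (totals[c] - xs[keep]) / (totals[c] * xs[keep])
            + (totals[ref_col] - rs[keep]) / (totals[ref_col] * rs[keep])
        )
        factors[c] = float(2.0 ** (np.sum(w * m[keep]) / np.sum(w)))

    f = pd.Series(factors)[cols]
    return f / np.exp(np.log(f).mean())


def normalize_tmm(
    matrix: AbundanceMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> AbundanceMatrix:
    """Divide each column by its TMM factor (factors have geometric mean 1)."""
    if matrix.values.shape[1] < 2:
        warnings.warn("TMM needs at least 2 columns; returning input unchanged")
        return matrix.copy()
    f = tmm_factors(matrix.values, trim_m=trim_m, trim_a=trim_a)
    out = matrix.copy()
    out.values = out.values.div(f, axis=1)
    out.provenance["tmm_factors"] = f.to_dict()
    return out


def normalize_pipeline(
    plex_matrices: Sequence[AbundanceMatrix],
    max_missing_frac: float = 0.5,
    tmm: bool = True,
    missing_filter_combined: bool = True,
) -> AbundanceMatrix:
    """SL within plex, IRS across plexes, then TMM on the combined matrix.

    The missingness filter runs on the combined matrix by default; set
    ``missing_filter_combined=False`` to apply it per plex before IRS.
    """
    mats = [normalize_sl(m) for m in plex_matrices]
    if not missing_filter_combined:
        mats = [filter_missing(m, max_missing_frac) for m in mats]
    combined = normalize_irs(mats)
    if missing_filter_combined:
        combined = filter_missing(combined, max_missing_frac)
    if tmm:
        combined = normalize_tmm(combined)
    return combined


# -- QC -----------------------------------------------------------------

def detect_outliers(
    matrix: AbundanceMatrix,
    sd_mult: float = 3.0,
    missing_quantile: float | None = None,
) -> pd.DataFrame:
    """Advisory outlier flags from PC-space distance and missingness.

    A sample is flagged when its distance from the centroid in the first two
    principal components exceeds ``sd_mult`` times the median distance, or —
    if ``missing_quantile`` is set — when its missing fraction strictly
    exceeds that quantile of all samples' missing fractions.
    """
    if matrix.values.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    log2 = matrix.log2()
    complete = log2.dropna(axis=0)
    n_samples = log2.shape[1]
    dist = np.zeros(n_samples)
    if complete.shape[0] >= 2:
        X = complete.to_numpy().T  # samples x features
        X = X - X.mean(axis=0, keepdims=True)
        if np.any(X.std(axis=0) > 0):
            from sklearn.decomposition import PCA

            pcs = PCA(n_components=min(2, min(X.shape))).fit_transform(X)
            dist = np.linalg.norm(pcs - pcs.mean(axis=0, keepdims=True), axis=1)
    med = np.median(dist)
    pc_flag = dist > sd_mult * med if med > 0 else np.zeros(n_samples, bool)

    frac_missing = matrix.values.isna().mean(axis=0).to_numpy()
    if missing_quantile is not None:
        cut = np.quantile(frac_missing, missing_quantile)
        miss_flag = (frac_missing > cut) & (frac_missing > 0)
    else:
        miss_flag = np.zeros(n_samples, bool)

    return pd.DataFrame(
        {
            "pc_distance": dist,
            "frac_missing": frac_missing,
            "pc_outlier": pc_flag,
            "missing_outlier": miss_flag,
            "flagged": pc_flag | miss_flag,
        },
        index=matrix.sample_ids,
    )


def ward_cluster(matrix: AbundanceMatrix, k: int, top_n: int | None = None) -> pd.Series:
    """Ward/Euclidean hierarchical clustering of samples on log2 values.

    Features with any missing value are dropped; optionally only the
    ``top_n`` most variable features are used. Returns integer labels.
    """
    from scipy.cluster.hierarchy import fcluster, linkage

    log2 = matrix.log2().dropna(axis=0)
    if top_n is not None and log2.shape[0] > top_n:
        log2 = log2.loc[log2.var(axis=1).nlargest(top_n).index]
    X = log2.to_numpy().T
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    Z = linkage(X, method="ward", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=matrix.sample_ids, name="cluster")
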