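import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmtkit import quantnorm as qn
from tmtkit.matrix import AbundanceMatrix, concat_plexes
from tmtkit.simulate import SimConfig, generate_experiment

from conftest import make_matrix, make_quant_table


class TestFilterHumanUnique:
    def test_only_human_rows_retained(self):
        t = make_quant_table(
            [
                {"peptide_id": "a", "species": "human", "S1": 1.0},
                {"peptide_id": "b", "species": "mouse", "S1": 2.0},
                {"peptide_id": "c", "species": "shared", "S1": 3.0},
            ],
            ["S1"],
        )
        out = qn.filter_human_unique(t)
        assert list(out["peptide_id"]) == ["a"]

    def test_all_human_identity(self):
        t = make_quant_table([{"peptide_id": "a", "S1": 1.0}, {"peptide_id": "b", "S1": 2.0}], ["S1"])
        out = qn.filter_human_unique(t)
        pd.testing.assert_frame_equal(out, t)

    def test_empty_table(self):
        t = make_quant_table([], ["S1"])
        assert len(qn.filter_human_unique(t)) == 0

    def test_missing_species_column_errors(self):
        with pytest.raises(qn.SchemaError):
            qn.filter_human_unique(pd.DataFrame({"S1": [1.0]}))


class TestRollupProteins:
    def test_sum_of_peptides(self):
        t = make_quant_table(
            [
                {"master_proteins": "P1", "S1": 10.0},
                {"master_proteins": "P1", "S1": 5.0},
            ],
            ["S1"],
        )
        m = qn.rollup_proteins(t)
        assert m.values.loc["P1", "S1"] == 15.0

    def test_single_peptide_protein(self):
        t = make_quant_table([{"master_proteins": "P9", "S1": 7.5}], ["S1"])
        assert qn.rollup_proteins(t).values.loc["P9", "S1"] == 7.5

    def test_multi_master_excluded(self):
        t = make_quant_table(
            [
                {"master_proteins": "P1;P2", "S1": 10.0},
                {"master_proteins": "P1", "S1": 5.0},
            ],
            ["S1"],
        )
        m = qn.rollup_proteins(t)
        assert m.values.loc["P1", "S1"] == 5.0
        assert "P2" not in m.values.index

    def test_all_missing_stays_missing(self):
        t = make_quant_table(
            [{"master_proteins": "P1", "S1": np.nan, "S2": 3.0}], ["S1", "S2"]
        )
        m = qn.rollup_proteins(t)
        assert np.isnan(m.values.loc["P1", "S1"])
        assert m.values.loc["P1", "S2"] == 3.0

    def test_brute_force_accumulation_oracle(self, rng):
        rows = []
        expected = {}
        for i in range(5):
            prot = "P1" if i < 3 else "P2"
            vals = {c: float(rng.uniform(1, 100)) for c in ["S1", "S2"]}
            rows.append({"master_proteins": prot, **vals})
            for c, v in vals.items():
                expected[(prot, c)] = expected.get((prot, c), 0.0) + v
        m = qn.rollup_proteins(make_quant_table(rows, ["S1", "S2"]))
        for (prot, c), v in expected.items():
            assert m.values.loc[prot, c] == pytest.approx(v)


class TestFilterMissing:
    def test_boundary_inclusive(self):
        vals = pd.DataFrame(
            {f"S{i}": [np.nan if i < 10 else 1.0, np.nan if i < 9 else 1.0]
             for i in range(20)},
            index=["half", "nine"],
        )
        m = make_matrix(vals)
        out = qn.filter_missing(m, 0.5)
        assert "half" not in out.values.index  # missing in 10/20 -> removed
        assert "nine" in out.values.index      # missing in 9/20 -> retained

    def test_fully_observed_unchanged(self):
        m = make_matrix(pd.DataFrame({"S1": [1.0, 2.0], "S2": [3.0, 4.0]}, index=["a", "b"]))
        out = qn.filter_missing(m)
        pd.testing.assert_frame_equal(out.values, m.values)


class TestNormalizeSL:
    def test_sums_equalized(self):
        vals = pd.DataFrame(
            {"S1": [50.0, 50.0], "S2": [100.0, 100.0], "S3": [150.0, 150.0]},
            index=["a", "b"],
        )
        out = qn.normalize_sl(make_matrix(vals))
        np.testing.assert_allclose(out.values.sum(axis=0), [200.0, 200.0, 200.0])

    def test_equal_sums_identity_factors(self):
        vals = pd.DataFrame({"S1": [1.0, 3.0], "S2": [2.0, 2.0]}, index=["a", "b"])
        out = qn.normalize_sl(make_matrix(vals))
        assert all(f == pytest.approx(1.0) for f in out.provenance["sl_factors"].values())

    def test_hand_computed_factors(self):
        vals = pd.DataFrame({"S1": [1.0, 2.0, 3.0], "S2": [2.0, 4.0, 6.0]}, index=list("abc"))
        out = qn.normalize_sl(make_matrix(vals))
        # column sums 6 and 12, mean 9 -> factors 1.5 and 0.75
        np.testing.assert_allclose(out.values["S1"], [1.5, 3.0, 4.5])
        np.testing.assert_allclose(out.values["S2"], [1.5, 3.0, 4.5])

    def test_zero_column_errors_with_name(self):
        vals = pd.DataFrame({"S1": [0.0, 0.0], "S2": [1.0, 1.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="S1"):
            qn.normalize_sl(make_matrix(vals))

    def test_within_plex_sums_equal_invariant(self, rng):
        vals = pd.DataFrame(rng.uniform(1, 100, size=(30, 6)),
                            columns=[f"S{i}" for i in range(6)])
        plex = {f"S{i}": ("plex1" if i < 3 else "plex2") for i in range(6)}
        out = qn.normalize_sl(make_matrix(vals, plex_ids=plex))
        sums = out.values.sum(axis=0)
        np.testing.assert_allclose(sums.iloc[:3], sums.iloc[0], rtol=1e-9)
        np.testing.assert_allclose(sums.iloc[3:], sums.iloc[3], rtol=1e-9)


def _two_plex_matrices(rng, n=20, ref_vals=None):
    mats = []
    for p in (1, 2):
        cols = [f"P{p}S{i}" for i in range(3)] + [f"ref_plex{p}"]
        vals = pd.DataFrame(
            rng.uniform(10, 1000, size=(n, 4)), columns=cols,
            index=[f"f{i}" for i in range(n)],
        )
        if ref_vals is not None:
            vals[f"ref_plex{p}"] = ref_vals[p - 1]
        mats.append(
            make_matrix(vals, plex_ids={c: f"plex{p}" for c in cols},
                        reference={f"ref_plex{p}"})
        )
    return mats


class TestNormalizeIRS:
    def test_geometric_mean_arithmetic(self, rng):
        mats = _two_plex_matrices(rng, n=1, ref_vals=[4.0, 16.0])
        out = qn.normalize_irs(mats, drop_reference=False)
        # geometric mean 8 -> factors 2 and 0.5; references equal 8 afterwards
        assert out.values.loc["f0", "ref_plex1"] == pytest.approx(8.0)
        assert out.values.loc["f0", "ref_plex2"] == pytest.approx(8.0)
        assert out.provenance["irs_factors"]["plex1"]["f0"] == pytest.approx(2.0)
        assert out.provenance["irs_factors"]["plex2"]["f0"] == pytest.approx(0.5)

    def test_single_plex_identity(self, rng):
        mats = _two_plex_matrices(rng)[:1]
        out = qn.normalize_irs(mats, drop_reference=False)
        np.testing.assert_allclose(out.values.to_numpy(), mats[0].values.to_numpy(), rtol=1e-12)

    def test_references_equal_across_plexes(self, rng):
        mats = _two_plex_matrices(rng)
        out = qn.normalize_irs(mats, drop_reference=False)
        np.testing.assert_allclose(
            out.values["ref_plex1"], out.values["ref_plex2"], rtol=1e-9
        )

    def test_reference_dropped_from_analytic_output(self, rng):
        out = qn.normalize_irs(_two_plex_matrices(rng))
        assert not any(c.startswith("ref_") for c in out.values.columns)
        assert out.values.shape[1] == 6

    def test_idempotence(self, rng):
        mats = _two_plex_matrices(rng)
        once = qn.normalize_irs(mats, drop_reference=False)
        again = qn.normalize_irs(
            [once.subset_plex(p) for p in once.plexes()], drop_reference=False
        )
        np.testing.assert_allclose(
            again.values.to_numpy(), once.values.loc[again.values.index, again.values.columns].to_numpy(),
            rtol=1e-9,
        )

    def test_zero_reference_feature_dropped(self, rng):
        mats = _two_plex_matrices(rng, n=5)
        mats[0].values.loc["f2", "ref_plex1"] = 0.0
        mats[1].values.loc["f4", "ref_plex2"] = np.nan
        out = qn.normalize_irs(mats)
        assert "f2" not in out.values.index and "f4" not in out.values.index
        assert out.provenance["irs_dropped"] == 2


def brute_force_tmm_factor(x, r, n_x, n_r, trim_m=0.30, trim_a=0.05):
    """Independent trimmed-mean implementation (sort-based, no rankdata)."""
    ok = (x > 0) & (r > 0)
    x, r = x[ok], r[ok]
    m = np.log2(x / r)
    a = 0.5 * (np.log2(x) + np.log2(r))
    n = len(m)
    m_order = np.argsort(np.argsort(m, kind="stable"), kind="stable") + 1.0
    a_order = np.argsort(np.argsort(a, kind="stable"), kind="stable") + 1.0
    # replicate average ranks for ties via scipy-free midrank not needed: values continuous
    keep = (
        (m_order > n * trim_m) & (m_order <= n * (1 - trim_m))
        & (a_order > n * trim_a) & (a_order <= n * (1 - trim_a))
    )
    w = 1.0 / ((n_x - x[keep]) / (n_x * x[keep]) + (n_r - r[keep]) / (n_r * r[keep]))
    return 2.0 ** (np.sum(w * m[keep]) / np.sum(w))


class TestNormalizeTMM:
    def test_identical_columns_unit_factors(self):
        vals = pd.DataFrame({"S1": [1.0, 2, 3, 4], "S2": [1.0, 2, 3, 4], "S3": [1.0, 2, 3, 4]})
        out = qn.normalize_tmm(make_matrix(vals))
        for f in out.provenance["tmm_factors"].values():
            assert f == pytest.approx(1.0)

    def test_doubled_column_recovered(self, rng):
        vals = pd.DataFrame(rng.lognormal(8, 1, size=(2000, 4)),
                            columns=["S1", "S2", "S3", "S4"])
        vals["S2"] = vals["S2"] * 2.0
        f = qn.tmm_factors(vals)
        rel = f["S2"] / np.exp(np.mean([np.log(f[c]) for c in ["S1", "S3", "S4"]]))
        assert abs(rel - 2.0) / 2.0 < 0.05

    def test_matches_brute_force_recomputation(self, rng):
        vals = pd.DataFrame(rng.lognormal(8, 1, size=(100, 3)), columns=["S1", "S2", "S3"])
        f = qn.tmm_factors(vals)
        uq = vals.quantile(0.75)
        ref = (uq - uq.mean()).abs().idxmin()
        raw = {}
        for c in vals.columns:
            if c == ref:
                raw[c] = 1.0
                continue
            raw[c] = brute_force_tmm_factor(
                vals[c].to_numpy(), vals[ref].to_numpy(),
                vals[c].sum(), vals[ref].sum(),
            )
        raw_series = pd.Series(raw)[vals.columns]
        expected = raw_series / np.exp(np.log(raw_series).mean())
        np.testing.assert_allclose(f.to_numpy(), expected.to_numpy(), rtol=1e-12)

    def test_single_column_warns_noop(self):
        vals = pd.DataFrame({"S1": [1.0, 2.0]})
        with pytest.warns(UserWarning):
            out = qn.normalize_tmm(make_matrix(vals))
        pd.testing.assert_frame_equal(out.values, vals)


class TestFilterPhosphopeptides:
    def _table(self, rows):
        return make_quant_table(rows, ["S1"])

    def test_score_in_one_plex_suffices(self):
        t = self._table([
            {"peptide_sequence": "AAK", "phospho_positions": "S5", "id_score": 250.0, "plex_id": "plex1"},
            {"peptide_sequence": "AAK", "phospho_positions": "S5", "id_score": 150.0, "plex_id": "plex2"},
        ])
        out = qn.filter_phosphopeptides(t)
        assert len(out) == 2  # both plex rows of the passing peptide kept

    def test_exactly_200_removed(self):
        t = self._table([
            {"peptide_sequence": "AAK", "phospho_positions": "S5", "id_score": 200.0, "plex_id": "plex1"},
            {"peptide_sequence": "AAK", "phospho_positions": "S5", "id_score": 200.0, "plex_id": "plex2"},
        ])
        assert len(qn.filter_phosphopeptides(t)) == 0

    def test_multi_master_removed(self):
        t = self._table([
            {"peptide_sequence": "AAK", "phospho_positions": "S5",
             "master_proteins": "P1;P2", "id_score": 400.0},
        ])
        assert len(qn.filter_phosphopeptides(t)) == 0

    def test_ambiguous_removed(self):
        t = self._table([
            {"peptide_sequence": "AAK", "phospho_positions": "S5",
             "localization_ambiguous": True, "id_score": 400.0},
        ])
        assert len(qn.filter_phosphopeptides(t)) == 0

    def test_non_phospho_removed(self):
        t = self._table([{"peptide_sequence": "AAK", "phospho_positions": "", "id_score": 400.0}])
        assert len(qn.filter_phosphopeptides(t)) == 0


class TestCondensePhosphosites:
    def test_mean_of_covering_peptides(self):
        m = make_matrix(pd.DataFrame({"S1": [8.0, 12.0]}, index=["pepA", "pepB"]))
        out = qn.condense_phosphosites(m, {"pepA": ["P1_S5"], "pepB": ["P1_S5"]})
        assert out.values.loc["P1_S5", "S1"] == pytest.approx(10.0)

    def test_single_peptide_site(self):
        m = make_matrix(pd.DataFrame({"S1": [4.0]}, index=["pepA"]))
        out = qn.condense_phosphosites(m, {"pepA": ["P1_T9"]})
        assert out.values.loc["P1_T9", "S1"] == 4.0

    def test_multiply_phosphorylated_contributes_to_each_site(self, rng):
        feats = {f"pep{i}": float(rng.uniform(1, 20)) for i in range(6)}
        m = make_matrix(pd.DataFrame({"S1": list(feats.values())}, index=list(feats)))
        site_map = {
            "pep0": ["P1_S5", "P1_T9"],  # doubly phosphorylated
            "pep1": ["P1_S5"],
            "pep2": ["P1_T9"],
            "pep3": ["P2_Y3"],
            "pep4": ["P2_Y3", "P2_S1"],
            "pep5": ["P2_S1"],
        }
        out = qn.condense_phosphosites(m, site_map)
        # brute-force enumeration of (peptide, site) pairs
        expected: dict[str, list[float]] = {}
        for pep, sites in site_map.items():
            for s in sites:
                expected.setdefault(s, []).append(feats[pep])
        for s, vals in expected.items():
            assert out.values.loc[s, "S1"] == pytest.approx(np.mean(vals))

    def test_commutes_with_sample_reordering(self, rng):
        vals = pd.DataFrame(rng.uniform(1, 9, size=(3, 4)),
                            index=["a", "b", "c"], columns=list("WXYZ"))
        site_map = {"a": ["P_S1"], "b": ["P_S1", "P_S2"], "c": ["P_S2"]}
        out1 = qn.condense_phosphosites(make_matrix(vals), site_map)
        out2 = qn.condense_phosphosites(make_matrix(vals[list("ZYXW")]), site_map)
        pd.testing.assert_frame_equal(out1.values, out2.values[out1.values.columns])

    def test_site_map_parser(self):
        t = make_quant_table(
            [{"peptide_sequence": "AK", "master_proteins": "P04637",
              "phospho_positions": "S15;T18", "S1": 1.0}],
            ["S1"],
        )
        mapping = qn.peptide_site_map(t)
        assert list(mapping.values()) == [["P04637_S15", "P04637_T18"]]

    def test_malformed_positions_rejected(self):
        t = make_quant_table(
            [{"master_proteins": "P1", "phospho_positions": "Z9", "S1": 1.0}], ["S1"]
        )
        with pytest.raises(qn.SchemaError):
            qn.peptide_site_map(t)


class TestMissingnessMaskPreserved:
    def test_all_normalizations_preserve_mask(self, rng):
        mats = _two_plex_matrices(rng, n=30)
        for m in mats:
            mask = rng.random(m.values.shape) < 0.15
            m.values[mask] = np.nan
            m.values[[c for c in m.values.columns if c.startswith("ref")]] = (
                m.values[[c for c in m.values.columns if c.startswith("ref")]].fillna(5.0)
            )
        before = [m.values.isna().copy() for m in mats]
        sl = [qn.normalize_sl(m) for m in mats]
        for b, a in zip(before, sl):
            pd.testing.assert_frame_equal(b, a.values.isna())
        combined = qn.normalize_irs(sl, drop_reference=False)
        for b, a in zip(before, [combined.subset_plex(p) for p in combined.plexes()]):
            pd.testing.assert_frame_equal(
                b.loc[a.values.index, a.values.columns], a.values.isna()
            )


class TestDetectOutliers:
    def test_homogeneous_gaussian_rarely_flagged(self):
        n_flagged_runs = 0
        runs = 60
        for seed in range(runs):
            r = np.random.default_rng(seed)
            vals = pd.DataFrame(2.0 ** r.normal(10, 1, size=(50, 12)),
                                columns=[f"S{i}" for i in range(12)])
            flags = qn.detect_outliers(make_matrix(vals))
            if flags["flagged"].any():
                n_flagged_runs += 1
        assert n_flagged_runs / runs <= 0.05

    def test_shifted_sample_flagged(self):
        r = np.random.default_rng(0)
        vals = pd.DataFrame(2.0 ** r.normal(10, 0.5, size=(60, 10)),
                            columns=[f"S{i}" for i in range(10)])
        vals["S0"] = vals["S0"] * 2.0 ** 5  # 10 SDs in log2
        flags = qn.detect_outliers(make_matrix(vals))
        assert flags.loc["S0", "flagged"]

    def test_identical_samples_no_flags(self):
        vals = pd.DataFrame({"S1": [1.0, 2.0], "S2": [1.0, 2.0], "S3": [1.0, 2.0]})
        flags = qn.detect_outliers(make_matrix(vals))
        assert not flags["flagged"].any()

    def test_missingness_quantile_flag(self):
        r = np.random.default_rng(1)
        vals = pd.DataFrame(2.0 ** r.normal(10, 0.5, size=(100, 8)),
                            columns=[f"S{i}" for i in range(8)])
        vals.loc[:49, "S7"] = np.nan
        flags = qn.detect_outliers(make_matrix(vals), missing_quantile=0.9)
        assert flags.loc["S7", "missing_outlier"]


class TestBatchEffectRemoval:
    def test_plex_anova_fraction_near_alpha(self):
        """SL+IRS removes the planted plex offset: plex-effect p-values ~ uniform."""
        from tmtkit.differential import anova_pvalues

        cfg = SimConfig(seed=42, n_proteins=2000, peptides_per_protein=(1, 1),
                        plex_effect_sd=0.5, noise_sd=0.3, group_effect_size=0.0,
                        frac_de=0.0, missing_rate=0.0)
        tables, truth = generate_experiment(cfg)
        mats = [qn.rollup_proteins(qn.filter_human_unique(t)) for t in tables]
        combined = qn.normalize_pipeline(mats, tmm=False)
        log2 = combined.log2()
        plex_labels = truth.sample_plex[log2.columns]
        p = anova_pvalues(log2, plex_labels)
        frac = float((p < 0.05).mean())
        half = 1.96 * np.sqrt(0.05 * 0.95 / len(p))
        assert 0.05 - half <= frac <= 0.05 + half


@settings(max_examples=25, deadline=None)
@given(
    data=st.lists(
        st.lists(st.floats(min_value=1.0, max_value=1e6), min_size=3, max_size=3),
        min_size=2, max_size=8,
    )
)
def test_sl_property_column_sums_equal(data):
    vals = pd.DataFrame(data, columns=["S1", "S2", "S3"]).astype(float)
    out = qn.normalize_sl(make_matrix(vals))
    sums = out.values.sum(axis=0)
    np.testing.assert_allclose(sums, sums.iloc[0], rtol=1e-9)
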