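"""I/O, harmonization and reference-panel QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cellmr.sumstats_io import (
    ReferencePanel, RegionSumStats, harmonize_pair, hwe_chisq_p, ld_corr,
    panel_qc, read_sumstats, write_sumstats,
)

from conftest import region_from_arrays


def _write_tsv(path, rows, columns):
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


COLS = ["chrom", "pos", "rsid", "ea", "oa", "eaf", "beta", "se", "pvalue", "n"]


class TestReadSumstats:
    def test_well_formed_identity_read(self, tmp_path):
        rows = [["1", 100, "rs1", "A", "G", 0.2, 0.1, 0.05, 0.0455, 500],
                ["1", 200, "rs2", "C", "A", 0.4, -0.2, 0.04, 1e-6, 500],
                ["1", 300, "rs3", "T", "C", 0.5, 0.0, 0.05, 1.0, 500]]
        _write_tsv(tmp_path / "s.tsv", rows, COLS)
        rss = read_sumstats(tmp_path / "s.tsv")
        assert len(rss) == 3
        assert list(rss.df["pos"]) == [100, 200, 300]

    def test_invalid_rows_dropped_with_count(self, tmp_path, caplog):
        rows = [["1", 100, "rs1", "A", "G", 0.2, 0.1, 0.05, 0.0455, 500],
                ["1", 200, "rs2", "C", "A", 0.4, -0.2, 0.0, 1e-6, 500]]  # se=0
        _write_tsv(tmp_path / "s.tsv", rows, COLS)
        with caplog.at_level("WARNING"):
            rss = read_sumstats(tmp_path / "s.tsv")
        assert len(rss) == 2 - 1
        assert "dropped 1" in caplog.text

    def test_missing_mandatory_column_fatal(self, tmp_path):
        _write_tsv(tmp_path / "s.tsv", [["1", 100, "rs1", "A", "G", 0.2, 0.1, 0.05]],
                   COLS[:-2])
        with pytest.raises(ValueError, match="mandatory"):
            read_sumstats(tmp_path / "s.tsv")

    def test_zero_valid_rows_fatal(self, tmp_path):
        _write_tsv(tmp_path / "s.tsv",
                   [["1", 100, "rs1", "A", "A", 0.2, 0.1, 0.05, 0.5, 500]], COLS)
        with pytest.raises(ValueError, match="no valid rows"):
            read_sumstats(tmp_path / "s.tsv")

    def test_dialect_mapping(self, tmp_path):
        _write_tsv(tmp_path / "s.tsv",
                   [["1", 100, "rs1", "A", "G", 0.2, 0.1, 0.05, 0.0455, 500]],
                   ["CHR", "BP", "SNP", "EA", "OA", "FRQ", "B", "SE", "P", "N"])
        rss = read_sumstats(tmp_path / "s.tsv", dialect={
            "CHR": "chrom", "BP": "pos", "SNP": "rsid", "EA": "ea", "OA": "oa",
            "FRQ": "eaf", "B": "beta", "SE": "se", "P": "pvalue", "N": "n"})
        assert rss.df["rsid"].iloc[0] == "rs1"

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_round_trip(self, tmp_path_factory, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(1, 30)
        df = pd.DataFrame({
            "chrom": "7",
            "pos": np.sort(rng.choice(10 ** 6, size=m, replace=False)),
            "rsid": [f"rs{j}" for j in range(m)],
            "ea": "A", "oa": "G",
            "eaf": rng.uniform(0.01, 0.99, m),
            "beta": rng.normal(0, 0.3, m),
            "se": rng.uniform(0.01, 0.2, m),
            "n": 777,
        })
        rss = RegionSumStats("t", "quantitative", df)
        path = tmp_path_factory.mktemp("rt") / "s.tsv"
        write_sumstats(rss, path)
        back = read_sumstats(path, trait_id="t")
        for col in ("pos", "eaf", "beta", "se", "n"):
            np.testing.assert_allclose(back.df[col], rss.df[col], rtol=1e-9)


class TestRegionInvariants:
    def test_multi_chromosome_rejected(self):
        df = pd.DataFrame({"chrom": ["1", "2"], "pos": [1, 2],
                           "rsid": ["a", "b"], "ea": "A", "oa": "G",
                           "eaf": 0.5, "beta": 0.0, "se": 1.0, "n": 10})
        with pytest.raises(ValueError, match="chromosome"):
            RegionSumStats("t", "quantitative", df)

    def test_duplicates_removed_and_sorted(self):
        df = pd.DataFrame({"chrom": "1", "pos": [300, 100, 100],
                           "rsid": ["c", "a", "a2"], "ea": "A", "oa": "G",
                           "eaf": 0.5, "beta": 0.0, "se": 1.0, "n": 10})
        rss = RegionSumStats("t", "quantitative", df)
        assert list(rss.df["pos"]) == [100, 300]


class TestHarmonize:
    def test_allele_swap_flips_beta_and_eaf(self):
        exp = region_from_arrays([100], [0.5], [0.1], ea="A", oa="G")
        out = region_from_arrays([100], [-0.2], [0.1], ea="G", oa="A", eaf=0.7,
                                 trait_id="o")
        m = harmonize_pair(exp, out)
        assert len(m) == 1
        assert m["beta_out"].iloc[0] == pytest.approx(0.2)
        assert m["eaf_out"].iloc[0] == pytest.approx(0.3)

    def test_palindromic_excluded(self):
        exp = region_from_arrays([100], [0.5], [0.1], ea="A", oa="T")
        out = region_from_arrays([100], [0.2], [0.1], ea="A", oa="T", trait_id="o")
        assert len(harmonize_pair(exp, out)) == 0

    def test_irreconcilable_alleles_dropped(self):
        exp = region_from_arrays([100], [0.5], [0.1], ea="A", oa="G")
        out = region_from_arrays([100], [0.2], [0.1], ea="A", oa="C", trait_id="o")
        assert len(harmonize_pair(exp, out)) == 0

    def test_empty_intersection_empty_result(self):
        exp = region_from_arrays([100], [0.5], [0.1])
        out = region_from_arrays([200], [0.2], [0.1], trait_id="o")
        assert len(harmonize_pair(exp, out)) == 0

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_involution_safe(self, seed):
        """Re-harmonizing already-aligned outcome stats changes nothing."""
        rng = np.random.default_rng(seed)
        m = 10
        pos = np.arange(1, m + 1) * 100
        alleles = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
        pick = [alleles[i] for i in rng.integers(0, 4, m)]
        exp = pd.DataFrame({"chrom": "1", "pos": pos,
                            "rsid": [f"rs{p}" for p in pos],
                            "ea": [p[0] for p in pick], "oa": [p[1] for p in pick],
                            "eaf": rng.uniform(0.1, 0.9, m),
                            "beta": rng.normal(size=m),
                            "se": rng.uniform(0.05, 0.2, m), "n": 100})
        out = exp.copy()
        swap = rng.random(m) < 0.5
        out.loc[swap, ["ea", "oa"]] = out.loc[swap, ["oa", "ea"]].to_numpy()
        out.loc[swap, "beta"] *= -1
        out.loc[swap, "eaf"] = 1 - out.loc[swap, "eaf"]
        e = RegionSumStats("e", "quantitative", exp)
        o = RegionSumStats("o", "quantitative", out)
        m1 = harmonize_pair(e, o)
        o2 = RegionSumStats("o", "quantitative", m1.assign(
            beta=m1["beta_out"], se=m1["se_out"], eaf=m1["eaf_out"], n=100)[
            ["chrom", "pos", "rsid", "ea", "oa", "eaf", "beta", "se", "n"]])
        m2 = harmonize_pair(e, o2)
        np.testing.assert_allclose(m2["beta_out"], m1["beta_out"])
        np.testing.assert_allclose(m2["eaf_out"], m1["eaf_out"])


def _panel_from_dosages(dos, ea="A", oa="G"):
    m = dos.shape[1]
    v = pd.DataFrame({"chrom": "1", "pos": np.arange(1, m + 1) * 100,
                      "rsid": [f"v{j}" for j in range(m)],
                      "ea": ea, "oa": oa})
    return ReferencePanel(v, dos)


class TestPanelQC:
    def test_exact_hwe_proportions_retained(self):
        # 25 AA + 50 Aa + 25 aa: chi-square exactly 0
        dos = np.repeat([2.0, 1.0, 0.0], [25, 50, 25])[:, None]
        assert hwe_chisq_p(dos[:, 0]) == pytest.approx(1.0)
        panel = _panel_from_dosages(np.hstack([dos, dos]))
        assert panel_qc(panel).n_variants == 2

    def test_low_maf_removed(self):
        common = np.repeat([2.0, 1.0, 0.0], [25, 50, 25])
        rare = np.zeros(100)
        rare[0] = 1.0  # MAF 0.005
        panel = _panel_from_dosages(np.column_stack([common, rare]))
        qc = panel_qc(panel)
        assert qc.n_variants == 1
        assert qc.variants["rsid"].iloc[0] == "v0"

    def test_hwe_chi_square_oracle(self):
        # counts AA=90, Aa=0, aa=10: hand-computed 1-df chi-square
        g = np.repeat([2.0, 0.0], [90, 10])
        p = 0.9
        n = 100
        exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p ** 2])
        obs = np.array([10.0, 0.0, 90.0])
        chi2 = np.sum((obs - exp) ** 2 / exp)
        assert hwe_chisq_p(g) == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-12)
        # chi2 = 100/81*... far beyond 1e-6 significance => removed
        common = np.repeat([2.0, 1.0, 0.0], [25, 50, 25])
        panel = _panel_from_dosages(np.column_stack([common, g]))
        qc = panel_qc(panel)
        expect_removed = stats.chi2.sf(chi2, 1) < 1e-6
        assert (qc.n_variants == 1) == expect_removed

    def test_ambiguous_alleles_removed(self):
        common = np.repeat([2.0, 1.0, 0.0], [25, 50, 25])
        panel = ReferencePanel(
            pd.DataFrame({"chrom": "1", "pos": [100, 200],
                          "rsid": ["v0", "v1"], "ea": ["A", "A"],
                          "oa": ["G", "T"]}),
            np.column_stack([common, common]))
        qc = panel_qc(panel)
        assert list(qc.variants["rsid"]) == ["v0"]

    def test_idempotent(self, small_panel):
        once = panel_qc(small_panel)
        twice = panel_qc(once)
        assert once.n_variants == twice.n_variants
        np.testing.assert_array_equal(once.dosages, twice.dosages)

    def test_all_removed_fatal(self):
        rare = np.zeros((100, 1))
        rare[0, 0] = 1.0
        with pytest.raises(ValueError, match="all variants"):
            panel_qc(_panel_from_dosages(rare))


class TestLdCorr:
    def test_duplicated_column_perfect_r(self, rng):
        x = rng.integers(0, 3, 200).astype(float)
        panel = _panel_from_dosages(np.column_stack([x, x]))
        R = ld_corr(panel, ["v0", "v1"])
        assert R[0, 1] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(5)
        X = rng.binomial(2, 0.4, size=(10000, 2)).astype(float)
        panel = _panel_from_dosages(X)
        R = ld_corr(panel, ["v0", "v1"])
        assert abs(R[0, 1]) < 0.05

    def test_flip_effect_allele_negates(self, rng):
        X = rng.binomial(2, 0.4, size=(500, 3)).astype(float)
        X[:, 1] = X[:, 0] + rng.normal(0, 0.3, 500)  # correlated pair
        panel = _panel_from_dosages(X)
        R = ld_corr(panel, ["v0", "v1", "v2"])
        Rf = ld_corr(panel, ["v0", "v1", "v2"], effect_alleles=["A", "G", "A"])
        expect = R.copy()
        expect[1, :] *= -1
        expect[:, 1] *= -1  # diagonal flipped twice, stays +1
        np.testing.assert_allclose(Rf, expect, atol=1e-12)

    def test_zero_variance_fatal(self):
        X = np.column_stack([np.ones(50), np.arange(50, dtype=float) % 3])
        panel = _panel_from_dosages(X)
        with pytest.raises(ValueError, match="zero-variance"):
            ld_corr(panel, ["v0", "v1"])

    def test_positive_semidefinite(self, small_panel):
        R = ld_corr(small_panel, list(small_panel.variants["rsid"]))
        w = np.linalg.eigvalsh(R)
        assert w.min() > -1e-8
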