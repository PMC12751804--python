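"""Colocalization posteriors, conditional analysis, and PWCoCo."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from cellmr import PipelineConfig
from cellmr.coloc_engine import (
    ABFTrack, coloc_abf, cojo_condition, cojo_fit, cojo_select, pwcoco,
    wakefield_labf,
)
from cellmr.sumstats_io import ReferencePanel, RegionSumStats
from cellmr.synthetic_data import (
    ScenarioSpec, simulate_quantitative_cohort, simulate_scenario,
)


class TestWakefield:
    def test_null_z_shrinks(self):
        V, W = 0.01, 0.0225
        labf = wakefield_labf(0.0, np.sqrt(V), W)
        assert labf == pytest.approx(0.5 * np.log(V / (V + W)))
        assert labf < 0

    def test_uninformative_limit(self):
        assert abs(wakefield_labf(0.1, 100.0, 0.0225)) < 1e-5

    @pytest.mark.parametrize("beta,se,W", [(0.1, 0.02, 0.0225),
                                           (-0.05, 0.01, 0.04),
                                           (0.0, 0.1, 0.0225),
                                           (0.3, 0.05, 0.04)])
    def test_matches_quadrature_oracle(self, beta, se, W):
        """ABF equals the normal-normal marginal-likelihood ratio computed
        by numerical integration."""
        V = se ** 2

        def integrand(b):
            return stats.norm.pdf(beta, b, np.sqrt(V)) * stats.norm.pdf(b, 0, np.sqrt(W))

        marg, _ = integrate.quad(integrand, -10 * np.sqrt(W), 10 * np.sqrt(W),
                                 limit=200)
        oracle = np.log(marg / stats.norm.pdf(beta, 0, np.sqrt(V)))
        assert wakefield_labf(beta, se, W) == pytest.approx(oracle, abs=1e-6)


def coloc_enumeration(l1, l2, p1, p2, p12):
    """Brute-force enumeration over all single-variant configuration pairs."""
    bf1, bf2 = np.exp(l1), np.exp(l2)
    m = len(l1)
    h = np.zeros(5)
    h[0] = 1.0
    h[1] = p1 * bf1.sum()
    h[2] = p2 * bf2.sum()
    for i in range(m):
        for j in range(m):
            if i != j:
                h[3] += p1 * p2 * bf1[i] * bf2[j]
    h[4] = p12 * (bf1 * bf2).sum()
    return h / h.sum()


def _tracks(l1, l2):
    ids = [f"rs{i}" for i in range(len(l1))]
    return ABFTrack(ids, l1), ABFTrack(ids, l2)


class TestColocAbf:
    def test_null_closed_form(self):
        m = 5
        t1, t2 = _tracks(np.zeros(m), np.zeros(m))
        p1 = p2 = 1e-4
        p12 = 5e-5
        res = coloc_abf(t1, t2, p1, p2, p12)
        denom = 1 + p1 * m + p2 * m + p1 * p2 * m * (m - 1) + p12 * m
        assert res.pph0 == pytest.approx(1 / denom, abs=1e-12)

    def test_single_variant_no_h3(self):
        t1, t2 = _tracks(np.array([25.0]), np.array([20.0]))
        res = coloc_abf(t1, t2)
        assert res.pph3 == 0.0
        assert res.pph4 > max(res.pph1, res.pph2)
        assert res.posteriors.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_variants_fatal(self):
        with pytest.raises(ValueError):
            coloc_abf(*_tracks(np.array([]), np.array([])))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(2, 7)
        l1 = rng.normal(0, 8, m)
        l2 = rng.normal(0, 8, m)
        res = coloc_abf(*_tracks(l1, l2))
        expect = coloc_enumeration(l1, l2, 1e-4, 1e-4, 5e-5)
        np.testing.assert_allclose(res.posteriors, expect, atol=1e-9)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_swap_symmetry_and_simplex(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(1, 12)
        l1, l2 = rng.normal(0, 6, m), rng.normal(0, 6, m)
        t1, t2 = _tracks(l1, l2)
        a = coloc_abf(t1, t2, 1e-4, 2e-4, 5e-5)
        b = coloc_abf(t2, t1, 2e-4, 1e-4, 5e-5)
        assert a.posteriors.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all((a.posteriors >= 0) & (a.posteriors <= 1))
        assert a.pph0 == pytest.approx(b.pph0, abs=1e-12)
        assert a.pph1 == pytest.approx(b.pph2, abs=1e-12)
        assert a.pph3 == pytest.approx(b.pph3, abs=1e-12)
        assert a.pph4 == pytest.approx(b.pph4, abs=1e-12)

    def test_prob_zero_variant_is_inert(self):
        rng = np.random.default_rng(3)
        l1, l2 = rng.normal(0, 5, 4), rng.normal(0, 5, 4)
        base = coloc_abf(*_tracks(l1, l2))
        aug = coloc_abf(*_tracks(np.append(l1, -np.inf), np.append(l2, -np.inf)))
        np.testing.assert_allclose(aug.posteriors, base.posteriors, atol=1e-12)


def _orthogonal_region():
    """Three variants with exactly orthogonal/dependent empirical dosages."""
    n = 400
    x1 = np.tile([0.0, 2.0], n // 2)
    x2 = np.tile([0.0, 0.0, 2.0, 2.0], n // 4)        # exactly r=0 with x1
    x3 = x1.copy()
    x3[:8] = [2, 0, 2, 0, 0, 2, 0, 2]                  # high but imperfect r
    dos = np.column_stack([x1, x2, x3])
    v = pd.DataFrame({"chrom": "1", "pos": [100, 200, 300],
                      "rsid": ["a", "b", "c"], "ea": "A", "oa": "G"})
    panel = ReferencePanel(v, dos)
    rng = np.random.default_rng(8)
    y = 0.2 * x1 + 0.1 * x2 + rng.standard_normal(n)
    rows = []
    for j, rsid in enumerate(["a", "b", "c"]):
        x = dos[:, j]
        xc = x - x.mean()
        sxx = xc @ xc
        b = xc @ (y - y.mean()) / sxx
        resid = y - y.mean() - b * xc
        se = np.sqrt(resid @ resid / (n - 2) / sxx)
        rows.append({"chrom": "1", "pos": (j + 1) * 100, "rsid": rsid,
                     "ea": "A", "oa": "G", "eaf": x.mean() / 2, "beta": b,
                     "se": se, "n": n})
    region = RegionSumStats("t", "quantitative", pd.DataFrame(rows))
    return region, panel


class TestCojoFit:
    def test_orthogonal_joint_equals_marginal(self):
        region, panel = _orthogonal_region()
        fit = cojo_fit(region, panel, ["a", "b"])
        marg = region.df.set_index("rsid")
        np.testing.assert_allclose(fit.joint_beta,
                                   marg.loc[["a", "b"], "beta"], rtol=1e-10)

    def test_single_variant_reproduces_marginal(self):
        region, panel = _orthogonal_region()
        marg = region.df.set_index("rsid")
        for rsid in ["a", "b", "c"]:
            fit = cojo_fit(region, panel, [rsid])
            assert fit.joint_beta[0] == pytest.approx(marg.loc[rsid, "beta"],
                                                      rel=1e-10)
            assert fit.joint_se[0] == pytest.approx(marg.loc[rsid, "se"],
                                                    rel=1e-10)

    def test_duplicate_selection_is_collinear_error(self):
        region, panel = _orthogonal_region()
        with pytest.raises(ValueError, match="collinear|more than once"):
            cojo_fit(region, panel, ["a", "a"])
        with pytest.raises(ValueError, match="collinear"):
            cojo_fit(region, panel, ["a", "c"])  # r ~ 0.96

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_multiple_regression_oracle(self, seed):
        """In-sample LD: joint estimates equal exact OLS coefficients."""
        rng = np.random.default_rng(seed)
        panel, y, rss = simulate_quantitative_cohort(
            n=2000, n_variants=20, block_size=10, rho=0.8,
            maf_range=(0.1, 0.5), causal_idx=[3, 14], h2=0.05, rng=rng)
        sel = [panel.variants["rsid"].iloc[i] for i in (2, 3, 14)]
        fit = cojo_fit(rss, panel, sel)
        X = np.column_stack([np.ones(2000), panel.columns(sel)])
        ols = np.linalg.lstsq(X, y, rcond=None)[0][1:]
        np.testing.assert_allclose(fit.joint_beta, ols, rtol=1e-8)


class TestCojoCondition:
    def test_empty_conditioning_is_identity(self):
        region, panel = _orthogonal_region()
        out = cojo_condition(region, panel, [])
        np.testing.assert_allclose(out.df["beta"], region.df["beta"])
        np.testing.assert_allclose(out.df["se"], region.df["se"])

    def test_orthogonal_conditioning_leaves_stats_unchanged(self):
        region, panel = _orthogonal_region()
        out = cojo_condition(region, panel, ["b"])  # b is exactly r=0 to a, c
        marg = region.df.set_index("rsid")
        sub = out.df.set_index("rsid")
        for rsid in ["a", "c"]:
            assert sub.loc[rsid, "beta"] == pytest.approx(
                marg.loc[rsid, "beta"], rel=1e-10)
            assert sub.loc[rsid, "se"] == pytest.approx(
                marg.loc[rsid, "se"], rel=1e-10)

    def test_conditioning_on_causal_shrinks_proxies(self):
        """Proxies (r2 > 0.5) of a conditioned-out causal variant have
        conditional |z| shrunk toward zero."""
        zs = []
        for seed in range(10):
            spec = ScenarioSpec(scenario="shared_causal", n_variants=20,
                                block_size=20, rho=0.9, n_ref=2000, seed=seed)
            data = simulate_scenario(spec)
            causal = data.truth.gwas_causal[0]
            cond = cojo_condition(data.gwas, data.panel, [causal])
            R2 = np.corrcoef(data.panel.dosages, rowvar=False) ** 2
            ci = int(data.panel.variants.index[
                data.panel.variants["rsid"] == causal][0])
            proxies = data.panel.variants["rsid"][
                (R2[ci] > 0.5) & (data.panel.variants["rsid"] != causal)]
            sub = cond.df.set_index("rsid").loc[[p for p in proxies]]
            zs.extend(np.abs(sub["beta"] / sub["se"]))
        assert np.mean(zs) < 1.5


class TestCojoSelect:
    def test_no_signal_empty_model(self):
        spec = ScenarioSpec(scenario="null", n_variants=30, block_size=10,
                            seed=41)
        data = simulate_scenario(spec)
        model = cojo_select(data.gwas, data.panel)
        assert model.rsids == []

    def test_single_causal_selects_causal_or_proxy(self):
        """At high power (z ~ 8), exactly one signal is selected and it is
        the causal variant or a tight LD proxy."""
        hits = 0
        for seed in range(10):
            spec = ScenarioSpec(scenario="shared_causal", n_variants=40,
                                block_size=10, gwas_h2=1e-3, seed=seed)
            data = simulate_scenario(spec)
            model = cojo_select(data.gwas, data.panel)
            if len(model.rsids) != 1:
                continue
            causal = data.truth.gwas_causal[0]
            if model.rsids[0] == causal:
                hits += 1
            else:
                r2 = np.corrcoef(
                    data.panel.columns([causal, model.rsids[0]]),
                    rowvar=False)[0, 1] ** 2
                hits += r2 > 0.8
        assert hits >= 9

    def test_masked_secondary_finds_two_signals(self):
        two = 0
        for seed in range(10):
            spec = ScenarioSpec(scenario="masked_secondary", n_variants=100,
                                block_size=20, seed=seed)
            data = simulate_scenario(spec)
            model = cojo_select(data.gwas, data.panel)
            two += len(model.rsids) == 2
        assert two >= 8


class TestPwcoco:
    def test_shared_causal_marginal_coloc(self):
        spec = ScenarioSpec(scenario="shared_causal", seed=51)
        data = simulate_scenario(spec)
        out = pwcoco(data.eqtl[("G1", "dataset_0")], data.gwas, data.panel)
        assert out.declared
        assert out.best.mode == "marginal"

    def test_masked_secondary_needs_conditioning(self):
        spec = ScenarioSpec(scenario="masked_secondary", seed=52)
        data = simulate_scenario(spec)
        out = pwcoco(data.eqtl[("G1", "dataset_0")], data.gwas, data.panel)
        marginal = out.grid[0]
        assert marginal.mode == "marginal"
        if out.declared:
            assert out.best.mode == "conditional"
            # the masking (independent) signal is conditioned out, the
            # shared signal is not
            share = data.truth.eqtl_causal["G1"]["dataset_0"][0]
            assert share not in out.best.conditioned_on["trait2"]

    def test_distinct_causal_favors_independence_when_informative(self):
        """Distinct causal variants in LD are resolved as H3 when both
        signals carry enough per-variant Bayes-factor discrimination to
        overcome the shared-signal prior (log p12/(p1 p2) ~ 8.5 nats);
        at r2=0.7 that needs strong signals on both traits."""
        n_h3 = 0
        for seed in range(5):
            spec = ScenarioSpec(scenario="distinct_causal", eqtl_h2=0.3,
                                gwas_h2=5e-3, seed=seed)
            data = simulate_scenario(spec)
            out = pwcoco(data.eqtl[("G1", "dataset_0")], data.gwas, data.panel)
            n_h3 += out.grid[0].pph3 > out.grid[0].pph4
        assert n_h3 >= 4

    def test_no_shared_variants_fatal(self, config):
        spec = ScenarioSpec(scenario="shared_causal", seed=54)
        data = simulate_scenario(spec)
        with pytest.raises(ValueError):
            pwcoco(data.eqtl[("G1", "dataset_0")], data.gwas, data.panel,
                   config, lead_pos=999_999_999)
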