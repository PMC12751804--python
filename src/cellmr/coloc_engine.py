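"""Approximate-Bayes-factor colocalization with conditional analysis.

Three layers:

* Wakefield log approximate Bayes factors per variant and the five-
  hypothesis colocalization posterior (PPH0: no signal for either trait;
  PPH1/PPH2: signal for one trait only; PPH3: two independent signals;
  PPH4: one shared signal), computed in log space with per-variant priors
  p1, p2, p12.
* Approximate conditional/joint analysis from marginal summary statistics
  plus a reference LD panel: joint fits, stepwise model selection with
  backward elimination, and per-variant conditional statistics, following
  the standard summary-data algebra with B_jk = r_jk * sqrt(D_j D_k).
* Pairwise conditional colocalization (PWCoCo): marginal colocalization
  first; if PPH4 falls short, each trait's independent signals are
  selected and every combination of marginal / conditioned-on-all-but-one
  summary statistics is colocalized, reporting the full grid and its
  maximum-PPH4 entry.

The per-variant "variance weight" D_j is taken as n_j times the reference
panel's empirical dosage variance, which equals 2*eaf*(1-eaf)*n_j under
Hardy-Weinberg and makes the joint fit reproduce exact multiple regression
when the panel is the analysis cohort itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .config import PipelineConfig
from .sumstats_io import (
    RegionSumStats, ReferencePanel, harmonize_pair, ld_corr, pvalue_from_z,
)

logger = logging.getLogger(__name__)


# --- Wakefield ABF and the five-hypothesis posterior -------------------------

def wakefield_labf(beta, se, W: float) -> np.ndarray:
    """Log approximate Bayes factor for H1 (effect ~ N(0, W)) vs H0.

    With V = se^2, z = beta/se and r = W/(V+W):
    labf = 0.5*(log(1-r) + z^2 * r).
    """
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    V = se ** 2
    z2 = (beta / se) ** 2
    r = W / (V + W)
    return 0.5 * (np.log1p(-r) + z2 * r)


@dataclass
class ABFTrack:
    """Per-variant log ABFs for one trait over a common variant list."""

    rsids: list[str]
    labf: np.ndarray
    trait_type: str = "quantitative"
    W: float = 0.15 ** 2

    def __post_init__(self):
        self.labf = np.asarray(self.labf, float)
        if len(self.rsids) != self.labf.size:
            raise ValueError("labf length does not match variant list")
        if not np.all(np.isfinite(self.labf) | (self.labf == -np.inf)):
            raise ValueError("labf contains non-finite values")

    @classmethod
    def from_stats(cls, rsids, beta, se, trait_type: str,
                   config: PipelineConfig | None = None) -> "ABFTrack":
        config = config or PipelineConfig()
        W = config.coloc_w_cc if trait_type == "case_control" else config.coloc_w_quant
        return cls(list(rsids), wakefield_labf(beta, se, W), trait_type, W)


@dataclass
class ColocResult:
    """Five-hypothesis posterior with conditioning provenance."""

    pph0: float
    pph1: float
    pph2: float
    pph3: float
    pph4: float
    n_variants: int
    mode: str = "marginal"                 # "marginal" | "conditional"
    conditioned_on: dict = field(default_factory=lambda: {"trait1": [], "trait2": []})

    def __post_init__(self):
        s = self.pph0 + self.pph1 + self.pph2 + self.pph3 + self.pph4
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"posteriors sum to {s}, not 1")

    @property
    def posteriors(self) -> np.ndarray:
        return np.array([self.pph0, self.pph1, self.pph2, self.pph3, self.pph4])


def coloc_abf(track1: ABFTrack, track2: ABFTrack,
              p1: float = 1e-4, p2: float = 1e-4, p12: float = 5e-5,
              mode: str = "marginal",
              conditioned_on: dict | None = None) -> ColocResult:
    """Colocalization posterior from two aligned ABF tracks.

    Tracks must share an identical variant list (intersect upstream).
    With a single shared variant the two-independent-signals hypothesis is
    impossible: PPH3 is set to zero and the rest renormalized.
    """
    if track1.rsids != track2.rsids:
        raise ValueError("tracks must share an identical variant list")
    m = len(track1.rsids)
    if m == 0:
        raise ValueError("colocalization needs at least one shared variant")
    l1, l2 = track1.labf, track2.labf
    S1 = logsumexp(l1)
    S2 = logsumexp(l2)
    S12 = logsumexp(l1 + l2)
    logh = np.empty(5)
    logh[0] = 0.0
    logh[1] = np.log(p1) + S1
    logh[2] = np.log(p2) + S2
    if m < 2:
        logh[3] = -np.inf
    else:
        # sum over i != j equals exp(S1+S2) - exp(S12), computed stably
        d = S12 - S1 - S2
        logh[3] = np.log(p1) + np.log(p2) + S1 + S2 + \
            (np.log1p(-np.exp(d)) if d < -1e-15 else -np.inf)
    logh[4] = np.log(p12) + S12
    post = np.exp(logh - logsumexp(logh))
    post = post / post.sum()
    return ColocResult(*post, n_variants=m, mode=mode,
                       conditioned_on=conditioned_on or {"trait1": [], "trait2": []})


# --- approximate conditional analysis from marginal statistics ---------------

@dataclass
class CojoModel:
    """A joint model of selected variants fitted from summary data."""

    rsids: list[str]
    joint_beta: np.ndarray
    joint_se: np.ndarray
    joint_p: np.ndarray
    sigma2: float
    p_cutoff: float
    collinearity_r2: float


class _CojoRegion:
    """Aligned working arrays for one trait region against the panel."""

    def __init__(self, region: RegionSumStats, panel: ReferencePanel):
        df = region.df
        present = df["rsid"].map(lambda r: r in panel)
        if (~present).any():
            logger.info("cojo: %d variants absent from panel dropped",
                        int((~present).sum()))
            df = df[present]
        df = df.reset_index(drop=True)
        rsids = list(df["rsid"])
        sub = panel.variants.set_index("rsid").loc[rsids]
        # orient panel dosages and frequencies to the summary effect allele
        X = panel.columns(rsids).copy()
        panel_eaf = sub["eaf"].to_numpy(float)
        for j, (ea, p_ea, p_oa) in enumerate(zip(df["ea"], sub["ea"], sub["oa"])):
            if ea == p_oa:
                X[:, j] = 2.0 - X[:, j]
                panel_eaf[j] = 1.0 - panel_eaf[j]
            elif ea != p_ea:
                raise ValueError(f"{rsids[j]}: alleles irreconcilable with panel")
        eaf = df["eaf"].to_numpy(float)
        miss = ~np.isfinite(eaf)
        eaf[miss] = panel_eaf[miss]
        drift = np.abs(eaf - panel_eaf) > 0.2
        if drift.any():
            logger.warning("cojo: excluding %d variants with panel/summary "
                           "frequency mismatch > 0.2", int(drift.sum()))
            keep = ~drift
            df, X = df[keep].reset_index(drop=True), X[:, keep]
            rsids = list(df["rsid"])
            eaf = eaf[keep]
        if not len(df):
            raise ValueError("no variants usable for conditional analysis")
        self.region = region
        self.df = df
        self.rsids = rsids
        self.index = {r: i for i, r in enumerate(rsids)}
        self.b = df["beta"].to_numpy(float)
        self.se = df["se"].to_numpy(float)
        nc, nk = df["n_case"].to_numpy(float), df["n_control"].to_numpy(float)
        n = df["n"].to_numpy(float)
        binary = np.isfinite(nc) & np.isfinite(nk)
        self.n = np.where(binary, 4.0 / (1.0 / np.where(binary, nc, 1) +
                                         1.0 / np.where(binary, nk, 1)), n)
        self.eaf = eaf
        Xc = X - X.mean(axis=0)
        var = (Xc ** 2).mean(axis=0)
        if np.any(var == 0):
            raise ValueError("zero-variance reference dosage in region")
        self.D = self.n * var
        self.R = np.corrcoef(X, rowvar=False) if len(rsids) > 1 else np.ones((1, 1))
        self.R = np.atleast_2d(self.R)
        # per-variant phenotypic sum of squares via the simple-OLS identity
        self.ypy = self.D * (self.se ** 2 * (self.n - 2) + self.b ** 2)
        self.sigma2_y = float(np.median(self.ypy / (self.n - 1)))

    def B(self, idx: list[int]) -> np.ndarray:
        d = np.sqrt(self.D[idx])
        return self.R[np.ix_(idx, idx)] * np.outer(d, d)


def cojo_fit(region: RegionSumStats, panel: ReferencePanel,
             selected: list[str], collinearity_r2: float = 0.9,
             p_cutoff: float = 5e-8) -> CojoModel:
    """Joint estimates for a chosen variant set from marginal statistics.

    Solves B @ beta_joint = D * beta_marginal with B built from reference
    LD; the residual variance comes from the median per-variant phenotypic
    sum of squares minus the model fit.  A pair of selected variants with
    reference r^2 >= ``collinearity_r2`` (including duplicates) is an
    error.
    """
    work = _CojoRegion(region, panel)
    if len(set(selected)) != len(selected):
        dup = [r for r in selected if selected.count(r) > 1]
        raise ValueError(f"variant selected more than once: {sorted(set(dup))}")
    idx = [work.index[r] for r in selected]
    k = len(idx)
    if k == 0:
        raise ValueError("no variants selected")
    R2 = work.R[np.ix_(idx, idx)] ** 2
    iu = np.triu_indices(k, 1)
    if k > 1 and np.any(R2[iu] >= collinearity_r2):
        i, j = [(a, b) for a, b in zip(*iu)][int(np.argmax(R2[iu] >= collinearity_r2))]
        raise ValueError(f"collinear selected pair: {selected[i]}, {selected[j]} "
                         f"(r^2={R2[i, j]:.3f})")
    B = work.B(idx)
    rhs = work.D[idx] * work.b[idx]
    joint = np.linalg.solve(B, rhs)
    nbar = float(np.median(work.n[idx]))
    ypy = float(np.median(work.ypy[idx]))
    rss = max(ypy - joint @ B @ joint, 1e-12)
    sigma2 = rss / max(nbar - k - 1, 1.0)
    se = np.sqrt(np.diag(np.linalg.inv(B)) * sigma2)
    p = pvalue_from_z(joint / se)
    return CojoModel(list(selected), joint, se, p, sigma2, p_cutoff, collinearity_r2)


def _conditional_arrays(work: _CojoRegion, cond_idx: list[int]
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Conditional beta/se for every variant outside the conditioning set."""
    m = len(work.rsids)
    targets = np.array([j for j in range(m) if j not in set(cond_idx)], dtype=int)
    if len(cond_idx) == 0:
        return targets, work.b[targets].copy(), work.se[targets].copy()
    Bcc = work.B(cond_idx)
    rhs_c = work.D[cond_idx] * work.b[cond_idx]
    bc = np.linalg.solve(Bcc, rhs_c)
    dj = np.sqrt(work.D[targets])
    dc = np.sqrt(work.D[cond_idx])
    # B_jc rows for all targets at once
    Bjc = work.R[np.ix_(targets, cond_idx)] * np.outer(dj, dc)
    Bcc_inv_Bcj = np.linalg.solve(Bcc, Bjc.T)          # k x t
    s = work.D[targets] - np.einsum("jk,kj->j", Bjc, Bcc_inv_Bcj)
    s = np.maximum(s, 1e-12)
    rhs_j = work.D[targets] * work.b[targets]
    b_cond = (rhs_j - Bjc @ bc) / s
    # per-target residual-variance proxy via the simple-OLS identity; it
    # reduces exactly to the marginal se when the conditioning set is
    # orthogonal to the target
    n_t = work.n[targets]
    resid = np.maximum(work.ypy[targets] - b_cond ** 2 * s, 1e-12)
    se_cond = np.sqrt(resid / (np.maximum(n_t - 2, 1.0) * s))
    return targets, b_cond, se_cond


def cojo_condition(region: RegionSumStats, panel: ReferencePanel,
                   conditioning: list[str],
                   collinearity_r2: float = 0.9) -> RegionSumStats:
    """Per-variant statistics conditional on a set of variants.

    Returns a region with conditional beta/se/p for every non-conditioning
    variant (empty conditioning set is the identity on marginal stats).
    """
    work = _CojoRegion(region, panel)
    cond_idx = [work.index[r] for r in conditioning]
    targets, b_cond, se_cond = _conditional_arrays(work, cond_idx)
    df = work.df.iloc[targets].copy().reset_index(drop=True)
    df["beta"] = b_cond
    df["se"] = se_cond
    df["pvalue"] = pvalue_from_z(b_cond / se_cond)
    out = RegionSumStats(trait_id=region.trait_id, trait_type=region.trait_type,
                         df=df, dataset_id=region.dataset_id,
                         cell_type=region.cell_type, gene_id=region.gene_id)
    return out


def cojo_select(region: RegionSumStats, panel: ReferencePanel,
                p_cutoff: float = 5e-8, collinearity_r2: float = 0.9,
                max_signals: int = 10) -> CojoModel:
    """Stepwise forward selection with backward elimination.

    Seeds with the minimum-p variant if below ``p_cutoff``; repeatedly adds
    the variant with the smallest conditional p below the cutoff (skipping
    candidates with reference r^2 >= ``collinearity_r2`` against any model
    variant), dropping model variants whose joint p rises above the cutoff,
    until a fixed point.  Returns an empty model when nothing reaches the
    cutoff.
    """
    work = _CojoRegion(region, panel)
    pvals = pvalue_from_z(work.b / work.se)
    order = np.lexsort((work.df["oa"], work.df["ea"], work.df["pos"], pvals))
    if pvals[order[0]] >= p_cutoff:
        return CojoModel([], np.array([]), np.array([]), np.array([]),
                         work.sigma2_y, p_cutoff, collinearity_r2)
    model = [int(order[0])]
    R2 = work.R ** 2
    for _ in range(4 * max_signals):
        changed = False
        if len(model) < max_signals:
            targets, b_c, se_c = _conditional_arrays(work, model)
            p_c = pvalue_from_z(np.divide(b_c, se_c, out=np.zeros_like(b_c),
                                          where=se_c > 0))
            ok = np.array([R2[j, model].max() < collinearity_r2 for j in targets])
            if ok.any() and p_c[ok].min() < p_cutoff:
                cand = targets[ok][int(np.argmin(p_c[ok]))]
                model.append(int(cand))
                changed = True
        # backward elimination on the joint model
        while len(model) > 1:
            fit = cojo_fit(region, panel,
                           [work.rsids[j] for j in model],
                           collinearity_r2, p_cutoff)
            bad = np.where(fit.joint_p >= p_cutoff)[0]
            if not len(bad):
                break
            worst = int(bad[np.argmax(fit.joint_p[bad])])
            model.pop(worst)
            changed = True
        if not changed:
            break
    return cojo_fit(region, panel, [work.rsids[j] for j in model],
                    collinearity_r2, p_cutoff)


# --- pairwise conditional colocalization -------------------------------------

@dataclass
class PwcocoOutcome:
    """Best colocalization over the marginal/conditional grid."""

    best: ColocResult
    grid: list[ColocResult]
    declared: bool
    signals1: list[str]
    signals2: list[str]


def _aligned_regions(trait1: RegionSumStats, trait2: RegionSumStats
                     ) -> tuple[RegionSumStats, RegionSumStats]:
    """Restrict both traits to harmonized shared variants (trait1 alleles)."""
    pairs = harmonize_pair(trait1, trait2)
    if not len(pairs):
        raise ValueError("no shared variants between the two traits")
    base = pairs[["chrom", "pos", "rsid", "ea", "oa"]]
    df1 = base.copy()
    df2 = base.copy()
    for col in ("eaf", "beta", "se", "pvalue", "n", "n_case", "n_control"):
        df1[col] = pairs.get(f"{col}_exp")
        df2[col] = pairs.get(f"{col}_out")
    r1 = RegionSumStats(trait_id=trait1.trait_id, trait_type=trait1.trait_type,
                        df=df1, dataset_id=trait1.dataset_id,
                        cell_type=trait1.cell_type, gene_id=trait1.gene_id)
    r2 = RegionSumStats(trait_id=trait2.trait_id, trait_type=trait2.trait_type,
                        df=df2, dataset_id=trait2.dataset_id,
                        cell_type=trait2.cell_type, gene_id=trait2.gene_id)
    return r1, r2


def _versions(region: RegionSumStats, panel: ReferencePanel,
              config: PipelineConfig) -> tuple[list[tuple[list[str], RegionSumStats]], list[str]]:
    """Marginal plus conditioned-on-all-but-one-signal versions of a trait."""
    model = cojo_select(region, panel, config.cojo_p,
                        config.collinearity_r2, config.max_signals)
    versions: list[tuple[list[str], RegionSumStats]] = [([], region)]
    if len(model.rsids) >= 2:
        for s in model.rsids:
            cond = [r for r in model.rsids if r != s]
            versions.append((cond, cojo_condition(region, panel, cond,
                                                  config.collinearity_r2)))
    return versions, model.rsids


def pwcoco(trait1: RegionSumStats, trait2: RegionSumStats,
           panel: ReferencePanel, config: PipelineConfig | None = None,
           lead_pos: int | None = None) -> PwcocoOutcome:
    """Pairwise conditional colocalization of two traits in one window.

    Runs marginal colocalization on the shared-variant window (±coloc
    window around ``lead_pos`` when given).  If PPH4 already reaches the
    evidence threshold the marginal result is returned.  Otherwise each
    trait's independent signals are selected and every combination of
    marginal / conditioned-on-all-but-one-signal summary statistics is
    colocalized; the maximum-PPH4 entry decides.
    """
    config = config or PipelineConfig()
    if lead_pos is not None:
        trait1 = trait1.window(lead_pos, config.coloc_window)
        trait2 = trait2.window(lead_pos, config.coloc_window)
    r1, r2 = _aligned_regions(trait1, trait2)

    def _track(region: RegionSumStats, rsids: list[str]) -> ABFTrack:
        sub = region.df.set_index("rsid").loc[rsids]
        return ABFTrack.from_stats(rsids, sub["beta"], sub["se"],
                                   region.trait_type, config)

    shared = r1.df["rsid"].tolist()
    marginal = coloc_abf(_track(r1, shared), _track(r2, shared),
                         config.p1, config.p2, config.p12, mode="marginal")
    if marginal.pph4 >= config.pph4_threshold:
        return PwcocoOutcome(marginal, [marginal], True, [], [])

    grid = [marginal]
    v1, sig1 = _versions(r1, panel, config)
    v2, sig2 = _versions(r2, panel, config)
    for cond1, reg1 in v1:
        for cond2, reg2 in v2:
            if not cond1 and not cond2:
                continue  # marginal x marginal already computed
            common = sorted(set(reg1.df["rsid"]) & set(reg2.df["rsid"]))
            if not common:
                continue
            common = [r for r in shared if r in set(common)]
            res = coloc_abf(_track(reg1, common), _track(reg2, common),
                            config.p1, config.p2, config.p12,
                            mode="conditional",
                            conditioned_on={"trait1": cond1, "trait2": cond2})
            grid.append(res)
    best = max(grid, key=lambda r: r.pph4)
    return PwcocoOutcome(best, grid, best.pph4 >= config.pph4_threshold,
                         sig1, sig2)


COLOC_COLUMNS = ["trait1", "trait2", "mode", "conditioned_trait1",
                 "conditioned_trait2", "pph0", "pph1", "pph2", "pph3", "pph4",
                 "n_variants"]


def coloc_table(outcome: PwcocoOutcome, trait1_id: str, trait2_id: str) -> pd.DataFrame:
    """One row per colocalization run in the PWCoCo grid."""
    rows = []
    for r in outcome.grid:
        rows.append({"trait1": trait1_id, "trait2": trait2_id, "mode": r.mode,
                     "conditioned_trait1": ",".join(r.conditioned_on["trait1"]),
                     "conditioned_trait2": ",".join(r.conditioned_on["trait2"]),
                     "pph0": r.pph0, "pph1": r.pph1, "pph2": r.pph2,
                     "pph3": r.pph3, "pph4": r.pph4, "n_variants": r.n_variants})
    return pd.DataFrame(rows, columns=COLOC_COLUMNS)
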