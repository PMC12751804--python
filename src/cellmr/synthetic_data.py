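"""LD-structured synthetic eQTL/GWAS data with known causal ground truth.

Genotypes follow a latent-Gaussian-threshold haplotype model: within each
LD block a haplotype's latent values follow an AR(1) process with
correlation ``rho``; an allele is carried where the latent value falls
below the MAF-matched normal quantile, and dosages are the sum of two
independent haplotypes.  This gives direct control of the block LD
structure without external simulators (adjacent-variant dosage correlation
is the latent rho attenuated by dichotomization).

Expression phenotypes are simulated at the individual level and summarised
by per-variant marginal regression.  Disease GWAS z-scores are drawn at the
summary level from z ~ MVN(R @ lambda, R) — the standard summary-statistics
model — where R is the panel LD matrix and lambda_j = sqrt(n_eff) * a_j with
``a`` the standardized causal effects on liability; this preserves the
LD/z-score structure that colocalization and conditional analysis consume
without simulating half a million individuals.

Scenarios
---------
null                no causal variants anywhere
shared_causal       one variant drives both expression and disease
distinct_causal     two variants in LD (target r^2 configurable) drive the
                    two traits separately — the confounding-by-LD case
masked_secondary    disease has a strong independent signal plus a weaker
                    signal shared with the eQTL (exercises conditioning)
horizontal_pleiotropy  one variant drives two genes' expression and disease
vertical_causal     variant -> expression -> disease with effect theta

All randomness flows from the single seed in the spec; identical specs
produce identical fixtures.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats_io import (
    RegionSumStats, ReferencePanel, pvalue_from_z, write_panel, write_sumstats,
)

logger = logging.getLogger(__name__)

SCENARIOS = (
    "null", "shared_causal", "distinct_causal", "masked_secondary",
    "horizontal_pleiotropy", "vertical_causal",
)

# non-palindromic allele pairs only, so fixtures survive harmonization QC
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass
class ScenarioSpec:
    """Study conditions for one simulated cis region.

    Sample sizes default to the seed study's scale: eQTL cohorts of a few
    hundred donors, and a case-control GWAS of 18,942 cases and 501,638
    controls (effective sample size ~73k).  ``eqtl_h2`` is the fraction of
    expression variance explained jointly by the causal cis-eQTL(s);
    ``gwas_h2`` the liability variance explained per causal disease
    variant; ``theta`` the causal effect of expression on liability
    (log-odds per SD of expression) used by vertical_causal.
    """

    scenario: str = "shared_causal"
    n_variants: int = 100
    block_size: int = 20
    rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_ref: int = 2000
    n_eqtl: int = 500
    n_datasets: int = 2
    n_case: int = 18_942
    n_control: int = 501_638
    eqtl_h2: float = 0.1
    gwas_h2: float = 5e-4
    gwas_h2_masking: float = 2e-3
    theta: float = 0.3
    distinct_r2: float = 0.7
    chrom: str = "1"
    region_start: int = 1_000_000
    spacing: int = 2_000
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if not 0 <= self.eqtl_h2 < 1:
            raise ValueError("eqtl_h2 must be in [0, 1)")
        if not (self.n_case > 0 and self.n_control > 0):
            raise ValueError("case/control counts must be positive")

    @property
    def coupled_pairs(self) -> list[tuple[int, int, float]]:
        """Haplotype-coupled variant pairs (i, j, r) for this scenario.

        Thresholding a latent AR(1) Gaussian attenuates correlation, and
        mismatched allele frequencies cap the attainable dosage r^2 well
        below 1, so the distinct-causal pair is built directly: variant j's
        haplotype is variant i's with probability r and an independent
        draw otherwise, which preserves the allele frequency and gives
        haplotype (hence dosage) correlation r.
        """
        if self.scenario == "distinct_causal":
            m = self.n_variants
            return [(m // 2, m // 2 + 1, float(np.sqrt(self.distinct_r2)))]
        return []

    @property
    def n_gwas(self) -> int:
        return self.n_case + self.n_control

    @property
    def case_fraction(self) -> float:
        return self.n_case / self.n_gwas

    @property
    def n_eff(self) -> float:
        """Effective GWAS sample size 4/(1/n_case + 1/n_control)."""
        return 4.0 / (1.0 / self.n_case + 1.0 / self.n_control)


@dataclass
class GroundTruth:
    """Causal configuration recorded before any noise is added."""

    eqtl_causal: dict = field(default_factory=dict)   # gene -> dataset -> [rsid]
    gwas_causal: list = field(default_factory=list)   # [rsid]
    theta: float = 0.0
    shared: dict = field(default_factory=dict)        # gene -> dataset -> bool

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _block_sizes(n_variants: int, block_size: int) -> list[int]:
    sizes = [block_size] * (n_variants // block_size)
    if n_variants % block_size:
        sizes.append(n_variants % block_size)
    return sizes


def _simulate_haplotype_dosages(mafs: np.ndarray, block_sizes: list[int],
                                rho: float, n: int, rng: np.random.Generator,
                                coupled: list[tuple[int, int, float]] = ()
                                ) -> np.ndarray:
    """Dosages for n individuals = sum of two thresholded AR(1) haplotypes.

    ``coupled`` pairs (i, j, r) overwrite haplotype j with a probabilistic
    copy of haplotype i (copied with probability r, redrawn at the same
    frequency otherwise), giving haplotype correlation exactly r in
    expectation.
    """
    m = mafs.size
    Z = np.empty((2 * n, m))
    j = 0
    for bs in block_sizes:
        Z[:, j] = rng.standard_normal(2 * n)
        for k in range(j + 1, j + bs):
            Z[:, k] = rho * Z[:, k - 1] + np.sqrt(1 - rho ** 2) * rng.standard_normal(2 * n)
        j += bs
    thr = stats.norm.ppf(mafs)
    hap = (Z < thr).astype(float)
    for i, j, r in coupled:
        fresh = (rng.random(2 * n) < mafs[i]).astype(float)
        copy = rng.random(2 * n) < r
        hap[:, j] = np.where(copy, hap[:, i], fresh)
    return hap[:n] + hap[n:]


def _region_variants(spec: ScenarioSpec, rng: np.random.Generator,
                     prefix: str = "rs", start: int | None = None) -> pd.DataFrame:
    m = spec.n_variants
    mafs = rng.uniform(*spec.maf_range, size=m)
    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), size=m)]
    start = spec.region_start if start is None else start
    return pd.DataFrame({
        "chrom": spec.chrom,
        "pos": start + spec.spacing * np.arange(m),
        "rsid": [f"{prefix}{start + spec.spacing * j}" for j in range(m)],
        "ea": [p[0] for p in pairs],
        "oa": [p[1] for p in pairs],
        "eaf": mafs,
    })


def simulate_panel(spec: ScenarioSpec, rng: np.random.Generator | None = None,
                   variants: pd.DataFrame | None = None) -> ReferencePanel:
    """Simulate the LD reference panel for one region."""
    rng = np.random.default_rng([spec.seed, 0]) if rng is None else rng
    if variants is None:
        variants = _region_variants(spec, rng)
    mafs = variants["eaf"].to_numpy().copy()
    for i, j, _ in spec.coupled_pairs:
        mafs[j] = mafs[i]
    variants = variants.assign(eaf=mafs)
    dos = _simulate_haplotype_dosages(mafs,
                                      _block_sizes(len(variants), spec.block_size),
                                      spec.rho, spec.n_ref, rng,
                                      spec.coupled_pairs)
    v = variants.copy()
    v["eaf"] = dos.mean(axis=0) / 2.0
    return ReferencePanel(v, dos)


def _marginal_linear_sumstats(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-variant simple-regression beta, se, z for phenotype y."""
    n = y.size
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", Xc, Xc)
    ok = sxx > 0
    sxy = Xc.T @ yc
    beta = np.zeros(X.shape[1])
    se = np.full(X.shape[1], np.inf)
    beta[ok] = sxy[ok] / sxx[ok]
    rss = (yc @ yc) - beta * sxy
    sigma2 = np.maximum(rss, 0.0) / max(n - 2, 1)
    se[ok] = np.sqrt(sigma2[ok] / sxx[ok])
    return beta, se, ok


def _standardized_effects(truth_rsids: list[str], variants: pd.DataFrame,
                          total_var: float) -> np.ndarray:
    """Equal per-variant standardized effects explaining total_var jointly.

    Causal variants sit in distinct LD positions in every scenario, so
    the joint variance is approximated by the sum of per-variant terms.
    """
    a = np.zeros(len(variants))
    if truth_rsids:
        idx = variants.index[variants["rsid"].isin(truth_rsids)]
        a[idx] = np.sqrt(total_var / len(truth_rsids))
    return a


def simulate_eqtl_sumstats(panel: ReferencePanel, spec: ScenarioSpec,
                           causal_rsids: list[str],
                           rng: np.random.Generator,
                           dataset_id: str = "dataset_0",
                           cell_type: str = "cell_type_0",
                           gene_id: str = "G1",
                           effects: np.ndarray | None = None) -> RegionSumStats:
    """Marginal cis-eQTL summary statistics from a fresh expression cohort.

    Expression y = sum_c b_c * x_c (standardized) + noise, with b scaled so
    the causal set jointly explains ``eqtl_h2`` of the expression variance.
    Individuals are drawn independently per dataset from the same haplotype
    model as the panel.
    """
    variants = panel.variants
    X = _simulate_haplotype_dosages(variants["eaf"].to_numpy(),
                                    _block_sizes(len(variants), spec.block_size),
                                    spec.rho, spec.n_eqtl, rng,
                                    spec.coupled_pairs)
    if effects is None:
        effects = _standardized_effects(causal_rsids, variants, spec.eqtl_h2)
    h2 = float(np.sum(effects ** 2))
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    y = Xs @ effects + rng.standard_normal(spec.n_eqtl) * np.sqrt(max(1 - h2, 1e-12))
    beta, se, ok = _marginal_linear_sumstats(X, y)
    freq = X.mean(axis=0) / 2.0
    ok &= (freq > 0) & (freq < 1)
    df = variants[["chrom", "pos", "rsid", "ea", "oa"]].copy()
    df["eaf"] = freq
    df["beta"] = beta
    df["se"] = se
    df["pvalue"] = pvalue_from_z(np.divide(beta, se, out=np.zeros_like(beta),
                                           where=se > 0))
    df["n"] = spec.n_eqtl
    df = df[ok]
    return RegionSumStats(trait_id=f"{gene_id}@{dataset_id}",
                          trait_type="quantitative", df=df,
                          dataset_id=dataset_id, cell_type=cell_type,
                          gene_id=gene_id)


def repair_psd(R: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Clip eigenvalues at ``floor`` to restore positive semidefiniteness."""
    w, V = np.linalg.eigh(R)
    if w.min() >= floor:
        return R
    logger.info("LD matrix repaired: min eigenvalue %.3g clipped to %.0e",
                w.min(), floor)
    w = np.clip(w, floor, None)
    return (V * w) @ V.T


def simulate_gwas_sumstats(panel: ReferencePanel, spec: ScenarioSpec,
                           effects: np.ndarray,
                           rng: np.random.Generator,
                           trait_id: str = "disease") -> RegionSumStats:
    """Case-control GWAS summary statistics from the summary-level model.

    z ~ MVN(R @ lambda, R) with lambda_j = sqrt(n_eff) * a_j, where ``a``
    holds standardized liability effects (a_j^2 = liability variance
    explained by variant j).  beta = z * se with
    se = 1/sqrt(n_eff * 2 * eaf * (1-eaf)).
    """
    X = panel.dosages
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    R = repair_psd(np.corrcoef(X, rowvar=False))
    lam = np.sqrt(spec.n_eff) * np.asarray(effects, float)
    L = np.linalg.cholesky(R + 1e-10 * np.eye(len(R)))
    z = R @ lam + L @ rng.standard_normal(len(lam))
    eaf = panel.variants["eaf"].to_numpy()
    se = 1.0 / np.sqrt(spec.n_eff * 2.0 * eaf * (1.0 - eaf))
    df = panel.variants[["chrom", "pos", "rsid", "ea", "oa", "eaf"]].copy()
    df["beta"] = z * se
    df["se"] = se
    df["pvalue"] = pvalue_from_z(z)
    df["n"] = spec.n_gwas
    df["n_case"] = spec.n_case
    df["n_control"] = spec.n_control
    return RegionSumStats(trait_id=trait_id, trait_type="case_control", df=df)


def plan_scenario(spec: ScenarioSpec, panel: ReferencePanel) -> GroundTruth:
    """Choose causal variants and record the ground truth for a scenario."""
    rs = panel.variants["rsid"]
    m = len(rs)
    mid = rs.iloc[m // 2]
    genes = ["G1"]
    datasets = [f"dataset_{d}" for d in range(spec.n_datasets)]
    truth = GroundTruth(theta=0.0)

    if spec.scenario == "null":
        eqtl, gwas, shared = [], [], False
    elif spec.scenario == "shared_causal":
        eqtl, gwas, shared = [mid], [mid], True
    elif spec.scenario == "distinct_causal":
        (i, j, _), = spec.coupled_pairs
        eqtl, gwas, shared = [rs.iloc[i]], [rs.iloc[j]], False
    elif spec.scenario == "masked_secondary":
        # masking signal in the first block, shared signal far away (last block)
        mask = rs.iloc[spec.block_size // 2]
        share = rs.iloc[m - spec.block_size // 2 - 1]
        eqtl, gwas, shared = [share], [mask, share], True
    elif spec.scenario == "horizontal_pleiotropy":
        genes = ["G1", "G2"]
        eqtl, gwas, shared = [mid], [mid], True
    elif spec.scenario == "vertical_causal":
        eqtl, gwas, shared = [mid], [], True
        truth.theta = spec.theta
    else:  # pragma: no cover
        raise AssertionError(spec.scenario)

    for g in genes:
        truth.eqtl_causal[g] = {d: list(eqtl) for d in datasets}
        truth.shared[g] = {d: shared for d in datasets}
    truth.gwas_causal = list(gwas)
    return truth


def gwas_effects_for_truth(spec: ScenarioSpec, panel: ReferencePanel,
                           truth: GroundTruth) -> np.ndarray:
    """Standardized liability effects implied by the scenario ground truth."""
    variants = panel.variants
    if spec.scenario == "vertical_causal":
        gene = next(iter(truth.eqtl_causal))
        causal = next(iter(truth.eqtl_causal[gene].values()))
        b = _standardized_effects(causal, variants, spec.eqtl_h2)
        return truth.theta * b
    if spec.scenario == "masked_secondary":
        a = np.zeros(len(variants))
        mask_rs, share_rs = truth.gwas_causal
        a[variants.index[variants["rsid"] == mask_rs]] = np.sqrt(spec.gwas_h2_masking)
        a[variants.index[variants["rsid"] == share_rs]] = np.sqrt(spec.gwas_h2)
        return a
    return _standardized_effects(truth.gwas_causal, variants, spec.gwas_h2 * max(len(truth.gwas_causal), 1))


@dataclass
class ScenarioData:
    """In-memory fixture set for one scenario region."""

    spec: ScenarioSpec
    panel: ReferencePanel
    eqtl: dict          # (gene_id, dataset_id) -> RegionSumStats
    gwas: RegionSumStats
    annotation: pd.DataFrame
    known_loci: pd.DataFrame
    truth: GroundTruth


def simulate_scenario(spec: ScenarioSpec) -> ScenarioData:
    """Simulate panel, eQTL datasets and GWAS for one scenario region."""
    panel = simulate_panel(spec, np.random.default_rng([spec.seed, 0]))
    truth = plan_scenario(spec, panel)
    eqtl = {}
    for g in truth.eqtl_causal:
        for di, d in enumerate(truth.eqtl_causal[g]):
            rng = np.random.default_rng([spec.seed, 1, di, _stable_tag(g)])
            eqtl[(g, d)] = simulate_eqtl_sumstats(
                panel, spec, truth.eqtl_causal[g][d], rng, dataset_id=d,
                cell_type=f"cell_type_{di}", gene_id=g)
    gwas = simulate_gwas_sumstats(panel, spec, gwas_effects_for_truth(spec, panel, truth),
                                  np.random.default_rng([spec.seed, 2]))
    center = int(panel.variants["pos"].iloc[len(panel.variants) // 2])
    genes = list(truth.eqtl_causal) or ["G1"]
    annotation = pd.DataFrame({
        "gene_id": genes, "chrom": spec.chrom,
        "tss": [center + 1000 * i for i in range(len(genes))],
        "protein_coding": True,
    })
    known = pd.DataFrame(columns=["chrom", "pos", "rsid"])
    return ScenarioData(spec, panel, eqtl, gwas, annotation, known, truth)


def _stable_tag(name: str) -> int:
    """Small deterministic integer from a name, for seed substreams."""
    h = 0
    for ch in name:
        h = (h * 31 + ord(ch)) % 1_000_003
    return h


def make_scenario_fixtures(spec: ScenarioSpec, outdir: str | Path) -> tuple[dict, GroundTruth]:
    """Write a scenario's panel/eQTL/GWAS/annotation/known-locus files.

    Returns the path map and the ground truth (also serialized as a JSON
    sidecar).  Files re-read through sumstats_io reproduce the written
    values.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = simulate_scenario(spec)
    paths: dict[str, str] = {}
    write_panel(data.panel, outdir / "panel")
    paths["panel"] = str(outdir / "panel")
    for (g, d), rss in data.eqtl.items():
        p = outdir / f"eqtl_{g}_{d}.tsv"
        write_sumstats(rss, p)
        paths[f"eqtl:{g}:{d}"] = str(p)
    write_sumstats(data.gwas, outdir / "gwas.tsv")
    paths["gwas"] = str(outdir / "gwas.tsv")
    data.annotation.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    paths["genes"] = str(outdir / "genes.tsv")
    data.known_loci.to_csv(outdir / "known_loci.tsv", sep="\t", index=False)
    paths["known_loci"] = str(outdir / "known_loci.tsv")
    data.truth.to_json(outdir / "ground_truth.json")
    paths["ground_truth"] = str(outdir / "ground_truth.json")
    return paths, data.truth


# --- multi-gene planted study -------------------------------------------------

@dataclass
class StudySpec:
    """A planted multi-gene study: lone shared-causal genes, horizontal-
    pleiotropy gene pairs, and null genes with cis-eQTL signal but no
    disease effect.  Gene units are spaced far apart on one chromosome so
    their LD blocks and ±250 kb regions are independent."""

    n_genes: int = 50
    n_shared: int = 3
    n_pleio_pairs: int = 2
    n_datasets: int = 2
    variants_per_gene: int = 60
    block_size: int = 15
    rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_ref: int = 2000
    n_eqtl: int = 500
    n_case: int = 18_942
    n_control: int = 501_638
    eqtl_h2: float = 0.1
    gwas_h2: float = 5e-4
    unit_spacing: int = 10_000_000
    chrom: str = "1"
    spacing: int = 2_000
    seed: int = 0

    def __post_init__(self):
        if self.n_shared + 2 * self.n_pleio_pairs > self.n_genes:
            raise ValueError("planted genes exceed n_genes")


@dataclass
class StudyData:
    spec: StudySpec
    panel: ReferencePanel
    eqtl: dict                # (gene_id, dataset_id) -> RegionSumStats
    gwas: RegionSumStats
    annotation: pd.DataFrame
    known_loci: pd.DataFrame
    truth: GroundTruth
    planted_prioritized: list
    planted_pleio_pairs: list


def simulate_study(study: StudySpec) -> StudyData:
    """Simulate the full planted study (panel, all eQTL datasets, GWAS)."""
    rng_master = np.random.default_rng([study.seed, 9])
    n_units = study.n_genes - study.n_pleio_pairs  # pair shares one unit
    unit_scn: list[tuple[str, list[str]]] = []
    g = 0
    for _ in range(study.n_shared):
        unit_scn.append(("shared_causal", [f"G{g:03d}"])); g += 1
    for _ in range(study.n_pleio_pairs):
        unit_scn.append(("horizontal_pleiotropy", [f"G{g:03d}", f"G{g+1:03d}"])); g += 2
    while g < study.n_genes:
        unit_scn.append(("eqtl_only", [f"G{g:03d}"])); g += 1

    truth = GroundTruth()
    panels, gwas_parts, eqtl = [], [], {}
    ann_rows = []
    datasets = [f"dataset_{d}" for d in range(study.n_datasets)]
    base = ScenarioSpec(scenario="shared_causal",
                        n_variants=study.variants_per_gene,
                        block_size=study.block_size, rho=study.rho,
                        maf_range=study.maf_range, n_ref=study.n_ref,
                        n_eqtl=study.n_eqtl, n_case=study.n_case,
                        n_control=study.n_control, eqtl_h2=study.eqtl_h2,
                        gwas_h2=study.gwas_h2, chrom=study.chrom,
                        spacing=study.spacing, seed=study.seed)

    for u, (scn, genes) in enumerate(unit_scn):
        start = 1_000_000 + u * study.unit_spacing
        rng = np.random.default_rng([study.seed, 3, u])
        variants = _region_variants(base, rng, prefix=f"rs{u}_", start=start)
        panel = simulate_panel(base, rng, variants=variants)
        panels.append(panel)
        mid_rs = panel.variants["rsid"].iloc[len(variants) // 2]
        causal_e = [mid_rs]
        gwas_effects = np.zeros(len(variants))
        shared = scn in ("shared_causal", "horizontal_pleiotropy")
        if shared:
            truth.gwas_causal.append(mid_rs)
            gwas_effects = _standardized_effects(causal_e, panel.variants, study.gwas_h2)
        for gi, gene in enumerate(genes):
            truth.eqtl_causal[gene] = {d: list(causal_e) for d in datasets}
            truth.shared[gene] = {d: shared for d in datasets}
            center = int(variants["pos"].iloc[len(variants) // 2])
            ann_rows.append({"gene_id": gene, "chrom": study.chrom,
                             "tss": center + 50_000 * gi, "protein_coding": True})
            for di, d in enumerate(datasets):
                erng = np.random.default_rng([study.seed, 4, u, gi, di])
                eqtl[(gene, d)] = simulate_eqtl_sumstats(
                    panel, base, causal_e, erng, dataset_id=d,
                    cell_type=f"cell_type_{di}", gene_id=gene)
        grng = np.random.default_rng([study.seed, 5, u])
        gwas_parts.append(simulate_gwas_sumstats(panel, base, gwas_effects, grng))

    panel = ReferencePanel(
        pd.concat([p.variants for p in panels], ignore_index=True),
        np.hstack([p.dosages for p in panels]))
    gwas = RegionSumStats(trait_id="disease", trait_type="case_control",
                          df=pd.concat([p.df for p in gwas_parts], ignore_index=True))
    annotation = pd.DataFrame(ann_rows)
    known = pd.DataFrame(columns=["chrom", "pos", "rsid"])
    planted = [genes[0] for scn, genes in unit_scn if scn == "shared_causal"]
    pleio = [tuple(genes) for scn, genes in unit_scn if scn == "horizontal_pleiotropy"]
    return StudyData(study, panel, eqtl, gwas, annotation, known, truth,
                     planted, pleio)


def make_study_fixtures(study: StudySpec, outdir: str | Path) -> dict:
    """Write the planted multi-gene study in the pipeline's file formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = simulate_study(study)
    paths: dict[str, str] = {}
    write_panel(data.panel, outdir / "panel")
    paths["panel"] = str(outdir / "panel")
    for (g, d), rss in sorted(data.eqtl.items()):
        p = outdir / f"eqtl_{g}_{d}.tsv"
        write_sumstats(rss, p)
    write_sumstats(data.gwas, outdir / "gwas.tsv")
    paths["gwas"] = str(outdir / "gwas.tsv")
    data.annotation.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    paths["genes"] = str(outdir / "genes.tsv")
    data.known_loci.to_csv(outdir / "known_loci.tsv", sep="\t", index=False)
    paths["known_loci"] = str(outdir / "known_loci.tsv")
    data.truth.to_json(outdir / "ground_truth.json")
    planted = {"prioritized": data.planted_prioritized,
               "pleiotropy_pairs": [list(p) for p in data.planted_pleio_pairs]}
    (outdir / "planted.json").write_text(json.dumps(planted, indent=1, sort_keys=True))
    paths["planted"] = str(outdir / "planted.json")
    return paths


def simulate_quantitative_cohort(n: int, n_variants: int, block_size: int,
                                 rho: float, maf_range: tuple[float, float],
                                 causal_idx: list[int], h2: float,
                                 rng: np.random.Generator,
                                 chrom: str = "1") -> tuple[ReferencePanel, np.ndarray, RegionSumStats]:
    """Individual-level cohort for small-n oracle checks (in-sample LD).

    Returns the cohort itself as a ReferencePanel, the phenotype vector,
    and marginal single-variant summary statistics computed from it.
    """
    spec = ScenarioSpec(scenario="null", n_variants=n_variants,
                        block_size=block_size, rho=rho, maf_range=maf_range,
                        n_ref=n, chrom=chrom, seed=0)
    variants = _region_variants(spec, rng)
    X = _simulate_haplotype_dosages(variants["eaf"].to_numpy(),
                                    _block_sizes(n_variants, block_size),
                                    rho, n, rng)
    effects = np.zeros(n_variants)
    if causal_idx:
        effects[causal_idx] = np.sqrt(h2 / len(causal_idx))
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    y = Xs @ effects + rng.standard_normal(n) * np.sqrt(max(1 - h2, 1e-12))
    beta, se, ok = _marginal_linear_sumstats(X, y)
    freq = X.mean(axis=0) / 2.0
    v = variants.copy()
    v["eaf"] = freq
    panel = ReferencePanel(v, X)
    df = v[["chrom", "pos", "rsid", "ea", "oa", "eaf"]].copy()
    df["beta"] = beta
    df["se"] = se
    df["pvalue"] = pvalue_from_z(np.divide(beta, se, out=np.zeros_like(beta), where=se > 0))
    df["n"] = n
    rss = RegionSumStats(trait_id="trait", trait_type="quantitative",
                         df=df[ok & (freq > 0) & (freq < 1)])
    return panel, y, rss
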