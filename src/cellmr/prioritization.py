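"""Gene-ledger construction: regions, pleiotropy, novelty, prioritization,
and phenome-wide scans of instrumental variants.

Results passing both MR and colocalization thresholds are grouped into
regions by single-linkage chaining of instrumental-variant positions
(pairwise proximity ±250 kb): regions positive for multiple unique genes
are flagged as horizontal pleiotropy, since a shared regulatory variant
can drive several genes' expression.  A gene is called novel when none of
its instrumental variants is correlated (reference r^2 >= 0.2) with, or
close to (±250 kb), any previously reported genome-wide-significant
disease variant, and the gene is not on a supplied prior-study exclusion
list.  Prioritized genes are those that pass, are the lone result in
their region, and are novel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .coloc_engine import ColocResult, pwcoco
from .mr_engine import wald_ratio
from .sumstats_io import RegionSumStats, ReferencePanel, harmonize_pair, ld_corr, pvalue_from_z

logger = logging.getLogger(__name__)


@dataclass
class Hit:
    """One gene x dataset result that passed MR and colocalization."""

    gene_id: str
    dataset_id: str
    cell_type: str
    chrom: str
    positions: list[int]          # instrumental-variant positions
    rsids: list[str]
    beta_mr: float
    mr_p: float
    pph4: float
    coloc_mode: str = "marginal"


@dataclass
class GeneLedgerEntry:
    """Per-gene rollup across datasets."""

    gene_id: str
    hits: list[Hit]
    region_ids: list[str]
    lone_in_region: bool
    novel: bool
    prioritized: bool
    direction_concordant: bool
    n_tested: int = 0
    n_significant: int = 0
    n_colocalized: int = 0


def group_regions(hits: list[Hit], window: int = 250_000) -> list[str]:
    """Single-linkage region assignment over instrumental-variant positions.

    Two hits share a region iff they are connected by a chain of
    instrument positions, each pair at most ``window`` apart on the same
    chromosome.  Returns one region id per hit (a partition); the ids are
    deterministic in (chrom, leftmost position) order.
    """
    parent = list(range(len(hits)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    points = sorted((h.chrom, p, i) for i, h in enumerate(hits) for p in h.positions)
    for (c1, p1, i1), (c2, p2, i2) in zip(points, points[1:]):
        if c1 == c2 and p2 - p1 <= window:
            union(i1, i2)
    roots = {}
    for i in range(len(hits)):
        roots.setdefault(find(i), []).append(i)
    # deterministic ids ordered by chromosome then leftmost instrument
    def key(r):
        members = roots[r]
        return (hits[members[0]].chrom, min(p for m in members for p in hits[m].positions))
    ids = {}
    for k, r in enumerate(sorted(roots, key=key), start=1):
        for m in roots[r]:
            ids[m] = f"region_{k:03d}"
    return [ids[i] for i in range(len(hits))]


def flag_pleiotropy(hits: list[Hit], region_ids: list[str]) -> dict[str, bool]:
    """Region -> horizontal-pleiotropy flag (>= 2 unique passing genes)."""
    genes: dict[str, set] = {}
    for h, r in zip(hits, region_ids):
        genes.setdefault(r, set()).add(h.gene_id)
    return {r: len(g) >= 2 for r, g in genes.items()}


def assess_novelty(hits: list[Hit], known_loci: pd.DataFrame,
                   panel: ReferencePanel, r2_max: float = 0.2,
                   window: int = 250_000,
                   excluded_genes: tuple[str, ...] = ()) -> dict[str, bool]:
    """Gene -> novelty call against previously reported disease variants.

    A gene is novel iff every instrumental variant of every passing result
    is both uncorrelated (reference r^2 < ``r2_max``) with and distant
    (> ``window``) from every known variant; genes named by prior MR
    studies (the exclusion list) are non-novel regardless.  Known variants
    absent from the panel are assessed by distance alone.
    """
    novelty: dict[str, bool] = {}
    known_by_chrom = {c: g for c, g in known_loci.groupby("chrom")} if len(known_loci) else {}
    for h in hits:
        novel = novelty.get(h.gene_id, True)
        if h.gene_id in excluded_genes:
            novel = False
        known = known_by_chrom.get(h.chrom)
        if novel and known is not None:
            for rsid, pos in zip(h.rsids, h.positions):
                near = np.abs(known["pos"].to_numpy() - pos) <= window
                if near.any():
                    novel = False
                    break
                for krs in known["rsid"]:
                    if krs in panel and rsid in panel:
                        r2 = float(ld_corr(panel, [rsid, krs])[0, 1] ** 2)
                        if r2 >= r2_max:
                            novel = False
                            break
                if not novel:
                    break
        novelty[h.gene_id] = novelty.get(h.gene_id, True) and novel
    return novelty


def build_ledger(hits: list[Hit], known_loci: pd.DataFrame,
                 panel: ReferencePanel, config: PipelineConfig | None = None,
                 excluded_genes: tuple[str, ...] = (),
                 tested_counts: dict[str, int] | None = None,
                 significant_counts: dict[str, int] | None = None) -> list[GeneLedgerEntry]:
    """Assemble the per-gene ledger from passing hits.

    ``tested_counts``/``significant_counts`` optionally supply per-gene
    dataset totals (instruments available / MR-significant) for the
    tested -> significant -> colocalized rollup.
    """
    config = config or PipelineConfig()
    region_ids = group_regions(hits, config.region_window)
    pleio = flag_pleiotropy(hits, region_ids)
    novelty = assess_novelty(hits, known_loci, panel, config.novelty_r2,
                             config.region_window, excluded_genes)
    by_gene: dict[str, list[int]] = {}
    for i, h in enumerate(hits):
        by_gene.setdefault(h.gene_id, []).append(i)
    ledger = []
    for gene, idxs in sorted(by_gene.items()):
        ghits = [hits[i] for i in idxs]
        regions = sorted({region_ids[i] for i in idxs})
        lone = all(not pleio[r] for r in regions)
        novel = novelty[gene]
        signs = {np.sign(h.beta_mr) for h in ghits}
        ledger.append(GeneLedgerEntry(
            gene_id=gene, hits=ghits, region_ids=regions,
            lone_in_region=lone, novel=novel,
            prioritized=bool(lone and novel),
            direction_concordant=len(signs) == 1,
            n_tested=(tested_counts or {}).get(gene, len(ghits)),
            n_significant=(significant_counts or {}).get(gene, len(ghits)),
            n_colocalized=len(ghits)))
    return ledger


def prioritize(ledger: list[GeneLedgerEntry]) -> pd.DataFrame:
    """Prioritized-gene table (passing AND lone-in-region AND novel)."""
    rows = []
    for e in ledger:
        rows.append({
            "gene_id": e.gene_id,
            "region_ids": ";".join(e.region_ids),
            "lone_in_region": e.lone_in_region,
            "novel": e.novel,
            "prioritized": e.prioritized,
            "direction_concordant": e.direction_concordant,
            "n_tested": e.n_tested,
            "n_significant": e.n_significant,
            "n_colocalized": e.n_colocalized,
            "datasets": ";".join(h.dataset_id for h in e.hits),
            "cell_types": ";".join(sorted({h.cell_type for h in e.hits})),
        })
    return pd.DataFrame(rows)


@dataclass
class PheWASHit:
    """One instrumental variant x phenotype scan result."""

    rsid: str
    phenotype_id: str
    beta: float
    se: float
    pvalue: float
    mr_beta: float
    coloc: ColocResult | None
    passes: bool


def phewas_scan(eqtl: RegionSumStats, instrument_table: pd.DataFrame,
                phenotypes: list[RegionSumStats], panel: ReferencePanel,
                config: PipelineConfig | None = None) -> list[PheWASHit]:
    """Scan one gene's top instrumental variant across a phenotype library.

    For multi-variant instruments the variant most strongly associated
    with expression (smallest exposure p) is queried.  Per phenotype, the
    variant-level association is looked up after harmonization to the
    exposure's effect allele; if p < the scan threshold, pairwise
    conditional colocalization is run between the eQTL track and the
    phenotype (±coloc window around the queried variant).  A hit passes
    iff both the p-value and PPH4 thresholds are met.  The variant-level
    MR beta is reported per higher genetically predicted expression.
    """
    config = config or PipelineConfig()
    top = instrument_table.sort_values(["pvalue_exp", "pos", "ea"]).iloc[0]
    query_rsid, query_pos = str(top["rsid"]), int(top["pos"])
    exp_single = RegionSumStats(
        trait_id=eqtl.trait_id, trait_type="quantitative",
        df=eqtl.df[eqtl.df["rsid"] == query_rsid],
        dataset_id=eqtl.dataset_id, cell_type=eqtl.cell_type,
        gene_id=eqtl.gene_id)
    hits = []
    for phen in phenotypes:
        m = harmonize_pair(exp_single, phen)
        if not len(m):
            continue
        row = m.iloc[0]
        p = float(row["pvalue_out"]) if np.isfinite(row["pvalue_out"]) else \
            float(pvalue_from_z(row["beta_out"] / row["se_out"]))
        mr_beta, _ = wald_ratio(row["beta_exp"], row["se_exp"],
                                row["beta_out"], row["se_out"])
        if p >= config.phewas_p:
            hits.append(PheWASHit(query_rsid, phen.trait_id, row["beta_out"],
                                  row["se_out"], p, mr_beta, None, False))
            continue
        out = pwcoco(eqtl, phen, panel, config, lead_pos=query_pos)
        hits.append(PheWASHit(query_rsid, phen.trait_id, row["beta_out"],
                              row["se_out"], p, mr_beta, out.best,
                              bool(out.best.pph4 >= config.pph4_threshold)))
    return hits


def phewas_table(hits: list[PheWASHit]) -> pd.DataFrame:
    rows = [{"rsid": h.rsid, "phenotype": h.phenotype_id, "beta": h.beta,
             "se": h.se, "pvalue": h.pvalue, "mr_beta": h.mr_beta,
             "pph4": (h.coloc.pph4 if h.coloc else np.nan),
             "coloc_mode": (h.coloc.mode if h.coloc else ""),
             "passes": h.passes} for h in hits]
    return pd.DataFrame(rows, columns=["rsid", "phenotype", "beta", "se",
                                       "pvalue", "mr_beta", "pph4",
                                       "coloc_mode", "passes"])
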