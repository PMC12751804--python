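"""cis-eQTL instrument selection.

Per gene x dataset: extract genome-wide-significant cis variants (within
±1 Mb of the TSS, outside the MHC, protein-coding genes only), greedily
clump to approximate independence (r^2 < 0.1), harmonize to the outcome,
and screen by single-variant F-statistic (> 10) and Steiger directionality
(variance explained in exposure exceeds that in outcome, P < 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .sumstats_io import RegionSumStats, ReferencePanel, harmonize_pair, ld_corr

logger = logging.getLogger(__name__)


@dataclass
class Instrument:
    """Selected instrumental variants for one gene in one dataset.

    ``table`` has one row per variant with exposure and harmonized outcome
    statistics plus F, steiger_p and steiger_dir.
    """

    gene_id: str
    dataset_id: str
    cell_type: str
    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    @property
    def positions(self) -> list[int]:
        return [int(p) for p in self.table["pos"]]

    @property
    def rsids(self) -> list[str]:
        return list(self.table["rsid"])


def extract_candidates(eqtl: RegionSumStats, gene_row: pd.Series,
                       config: PipelineConfig) -> pd.DataFrame:
    """Genome-wide-significant cis candidates for one gene.

    Keeps variants within ``cis_window`` of the TSS with
    p < ``p_instrument`` that lie outside the MHC window.  Non-protein-
    coding genes are skipped entirely (empty result, logged).
    """
    if not bool(gene_row["protein_coding"]):
        logger.info("gene %s skipped: not protein-coding", gene_row["gene_id"])
        return eqtl.df.iloc[0:0]
    tss = int(gene_row["tss"])
    df = eqtl.df
    m = (df["pos"] >= tss - config.cis_window) & (df["pos"] <= tss + config.cis_window)
    m &= df["pvalue"] < config.p_instrument
    in_mhc = (df["chrom"] == config.mhc_chrom) & \
             (df["pos"] >= config.mhc_start) & (df["pos"] <= config.mhc_end)
    return df[m & ~in_mhc].reset_index(drop=True)


def clump(candidates: pd.DataFrame, panel: ReferencePanel,
          r2_max: float = 0.1) -> list[str]:
    """Greedy p-value clumping under an r^2 ceiling.

    Repeatedly takes the smallest-p remaining variant as an index and
    removes remaining variants with reference r^2 >= ``r2_max`` against
    it.  Ties are broken by position, then alleles, so the output does not
    depend on the input ordering.  Variants absent from the panel are
    dropped (their LD cannot be assessed).  Returns rsids in selection
    order.
    """
    df = candidates.copy()
    present = df["rsid"].map(lambda r: r in panel)
    if (~present).any():
        logger.info("clump: dropped %d candidates absent from panel",
                    int((~present).sum()))
        df = df[present]
    if not len(df):
        return []
    df = df.sort_values(["pvalue", "pos", "ea", "oa"], kind="mergesort")
    rsids = list(df["rsid"])
    R2 = ld_corr(panel, rsids) ** 2
    alive = np.ones(len(rsids), dtype=bool)
    selected: list[str] = []
    for i in range(len(rsids)):
        if not alive[i]:
            continue
        selected.append(rsids[i])
        alive &= R2[i] < r2_max
        alive[i] = False
    return selected


def f_statistic(beta: float, se: float) -> float:
    """Single-variant instrument-strength F = (beta/se)^2."""
    return (beta / se) ** 2


def _n_eff(row) -> float:
    """Effective sample size: 4/(1/ncase+1/nctrl) for binary, else n."""
    nc, nk = row.get("n_case"), row.get("n_control")
    if nc is not None and nk is not None and not (pd.isna(nc) or pd.isna(nk)):
        return 4.0 / (1.0 / nc + 1.0 / nk)
    return float(row["n"])


def steiger(z_exp: float, n_exp: float, z_out: float, n_out: float) -> tuple[bool, float]:
    """Directionality test: does the variant explain more exposure variance?

    Variance explained is approximated as r^2 = z^2/(z^2+n) per trait
    (with the binary-trait effective sample size for the outcome).  The
    p-value compares the Fisher-z transformed |correlations| by a
    two-sample z-test with variances 1/(n-3); direction is true iff
    r^2_exposure > r^2_outcome (ties are conservatively false).
    """
    if n_exp <= 3 or n_out <= 3:
        raise ValueError("Steiger test requires n > 3 for both traits")
    r2_exp = z_exp ** 2 / (z_exp ** 2 + n_exp)
    r2_out = z_out ** 2 / (z_out ** 2 + n_out)
    direction = bool(r2_exp > r2_out)
    fz = np.arctanh(np.sqrt(r2_exp)) - np.arctanh(np.sqrt(r2_out))
    sd = np.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    p = float(2.0 * stats.norm.sf(abs(fz) / sd))
    return direction, p


INSTRUMENT_COLUMNS = [
    "gene_id", "dataset_id", "cell_type", "rsid", "chrom", "pos", "ea", "oa",
    "eaf_exp", "beta_exp", "se_exp", "pvalue_exp", "n_exp",
    "beta_out", "se_out", "pvalue_out",
    "F", "steiger_p", "steiger_dir",
]


def build_instruments(eqtl_datasets: dict, outcome: RegionSumStats,
                      annotation: pd.DataFrame, panel: ReferencePanel,
                      config: PipelineConfig | None = None) -> list[Instrument]:
    """Full instrument selection per gene x dataset.

    ``eqtl_datasets`` maps (gene_id, dataset_id) to an eQTL
    RegionSumStats.  Pipeline: extract -> clump -> harmonize to outcome ->
    F filter -> Steiger filter.  Gene/dataset combinations ending with no
    qualifying variant are omitted.
    """
    config = config or PipelineConfig()
    ann = annotation.set_index("gene_id")
    out: list[Instrument] = []
    for (gene, dataset), eqtl in sorted(eqtl_datasets.items()):
        if gene not in ann.index:
            logger.info("gene %s absent from annotation; skipped", gene)
            continue
        gene_row = pd.Series(ann.loc[gene].to_dict() | {"gene_id": gene})
        cand = extract_candidates(eqtl, gene_row, config)
        if not len(cand):
            continue
        kept = clump(cand, panel, config.clump_r2)
        if not kept:
            continue
        sel = cand[cand["rsid"].isin(kept)]
        exp = RegionSumStats(trait_id=eqtl.trait_id, trait_type=eqtl.trait_type,
                             df=sel, dataset_id=dataset, cell_type=eqtl.cell_type,
                             gene_id=gene)
        pairs = harmonize_pair(exp, outcome)
        if not len(pairs):
            continue
        rows = []
        for r in pairs.itertuples(index=False):
            F = f_statistic(r.beta_exp, r.se_exp)
            if F <= config.f_min:
                continue
            z_exp = r.beta_exp / r.se_exp
            z_out = r.beta_out / r.se_out
            n_out = _n_eff({"n": r.n_out, "n_case": getattr(r, "n_case_out", None),
                            "n_control": getattr(r, "n_control_out", None)})
            direction, p_st = steiger(z_exp, float(r.n_exp), z_out, n_out)
            if not direction or p_st >= config.steiger_alpha:
                continue
            rows.append({
                "gene_id": gene, "dataset_id": dataset, "cell_type": eqtl.cell_type,
                "rsid": r.rsid, "chrom": str(r.chrom), "pos": int(r.pos),
                "ea": r.ea, "oa": r.oa,
                "eaf_exp": r.eaf_exp, "beta_exp": r.beta_exp, "se_exp": r.se_exp,
                "pvalue_exp": r.pvalue_exp, "n_exp": r.n_exp,
                "beta_out": r.beta_out, "se_out": r.se_out, "pvalue_out": r.pvalue_out,
                "F": F, "steiger_p": p_st, "steiger_dir": direction,
            })
        if rows:
            out.append(Instrument(gene_id=gene, dataset_id=dataset,
                                  cell_type=eqtl.cell_type,
                                  table=pd.DataFrame(rows, columns=INSTRUMENT_COLUMNS)))
    return out


def instruments_table(instruments: list[Instrument]) -> pd.DataFrame:
    """Flat instrument table (one row per selected variant)."""
    if not instruments:
        return pd.DataFrame(columns=INSTRUMENT_COLUMNS)
    return pd.concat([i.table for i in instruments], ignore_index=True)
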