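"""Replication: fixed-effect GWAS meta-analysis and replication MR.

The outcome for replication is an inverse-variance fixed-effect
meta-analysis of two non-overlapping GWAS (the effect-size analogue of
the METAL scheme); instruments are re-selected from an independent
replication eQTL source with the same rules as the primary analysis, and
per-gene results are reported with a directional-concordance flag and the
P < 0.1 reporting threshold.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .instruments import build_instruments
from .mr_engine import mr_for_instrument
from .sumstats_io import RegionSumStats, ReferencePanel, harmonize_pair, pvalue_from_z

logger = logging.getLogger(__name__)


def meta_fixed(gwas1: RegionSumStats, gwas2: RegionSumStats) -> RegionSumStats:
    """Inverse-variance fixed-effect meta-analysis of two GWAS.

    Study 2 is harmonized to study 1's effect alleles on shared (chrom,
    pos); w_i = 1/se_i^2, beta = sum(w_i b_i)/sum(w_i), se = 1/sqrt(sum
    w_i).  Variants present in only one study are carried through
    unchanged with ``n_studies`` = 1.
    """
    m = harmonize_pair(gwas1, gwas2)
    shared_pos = set(m["pos"]) if len(m) else set()
    rows = []
    if len(m):
        w1 = 1.0 / m["se_exp"] ** 2
        w2 = 1.0 / m["se_out"] ** 2
        beta = (w1 * m["beta_exp"] + w2 * m["beta_out"]) / (w1 + w2)
        se = 1.0 / np.sqrt(w1 + w2)
        meta = m[["chrom", "pos", "rsid", "ea", "oa"]].copy()
        meta["eaf"] = m["eaf_exp"]
        meta["beta"] = beta
        meta["se"] = se
        meta["pvalue"] = pvalue_from_z(beta / se)
        meta["n"] = m["n_exp"] + m["n_out"]
        for col in ("n_case", "n_control"):
            meta[col] = m[f"{col}_exp"].fillna(0) + m[f"{col}_out"].fillna(0)
        meta["n_studies"] = 2
        rows.append(meta)
    for g in (gwas1, gwas2):
        solo = g.df[~g.df["pos"].isin(shared_pos)].copy()
        if len(solo):
            solo["n_studies"] = 1
            rows.append(solo)
    df = pd.concat(rows, ignore_index=True) if rows else gwas1.df.iloc[0:0]
    return RegionSumStats(trait_id=f"meta({gwas1.trait_id},{gwas2.trait_id})",
                          trait_type="case_control", df=df)


REPLICATION_COLUMNS = ["gene_id", "status", "n_variants", "beta_mr", "se_mr",
                       "pvalue", "p_lt_0.1", "directionally_concordant"]


def replicate(prioritized: pd.DataFrame, replication_eqtl: dict,
              meta_outcome: RegionSumStats, annotation: pd.DataFrame,
              panel: ReferencePanel, primary_betas: dict[str, float],
              config: PipelineConfig | None = None) -> pd.DataFrame:
    """Replication MR for prioritized genes against the meta-analyzed outcome.

    ``replication_eqtl`` maps (gene_id, dataset_id) to the replication
    eQTL source regions; instruments are re-selected with the primary
    rules (P < 5e-8, clumping r^2 < 0.1, F and Steiger screens).  Genes
    with no qualifying cis-eQTL get a "no instrument" row.
    ``primary_betas`` maps gene_id to the primary MR estimate for the
    sign-concordance call.  Replication is read-only on primary results.
    """
    config = config or PipelineConfig()
    genes = list(prioritized["gene_id"])
    eqtl = {k: v for k, v in replication_eqtl.items() if k[0] in genes}
    instruments = build_instruments(eqtl, meta_outcome, annotation, panel, config)
    by_gene = {i.gene_id: i for i in instruments}
    rows = []
    for gene in genes:
        inst = by_gene.get(gene)
        if inst is None:
            rows.append({"gene_id": gene, "status": "no instrument",
                         "n_variants": 0, "beta_mr": np.nan, "se_mr": np.nan,
                         "pvalue": np.nan, "p_lt_0.1": False,
                         "directionally_concordant": pd.NA})
            continue
        res = mr_for_instrument(inst)
        concord = pd.NA
        if gene in primary_betas:
            concord = bool(np.sign(res.beta_mr) == np.sign(primary_betas[gene]))
        rows.append({"gene_id": gene, "status": "ok",
                     "n_variants": res.n_variants, "beta_mr": res.beta_mr,
                     "se_mr": res.se_mr, "pvalue": res.pvalue,
                     "p_lt_0.1": bool(res.pvalue < config.replication_p),
                     "directionally_concordant": concord})
    return pd.DataFrame(rows, columns=REPLICATION_COLUMNS)
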