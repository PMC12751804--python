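"""End-to-end orchestration: instruments -> MR -> PWCoCo -> gene ledger.

PWCoCo is run once per MR-significant gene x dataset at the default PPH4
evidence threshold; the alternative thresholds (0.7, 0.9) are applied to
the same maximum-PPH4 values afterwards, so the passing sets are nested
by construction, matching how alternative cut-offs are explored on a
single set of colocalization results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .coloc_engine import PwcocoOutcome, pwcoco
from .instruments import Instrument, build_instruments, instruments_table
from .mr_engine import MRResult, mr_table, run_mr
from .prioritization import GeneLedgerEntry, Hit, build_ledger, prioritize
from .sumstats_io import RegionSumStats, ReferencePanel

logger = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    instruments: list[Instrument]
    mr_results: list[MRResult]
    coloc: dict                      # (gene, dataset) -> PwcocoOutcome
    ledgers: dict                    # threshold -> list[GeneLedgerEntry]
    summary: dict

    @property
    def instruments_df(self) -> pd.DataFrame:
        return instruments_table(self.instruments)

    @property
    def mr_df(self) -> pd.DataFrame:
        return mr_table(self.mr_results)

    @property
    def coloc_df(self) -> pd.DataFrame:
        rows = []
        for (gene, dataset), out in sorted(self.coloc.items()):
            for r in out.grid:
                rows.append({"gene_id": gene, "dataset_id": dataset,
                             "mode": r.mode,
                             "conditioned_trait1": ",".join(r.conditioned_on["trait1"]),
                             "conditioned_trait2": ",".join(r.conditioned_on["trait2"]),
                             "pph0": r.pph0, "pph1": r.pph1, "pph2": r.pph2,
                             "pph3": r.pph3, "pph4": r.pph4,
                             "n_variants": r.n_variants,
                             "best": r is out.best})
        return pd.DataFrame(rows)

    def ledger_df(self, threshold: float) -> pd.DataFrame:
        return prioritize(self.ledgers[threshold])


def analyze_study(eqtl: dict, gwas: RegionSumStats, annotation: pd.DataFrame,
                  known_loci: pd.DataFrame, panel: ReferencePanel,
                  config: PipelineConfig | None = None,
                  excluded_genes: tuple[str, ...] = ()) -> AnalysisResult:
    """Run the full primary analysis on in-memory study data.

    ``eqtl`` maps (gene_id, dataset_id) to a cis-region RegionSumStats.
    """
    config = config or PipelineConfig()
    instruments = build_instruments(eqtl, gwas, annotation, panel, config)
    mr_results = run_mr(instruments, config.mr_alpha)
    inst_by_key = {(i.gene_id, i.dataset_id): i for i in instruments}
    mr_by_key = {(r.gene_id, r.dataset_id): r for r in mr_results}

    coloc: dict = {}
    for key, res in sorted(mr_by_key.items()):
        if not res.significant:
            continue
        inst = inst_by_key[key]
        lead = int(inst.table.sort_values(["pvalue_exp", "pos"])["pos"].iloc[0])
        try:
            coloc[key] = pwcoco(eqtl[key], gwas, panel, config, lead_pos=lead)
        except ValueError as e:
            logger.warning("pwcoco skipped for %s: %s", key, e)

    tested_counts: dict[str, int] = {}
    sig_counts: dict[str, int] = {}
    for i in instruments:
        tested_counts[i.gene_id] = tested_counts.get(i.gene_id, 0) + 1
    for r in mr_results:
        if r.significant:
            sig_counts[r.gene_id] = sig_counts.get(r.gene_id, 0) + 1

    thresholds = sorted({config.pph4_threshold, *config.pph4_alternates})
    ledgers = {}
    for thr in thresholds:
        hits = []
        for key, out in coloc.items():
            if out.best.pph4 < thr:
                continue
            inst = inst_by_key[key]
            res = mr_by_key[key]
            hits.append(Hit(gene_id=key[0], dataset_id=key[1],
                            cell_type=inst.cell_type,
                            chrom=str(inst.table["chrom"].iloc[0]),
                            positions=inst.positions, rsids=inst.rsids,
                            beta_mr=res.beta_mr, mr_p=res.pvalue,
                            pph4=out.best.pph4, coloc_mode=out.best.mode))
        ledgers[thr] = build_ledger(hits, known_loci, panel, config,
                                    excluded_genes, tested_counts, sig_counts)

    summary = _summarize(instruments, mr_results, coloc, ledgers, config)
    return AnalysisResult(instruments, mr_results, coloc, ledgers, summary)


def _summarize(instruments, mr_results, coloc, ledgers, config) -> dict:
    datasets = sorted({i.dataset_id for i in instruments})
    per_dataset = {}
    for d in datasets:
        tested = [r for r in mr_results if r.dataset_id == d]
        sig = [r for r in tested if r.significant]
        col = [k for k, out in coloc.items()
               if k[1] == d and out.best.pph4 >= config.pph4_threshold]
        per_dataset[d] = {"tested": len(tested), "mr_significant": len(sig),
                          "colocalized": len(col)}
    default = ledgers[config.pph4_threshold]
    uniq = {
        "genes_tested": len({r.gene_id for r in mr_results}),
        "genes_mr_significant": len({r.gene_id for r in mr_results if r.significant}),
        "genes_colocalized": len({e.gene_id for e in default}),
        "genes_prioritized": sorted(e.gene_id for e in default if e.prioritized),
        "pleiotropy_genes": sorted(e.gene_id for e in default if not e.lone_in_region),
    }
    by_threshold = {f"{thr:g}": sorted(e.gene_id for e in entries)
                    for thr, entries in ledgers.items()}
    return {"per_dataset": per_dataset, "unique_genes": uniq,
            "colocalized_by_threshold": by_threshold}


def summary_text(summary: dict) -> str:
    lines = ["Per-dataset results (tested / MR-significant / colocalized):"]
    for d, c in summary["per_dataset"].items():
        lines.append(f"  {d}: {c['tested']} / {c['mr_significant']} / {c['colocalized']}")
    u = summary["unique_genes"]
    lines += [
        "Unique genes:",
        f"  tested: {u['genes_tested']}",
        f"  MR-significant: {u['genes_mr_significant']}",
        f"  colocalized: {u['genes_colocalized']}",
        f"  prioritized (lone-in-region and novel): "
        f"{len(u['genes_prioritized'])} ({', '.join(u['genes_prioritized']) or 'none'})",
        f"  in pleiotropy regions: {len(u['pleiotropy_genes'])}",
        "Colocalizing genes by PPH4 threshold:",
    ]
    for thr, genes in summary["colocalized_by_threshold"].items():
        lines.append(f"  >{thr}: {len(genes)}")
    return "\n".join(lines) + "\n"
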