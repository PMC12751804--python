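"""Summary-statistics and LD-reference-panel I/O, validation and harmonization.

Per-variant GWAS/eQTL association records are carried as pandas DataFrames
with canonical columns ``chrom, pos, rsid, ea, oa, eaf, beta, se, pvalue,
n, n_case, n_control`` wrapped in :class:`RegionSumStats`, which adds trait
metadata (quantitative vs case-control, dataset/cell-type, gene for eQTL
traits).  The LD reference is an individuals x variants additive dosage
matrix (:class:`ReferencePanel`) supporting Pearson-correlation queries and
the panel QC rules (MAF, Hardy-Weinberg, strand-ambiguous exclusion).

Variant matching is positional — (chrom, pos) with allele reconciliation —
because rsids drift across sources.  Positions are 1-based; all window
arithmetic is closed ([pos-w, pos+w]).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = [
    "chrom", "pos", "rsid", "ea", "oa", "eaf", "beta", "se", "pvalue",
    "n", "n_case", "n_control",
]
MANDATORY_COLUMNS = ["chrom", "pos", "rsid", "ea", "oa", "eaf", "beta", "se", "n"]

_VALID_ALLELES = {"A", "C", "G", "T"}
_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def is_palindromic(ea: str, oa: str) -> bool:
    """True for A/T or C/G variant whose strand cannot be resolved."""
    return (ea, oa) in _AMBIGUOUS_PAIRS


def pvalue_from_z(z) -> np.ndarray:
    """Two-sided normal p-value, floored at the smallest positive float."""
    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.maximum(p, np.finfo(float).tiny)


@dataclass(frozen=True)
class VariantAssoc:
    """One variant's association with one trait."""

    chrom: str
    pos: int
    rsid: str
    ea: str
    oa: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: float
    n_case: float | None = None
    n_control: float | None = None

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError(f"{self.rsid}: se must be > 0")
        if not 0 < self.eaf < 1:
            raise ValueError(f"{self.rsid}: eaf must be in (0,1)")
        if self.ea == self.oa:
            raise ValueError(f"{self.rsid}: effect and other allele identical")

    @property
    def z(self) -> float:
        return self.beta / self.se


@dataclass
class RegionSumStats:
    """All association records for one trait in one genomic window."""

    trait_id: str
    trait_type: str  # "quantitative" | "case_control"
    df: pd.DataFrame
    dataset_id: str = ""
    cell_type: str = ""
    gene_id: str | None = None

    def __post_init__(self):
        if self.trait_type not in ("quantitative", "case_control"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        df = self.df.copy()
        for col in CANONICAL_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        extra = [c for c in df.columns if c not in CANONICAL_COLUMNS]
        df = df[CANONICAL_COLUMNS + extra]
        if len(df):
            chroms = df["chrom"].astype(str).unique()
            if len(chroms) > 1:
                raise ValueError(f"records span multiple chromosomes: {chroms}")
            df["chrom"] = df["chrom"].astype(str)
            df = df.sort_values(["pos", "ea", "oa"], kind="mergesort")
            dup = df.duplicated(subset=["pos", "ea", "oa"])
            if dup.any():
                logger.warning("%s: dropping %d duplicate (pos, ea, oa) records",
                               self.trait_id, int(dup.sum()))
                df = df[~dup]
            df = df.reset_index(drop=True)
        self.df = df

    @property
    def chrom(self) -> str:
        return str(self.df["chrom"].iloc[0])

    @property
    def records(self) -> list[VariantAssoc]:
        out = []
        for r in self.df.itertuples(index=False):
            out.append(VariantAssoc(
                chrom=str(r.chrom), pos=int(r.pos), rsid=str(r.rsid),
                ea=str(r.ea), oa=str(r.oa), eaf=float(r.eaf),
                beta=float(r.beta), se=float(r.se), pvalue=float(r.pvalue),
                n=float(r.n),
                n_case=None if pd.isna(r.n_case) else float(r.n_case),
                n_control=None if pd.isna(r.n_control) else float(r.n_control)))
        return out

    def window(self, center: int, half_width: int) -> "RegionSumStats":
        """Records with pos in the closed interval [center-w, center+w]."""
        m = (self.df["pos"] >= center - half_width) & (self.df["pos"] <= center + half_width)
        return replace(self, df=self.df[m].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.df)


def _coerce_sumstats(df: pd.DataFrame, trait_id: str) -> pd.DataFrame:
    """Validate canonical-column rows; drop (and count) rows breaking invariants."""
    n_in = len(df)
    for col in ("pos", "eaf", "beta", "se", "pvalue", "n", "n_case", "n_control"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    df["ea"] = df["ea"].astype(str).str.upper()
    df["oa"] = df["oa"].astype(str).str.upper()
    ok = (
        df["pos"].notna() & df["eaf"].notna() & df["beta"].notna()
        & df["se"].notna() & df["n"].notna()
        & (df["se"] > 0) & (df["eaf"] > 0) & (df["eaf"] < 1)
        & (df["ea"] != df["oa"])
        & df["ea"].isin(_VALID_ALLELES) & df["oa"].isin(_VALID_ALLELES)
    )
    df = df[ok].copy()
    if len(df) < n_in:
        logger.warning("%s: dropped %d/%d rows failing validation",
                       trait_id, n_in - len(df), n_in)
    if df["pvalue"].isna().any():
        miss = df["pvalue"].isna()
        df.loc[miss, "pvalue"] = pvalue_from_z(df.loc[miss, "beta"] / df.loc[miss, "se"])
    # p vs |beta/se| consistency: warn beyond 10% relative on -log10 scale
    with np.errstate(divide="ignore"):
        lp_obs = -np.log10(df["pvalue"].to_numpy(float))
        lp_exp = -np.log10(pvalue_from_z(df["beta"].to_numpy(float) / df["se"].to_numpy(float)))
    bad = np.abs(lp_obs - lp_exp) > 0.1 * np.maximum(lp_exp, 1.0)
    if bad.any():
        logger.warning("%s: %d rows with p-value inconsistent with beta/se",
                       trait_id, int(bad.sum()))
    df["pos"] = df["pos"].astype(int)
    return df


def read_sumstats(path: str | Path, dialect: dict[str, str] | None = None,
                  trait_id: str | None = None, trait_type: str = "quantitative",
                  dataset_id: str = "", cell_type: str = "",
                  gene_id: str | None = None) -> RegionSumStats:
    """Read tab-delimited summary statistics into a validated region.

    ``dialect`` maps foreign header names onto the canonical ones
    (e.g. ``{"CHR": "chrom", "BP": "pos"}``).  Rows failing type coercion
    or record invariants (se <= 0, eaf outside (0,1), non-ACGT alleles)
    are dropped with a logged count; a missing pvalue column is recomputed
    from beta/se under the two-sided normal approximation.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if dialect:
        df = df.rename(columns=dialect)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    tid = trait_id or path.stem
    df = _coerce_sumstats(df, tid)
    if not len(df):
        raise ValueError(f"{path}: no valid rows after validation")
    return RegionSumStats(trait_id=tid, trait_type=trait_type, df=df,
                          dataset_id=dataset_id, cell_type=cell_type,
                          gene_id=gene_id)


def write_sumstats(region: RegionSumStats, path: str | Path) -> None:
    """Write canonical tab-delimited summary statistics (lossless round-trip)."""
    df = region.df.copy()
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")


def harmonize_pair(exposure: RegionSumStats, outcome: RegionSumStats) -> pd.DataFrame:
    """Align outcome records to the exposure's effect alleles on shared positions.

    Matching is on (chrom, pos).  If the outcome's allele pair is swapped
    relative to the exposure, the outcome beta sign is flipped and its eaf
    replaced by 1-eaf.  Strand-ambiguous (A/T, C/G) variants and allele
    sets that cannot be reconciled are dropped with a logged count.
    Harmonizing an already-harmonized pair is a no-op on the result.

    Returns a DataFrame with the exposure's chrom/pos/rsid/ea/oa and
    suffixed columns ``*_exp`` / ``*_out``; empty if no variant is shared.
    """
    if len(exposure) and len(outcome) and exposure.chrom != outcome.chrom:
        raise ValueError("exposure and outcome are on different chromosomes")
    m = exposure.df.merge(outcome.df, on=["chrom", "pos"], suffixes=("_exp", "_out"))
    if not len(m):
        return m
    n_in = len(m)
    pal = (m["ea_exp"] + m["oa_exp"]).isin({"AT", "TA", "CG", "GC"}) | \
          (m["ea_out"] + m["oa_out"]).isin({"AT", "TA", "CG", "GC"})
    same = (m["ea_out"] == m["ea_exp"]) & (m["oa_out"] == m["oa_exp"])
    swapped = (m["ea_out"] == m["oa_exp"]) & (m["oa_out"] == m["ea_exp"])
    keep = ~pal & (same | swapped)
    m = m[keep].copy()
    dropped = n_in - len(m)
    if dropped:
        logger.info("harmonize: dropped %d variants (palindromic or irreconcilable alleles)",
                    dropped)
    flip = (m["ea_out"] == m["oa_exp"]).to_numpy()
    m.loc[flip, "beta_out"] = -m.loc[flip, "beta_out"]
    m.loc[flip, "eaf_out"] = 1.0 - m.loc[flip, "eaf_out"]
    m.loc[flip, ["ea_out", "oa_out"]] = m.loc[flip, ["oa_out", "ea_out"]].to_numpy()
    m = m.rename(columns={"ea_exp": "ea", "oa_exp": "oa", "rsid_exp": "rsid"})
    m = m.drop(columns=["ea_out", "oa_out", "rsid_out"])
    return m.reset_index(drop=True)


@dataclass
class ReferencePanel:
    """Variant-indexed additive genotype dosages for LD queries.

    ``variants`` carries chrom/pos/rsid/ea/oa/eaf in column order matching
    the ``dosages`` matrix (individuals x variants, values in [0, 2]
    counting copies of ``ea``).
    """

    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self):
        self.variants = self.variants.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("dosage column count does not match variant index")
        if "eaf" not in self.variants.columns:
            self.variants["eaf"] = self.dosages.mean(axis=0) / 2.0
        self.variants["chrom"] = self.variants["chrom"].astype(str)
        self._col = {r: i for i, r in enumerate(self.variants["rsid"])}

    @property
    def n_ref(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._col

    def columns(self, rsids: Sequence[str]) -> np.ndarray:
        try:
            idx = [self._col[r] for r in rsids]
        except KeyError as e:
            raise KeyError(f"variant {e.args[0]} not in reference panel") from None
        return self.dosages[:, idx]

    def subset(self, mask: np.ndarray) -> "ReferencePanel":
        return ReferencePanel(self.variants.loc[mask].reset_index(drop=True),
                              self.dosages[:, np.asarray(mask)])


def hwe_chisq_p(dosages_col: np.ndarray) -> float:
    """Hardy-Weinberg 1-df chi-square p on hard-called genotypes.

    Dosages are rounded to the nearest integer genotype; the test compares
    observed genotype counts with Hardy-Weinberg expectations at the
    empirical allele frequency.
    """
    g = np.clip(np.rint(dosages_col), 0, 2).astype(int)
    n = g.size
    counts = np.bincount(g, minlength=3).astype(float)
    p = (2 * counts[2] + counts[1]) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p ** 2])
    chi2 = float(np.sum((counts - exp) ** 2 / exp))
    return float(stats.chi2.sf(chi2, df=1))


def panel_qc(panel: ReferencePanel, maf_min: float = 0.01,
             hwe_p_min: float = 1e-6) -> ReferencePanel:
    """Apply reference-panel QC: MAF, Hardy-Weinberg and strand-ambiguity.

    Variants with MAF < ``maf_min``, HWE p < ``hwe_p_min`` (1-df chi-square
    on hard calls), or A/T / C/G ambiguous alleles are removed.  Idempotent.
    """
    freq = panel.dosages.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    hwe = np.array([hwe_chisq_p(panel.dosages[:, j]) for j in range(panel.n_variants)])
    amb = np.array([is_palindromic(ea, oa) for ea, oa in
                    zip(panel.variants["ea"], panel.variants["oa"])])
    keep = (maf >= maf_min) & (hwe >= hwe_p_min) & ~amb
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("panel_qc: removed %d/%d variants", n_drop, panel.n_variants)
    if not keep.any():
        raise ValueError("panel QC removed all variants")
    return panel.subset(keep)


def ld_corr(panel: ReferencePanel, rsids: Sequence[str],
            effect_alleles: Sequence[str] | None = None) -> np.ndarray:
    """Pearson dosage correlation among the named variants.

    If ``effect_alleles`` is given, each variant's dosage is oriented to
    count that allele (flipping 2-d where it is the panel's other allele),
    so flipping one variant's effect allele negates its row and column.
    Zero-variance columns are an error: LD is undefined for them.
    """
    X = panel.columns(rsids).copy()
    if effect_alleles is not None:
        sub = panel.variants.set_index("rsid").loc[list(rsids)]
        for j, (r, ea) in enumerate(zip(rsids, effect_alleles)):
            if ea == sub["oa"].iloc[j]:
                X[:, j] = 2.0 - X[:, j]
            elif ea != sub["ea"].iloc[j]:
                raise ValueError(f"{r}: allele {ea} not in panel record")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [rsids[j] for j in np.where(sd == 0)[0]]
        raise ValueError(f"zero-variance dosage column(s): {bad}")
    R = np.corrcoef(X, rowvar=False)
    R = np.atleast_2d(R)
    np.fill_diagonal(R, 1.0)
    return R


# --- panel / annotation / known-locus file formats (tab-delimited) -----------

def write_panel(panel: ReferencePanel, prefix: str | Path) -> None:
    """Write ``<prefix>.variants.tsv`` and ``<prefix>.dosages.tsv``.

    The dosage matrix is individuals x variants with rsid header; the
    sidecar variant index carries chrom/pos/alleles/eaf in matching order.
    """
    prefix = Path(prefix)
    panel.variants.to_csv(f"{prefix}.variants.tsv", sep="\t", index=False,
                          float_format="%.10g")
    pd.DataFrame(panel.dosages, columns=panel.variants["rsid"]).to_csv(
        f"{prefix}.dosages.tsv", sep="\t", index=False, float_format="%.6g")


def read_panel(prefix: str | Path) -> ReferencePanel:
    prefix = Path(prefix)
    variants = pd.read_csv(f"{prefix}.variants.tsv", sep="\t", dtype={"chrom": str})
    dos = pd.read_csv(f"{prefix}.dosages.tsv", sep="\t")
    if list(dos.columns) != list(variants["rsid"]):
        raise ValueError("dosage columns do not match variant index order")
    return ReferencePanel(variants, dos.to_numpy(float))


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Gene annotation table: gene_id, chrom, tss, protein_coding."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    need = {"gene_id", "chrom", "tss", "protein_coding"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation column(s) {sorted(missing)}")
    df["tss"] = df["tss"].astype(int)
    df["protein_coding"] = df["protein_coding"].astype(bool)
    return df


def read_known_loci(path: str | Path) -> pd.DataFrame:
    """Previously reported genome-wide-significant variants: chrom, pos, rsid."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"chrom", "pos", "rsid"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing known-locus column(s) {sorted(missing)}")
    df["pos"] = df["pos"].astype(int)
    return df
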