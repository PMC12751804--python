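"""Pipeline-wide thresholds and priors.

All defaults reproduce the analysis settings of the immune-cell eQTL
MR + conditional-colocalization workflow: genome-wide instrument
significance, r^2 < 0.1 clumping, the MHC exclusion window, PWCoCo
default priors and the PPH4 evidence thresholds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


@dataclass
class PipelineConfig:
    """Thresholds shared across pipeline stages.

    Attributes
    ----------
    p_instrument : instrument extraction p-value ceiling (genome-wide).
    clump_r2 : LD ceiling for clumping; variants with r^2 >= this against a
        retained index variant are removed.
    cis_window : half-width (bp) of the cis window around a gene's TSS.
    mhc_chrom, mhc_start, mhc_end : MHC exclusion window (GRCh37 chr6
        coordinates); instrumental variants inside it are discarded.
    coloc_window : half-width (bp) of the colocalization window around an
        instrumental variant.
    pph4_threshold : posterior probability of a shared causal variant
        required to declare colocalization; 0.7 and 0.9 are reported as
        sensitivity thresholds.
    region_window : pairwise proximity (bp) that places two instrumented
        genes in the same region for pleiotropy grouping and novelty.
    novelty_r2 : LD ceiling against known disease loci for a novelty call.
    phewas_p : display/coloc-trigger threshold for phenome-wide scans.
    p1, p2, p12 : per-variant prior probabilities of association with
        trait 1 only, trait 2 only, and both.
    f_min : minimum single-variant F-statistic for instrument strength.
    steiger_alpha : directionality-test significance level.
    cojo_p : conditional-selection p-value cutoff for stepwise signal
        selection (matches instrument-level stringency).
    collinearity_r2 : reference r^2 above which a candidate is considered
        collinear with the conditional model and skipped.
    max_signals : cap on selected signals per trait per region.
    coloc_w_quant, coloc_w_cc : prior effect-size variances (W) for the
        approximate Bayes factor, quantitative and case-control traits.
    """

    p_instrument: float = 5e-8
    clump_r2: float = 0.1
    cis_window: int = 1_000_000
    mhc_chrom: str = "6"
    mhc_start: int = 25_726_063
    mhc_end: int = 33_400_644
    coloc_window: int = 500_000
    pph4_threshold: float = 0.8
    pph4_alternates: tuple[float, ...] = (0.7, 0.9)
    region_window: int = 250_000
    novelty_r2: float = 0.2
    phewas_p: float = 5e-5
    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 5e-5
    f_min: float = 10.0
    steiger_alpha: float = 0.05
    cojo_p: float = 5e-8
    collinearity_r2: float = 0.9
    max_signals: int = 10
    coloc_w_quant: float = 0.15 ** 2
    coloc_w_cc: float = 0.2 ** 2
    mr_alpha: float = 0.05
    replication_p: float = 0.1

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool) and v <= 0:
                raise ValueError(f"config threshold {f.name} must be positive, got {v}")

    def in_mhc(self, chrom: str, pos: int) -> bool:
        return str(chrom) == self.mhc_chrom and self.mhc_start <= pos <= self.mhc_end

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "pph4_alternates" in d:
            d = {**d, "pph4_alternates": tuple(d["pph4_alternates"])}
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pph4_alternates"] = list(d["pph4_alternates"])
        return d
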