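"""Two-sample Mendelian randomization estimators and heterogeneity.

Single-variant instruments use the Wald ratio (outcome effect over
exposure effect, first-order delta-method SE).  Multi-variant instruments
are combined by fixed-effect inverse-variance weighting of the
variant-level ratios, with Cochran's Q and I^2 reported as heterogeneity
diagnostics (heterogeneous variants are not removed).  Significance is
Bonferroni-corrected for the number of unique genes tested within each
dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import Instrument
from .sumstats_io import pvalue_from_z


@dataclass
class MRResult:
    """MR estimate for one gene in one dataset.

    ``beta_mr`` is the log-odds of the outcome per unit of genetically
    predicted expression.  Q/Q_p/I2 are None for single-variant (Wald)
    instruments.
    """

    gene_id: str
    dataset_id: str
    cell_type: str
    method: str               # "wald" | "ivw_fe"
    beta_mr: float
    se_mr: float
    pvalue: float
    n_variants: int
    Q: float | None = None
    Q_p: float | None = None
    I2: float | None = None
    significant: bool = False
    ci_low: float = float("nan")
    ci_high: float = float("nan")


def wald_ratio(b_exp: float, se_exp: float, b_out: float, se_out: float,
               first_order: bool = False) -> tuple[float, float]:
    """Single-variant causal estimate beta = b_out/b_exp with delta-method SE.

    The default SE propagates both outcome and exposure uncertainty,
    se = sqrt(se_out^2/b_exp^2 + b_out^2 se_exp^2 / b_exp^4): with a very
    large outcome GWAS the outcome z-statistic can exceed the instrument's,
    and the common first-order form se_out/|b_exp| then badly understates
    the ratio variance (interval coverage collapses).  ``first_order=True``
    gives that simpler form for comparison with tools that use it.
    """
    if b_exp == 0:
        raise ValueError("Wald ratio undefined for zero exposure effect")
    beta = b_out / b_exp
    if first_order:
        return beta, se_out / abs(b_exp)
    var = se_out ** 2 / b_exp ** 2 + b_out ** 2 * se_exp ** 2 / b_exp ** 4
    return beta, float(np.sqrt(var))


def fieller_ci(b_exp: float, se_exp: float, b_out: float, se_out: float,
               alpha: float = 0.05) -> tuple[float, float]:
    """Fieller confidence interval for the ratio b_out/b_exp.

    The set {theta : |b_out - theta*b_exp| <= z * sqrt(se_out^2 +
    theta^2 se_exp^2)} — exact for a ratio of independent normals, and a
    bounded interval whenever the instrument F-statistic exceeds z^2.
    Delta-method intervals centred on the ratio undercover when the
    exposure z-statistic is not much larger than the outcome's; Fieller
    does not.  Returns (nan, nan) if the instrument is too weak for a
    bounded interval.
    """
    c2 = stats.norm.ppf(1 - alpha / 2) ** 2
    a = b_exp ** 2 - c2 * se_exp ** 2
    b = -2.0 * b_out * b_exp
    c = b_out ** 2 - c2 * se_out ** 2
    if a <= 0:
        return float("nan"), float("nan")
    disc = b ** 2 - 4 * a * c
    if disc < 0:
        return float("nan"), float("nan")
    root = np.sqrt(disc)
    return float((-b - root) / (2 * a)), float((-b + root) / (2 * a))


def ivw_fixed(betas, ses) -> tuple[float, float, float]:
    """Fixed-effect inverse-variance-weighted combination of ratios."""
    betas = np.asarray(betas, float)
    ses = np.asarray(ses, float)
    if betas.size == 0:
        raise ValueError("ivw_fixed requires at least one ratio")
    w = 1.0 / ses ** 2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    p = float(pvalue_from_z(beta / se))
    return beta, se, p


def cochran_q(betas, ses) -> tuple[float, float, float]:
    """Cochran's Q, its chi-square p (k-1 df) and I^2 = max(0, (Q-(k-1))/Q)."""
    betas = np.asarray(betas, float)
    ses = np.asarray(ses, float)
    k = betas.size
    if k < 2:
        raise ValueError("heterogeneity needs >= 2 ratios")
    w = 1.0 / ses ** 2
    beta_ivw = np.sum(w * betas) / np.sum(w)
    Q = float(np.sum(w * (betas - beta_ivw) ** 2))
    Q_p = float(stats.chi2.sf(Q, df=k - 1))
    I2 = float(max(0.0, (Q - (k - 1)) / Q)) if Q > 0 else 0.0
    return Q, Q_p, I2


def mr_for_instrument(instr: Instrument) -> MRResult:
    """Wald ratio (k=1) or fixed-effect IVW (k>1) for one instrument."""
    t = instr.table
    ratios = [wald_ratio(b_exp, se_exp, b_out, se_out)
              for b_exp, se_exp, b_out, se_out
              in zip(t["beta_exp"], t["se_exp"], t["beta_out"], t["se_out"])]
    betas = [r[0] for r in ratios]
    ses = [r[1] for r in ratios]
    k = len(ratios)
    if k == 1:
        beta, se = betas[0], ses[0]
        p = float(pvalue_from_z(beta / se))
        lo, hi = fieller_ci(t["beta_exp"].iloc[0], t["se_exp"].iloc[0],
                            t["beta_out"].iloc[0], t["se_out"].iloc[0])
        return MRResult(instr.gene_id, instr.dataset_id, instr.cell_type,
                        "wald", beta, se, p, 1, ci_low=lo, ci_high=hi)
    beta, se, p = ivw_fixed(betas, ses)
    Q, Q_p, I2 = cochran_q(betas, ses)
    z = stats.norm.ppf(0.975)
    return MRResult(instr.gene_id, instr.dataset_id, instr.cell_type,
                    "ivw_fe", beta, se, p, k, Q, Q_p, I2,
                    ci_low=beta - z * se, ci_high=beta + z * se)


def bonferroni_flag(results: list[MRResult], alpha: float = 0.05) -> list[MRResult]:
    """Set ``significant`` per dataset: p < alpha / (unique genes tested there)."""
    genes_per_dataset: dict[str, set] = {}
    for r in results:
        genes_per_dataset.setdefault(r.dataset_id, set()).add(r.gene_id)
    for r in results:
        thr = alpha / len(genes_per_dataset[r.dataset_id])
        r.significant = bool(r.pvalue < thr)
    return results


def run_mr(instruments: list[Instrument], alpha: float = 0.05) -> list[MRResult]:
    """MR for every instrument, then per-dataset Bonferroni flags."""
    return bonferroni_flag([mr_for_instrument(i) for i in instruments], alpha)


MR_COLUMNS = ["gene_id", "dataset_id", "cell_type", "method", "beta_mr",
              "se_mr", "pvalue", "n_variants", "Q", "Q_p", "I2", "significant"]


def mr_table(results: list[MRResult]) -> pd.DataFrame:
    """Flat MR results table (one row per gene x dataset)."""
    rows = [{c: getattr(r, c if c != "beta_mr" else "beta_mr") for c in MR_COLUMNS}
            for r in results]
    return pd.DataFrame(rows, columns=MR_COLUMNS)
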