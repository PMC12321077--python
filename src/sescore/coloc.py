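"""Approximate-Bayes-factor colocalization of eQTL and GWAS signals.

A single-instrument MR estimate is only credible if the eQTL and the outcome
association at the locus are driven by the same causal variant. For each
(gene, phenotype) locus the per-SNP Wakefield approximate Bayes factor

    log ABF = 0.5 * log(V / (V + W)) + 0.5 * z^2 * W / (V + W)

(V = se^2, W = prior effect variance, z = beta/se) is computed for both
traits, and the five causal configurations are weighed:

    H0  no association with either trait
    H1  association with trait 1 only
    H2  association with trait 2 only
    H3  both traits, distinct causal variants
    H4  both traits, one shared causal variant

with per-SNP priors p1, p2 (single-trait causal) and p12 (shared causal).
All sums run in log space, so loci with |z| up to 60 and beyond stay finite.
A locus passes the gate when PP(H4) >= 0.6 and PP(H3) < 0.1 -- the relaxed
H4 bound admits under-powered outcome traits while the H3 bound still
rejects loci with evidence of distinct variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .config import RunConfig
from .io import harmonize_frames

logger = logging.getLogger("sescore.coloc")

HYPOTHESES = ("pp0", "pp1", "pp2", "pp3", "pp4")


@dataclass(frozen=True)
class ColocResult:
    """Posterior probabilities of the five causal configurations at a locus."""

    pp: np.ndarray  # shape (5,): PP(H0) .. PP(H4)
    n_snps: int
    passed: bool


def log_abf(beta: float, se: float, prior_sd: float) -> float:
    """Wakefield log approximate Bayes factor for one SNP-trait association."""
    if se <= 0:
        raise ValueError("se must be positive")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    v = se**2
    w = prior_sd**2
    z = beta / se
    return 0.5 * np.log(v / (v + w)) + 0.5 * z**2 * w / (v + w)


def coloc_abf(
    beta1,
    se1,
    beta2,
    se2,
    priors: tuple[float, float, float] = (1e-4, 1e-4, 1e-5),
    prior_sd: tuple[float, float] = (0.15, 0.15),
    config: RunConfig | None = None,
) -> ColocResult:
    """Colocalization over an allele-aligned locus.

    Parameters
    ----------
    beta1, se1, beta2, se2
        Aligned per-SNP effect estimates and SEs for the two traits (same SNP
        order, same effect allele).
    priors
        ``(p1, p2, p12)`` per-SNP prior probabilities.
    prior_sd
        Effect-size prior SDs for trait 1 and trait 2.

    Unnormalized hypothesis weights: H0 = 1, H1 = p1 * sum_i BF1_i,
    H2 = p2 * sum_j BF2_j, H3 = p1*p2 * sum_{i != j} BF1_i * BF2_j,
    H4 = p12 * sum_i BF1_i * BF2_i; all evaluated in log space. A single-SNP
    locus has exactly zero H3 weight (no distinct-variant configuration
    exists).
    """
    beta1 = np.asarray(beta1, dtype=float)
    se1 = np.asarray(se1, dtype=float)
    beta2 = np.asarray(beta2, dtype=float)
    se2 = np.asarray(se2, dtype=float)
    m = beta1.size
    if m == 0:
        raise ValueError("locus must contain at least one SNP")
    if not (se1.size == beta2.size == se2.size == m):
        raise ValueError("trait vectors must share one SNP ordering")
    if np.any(se1 <= 0) or np.any(se2 <= 0):
        raise ValueError("all SEs must be positive")
    p1, p2, p12 = priors
    l1 = log_abf_vec(beta1, se1, prior_sd[0])
    l2 = log_abf_vec(beta2, se2, prior_sd[1])

    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    # H3 exactly: sum over ordered pairs i != j of BF1_i * BF2_j
    if m == 1:
        logw3 = -np.inf
    else:
        grid = l1[:, None] + l2[None, :]
        np.fill_diagonal(grid, -np.inf)
        logw3 = np.log(p1) + np.log(p2) + logsumexp(grid)
    logw = np.array(
        [
            0.0,
            np.log(p1) + s1,
            np.log(p2) + s2,
            logw3,
            np.log(p12) + s12,
        ]
    )
    pp = np.exp(logw - logsumexp(logw))
    pp /= pp.sum()
    cfg = config or RunConfig()
    res = ColocResult(pp=pp, n_snps=m, passed=False)
    return ColocResult(pp=pp, n_snps=m, passed=passes_coloc(res, cfg))


def log_abf_vec(beta: np.ndarray, se: np.ndarray, prior_sd: float) -> np.ndarray:
    """Vectorized Wakefield log ABF."""
    v = se**2
    w = prior_sd**2
    z = beta / se
    return 0.5 * np.log(v / (v + w)) + 0.5 * z**2 * w / (v + w)


def passes_coloc(result: ColocResult, config: RunConfig | None = None) -> bool:
    """Gate: PP(H4) >= h4_min (default 0.6) and PP(H3) < h3_max (default 0.1)."""
    cfg = config or RunConfig()
    return bool(result.pp[4] >= cfg.h4_min and result.pp[3] < cfg.h3_max)


def route_dataset(phenotype_id: str, side_effect_map: pd.DataFrame) -> str:
    """Choose the eQTL dataset class for a phenotype: ``"brain"`` or ``"blood"``.

    The routing flag is data (the ``brain_relevant`` column of the map), not
    an inference made here.
    """
    hits = side_effect_map.loc[
        side_effect_map["phenotype_id"] == phenotype_id, "brain_relevant"
    ]
    if hits.empty:
        raise KeyError(f"phenotype '{phenotype_id}' not present in side-effect map")
    return "brain" if bool(hits.iloc[0]) else "blood"


def build_locus_pair(
    eqtl_locus: pd.DataFrame,
    gwas: pd.DataFrame,
    gene_interval: tuple[str, int, int] | None = None,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Align eQTL and GWAS records over a cis locus for colocalization.

    Merges on SNP id, harmonizes the GWAS effect allele to the eQTL one
    (dropping palindromic and mismatched variants), and optionally restricts
    to the cis window around ``gene_interval``. Returns a frame with columns
    ``snp, beta1, se1, beta2, se2``.
    """
    sub = eqtl_locus
    if gene_interval is not None:
        chrom, start, end = gene_interval
        sub = sub[
            (sub["chr"].astype(str) == str(chrom))
            & (sub["pos"] >= start - window)
            & (sub["pos"] <= end + window)
        ]
    merged = harmonize_frames(sub, gwas, suffixes=("_x", "_y"))
    out = pd.DataFrame(
        {
            "snp": merged["snp"],
            "beta1": merged["beta_x"],
            "se1": merged["se_x"],
            "beta2": merged["beta_y"],
            "se2": merged["se_y"],
        }
    )
    out.attrs["n_rejected"] = merged.attrs.get("n_rejected", 0)
    return out


def coloc_gene_phenotype(
    eqtl: pd.DataFrame,
    gwas: pd.DataFrame,
    gene: str,
    tissue: str,
    gene_interval: tuple[str, int, int],
    config: RunConfig | None = None,
    binary_outcome: bool = False,
) -> ColocResult | None:
    """Run colocalization for one (gene, tissue, phenotype) locus.

    Returns None when no SNP survives alignment.
    """
    cfg = config or RunConfig()
    locus_eqtl = eqtl[(eqtl["gene"] == gene) & (eqtl["tissue"] == tissue)]
    pair = build_locus_pair(locus_eqtl, gwas, gene_interval, cfg.cis_window_bp)
    if pair.empty:
        logger.info("coloc: empty locus for gene %s tissue %s", gene, tissue)
        return None
    sd2 = cfg.prior_sd_binary if binary_outcome else cfg.prior_sd_quant
    return coloc_abf(
        pair["beta1"].to_numpy(),
        pair["se1"].to_numpy(),
        pair["beta2"].to_numpy(),
        pair["se2"].to_numpy(),
        priors=(cfg.coloc_p1, cfg.coloc_p2, cfg.coloc_p12),
        prior_sd=(cfg.prior_sd_quant, sd2),
        config=cfg,
    )
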