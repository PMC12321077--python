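"""Instrument selection and single-instrument Mendelian randomization.

Each receptor gene gets at most one cis-eQTL instrument per tissue: the
smallest-p SNP within +/- 1 Mb of the gene interval. Instrument strength is
the first-stage F statistic (beta/se)^2; instruments at or below F = 22 are
flagged weak and excluded, guarding against weak-instrument bias.

The phenome-wide screen pairs every retained instrument with every mapped
side-effect phenotype, harmonizes alleles, and computes the Wald ratio

    beta_IV = beta_ZY / beta_ZX

with the first-order delta-method SE |se_ZY / beta_ZX|. p-values across the
whole screen are adjusted with Benjamini-Hochberg FDR, and redundant
phenotype proxies are collapsed to one result per (side-effect, receptor)
pair.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import RunConfig
from .io import harmonize_frames

logger = logging.getLogger("sescore.mr")

#: Columns of the MR screen result table.
MR_COLUMNS = [
    "gene",
    "tissue",
    "snp",
    "side_effect",
    "phenotype_id",
    "beta_zx",
    "se_zx",
    "f_stat",
    "beta_zy",
    "se_zy",
    "beta_iv",
    "se_iv",
    "pval",
    "qval",
]


def f_statistic(beta_zx: float, se_zx: float) -> float:
    """First-stage instrument F statistic from summary stats: (beta/se)^2."""
    if se_zx <= 0:
        raise ValueError("se_zx must be positive")
    return (beta_zx / se_zx) ** 2


def select_instruments(
    eqtl: pd.DataFrame,
    gene: str,
    gene_interval: tuple[str, int, int],
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Pick the top cis-eQTL SNP per tissue for one gene.

    Parameters
    ----------
    eqtl
        Canonical eQTL table (may cover many genes).
    gene_interval
        ``(chrom, start, end)`` of the gene, 1-based inclusive.
    window
        cis window in bp measured from the interval boundaries.

    Returns one row per tissue (the smallest-p cis SNP; ties broken by
    smallest snp id for determinism), with an ``f_stat`` column. Tissues
    sharing a top SNP yield distinct (gene, tissue) instruments with the
    same SNP. Trans variants (outside the window or on another chromosome)
    never qualify.
    """
    chrom, start, end = gene_interval
    sub = eqtl[
        (eqtl["gene"] == gene)
        & (eqtl["chr"].astype(str) == str(chrom))
        & (eqtl["pos"] >= start - window)
        & (eqtl["pos"] <= end + window)
    ]
    if sub.empty:
        logger.info("select_instruments: no cis association for gene %s", gene)
        return pd.DataFrame(columns=list(eqtl.columns) + ["f_stat"])
    sub = sub.sort_values(["tissue", "pval", "snp"], kind="mergesort")
    top = sub.groupby("tissue", sort=True).head(1).copy()
    top["f_stat"] = (top["beta"] / top["se"]) ** 2
    return top.reset_index(drop=True)


def wald_ratio(
    beta_zy: float,
    se_zy: float,
    beta_zx: float,
    se_zx: float,
    second_order: bool = False,
) -> tuple[float, float, float]:
    """Wald-ratio MR estimate, its SE and two-sided normal p-value.

    The default SE is the first-order delta-method term |se_zy / beta_zx|;
    ``second_order=True`` adds the exposure-uncertainty term
    beta_zy^2 * se_zx^2 / beta_zx^4 under the square root.
    """
    if beta_zx == 0:
        raise ValueError("undefined ratio: beta_zx is zero")
    beta_iv = beta_zy / beta_zx
    if second_order:
        se_iv = math.sqrt(se_zy**2 / beta_zx**2 + beta_zy**2 * se_zx**2 / beta_zx**4)
    else:
        se_iv = abs(se_zy / beta_zx)
    if beta_iv == 0:
        pval = 1.0
    elif se_iv == 0:
        pval = 0.0
    else:
        pval = 2.0 * float(stats.norm.sf(abs(beta_iv) / se_iv))
    return beta_iv, se_iv, pval


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen(
    instruments: pd.DataFrame,
    gwas_store,
    side_effect_map: pd.DataFrame,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Phenome-wide MR screen: every instrument against every mapped phenotype.

    ``instruments`` must already have passed the F filter. For each
    (instrument, phenotype) pair with a harmonizable outcome record a Wald
    ratio is computed; q-values are assigned jointly across the whole screen.
    Pairs whose SNP is absent from the phenotype's GWAS, or fails
    harmonization, are skipped and counted in ``df.attrs["n_skipped"]``.

    Returns the full screen with a ``pass_fdr`` column (q < config.fdr); no
    rows are dropped here so that the screen's cardinality stays auditable.
    """
    cfg = config or RunConfig()
    rows = []
    n_skipped = 0
    phenos = side_effect_map[["side_effect", "phenotype_id"]].drop_duplicates()
    for pheno_id, grp in phenos.groupby("phenotype_id", sort=True):
        try:
            gwas = gwas_store.get(pheno_id)
        except FileNotFoundError:
            logger.warning("screen: no GWAS table for %s; skipping", pheno_id)
            n_skipped += len(instruments) * len(grp)
            continue
        merged = harmonize_frames(instruments, gwas, suffixes=("_x", "_y"))
        n_skipped += (len(instruments) - len(merged)) * len(grp)
        for _, inst in merged.iterrows():
            beta_iv, se_iv, pval = wald_ratio(
                inst["beta_y"],
                inst["se_y"],
                inst["beta_x"],
                inst["se_x"],
                second_order=cfg.second_order_se,
            )
            for side_effect in grp["side_effect"]:
                rows.append(
                    {
                        "gene": inst["gene"],
                        "tissue": inst["tissue"],
                        "snp": inst["snp"],
                        "side_effect": side_effect,
                        "phenotype_id": pheno_id,
                        "beta_zx": inst["beta_x"],
                        "se_zx": inst["se_x"],
                        "f_stat": inst["f_stat"],
                        "beta_zy": inst["beta_y"],
                        "se_zy": inst["se_y"],
                        "beta_iv": beta_iv,
                        "se_iv": se_iv,
                        "pval": pval,
                    }
                )
    out = pd.DataFrame(rows, columns=[c for c in MR_COLUMNS if c != "qval"])
    if len(out):
        out["qval"] = bh_fdr(out["pval"].to_numpy())
        out["pass_fdr"] = out["qval"] < cfg.fdr
    else:
        out["qval"] = pd.Series(dtype=float)
        out["pass_fdr"] = pd.Series(dtype=bool)
    out = out.sort_values(
        ["gene", "tissue", "side_effect", "phenotype_id"], kind="mergesort"
    ).reset_index(drop=True)
    out.attrs["n_skipped"] = n_skipped
    return out


def dedupe_pair_results(results: pd.DataFrame) -> pd.DataFrame:
    """Retain one MR result per (side_effect, gene) pair.

    Selection: smallest q-value, ties broken by larger F statistic, then by
    lexicographically smallest SNP id -- a deterministic chain.
    """
    if results.empty:
        return results.copy()
    ordered = results.sort_values(
        ["side_effect", "gene", "qval", "f_stat", "snp"],
        ascending=[True, True, True, False, True],
        kind="mergesort",
    )
    return ordered.groupby(["side_effect", "gene"], sort=True).head(1).reset_index(drop=True)
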