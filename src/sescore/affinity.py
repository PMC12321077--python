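"""Binding-affinity summaries: trimmed-mean Ki aggregation and pKi scaling.

Ki measurements for one (drug, receptor) pair come from multiple labs and
occasionally contain order-of-magnitude outliers, so the pair-level constant
is a trimmed mean. Measurements at or above 10,000 nM are discarded first as
pharmacologically inert. The aggregated Ki (in molar units, via the
conversion M = nM * 1e-8 used throughout) is then put on the scaled log
affinity scale

    pKi = -log10(Ki_M) - 4

which maps the discard boundary (10,000 nM) to exactly 0 and strong binders
(~1 nM) to 4, so pKi lives in roughly [0, 4.5]. Pairs known to bind but with
no surviving measurement fall in one of two classes:

* unmeasured (no measurement at all): imputed with the default
  pKi = 0.824 (SE 0.15), the mean over all measured pairs;
* non-binding (every measurement >= the discard threshold): excluded from
  scoring entirely -- the data say the drug does not meaningfully engage the
  receptor, which is different from not knowing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig

logger = logging.getLogger("sescore.affinity")

LN10 = math.log(10.0)


@dataclass(frozen=True)
class AffinitySummary:
    """Aggregated binding affinity for one (drug, receptor) pair."""

    drug: str
    receptor: str
    action: str
    pki: float
    pki_se: float
    ki_mean_m: float  # trimmed-mean Ki in molar units (NaN when default/non-binding)
    ki_se_m: float  # SE of the trimmed mean, molar units
    n_used: int  # measurements surviving the discard filter
    is_default: bool  # True when the default pKi was imputed
    is_nonbinding: bool  # True when every measurement was discarded


def discard_weak(measurements: Iterable[float], threshold_nm: float = 10_000.0) -> list[float]:
    """Drop measurements at or above the discard threshold (default 10,000 nM)."""
    out = []
    for v in measurements:
        if v <= 0:
            raise ValueError(f"Ki measurements must be positive, got {v}")
        if v < threshold_nm:
            out.append(float(v))
    return out


def trimmed_mean(values: Sequence[float], trim: float = 0.1) -> tuple[float, float]:
    """Symmetric trimmed mean and its standard error.

    Removes ``floor(trim * n)`` values from each tail, returns the arithmetic
    mean of the remainder and ``sd / sqrt(k)`` over the k survivors (0 when
    k == 1).
    """
    if not 0 <= trim < 0.5:
        raise ValueError("trim must be in [0, 0.5)")
    vals = np.sort(np.asarray(values, dtype=float))
    n = vals.size
    if n == 0:
        raise ValueError("no measurements")
    k = int(math.floor(trim * n))
    kept = vals[k : n - k]
    mean = float(kept.mean())
    se = 0.0 if kept.size == 1 else float(kept.std(ddof=1) / math.sqrt(kept.size))
    return mean, se


def scale_pki(ki_mean_nm: float, nm_to_m: float = 1e-8) -> float:
    """Scaled binding affinity: pKi = -log10(Ki_nM * nm_to_m) - 4.

    With the conversion factor 1e-8 this maps 10,000 nM (the discard
    boundary) to 0 and 1 nM to 4.
    """
    if ki_mean_nm <= 0:
        raise ValueError(f"Ki must be positive, got {ki_mean_nm}")
    return -math.log10(ki_mean_nm * nm_to_m) - 4.0


def dose_adjustment(pki: float, de: float) -> float:
    """Dose adjustment a_d = pKi * log10(de); zero at the reference dose de = 1."""
    if de <= 0:
        raise ValueError(f"dose equivalent must be positive, got {de}")
    return pki * math.log10(de)


def summarize_affinity(
    drug: str,
    receptor: str,
    measurements: Sequence[float],
    action: str,
    config: RunConfig | None = None,
) -> AffinitySummary:
    """Aggregate raw Ki measurements for one pair into an :class:`AffinitySummary`.

    Pipeline: discard weak (>= 10,000 nM) -> trimmed mean -> pKi scaling.
    No measurement at all yields the default pKi; all measurements discarded
    yields the non-binding sentinel.
    """
    cfg = config or RunConfig()
    if len(measurements) == 0:
        return AffinitySummary(
            drug=drug,
            receptor=receptor,
            action=action,
            pki=cfg.default_pki,
            pki_se=cfg.default_pki_se,
            ki_mean_m=float("nan"),
            ki_se_m=float("nan"),
            n_used=0,
            is_default=True,
            is_nonbinding=False,
        )
    kept = discard_weak(measurements, cfg.ki_discard_nm)
    if not kept:
        logger.info("affinity: %s/%s non-binding (all %d measurements discarded)",
                    drug, receptor, len(measurements))
        return AffinitySummary(
            drug=drug,
            receptor=receptor,
            action=action,
            pki=float("nan"),
            pki_se=float("nan"),
            ki_mean_m=float("nan"),
            ki_se_m=float("nan"),
            n_used=0,
            is_default=False,
            is_nonbinding=True,
        )
    mean_nm, se_nm = trimmed_mean(kept, cfg.trim)
    pki = scale_pki(mean_nm, cfg.nm_to_m)
    # delta-method SE on the pKi scale, for reporting; the bootstrap resamples
    # the Ki mean itself and re-scales, so this is not used in propagation
    pki_se = se_nm / (mean_nm * LN10)
    return AffinitySummary(
        drug=drug,
        receptor=receptor,
        action=action,
        pki=pki,
        pki_se=pki_se,
        ki_mean_m=mean_nm * cfg.nm_to_m,
        ki_se_m=se_nm * cfg.nm_to_m,
        n_used=len(kept),
        is_default=False,
        is_nonbinding=False,
    )


def build_affinity_table(raw: pd.DataFrame, config: RunConfig | None = None) -> pd.DataFrame:
    """Summarize a raw measurement table into one row per (drug, receptor).

    The raw table (from :func:`sescore.io.read_affinity_table`) may carry
    several measurement rows per pair and rows with missing Ki; a pair whose
    every Ki is missing is treated as unmeasured (default imputation).
    """
    cfg = config or RunConfig()
    rows = []
    for (drug, receptor), grp in raw.groupby(["drug", "receptor"], sort=True):
        meas = grp["ki_nM"].dropna().tolist()
        actions = [a for a in grp["action"] if a != "unknown"]
        action = actions[0] if actions else "unknown"
        s = summarize_affinity(drug, receptor, meas, action, cfg)
        rows.append(
            {
                "drug": s.drug,
                "receptor": s.receptor,
                "action": s.action,
                "pki": s.pki,
                "pki_se": s.pki_se,
                "ki_mean_m": s.ki_mean_m,
                "ki_se_m": s.ki_se_m,
                "n_used": s.n_used,
                "is_default": s.is_default,
                "is_nonbinding": s.is_nonbinding,
            }
        )
    return pd.DataFrame(rows)
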