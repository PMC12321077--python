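"""Drug side-effect scores: MR effects weighted by binding and dose.

The contribution of receptor e to drug d's profile for side-effect t is

    term_{d,t,e} = direction_e * beta_IV_e * (pKi_{d,e} + a_d),
    a_d = pKi_{d,e} * log10(de_d),

i.e. the causal effect of receptor expression on the trait, weighted by how
strongly (pKi) and at what relative dose (de) the drug engages the receptor.
The per-(drug, side-effect) score is the sum over receptors that survived
the MR and colocalization gates,

    S_{d,t} = sum_e term_{d,t,e},

and S_d = sum_t S_{d,t} is the drug total. Cumulative reporting uses the
absolute-value variant (sum of |term|), which ranks burden without committing
to a direction; signed terms are always retained for direction-aware views.

Direction corrects for pharmacological action: blocking a receptor
(antagonist, inverse agonist, inhibitor) inverts the sign of an
expression-mediated effect, agonism and positive modulation preserve it, and
partial agonists / unknown actions default to +1 with a logged warning since
their binding relationship is non-linear.

Standard errors come from a parametric bootstrap (default 1000 iterations):
beta_IV is resampled from N(beta_IV, se_IV); measured binding resamples the
trimmed-mean Ki from N(mean, SE) (truncated positive) and re-scales to pKi;
default-imputed binding resamples pKi ~ N(0.824, 0.15). Affinity draws are
shared across all terms of a drug within an iteration, so drug-level SEs
respect the within-drug dependence on common binding estimates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .affinity import AffinitySummary
from .config import RunConfig

logger = logging.getLogger("sescore.scoring")

#: Sign applied to a receptor's term by pharmacological action.
ACTION_DIRECTION = {
    "agonist": 1,
    "positive_modulator": 1,
    "antagonist": -1,
    "inverse_agonist": -1,
    "inhibitor": -1,
    "partial_agonist": 1,  # non-linear binding; sign not principled
    "unknown": 1,
}

#: Minimum Ki draw (in molar units) so log10 stays defined in the bootstrap.
KI_FLOOR_M = 1e-12

TERM_COLUMNS = [
    "drug",
    "side_effect",
    "receptor",
    "beta_iv",
    "se_iv",
    "pki",
    "a_d",
    "de",
    "direction",
    "signed_value",
    "used_default_pki",
]


@dataclass(frozen=True)
class ScoreTerm:
    """One receptor's contribution to a (drug, side-effect) score."""

    drug: str
    side_effect: str
    receptor: str
    beta_iv: float
    pki: float
    a_d: float
    direction: int
    signed_value: float
    used_default_pki: bool


@dataclass(frozen=True)
class ScoreEntry:
    """Per-(drug, side-effect) score with its bootstrap SE."""

    drug: str
    side_effect: str
    score: float
    abs_score: float
    se: float
    n_boot: int
    n_terms: int


class NonBindingError(ValueError):
    """Raised when a term is requested for a non-binding (drug, receptor) pair."""


def action_direction(action: str) -> int:
    """Direction (+1/-1) for a pharmacological action, warning when unprincipled."""
    if action not in ACTION_DIRECTION:
        raise ValueError(f"unrecognized action '{action}'")
    if action in ("partial_agonist", "unknown"):
        logger.warning(
            "scoring: action '%s' has no principled direction; using +1", action
        )
    return ACTION_DIRECTION[action]


def signed_term(
    beta_iv: float,
    aff: AffinitySummary,
    de: float,
    side_effect: str = "",
) -> ScoreTerm:
    """Build one score term from an MR estimate, an affinity summary and a dose.

    Raises :class:`NonBindingError` for pairs whose every measurement was
    discarded -- such terms are omitted, not silently zeroed.
    """
    if aff.is_nonbinding:
        logger.info(
            "scoring: omitting non-binding pair %s/%s", aff.drug, aff.receptor
        )
        raise NonBindingError(f"{aff.drug}/{aff.receptor} is non-binding")
    if de <= 0:
        raise ValueError("dose equivalent must be positive")
    direction = action_direction(aff.action)
    a_d = aff.pki * math.log10(de)
    raw = beta_iv * (aff.pki + a_d)
    return ScoreTerm(
        drug=aff.drug,
        side_effect=side_effect,
        receptor=aff.receptor,
        beta_iv=beta_iv,
        pki=aff.pki,
        a_d=a_d,
        direction=direction,
        signed_value=direction * raw,
        used_default_pki=aff.is_default,
    )


def score_side_effect(terms: Sequence[ScoreTerm]) -> ScoreEntry:
    """Sum a (drug, side-effect)'s terms into signed and absolute scores."""
    if not terms:
        return ScoreEntry(
            drug="", side_effect="", score=0.0, abs_score=0.0, se=0.0,
            n_boot=0, n_terms=0,
        )
    drugs = {t.drug for t in terms}
    ses = {t.side_effect for t in terms}
    if len(drugs) > 1 or len(ses) > 1:
        raise ValueError("terms must share one (drug, side_effect)")
    return ScoreEntry(
        drug=terms[0].drug,
        side_effect=terms[0].side_effect,
        score=float(sum(t.signed_value for t in terms)),
        abs_score=float(sum(abs(t.signed_value) for t in terms)),
        se=float("nan"),
        n_boot=0,
        n_terms=len(terms),
    )


# ---------------------------------------------------------------------------
# parametric bootstrap


def _draw_pair_pki(
    pairs: pd.DataFrame, n_boot: int, rng: np.random.Generator, cfg: RunConfig
) -> np.ndarray:
    """Resampled pKi per (drug, receptor) pair; shape (n_boot, n_pairs).

    Pairs are processed in their (sorted) frame order so draws are
    reproducible given the generator state.
    """
    out = np.empty((n_boot, len(pairs)))
    floor_nm = KI_FLOOR_M / cfg.nm_to_m
    for j, row in enumerate(pairs.itertuples(index=False)):
        if row.used_default_pki:
            out[:, j] = rng.normal(cfg.default_pki, cfg.default_pki_se, size=n_boot)
        else:
            se_nm = row.ki_se_m / cfg.nm_to_m
            mean_nm = row.ki_mean_m / cfg.nm_to_m
            if se_nm == 0:
                out[:, j] = -np.log10(mean_nm * cfg.nm_to_m) - 4.0
            else:
                ki_nm = rng.normal(mean_nm, se_nm, size=n_boot)
                ki_nm = np.maximum(ki_nm, floor_nm)
                out[:, j] = -np.log10(ki_nm * cfg.nm_to_m) - 4.0
    return out


def bootstrap_replicates(
    terms: pd.DataFrame,
    n_boot: int,
    seed: int,
    config: RunConfig | None = None,
) -> np.ndarray:
    """Signed per-term score replicates, shape (n_boot, n_terms).

    ``terms`` needs columns drug, receptor, beta_iv, se_iv, de, direction,
    used_default_pki and (for measured pairs) ki_mean_m, ki_se_m. Affinity is
    drawn once per (drug, receptor) per iteration and shared across every
    term that references the pair.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    cfg = config or RunConfig()
    rng = np.random.default_rng(seed)
    cols = ["drug", "receptor", "used_default_pki", "ki_mean_m", "ki_se_m"]
    for c in ("ki_mean_m", "ki_se_m"):
        if c not in terms.columns:
            terms = terms.assign(**{c: np.nan})
    pairs = (
        terms[cols]
        .drop_duplicates(["drug", "receptor"])
        .sort_values(["drug", "receptor"], kind="mergesort")
        .reset_index(drop=True)
    )
    pair_key = pairs["drug"] + "\x00" + pairs["receptor"]
    term_key = terms["drug"] + "\x00" + terms["receptor"]
    pair_idx = term_key.map({k: i for i, k in enumerate(pair_key)}).to_numpy()

    pki_draws = _draw_pair_pki(pairs, n_boot, rng, cfg)  # (n_boot, n_pairs)
    beta = terms["beta_iv"].to_numpy(dtype=float)
    se = terms["se_iv"].to_numpy(dtype=float)
    beta_draws = beta[None, :] + se[None, :] * rng.standard_normal((n_boot, len(terms)))
    dose_mult = 1.0 + np.log10(terms["de"].to_numpy(dtype=float))  # pki + a_d = pki*(1+log10 de)
    direction = terms["direction"].to_numpy(dtype=float)
    return direction[None, :] * beta_draws * pki_draws[:, pair_idx] * dose_mult[None, :]


def bootstrap_se(
    terms: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    config: RunConfig | None = None,
) -> float:
    """Parametric-bootstrap SE of one (drug, side-effect) score S_{d,t}.

    All rows of ``terms`` must belong to a single entry; resamples every
    stochastic input, recomputes S through the full formula (including the
    dose adjustment) per iteration, and returns the SD across iterations.
    Deterministic given ``seed``; exactly 0 when every input SE is 0.
    """
    reps = bootstrap_replicates(terms, n_boot, seed, config)
    return float(reps.sum(axis=1).std(ddof=1))


# ---------------------------------------------------------------------------
# aggregation


def aggregate(terms: pd.DataFrame, config: RunConfig | None = None) -> dict[str, pd.DataFrame]:
    """Group-sum the signed term table into the reporting views.

    Returns per-drug totals (signed and absolute), per-(drug, receptor) and
    per-(drug, side-effect) cumulative tables, the full per-side-effect-by-
    receptor breakdown with direction, and the on-/off-target classification
    of each side-effect (on-target-dominated when on- or suspected-target
    receptors contribute more than half of the cumulative absolute score).
    """
    cfg = config or RunConfig()
    if terms.empty:
        empty_cols = {
            "entries": ["drug", "side_effect", "score", "abs_score", "n_terms"],
            "drugs": ["drug", "score", "abs_score", "n_side_effects"],
            "per_receptor": ["drug", "receptor", "score", "abs_score"],
            "per_side_effect": ["drug", "side_effect", "score", "abs_score"],
            "breakdown": list(terms.columns) + ["abs_value"],
            "classification": ["side_effect", "abs_total", "on_target_abs",
                               "on_target_frac", "classification"],
        }
        return {k: pd.DataFrame(columns=v) for k, v in empty_cols.items()}
    t = terms.copy()
    t["abs_value"] = t["signed_value"].abs()
    entries = (
        t.groupby(["drug", "side_effect"], sort=True)
        .agg(score=("signed_value", "sum"), abs_score=("abs_value", "sum"),
             n_terms=("signed_value", "size"))
        .reset_index()
    )
    drugs = (
        t.groupby("drug", sort=True)
        .agg(score=("signed_value", "sum"), abs_score=("abs_value", "sum"))
        .reset_index()
    )
    nonzero = entries[entries["abs_score"] > 0].groupby("drug")["side_effect"].nunique()
    drugs["n_side_effects"] = drugs["drug"].map(nonzero).fillna(0).astype(int)
    per_receptor = (
        t.groupby(["drug", "receptor"], sort=True)
        .agg(score=("signed_value", "sum"), abs_score=("abs_value", "sum"))
        .reset_index()
    )
    breakdown = t.sort_values(
        ["drug", "side_effect", "receptor"], kind="mergesort"
    ).reset_index(drop=True)

    on_targets = set(cfg.on_target_receptors) | set(cfg.suspected_target_receptors)
    t["on_target"] = t["receptor"].isin(on_targets)
    by_se = t.groupby("side_effect", sort=True).apply(
        lambda g: pd.Series(
            {
                "abs_total": g["abs_value"].sum(),
                "on_target_abs": g.loc[g["on_target"], "abs_value"].sum(),
            }
        ),
        include_groups=False,
    )
    by_se["on_target_frac"] = np.where(
        by_se["abs_total"] > 0, by_se["on_target_abs"] / by_se["abs_total"], 0.0
    )
    by_se["classification"] = np.where(
        by_se["on_target_frac"] > 0.5, "on_target", "off_target"
    )
    classification = by_se.reset_index()
    return {
        "entries": entries,
        "drugs": drugs,
        "per_receptor": per_receptor,
        "per_side_effect": entries[["drug", "side_effect", "score", "abs_score"]].copy(),
        "breakdown": breakdown,
        "classification": classification,
    }


class ScoreTables(NamedTuple):
    """All scoring outputs of a run."""

    terms: pd.DataFrame
    entries: pd.DataFrame
    drugs: pd.DataFrame
    per_receptor: pd.DataFrame
    per_side_effect: pd.DataFrame
    breakdown: pd.DataFrame
    classification: pd.DataFrame


def compute_scores(
    selected: pd.DataFrame,
    affinity: pd.DataFrame,
    dose: pd.DataFrame,
    config: RunConfig | None = None,
    seed: int = 0,
    n_boot: int | None = None,
) -> ScoreTables:
    """Build the full score tables from gated MR results and affinity summaries.

    Parameters
    ----------
    selected
        One MR result per (side_effect, gene) that survived the F, FDR and
        colocalization gates; needs columns gene, side_effect, beta_iv,
        se_iv (extra columns such as snp, tissue, pp4 are carried through).
    affinity
        Output of :func:`sescore.affinity.build_affinity_table`.
    dose
        Dose-equivalents table (drug, dose_equivalent).
    """
    cfg = config or RunConfig()
    nb = cfg.n_boot if n_boot is None else n_boot
    de_map = dict(zip(dose["drug"], dose["dose_equivalent"]))
    usable = affinity[~affinity["is_nonbinding"]]
    skipped_nonbinding = int(affinity["is_nonbinding"].sum())
    if skipped_nonbinding:
        logger.info("scoring: %d non-binding pair(s) omitted", skipped_nonbinding)

    terms = usable.merge(selected, left_on="receptor", right_on="gene", how="inner")
    if terms.empty:
        empty = pd.DataFrame(columns=TERM_COLUMNS)
        zero = pd.DataFrame()
        return ScoreTables(empty, zero, zero, zero, zero, zero, zero)
    terms["de"] = terms["drug"].map(de_map)
    if terms["de"].isna().any():
        missing = sorted(terms.loc[terms["de"].isna(), "drug"].unique())
        raise ValueError(f"no dose equivalent for drug(s): {missing}")
    terms["direction"] = terms["action"].map(ACTION_DIRECTION)
    unprincipled = terms["action"].isin(["partial_agonist", "unknown"])
    if unprincipled.any():
        logger.warning(
            "scoring: %d term(s) with partial-agonist/unknown action signed +1",
            int(unprincipled.sum()),
        )
    terms["a_d"] = terms["pki"] * np.log10(terms["de"])
    terms["signed_value"] = (
        terms["direction"] * terms["beta_iv"] * (terms["pki"] + terms["a_d"])
    )
    terms["used_default_pki"] = terms["is_default"]
    terms = terms.sort_values(
        ["drug", "side_effect", "receptor"], kind="mergesort"
    ).reset_index(drop=True)

    views = aggregate(terms, cfg)
    entries, drugs = views["entries"], views["drugs"]

    # bootstrap SEs: one replicate matrix for the whole run so affinity draws
    # are shared within drugs, then group-sum replicates before taking SDs
    reps = bootstrap_replicates(terms, nb, seed, cfg)  # (nb, n_terms)
    ekey, _ = pd.factorize(
        terms["drug"] + "\x00" + terms["side_effect"], sort=True
    )
    n_entries = ekey.max() + 1
    entry_reps = np.zeros((nb, n_entries))
    entry_abs_reps = np.zeros((nb, n_entries))
    np.add.at(entry_reps.T, ekey, reps.T)
    np.add.at(entry_abs_reps.T, ekey, np.abs(reps).T)
    dkey, _ = pd.factorize(terms["drug"], sort=True)
    drug_reps = np.zeros((nb, dkey.max() + 1))
    drug_abs_reps = np.zeros((nb, dkey.max() + 1))
    np.add.at(drug_reps.T, dkey, reps.T)
    np.add.at(drug_abs_reps.T, dkey, np.abs(reps).T)

    entries = entries.sort_values(["drug", "side_effect"], kind="mergesort").reset_index(drop=True)
    entries["se"] = entry_reps.std(axis=0, ddof=1)
    entries["se_abs"] = entry_abs_reps.std(axis=0, ddof=1)
    entries["n_boot"] = nb
    drugs = drugs.sort_values("drug", kind="mergesort").reset_index(drop=True)
    drugs["se"] = drug_reps.std(axis=0, ddof=1)
    drugs["se_abs"] = drug_abs_reps.std(axis=0, ddof=1)
    drugs["n_boot"] = nb

    return ScoreTables(
        terms=terms,
        entries=entries,
        drugs=drugs,
        per_receptor=views["per_receptor"],
        per_side_effect=views["per_side_effect"],
        breakdown=views["breakdown"],
        classification=views["classification"],
    )
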