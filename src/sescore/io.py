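"""Readers, writers and allele harmonization for all tabular inputs.

All summary statistics travel as tab-separated tables with a fixed header
(``snp chr pos ea oa eaf beta se pval n``; eQTL tables add ``gene`` and
``tissue``). Readers validate every row against the record invariants
(distinct A/C/G/T alleles, positive SE, p in (0, 1], positive n, allele
frequency in [0, 1] when present) and drop invalid rows with a logged count,
so downstream math never sees an inconsistent record.

Harmonization aligns an outcome record to the effect allele of its exposure
record, flipping the outcome beta when the alleles are swapped and rejecting
strand-ambiguous (palindromic A/T, C/G) variants outright: with a single
instrument per gene there is no way to recover from a mis-oriented allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("sescore.io")

VALID_ALLELES = frozenset("ACGT")
PALINDROMIC_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})

SUMSTAT_COLUMNS = ["snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "pval", "n"]
EQTL_COLUMNS = SUMSTAT_COLUMNS + ["gene", "tissue"]

ACTION_VOCAB = frozenset(
    {
        "agonist",
        "antagonist",
        "partial_agonist",
        "inverse_agonist",
        "positive_modulator",
        "inhibitor",
        "unknown",
    }
)

# pandas' default float serialization is the shortest round-trip repr:
# exact on re-read and deterministic, so identical runs write identical bytes.
FLOAT_FMT = None


@dataclass(frozen=True)
class VariantRecord:
    """One SNP-trait association from a summary-statistics table."""

    snp: str
    chr: str
    pos: int
    ea: str
    oa: str
    beta: float
    se: float
    pval: float
    n: float
    eaf: float | None = None


@dataclass(frozen=True)
class EqtlRecord(VariantRecord):
    """A SNP-expression association, tagged with its gene and tissue."""

    gene: str = ""
    tissue: str = ""


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure/outcome records sharing an orientation of the effect allele."""

    exposure: VariantRecord
    outcome: VariantRecord
    flipped: bool


class HarmonizationError(ValueError):
    """Raised when an exposure/outcome pair cannot be allele-aligned."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


# --------------------------------------------------------------------------
# summary-statistic tables


def _row_valid_mask(df: pd.DataFrame) -> pd.Series:
    ea = df["ea"].astype(str).str.upper()
    oa = df["oa"].astype(str).str.upper()
    ok = ea.isin(VALID_ALLELES) & oa.isin(VALID_ALLELES) & (ea != oa)
    ok &= pd.to_numeric(df["se"], errors="coerce") > 0
    pval = pd.to_numeric(df["pval"], errors="coerce")
    ok &= (pval > 0) & (pval <= 1)
    ok &= pd.to_numeric(df["n"], errors="coerce") > 0
    ok &= pd.to_numeric(df["beta"], errors="coerce").notna()
    ok &= pd.to_numeric(df["pos"], errors="coerce") > 0
    eaf = pd.to_numeric(df["eaf"], errors="coerce")
    ok &= eaf.isna() | ((eaf >= 0) & (eaf <= 1))
    return ok


def read_sumstats(
    path: str | Path,
    schema: dict[str, str] | None = None,
    eqtl: bool = False,
) -> pd.DataFrame:
    """Read a TSV of summary statistics, validating every row.

    Parameters
    ----------
    path
        Tab-separated file with a header.
    schema
        Optional mapping from canonical column name to the column name used
        in the file (e.g. ``{"snp": "rsid"}``).
    eqtl
        When true, ``gene`` and ``tissue`` columns are required as well.

    Returns
    -------
    DataFrame with canonical columns; rows violating the record invariants
    are dropped and counted in ``df.attrs["n_rejected"]``.
    """
    required = EQTL_COLUMNS if eqtl else SUMSTAT_COLUMNS
    df = pd.read_csv(path, sep="\t", dtype={"snp": str, "chr": str})
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s) {missing} in {path}")
    df = df[required].copy()
    for col in ("pos",):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["ea"] = df["ea"].astype(str).str.upper()
    df["oa"] = df["oa"].astype(str).str.upper()
    mask = _row_valid_mask(df)
    n_rejected = int((~mask).sum())
    if n_rejected:
        logger.info("read_sumstats(%s): rejected %d invalid row(s)", path, n_rejected)
    out = df[mask].reset_index(drop=True)
    out["pos"] = out["pos"].astype(np.int64)
    out.attrs["n_rejected"] = n_rejected
    out.attrs["n_input"] = len(df)
    return out


def write_sumstats(df: pd.DataFrame, path: str | Path) -> None:
    """Write a summary-statistics table in the canonical TSV dialect."""
    cols = [c for c in EQTL_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Read gene annotations: columns gene, chr, start, end (1-based, inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chr": str})
    missing = [c for c in ("gene", "chr", "start", "end") if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s) {missing} in {path}")
    if (df["end"] < df["start"]).any():
        raise ValueError("gene table has end < start")
    return df


# --------------------------------------------------------------------------
# harmonization


def is_palindromic(ea: str, oa: str) -> bool:
    return (ea.upper(), oa.upper()) in PALINDROMIC_PAIRS


def harmonize(exposure: VariantRecord, outcome: VariantRecord) -> HarmonizedPair:
    """Align an outcome record to the exposure's effect allele.

    Raises :class:`HarmonizationError` with reason ``"palindromic"`` for
    strand-ambiguous variants, ``"allele_mismatch"`` when the allele sets
    differ, or ``"snp_mismatch"`` when the identifiers differ.
    """
    if exposure.snp != outcome.snp:
        raise HarmonizationError("snp_mismatch")
    if is_palindromic(exposure.ea, exposure.oa) or is_palindromic(outcome.ea, outcome.oa):
        raise HarmonizationError("palindromic")
    if (exposure.ea, exposure.oa) == (outcome.ea, outcome.oa):
        return HarmonizedPair(exposure, outcome, flipped=False)
    if (exposure.ea, exposure.oa) == (outcome.oa, outcome.ea):
        flipped = replace(
            outcome,
            ea=outcome.oa,
            oa=outcome.ea,
            beta=-outcome.beta,
            eaf=None if outcome.eaf is None else 1.0 - outcome.eaf,
        )
        return HarmonizedPair(exposure, flipped, flipped=True)
    raise HarmonizationError("allele_mismatch")


def harmonize_frames(
    exposure: pd.DataFrame, outcome: pd.DataFrame, suffixes=("_x", "_y")
) -> pd.DataFrame:
    """Vectorized harmonization of two tables merged on ``snp``.

    Returns the inner join with outcome ``beta_y``/``eaf_y`` flipped where the
    alleles were swapped; palindromic and allele-mismatched SNPs are dropped.
    The number dropped is in ``df.attrs["n_rejected"]``.
    """
    sx, sy = suffixes
    merged = exposure.merge(outcome, on="snp", suffixes=suffixes)
    if merged.empty:
        merged.attrs["n_rejected"] = 0
        return merged
    ea_x, oa_x = merged["ea" + sx], merged["oa" + sx]
    ea_y, oa_y = merged["ea" + sy], merged["oa" + sy]
    pal = [
        is_palindromic(a, b) or is_palindromic(c, d)
        for a, b, c, d in zip(ea_x, oa_x, ea_y, oa_y)
    ]
    pal = np.asarray(pal)
    same = (ea_x == ea_y) & (oa_x == oa_y)
    swapped = (ea_x == oa_y) & (oa_x == ea_y)
    keep = ~pal & (same | swapped)
    out = merged[keep].copy()
    flip = swapped[keep].to_numpy()
    out.loc[flip, "beta" + sy] = -out.loc[flip, "beta" + sy]
    if "eaf" + sy in out.columns:
        out.loc[flip, "eaf" + sy] = 1.0 - out.loc[flip, "eaf" + sy]
    out.loc[flip, ["ea" + sy, "oa" + sy]] = out.loc[flip, ["oa" + sy, "ea" + sy]].to_numpy()
    out["flipped"] = flip
    out.attrs["n_rejected"] = int((~keep).sum())
    return out.reset_index(drop=True)


# --------------------------------------------------------------------------
# affinity, map, dose tables


def read_affinity_table(path: str | Path) -> pd.DataFrame:
    """Read the drug-receptor binding table (CSV: drug, receptor, ki_nM, action, source).

    Blank Ki values are retained (they mark pairs known to bind with no
    measurement, which later receive the default pKi); negative Ki rows are
    rejected. Duplicated (drug, receptor) rows are kept as independent
    measurements. Actions outside the controlled vocabulary are coerced to
    ``"unknown"`` with a warning.
    """
    df = pd.read_csv(path, dtype={"drug": str, "receptor": str})
    missing = [c for c in ("drug", "receptor", "ki_nM", "action") if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s) {missing} in {path}")
    if "source" not in df.columns:
        df["source"] = ""
    df["ki_nM"] = pd.to_numeric(df["ki_nM"], errors="coerce")
    bad = df["ki_nM"].notna() & (df["ki_nM"] <= 0)
    if bad.any():
        logger.info("read_affinity_table: rejected %d non-positive Ki row(s)", int(bad.sum()))
    df = df[~bad].copy()
    action = df["action"].astype(str).str.strip().str.lower().str.replace(" ", "_")
    unknown = ~action.isin(ACTION_VOCAB)
    if unknown.any():
        logger.warning(
            "read_affinity_table: %d row(s) with unrecognized action coerced to 'unknown'",
            int(unknown.sum()),
        )
        action[unknown] = "unknown"
    df["action"] = action
    df.attrs["n_rejected"] = int(bad.sum())
    return df.reset_index(drop=True)


def read_side_effect_map(path: str | Path) -> pd.DataFrame:
    """Read the side-effect -> GWAS phenotype map (CSV).

    Columns: side_effect, phenotype_id, brain_relevant. A side-effect may map
    to several phenotypes; each (side_effect, phenotype_id) pair must be
    unique.
    """
    df = pd.read_csv(path, dtype={"side_effect": str, "phenotype_id": str})
    missing = [
        c for c in ("side_effect", "phenotype_id", "brain_relevant") if c not in df.columns
    ]
    if missing:
        raise ValueError(f"missing mandatory column(s) {missing} in {path}")
    if df.duplicated(["side_effect", "phenotype_id"]).any():
        raise ValueError("duplicate (side_effect, phenotype_id) pairs in map")
    df["brain_relevant"] = df["brain_relevant"].astype(bool)
    return df


def read_dose_equivalents(path: str | Path) -> pd.DataFrame:
    """Read per-drug dose equivalents (CSV: drug, dose_equivalent; all > 0)."""
    df = pd.read_csv(path, dtype={"drug": str})
    missing = [c for c in ("drug", "dose_equivalent") if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s) {missing} in {path}")
    df["dose_equivalent"] = pd.to_numeric(df["dose_equivalent"])
    if (df["dose_equivalent"] <= 0).any():
        raise ValueError("dose equivalents must be positive")
    return df


class GwasStore:
    """Lazily loads per-phenotype GWAS summary statistics from a directory.

    Each phenotype lives in ``<dir>/<phenotype_id>.tsv`` in the canonical
    sumstats dialect. Loaded tables are cached.
    """

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)
        self._cache: dict[str, pd.DataFrame] = {}

    def phenotypes(self) -> list[str]:
        return sorted(p.stem for p in self.directory.glob("*.tsv"))

    def get(self, phenotype_id: str) -> pd.DataFrame:
        if phenotype_id not in self._cache:
            path = self.directory / f"{phenotype_id}.tsv"
            if not path.exists():
                raise FileNotFoundError(f"no GWAS file for phenotype '{phenotype_id}'")
            self._cache[phenotype_id] = read_sumstats(path)
        return self._cache[phenotype_id]


class FrameGwasStore:
    """In-memory GWAS store over a dict of DataFrames (used by simulations)."""

    def __init__(self, frames: dict[str, pd.DataFrame]):
        self._frames = frames

    def phenotypes(self) -> list[str]:
        return sorted(self._frames)

    def get(self, phenotype_id: str) -> pd.DataFrame:
        if phenotype_id not in self._frames:
            raise FileNotFoundError(f"no GWAS table for phenotype '{phenotype_id}'")
        return self._frames[phenotype_id]
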