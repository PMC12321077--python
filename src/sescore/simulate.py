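"""Ground-truth-labelled synthetic input bundles for the full pipeline.

Real inputs (brain/blood eQTL catalogues, GWAS summary statistics,
multi-lab Ki tables) cannot ship with the package, so this module generates
statistically faithful stand-ins at summary-statistic level:

* loci with AR(1) linkage disequilibrium (corr(i, j) = rho^|i-j|), marginal
  effects equal to the LD row times the causal-effect vector, and estimation
  noise with SE = 1 / sqrt(2 * maf * (1 - maf) * n) correlated according to
  the same LD;
* the five causal configurations used by colocalization (no signal, one
  trait only, distinct variants, shared variant), with the shared-variant
  outcome effect beta_ZY = theta * beta_ZX;
* multi-lab Ki measurement sets with log-normal lab noise, occasional
  order-of-magnitude outliers (to exercise the trimmed mean) and pairs with
  no measurement at all (to exercise default-pKi imputation).

``simulate_study`` assembles a complete five-file input bundle plus a truth
manifest listing every planted causal (drug, receptor, side-effect) triple,
so recovery and false-admission rates of the gate chain are measurable.
All generators take explicit seeds; there is no hidden global randomness.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import BLOOD_TISSUE, BRAIN_TISSUES
from .io import write_sumstats

HYPOTHESES = ("H0", "H1", "H2", "H3", "H4")

# non-palindromic ordered allele pairs to draw from
_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulated locus shared by an exposure (eQTL) and an outcome trait."""

    hypothesis: str  # H0 | H1 | H2 | H3 | H4
    m_snps: int = 40
    ld_rho: float = 0.9
    maf: float = 0.3
    beta_zx: float = 0.3
    theta: float = 0.5  # causal effect of expression on trait (H4)
    beta_zy: float | None = None  # H3 outcome effect at its own SNP; default theta*beta_zx
    n_eqtl: int = 50_000
    n_gwas: int = 50_000
    seed: int = 0
    causal_index: int | None = None  # exposure causal SNP (default: centre)
    causal_index2: int | None = None  # outcome causal SNP under H3
    gene: str = "GENE1"
    tissue: str = "cortex"
    phenotype_id: str = "pheno1"
    chrom: str = "1"
    start_pos: int = 1_000_000
    snp_spacing: int = 10_000
    snp_prefix: str = "rs"

    def __post_init__(self):
        if self.hypothesis not in HYPOTHESES:
            raise ValueError(f"hypothesis must be one of {HYPOTHESES}")
        if not 0 < self.maf < 0.5:
            raise ValueError("maf must be in (0, 0.5)")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")
        if self.m_snps < 1:
            raise ValueError("m_snps must be >= 1")


def ar1_corr(m: int, rho: float) -> np.ndarray:
    """AR(1) LD correlation matrix: rho^|i-j|."""
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def analytic_se(maf: float, n: float) -> float:
    """Per-SNP SE of a standardized marginal effect: 1/sqrt(2*maf*(1-maf)*n)."""
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _simulate_trait(
    chol: np.ndarray,
    sigma: np.ndarray,
    causal: np.ndarray,
    maf: float,
    n: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Marginal effect estimates for one trait over an LD locus.

    Mean = Sigma @ causal; noise ~ MVN(0, se^2 * Sigma).
    Returns (betahat, se, pval).
    """
    m = sigma.shape[0]
    se = analytic_se(maf, n)
    mean = sigma @ causal
    betahat = mean + se * (chol @ rng.standard_normal(m))
    pval = 2.0 * stats.norm.sf(np.abs(betahat / se))
    pval = np.clip(pval, np.nextafter(0, 1), 1.0)
    return betahat, se, pval


def _locus_frame(
    spec: ScenarioSpec,
    snps: list[str],
    alleles: list[tuple[str, str]],
    betahat: np.ndarray,
    se: float,
    pval: np.ndarray,
    n: float,
    eqtl: bool,
) -> pd.DataFrame:
    pos = spec.start_pos + spec.snp_spacing * np.arange(spec.m_snps)
    df = pd.DataFrame(
        {
            "snp": snps,
            "chr": spec.chrom,
            "pos": pos,
            "ea": [a for a, _ in alleles],
            "oa": [b for _, b in alleles],
            "eaf": spec.maf,
            "beta": betahat,
            "se": se,
            "pval": pval,
            "n": float(n),
        }
    )
    if eqtl:
        df["gene"] = spec.gene
        df["tissue"] = spec.tissue
    return df


def causal_vectors(spec: ScenarioSpec) -> tuple[np.ndarray, np.ndarray, int, int]:
    """True causal-effect vectors (exposure, outcome) and causal indices."""
    m = spec.m_snps
    c1 = spec.causal_index if spec.causal_index is not None else m // 2
    c2 = spec.causal_index2
    if c2 is None:
        c2 = (c1 + max(1, m // 4)) % m
    if spec.hypothesis == "H3" and c2 == c1:
        raise ValueError("H3 requires distinct causal indices")
    b1 = np.zeros(m)
    b2 = np.zeros(m)
    zy = spec.beta_zy if spec.beta_zy is not None else spec.theta * spec.beta_zx
    if spec.hypothesis in ("H1", "H3", "H4"):
        b1[c1] = spec.beta_zx
    if spec.hypothesis == "H2":
        b2[c2] = zy
    elif spec.hypothesis == "H3":
        b2[c2] = zy
    elif spec.hypothesis == "H4":
        b2[c1] = spec.theta * spec.beta_zx
    return b1, b2, c1, c2


def simulate_locus_pair(spec: ScenarioSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an aligned (eQTL, GWAS) locus under one causal configuration.

    Both tables cover identical SNPs with consistent alleles; deterministic
    given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.m_snps
    sigma = ar1_corr(m, spec.ld_rho)
    chol = np.linalg.cholesky(sigma)
    snps = [f"{spec.snp_prefix}{i:05d}" for i in range(m)]
    alleles = [_ALLELE_PAIRS[int(rng.integers(len(_ALLELE_PAIRS)))] for _ in range(m)]
    b1, b2, _, _ = causal_vectors(spec)
    bh1, se1, p1 = _simulate_trait(chol, sigma, b1, spec.maf, spec.n_eqtl, rng)
    bh2, se2, p2 = _simulate_trait(chol, sigma, b2, spec.maf, spec.n_gwas, rng)
    eqtl = _locus_frame(spec, snps, alleles, bh1, se1, p1, spec.n_eqtl, eqtl=True)
    gwas = _locus_frame(spec, snps, alleles, bh2, se2, p2, spec.n_gwas, eqtl=False)
    return eqtl, gwas


def simulate_affinity_table(
    drugs,
    receptors,
    truth_ki: dict[tuple[str, str], float],
    noise_sd_log10: float = 0.15,
    outlier_rate: float = 0.05,
    missing_rate: float = 0.1,
    seed: int = 0,
    actions: dict[tuple[str, str], str] | None = None,
) -> pd.DataFrame:
    """Multi-lab Ki measurement rows for every (drug, receptor) pair in truth_ki.

    Each measured pair gets 3-8 log-normal measurements around its true Ki;
    at ``outlier_rate`` a measurement is inflated by a factor of 10^2..10^3;
    at ``missing_rate`` a pair keeps a single row with blank Ki (binding
    known, affinity unmeasured -- the default-pKi path).
    """
    for r, label in ((noise_sd_log10, "noise_sd_log10"),):
        if r < 0:
            raise ValueError(f"{label} must be >= 0")
    for r, label in ((outlier_rate, "outlier_rate"), (missing_rate, "missing_rate")):
        if not 0 <= r <= 1:
            raise ValueError(f"{label} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for drug in drugs:
        for receptor in receptors:
            key = (drug, receptor)
            if key not in truth_ki:
                continue
            action = (actions or {}).get(key, "antagonist")
            if rng.random() < missing_rate:
                rows.append(
                    {"drug": drug, "receptor": receptor, "ki_nM": np.nan,
                     "action": action, "source": "synthetic-unmeasured"}
                )
                continue
            k = int(rng.integers(3, 9))
            logki = np.log10(truth_ki[key]) + noise_sd_log10 * rng.standard_normal(k)
            ki = 10.0 ** logki
            out_mask = rng.random(k) < outlier_rate
            ki[out_mask] *= 10.0 ** rng.uniform(2.0, 3.0, size=int(out_mask.sum()))
            for v in ki:
                rows.append(
                    {"drug": drug, "receptor": receptor, "ki_nM": float(v),
                     "action": action, "source": "synthetic-lab"}
                )
    return pd.DataFrame(rows, columns=["drug", "receptor", "ki_nM", "action", "source"])


# ---------------------------------------------------------------------------
# full study bundles


@dataclass(frozen=True)
class StudyConfig:
    """Design of a synthetic study: entities, causal truth and locus settings."""

    drugs: tuple[str, ...] = ("drug_a", "drug_b")
    receptors: tuple[str, ...] = (
        "DRD2", "HTR2A", "HRH1", "ADRA1A", "GABRA5", "CHRM1",
    )
    #: drug -> receptors it binds; None means every drug binds every receptor
    binding: dict[str, tuple[str, ...]] | None = None
    #: (side_effect, phenotype_id, brain_relevant)
    side_effect_map: tuple[tuple[str, str, bool], ...] = (
        ("weight_gain", "ph_bmi", True),
        ("weight_gain", "ph_whr", True),
        ("sedation", "ph_sleep", True),
        ("dizziness", "ph_dizzy", True),
        ("constipation", "ph_constip", False),
        ("dry_mouth", "ph_saliva", False),
        ("tremor", "ph_tremor", True),
    )
    #: (receptor, side_effect) pairs with a shared causal variant (H4 loci)
    causal_pairs: tuple[tuple[str, str], ...] = (
        ("DRD2", "weight_gain"),
        ("HRH1", "sedation"),
        ("HTR2A", "dizziness"),
        ("ADRA1A", "constipation"),
        ("GABRA5", "tremor"),
    )
    #: (receptor, side_effect) decoys with distinct causal variants (H3 loci)
    distinct_pairs: tuple[tuple[str, str], ...] = (
        ("DRD2", "sedation"),
        ("HTR2A", "dry_mouth"),
        ("HRH1", "tremor"),
    )
    #: receptors with no true eQTL (instruments must fail the F gate)
    weak_genes: tuple[str, ...] = ("CHRM1",)
    brain_tissues: tuple[str, ...] = BRAIN_TISSUES
    blood_tissue: str = BLOOD_TISSUE
    m_snps: int = 40
    ld_rho: float = 0.9
    maf: float = 0.3
    beta_zx: float = 0.3
    theta: float = 0.5
    n_eqtl: int = 50_000
    n_gwas: int = 50_000
    noise_sd_log10: float = 0.15
    outlier_rate: float = 0.05
    missing_rate: float = 0.1
    swap_allele_rate: float = 0.3  # fraction of GWAS rows stored on the swapped allele
    ki_log10_range: tuple[float, float] = (0.0, 3.5)  # true Ki in [1, ~3000] nM

    def bound_receptors(self, drug: str) -> tuple[str, ...]:
        if self.binding is None:
            return self.receptors
        return tuple(r for r in self.binding.get(drug, ()) if r in self.receptors)


def default_study_config(**overrides) -> StudyConfig:
    """The packaged demo/benchmark study design."""
    return dataclasses.replace(StudyConfig(), **overrides) if overrides else StudyConfig()


def null_screen_config(
    n_genes: int = 100,
    n_phenotypes: int = 10,
    m_snps: int = 11,
    **overrides,
) -> StudyConfig:
    """A study with strong instruments but no true outcome effects anywhere.

    Every (gene, phenotype) locus is null on the outcome side, so every MR
    test in the screen is a true null: the design for measuring the false
    discovery proportion of the FDR gate. One brain tissue keeps the screen
    at exactly ``n_genes * n_phenotypes`` tests.
    """
    return dataclasses.replace(
        StudyConfig(
            receptors=tuple(f"G{i:03d}" for i in range(n_genes)),
            side_effect_map=tuple(
                (f"se{j}", f"ph{j:02d}", True) for j in range(n_phenotypes)
            ),
            causal_pairs=(),
            distinct_pairs=(),
            weak_genes=(),
            brain_tissues=("cortex",),
            m_snps=m_snps,
        ),
        **overrides,
    )


def _gene_layout(cfg: StudyConfig) -> pd.DataFrame:
    rows = []
    for gi, gene in enumerate(cfg.receptors):
        start = 10_000_000 + gi * 5_000_000
        rows.append({"gene": gene, "chr": "1", "start": start, "end": start + 50_000})
    return pd.DataFrame(rows)


def _swap_alleles(df: pd.DataFrame, rate: float, rng: np.random.Generator) -> pd.DataFrame:
    """Store a fraction of rows on the opposite effect allele (beta negated).

    The information is unchanged; harmonization must undo the swap.
    """
    if rate <= 0:
        return df
    out = df.copy()
    mask = rng.random(len(out)) < rate
    out.loc[mask, ["ea", "oa"]] = out.loc[mask, ["oa", "ea"]].to_numpy()
    out.loc[mask, "beta"] = -out.loc[mask, "beta"]
    out.loc[mask, "eaf"] = 1.0 - out.loc[mask, "eaf"]
    return out


def simulate_study(
    config: StudyConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[dict, dict]:
    """Generate a complete input bundle plus its truth manifest.

    Returns ``(bundle, truth)`` where ``bundle`` holds DataFrames keyed
    ``eqtl, genes, gwas (dict phenotype -> frame), affinity,
    side_effect_map, dose`` and ``truth`` records every planted causal
    triple, decoy triple, per-pair true Ki and per-locus scenario. When
    ``out_dir`` is given the bundle is also written in the exact dialects the
    readers consume, plus ``truth.json``.
    """
    cfg = config or StudyConfig()
    rng = np.random.default_rng(seed)
    genes = _gene_layout(cfg)
    se_map = pd.DataFrame(
        list(cfg.side_effect_map),
        columns=["side_effect", "phenotype_id", "brain_relevant"],
    )
    pheno_of_se: dict[str, list[str]] = {}
    for se, ph, _ in cfg.side_effect_map:
        pheno_of_se.setdefault(se, []).append(ph)
    se_of_pheno = {ph: se for se, ph, _ in cfg.side_effect_map}
    phenotypes = sorted(se_of_pheno)
    tissues = list(cfg.brain_tissues) + [cfg.blood_tissue]

    # fixed per-gene locus geometry: SNP ids, alleles, LD, causal indices
    sigma = ar1_corr(cfg.m_snps, cfg.ld_rho)
    chol = np.linalg.cholesky(sigma)
    c1 = cfg.m_snps // 2
    c2 = (c1 + max(1, cfg.m_snps // 4)) % cfg.m_snps
    locus_geo = {}
    for gi, grow in genes.iterrows():
        sub_rng = np.random.default_rng(rng.integers(2**31))
        snps = [f"rs{100000 * (gi + 1) + i}" for i in range(cfg.m_snps)]
        alleles = [
            _ALLELE_PAIRS[int(sub_rng.integers(len(_ALLELE_PAIRS)))]
            for _ in range(cfg.m_snps)
        ]
        locus_geo[grow["gene"]] = (snps, alleles, grow)

    def frame(gene, tissue_or_none, betahat, se, pval, n, pheno=None):
        snps, alleles, grow = locus_geo[gene]
        start = int(grow["start"]) - 200_000
        df = pd.DataFrame(
            {
                "snp": snps,
                "chr": grow["chr"],
                "pos": start + 10_000 * np.arange(cfg.m_snps),
                "ea": [a for a, _ in alleles],
                "oa": [b for _, b in alleles],
                "eaf": cfg.maf,
                "beta": betahat,
                "se": se,
                "pval": pval,
                "n": float(n),
            }
        )
        if tissue_or_none is not None:
            df["gene"] = gene
            df["tissue"] = tissue_or_none
        return df

    # --- eQTL tables: one locus per (gene, tissue)
    eqtl_frames = []
    for gene in cfg.receptors:
        b1 = np.zeros(cfg.m_snps)
        if gene not in cfg.weak_genes:
            b1[c1] = cfg.beta_zx
        for tissue in tissues:
            bh, se, p = _simulate_trait(chol, sigma, b1, cfg.maf, cfg.n_eqtl, rng)
            eqtl_frames.append(frame(gene, tissue, bh, se, p, cfg.n_eqtl))
    eqtl = pd.concat(eqtl_frames, ignore_index=True)

    # --- GWAS tables: per phenotype, concatenated gene loci
    causal_set = set(cfg.causal_pairs)
    distinct_set = set(cfg.distinct_pairs)
    scenarios: dict[str, str] = {}
    gwas: dict[str, pd.DataFrame] = {}
    for pheno in phenotypes:
        se_label = se_of_pheno[pheno]
        parts = []
        for gene in cfg.receptors:
            b2 = np.zeros(cfg.m_snps)
            if gene in cfg.weak_genes:
                scen = "weak_gene"
            elif (gene, se_label) in causal_set:
                scen = "shared"
                b2[c1] = cfg.theta * cfg.beta_zx
            elif (gene, se_label) in distinct_set:
                scen = "distinct"
                b2[c2] = cfg.theta * cfg.beta_zx
            else:
                scen = "null"
            scenarios[f"{gene}|{pheno}"] = scen
            bh, se, p = _simulate_trait(chol, sigma, b2, cfg.maf, cfg.n_gwas, rng)
            parts.append(frame(gene, None, bh, se, p, cfg.n_gwas))
        df = pd.concat(parts, ignore_index=True)
        gwas[pheno] = _swap_alleles(df, cfg.swap_allele_rate, rng)

    # --- binding affinity and dose equivalents
    lo, hi = cfg.ki_log10_range
    truth_ki = {}
    actions = {}
    action_cycle = ["antagonist", "agonist", "inverse_agonist", "partial_agonist"]
    k = 0
    for drug in cfg.drugs:
        for receptor in cfg.bound_receptors(drug):
            truth_ki[(drug, receptor)] = float(10.0 ** rng.uniform(lo, hi))
            actions[(drug, receptor)] = action_cycle[k % len(action_cycle)]
            k += 1
    affinity = simulate_affinity_table(
        cfg.drugs,
        cfg.receptors,
        truth_ki,
        noise_sd_log10=cfg.noise_sd_log10,
        outlier_rate=cfg.outlier_rate,
        missing_rate=cfg.missing_rate,
        seed=int(rng.integers(2**31)),
        actions=actions,
    )
    dose = pd.DataFrame(
        {
            "drug": list(cfg.drugs),
            "dose_equivalent": np.round(rng.uniform(0.5, 2.0, size=len(cfg.drugs)), 3),
        }
    )

    planted = sorted(
        (d, r, s)
        for (r, s) in causal_set
        for d in cfg.drugs
        if r in cfg.bound_receptors(d)
    )
    decoys = sorted(
        (d, r, s)
        for (r, s) in distinct_set
        for d in cfg.drugs
        if r in cfg.bound_receptors(d)
    )
    truth = {
        "seed": seed,
        "planted_triples": [list(t) for t in planted],
        "decoy_triples": [list(t) for t in decoys],
        "causal_pairs": sorted([list(p) for p in causal_set]),
        "distinct_pairs": sorted([list(p) for p in distinct_set]),
        "weak_genes": list(cfg.weak_genes),
        "true_ki_nM": {f"{d}|{r}": v for (d, r), v in sorted(truth_ki.items())},
        "scenario_per_locus": scenarios,
        "theta": cfg.theta,
        "beta_zx": cfg.beta_zx,
    }
    bundle = {
        "eqtl": eqtl,
        "genes": genes,
        "gwas": gwas,
        "affinity": affinity,
        "side_effect_map": se_map,
        "dose": dose,
    }
    if out_dir is not None:
        write_bundle(bundle, truth, out_dir)
    return bundle, truth


def write_bundle(bundle: dict, truth: dict, out_dir: str | Path) -> None:
    """Write a bundle in exactly the dialects the io readers consume."""
    out = Path(out_dir)
    (out / "gwas").mkdir(parents=True, exist_ok=True)
    write_sumstats(bundle["eqtl"], out / "eqtl.tsv")
    bundle["genes"].to_csv(out / "genes.tsv", sep="\t", index=False)
    for pheno, df in sorted(bundle["gwas"].items()):
        write_sumstats(df, out / "gwas" / f"{pheno}.tsv")
    bundle["affinity"].to_csv(out / "affinity.csv", index=False)
    bundle["side_effect_map"].to_csv(out / "side_effect_map.csv", index=False)
    bundle["dose"].to_csv(out / "dose_equivalents.csv", index=False)
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
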