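"""Model and results objects orchestrating the full screening pipeline.

:class:`SideEffectScreen` is built from the five input tables (eQTL summary
statistics with gene annotations, per-phenotype GWAS summary statistics, the
drug-receptor binding table, the side-effect -> phenotype map, and dose
equivalents). ``fit()`` runs

    affinity aggregation -> instrument selection (cis top hits, F > 22)
    -> phenome-wide Wald-ratio screen (joint BH-FDR < 0.05)
    -> colocalization gate (PP4 >= 0.6, PP3 < 0.1)
    -> one result per (side-effect, receptor)
    -> scores with parametric-bootstrap SEs

and returns a :class:`ScreenResults` carrying every stage table, the score
tables with uncertainties, a run manifest and a ``summary()``.

Brain-relevant phenotypes are screened against brain-tissue instruments,
all others against blood; when several tissues pass colocalization for one
(side-effect, receptor) pair the tissue with the highest PP4 supplies the
Wald ratio (ties broken by smaller q-value, larger F, then SNP id).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .affinity import build_affinity_table
from .coloc import coloc_gene_phenotype, route_dataset
from .config import RunConfig
from .mr import bh_fdr, screen, select_instruments
from .scoring import ScoreTables, compute_scores

logger = logging.getLogger("sescore.model")

COLOC_COLUMNS = ["gene", "tissue", "phenotype_id", "n_snps",
                 "pp0", "pp1", "pp2", "pp3", "pp4", "passed"]


class SideEffectScreen:
    """Genetic side-effect screening model for a set of drugs and receptors.

    Parameters
    ----------
    eqtl
        Canonical eQTL summary statistics over every receptor gene's cis
        region (columns snp, chr, pos, ea, oa, eaf, beta, se, pval, n, gene,
        tissue).
    genes
        Gene annotation table (gene, chr, start, end).
    gwas_store
        Object with ``get(phenotype_id) -> DataFrame``; see
        :class:`sescore.io.GwasStore` / :class:`sescore.io.FrameGwasStore`.
    affinity
        Raw binding measurement rows (drug, receptor, ki_nM, action, source).
    side_effect_map
        Mapping (side_effect, phenotype_id, brain_relevant).
    dose
        Per-drug dose equivalents.
    config
        :class:`RunConfig`; defaults mirror the published protocol.
    """

    def __init__(
        self,
        eqtl: pd.DataFrame,
        genes: pd.DataFrame,
        gwas_store,
        affinity: pd.DataFrame,
        side_effect_map: pd.DataFrame,
        dose: pd.DataFrame,
        config: RunConfig | None = None,
    ):
        self.eqtl = eqtl
        self.genes = genes
        self.gwas_store = gwas_store
        self.affinity_raw = affinity
        self.side_effect_map = side_effect_map
        self.dose = dose
        self.config = config or RunConfig()

    # ------------------------------------------------------------- builders
    @classmethod
    def from_files(cls, config: RunConfig) -> "SideEffectScreen":
        """Build the model from the file paths recorded in ``config``."""
        needed = {
            "eqtl_path": config.eqtl_path,
            "genes_path": config.genes_path,
            "gwas_dir": config.gwas_dir,
            "affinity_path": config.affinity_path,
            "side_effect_map_path": config.side_effect_map_path,
            "dose_equivalents_path": config.dose_equivalents_path,
        }
        missing = [k for k, v in needed.items() if not v]
        if missing:
            raise ValueError(f"config is missing input path(s): {missing}")
        return cls(
            eqtl=sio.read_sumstats(config.eqtl_path, eqtl=True),
            genes=sio.read_gene_table(config.genes_path),
            gwas_store=sio.GwasStore(config.gwas_dir),
            affinity=sio.read_affinity_table(config.affinity_path),
            side_effect_map=sio.read_side_effect_map(config.side_effect_map_path),
            dose=sio.read_dose_equivalents(config.dose_equivalents_path),
            config=config,
        )

    @classmethod
    def from_dir(cls, bundle_dir: str | Path, config: RunConfig | None = None) -> "SideEffectScreen":
        """Build from a bundle directory laid out as ``simulate_study`` writes it."""
        d = Path(bundle_dir)
        cfg = (config or RunConfig()).replace(
            eqtl_path=str(d / "eqtl.tsv"),
            genes_path=str(d / "genes.tsv"),
            gwas_dir=str(d / "gwas"),
            affinity_path=str(d / "affinity.csv"),
            side_effect_map_path=str(d / "side_effect_map.csv"),
            dose_equivalents_path=str(d / "dose_equivalents.csv"),
        )
        return cls.from_files(cfg)

    @classmethod
    def from_bundle(cls, bundle: dict, config: RunConfig | None = None) -> "SideEffectScreen":
        """Build directly from an in-memory bundle (``simulate_study`` output)."""
        return cls(
            eqtl=bundle["eqtl"],
            genes=bundle["genes"],
            gwas_store=sio.FrameGwasStore(bundle["gwas"]),
            affinity=bundle["affinity"],
            side_effect_map=bundle["side_effect_map"],
            dose=bundle["dose"],
            config=config,
        )

    # ------------------------------------------------------------ pipeline
    def _gene_interval(self, gene: str) -> tuple[str, int, int]:
        row = self.genes.loc[self.genes["gene"] == gene]
        if row.empty:
            raise KeyError(f"gene '{gene}' absent from gene table")
        r = row.iloc[0]
        return str(r["chr"]), int(r["start"]), int(r["end"])

    def fit_instruments(self) -> pd.DataFrame:
        """Top cis SNP per (gene, tissue), F-filtered at config.f_min."""
        cfg = self.config
        parts = []
        for gene in sorted(self.genes["gene"]):
            parts.append(
                select_instruments(
                    self.eqtl, gene, self._gene_interval(gene), cfg.cis_window_bp
                )
            )
        inst = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
        if inst.empty:
            inst = pd.DataFrame(columns=list(self.eqtl.columns) + ["f_stat", "weak"])
            inst.attrs["n_weak"] = 0
            return inst
        inst["weak"] = inst["f_stat"] <= cfg.f_min
        n_weak = int(inst["weak"].sum())
        if n_weak:
            logger.info("instruments: %d flagged weak (F <= %g) and excluded",
                        n_weak, cfg.f_min)
        out = inst[~inst["weak"]].reset_index(drop=True)
        out.attrs["n_weak"] = n_weak
        out.attrs["n_selected"] = len(inst)
        return out

    def fit_screen(self, instruments: pd.DataFrame) -> pd.DataFrame:
        """Phenome-wide MR screen with dataset routing and one joint FDR pass."""
        cfg = self.config
        semap = self.side_effect_map
        brain = set(cfg.brain_tissues)
        inst_brain = instruments[instruments["tissue"].isin(brain)]
        inst_blood = instruments[instruments["tissue"] == cfg.blood_tissue]
        parts, n_skipped = [], 0
        for relevant, inst in ((True, inst_brain), (False, inst_blood)):
            sub_map = semap[semap["brain_relevant"] == relevant]
            if sub_map.empty or inst.empty:
                continue
            res = screen(inst, self.gwas_store, sub_map, cfg)
            n_skipped += res.attrs.get("n_skipped", 0)
            parts.append(res)
        if not parts:
            out = pd.DataFrame()
            out.attrs["n_skipped"] = n_skipped
            return out
        out = pd.concat(parts, ignore_index=True)
        # joint BH across the entire screen (brain + blood)
        out["qval"] = bh_fdr(out["pval"].to_numpy())
        out["pass_fdr"] = out["qval"] < cfg.fdr
        out = out.sort_values(
            ["gene", "tissue", "side_effect", "phenotype_id"], kind="mergesort"
        ).reset_index(drop=True)
        out.attrs["n_skipped"] = n_skipped
        return out

    def fit_coloc(self, survivors: pd.DataFrame) -> pd.DataFrame:
        """Colocalization for every FDR-surviving (gene, tissue, phenotype) locus."""
        cfg = self.config
        rows = []
        seen = survivors[["gene", "tissue", "phenotype_id"]].drop_duplicates()
        for _, r in seen.sort_values(list(seen.columns), kind="mergesort").iterrows():
            res = coloc_gene_phenotype(
                self.eqtl,
                self.gwas_store.get(r["phenotype_id"]),
                r["gene"],
                r["tissue"],
                self._gene_interval(r["gene"]),
                cfg,
            )
            if res is None:
                continue
            rows.append(
                {
                    "gene": r["gene"],
                    "tissue": r["tissue"],
                    "phenotype_id": r["phenotype_id"],
                    "n_snps": res.n_snps,
                    **{f"pp{i}": res.pp[i] for i in range(5)},
                    "passed": res.passed,
                }
            )
        return pd.DataFrame(rows, columns=COLOC_COLUMNS)

    @staticmethod
    def _select_per_pair(gated: pd.DataFrame) -> pd.DataFrame:
        """One result per (side_effect, gene): best PP4, then q, F, SNP id."""
        if gated.empty:
            return gated
        ordered = gated.sort_values(
            ["side_effect", "gene", "pp4", "qval", "f_stat", "snp"],
            ascending=[True, True, False, True, False, True],
            kind="mergesort",
        )
        return (
            ordered.groupby(["side_effect", "gene"], sort=True)
            .head(1)
            .reset_index(drop=True)
        )

    def fit(self, seed: int | None = None, n_boot: int | None = None) -> "ScreenResults":
        """Run the full pipeline and return a :class:`ScreenResults`."""
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        affinity = build_affinity_table(self.affinity_raw, cfg)
        instruments = self.fit_instruments()
        mr_results = self.fit_screen(instruments)
        survivors = (
            mr_results[mr_results["pass_fdr"]]
            if len(mr_results)
            else mr_results
        )
        coloc_results = self.fit_coloc(survivors)
        if len(coloc_results) and len(survivors):
            gated = survivors.merge(
                coloc_results, on=["gene", "tissue", "phenotype_id"], how="inner"
            )
            gated = gated[gated["passed"]]
        else:
            gated = survivors.iloc[0:0].copy()
            for c in ("pp4",):
                gated[c] = pd.Series(dtype=float)
        selected = self._select_per_pair(gated)
        scores = compute_scores(
            selected, affinity, self.dose, cfg, seed=seed, n_boot=n_boot
        )
        manifest = {
            "config_hash": cfg.config_hash(),
            "seed": seed,
            "n_boot": cfg.n_boot if n_boot is None else n_boot,
            "version": _version(),
            "counts": {
                "instruments_selected": int(instruments.attrs.get("n_selected", len(instruments))),
                "instruments_weak": int(instruments.attrs.get("n_weak", 0)),
                "instruments_used": len(instruments),
                "screen_results": len(mr_results),
                "screen_skipped": int(mr_results.attrs.get("n_skipped", 0)),
                "fdr_survivors": len(survivors),
                "coloc_tested": len(coloc_results),
                "coloc_passed": int(coloc_results["passed"].sum()) if len(coloc_results) else 0,
                "selected_pairs": len(selected),
                "score_terms": len(scores.terms),
                "score_entries": len(scores.entries),
            },
        }
        return ScreenResults(
            model=self,
            config=cfg,
            seed=seed,
            affinity=affinity,
            instruments=instruments,
            mr_results=mr_results,
            coloc_results=coloc_results,
            selected=selected,
            scores=scores,
            manifest=manifest,
        )


def _version() -> str:
    from . import __version__

    return __version__


@dataclass
class ScreenResults:
    """Fitted results: stage tables, score tables with bootstrap SEs, manifest."""

    model: SideEffectScreen
    config: RunConfig
    seed: int
    affinity: pd.DataFrame
    instruments: pd.DataFrame
    mr_results: pd.DataFrame
    coloc_results: pd.DataFrame
    selected: pd.DataFrame
    scores: ScoreTables
    manifest: dict = field(default_factory=dict)

    # convenient aliases
    @property
    def score_entries(self) -> pd.DataFrame:
        return self.scores.entries

    @property
    def drug_scores(self) -> pd.DataFrame:
        return self.scores.drugs

    @property
    def score_table(self) -> pd.DataFrame:
        """Evidence table: one row per (drug, side-effect, receptor) term with
        the SNP, Wald ratio, colocalization PP4, eQTL source tissue and the
        signed score contribution."""
        t = self.scores.terms
        if t.empty:
            return t
        cols = [
            "drug", "side_effect", "receptor", "snp", "tissue", "phenotype_id",
            "beta_iv", "se_iv", "qval", "pp4", "pki", "a_d", "direction",
            "signed_value", "used_default_pki",
        ]
        return t[[c for c in cols if c in t.columns]].copy()

    def summary(self) -> str:
        """Human-readable run summary (stage counts and top score entries)."""
        c = self.manifest.get("counts", {})
        lines = [
            "Side-effect screening results",
            "=" * 64,
            f"instruments: {c.get('instruments_used', 0)} used"
            f" ({c.get('instruments_weak', 0)} weak excluded, F <= {self.config.f_min:g})",
            f"MR screen:   {c.get('screen_results', 0)} tests,"
            f" {c.get('fdr_survivors', 0)} pass FDR < {self.config.fdr:g}",
            f"coloc:       {c.get('coloc_passed', 0)}/{c.get('coloc_tested', 0)} loci pass"
            f" (PP4 >= {self.config.h4_min:g}, PP3 < {self.config.h3_max:g})",
            f"scores:      {c.get('score_entries', 0)} (drug, side-effect) entries"
            f" from {c.get('score_terms', 0)} receptor terms"
            f" [bootstrap n = {self.manifest.get('n_boot')}]",
            "-" * 64,
        ]
        if len(self.scores.drugs):
            lines.append("drug totals (absolute aggregation):")
            for _, r in self.scores.drugs.iterrows():
                lines.append(
                    f"  {r['drug']:<16} S_d = {r['abs_score']:8.3f}"
                    f" (SE {r['se_abs']:.3f}), {int(r['n_side_effects'])} side-effect(s)"
                )
        if len(self.scores.entries):
            top = self.scores.entries.sort_values("abs_score", ascending=False).head(10)
            lines.append("top (drug, side-effect) entries:")
            for _, r in top.iterrows():
                lines.append(
                    f"  {r['drug']:<14} {r['side_effect']:<18}"
                    f" S = {r['score']:8.3f} (SE {r['se']:.3f}),"
                    f" |S| = {r['abs_score']:.3f}"
                )
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> Path:
        """Write every stage table (TSV), the score tables and the manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = sio.FLOAT_FMT

        def w(df: pd.DataFrame, name: str):
            df.to_csv(out / name, sep="\t", index=False, float_format=fmt)

        w(self.affinity, "affinity_summary.tsv")
        w(self.instruments, "instruments.tsv")
        w(self.mr_results, "mr_screen.tsv")
        w(self.coloc_results, "coloc.tsv")
        w(self.selected, "selected.tsv")
        w(self.scores.terms, "score_terms.tsv")
        w(self.scores.entries, "score_entries.tsv")
        w(self.scores.drugs, "drug_scores.tsv")
        w(self.scores.per_receptor, "per_receptor.tsv")
        w(self.scores.per_side_effect, "per_side_effect.tsv")
        w(self.scores.breakdown, "breakdown.tsv")
        w(self.scores.classification, "classification.tsv")
        w(self.score_table, "score_table.tsv")
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=1, sort_keys=True))
        return out

    def plot_profile(self, ax=None):
        """Bar chart of cumulative absolute side-effect burden per drug."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        d = self.scores.drugs
        ax.bar(d["drug"], d["abs_score"], yerr=d["se_abs"], capsize=4)
        ax.set_ylabel("cumulative |score|")
        ax.set_title("Predicted side-effect burden per drug")
        return ax
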