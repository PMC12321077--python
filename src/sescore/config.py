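"""Run configuration: thresholds, priors and input paths for a full screen.

Every analysis constant has a single home here so that the pipeline stages
never hard-code a threshold. The defaults mirror the published protocol:
instrument F > 22, screen FDR < 0.05, colocalization gate H4 >= 0.6 and
H3 < 0.1, binding measurements >= 10,000 nM discarded, trimmed mean with
trim proportion 0.1, default (unmeasured) binding pKi = 0.824 (SE 0.15),
parametric bootstrap with 1000 iterations, +/- 1 Mb cis window, and the
nM -> M conversion factor 1e-8 used by the pKi scaling.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Receptors intentionally targeted for the therapeutic (antipsychotic) effect.
ON_TARGET_RECEPTORS = ("DRD2", "DRD3", "DRD4", "HTR2A", "HTR2C")
#: Receptors with weaker, suspected involvement in the therapeutic effect.
SUSPECTED_TARGET_RECEPTORS = ("GABRA5", "HRH2", "HRH3")

#: Brain eQTL tissue labels; everything else routes to the blood dataset.
BRAIN_TISSUES = ("basal_ganglia", "cerebellum", "cortex", "hippocampus", "spinal_cord")
BLOOD_TISSUE = "blood"


@dataclass
class RunConfig:
    """All tunable parameters of a screening run.

    Round-trips losslessly through YAML (``to_yaml`` / ``from_yaml``) and
    validates its thresholds eagerly so a bad config fails before any
    computation starts.
    """

    # --- input paths (may stay None when the model is built from DataFrames)
    eqtl_path: str | None = None
    genes_path: str | None = None
    gwas_dir: str | None = None
    affinity_path: str | None = None
    side_effect_map_path: str | None = None
    dose_equivalents_path: str | None = None
    out_dir: str | None = None

    # --- gate thresholds
    fdr: float = 0.05
    f_min: float = 22.0
    h4_min: float = 0.6
    h3_max: float = 0.1

    # --- binding affinity handling
    ki_discard_nm: float = 10_000.0
    trim: float = 0.1
    default_pki: float = 0.824
    default_pki_se: float = 0.15
    nm_to_m: float = 1e-8  # printed conversion; physical would be 1e-9

    # --- MR / instruments
    cis_window_bp: int = 1_000_000
    second_order_se: bool = False  # Wald-ratio SE: include exposure-SE term

    # --- colocalization priors
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    prior_sd_quant: float = 0.15
    prior_sd_binary: float = 0.2

    # --- bootstrap
    n_boot: int = 1000
    seed: int = 0

    # --- metadata
    genome_build: str = "GRCh38"
    brain_tissues: tuple[str, ...] = BRAIN_TISSUES
    blood_tissue: str = BLOOD_TISSUE
    on_target_receptors: tuple[str, ...] = ON_TARGET_RECEPTORS
    suspected_target_receptors: tuple[str, ...] = SUSPECTED_TARGET_RECEPTORS

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Raise ``ValueError`` on any threshold outside its documented range."""
        checks = [
            (0 < self.fdr < 1, "fdr must be in (0, 1)"),
            (self.f_min >= 0, "f_min must be >= 0"),
            (0 <= self.h4_min <= 1, "h4_min must be in [0, 1]"),
            (0 <= self.h3_max <= 1, "h3_max must be in [0, 1]"),
            (self.ki_discard_nm > 0, "ki_discard_nm must be positive"),
            (0 <= self.trim < 0.5, "trim must be in [0, 0.5)"),
            (self.default_pki_se >= 0, "default_pki_se must be >= 0"),
            (self.nm_to_m > 0, "nm_to_m must be positive"),
            (self.cis_window_bp > 0, "cis_window_bp must be positive"),
            (self.n_boot >= 2, "n_boot must be >= 2"),
            (
                all(p > 0 for p in (self.coloc_p1, self.coloc_p2, self.coloc_p12)),
                "coloc priors must be positive",
            ),
            (
                self.prior_sd_quant > 0 and self.prior_sd_binary > 0,
                "coloc prior SDs must be positive",
            ),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: {msg}")

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        for f in dataclasses.fields(cls):
            if f.name in kwargs and isinstance(kwargs[f.name], list):
                kwargs[f.name] = tuple(kwargs[f.name])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """Stable hash of the full configuration, recorded in run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)
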