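"""Pipeline configuration with the analysis' standard thresholds as defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

from .datatypes import ValidationError
from .io import write_json


@dataclass
class PipelineConfig:
    """Thresholds and paths driving the staged pipeline.

    Defaults encode the analysis contract: correlation gate at BH FDR 1%
    with |rho| >= 0.4, DC calls at FDR 1%, module ORA at FDR 5%, DE flags at
    FDR 0.05/0.1/0.2, a 20-gene module minimum and 10 enrichment
    permutations.
    """

    fdr_corr: float = 0.01
    rho_min: float = 0.4
    fdr_dc: float = 0.01
    fdr_ora: float = 0.05
    de_cutoffs: tuple[float, ...] = (0.05, 0.1, 0.2)
    min_module_genes: int = 20
    n_perm: int = 10
    min_group_size: int = 10
    covariates: tuple[str, ...] = ("age", "sex", "RIN")
    seed: int = 0
    block_size: int = 512

    def validate(self) -> None:
        for name in ("fdr_corr", "fdr_dc", "fdr_ora"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValidationError(f"config field {name}={v} must be in (0, 1]")
        if not 0 <= self.rho_min <= 1:
            raise ValidationError(f"config field rho_min={self.rho_min} must be in [0, 1]")
        for name in ("min_module_genes", "n_perm", "block_size"):
            if getattr(self, name) < 1:
                raise ValidationError(f"config field {name} must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["de_cutoffs"] = list(self.de_cutoffs)
        d["covariates"] = list(self.covariates)
        return d

    def write(self, out_dir: str | Path) -> None:
        """Serialize the resolved config (provenance) into an output directory."""
        write_json(self.to_dict(), Path(out_dir) / "config.json")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config field(s): {sorted(unknown)}")
        d = dict(d)
        for tup in ("de_cutoffs", "covariates"):
            if tup in d:
                d[tup] = tuple(d[tup])
        cfg = cls(**d)
        cfg.validate()
        return cfg
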