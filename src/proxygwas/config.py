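"""Configuration for the synthetic trio-cohort simulator.

The defaults describe the standard study conditions used throughout the
package's validation runs: 20,000 genotyped offspring, 2,000 autosomal SNPs
of which 50 carry a per-allele log-odds effect of 0.18 on parental disease,
maternal/paternal disease prevalences of 0.096 and 0.055, and plausible
informant-report error (sensitivity 0.85, specificity 0.99).
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field

import yaml


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    # cohort dimensions
    n_offspring: int = 20_000
    n_snps: int = 2_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    bp_spacing: int = 10_000

    # genetic architecture of parental disease; causal_log_or is a scalar
    # applied to every causal SNP or a sequence of per-SNP values
    n_causal: int = 50
    causal_log_or: float | tuple = 0.18

    # disease prevalences (population risk of the parental disease)
    k_maternal: float = 0.096
    k_paternal: float = 0.055

    # informant-report misclassification
    report_sensitivity: float = 0.85
    report_specificity: float = 0.99

    # parental age model (years); drives the age-based exclusion rules
    parent_age_mean: float = 78.0
    parent_age_sd: float = 9.0
    p_death_before_60: float = 0.04
    p_missing_age: float = 0.02

    # covariate structure
    n_centres: int = 5
    n_batches: int = 10
    n_arrays: int = 2
    n_pcs: int = 10
    covariate_report_effect: float = 0.0

    # optional LD structure: haplotypes are correlated within blocks of
    # `ld_block_size` adjacent SNPs with Gaussian-copula parameter `ld_rho`
    ld_block_size: int = 1
    ld_rho: float = 0.0

    seed: int = 0

    def __post_init__(self) -> None:
        self.maf_range = tuple(float(x) for x in self.maf_range)
        self.validate()

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.01 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must lie within (0.01, 0.5], got {self.maf_range}")
        if self.n_offspring < 1 or self.n_snps < 1:
            raise ConfigError("n_offspring and n_snps must be positive")
        if not 0 <= self.n_causal <= self.n_snps:
            raise ConfigError(f"n_causal ({self.n_causal}) must be in [0, n_snps]")
        if not isinstance(self.causal_log_or, (int, float)):
            self.causal_log_or = tuple(float(x) for x in self.causal_log_or)
            if len(self.causal_log_or) != self.n_causal:
                raise ConfigError(
                    f"causal_log_or sequence length {len(self.causal_log_or)} "
                    f"!= n_causal {self.n_causal}"
                )
        if not (0.0 < self.k_paternal <= self.k_maternal < 1.0):
            raise ConfigError(
                "prevalences must satisfy 0 < k_paternal <= k_maternal < 1, "
                f"got maternal={self.k_maternal}, paternal={self.k_paternal}"
            )
        for name in (
            "report_sensitivity",
            "report_specificity",
            "p_death_before_60",
            "p_missing_age",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a probability in [0, 1], got {v}")
        if self.ld_block_size < 1 or not -1.0 < self.ld_rho < 1.0:
            raise ConfigError("ld_block_size >= 1 and |ld_rho| < 1 required")
        if self.parent_age_sd <= 0:
            raise ConfigError("parent_age_sd must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, value in d.items():
            if isinstance(value, (bool, int, float)) or value is None:
                continue
            if hasattr(value, "item"):  # numpy scalar
                d[key] = value.item()
        d["maf_range"] = [float(x) for x in self.maf_range]
        if not isinstance(self.causal_log_or, (int, float)):
            d["causal_log_or"] = [float(x) for x in self.causal_log_or]
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def config_hash(self) -> str:
        """Stable hash of the full configuration (logged with every run)."""
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
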