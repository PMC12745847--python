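"""Simulation configuration and named presets.

The default configuration describes a "desk-scale" version of a continuously
monitored nestbox population: a ~4 km woodland with a few hundred usable
boxes, 25-50% spring occupancy, roughly half of each year's breeders arriving
as immigrants from a weakly differentiated external pool, and female-biased
natal dispersal (median just over 1 km for females, ~700 m for males, ratio
1.5).  Genotypes are biallelic SNPs on several autosomes plus a Z chromosome
inherited under ZW rules.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["SimulationConfig", "desk_preset", "field_preset", "load_config"]


@dataclass
class SimulationConfig:
    # landscape
    n_boxes: int = 250
    extent_m: float = 4000.0
    # demography
    occupancy: float = 0.25
    adult_survival: float = 0.5
    recruit_prob: float = 0.12
    clutch_size_mean: float = 7.0
    immigration_fill: float = 0.5
    n_years: int = 20
    # natal dispersal
    disp_median_male_m: float = 700.0
    disp_median_female_m: float = 1050.0
    disp_log_sigma: float = 0.6
    kernel_family: str = "lognormal"  # or "weibull"
    # genetics
    n_autosomal_snps: int = 5000
    n_z_snps: int = 500
    n_autosomes: int = 10
    autosome_length_bp: int = 60_000_000
    z_length_bp: int = 75_000_000
    recomb_cm_per_mb: float = 1.0
    founder_maf_beta: tuple[float, float] = (2.0, 2.0)
    immigrant_divergence_fst: float = 0.001
    epp_rate: float = 0.0
    epp_radius_m: float = 500.0
    track_genotypes: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("occupancy", "adult_survival", "recruit_prob",
                     "immigration_fill", "epp_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.extent_m <= 0:
            raise ValueError("extent_m must be positive")
        if self.n_boxes < 2:
            raise ValueError("need at least 2 nest boxes")
        if self.disp_median_female_m < self.disp_median_male_m:
            raise ValueError("female dispersal median must be >= male median")
        if self.immigrant_divergence_fst < 0:
            raise ValueError("immigrant_divergence_fst must be >= 0")
        if self.kernel_family not in ("lognormal", "weibull"):
            raise ValueError(f"unknown kernel_family {self.kernel_family!r}")

    @property
    def chrom_names(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_autosomes)] + ["Z"]

    @property
    def chrom_lengths_bp(self) -> dict[str, int]:
        d = {str(i + 1): self.autosome_length_bp for i in range(self.n_autosomes)}
        d["Z"] = self.z_length_bp
        return d

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["founder_maf_beta"] = list(d["founder_maf_beta"])
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "founder_maf_beta" in d:
            d["founder_maf_beta"] = tuple(d["founder_maf_beta"])
        return cls(**d)


def desk_preset(**overrides) -> SimulationConfig:
    """Default desk-scale run: ~1,000-1,500 genotyped breeders over 20 years."""
    return SimulationConfig(**overrides)


def field_preset(**overrides) -> SimulationConfig:
    """Larger preset at the 10K-chip scale (~2,600 genotyped, 10,000 SNPs)."""
    base = dict(
        n_boxes=1019,
        occupancy=0.25,
        n_years=22,
        n_autosomal_snps=9000,
        n_z_snps=1000,
    )
    base.update(overrides)
    return SimulationConfig(**base)


_PRESETS = {"desk": desk_preset, "field": field_preset,
            "field_scale": field_preset}


def load_config(path: str | Path | None = None, preset: str | None = None,
                **overrides) -> SimulationConfig:
    """Build a config from a YAML/JSON file, a named preset, or both."""
    d: dict = {}
    if preset is not None:
        d = _PRESETS[preset]().to_dict()
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        d.update(loaded)
    d.update(overrides)
    return SimulationConfig.from_dict(d) if d else SimulationConfig()
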