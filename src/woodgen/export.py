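"""Disk export of a completed simulation: VCF + PLINK text genotypes,
pedigree and location CSVs, and the configuration as JSON."""

from __future__ import annotations

from pathlib import Path

from . import genio
from .simulate import SimResult

__all__ = ["export_simulation"]


def export_simulation(sim: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write genotypes (VCF and PLINK .ped/.map), pedigree.csv,
    locations.csv, breeding.csv and config.json; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ped = sim.individuals.rename(columns={"dam": "dam", "sire": "sire"})
    paths["pedigree"] = outdir / "pedigree.csv"
    ped.to_csv(paths["pedigree"], index=False)

    paths["locations"] = outdir / "locations.csv"
    sim.nestbox_map.to_frame().to_csv(paths["locations"], index=False)

    paths["breeding"] = outdir / "breeding.csv"
    sim.breeding.to_csv(paths["breeding"], index=False)

    paths["config"] = outdir / "config.json"
    sim.config.to_json(paths["config"])

    if sim.genome is not None:
        g = genio.from_simulation(sim)
        paths["vcf"] = outdir / "genotypes.vcf"
        genio.write_vcf(g, paths["vcf"])
        genio.write_plink(g, outdir / "genotypes")
        paths["plink"] = outdir / "genotypes.ped"
    return paths
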