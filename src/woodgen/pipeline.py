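"""End-to-end replay: simulate a population, then run every analysis stage
(QC, kinship, isolation by distance, temporal renewal, immigrant
classification, F_ST scan, ROH) and bundle the results.

The run manifest records the seed, a hash of the configuration and SHA-256
digests of every written file, so identical seed + config reproduce
byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import divscan, genio, kincalc, migclass, renewal, spatial
from .config import SimulationConfig
from .export import export_simulation
from .simulate import run_simulation

__all__ = ["replay", "RunManifest"]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: dict = field(default_factory=dict)
    digests: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)

    def to_json(self, path: Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2,
                                         sort_keys=True, default=str))


def _digest(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def replay(config: SimulationConfig, outdir: str | Path,
           max_pair_individuals: int = 600, n_boot: int = 100,
           area_k: int = 30, write_genotypes: bool = False) -> dict:
    """Run the full pipeline on one simulated population.

    Pairwise stages subsample to at most ``max_pair_individuals`` genotyped
    breeders to keep the pair count tractable.  Returns the report dict
    (also written to ``outdir/report.json`` with stage CSVs alongside).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_text = json.dumps(config.to_dict(), sort_keys=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_text.encode()).hexdigest()[:16],
        seed=config.seed)
    report: dict = {"seed": config.seed, "config": config.to_dict()}
    rng = np.random.default_rng(config.seed + 1)
    t0 = time.time()

    def stage_done(name, ok=True, note=""):
        manifest.stages[name] = {"ok": ok, "note": note}
        manifest.timings_s[name] = round(time.time() - t0, 3)

    try:
        sim = run_simulation(config)
        if sim.extinct:
            report["extinct_year"] = sim.extinct_year
            stage_done("simwood", ok=False,
                       note=f"extinct at year {sim.extinct_year}")
            _finish(report, manifest, outdir)
            return report
        stage_done("simwood")

        g = genio.from_simulation(sim)
        g_qc, qc_report = genio.apply_qc(g)
        report["qc"] = qc_report.to_dict()
        splits = genio.split_datasets(g_qc)
        g_auto, g_z = splits["autosomal"], splits["z_only"]
        kept = genio.ld_prune(g_auto)
        g_pruned = g_auto.select_loci(kept)
        report["n_pruned_loci"] = int(len(kept))
        stage_done("genio")

        # subsample breeders for pairwise stages
        n = g_auto.n_samples
        if n > max_pair_individuals:
            sel = np.sort(rng.choice(n, size=max_pair_individuals,
                                     replace=False))
        else:
            sel = np.arange(n)
        ga = g_auto.select_samples(sel)
        gz = g_z.select_samples(sel) if g_z.n_loci else None

        pairs = kincalc.mom_ibd(ga)
        king = kincalc.king_robust(ga)
        pairs = pairs.merge(king[["id_a", "id_b", "phi"]], on=["id_a", "id_b"])
        pairs["degree"] = kincalc.classify_degree(pairs["phi"].to_numpy())
        pairs = spatial.pair_table(pairs, sim.individuals, sim.breeding,
                                   sim.nestbox_map)
        pairs.to_csv(outdir / "pairs.csv", index=False)
        stage_done("kincalc")

        pcs = spatial.pca(g_pruned, n_components=15)
        report["pc_variance"] = pcs.variance_explained[:5].tolist()

        curves = {}
        for level in ("none", "no_first", "no_first_second"):
            sub = spatial.strip_kin(pairs, level=level)
            curves[level] = spatial.decay_curve(sub, n_boot=n_boot,
                                                seed=config.seed,
                                                stratum=level).to_frame()
        pd.concat(curves.values()).to_csv(outdir / "decay_curves.csv",
                                          index=False)
        fits = spatial.stratified_fit(pairs, n_boot=min(n_boot, 50),
                                      seed=config.seed)
        report["ibd_distance_fits"] = [
            dict(stratum=f.stratum, beta_std=f.beta_std,
                 beta_std_ci=list(f.beta_std_ci), beta_per_km=f.beta_per_km,
                 n_pairs=f.n_pairs) for f in fits]
        if gz is not None:
            zpairs = spatial.z_relatedness(gz)
            zpairs = spatial.pair_table(zpairs, sim.individuals, sim.breeding,
                                        sim.nestbox_map)
            contrast = spatial.chrom_sex_contrast(pairs, zpairs,
                                                  n_boot=min(n_boot, 50),
                                                  seed=config.seed)
            pd.concat([c.to_frame() for c in contrast.values()]).to_csv(
                outdir / "chrom_sex_curves.csv", index=False)
            report["mean_pi_z"] = float(np.nanmean(zpairs["pi_z"]))
            report["mean_pi_auto"] = float(np.nanmean(pairs["pi_hat"]))
        stage_done("spatial")

        try:
            sel_areas = renewal.select_areas(sim.nestbox_map, k=area_k)
            # cohort analysis needs the birds actually born in the two
            # focal areas, not the generic subsample
            members = (set(sel_areas.member_boxes_a.tolist())
                       | set(sel_areas.member_boxes_b.tolist()))
            area_ids = sim.individuals[
                sim.individuals["natal_box"].isin(members)]["id"]
            amask = g_auto.samples["id"].isin(area_ids).to_numpy()
            if amask.sum() >= 10:
                g_area = g_auto.select_samples(np.flatnonzero(amask))
                area_pairs = kincalc.mom_ibd(g_area)
            else:
                area_pairs = pairs
            lcurves = renewal.lag_curve(area_pairs, sel_areas,
                                        sim.individuals,
                                        n_boot=n_boot, seed=config.seed)
            pd.concat([c.to_frame() for c in lcurves.values()]).to_csv(
                outdir / "lag_curves.csv", index=False)
            report["renewal"] = {
                "baseline": lcurves["A"].baseline,
                "crossing_lag": {a: c.crossing_lag
                                 for a, c in lcurves.items()},
                "density_boxes_per_ha": list(sel_areas.density_boxes_per_ha)}
            stage_done("renewal")
        except ValueError as exc:
            stage_done("renewal", ok=False, note=str(exc))

        status = g_pruned.samples["status"].to_numpy()
        if (config.immigration_fill > 0 and len(np.unique(status)) == 2
                and min(np.bincount(pd.factorize(status)[0])) >= 10):
            cfg_rf = migclass.ClassifierConfig(seed=config.seed,
                                               n_repeats=20, n_forests=20,
                                               trees_per_forest=200)
            rep = migclass.rf_ensemble(pcs.scores, status, cfg_rf,
                                       sample_ids=pcs.sample_ids,
                                       with_null=True)
            report["classifier"] = rep.to_dict()

            k_sub = min(50, int((rep.vote_fraction["label"]
                                 == "immigrant").sum()),
                        int((rep.vote_fraction["label"] == "local").sum()))
            phi_sub = king
            top_imm, top_loc, screen = divscan.extreme_subsets(
                rep.mds, rep.vote_fraction["label"].to_numpy(),
                rep.sample_ids, k=k_sub, phi_pairs=phi_sub)
            per_snp = divscan.fst_per_snp(g_auto, g_auto.samples["status"]
                                          .to_numpy())
            report["fst_all"] = divscan.global_fst(per_snp)
            ids_sub = set(top_imm.tolist()) | set(top_loc.tolist())
            mask = g_auto.samples["id"].isin(ids_sub).to_numpy()
            g_top = g_auto.select_samples(np.flatnonzero(mask))
            per_snp_top = divscan.fst_per_snp(
                g_top, g_top.samples["status"].to_numpy())
            report["fst_top_subsets"] = divscan.global_fst(per_snp_top)
            report["kinship_screen"] = _jsonable(screen)
            divscan.window_fst(per_snp).to_csv(outdir / "fst_windows.csv",
                                               index=False)
            stage_done("migclass+divscan")
        else:
            report["classifier"] = None
            stage_done("migclass+divscan", ok=False,
                       note="closed population: immigrant analyses skipped")

        # g is the raw simulated matrix (no MAF/LD filtering applied);
        # the rare-variant heuristic misfires on founder-pool frequencies
        roh = kincalc.detect_roh(g, kincalc.RohParams(
            window_snp=20, min_snp=25, min_kb=2000.0,
            min_density_kb_per_snp=500.0, max_gap_kb=5000.0),
            allow_filtered=True)
        genome_kb = sum(v for k, v in config.chrom_lengths_bp.items()
                        if k != "Z") / 1000.0
        summ = kincalc.roh_sample_summary(roh, g.samples["id"], genome_kb)
        summ = summ.merge(g.samples[["id", "status"]],
                          left_on="sample_id", right_on="id")
        report["roh"] = {
            status: {"mean_n_roh": float(grp["n_roh"].mean()),
                     "mean_froh": float(grp["froh"].mean())}
            for status, grp in summ.groupby("status")}
        stage_done("kincalc_roh")
        if write_genotypes:
            export_simulation(sim, outdir / "data")
    except Exception as exc:  # pragma: no cover - partial-failure path
        stage_done("FAILED", ok=False, note=repr(exc))
        _finish(report, manifest, outdir)
        raise

    _finish(report, manifest, outdir)
    return report


def _finish(report: dict, manifest: RunManifest, outdir: Path) -> None:
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(_jsonable(report), indent=2,
                                      sort_keys=True))
    for p in sorted(outdir.glob("*.csv")) + [report_path]:
        manifest.digests[p.name] = _digest(p)
    manifest.to_json(outdir / "manifest.json")
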