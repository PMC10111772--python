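"""End-to-end orchestration: configure once, run the stages in dependency
order, and leave a manifest recording inputs, parameters, seeds, and row
counts.

A run starts either from a VCF + population map or from the built-in
simulator; every stage writes TSV/JSON (trees as Newick) into the output
directory.  The top-level seed fans out to per-stage seeds by a fixed
derivation so any stage can be re-run in isolation reproducibly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity as dv
from . import introgression as ig
from . import mutation_load as ml
from . import relatedness as rel
from . import roh as rh
from . import synthetic_data as sd
from .variant_store import (ConfigurationError, FilterConfig,
                            PopulationSpec, apply_site_filters,
                            polarize_by_outgroup, read_bed, read_vcf)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "filter", "polarize", "diversity", "fst",
              "relatedness", "pca", "nj", "roh", "inbreeding", "dstat",
              "f4ratio", "load", "sfs", "rxy", "report")

#: stages that require polarized (outgroup-oriented) sites
NEEDS_POLARIZATION = {"dstat", "f4ratio", "load", "sfs", "rxy"}


@dataclass
class RunConfig:
    output_dir: str
    seed: int = 0
    # inputs (either a VCF+map, or simulate=True)
    vcf: str | None = None
    population_map: str | None = None
    outgroup: str | None = None          # outgroup population label
    gaps_bed: str | None = None
    gff3: str | None = None
    fasta: str | None = None
    quartets: str | None = None
    simulate: bool = False
    sim_preset: str = "founder_captive"  # founder_captive | purging_pair | neutral
    sim_options: dict = field(default_factory=dict)
    # stage parameters
    stages: tuple[str, ...] = ALL_STAGES
    filter_options: dict = field(default_factory=dict)
    window_length: int = 20_000
    window_step: int = 10_000
    roh_options: dict = field(default_factory=dict)
    block_size: int = 1000
    fdr: float = 0.05
    fst_estimator: str = "wc84"
    bootstrap_reps: int = 100
    genome_length: int | None = None

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31)


def _validate(cfg: RunConfig) -> None:
    unknown = set(cfg.stages) - set(ALL_STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
    if not cfg.simulate and cfg.vcf is None:
        raise ConfigurationError("either simulate=True or a VCF is required")
    for path_attr in ("vcf", "population_map", "gaps_bed", "gff3", "fasta",
                      "quartets"):
        p = getattr(cfg, path_attr)
        if p is not None and not Path(p).exists():
            raise ConfigurationError(f"{path_attr} path does not exist: {p}")
    needing = NEEDS_POLARIZATION & set(cfg.stages)
    if needing and "polarize" not in cfg.stages:
        raise ConfigurationError(
            f"stages {sorted(needing)} require the 'polarize' stage (an "
            f"outgroup-polarized matrix)")
    if needing and cfg.outgroup is None and not cfg.simulate:
        raise ConfigurationError(
            f"stages {sorted(needing)} require an outgroup population")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages; returns the manifest (also written to
    ``manifest.json``).  Configuration errors are raised before any stage
    runs; a stage failure is recorded without corrupting earlier outputs."""
    _validate(cfg)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "parameters": {
        "window_length": cfg.window_length, "window_step": cfg.window_step,
        "block_size": cfg.block_size, "fdr": cfg.fdr,
        "fst_estimator": cfg.fst_estimator,
        "roh": dataclasses.asdict(rh.ROHParams(**cfg.roh_options)),
        "filter": dataclasses.asdict(FilterConfig(**cfg.filter_options)),
    }}

    def done(stage, **info):
        manifest["stages"][stage] = info
        logger.info("stage %s: %s", stage, info)

    # ---------------------------------------------------------------- inputs
    truth = None
    if cfg.simulate and "simulate" in cfg.stages:
        sim_seed = cfg.stage_seed("simulate")
        preset = {
            "founder_captive": sd.founder_captive_config,
            "purging_pair": sd.purging_pair_config,
            "neutral": sd.neutral_single_population_config,
        }[cfg.sim_preset]
        result = sd.simulate(preset(seed=sim_seed, **cfg.sim_options))
        result.write(out / "sim")
        gm, spec, truth = result.genotypes, result.population_spec, result.truth
        done("simulate", preset=cfg.sim_preset, seed=sim_seed,
             n_samples=gm.n_samples, n_sites=gm.n_sites)
    else:
        spec = (PopulationSpec.from_tsv(cfg.population_map, outgroup=cfg.outgroup)
                if cfg.population_map else None)
        gm = read_vcf(cfg.vcf, spec)
        if spec is None:
            spec = PopulationSpec({s: "all" for s in gm.samples})

    window = dv.WindowSpec(cfg.window_length, cfg.window_step)
    genome_length = cfg.genome_length or sum(gm.contig_lengths.values()) or None

    # ---------------------------------------------------------------- stages
    if "filter" in cfg.stages:
        gaps = read_bed(cfg.gaps_bed) if cfg.gaps_bed else None
        gm, report = apply_site_filters(gm, FilterConfig(**cfg.filter_options), gaps)
        report.to_tsv(out / "filter_report.tsv")
        done("filter", n_output=gm.n_sites, removed=report.removed_by_rule,
             skipped=report.skipped_rules)

    if "polarize" in cfg.stages:
        og_label = spec.outgroup or cfg.outgroup
        if og_label is None:
            raise ConfigurationError("polarize stage requires an outgroup")
        og_samples = spec.samples_in(og_label)
        gm = polarize_by_outgroup(gm, og_samples[0])
        done("polarize", outgroup_sample=og_samples[0],
             n_polarized=int(gm.polarized_mask.sum()))

    ingroup = spec.ingroup_populations
    het_tab = None
    if "diversity" in cfg.stages:
        frames = []
        for pop in ingroup:
            t = dv.diversity_windows(gm, pop, spec, window)
            t.insert(0, "population", pop)
            frames.append(t)
        div = pd.concat(frames, ignore_index=True)
        div.to_csv(out / "diversity_windows.tsv", sep="\t", index=False)
        het_tab = pd.DataFrame(
            [{"sample": s, "population": spec.mapping[s],
              "heterozygosity": dv.individual_heterozygosity(gm, s)}
             for s in gm.samples])
        het_tab.to_csv(out / "heterozygosity.tsv", sep="\t", index=False)
        done("diversity", n_windows=len(div), n_samples=len(het_tab))

    fst_mat = None
    if "fst" in cfg.stages and len(ingroup) >= 2:
        fst_mat = dv.fst_matrix(gm, spec, window, cfg.fst_estimator)
        fst_mat.to_csv(out / "fst_matrix.tsv", sep="\t")
        done("fst", n_populations=len(ingroup))

    if "relatedness" in cfg.stages:
        dm = rel.p_distance_matrix(gm)
        dm.to_csv(out / "p_distance.tsv", sep="\t")
        rel.write_phylip(dm, out / "p_distance.phy")
        ingroup_samples = [s for s in gm.samples
                           if spec.mapping[s] != spec.outgroup]
        ibd = rel.ibd_moments(gm, samples=ingroup_samples)
        ibd.table.to_csv(out / "ibd.tsv", sep="\t", index=False)
        done("relatedness", n_pairs=len(ibd.table))

    if "pca" in cfg.stages:
        ingroup_samples = [s for s in gm.samples
                           if spec.mapping[s] != spec.outgroup]
        pca = rel.genotype_pca(gm.take_samples(ingroup_samples), k=2)
        coords = pca.coordinates.copy()
        coords["explained_variance_ratio"] = np.resize(
            pca.explained_variance_ratio, len(coords))
        pca.coordinates.to_csv(out / "pca.tsv", sep="\t")
        done("pca", explained=[round(float(v), 4)
                               for v in pca.explained_variance_ratio])

    if "nj" in cfg.stages:
        og_label = spec.outgroup
        og_sample = spec.samples_in(og_label)[0] if og_label else None
        tree, support = rel.bootstrap_support(
            gm, n_reps=cfg.bootstrap_reps, seed=cfg.stage_seed("nj"),
            outgroup=og_sample)
        tree.write(str(out / "nj_tree.nwk"))
        done("nj", n_bipartitions=len(support),
             min_support=min(support.values()) if support else None)

    segments = None
    if "roh" in cfg.stages:
        segments = rh.detect_roh_all(gm, rh.ROHParams(**cfg.roh_options))
        segments.to_csv(out / "roh_segments.tsv", sep="\t", index=False)
        done("roh", n_segments=len(segments))

    inb = None
    if "inbreeding" in cfg.stages:
        if segments is None:
            segments = rh.detect_roh_all(gm, rh.ROHParams(**cfg.roh_options))
        inb = rh.inbreeding_table(gm, segments, genome_length)
        inb.to_csv(out / "inbreeding.tsv", sep="\t", index=False)
        done("inbreeding", n_samples=len(inb))

    quartets = ig.read_quartets(cfg.quartets) if cfg.quartets else None
    if "dstat" in cfg.stages and len(ingroup) >= 3:
        rows = []
        og = spec.outgroup
        if quartets is not None and {"P1", "P2", "P3"} <= set(quartets.columns):
            combos = [(q.P1, q.P2, q.P3) for q in quartets.itertuples()]
        else:
            combos = [(a, b, c) for i, a in enumerate(ingroup)
                      for b in ingroup[i + 1:] for c in ingroup
                      if c not in (a, b)]
        for p1, p2, p3 in combos:
            rows.append(ig.d_statistic(gm, spec, p1, p2, p3, og,
                                       cfg.block_size).to_row())
        dstat = pd.DataFrame(rows)
        dstat.to_csv(out / "dstat.tsv", sep="\t", index=False)
        done("dstat", n_tests=len(dstat),
             n_significant=int(dstat["significant"].sum()))

    if "f4ratio" in cfg.stages and len(ingroup) >= 2:
        focal_pop = ingroup[-1]
        focal = spec.samples_in(focal_pop)
        donors = [p for p in ingroup if p != focal_pop]
        tests, summary = ig.per_individual_mean_introgression(
            gm, spec, focal, donors, cfg.fdr, quartets, cfg.block_size)
        tests.to_csv(out / "f4ratio_tests.tsv", sep="\t", index=False)
        summary.to_csv(out / "f4ratio_summary.tsv", sep="\t", index=False)
        done("f4ratio", n_tests=len(tests),
             n_retained=int(tests["retained"].sum()))

    categories = None
    if {"load", "sfs", "rxy"} & set(cfg.stages):
        if cfg.gff3 and cfg.fasta:
            categories = ml.classify_effects(gm, cfg.gff3, cfg.fasta)
        elif truth is not None:
            key = truth.sites.set_index(["chrom", "pos"])["category"]
            cats = key.reindex(list(zip(gm.sites["chrom"], gm.sites["pos"])))
            categories = pd.Series(
                np.where(cats.isin(ml.CATEGORIES), cats, None),
                index=gm.sites.index, dtype=object)
        else:
            raise ConfigurationError(
                "load/sfs/rxy stages need gene models (gff3+fasta) or "
                "simulator truth")
        pd.DataFrame({"chrom": gm.sites["chrom"], "pos": gm.sites["pos"],
                      "impact": categories}).to_csv(
            out / "site_impact.tsv", sep="\t", index=False)

    load = None
    if "load" in cfg.stages:
        load = ml.load_table(gm, categories, spec)
        load.per_sample.to_csv(out / "load_per_sample.tsv", sep="\t", index=False)
        load.population_means.to_csv(out / "load_population_means.tsv",
                                     sep="\t", index=False)
        load.t_tests.to_csv(out / "load_t_tests.tsv", sep="\t", index=False)
        done("load", n_excluded_unpolarized=load.n_unpolarized_excluded)

    if "sfs" in cfg.stages:
        frames = []
        for pop in ingroup:
            for cat in ml.CATEGORIES:
                spectrum = ml.sfs(gm, categories, pop, spec, cat)
                if spectrum.n_copies == 0:
                    continue
                f = spectrum.binned()
                f.insert(0, "population", pop)
                f.insert(1, "category", cat)
                frames.append(f)
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(
                out / "sfs.tsv", sep="\t", index=False)
        done("sfs", n_tables=len(frames))

    rxy_tab = None
    if "rxy" in cfg.stages and len(ingroup) >= 2:
        rows = []
        for i, px in enumerate(ingroup):
            for py in ingroup:
                if px == py:
                    continue
                for cat in ml.CATEGORIES:
                    r = ml.rxy(gm, categories, px, py, spec, cat)
                    rows.append(dataclasses.asdict(r))
        rxy_tab = pd.DataFrame(rows)
        rxy_tab.to_csv(out / "rxy.tsv", sep="\t", index=False)
        done("rxy", n_comparisons=len(rxy_tab))

    if "report" in cfg.stages:
        summary = summary_report(out)
        done("report", sections=sorted(summary))

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def summary_report(outdir) -> dict:
    """Aggregate per-population means from stage outputs into one JSON + TSV
    bundle (``summary.json`` / ``summary_<section>.tsv``); sections whose
    stage did not run are omitted."""
    out = Path(outdir)
    summary: dict = {}

    def load_tsv(name, **kw):
        p = out / name
        return pd.read_csv(p, sep="\t", **kw) if p.exists() else None

    het = load_tsv("heterozygosity.tsv")
    if het is not None:
        summary["heterozygosity"] = (het.groupby("population")["heterozygosity"]
                                     .mean().to_dict())
    div = load_tsv("diversity_windows.tsv")
    if div is not None:
        summary["pi"] = div.groupby("population")["pi"].mean().to_dict()
        summary["theta_w"] = div.groupby("population")["theta_w"].mean().to_dict()
    fst = load_tsv("fst_matrix.tsv", index_col=0)
    if fst is not None:
        summary["fst"] = {f"{a}|{b}": float(fst.loc[a, b])
                          for i, a in enumerate(fst.index)
                          for b in fst.columns[i + 1:]}
    inb = load_tsv("inbreeding.tsv")
    if inb is not None:
        summary["F_H_mean"] = float(inb["F_H"].mean())
        summary["F_ROH_100kb_mean"] = float(inb["F_ROH_100kb"].mean())
    means = load_tsv("load_population_means.tsv")
    if means is not None:
        summary["load_mean_hom"] = {
            f"{r.population}|{r.category}": r.mean_hom
            for r in means.itertuples()}
    rxy_tab = load_tsv("rxy.tsv")
    if rxy_tab is not None:
        summary["rxy"] = {f"{r.pop_x}|{r.pop_y}|{r.category}": r.rxy
                          for r in rxy_tab.itertuples()}
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    for section, data in summary.items():
        if isinstance(data, dict):
            pd.Series(data).rename(section).to_csv(
                out / f"summary_{section}.tsv", sep="\t")
    return summary
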