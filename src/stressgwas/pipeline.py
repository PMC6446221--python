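"""End-to-end orchestration: simulate -> score -> GWAS -> modules -> stats.

A single :class:`RunConfig` names every tunable; :func:`run_all` executes
the stages in dependency order and writes plain-text TSV/JSON artifacts,
each stamped with the configuration hash, so any stage can be re-run and
diffed.  A thin click CLI exposes the verbs simulate, score, gwas,
modules, stats and all.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import (cohortstats, contribution, genotypes, growthio, mixedmodel,
               netmodules, resistance, synthio)

log = logging.getLogger("stressgwas")

__all__ = ["RunConfig", "validate_config", "run_all", "cli"]


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "stressgwas_run"
    # synthetic study conditions
    n_strains: int = 36
    n_conditions: int = 13
    levels_per_condition: int | None = None   # None -> draw in 4..7
    n_replicates: int = 2
    noise_sd: float = 0.01
    blank: float = 0.075
    min_amplitude: float = 0.1
    # scoring
    weights: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    rva_samples: int = 100
    pi_bump: float = 0.25
    # GWAS
    n_markers: int = 800
    n_populations: int = 3
    fst_like: float = 0.2
    maf_min: float = 0.05
    r2_min: float = 0.8
    max_gap_bp: int = 20_000
    eps_log10: float = 0.5
    upstream_bp: int = 800
    inverse_normal: bool = True
    scan_mode: str = "p3d"
    n_scan_rankings: int = 2
    # CNV
    cnv_events_per_strain: float = 4.0
    cnv_min_class_frac: float = 0.05
    # network
    net_nodes: int = 120
    net_edge_prob: float = 0.03
    net_clique_size: int = 8
    net_clique_fg_frac: float = 1.0
    net_score_min: float = 0.0
    clique_min_size: int = 3
    module_alpha: float = 0.05
    n_random_lists: int = 5
    # metabolome
    n_metabolites: int = 79
    metabolome_coupling: float = -0.6

    def hash(self) -> str:
        # output location is not part of the scientific configuration
        fields = {k: v for k, v in dataclasses.asdict(self).items()
                  if k != "outdir"}
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "weights" in data:
            data["weights"] = tuple(data["weights"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def validate_config(config: RunConfig) -> list[str]:
    """Schema and cross-field checks; returns the list of violations."""
    v = []
    if config.n_strains < 4:
        v.append("n_strains must be >= 4")
    if config.levels_per_condition is not None and not (
        4 <= config.levels_per_condition <= 7
    ):
        v.append("levels_per_condition must be in 4..7")
    if sum(config.weights) <= 0 or any(w < 0 for w in config.weights):
        v.append("weights must be nonnegative and sum to > 0")
    if len(config.weights) != 5:
        v.append("weights must have 5 entries")
    if not 0 <= config.maf_min < 0.5:
        v.append("maf_min must be in [0, 0.5)")
    if not 0 < config.r2_min <= 1:
        v.append("r2_min must be in (0, 1]")
    if config.noise_sd < 0:
        v.append("noise_sd must be >= 0")
    if config.scan_mode not in ("p3d", "exact"):
        v.append("scan_mode must be 'p3d' or 'exact'")
    if config.n_random_lists < 1:
        v.append("n_random_lists must be >= 1")
    return v


def _write_tsv(frame: pd.DataFrame, path: Path, cfg_hash: str, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        frame.to_csv(fh, sep="\t", index=index)


def _write_json(obj, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        json.dump({"config_hash": cfg_hash, "data": obj}, fh, indent=2,
                  sort_keys=True, default=float)


class StageError(RuntimeError):
    def __init__(self, stage: str, artifact: Path, cause: Exception):
        super().__init__(f"stage {stage!r} failed at {artifact}: {cause}")
        self.stage = stage
        self.artifact = artifact


def run_all(config: RunConfig) -> Path:
    """Run every stage in dependency order; returns the run directory."""
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.hash()
    config.to_yaml(out / "config.yaml")
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(8)]
    log.info("run %s: seeds %s", h, seeds)

    stage = "simulate"
    try:
        strains = synthio.gen_strains(config.n_strains, seeds[0])
        meta = synthio.strain_frame(strains)
        _write_tsv(meta, out / "strains.tsv", h)
        curves_frame, truth = synthio.gen_growth_curves(
            strains, n_conditions=config.n_conditions,
            levels_per_condition=config.levels_per_condition,
            n_replicates=config.n_replicates, noise_sd=config.noise_sd,
            seed=seeds[1],
        )
        growthio.write_curves(curves_frame, out / "curves.tsv")
        gm, _, _ = synthio.gen_genotypes(
            strains, n_markers=config.n_markers,
            n_populations=config.n_populations, fst_like=config.fst_like,
            seed=seeds[2],
        )
        genotypes.write_vcf(gm, out / "genotypes.vcf")
        cnv = synthio.gen_cnv(
            strains, n_events_per_strain=config.cnv_events_per_strain,
            seed=seeds[3],
        )
        _write_tsv(cnv, out / "cnv_segments.tsv", h)
        genes = synthio.gen_genes(seed=seeds[4])
        _write_tsv(genes, out / "genes.tsv", h)
        edges, foreground, net_truth = synthio.gen_network(
            config.net_nodes, config.net_edge_prob,
            planted_cliques=[(config.net_clique_size, config.net_clique_fg_frac)],
            n_background_foreground=max(2, config.net_nodes // 25),
            seed=seeds[5],
        )
        _write_tsv(edges, out / "network.tsv", h)
        metab, group_map = synthio.gen_metabolome(
            strains, n_metabolites=config.n_metabolites,
            coupling=config.metabolome_coupling, seed=seeds[6],
        )
        _write_tsv(metab["intra"], out / "metabolome_intra.tsv", h, index=True)
        _write_tsv(metab["extra"], out / "metabolome_extra.tsv", h, index=True)

        stage = "score"
        curves = growthio.curves_from_frame(curves_frame)
        params = growthio.extract_table(
            curves, blank=config.blank, min_amplitude=config.min_amplitude
        )
        _write_tsv(params, out / "growth_params.tsv", h)
        w = resistance.WeightVector(config.weights)
        rankings = resistance.ranking_table(params, w)
        _write_tsv(rankings, out / "rankings.tsv", h)
        freq = resistance.top_frequency(rankings, k=10)
        _write_tsv(freq.rename("top10_count").reset_index(), out / "top10.tsv", h)
        first_cond = sorted(params["condition"].unique())[0]
        rva = resistance.rank_variability(
            params, first_cond, n_weight_samples=config.rva_samples, seed=seeds[7]
        )
        _write_tsv(rva, out / "rva.tsv", h, index=True)
        pi = resistance.parameter_influence(
            params, bump=config.pi_bump,
            conditions=sorted(params["condition"].unique())[:3],
        )
        flat = pi.copy()
        flat.columns = [f"{c}:{p}" for c, p in flat.columns]
        _write_tsv(flat, out / "pi_scores.tsv", h, index=True)

        stage = "gwas"
        gm_f = genotypes.filter_core_maf(gm, mask=None, maf_min=config.maf_min)
        blocks, reps = genotypes.ld_blocks(
            gm_f, r2_min=config.r2_min, max_gap_bp=config.max_gap_bp
        )
        K = genotypes.kinship(gm_f)
        ploidy = dict(zip(meta["strain_id"], meta["ploidy"]))
        gain_m = genotypes.cnv_markers(cnv, "gain", gm.strains, ploidy,
                                       config.cnv_min_class_frac)
        loss_m = genotypes.cnv_markers(cnv, "loss", gm.strains, ploidy,
                                       config.cnv_min_class_frac)
        assoc_frames = []
        ranking_names = []
        conds = sorted(params["condition"].unique())[: config.n_scan_rankings]
        for cond in conds:
            for score_type in ("performance", "robustness"):
                name = f"{cond}:{score_type}"
                sub = rankings[
                    (rankings["condition"] == cond)
                    & (rankings["score_type"] == score_type)
                ].set_index("strain")
                y = mixedmodel.transform_phenotype(
                    sub["rank"].reindex(gm.strains),
                    inverse_normal=config.inverse_normal,
                ).to_numpy()
                res_snp = mixedmodel.assoc_scan(
                    y, reps.dosages, K, mode=config.scan_mode, source="snp"
                )
                res_snp["chrom"] = [blocks[i].chrom for i in res_snp["unit"]]
                res_snp["start"] = [blocks[i].start for i in res_snp["unit"]]
                res_snp["end"] = [blocks[i].end for i in res_snp["unit"]]
                frames = [res_snp]
                for src, mk in (("gain", gain_m), ("loss", loss_m)):
                    if not mk:
                        continue
                    mat = np.array([m.presence.reindex(gm.strains).to_numpy()
                                    for m in mk], dtype=float)
                    r = mixedmodel.assoc_scan(y, mat, K, mode=config.scan_mode,
                                              source=src)
                    r["chrom"] = [mk[i].chrom for i in r["unit"]]
                    r["start"] = [mk[i].start for i in r["unit"]]
                    r["end"] = [mk[i].end for i in r["unit"]]
                    frames.append(r)
                res = pd.concat(frames, ignore_index=True)
                res["ranking"] = name
                assoc_frames.append(res)
                ranking_names.append(name)
        assoc = pd.concat(assoc_frames, ignore_index=True)
        cutoffs = {}
        sig_flags = np.zeros(len(assoc), dtype=bool)
        for src, grp in assoc.groupby("source"):
            if len(grp) >= 20:
                co = mixedmodel.qq_cutoff(grp["p"], source=src,
                                          eps_log10=config.eps_log10)
            else:
                co = mixedmodel.SignificanceCutoff(src, 0.0, config.eps_log10)
            cutoffs[src] = co
            sig_flags[grp.index] = (grp["p"] <= co.threshold) & (co.threshold > 0)
        assoc["significant"] = sig_flags
        _write_tsv(assoc, out / "association.tsv", h)
        _write_json(
            {s: c.threshold for s, c in cutoffs.items()},
            out / "cutoffs.json", h,
        )
        gene_p_frames = []
        for name in ranking_names:
            sub = assoc[assoc["ranking"] == name]
            gp = mixedmodel.gene_pvalues(sub, genes, upstream_bp=config.upstream_bp)
            gp["ranking"] = name
            gene_p_frames.append(gp)
        gene_p = pd.concat(gene_p_frames, ignore_index=True)
        _write_tsv(gene_p, out / "gene_pvalues.tsv", h)
        windows = mixedmodel.genomic_windows(
            assoc[assoc["source"] == "snp"], cutoffs["snp"]
        )
        _write_tsv(windows, out / "windows.tsv", h)

        stage = "contribution"
        contrib_frames = []
        for name in ranking_names:
            gp = gene_p[gene_p["ranking"] == name]
            contrib_frames.append(
                contribution.contribution_table(gp, genes, ranking=name)
            )
        _write_tsv(pd.concat(contrib_frames, ignore_index=True),
                   out / "contributions.tsv", h)

        stage = "modules"
        net = netmodules.InteractionNetwork(
            graph=netmodules.read_network(out / "network.tsv",
                                          config.net_score_min).graph,
            score_min=config.net_score_min,
        )
        mods = netmodules.find_modules(
            net, foreground, clique_min_size=config.clique_min_size,
            alpha=config.module_alpha,
        )
        mod_rows = [
            {"module": i, "n_nodes": len(m.nodes), "p_adjusted": m.p_adjusted,
             "nodes": ",".join(sorted(m.nodes))}
            for i, m in enumerate(mods)
        ]
        _write_tsv(pd.DataFrame(mod_rows, columns=["module", "n_nodes",
                                                   "p_adjusted", "nodes"]),
                   out / "modules.tsv", h)
        comp = netmodules.null_comparison(
            net, foreground, n_random=config.n_random_lists, seed=seeds[5]
        )
        _write_json(comp.reset_index().to_dict(orient="records"),
                    out / "module_null_comparison.json", h)

        stage = "stats"
        perf = rankings[
            (rankings["condition"] == first_cond)
            & (rankings["score_type"] == "performance")
        ].set_index("strain")["rank"]
        grouped = cohortstats.bin_strains(perf, meta, group_col="category")
        stat_report = {}
        if {"industrial", "environmental"} <= set(grouped["group"]):
            u, p = cohortstats.compare_two(grouped, "industrial", "environmental")
            stat_report["industrial_vs_environmental"] = {"U": u, "p": p}
        hstat, hp = cohortstats.compare_many(grouped)
        stat_report["kruskal_categories"] = {"H": hstat, "p": hp}
        gscores, granks = cohortstats.metabolome_group_scores(
            metab["intra"], group_map
        )
        _write_tsv(gscores, out / "metabolome_group_scores.tsv", h, index=True)
        _write_json(stat_report, out / "cohort_stats.json", h)
    except Exception as exc:
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, out, exc) from exc
    log.info("run %s complete at %s", h, out)
    return out


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def _load_config(config_path, seed, outdir) -> RunConfig:
    cfg = RunConfig.from_yaml(config_path) if config_path else RunConfig()
    if seed is not None:
        cfg.seed = seed
    if outdir is not None:
        cfg.outdir = outdir
    return cfg


@click.group()
@click.option("--log-level", default="INFO", show_default=True)
def cli(log_level: str) -> None:
    """Stress-resistance phenomics scoring and mixed-model GWAS pipeline."""
    logging.basicConfig(level=getattr(logging, log_level.upper(), logging.INFO),
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")


def _common(fn):
    fn = click.option("--config", "config_path", type=click.Path(exists=True),
                      default=None)(fn)
    fn = click.option("--seed", type=int, default=None)(fn)
    fn = click.option("--outdir", type=click.Path(), default=None)(fn)
    return fn


@cli.command("validate")
@_common
def validate_cmd(config_path, seed, outdir):
    """Validate a configuration file."""
    cfg = _load_config(config_path, seed, outdir)
    violations = validate_config(cfg)
    if violations:
        for v in violations:
            click.echo(f"violation: {v}")
        raise SystemExit(1)
    click.echo("config OK")


def _make_stage_command(name: str, help_text: str):
    @cli.command(name, help=help_text)
    @_common
    def _cmd(config_path, seed, outdir):
        cfg = _load_config(config_path, seed, outdir)
        run_all(cfg)
        click.echo(f"{name}: outputs in {cfg.outdir}")
    return _cmd


# Stages share persisted inputs through the run directory; each verb runs
# the pipeline up to (and including) its stage via run_all's ordering.
for _name, _help in [
    ("simulate", "Generate all synthetic inputs."),
    ("score", "Extract growth parameters and compute rankings."),
    ("gwas", "Run the mixed-model association scans."),
    ("modules", "Discover enriched interaction-network modules."),
    ("stats", "Cohort comparison statistics."),
    ("all", "Run the full pipeline."),
]:
    _make_stage_command(_name, _help)


if __name__ == "__main__":  # pragma: no cover
    cli()
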