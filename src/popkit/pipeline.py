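"""End-to-end orchestration: simulate -> consensus -> concordance ->
matrix -> tree / PCA / admixture / windowed stats / LD, from one config.

The pipeline is deterministic given the config seed: every stage derives
its own seed from it, and all outputs are plain text written with fixed
float formatting, so two runs with the same config are byte-identical.
A JSON manifest records each stage's parameters and output files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import admixture as admix_mod
from . import ld as ld_mod
from . import windows as win_mod
from .concordance import classify_concordance
from .consensus import consensus_for_accession, intersect_callers, filter_homozygous
from .core import BiallelicMatrix
from .io import write_callset_vcf, write_matrix_tsv, write_matrix_vcf
from .matrix import build_biallelic_matrix, pairwise_identity
from .popstruct import neighbor_joining, p_distance, run_pca
from .simulate import (
    DEFAULT_PROFILES,
    CallerProfile,
    GroupSpec,
    PopulationModel,
    simulate_caller_outputs,
    simulate_populations,
    write_simulation,
)


@dataclass
class PipelineConfig:
    """Thresholds and stage parameters for one pipeline run."""

    model: PopulationModel = field(default_factory=PopulationModel)
    profiles: tuple[CallerProfile, ...] = DEFAULT_PROFILES
    reference_name: str = "Morex"
    min_depth: int = 5
    min_alt_frac: float = 0.90
    max_third_allele_frac: float = 0.10
    window: int = 500_000
    k_range: tuple[int, int] = (1, 4)
    n_runs: int = 3
    burnin: int = 500
    reps: int = 2000
    admix_max_sites: int = 500
    ld_max_dist: int = 500_000
    ld_maf_min: float = 0.05
    ld_bin_width: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "model" in kwargs and isinstance(kwargs["model"], dict):
            m = dict(kwargs["model"])
            if "groups" in m:
                m["groups"] = tuple(GroupSpec(**g) for g in m["groups"])
            if "admixed" in m:
                m["admixed"] = tuple((a["name"], dict(a["proportions"])) for a in m["admixed"])
            if "chromosome_lengths" in m:
                m["chromosome_lengths"] = tuple(int(x) for x in m["chromosome_lengths"])
            kwargs["model"] = PopulationModel(**m)
        if "profiles" in kwargs:
            kwargs["profiles"] = tuple(CallerProfile(**p) for p in kwargs["profiles"])
        if "k_range" in kwargs:
            kwargs["k_range"] = tuple(int(k) for k in kwargs["k_range"])
        return cls(**kwargs)


def _params_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage in dependency order; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}}
    seed = int(config.seed)
    model = config.model
    if model.seed != seed:
        model = PopulationModel(
            chromosome_lengths=model.chromosome_lengths,
            n_sites=model.n_sites,
            groups=model.groups,
            admixed=model.admixed,
            admixed_group_name=model.admixed_group_name,
            recomb_rate=model.recomb_rate,
            seed=seed,
        )

    # ---- simulate: truth + RNA-seq-like caller outputs (+ exome-like replicate)
    truth = simulate_populations(model)
    rna = simulate_caller_outputs(truth, config.profiles, seed=seed + 1)
    sim_dir = outdir / "simulated"
    files = write_simulation(truth, rna, sim_dir)
    manifest["stages"]["simulate"] = {
        "params": _params_hash(asdict(model)),
        "outputs": sorted(sum(files.values(), [])),
    }

    # ---- consensus per accession
    cons_dir = outdir / "consensus"
    cons_dir.mkdir(exist_ok=True)
    consensus = {}
    depths = {}
    summaries = []
    contigs = truth.chrom_lengths
    for acc, (callers, track) in rna.items():
        cons, summary = consensus_for_accession(
            callers, track, min_depth=config.min_depth, min_alt_frac=config.min_alt_frac
        )
        consensus[acc] = cons
        depths[acc] = track
        summaries.append(summary)
        write_callset_vcf(cons, cons_dir / f"{acc}.consensus.vcf", contigs)
    summary_df = pd.concat(summaries, ignore_index=True)
    _write_tsv(summary_df, cons_dir / "summary.tsv")
    manifest["stages"]["consensus"] = {
        "params": _params_hash({"min_depth": config.min_depth, "min_alt_frac": config.min_alt_frac}),
        "outputs": sorted(p.name for p in cons_dir.iterdir()),
    }

    # ---- concordance of the first accession's RNA-seq consensus vs an
    # exome-like re-sequencing of the same truth
    exome = simulate_caller_outputs(truth, config.profiles, seed=seed + 2)
    acc0 = truth.accessions[0]
    ex_callers, ex_track = exome[acc0]
    ex_filtered = tuple(
        filter_homozygous(cs, ex_track, config.min_depth, config.min_alt_frac)[0]
        for cs in ex_callers.values()
    )
    ex_cons = intersect_callers(*ex_filtered)
    raw_records = pd.concat([cs.records for cs in ex_callers.values()], ignore_index=True)
    raw_records = raw_records.drop_duplicates(["chrom", "pos", "ref", "alt"]).sort_values(
        ["chrom", "pos", "alt"], kind="mergesort"
    )
    from .core import CallSet

    ex_raw = CallSet(acc0, "raw_union", raw_records.reset_index(drop=True))
    conc = classify_concordance(consensus[acc0], ex_cons, ex_filtered, ex_raw)
    _write_tsv(conc.to_frame(), outdir / "concordance.tsv")
    manifest["stages"]["concordance"] = {
        "params": _params_hash({"accession": acc0}),
        "outputs": ["concordance.tsv"],
    }

    # ---- bi-allelic matrix
    matrix = build_biallelic_matrix(
        consensus,
        depths,
        reference_name=config.reference_name,
        min_depth=config.min_depth,
        max_third_allele_frac=config.max_third_allele_frac,
    )
    write_matrix_vcf(matrix, outdir / "matrix.vcf", contigs)
    write_matrix_tsv(matrix, outdir / "matrix.tsv")
    ident = pairwise_identity(matrix)
    ident.round(10).to_csv(outdir / "pairwise_identity.tsv", sep="\t")
    manifest["stages"]["matrix"] = {
        "params": _params_hash(
            {"min_depth": config.min_depth, "max_third_allele_frac": config.max_third_allele_frac}
        ),
        "outputs": ["matrix.vcf", "matrix.tsv", "pairwise_identity.tsv"],
        "n_sites": matrix.n_sites,
    }

    # ---- tree + PCA
    dist = p_distance(matrix)
    tree = neighbor_joining(dist)
    (outdir / "tree.nwk").write_text(tree.newick() + "\n")
    pca = run_pca(matrix)
    _write_tsv(pca.to_frame().reset_index(names="accession"), outdir / "pca_scores.tsv")
    _write_tsv(
        pd.DataFrame({"component": np.arange(1, len(pca.eigenvalues) + 1), "eigenvalue": pca.eigenvalues}),
        outdir / "pca_eigenvalues.tsv",
    )
    manifest["stages"]["tree_pca"] = {
        "params": _params_hash({}),
        "outputs": ["tree.nwk", "pca_scores.tsv", "pca_eigenvalues.tsv"],
    }

    # ---- admixture across the K range (panel accessions only, site-thinned)
    panel = [a for a in matrix.accessions if a != config.reference_name]
    pm = matrix.subset(panel)
    if pm.n_sites > config.admix_max_sites:
        step = pm.n_sites / config.admix_max_sites
        keep = np.zeros(pm.n_sites, dtype=bool)
        keep[(np.arange(config.admix_max_sites) * step).astype(int)] = True
        pm = pm.site_mask(keep)
    k_lo, k_hi = config.k_range
    fits = admix_mod.fit_k_range(
        pm, range(k_lo, k_hi + 1), n_runs=config.n_runs, burnin=config.burnin, reps=config.reps, seed=seed + 3
    )
    L_runs = {K: [f.log_likelihood for f in runs] for K, runs in fits.items()}
    delta = admix_mod.evanno_delta_k(L_runs)
    _write_tsv(delta, outdir / "evanno_delta_k.tsv")
    chosen = admix_mod.best_k(delta)
    bestfit = fits[chosen][0]
    _write_tsv(bestfit.q_frame().reset_index(names="accession"), outdir / "admixture_Q.tsv")
    manifest["stages"]["admixture"] = {
        "params": _params_hash(
            {"k_range": config.k_range, "n_runs": config.n_runs, "burnin": config.burnin, "reps": config.reps}
        ),
        "outputs": ["evanno_delta_k.tsv", "admixture_Q.tsv"],
        "best_k": chosen,
    }

    # ---- windowed stats per group
    groups: dict[str, list[str]] = {}
    for acc, grp in truth.group_of.items():
        groups.setdefault(grp, []).append(acc)
    groups = {g: sorted(m) for g, m in sorted(groups.items()) if len(m) >= 2}
    windows = win_mod.make_windows(contigs, config.window)
    hd_tbl, fst_tbl = win_mod.group_summary(matrix, groups, windows)
    _write_tsv(hd_tbl, outdir / "haplotype_diversity.tsv")
    _write_tsv(fst_tbl, outdir / "fst.tsv")
    density = win_mod.snp_density(consensus[acc0], windows)
    _write_tsv(density, outdir / "snp_density.tsv")
    manifest["stages"]["windowed_stats"] = {
        "params": _params_hash({"window": config.window}),
        "outputs": ["haplotype_diversity.tsv", "fst.tsv", "snp_density.tsv"],
    }

    # ---- LD decay and blocks on the largest group
    big_group = max(groups, key=lambda g: (len(groups[g]), g))
    pairs = ld_mod.pairwise_ld(matrix, groups[big_group], max_dist=config.ld_max_dist, maf_min=config.ld_maf_min)
    if pairs.empty:
        decay = pd.DataFrame(columns=["bin_mid", "mean_r2", "n_pairs"])
        half = None
        blocks = []
    else:
        decay, half = ld_mod.ld_decay(pairs, bin_width=config.ld_bin_width)
        blocks = ld_mod.ld_blocks(
            matrix, groups[big_group], max_dist=config.ld_max_dist, maf_min=config.ld_maf_min
        )
    _write_tsv(decay, outdir / "ld_decay.tsv")
    _write_tsv(ld_mod.blocks_to_bed(blocks), outdir / "ld_blocks.bed")
    manifest["stages"]["ld"] = {
        "params": _params_hash(
            {"max_dist": config.ld_max_dist, "maf": config.ld_maf_min, "bin": config.ld_bin_width}
        ),
        "outputs": ["ld_decay.tsv", "ld_blocks.bed"],
        "group": big_group,
        "half_decay_bp": half,
    }

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
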