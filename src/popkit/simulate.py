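"""Synthetic structured-population genotypes and caller outputs.

The generator stands in for a panel of inbred accessions sequenced by
RNA-seq: structured sub-populations (two diverged groups plus admixed
accessions) are simulated under a Balding-Nichols model, and three
variant callers with distinct error profiles are emulated on top of the
true genotypes, so every downstream stage of the pipeline can be tested
against a known truth.

Model
-----
For each segregating site an ancestral allele frequency p is drawn
Uniform(0.05, 0.95); each group's frequency is drawn from the
Balding-Nichols distribution Beta(p(1-F)/F, (1-p)(1-F)/F), which has
mean p and variance F p(1-p), so F is the expected Hudson F_ST of the
group against the ancestral pool (and between two groups simulated at
the same F). Accession haplotypes are donor mosaics: walking along a
chromosome, the current donor group persists between adjacent sites
with probability exp(-c * distance) and is otherwise re-drawn from the
accession's ancestry proportions; alleles are Bernoulli draws from the
donor group's site frequency. For admixed accessions this induces
linkage disequilibrium that decays with physical distance at scale 1/c.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CallSet, DepthTrack
from .io import BASES, write_bedgraph, write_callset_vcf

SEQ_ERROR = 0.01  # per-read probability that a base is miscalled


@dataclass
class GroupSpec:
    """One sub-population: its name, panel size, and divergence F from the ancestral pool."""

    name: str
    n_accessions: int
    fst: float


@dataclass
class PopulationModel:
    """Study design for the synthetic panel.

    chromosome_lengths are bp; n_sites segregating sites are placed per
    chromosome at distinct positions. ``admixed`` accessions carry
    explicit ancestry proportions over the named groups; group members
    are pure (one-hot ancestry). recomb_rate c is the per-bp probability
    scale of donor switching (expected tract length 1/c bp).
    """

    chromosome_lengths: tuple[int, ...] = (2_000_000, 2_000_000)
    n_sites: int = 1000
    groups: tuple[GroupSpec, ...] = (
        GroupSpec("occidental", 8, 0.3),
        GroupSpec("oriental", 8, 0.3),
    )
    admixed: tuple[tuple[str, dict[str, float]], ...] = (
        ("marginal_1", {"occidental": 0.7, "oriental": 0.3}),
        ("marginal_2", {"occidental": 0.6, "oriental": 0.4}),
        ("marginal_3", {"occidental": 0.5, "oriental": 0.5}),
        ("marginal_4", {"occidental": 0.4, "oriental": 0.6}),
        ("marginal_5", {"occidental": 0.3, "oriental": 0.7}),
    )
    admixed_group_name: str = "marginal"
    recomb_rate: float = 2e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.chromosome_lengths):
            raise ValueError("chromosome lengths must be positive")
        if any(l < self.n_sites for l in self.chromosome_lengths):
            raise ValueError("chromosome_lengths must be >= n_sites (distinct site positions)")
        for g in self.groups:
            if not (0 <= g.fst < 1):
                raise ValueError(f"group {g.name!r}: F must lie in [0, 1), got {g.fst}")
        for name, props in self.admixed:
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"admixed accession {name!r}: ancestry proportions sum to {total}")
            unknown = set(props) - {g.name for g in self.groups}
            if unknown:
                raise ValueError(f"admixed accession {name!r}: unknown groups {unknown}")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be >= 0")
        names = self.accession_names()
        if len(names) != len(set(names)):
            raise ValueError("duplicate accession names in the model")

    def accession_names(self) -> list[str]:
        names = [f"{g.name}_{i + 1}" for g in self.groups for i in range(g.n_accessions)]
        names += [name for name, _ in self.admixed]
        return names

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}H" for i in range(len(self.chromosome_lengths))]

    def chrom_lengths_dict(self) -> dict[str, int]:
        return dict(zip(self.chrom_names(), self.chromosome_lengths))

    def ancestry_matrix(self) -> np.ndarray:
        """accessions x groups ancestry proportions (one-hot for pure lines)."""
        group_index = {g.name: k for k, g in enumerate(self.groups)}
        rows = []
        for k, g in enumerate(self.groups):
            one_hot = np.zeros(len(self.groups))
            one_hot[k] = 1.0
            rows += [one_hot] * g.n_accessions
        for _, props in self.admixed:
            q = np.zeros(len(self.groups))
            for name, p in props.items():
                q[group_index[name]] = p
            rows.append(q)
        return np.asarray(rows)

    def group_of(self) -> dict[str, str]:
        out = {}
        for g in self.groups:
            for i in range(g.n_accessions):
                out[f"{g.name}_{i + 1}"] = g.name
        for name, _ in self.admixed:
            out[name] = self.admixed_group_name
        return out


@dataclass
class CallerProfile:
    """Error profile of one emulated variant caller.

    fn_rate: probability a true SNP is missed entirely. fp_rate:
    expected spurious homozygous-looking calls per Mb of reference,
    placed at covered non-SNP positions. depth_lambda: Poisson mean of
    per-base coverage.
    """

    name: str
    fn_rate: float = 0.0
    fp_rate: float = 0.0
    depth_lambda: float = 30.0

    def __post_init__(self) -> None:
        if not (0 <= self.fn_rate <= 1):
            raise ValueError("fn_rate must lie in [0, 1]")
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be >= 0")
        if self.depth_lambda <= 0:
            raise ValueError("depth_lambda must be > 0")


#: Three-caller default emulating the relative behaviour of freebayes,
#: glfMultiples and samtools: one conservative caller, one permissive
#: caller with many spurious calls, one in between.
DEFAULT_PROFILES = (
    CallerProfile("freebayes", fn_rate=0.10, fp_rate=2.0, depth_lambda=30.0),
    CallerProfile("glfMultiples", fn_rate=0.02, fp_rate=20.0, depth_lambda=30.0),
    CallerProfile("samtools", fn_rate=0.06, fp_rate=8.0, depth_lambda=30.0),
)


@dataclass
class TrueGenotypes:
    """Planted truth: site table, binary genotype matrix, group labels."""

    accessions: list[str]
    sites: pd.DataFrame  # chrom, pos, ref, alt — (chrom, pos) sorted
    genotypes: np.ndarray  # accessions x sites in {0, 1}
    group_of: dict[str, str]
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        assert self.genotypes.shape == (len(self.accessions), len(self.sites))

    def accession_calls(self, accession: str) -> pd.DataFrame:
        """Site rows where this accession carries the alternative allele."""
        i = self.accessions.index(accession)
        return self.sites.loc[self.genotypes[i] == 1].reset_index(drop=True)

    def to_tsv(self, path) -> None:
        rows = []
        for i, acc in enumerate(self.accessions):
            df = self.sites[["chrom", "pos"]].copy()
            df.insert(0, "accession", acc)
            df["genotype"] = self.genotypes[i]
            df["group"] = self.group_of[acc]
            rows.append(df)
        pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def _mosaic_donors(rng: np.random.Generator, q: np.ndarray, gaps: np.ndarray, c: float) -> np.ndarray:
    """Donor group index at each site for one accession on one chromosome.

    The donor persists across a gap of d bp with probability exp(-c*d);
    on a switch it is re-drawn from the ancestry proportions q (possibly
    landing on the same group). Pure accessions (one-hot q) always
    re-draw the same donor.
    """
    n = len(gaps) + 1
    # candidate donor at every site; used only where a reset happens
    candidates = rng.choice(len(q), size=n, p=q)
    keep = np.empty(n, dtype=bool)
    keep[0] = False
    if c > 0:
        keep[1:] = rng.random(n - 1) < np.exp(-c * gaps)
    else:
        keep[1:] = True
    # forward-fill candidate donors over kept positions
    idx = np.where(~keep, np.arange(n), 0)
    idx = np.maximum.accumulate(idx)
    return candidates[idx]


def simulate_populations(model: PopulationModel) -> TrueGenotypes:
    """Draw group allele frequencies and accession haplotypes for the model."""
    rng = np.random.default_rng(model.seed)
    accessions = model.accession_names()
    ancestry = model.ancestry_matrix()
    n_groups = len(model.groups)

    site_frames = []
    geno_blocks = []
    for chrom, length in zip(model.chrom_names(), model.chromosome_lengths):
        pos = np.sort(rng.choice(length, size=model.n_sites, replace=False)) + 1
        ref_idx = rng.integers(0, 4, size=model.n_sites)
        alt_idx = (ref_idx + rng.integers(1, 4, size=model.n_sites)) % 4
        p = rng.uniform(0.05, 0.95, size=model.n_sites)
        freqs = np.empty((n_groups, model.n_sites))
        for k, g in enumerate(model.groups):
            if g.fst == 0.0:
                freqs[k] = p  # point mass: no drift from the ancestral pool
            else:
                ratio = (1.0 - g.fst) / g.fst
                freqs[k] = rng.beta(p * ratio, (1.0 - p) * ratio)
        gaps = np.diff(pos).astype(float)
        block = np.empty((len(accessions), model.n_sites), dtype=np.int8)
        for a in range(len(accessions)):
            donors = _mosaic_donors(rng, ancestry[a], gaps, model.recomb_rate)
            block[a] = rng.random(model.n_sites) < freqs[donors, np.arange(model.n_sites)]
        site_frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": np.array(BASES)[ref_idx],
                    "alt": np.array(BASES)[alt_idx],
                }
            )
        )
        geno_blocks.append(block)

    sites = pd.concat(site_frames, ignore_index=True)
    genotypes = np.concatenate(geno_blocks, axis=1)
    return TrueGenotypes(accessions, sites, genotypes, model.group_of(), model.chrom_lengths_dict())


def simulate_caller_outputs(
    truth: TrueGenotypes,
    profiles: tuple[CallerProfile, ...] = DEFAULT_PROFILES,
    seed: int = 0,
    seq_error: float = SEQ_ERROR,
) -> dict[str, tuple[dict[str, CallSet], DepthTrack]]:
    """Emulate three variant callers on the planted genotypes.

    Per accession, per-base depth is Poisson with the mean of the three
    profiles' depth_lambda and is shared by the callers (they see the
    same reads). A caller reports each of the accession's true alt sites
    with alt-read count Binomial(depth, 1-seq_error), missing it with
    probability fn_rate; spurious calls are placed uniformly at covered
    non-SNP positions at fp_rate per Mb with the same alt-read model.

    Returns {accession: ({caller: CallSet}, DepthTrack)}.
    """
    if len(profiles) != 3:
        raise ValueError("exactly three caller profiles are required")
    n_true = int(truth.genotypes.sum(axis=1).mean())
    genome_mb = sum(truth.chrom_lengths.values()) / 1e6
    for prof in profiles:
        if n_true > 0 and prof.fp_rate * genome_mb > 0.5 * n_true:
            raise ValueError(
                f"profile {prof.name!r}: fp_rate {prof.fp_rate}/Mb implies more than "
                "0.5 false calls per true call; fixture would be meaningless"
            )
    rng = np.random.default_rng(seed)
    mean_lambda = float(np.mean([p.depth_lambda for p in profiles]))
    chroms = list(truth.chrom_lengths)
    out: dict[str, tuple[dict[str, CallSet], DepthTrack]] = {}

    for i, acc in enumerate(truth.accessions):
        depth = {
            c: rng.poisson(mean_lambda, size=truth.chrom_lengths[c]).astype(np.int32)
            for c in chroms
        }
        track = DepthTrack(acc, depth)
        alt_sites = truth.sites.loc[truth.genotypes[i] == 1]
        site_depth = np.concatenate(
            [track.at_many(c, g["pos"].to_numpy()) for c, g in alt_sites.groupby("chrom", sort=False)]
        ) if len(alt_sites) else np.zeros(0, dtype=np.int64)
        # callers share the same reads: one alt-read draw per site
        alt_reads = rng.binomial(site_depth, 1.0 - seq_error)
        callers: dict[str, CallSet] = {}
        for prof in profiles:
            miss = rng.random(len(alt_sites)) < prof.fn_rate
            rec = alt_sites.loc[~miss, ["chrom", "pos", "ref", "alt"]].copy()
            rec["alt_reads"] = alt_reads[~miss]
            rec["depth"] = site_depth[~miss]
            frames = [rec]
            for chrom in chroms:
                n_fp = rng.poisson(prof.fp_rate * truth.chrom_lengths[chrom] / 1e6)
                if n_fp == 0:
                    continue
                frames.append(_false_positive_calls(rng, truth, chrom, n_fp, track, seq_error))
            records = pd.concat(frames, ignore_index=True)
            records = records.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
            callers[prof.name] = CallSet(acc, prof.name, records)
        out[acc] = (callers, track)
    return out


def _false_positive_calls(rng, truth: TrueGenotypes, chrom: str, n_fp: int, track: DepthTrack, seq_error: float) -> pd.DataFrame:
    """Spurious homozygous-looking calls at covered non-SNP positions."""
    length = truth.chrom_lengths[chrom]
    taken = set(truth.sites.loc[truth.sites["chrom"] == chrom, "pos"])
    positions = []
    while len(positions) < n_fp:
        cand = int(rng.integers(1, length + 1))
        if cand in taken or track.at(chrom, cand) == 0:
            continue
        taken.add(cand)
        positions.append(cand)
    positions = np.sort(np.asarray(positions, dtype=np.int64))
    depth = track.at_many(chrom, positions)
    ref_idx = rng.integers(0, 4, size=n_fp)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_fp)) % 4
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "ref": np.array(BASES)[ref_idx],
            "alt": np.array(BASES)[alt_idx],
            "alt_reads": rng.binomial(depth, 1.0 - seq_error),
            "depth": depth,
        }
    )


def write_simulation(
    truth: TrueGenotypes,
    outputs: dict[str, tuple[dict[str, CallSet], DepthTrack]],
    outdir,
) -> dict[str, list[str]]:
    """Write VCFs, BEDGraph depth tracks, truth TSV and group table.

    Returns a manifest of relative paths per artifact kind.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs = truth.chrom_lengths
    manifest: dict[str, list[str]] = {"vcf": [], "bedgraph": [], "tables": []}
    for acc, (callers, track) in outputs.items():
        for caller, cs in callers.items():
            p = outdir / f"{acc}.{caller}.vcf"
            write_callset_vcf(cs, p, contigs)
            manifest["vcf"].append(p.name)
        bp = outdir / f"{acc}.depth.bedgraph"
        write_bedgraph(track, bp)
        manifest["bedgraph"].append(bp.name)
    truth.to_tsv(outdir / "truth.tsv")
    groups = pd.DataFrame(sorted(truth.group_of.items()), columns=["accession", "group"])
    groups.to_csv(outdir / "groups.tsv", sep="\t", index=False)
    manifest["tables"] = ["truth.tsv", "groups.tsv"]
    return manifest
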