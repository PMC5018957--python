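"""Reading and writing of the plain-text formats the pipeline exchanges.

Single-accession call sets travel as minimal VCF v4.2 (INFO DP/AO),
depth as BEDGraph (0-based half-open), the genotype matrix as a
multi-sample VCF with haploid GT plus a TSV table. VCF parsing is
delegated to cyvcf2.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import BiallelicMatrix, CallSet, DepthTrack

BASES = ("A", "C", "G", "T")


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed into SNP records."""


def _vcf_header(contigs: dict[str, int] | None, samples: list[str] | None = None) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=popkit"]
    for name, length in (contigs or {}).items():
        lines.append(f"##contig=<ID={name},length={int(length)}>")
    lines.append('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">')
    lines.append('##INFO=<ID=AO,Number=A,Type=Integer,Description="Alternate allele read count">')
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if samples:
        lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Haploid genotype">')
        cols += ["FORMAT"] + list(samples)
    lines.append("\t".join(cols))
    return "\n".join(lines) + "\n"


def write_callset_vcf(callset: CallSet, path: str | os.PathLike, contigs: dict[str, int] | None = None) -> None:
    """Write one accession's calls as a minimal single-sample-free VCF."""
    path = Path(path)
    rec = callset.records.sort_values(["chrom", "pos", "alt"], kind="mergesort")
    with open(path, "w") as fh:
        fh.write(_vcf_header(contigs))
        for row in rec.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{int(row.pos)}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t"
                f"DP={int(row.depth)};AO={int(row.alt_reads)}\n"
            )


def read_callset_vcf(path: str | os.PathLike, accession: str | None = None, caller: str | None = None) -> tuple[CallSet, int]:
    """Parse a VCF into a CallSet, decomposing multi-allelic records.

    Non-SNP alleles (indels, MNPs, symbolic) are dropped; the count of
    dropped alleles is returned alongside the call set. alt_reads/depth
    come from AO/DP INFO fields when present, else from per-sample AD/DP.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    name = accession or path.stem.split(".")[0]
    caller = caller or "unknown"
    _prevalidate_vcf(path)
    rows: list[tuple] = []
    dropped = 0
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises plain OSError on bad headers
        raise VcfParseError(f"{path}: cannot open as VCF ({exc})") from exc
    n = 0
    try:
        for var in vcf:
            n += 1
            ref = var.REF
            depth = var.INFO.get("DP")
            ao = var.INFO.get("AO")
            if isinstance(ao, (int, float)):
                ao = (ao,)
            if depth is None or ao is None:
                depth, ao = _genotype_level_depth(var)
            for k, alt in enumerate(var.ALT):
                if len(ref) != 1 or len(alt) != 1 or alt not in BASES or ref not in BASES:
                    dropped += 1
                    continue
                alt_reads = int(ao[k]) if ao is not None and k < len(ao) else 0
                rows.append((var.CHROM, var.POS, ref, alt, alt_reads, int(depth or 0)))
    except Exception as exc:
        raise VcfParseError(f"{path}: malformed VCF near record {n + 1}: {exc}") from exc
    rec = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "alt_reads", "depth"])
    if rec.empty:
        return CallSet(name, caller), dropped
    return CallSet(name, caller, rec), dropped


def _prevalidate_vcf(path: Path) -> None:
    """Structural sanity scan; htslib aborts hard on broken records, so
    reject them with a line-numbered error before it sees the file."""
    saw_header = False
    with open(path, "rb") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.decode("utf-8", errors="replace").rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                saw_header = True
                continue
            fields = line.split("\t")
            if not saw_header or len(fields) < 8 or not fields[1].isdigit():
                raise VcfParseError(f"{path}: malformed VCF line {lineno}: {line[:60]!r}")
    if not saw_header:
        raise VcfParseError(f"{path}: missing #CHROM header line")


def _genotype_level_depth(var) -> tuple[int | None, tuple | None]:
    """Fall back to FORMAT AD/DP of the first sample for depth fields."""
    try:
        ad = var.format("AD")
    except Exception:
        ad = None
    if ad is not None and ad.size >= 2:
        ad = np.asarray(ad[0]).ravel()
        return int(ad.sum()), tuple(int(x) for x in ad[1:])
    try:
        dp = var.format("DP")
        if dp is not None:
            return int(np.asarray(dp).ravel()[0]), None
    except Exception:
        pass
    raise VcfParseError(
        "record carries neither INFO DP/AO nor FORMAT AD/DP; supply a depth "
        "track (BEDGraph) so depths can be taken from coverage instead"
    )


def write_bedgraph(track: DepthTrack, path: str | os.PathLike) -> None:
    """Write per-base depth as run-length-merged BEDGraph (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom in track.depth:
            arr = np.asarray(track.depth[chrom])
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{int(arr[s])}\n")


def read_bedgraph(path: str | os.PathLike, chrom_lengths: dict[str, int], accession: str | None = None) -> DepthTrack:
    """Load a BEDGraph into dense per-chromosome arrays (0 where uncovered)."""
    path = Path(path)
    name = accession or path.stem.split(".")[0]
    depth = {c: np.zeros(int(n), dtype=np.int32) for c, n in chrom_lengths.items()}
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "depth"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "depth": np.int64},
        comment="#",
    )
    for row in df.itertuples(index=False):
        arr = depth.get(row.chrom)
        if arr is None:
            raise ValueError(f"{path}: chromosome {row.chrom!r} not in the supplied lengths")
        arr[row.start : min(row.end, len(arr))] = row.depth
    return DepthTrack(name, depth)


def write_matrix_vcf(matrix: BiallelicMatrix, path: str | os.PathLike, contigs: dict[str, int] | None = None) -> None:
    """Write the genotype matrix as a multi-sample VCF with haploid GT calls."""
    with open(path, "w") as fh:
        fh.write(_vcf_header(contigs, samples=matrix.accessions))
        for j, row in enumerate(matrix.sites.itertuples(index=False)):
            gts = "\t".join(str(int(g)) for g in matrix.genotypes[:, j])
            fh.write(f"{row.chrom}\t{int(row.pos)}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_matrix_vcf(path: str | os.PathLike) -> BiallelicMatrix:
    """Round-trip reader for :func:`write_matrix_vcf`."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, gts = [], []
    for var in vcf:
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        gts.append((var.genotype.array()[:, 0] > 0).astype(np.int8))
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    geno = np.asarray(gts, dtype=np.int8).T if gts else np.zeros((len(samples), 0), dtype=np.int8)
    return BiallelicMatrix(samples, sites, geno)


def write_matrix_tsv(matrix: BiallelicMatrix, path: str | os.PathLike) -> None:
    """Genotype table: one row per site, one 0/1 column per accession."""
    df = matrix.sites.copy()
    for i, acc in enumerate(matrix.accessions):
        df[acc] = matrix.genotypes[i]
    df.to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path: str | os.PathLike) -> BiallelicMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    site_cols = ["chrom", "pos", "ref", "alt"]
    accs = [c for c in df.columns if c not in site_cols]
    geno = df[accs].to_numpy(dtype=np.int8).T
    return BiallelicMatrix(accs, df[site_cols].copy(), geno)


def read_groups_tsv(path: str | os.PathLike) -> dict[str, str]:
    """accession -> group map from a two-column TSV (header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["accession", "group"]:
        df = pd.read_csv(path, sep="\t", header=None, names=["accession", "group"], dtype=str)
    return dict(zip(df["accession"], df["group"]))
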