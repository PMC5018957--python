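"""Per-accession homozygous-SNP filtering and three-caller intersection.

A SNP is accepted for an inbred accession when the position read depth
is at least 5 and the alternative-allele read fraction exceeds 90%
(strict inequality: "above" 90%); calls failing either bound are
discarded, not emitted as heterozygous genotypes. The reliable set for
an accession is the intersection of the three callers' filtered calls,
matched on (chromosome, position, ref, alt).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CallSet, DepthTrack
from .io import read_callset_vcf  # re-exported: parsing lives in io

__all__ = ["read_vcf", "filter_homozygous", "intersect_callers", "consensus_for_accession", "FilterReport"]

log = logging.getLogger(__name__)

read_vcf = read_callset_vcf


@dataclass
class FilterReport:
    """Bookkeeping for one filter pass."""

    n_input: int
    n_kept: int
    n_low_depth: int
    n_low_alt_frac: int
    n_zero_depth: int
    n_depth_disagreements: int  # caller DP vs depth-track disagreement at kept positions


def filter_homozygous(
    calls: CallSet,
    depth_track: DepthTrack | None = None,
    min_depth: int = 5,
    min_alt_frac: float = 0.90,
) -> tuple[CallSet, FilterReport]:
    """Keep putative homozygous SNPs: depth >= min_depth and alt fraction > min_alt_frac.

    The depth bound is checked against the coverage track when one is
    supplied (coverage is the authority on position depth), else against
    the caller-reported DP. The alt fraction always uses the caller's
    own alt_reads/depth. Records with zero reported depth are dropped
    and counted separately.
    """
    rec = calls.records
    if rec.empty:
        report = FilterReport(0, 0, 0, 0, 0, 0)
        return CallSet(calls.accession, calls.caller, rec.copy()), report

    caller_depth = rec["depth"].to_numpy(dtype=np.int64)
    zero = caller_depth == 0
    if depth_track is not None:
        pos_depth = np.concatenate(
            [depth_track.at_many(chrom, g["pos"].to_numpy()) for chrom, g in rec.groupby("chrom", sort=False)]
        )
        disagree = int(np.sum(pos_depth[~zero] != caller_depth[~zero]))
        if disagree:
            log.info(
                "%s/%s: caller DP disagrees with the depth track at %d positions; "
                "using the track for the depth threshold",
                calls.accession, calls.caller, disagree,
            )
    else:
        pos_depth = caller_depth
        disagree = 0

    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(zero, 0.0, rec["alt_reads"].to_numpy(dtype=float) / np.where(zero, 1, caller_depth))
    deep = pos_depth >= min_depth
    homozygous = frac > min_alt_frac
    keep = deep & homozygous & ~zero
    report = FilterReport(
        n_input=len(rec),
        n_kept=int(keep.sum()),
        n_low_depth=int((~deep & ~zero).sum()),
        n_low_alt_frac=int((deep & ~homozygous & ~zero).sum()),
        n_zero_depth=int(zero.sum()),
        n_depth_disagreements=disagree,
    )
    out = rec.loc[keep].reset_index(drop=True)
    return CallSet(calls.accession, calls.caller, out), report


def intersect_callers(a: CallSet, b: CallSet, c: CallSet) -> CallSet:
    """SNPs present, with identical (chrom, pos, ref, alt), in all three call sets.

    alt_reads/depth of the surviving records are taken from the first
    call set. Intersection is allele-aware: a shared position with a
    different alternative allele does not count.
    """
    accessions = {a.accession, b.accession, c.accession}
    if len(accessions) != 1:
        raise ValueError(f"call sets belong to different accessions: {sorted(accessions)}")
    shared = a.keys() & b.keys() & c.keys()
    rec = a.records
    key = list(zip(rec["chrom"], rec["pos"].astype(int), rec["ref"], rec["alt"]))
    mask = np.fromiter((k in shared for k in key), dtype=bool, count=len(key)) if key else np.zeros(0, bool)
    out = rec.loc[mask].sort_values(["chrom", "pos", "alt"], kind="mergesort").reset_index(drop=True)
    return CallSet(a.accession, "consensus", out)


def consensus_for_accession(
    callsets: dict[str, CallSet],
    depth_track: DepthTrack | None = None,
    min_depth: int = 5,
    min_alt_frac: float = 0.90,
) -> tuple[CallSet, pd.DataFrame]:
    """Filter each caller's calls and intersect them for one accession.

    Returns the consensus CallSet and a summary table with one row per
    caller (n_raw, n_filtered) plus the consensus size, mirroring a
    per-accession slice of the callers-vs-consensus count table.
    """
    if len(callsets) != 3:
        raise ValueError(f"expected three callers, got {sorted(callsets)}")
    filtered, rows = [], []
    for caller, cs in callsets.items():
        fcs, rep = filter_homozygous(cs, depth_track, min_depth, min_alt_frac)
        filtered.append(fcs)
        rows.append({"accession": cs.accession, "caller": caller, "n_raw": rep.n_input, "n_filtered": rep.n_kept})
    cons = intersect_callers(*filtered)
    summary = pd.DataFrame(rows)
    summary["n_consensus"] = len(cons)
    return cons, summary
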