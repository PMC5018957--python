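"""Windowed SNP density, haplotype diversity and Hudson F_ST.

The genome is tiled into non-overlapping windows (default 5 Mb, the
last window truncated at the chromosome end). Within a window each
accession's genotype string over the window's sites is one haplotype;
diversity is Nei's Hd = n/(n-1) (1 - sum p_i^2) over haplotype
frequencies. Differentiation between two groups is Hudson's
F_ST = 1 - Hw/Hb with Hw the mean pairwise difference count within
groups (averaged over the two groups) and Hb the mean pairwise
difference count between groups, summed over the window's sites.
Windows where a statistic is undefined (no sites, or Hb = 0) carry NaN
and are excluded from genome-wide averages, never zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BiallelicMatrix, CallSet


@dataclass
class GenomeWindows:
    """Non-overlapping half-open tiles [start, end) per chromosome (0-based bp)."""

    table: pd.DataFrame  # columns: chrom, start, end

    @property
    def n(self) -> int:
        return len(self.table)

    def __iter__(self):
        return self.table.itertuples(index=False)


def make_windows(chrom_lengths: dict[str, int], width: int = 5_000_000) -> GenomeWindows:
    """Tile each chromosome into width-bp windows; the last may be shorter."""
    if width <= 0:
        raise ValueError("window width must be positive")
    rows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
        for start in range(0, int(length), width):
            rows.append((chrom, start, min(start + width, int(length))))
    return GenomeWindows(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def _window_index(windows: GenomeWindows, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Window row index for each (chrom, 1-based pos); -1 if outside every window."""
    out = np.full(len(pos), -1, dtype=np.int64)
    tbl = windows.table
    for c in np.unique(chrom):
        rows = tbl.index[tbl["chrom"] == c].to_numpy()
        if rows.size == 0:
            continue
        starts = tbl.loc[rows, "start"].to_numpy()
        ends = tbl.loc[rows, "end"].to_numpy()
        sel = chrom == c
        p0 = pos[sel] - 1  # 0-based coordinate of the site
        k = np.searchsorted(starts, p0, side="right") - 1
        ok = (k >= 0) & (p0 < ends[np.clip(k, 0, len(rows) - 1)])
        res = np.where(ok, rows[np.clip(k, 0, len(rows) - 1)], -1)
        out[sel] = res
    return out


def snp_density(calls: CallSet, windows: GenomeWindows) -> pd.DataFrame:
    """Count of call positions per window; every call must fall inside a window."""
    tbl = windows.table.copy()
    if len(calls) == 0:
        tbl["snp_count"] = 0
        return tbl
    rec = calls.records
    idx = _window_index(windows, rec["chrom"].to_numpy(), rec["pos"].to_numpy(dtype=np.int64))
    if (idx < 0).any():
        bad = rec.iloc[int(np.flatnonzero(idx < 0)[0])]
        raise ValueError(
            f"call at {bad['chrom']}:{bad['pos']} lies beyond the chromosome windows"
        )
    counts = np.bincount(idx, minlength=windows.n)
    tbl["snp_count"] = counts
    return tbl


def _group_rows(matrix: BiallelicMatrix, group: list[str]) -> np.ndarray:
    missing = [a for a in group if a not in matrix.accessions]
    if missing:
        raise ValueError(f"accessions not in the matrix: {missing}")
    return np.array([matrix.accessions.index(a) for a in group])


def haplotype_diversity(matrix: BiallelicMatrix, group: list[str], windows: GenomeWindows) -> pd.DataFrame:
    """Nei's haplotype diversity per window for one group of accessions.

    Windows containing no sites get NaN; windows whose sites are
    monomorphic in the group get 0 (a single haplotype).
    """
    rows = _group_rows(matrix, group)
    n = len(rows)
    if n < 2:
        raise ValueError("haplotype diversity needs at least two accessions")
    idx = _window_index(windows, matrix.sites["chrom"].to_numpy(), matrix.sites["pos"].to_numpy(dtype=np.int64))
    out = windows.table.copy()
    hd = np.full(windows.n, np.nan)
    G = matrix.genotypes[rows]
    for w in range(windows.n):
        sites = np.flatnonzero(idx == w)
        if sites.size == 0:
            continue
        haplotypes = [tuple(row) for row in G[:, sites]]
        _, counts = np.unique(np.array(haplotypes, dtype=np.int8), axis=0, return_counts=True)
        freqs = counts / n
        hd[w] = (n / (n - 1)) * (1.0 - np.sum(freqs**2))
    out["hd"] = hd
    return out


def _pairwise_diff_sums(G: np.ndarray, rows_a: np.ndarray, rows_b: np.ndarray, within: bool) -> tuple[float, int]:
    """Sum over pairs of per-pair difference counts, and the number of pairs."""
    A = G[rows_a].astype(np.int64)
    B = G[rows_b].astype(np.int64)
    if within:
        n = len(rows_a)
        ca = A.sum(axis=0)
        # per-site count of differing pairs: ones * zeros
        diff = float((ca * (n - ca)).sum())
        return diff, n * (n - 1) // 2
    ca, cb = A.sum(axis=0), B.sum(axis=0)
    na, nb = len(rows_a), len(rows_b)
    diff = float((ca * (nb - cb) + cb * (na - ca)).sum())
    return diff, na * nb


def pairwise_fst(
    matrix: BiallelicMatrix,
    group_a: list[str],
    group_b: list[str],
    windows: GenomeWindows,
) -> tuple[pd.DataFrame, float]:
    """Hudson's F_ST = 1 - Hw/Hb per window, and the genome-wide mean.

    Hw averages the two within-group mean pairwise difference counts;
    Hb is the between-group mean pairwise difference count; both sum
    over the window's sites. Estimates are clamped to [0, 1]; windows
    with Hb = 0 (or no sites) are NaN and excluded from the mean.
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    rows_a = _group_rows(matrix, group_a)
    rows_b = _group_rows(matrix, group_b)
    if len(rows_a) < 2 or len(rows_b) < 2:
        raise ValueError("both groups need at least two accessions")
    idx = _window_index(windows, matrix.sites["chrom"].to_numpy(), matrix.sites["pos"].to_numpy(dtype=np.int64))
    out = windows.table.copy()
    fst = np.full(windows.n, np.nan)
    for w in range(windows.n):
        sites = np.flatnonzero(idx == w)
        if sites.size == 0:
            continue
        G = matrix.genotypes[:, sites]
        da, na_pairs = _pairwise_diff_sums(G, rows_a, rows_a, within=True)
        db, nb_pairs = _pairwise_diff_sums(G, rows_b, rows_b, within=True)
        dab, nab_pairs = _pairwise_diff_sums(G, rows_a, rows_b, within=False)
        hw = 0.5 * (da / na_pairs + db / nb_pairs)
        hb = dab / nab_pairs
        if hb == 0.0:
            continue
        fst[w] = min(max(1.0 - hw / hb, 0.0), 1.0)
    out["fst"] = fst
    genome_wide = float(np.nanmean(fst)) if np.isfinite(fst).any() else float("nan")
    return out, genome_wide


def group_summary(
    matrix: BiallelicMatrix,
    groups: dict[str, list[str]],
    windows: GenomeWindows,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group mean Hd and per-pair genome-wide F_ST (layout of a diversity summary table)."""
    hd_rows = []
    for name, members in groups.items():
        hd = haplotype_diversity(matrix, members, windows)["hd"]
        hd_rows.append({"group": name, "mean_hd": float(np.nanmean(hd.to_numpy()))})
    fst_rows = []
    names = list(groups)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            _, gw = pairwise_fst(matrix, groups[names[i]], groups[names[j]], windows)
            fst_rows.append({"group_a": names[i], "group_b": names[j], "fst": gw})
    return pd.DataFrame(hd_rows), pd.DataFrame(fst_rows)
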