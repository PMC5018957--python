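"""Linkage disequilibrium: r2 / D', distance-binned decay, Gabriel blocks.

Accessions are inbred, so haplotypes are observed directly: no phasing
is needed. For a site pair with haplotype frequency p_AB and allele
frequencies p_A, p_B (of the alternative alleles), D = p_AB - p_A p_B,
r2 = D^2 / (p_A(1-p_A) p_B(1-p_B)) and D' = |D| / D_max with D_max the
usual bound given the sign of D. Block detection follows the Gabriel et
al. confidence-interval rule as implemented in Haploview's GAB output:
a two-sided 90% CI on D' is obtained by normalising the multinomial
likelihood of the observed two-locus haplotype counts over a D' grid;
pairs are classed strong LD (CI lower >= 0.70 and upper >= 0.98) or
strong recombination (upper < 0.90); a candidate site range is a block
when at least 95% of its informative pairs are strong LD, and maximal
non-overlapping blocks are chosen greedily by bp span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BiallelicMatrix


def _group_matrix(matrix: BiallelicMatrix, group: list[str] | None) -> np.ndarray:
    if group is None:
        return matrix.genotypes
    missing = [a for a in group if a not in matrix.accessions]
    if missing:
        raise ValueError(f"accessions not in the matrix: {missing}")
    return matrix.genotypes[[matrix.accessions.index(a) for a in group]]


def pairwise_ld(
    matrix: BiallelicMatrix,
    group: list[str] | None = None,
    max_dist: int = 500_000,
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """r2 and D' for same-chromosome site pairs within ``max_dist`` bp.

    Sites with minor-allele frequency below ``maf_min`` in the group are
    excluded; monomorphic pairs are undefined and skipped. Returns a
    DataFrame with columns chrom, i, j (site indices into the matrix),
    dist, r2, dprime.
    """
    G = _group_matrix(matrix, group)
    if G.shape[0] < 4:
        raise ValueError("LD needs at least four accessions")
    n = G.shape[0]
    freq = G.mean(axis=0)
    usable = np.minimum(freq, 1.0 - freq) >= maf_min
    rows = []
    for chrom, site_idx in matrix.sites.groupby("chrom", sort=False).groups.items():
        site_idx = np.asarray(site_idx)
        site_idx = site_idx[usable[site_idx]]
        if site_idx.size < 2:
            continue
        pos = matrix.sites.loc[site_idx, "pos"].to_numpy(dtype=np.int64)
        H = G[:, site_idx].astype(np.float64)
        p = H.mean(axis=0)
        pab = (H.T @ H) / n  # joint alt-alt haplotype frequency
        D = pab - np.outer(p, p)
        denom = np.outer(p * (1 - p), p * (1 - p))
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(denom > 0, D**2 / denom, np.nan)
        # D_max depends on the sign of D
        pa = p[:, None]
        pb = p[None, :]
        dmax = np.where(
            D >= 0,
            np.minimum(pa * (1 - pb), (1 - pa) * pb),
            np.minimum(pa * pb, (1 - pa) * (1 - pb)),
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            dprime = np.where(dmax > 0, np.abs(D) / dmax, np.nan)
        m = site_idx.size
        iu, ju = np.triu_indices(m, k=1)
        dist = pos[ju] - pos[iu]
        keep = (dist > 0) & (dist <= max_dist) & np.isfinite(r2[iu, ju])
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "i": site_idx[iu[keep]],
                    "j": site_idx[ju[keep]],
                    "dist": dist[keep],
                    "r2": np.clip(r2[iu, ju][keep], 0.0, 1.0),
                    "dprime": np.clip(dprime[iu, ju][keep], 0.0, 1.0),
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["chrom", "i", "j", "dist", "r2", "dprime"])
    return pd.concat(rows, ignore_index=True)


def ld_decay(pairs: pd.DataFrame, bin_width: int = 1000) -> tuple[pd.DataFrame, float | None]:
    """Distance-binned mean r2 and the half-decay distance.

    Pairs are binned by physical distance (bin k covers
    [k*bin_width, (k+1)*bin_width)); the half-decay distance is the
    midpoint of the first non-empty bin whose mean r2 falls to half of
    the first non-empty bin's mean, or None if never reached.
    """
    if pairs.empty:
        raise ValueError("no pairs to bin")
    k = (pairs["dist"].to_numpy(dtype=np.int64)) // bin_width
    df = pd.DataFrame({"bin": k, "r2": pairs["r2"].to_numpy()})
    agg = df.groupby("bin").agg(mean_r2=("r2", "mean"), n_pairs=("r2", "size")).reset_index()
    agg["bin_mid"] = (agg["bin"] * bin_width + bin_width / 2).astype(float)
    agg = agg.sort_values("bin").reset_index(drop=True)[["bin_mid", "mean_r2", "n_pairs"]]
    target = agg.loc[0, "mean_r2"] / 2.0
    half = None
    for row in agg.itertuples(index=False):
        if row.mean_r2 <= target:
            half = float(row.bin_mid)
            break
    return agg, half


# ---------------------------------------------------------------- Gabriel blocks

_DPRIME_GRID = np.linspace(0.0, 1.0, 1001)


def dprime_confidence_interval(h11: int, h10: int, h01: int, h00: int, conf: float = 0.90) -> tuple[float, float]:
    """Two-sided CI on |D'| by likelihood normalisation over a D' grid.

    The observed two-locus haplotype counts (alt-alt, alt-ref, ref-alt,
    ref-ref) are scored under each grid value of D' (allele frequencies
    fixed at their MLEs, D taking the sign of the observed D); the
    likelihood is normalised over the grid and the central ``conf`` mass
    determines the interval.
    """
    n = h11 + h10 + h01 + h00
    if n == 0:
        raise ValueError("no haplotypes observed")
    pa = (h11 + h10) / n
    pb = (h11 + h01) / n
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("monomorphic site: D' undefined")
    d_obs = h11 / n - pa * pb
    if d_obs >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
        sign = 1.0
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
        sign = -1.0
    counts = np.array([h11, h10, h01, h00], dtype=float)
    d_grid = sign * _DPRIME_GRID * dmax
    f11 = np.clip(pa * pb + d_grid, 1e-12, 1.0)
    f10 = np.clip(pa - f11, 1e-12, 1.0)
    f01 = np.clip(pb - f11, 1e-12, 1.0)
    f00 = np.clip(1.0 - pa - pb + f11, 1e-12, 1.0)
    loglik = (
        counts[0] * np.log(f11)
        + counts[1] * np.log(f10)
        + counts[2] * np.log(f01)
        + counts[3] * np.log(f00)
    )
    lik = np.exp(loglik - loglik.max())
    post = np.cumsum(lik)
    post /= post[-1]
    tail = (1.0 - conf) / 2.0
    lo = _DPRIME_GRID[int(np.searchsorted(post, tail))]
    hi = _DPRIME_GRID[min(int(np.searchsorted(post, 1.0 - tail)), len(_DPRIME_GRID) - 1)]
    return float(lo), float(hi)


@dataclass
class LDBlock:
    chrom: str
    start_index: int  # first site index (into matrix.sites)
    end_index: int  # last site index, inclusive
    start_bp: int  # 1-based position of the first site
    end_bp: int  # 1-based position of the last site
    n_sites: int

    @property
    def span(self) -> int:
        return self.end_bp - self.start_bp


def ld_blocks(
    matrix: BiallelicMatrix,
    group: list[str] | None = None,
    max_dist: int = 500_000,
    maf_min: float = 0.05,
    ci_strong: tuple[float, float] = (0.70, 0.98),
    ci_recomb_high: float = 0.90,
    min_strong_frac: float = 0.95,
    min_span_bp: int = 0,
) -> list[LDBlock]:
    """Gabriel confidence-interval LD blocks, non-overlapping, longest first.

    A pair is informative when its D' CI classifies it as strong LD
    (lower >= ci_strong[0], upper >= ci_strong[1]) or strong
    recombination (upper < ci_recomb_high); inconclusive pairs do not
    count. A site range [i..j] is a candidate block when it has at least
    one informative pair, all within ``max_dist``, and the strong-LD
    fraction among informative pairs is >= min_strong_frac. Blocks below
    ``min_span_bp`` are filtered from the output.
    """
    G = _group_matrix(matrix, group)
    if G.shape[0] < 4:
        raise ValueError("LD block detection needs at least four accessions")
    n = G.shape[0]
    freq = G.mean(axis=0)
    blocks: list[LDBlock] = []
    for chrom, site_idx in matrix.sites.groupby("chrom", sort=False).groups.items():
        site_idx = np.asarray(site_idx)
        ok = np.minimum(freq[site_idx], 1.0 - freq[site_idx]) >= maf_min
        site_idx = site_idx[ok]
        m = site_idx.size
        if m < 2:
            continue
        pos = matrix.sites.loc[site_idx, "pos"].to_numpy(dtype=np.int64)
        H = G[:, site_idx]
        strong = np.zeros((m, m), dtype=np.int64)
        informative = np.zeros((m, m), dtype=np.int64)
        for a in range(m):
            for b in range(a + 1, m):
                if pos[b] - pos[a] > max_dist:
                    break
                h11 = int(np.sum((H[:, a] == 1) & (H[:, b] == 1)))
                h10 = int(np.sum((H[:, a] == 1) & (H[:, b] == 0)))
                h01 = int(np.sum((H[:, a] == 0) & (H[:, b] == 1)))
                h00 = n - h11 - h10 - h01
                try:
                    lo, hi = dprime_confidence_interval(h11, h10, h01, h00)
                except ValueError:
                    continue
                if lo >= ci_strong[0] and hi >= ci_strong[1]:
                    strong[a, b] = strong[b, a] = 1
                    informative[a, b] = informative[b, a] = 1
                elif hi < ci_recomb_high:
                    informative[a, b] = informative[b, a] = 1
        cs = strong.cumsum(axis=0).cumsum(axis=1)
        ci = informative.cumsum(axis=0).cumsum(axis=1)

        def pairs_in(mat_cs: np.ndarray, a: int, b: int) -> int:
            total = mat_cs[b, b]
            if a > 0:
                total -= mat_cs[a - 1, b] + mat_cs[b, a - 1] - mat_cs[a - 1, a - 1]
            return int(total) // 2  # symmetric matrix, zero diagonal

        candidates = []
        for a in range(m):
            for b in range(a + 1, m):
                if pos[b] - pos[a] > max_dist:
                    break
                n_inf = pairs_in(ci, a, b)
                if n_inf == 0:
                    continue
                n_str = pairs_in(cs, a, b)
                if n_str / n_inf >= min_strong_frac:
                    candidates.append((a, b))
        candidates.sort(key=lambda ab: (-(pos[ab[1]] - pos[ab[0]]), ab[0]))
        taken = np.zeros(m, dtype=bool)
        for a, b in candidates:
            if taken[a : b + 1].any():
                continue
            taken[a : b + 1] = True
            blocks.append(
                LDBlock(
                    chrom=str(chrom),
                    start_index=int(site_idx[a]),
                    end_index=int(site_idx[b]),
                    start_bp=int(pos[a]),
                    end_bp=int(pos[b]),
                    n_sites=b - a + 1,
                )
            )
    blocks = [bl for bl in blocks if bl.span >= min_span_bp]
    blocks.sort(key=lambda bl: (bl.chrom, bl.start_bp))
    return blocks


def blocks_to_bed(blocks: list[LDBlock]) -> pd.DataFrame:
    """BED-style table (0-based half-open) of detected blocks."""
    return pd.DataFrame(
        {
            "chrom": [b.chrom for b in blocks],
            "start": [b.start_bp - 1 for b in blocks],
            "end": [b.end_bp for b in blocks],
            "n_sites": [b.n_sites for b in blocks],
        }
    )
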