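"""Missing-data-free bi-allelic genotype matrix across the panel.

Candidate sites are the union of all accessions' consensus SNP
positions. A site enters the matrix iff (i) at least one accession
carries a call there (true for any union member), (ii) read depth at the
position is >= min_depth in every accession, and (iii) alleles other
than the site's majority alternative are carried by fewer than
max_third_allele_frac of all accessions. Covered-but-uncalled accessions
are genotyped as the reference allele — criterion (ii) guarantees
coverage, which is what makes a dense, missing-data-free matrix
attainable. Minority third-allele carriers are recoded to reference by
default (configurable to site exclusion), and the reference accession
itself is included as an all-zero row.
"""

from __future__ import annotations

import logging
from collections import Counter

import numpy as np
import pandas as pd

from .core import BiallelicMatrix, CallSet, DepthTrack

log = logging.getLogger(__name__)


def build_biallelic_matrix(
    consensus: dict[str, CallSet],
    depths: dict[str, DepthTrack],
    reference_name: str = "reference",
    min_depth: int = 5,
    max_third_allele_frac: float = 0.10,
    recode_third_allele: bool = True,
) -> BiallelicMatrix:
    """Assemble the accessions x sites 0/1 matrix from per-accession consensus calls.

    ``consensus`` maps accession name to its three-caller consensus
    CallSet; ``depths`` must provide a DepthTrack for every accession.
    The reference accession contributes an all-reference row and counts
    toward the third-allele denominator. With
    ``recode_third_allele=False`` sites with any minority-allele carrier
    below the tolerance are excluded instead of recoded.
    """
    missing = sorted(set(consensus) - set(depths))
    if missing:
        raise ValueError(f"no depth track for accession(s): {missing}")
    panel = sorted(consensus)
    accessions = panel + [reference_name]
    n_all = len(accessions)  # denominator of criterion (iii) includes the reference row

    # calls per (chrom, pos): {accession: (ref, alt)}
    calls_at: dict[tuple[str, int], dict[str, tuple[str, str]]] = {}
    for acc in panel:
        for row in consensus[acc].records.itertuples(index=False):
            calls_at.setdefault((row.chrom, int(row.pos)), {})[acc] = (row.ref, row.alt)

    kept_rows, geno_cols = [], []
    n_depth_fail = n_third_fail = 0
    for (chrom, pos) in sorted(calls_at):
        site_calls = calls_at[(chrom, pos)]
        # criterion (ii): every panel accession covered >= min_depth
        if any(depths[acc].at(chrom, pos) < min_depth for acc in panel):
            n_depth_fail += 1
            continue
        alt_counts = Counter(alt for _, alt in site_calls.values())
        top = max(alt_counts.values())
        site_alt = min(a for a, n in alt_counts.items() if n == top)  # ties: A<C<G<T
        ref = next(iter(site_calls.values()))[0]
        third_carriers = [acc for acc, (_, alt) in site_calls.items() if alt != site_alt]
        if len(third_carriers) / n_all >= max_third_allele_frac:
            n_third_fail += 1
            continue
        if third_carriers and not recode_third_allele:
            n_third_fail += 1
            continue
        g = np.zeros(n_all, dtype=np.int8)
        for i, acc in enumerate(panel):
            called = site_calls.get(acc)
            g[i] = 1 if (called is not None and called[1] == site_alt) else 0
        kept_rows.append((chrom, pos, ref, site_alt))
        geno_cols.append(g)

    if not kept_rows:
        log.warning("no site passed the bi-allelic criteria; returning an empty matrix")
        sites = pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])
        return BiallelicMatrix(accessions, sites, np.zeros((n_all, 0), dtype=np.int8))
    log.info(
        "bi-allelic matrix: %d sites kept, %d failed depth criterion, %d failed third-allele criterion",
        len(kept_rows), n_depth_fail, n_third_fail,
    )
    sites = pd.DataFrame(kept_rows, columns=["chrom", "pos", "ref", "alt"])
    genotypes = np.stack(geno_cols, axis=1)
    return BiallelicMatrix(accessions, sites, genotypes)


def pairwise_identity(matrix: BiallelicMatrix) -> pd.DataFrame:
    """Proportion of bi-allelic sites at which two accessions agree.

    Returns a symmetric accessions x accessions DataFrame with unit
    diagonal; entry (a, b) is |{sites: G[a] = G[b]}| / n_sites.
    """
    if matrix.n_sites == 0:
        raise ValueError("pairwise identity is undefined on an empty matrix")
    G = matrix.genotypes.astype(np.int16)
    diff = _pairwise_difference_counts(G)
    ident = 1.0 - diff / matrix.n_sites
    return pd.DataFrame(ident, index=matrix.accessions, columns=matrix.accessions)


def _pairwise_difference_counts(G: np.ndarray) -> np.ndarray:
    """Accession x accession count of differing sites for a 0/1 matrix."""
    ones = G @ G.T  # sites where both carry alt
    tot = G.sum(axis=1)
    # differing sites = |a| + |b| - 2*(both alt)
    return tot[:, None] + tot[None, :] - 2 * ones
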