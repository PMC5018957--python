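"""Shared containers for call sets, depth tracks and genotype matrices.

The panel is assumed to consist of fully inbred accessions, so every
genotype is effectively haploid: a site carries either the reference
allele (0) or a single alternative allele (1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CALL_COLUMNS = ["chrom", "pos", "ref", "alt", "alt_reads", "depth"]


def _empty_calls() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "ref": pd.Series(dtype=str),
            "alt": pd.Series(dtype=str),
            "alt_reads": pd.Series(dtype=np.int64),
            "depth": pd.Series(dtype=np.int64),
        }
    )


@dataclass
class CallSet:
    """SNP calls of one caller (or a consensus) for one accession.

    ``records`` is a DataFrame with columns chrom, pos (1-based), ref, alt
    (single bases), alt_reads and depth. Indels/MNPs never enter a CallSet;
    they are dropped at parse time.
    """

    accession: str
    caller: str
    records: pd.DataFrame = field(default_factory=_empty_calls)

    def __post_init__(self) -> None:
        if list(self.records.columns) != CALL_COLUMNS:
            self.records = self.records.loc[:, CALL_COLUMNS]
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def keys(self) -> set[tuple[str, int, str, str]]:
        """(chrom, pos, ref, alt) tuples — the identity used for intersections."""
        r = self.records
        return set(zip(r["chrom"], r["pos"].astype(int), r["ref"], r["alt"]))

    def positions(self) -> set[tuple[str, int]]:
        r = self.records
        return set(zip(r["chrom"], r["pos"].astype(int)))

    def sorted(self) -> "CallSet":
        rec = self.records.sort_values(["chrom", "pos", "alt"], kind="mergesort")
        return CallSet(self.accession, self.caller, rec.reset_index(drop=True))


@dataclass
class DepthTrack:
    """Per-base read depth for one accession over the reference.

    ``depth`` maps chromosome name to a dense int32 array where index i
    holds the depth at 1-based position i+1. Positions outside any array
    (or outside the chromosome) report depth 0, i.e. uncovered.
    """

    accession: str
    depth: dict[str, np.ndarray]

    def at(self, chrom: str, pos: int) -> int:
        arr = self.depth.get(chrom)
        if arr is None or not (1 <= pos <= len(arr)):
            return 0
        return int(arr[pos - 1])

    def at_many(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        arr = self.depth.get(chrom)
        positions = np.asarray(positions, dtype=np.int64)
        out = np.zeros(len(positions), dtype=np.int64)
        if arr is None:
            return out
        ok = (positions >= 1) & (positions <= len(arr))
        out[ok] = arr[positions[ok] - 1]
        return out

    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.depth.items()}


@dataclass
class BiallelicMatrix:
    """Dense accessions x sites genotype matrix with no missing entries.

    ``genotypes`` entries are 0 (reference allele) or 1 (site alternative
    allele). ``sites`` has columns chrom, pos, ref, alt sorted by
    (chrom, pos); the reference accession, when present, is an all-zero row.
    """

    accessions: list[str]
    sites: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.accessions), len(self.sites)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.accessions)} accessions x {len(self.sites)} sites"
            )
        if len(self.sites) and not set(np.unique(self.genotypes)) <= {0, 1}:
            raise ValueError("genotypes must be binary (0 = ref, 1 = alt)")

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def row(self, accession: str) -> np.ndarray:
        return self.genotypes[self.accessions.index(accession)]

    def subset(self, accessions: list[str]) -> "BiallelicMatrix":
        idx = [self.accessions.index(a) for a in accessions]
        return BiallelicMatrix(list(accessions), self.sites, self.genotypes[idx])

    def site_mask(self, mask: np.ndarray) -> "BiallelicMatrix":
        return BiallelicMatrix(
            list(self.accessions),
            self.sites.loc[mask].reset_index(drop=True),
            self.genotypes[:, np.asarray(mask)],
        )
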