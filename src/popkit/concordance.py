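"""Concordance classification of RNA-seq consensus SNPs against exome calls.

Each RNA-seq consensus SNP of an accession is assigned to exactly one of
five disjoint categories, evaluated in precedence order:

identical_A   same (chrom, pos, alt) in the exome three-caller consensus
identical_B   same allele passing the filter in one or two exome callers
              (but not the full consensus)
identical_C   same allele present only in the raw (pre-filter) exome calls
different_call a raw exome call exists at the position with another alt
rnaseq_only   no exome call at the position at all

The precedence enforces disjointness, so the counts always partition the
input and the proportions sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core import CallSet

CATEGORIES = ("identical_A", "identical_B", "identical_C", "different_call", "rnaseq_only")


@dataclass
class ConcordanceResult:
    """Counts and proportions over the five concordance categories."""

    counts: dict[str, int]
    total: int
    proportions: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        if set(self.counts) != set(CATEGORIES):
            raise ValueError(f"counts must cover exactly {CATEGORIES}")
        if sum(self.counts.values()) != self.total:
            raise ValueError("category counts do not sum to the total")
        denom = self.total if self.total else 1
        self.proportions = {k: self.counts[k] / denom for k in CATEGORIES}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": list(CATEGORIES),
                "count": [self.counts[k] for k in CATEGORIES],
                "proportion": [self.proportions[k] for k in CATEGORIES],
            }
        )


def classify_concordance(
    rnaseq_consensus: CallSet,
    exome_consensus: CallSet,
    exome_filtered_by_caller: tuple[CallSet, CallSet, CallSet],
    exome_raw_union: CallSet,
) -> ConcordanceResult:
    """Assign every RNA-seq consensus SNP to its first matching category.

    All inputs must belong to the same accession. ``exome_raw_union`` is
    the union of the three exome callers' unfiltered calls. A reference
    allele that differs between the two technologies at a shared
    position indicates mismatched references and raises.
    """
    accs = {
        rnaseq_consensus.accession,
        exome_consensus.accession,
        exome_raw_union.accession,
        *(cs.accession for cs in exome_filtered_by_caller),
    }
    if len(accs) != 1:
        raise ValueError(f"inputs belong to different accessions: {sorted(accs)}")
    if len(exome_filtered_by_caller) != 3:
        raise ValueError("exactly three filtered exome call sets are required")

    cons_keys = {(c, p, a) for c, p, _, a in exome_consensus.keys()}
    caller_keys = [{(c, p, a) for c, p, _, a in cs.keys()} for cs in exome_filtered_by_caller]
    raw_keys = {(c, p, a) for c, p, _, a in exome_raw_union.keys()}
    raw_positions = exome_raw_union.positions()

    ref_at: dict[tuple[str, int], str] = {}
    for cs in (exome_consensus, *exome_filtered_by_caller, exome_raw_union):
        for chrom, pos, ref, _ in cs.keys():
            ref_at.setdefault((chrom, pos), ref)

    counts = dict.fromkeys(CATEGORIES, 0)
    for chrom, pos, ref, alt in rnaseq_consensus.keys():
        exome_ref = ref_at.get((chrom, pos))
        if exome_ref is not None and exome_ref != ref:
            raise ValueError(
                f"reference allele mismatch at {chrom}:{pos}: RNA-seq says {ref}, exome says {exome_ref}"
            )
        key = (chrom, pos, alt)
        n_callers = sum(key in ck for ck in caller_keys)
        if key in cons_keys:
            counts["identical_A"] += 1
        elif 1 <= n_callers <= 2:
            counts["identical_B"] += 1
        elif key in raw_keys:
            counts["identical_C"] += 1
        elif (chrom, pos) in raw_positions:
            counts["different_call"] += 1
        else:
            counts["rnaseq_only"] += 1
    return ConcordanceResult(counts, len(rnaseq_consensus.keys()))
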