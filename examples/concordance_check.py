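"""Classify one accession's RNA-seq consensus SNPs against an exome-style
re-sequencing of the same truth.

Categories: identical_A (in the exome three-caller consensus),
identical_B (passing the filter in one or two exome callers),
identical_C (present only in raw exome calls), different_call (another
allele at the position), rnaseq_only (no exome call there). The five
proportions always sum to 1.
"""

import pandas as pd

import popkit as pk

model = pk.PopulationModel(
    chromosome_lengths=(400_000,),
    n_sites=400,
    groups=(pk.GroupSpec("a", 4, 0.3), pk.GroupSpec("b", 4, 0.3)),
    admixed=(),
    seed=7,
)
truth = pk.simulate_populations(model)
rna = pk.simulate_caller_outputs(truth, pk.DEFAULT_PROFILES, seed=8)
exome = pk.simulate_caller_outputs(truth, pk.DEFAULT_PROFILES, seed=9)

acc = truth.accessions[0]
rna_consensus, _ = pk.consensus_for_accession(*rna[acc])
ex_callers, ex_track = exome[acc]
ex_filtered = tuple(pk.filter_homozygous(cs, ex_track)[0] for cs in ex_callers.values())
ex_consensus = pk.intersect_callers(*ex_filtered)
raw = pd.concat([cs.records for cs in ex_callers.values()]).drop_duplicates(
    ["chrom", "pos", "ref", "alt"]
)
ex_raw = pk.CallSet(acc, "raw_union", raw.reset_index(drop=True))

result = pk.classify_concordance(rna_consensus, ex_consensus, ex_filtered, ex_raw)
print(result.to_frame().to_string(index=False))
print(
    f"\n{result.total} RNA-seq consensus SNPs classified; a high identical_A "
    "share means the two technologies call the same homozygous variants."
)
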